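"""Numba-compiled core: change statistics and the Metropolis tie-toggle chain.

State is carried as four arrays updated in lockstep:

* ``y``   — (n, n) int8 arc matrix,
* ``TP``  — (n, n) int32 directed two-path counts, ``TP[i, j] = #{k: y_ik y_kj}``,
* ``din``/``dout`` — int32 degree vectors.

Every effect term is encoded by an integer code plus, for dyad-independent
terms, a precomputed (n, n) matrix of change statistics:

==== ==========================================================
code meaning
==== ==========================================================
0    dyadic: change statistic is the fixed matrix entry D[t, i, j]
1    reciprocity
2    alternating in-star (popularity spread), smoothing lams[t]
3    alternating out-star (activity spread)
4    alternating path closure (transitive closure of an arc)
5    alternating multiple two-paths
==== ==========================================================

``delta_add`` returns z(y + ij) - z(y - ij) evaluated on a state *without*
the arc; removals negate it.  The same compiled function backs both the
public change-statistic API and the sampler, so there is a single
implementation to validate against full recounts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CODE_DYADIC = 0
CODE_RECIP = 1
CODE_AINS = 2
CODE_AOUTS = 3
CODE_ATA = 4
CODE_A2PA = 5


@njit(cache=True)
def delta_add(y, TP, din, dout, D, codes, lams, i, j, out):  # pragma: no cover - jit
    n = y.shape[0]
    for t in range(codes.size):
        c = codes[t]
        if c == 0:
            out[t] = D[t, i, j]
        elif c == 1:
            out[t] = y[j, i]
        elif c == 2:
            lam = lams[t]
            r = 1.0 - 1.0 / lam
            out[t] = lam * (1.0 - r ** din[j])
        elif c == 3:
            lam = lams[t]
            r = 1.0 - 1.0 / lam
            out[t] = lam * (1.0 - r ** dout[i])
        elif c == 4:
            lam = lams[t]
            r = 1.0 - 1.0 / lam
            s = lam * (1.0 - r ** TP[i, j])
            for b in range(n):
                if y[i, b] == 1 and y[j, b] == 1:
                    s += r ** TP[i, b]
                if y[b, j] == 1 and y[b, i] == 1:
                    s += r ** TP[b, j]
            out[t] = s
        else:
            lam = lams[t]
            r = 1.0 - 1.0 / lam
            s = 0.0
            for b in range(n):
                if b != i and y[j, b] == 1:
                    s += r ** TP[i, b]
                if b != j and y[b, i] == 1:
                    s += r ** TP[b, j]
            out[t] = s


@njit(cache=True)
def _apply_add(y, TP, din, dout, i, j):  # pragma: no cover - jit
    n = y.shape[0]
    for b in range(n):
        TP[i, b] += y[j, b]
        TP[b, j] += y[b, i]
    y[i, j] = 1
    dout[i] += 1
    din[j] += 1


@njit(cache=True)
def _apply_remove(y, TP, din, dout, i, j):  # pragma: no cover - jit
    n = y.shape[0]
    y[i, j] = 0
    dout[i] -= 1
    din[j] -= 1
    for b in range(n):
        TP[i, b] -= y[j, b]
        TP[b, j] -= y[b, i]


@njit(cache=True)
def run_chain(y, TP, din, dout, D, codes, lams, theta, senders, max_out,
              respect_cap, si, jo, uu, record, bits, code0):  # pragma: no cover - jit
    """Advance the single-dyad-toggle Metropolis chain by ``si.size`` steps.

    ``si`` indexes into ``senders`` (uniform respondent pick), ``jo`` is the
    receiver offset in [0, n-2], ``uu`` the acceptance uniforms.  Proposals
    that would push a respondent's out-degree past ``max_out`` are rejected
    when ``respect_cap`` is set (Metropolis on the constrained space).

    When ``record`` is non-empty, the visited free-dyad bit code (bit
    positions from ``bits``) is written after every step — used by the
    exact-enumeration oracle on desk-scale state spaces.

    Returns ``(accepted_moves, final_code)``.
    """
    k = theta.size
    dz = np.empty(k)
    acc = 0
    code = code0
    do_rec = record.size > 0
    for t in range(si.size):
        i = senders[si[t]]
        j = jo[t]
        if j >= i:
            j += 1
        if y[i, j] == 0:
            if not (respect_cap and dout[i] >= max_out):
                delta_add(y, TP, din, dout, D, codes, lams, i, j, dz)
                lp = 0.0
                for q in range(k):
                    lp += theta[q] * dz[q]
                if lp >= 0.0 or uu[t] < np.exp(lp):
                    _apply_add(y, TP, din, dout, i, j)
                    acc += 1
                    if do_rec:
                        code ^= np.int64(1) << bits[i, j]
        else:
            _apply_remove(y, TP, din, dout, i, j)
            delta_add(y, TP, din, dout, D, codes, lams, i, j, dz)
            lp = 0.0
            for q in range(k):
                lp -= theta[q] * dz[q]
            if lp >= 0.0 or uu[t] < np.exp(lp):
                acc += 1
                if do_rec:
                    code ^= np.int64(1) << bits[i, j]
            else:
                _apply_add(y, TP, din, dout, i, j)
        if do_rec:
            record[t] = code
    return acc, code
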