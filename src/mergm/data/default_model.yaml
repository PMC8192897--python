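# Default per-school model: the full 26-effect specification used in reporting.
# Alternating statistics use smoothing lambda = 2; estimation is conditioned on
# the survey's out-degree cap of six nominations.
condition_max_out: true
terms:
- {name: ArcA}
- {name: ReciprocityA}
- {name: AinSA, lambda: 2.0}
- {name: AoutSA, lambda: 2.0}
- {name: ATA-T, lambda: 2.0}
- {name: A2PA-T, lambda: 2.0}
- {name: Sender, attribute: gender}
- {name: Receiver, attribute: gender}
- {name: Interaction, attribute: gender}
- {name: Sender, attribute: ps}
- {name: Receiver, attribute: ps}
- {name: Sender, attribute: knowledge}
- {name: Receiver, attribute: knowledge}
- {name: Difference, attribute: knowledge}
- {name: Sender, attribute: norms}
- {name: Receiver, attribute: norms}
- {name: Difference, attribute: norms}
- {name: Sender, attribute: talking}
- {name: Receiver, attribute: talking}
- {name: Difference, attribute: talking}
- {name: PSTalkingSender}
- {name: PSTalkingReceiver}
- {name: In2StarAX}
- {name: Out2StarAX}
- {name: TXAXarc}
- {name: L3XAX}
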