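school,effect,parameter,stderr,significant
School1,ArcA,-3.681,0.412,1
School2,ArcA,-3.211,0.536,1
School3,ArcA,-3.855,0.382,1
School5,ArcA,-3.973,0.413,1
School6,ArcA,-2.476,0.493,1
School1,ReciprocityA,3.103,0.247,1
School2,ReciprocityA,1.866,0.238,1
School3,ReciprocityA,2.705,0.207,1
School5,ReciprocityA,2.894,0.243,1
School6,ReciprocityA,1.926,0.24,1
School1,AinSA,-0.74,0.17,1
School2,AinSA,-0.8,0.249,1
School3,AinSA,-0.368,0.14,1
School5,AinSA,-0.47,0.179,1
School6,AinSA,-0.596,0.186,1
School1,AoutSA,0.768,0.153,1
School2,AoutSA,1.057,0.208,1
School3,AoutSA,0.789,0.182,1
School5,AoutSA,0.659,0.182,1
School6,AoutSA,0.364,0.216,0
School1,ATA-T,1.048,0.08,1
School2,ATA-T,0.975,0.08,1
School3,ATA-T,1.249,0.061,1
School5,ATA-T,1.173,0.08,1
School6,ATA-T,1.292,0.079,1
School1,A2PA-T,-0.14,0.032,1
School2,A2PA-T,-0.203,0.034,1
School3,A2PA-T,-0.145,0.023,1
School5,A2PA-T,-0.104,0.031,1
School6,A2PA-T,-0.144,0.03,1
School1,Gender-Sender,-0.761,0.19,1
School2,Gender-Sender,-1.806,0.418,1
School3,Gender-Sender,-0.73,0.141,1
School5,Gender-Sender,-0.69,0.171,1
School6,Gender-Sender,-0.474,0.166,1
School1,Gender-Receiver,-0.496,0.183,1
School2,Gender-Receiver,-1.409,0.344,1
School3,Gender-Receiver,-0.12,0.103,0
School5,Gender-Receiver,-0.419,0.167,1
School6,Gender-Receiver,-0.539,0.17,1
School1,Gender-Interaction,1.35,0.234,1
School2,Gender-Interaction,3.516,0.515,1
School3,Gender-Interaction,0.883,0.12,1
School5,Gender-Interaction,0.942,0.191,1
School6,Gender-Interaction,1.144,0.181,1
School1,PS-Sender,0.061,0.281,0
School2,PS-Sender,-0.927,0.364,1
School3,PS-Sender,1.304,0.628,1
School5,PS-Sender,-0.605,0.315,0
School6,PS-Sender,0.158,0.36,0
School1,PS-Receiver,0.292,0.316,0
School2,PS-Receiver,0.272,0.364,0
School3,PS-Receiver,-0.205,0.393,0
School5,PS-Receiver,0.824,0.267,1
School6,PS-Receiver,0.093,0.283,0
School1,Knowledge-Sender,0.109,0.049,1
School2,Knowledge-Sender,0.03,0.06,0
School3,Knowledge-Sender,-0.099,0.046,1
School5,Knowledge-Sender,0.039,0.051,0
School6,Knowledge-Sender,0.001,0.051,0
School1,Knowledge-Receiver,-0.006,0.057,0
School2,Knowledge-Receiver,-0.04,0.064,0
School3,Knowledge-Receiver,0.041,0.039,0
School5,Knowledge-Receiver,0.004,0.054,0
School6,Knowledge-Receiver,-0.007,0.044,0
School1,Knowledge-Difference,-0.025,0.042,0
School2,Knowledge-Difference,-0.032,0.055,0
School3,Knowledge-Difference,-0.091,0.025,1
School5,Knowledge-Difference,-0.111,0.038,1
School6,Knowledge-Difference,-0.128,0.028,1
School1,Norms-Sender,-0.061,0.044,0
School2,Norms-Sender,0.033,0.049,0
School3,Norms-Sender,0.035,0.046,0
School5,Norms-Sender,-0.079,0.049,0
School6,Norms-Sender,-0.052,0.051,0
School1,Norms-Receiver,0.05,0.053,0
School2,Norms-Receiver,0.049,0.053,0
School3,Norms-Receiver,-0.001,0.039,0
School5,Norms-Receiver,0.107,0.05,1
School6,Norms-Receiver,-0.017,0.043,0
School1,Norms-Difference,-0.104,0.043,1
School2,Norms-Difference,-0.065,0.044,0
School3,Norms-Difference,-0.088,0.029,1
School5,Norms-Difference,-0.061,0.04,0
School6,Norms-Difference,-0.008,0.04,0
School1,Talking-Sender,0.012,0.035,0
School2,Talking-Sender,-0.098,0.046,1
School3,Talking-Sender,0.049,0.037,0
School5,Talking-Sender,-0.134,0.045,1
School6,Talking-Sender,-0.025,0.041,0
School1,Talking-Receiver,-0.058,0.046,0
School2,Talking-Receiver,0.223,0.049,1
School3,Talking-Receiver,-0.02,0.029,0
School5,Talking-Receiver,0.151,0.047,1
School6,Talking-Receiver,0.072,0.036,1
School1,Talking-Difference,-0.069,0.028,1
School2,Talking-Difference,-0.035,0.034,0
School3,Talking-Difference,-0.073,0.02,1
School5,Talking-Difference,-0.071,0.028,1
School6,Talking-Difference,-0.07,0.028,1
School1,PS Talking-Sender,0.031,0.086,0
School2,PS Talking-Sender,0.635,0.225,1
School3,PS Talking-Sender,-0.424,0.173,1
School5,PS Talking-Sender,0.118,0.103,0
School6,PS Talking-Sender,-0.086,0.16,0
School1,PS Talking-Receiver,0.026,0.087,0
School2,PS Talking-Receiver,-0.367,0.176,1
School3,PS Talking-Receiver,0.134,0.113,0
School5,PS Talking-Receiver,-0.046,0.074,0
School6,PS Talking-Receiver,0.136,0.105,0
School1,In2StarAX,0.01,0.037,0
School2,In2StarAX,0.129,0.063,1
School3,In2StarAX,-0.009,0.068,0
School5,In2StarAX,-0.077,0.037,1
School6,In2StarAX,-0.017,0.042,0
School1,Out2StarAX,-0.028,0.032,0
School2,Out2StarAX,-0.204,0.07,1
School3,Out2StarAX,0.013,0.096,0
School5,Out2StarAX,0.045,0.038,0
School6,Out2StarAX,-0.086,0.05,0
School1,TXAXarc,0.415,0.048,1
School2,TXAXarc,0.627,0.117,1
School3,TXAXarc,0.793,0.243,1
School5,TXAXarc,0.294,0.041,1
School6,TXAXarc,0.535,0.107,1
School1,L3XAX,-0.024,0.006,1
School2,L3XAX,-0.052,0.018,1
School3,L3XAX,-0.117,0.076,0
School5,L3XAX,-0.02,0.005,1
School6,L3XAX,-0.049,0.022,1
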