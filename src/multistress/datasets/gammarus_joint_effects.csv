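design,population,temperature,prochloraz,observed_ec50,predicted_ec50,mdr_ca,mdr_ea,mdr_sam,control
mixture_toxicity,reference,16,0,66.82,,,,,1
mixture_toxicity,reference,16,1,58.20,66.82,1.15,1.15,1.00,0
mixture_toxicity,reference,16,10,45.02,66.82,1.48,1.48,1.00,0
mixture_toxicity,reference,19,0,40.32,,,,,1
mixture_toxicity,reference,19,1,31.10,40.32,1.30,1.30,1.11,0
mixture_toxicity,reference,19,10,25.41,40.32,1.59,1.59,1.11,0
mixture_toxicity,reference,22,0,38.21,,,,,1
mixture_toxicity,reference,22,1,27.96,38.21,1.37,1.36,1.19,0
mixture_toxicity,reference,22,10,24.64,38.21,1.55,1.55,1.12,0
mixture_toxicity,agricultural,16,0,145.34,,,,,1
mixture_toxicity,agricultural,16,1,175.49,145.34,0.83,0.85,0.70,0
mixture_toxicity,agricultural,16,10,117.44,145.34,1.24,1.27,0.84,0
mixture_toxicity,agricultural,19,0,75.84,,,,,1
mixture_toxicity,agricultural,19,1,67.15,75.84,1.13,1.13,0.95,0
mixture_toxicity,agricultural,19,10,60.26,75.84,1.26,1.30,0.85,0
mixture_toxicity,agricultural,22,0,50.75,,,,,1
mixture_toxicity,agricultural,22,1,33.31,50.75,1.52,1.54,1.27,0
mixture_toxicity,agricultural,22,10,36.99,50.75,1.37,1.37,0.90,0
multiple_stress,reference,16,0,66.82,,,,,1
multiple_stress,reference,19,0,40.39,66.46,1.65,1.65,1.00,0
multiple_stress,reference,19,1,31.12,66.46,2.15,2.14,1.02,0
multiple_stress,reference,19,10,25.40,66.28,2.63,2.61,1.03,0
multiple_stress,reference,22,0,38.24,66.33,1.75,1.73,1.00,0
multiple_stress,reference,22,1,27.97,66.21,2.39,2.37,0.98,0
multiple_stress,reference,22,10,24.67,66.46,2.71,2.69,0.91,0
multiple_stress,agricultural,16,0,145.34,,,,,1
multiple_stress,agricultural,19,0,75.83,148.69,1.92,1.96,0.98,0
multiple_stress,agricultural,19,1,67.06,146.61,2.17,2.19,0.89,0
multiple_stress,agricultural,19,10,60.19,152.45,2.41,2.53,0.79,0
multiple_stress,agricultural,22,0,50.70,149.65,2.87,2.95,1.24,0
multiple_stress,agricultural,22,1,36.55,150.47,3.98,4.12,1.38,0
multiple_stress,agricultural,22,10,36.27,149.65,4.01,4.13,1.10,0
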