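# Random-coil CA/CB chemical shifts (ppm, DSS-referenced) per amino acid,
# from the standard published random-coil compilation for unstructured
# peptides. dCA_dT / dCB_dT are temperature coefficients (ppm/K relative to
# 298 K); they default to 0 here and are swappable by config.
aa,CA,CB,dCA_dT,dCB_dT
A,52.5,19.1,0.0,0.0
C,58.2,28.0,0.0,0.0
D,54.2,41.1,0.0,0.0
E,56.6,29.9,0.0,0.0
F,57.7,39.6,0.0,0.0
G,45.1,,0.0,0.0
H,55.0,29.0,0.0,0.0
I,61.1,38.8,0.0,0.0
K,56.2,33.1,0.0,0.0
L,55.1,42.4,0.0,0.0
M,55.4,32.9,0.0,0.0
N,53.1,38.9,0.0,0.0
P,63.3,32.1,0.0,0.0
Q,55.7,29.4,0.0,0.0
R,56.0,30.9,0.0,0.0
S,58.3,63.8,0.0,0.0
T,61.8,69.8,0.0,0.0
V,62.2,32.9,0.0,0.0
W,57.5,29.6,0.0,0.0
Y,57.9,38.8,0.0,0.0
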