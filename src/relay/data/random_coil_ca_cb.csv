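# Random-coil 13Ca / 13Cb chemical shifts (ppm), one-letter residue codes.
# Values follow the Kjaergaard & Poulsen random-coil compilation
# (pH 6.5 / 25 C conditions); glycine has no Cb.
restype,ca,cb
A,52.82,19.25
C,58.63,28.14
D,54.45,41.12
E,56.93,30.02
F,58.10,39.78
G,45.38,
H,55.90,29.54
I,61.37,38.72
K,56.69,32.96
L,55.47,42.25
M,55.90,32.80
N,53.51,38.89
P,63.47,32.05
Q,56.17,29.41
R,56.36,30.77
S,58.58,63.86
T,62.03,69.82
V,62.45,32.73
W,57.63,29.55
Y,58.05,38.85
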