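patient,exam_count,slices,spacing_x_mm,spacing_y_mm,spacing_z_mm
A,5,86,1.36,1.36,5
B,3,87,1.28,1.28,5
C,3,90,1.28,1.28,5
D,6,81,1.30,1.30,5
E,2,93,1.28,1.28,5
F,2,86,1.28,1.28,5
G,3,111,1.28,1.28,5
H,3,90,1.38,1.38,5
I,6,65,0.64,0.64,5
J,5,70,0.76,0.76,5
K,13,55,0.75,0.75,5
L,14,81,0.76,0.76,5
M,9,57,0.75,0.75,5
N,4,64,0.65,0.65,5
O,6,81,0.66,0.66,5
P,4,72,0.70,0.70,7
Q,2,124,1.42,1.42,2.5
R,2,119,1.33,1.33,2.5
S,2,66,1.35,1.35,1.25
T,2,123,1.54,1.54,2.5
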