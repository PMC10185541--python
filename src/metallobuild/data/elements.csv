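symbol,z,rcov,rvdw,ox_states,cns
H,1,0.31,1.20,,
B,5,0.84,1.91,,
C,6,0.76,1.77,,
N,7,0.71,1.66,,
O,8,0.66,1.50,,
F,9,0.57,1.46,,
Si,14,1.11,2.19,,
P,15,1.07,1.90,,
S,16,1.05,1.89,,
Cl,17,1.02,1.82,,
As,33,1.19,1.88,,
Se,34,1.20,1.82,,
Br,35,1.20,1.86,,
Te,52,1.38,1.99,,
I,53,1.39,2.04,,
Li,3,1.28,2.12,1,4;6
Be,4,0.96,1.98,2,4
Na,11,1.66,2.50,1,6
Mg,12,1.41,2.51,2,6
Al,13,1.21,2.25,3,6;4
K,19,2.03,2.73,1,6;8
Ca,20,1.76,2.62,2,6;8
Sc,21,1.70,2.58,3,6
Ti,22,1.60,2.46,4;3,6
V,23,1.53,2.42,3;4;5;2,6
Cr,24,1.39,2.45,3;2;6,6
Mn,25,1.61,2.45,2;3;4;7,6;4
Fe,26,1.52,2.44,3;2,6;4
Co,27,1.50,2.40,2;3,6;4
Ni,28,1.24,2.40,2,6;4
Cu,29,1.32,2.38,2;1,4;6;2
Zn,30,1.22,2.39,2,4;6
Ga,31,1.22,2.32,3,6;4
Rb,37,2.20,3.21,1,6;8
Sr,38,1.95,2.84,2,6;8
Y,39,1.90,2.75,3,6;8
Zr,40,1.75,2.52,4,6;8
Nb,41,1.64,2.56,5,6
Mo,42,1.54,2.45,6;4,6
Tc,43,1.47,2.44,7;4,6
Ru,44,1.46,2.46,3;2,6
Rh,45,1.42,2.44,3;1,6;4
Pd,46,1.39,2.15,2,4
Ag,47,1.45,2.53,1,2;4
Cd,48,1.44,2.49,2,4;6
In,49,1.42,2.43,3,6;4
Sn,50,1.39,2.42,2;4,6;4
Cs,55,2.44,3.48,1,6;8
Ba,56,2.15,3.03,2,8;6
La,57,2.07,2.98,3,8;9;6;7;10
Ce,58,2.04,2.88,3;4,8;9;10;6
Pr,59,2.03,2.92,3,8;9
Nd,60,2.01,2.95,3,8;9
Pm,61,1.99,2.90,3,8;9
Sm,62,1.98,2.90,3;2,8;9
Eu,63,1.98,2.87,3;2,8;9
Gd,64,1.96,2.83,3,8;9
Tb,65,1.94,2.79,3,8
Dy,66,1.92,2.87,3,8
Ho,67,1.92,2.81,3,8
Er,68,1.89,2.83,3,8;6
Tm,69,1.90,2.79,3,8;6
Yb,70,1.87,2.80,3;2,8;6
Lu,71,1.87,2.74,3,8;6
Hf,72,1.75,2.63,4,6;8
Ta,73,1.70,2.53,5,6
W,74,1.62,2.57,6;4,6
Re,75,1.51,2.49,7;4,6
Os,76,1.44,2.48,4;3,6
Ir,77,1.41,2.41,3;4;1,6
Pt,78,1.36,2.29,2;4,4;6
Au,79,1.36,2.32,3;1,4;2
Hg,80,1.32,2.45,2;1,2;4
Tl,81,1.45,2.47,1;3,6
Pb,82,1.46,2.60,2;4,6;4
Bi,83,1.48,2.54,3,6
Ac,89,2.15,2.80,3,9;8;6
Th,90,2.06,2.93,4,8;9;10
Pa,91,2.00,2.88,5;4,8;9
U,92,1.96,2.71,6;4;3,8;9;6;7
Np,93,1.90,2.82,5;4;3;6,8;9
Pu,94,1.87,2.81,4;3;6,8;9
Am,95,1.80,2.83,3,8;9
Cm,96,1.69,3.05,3,8;9
Bk,97,1.68,3.00,3,8
Cf,98,1.68,3.00,3,8
Es,99,1.65,3.00,3,8
Fm,100,1.67,3.00,3,8
Md,101,1.73,3.00,3;2,8
No,102,1.76,3.00,2;3,8
Lr,103,1.61,3.00,3,8
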