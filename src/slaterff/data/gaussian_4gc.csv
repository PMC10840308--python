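# Four-Gaussian-plus-constant (4G+c) X-ray scattering factor coefficients,
# transcribed from the standard International Tables for Crystallography
# Vol. C parameterization (a1..a4, b1..b4 in A^2, c in electrons).
# f(s) = sum_i a_i exp(-b_i s^2) + c with s = sin(theta)/lambda in A^-1.
species,a1,a2,a3,a4,a5,b1,b2,b3,b4,b5,c
H,0.489918,0.262003,0.196767,0.049879,0,20.6593,7.74039,49.5519,2.20159,0,0.001305
C,2.31,1.02,1.5886,0.865,0,20.8439,10.2075,0.5687,51.6512,0,0.2156
N,12.2126,3.1322,2.0125,1.1663,0,0.0057,9.8933,28.9975,0.5826,0,-11.529
O,3.0485,2.2868,1.5463,0.867,0,13.2771,5.7011,0.3239,32.9089,0,0.2508
Ca,8.6266,7.3873,1.5899,1.0211,0,10.4421,0.6599,85.7484,178.437,0,1.3751
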