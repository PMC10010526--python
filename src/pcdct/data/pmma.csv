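# material: pmma
# density_g_cm3: 1.19
energy_keV,mu_per_cm
1,3.324860e+03
2,5.065830e+02
3,1.566040e+02
4,6.652100e+01
5,3.398640e+01
6,1.955170e+01
7,1.232157e+01
8,8.259790e+00
9,5.629275e+00
10,3.994830e+00
11,3.073894e+00
12,2.419853e+00
13,1.941826e+00
14,1.583866e+00
15,1.310190e+00
16,1.130920e+00
17,9.849282e-01
18,8.645884e-01
19,7.643196e-01
20,6.799660e-01
21,6.300437e-01
22,5.858616e-01
23,5.465416e-01
24,5.113706e-01
25,4.797640e-01
26,4.512388e-01
27,4.253927e-01
28,4.018883e-01
29,3.804407e-01
30,3.608080e-01
31,3.504798e-01
32,3.407614e-01
33,3.315993e-01
34,3.229462e-01
35,3.147601e-01
36,3.070035e-01
37,2.996429e-01
38,2.926480e-01
39,2.859919e-01
40,2.796500e-01
41,2.758104e-01
42,2.721141e-01
43,2.685527e-01
44,2.651181e-01
45,2.618032e-01
46,2.586012e-01
47,2.555061e-01
48,2.525119e-01
49,2.496136e-01
50,2.468060e-01
51,2.448017e-01
52,2.428522e-01
53,2.409549e-01
54,2.391075e-01
55,2.373077e-01
56,2.355536e-01
57,2.338431e-01
58,2.321745e-01
59,2.305460e-01
60,2.289560e-01
61,2.277199e-01
62,2.265104e-01
63,2.253265e-01
64,2.241673e-01
65,2.230319e-01
66,2.219195e-01
67,2.208292e-01
68,2.197603e-01
69,2.187121e-01
70,2.176838e-01
71,2.166749e-01
72,2.156846e-01
73,2.147125e-01
74,2.137579e-01
75,2.128202e-01
76,2.118990e-01
77,2.109937e-01
78,2.101040e-01
79,2.092292e-01
80,2.083690e-01
81,2.076177e-01
82,2.068783e-01
83,2.061505e-01
84,2.054339e-01
85,2.047282e-01
86,2.040332e-01
87,2.033485e-01
88,2.026739e-01
89,2.020091e-01
90,2.013539e-01
91,2.007080e-01
92,2.000712e-01
93,1.994433e-01
94,1.988240e-01
95,1.982132e-01
96,1.976107e-01
97,1.970161e-01
98,1.964295e-01
99,1.958505e-01
100,1.952790e-01
101,1.947066e-01
102,1.941415e-01
103,1.935836e-01
104,1.930326e-01
105,1.924884e-01
106,1.919510e-01
107,1.914200e-01
108,1.908954e-01
109,1.903771e-01
110,1.898649e-01
111,1.893587e-01
112,1.888583e-01
113,1.883637e-01
114,1.878748e-01
115,1.873914e-01
116,1.869134e-01
117,1.864406e-01
118,1.859731e-01
119,1.855107e-01
120,1.850533e-01
121,1.846009e-01
122,1.841532e-01
123,1.837103e-01
124,1.832719e-01
125,1.828382e-01
126,1.824089e-01
127,1.819840e-01
128,1.815635e-01
129,1.811471e-01
130,1.807349e-01
131,1.803268e-01
132,1.799227e-01
133,1.795226e-01
134,1.791263e-01
135,1.787339e-01
136,1.783452e-01
137,1.779601e-01
138,1.775787e-01
139,1.772009e-01
140,1.768266e-01
141,1.764557e-01
142,1.760882e-01
143,1.757240e-01
144,1.753632e-01
145,1.750055e-01
146,1.746510e-01
147,1.742997e-01
148,1.739515e-01
149,1.736062e-01
150,1.732640e-01
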