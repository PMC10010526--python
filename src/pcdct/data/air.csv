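# material: air
# density_g_cm3: 0.001205
energy_keV,mu_per_cm
1,4.345230e+00
2,6.361195e-01
3,1.958125e-01
4,8.941100e-02
5,4.852535e-02
6,2.820905e-02
7,1.780754e-02
8,1.195481e-02
9,8.431466e-03
10,6.169600e-03
11,4.703313e-03
12,3.671237e-03
13,2.923061e-03
14,2.367019e-03
15,1.944870e-03
16,1.651123e-03
17,1.415731e-03
18,1.224620e-03
19,1.067647e-03
20,9.373695e-04
21,8.525847e-04
22,7.788969e-04
23,7.144434e-04
24,6.577372e-04
25,6.075798e-04
26,5.629963e-04
27,5.231871e-04
28,4.874914e-04
29,4.553590e-04
30,4.263290e-04
31,4.095028e-04
32,3.938439e-04
33,3.792385e-04
34,3.655870e-04
35,3.528017e-04
36,3.408051e-04
37,3.295287e-04
38,3.189114e-04
39,3.088989e-04
40,2.994425e-04
41,2.936051e-04
42,2.880182e-04
43,2.826653e-04
44,2.775316e-04
45,2.726034e-04
46,2.678682e-04
47,2.633144e-04
48,2.589315e-04
49,2.547097e-04
50,2.506400e-04
51,2.478312e-04
52,2.451076e-04
53,2.424649e-04
54,2.398993e-04
55,2.374072e-04
56,2.349851e-04
57,2.326301e-04
58,2.303389e-04
59,2.281089e-04
60,2.259375e-04
61,2.243775e-04
62,2.228534e-04
63,2.213637e-04
64,2.199073e-04
65,2.184828e-04
66,2.170890e-04
67,2.157249e-04
68,2.143894e-04
69,2.130815e-04
70,2.118002e-04
71,2.105446e-04
72,2.093139e-04
73,2.081072e-04
74,2.069238e-04
75,2.057628e-04
76,2.046235e-04
77,2.035054e-04
78,2.024077e-04
79,2.013297e-04
80,2.002710e-04
81,1.994300e-04
82,1.986028e-04
83,1.977890e-04
84,1.969882e-04
85,1.962000e-04
86,1.954242e-04
87,1.946604e-04
88,1.939082e-04
89,1.931674e-04
90,1.924377e-04
91,1.917187e-04
92,1.910102e-04
93,1.903120e-04
94,1.896237e-04
95,1.889452e-04
96,1.882762e-04
97,1.876164e-04
98,1.869657e-04
99,1.863238e-04
100,1.856905e-04
101,1.851086e-04
102,1.845343e-04
103,1.839673e-04
104,1.834075e-04
105,1.828547e-04
106,1.823088e-04
107,1.817697e-04
108,1.812371e-04
109,1.807110e-04
110,1.801912e-04
111,1.796776e-04
112,1.791700e-04
113,1.786683e-04
114,1.781725e-04
115,1.776823e-04
116,1.771978e-04
117,1.767187e-04
118,1.762449e-04
119,1.757764e-04
120,1.753130e-04
121,1.748547e-04
122,1.744014e-04
123,1.739529e-04
124,1.735092e-04
125,1.730702e-04
126,1.726357e-04
127,1.722058e-04
128,1.717803e-04
129,1.713592e-04
130,1.709423e-04
131,1.705296e-04
132,1.701211e-04
133,1.697166e-04
134,1.693160e-04
135,1.689194e-04
136,1.685267e-04
137,1.681377e-04
138,1.677524e-04
139,1.673708e-04
140,1.669928e-04
141,1.666183e-04
142,1.662473e-04
143,1.658798e-04
144,1.655155e-04
145,1.651546e-04
146,1.647970e-04
147,1.644426e-04
148,1.640913e-04
149,1.637431e-04
150,1.633980e-04
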