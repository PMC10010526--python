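# material: water
# density_g_cm3: 1.0
energy_keV,mu_per_cm
1,4.078000e+03
2,6.173000e+02
3,1.929000e+02
4,8.278000e+01
5,4.258000e+01
6,2.464000e+01
7,1.549673e+01
8,1.037000e+01
9,7.297333e+00
10,5.329000e+00
11,4.058573e+00
12,3.165186e+00
13,2.518098e+00
14,2.037561e+00
15,1.673000e+00
16,1.421603e+00
17,1.219971e+00
18,1.056133e+00
19,9.214563e-01
20,8.096000e-01
21,7.381329e-01
22,6.758746e-01
23,6.212968e-01
24,5.731768e-01
25,5.305270e-01
26,4.925424e-01
27,4.585615e-01
28,4.280364e-01
29,4.005104e-01
30,3.756000e-01
31,3.614703e-01
32,3.482960e-01
33,3.359854e-01
34,3.244584e-01
35,3.136441e-01
36,3.034800e-01
37,2.939104e-01
38,2.848859e-01
39,2.763623e-01
40,2.683000e-01
41,2.633700e-01
42,2.586462e-01
43,2.541152e-01
44,2.497652e-01
45,2.455848e-01
46,2.415641e-01
47,2.376935e-01
48,2.339645e-01
49,2.303692e-01
50,2.269000e-01
51,2.245191e-01
52,2.222088e-01
53,2.199655e-01
54,2.177862e-01
55,2.156679e-01
56,2.136078e-01
57,2.116033e-01
58,2.096520e-01
59,2.077517e-01
60,2.059000e-01
61,2.045547e-01
62,2.032399e-01
63,2.019544e-01
64,2.006970e-01
65,1.994668e-01
66,1.982628e-01
67,1.970839e-01
68,1.959294e-01
69,1.947984e-01
70,1.936900e-01
71,1.926035e-01
72,1.915382e-01
73,1.904933e-01
74,1.894682e-01
75,1.884623e-01
76,1.874750e-01
77,1.865056e-01
78,1.855537e-01
79,1.846187e-01
80,1.837000e-01
81,1.829509e-01
82,1.822141e-01
83,1.814890e-01
84,1.807755e-01
85,1.800732e-01
86,1.793818e-01
87,1.787009e-01
88,1.780304e-01
89,1.773700e-01
90,1.767193e-01
91,1.760782e-01
92,1.754464e-01
93,1.748236e-01
94,1.742097e-01
95,1.736044e-01
96,1.730075e-01
97,1.724188e-01
98,1.718381e-01
99,1.712652e-01
100,1.707000e-01
101,1.701732e-01
102,1.696532e-01
103,1.691399e-01
104,1.686330e-01
105,1.681325e-01
106,1.676382e-01
107,1.671500e-01
108,1.666677e-01
109,1.661913e-01
110,1.657205e-01
111,1.652553e-01
112,1.647956e-01
113,1.643412e-01
114,1.638920e-01
115,1.634480e-01
116,1.630091e-01
117,1.625750e-01
118,1.621458e-01
119,1.617213e-01
120,1.613015e-01
121,1.608863e-01
122,1.604755e-01
123,1.600691e-01
124,1.596670e-01
125,1.592691e-01
126,1.588754e-01
127,1.584858e-01
128,1.581001e-01
129,1.577184e-01
130,1.573406e-01
131,1.569665e-01
132,1.565962e-01
133,1.562295e-01
134,1.558664e-01
135,1.555069e-01
136,1.551508e-01
137,1.547981e-01
138,1.544488e-01
139,1.541028e-01
140,1.537601e-01
141,1.534205e-01
142,1.530841e-01
143,1.527508e-01
144,1.524205e-01
145,1.520932e-01
146,1.517689e-01
147,1.514474e-01
148,1.511288e-01
149,1.508130e-01
150,1.505000e-01
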