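# material: aluminum
# density_g_cm3: 2.699
energy_keV,mu_per_cm
1,3.198315e+03
2,6.107837e+03
3,2.126812e+03
4,9.729895e+02
5,5.219866e+02
6,3.111947e+02
7,1.995858e+02
8,1.358407e+02
9,9.630245e+01
10,7.079477e+01
11,5.348118e+01
12,4.140054e+01
13,3.271272e+01
14,2.630338e+01
15,2.147055e+01
16,1.779071e+01
17,1.491061e+01
18,1.262358e+01
19,1.078401e+01
20,9.287259e+00
21,8.120859e+00
22,7.145430e+00
23,6.323034e+00
24,5.624489e+00
25,5.027087e+00
26,4.512973e+00
27,4.067967e+00
28,3.680714e+00
29,3.342038e+00
30,3.044472e+00
31,2.815750e+00
32,2.610678e+00
33,2.426180e+00
34,2.259660e+00
35,2.108912e+00
36,1.972052e+00
37,1.847468e+00
38,1.733769e+00
39,1.629754e+00
40,1.534381e+00
41,1.462329e+00
42,1.395276e+00
43,1.332769e+00
44,1.274404e+00
45,1.219823e+00
46,1.168703e+00
47,1.120756e+00
48,1.075725e+00
49,1.033377e+00
50,9.935019e-01
51,9.635904e-01
52,9.351344e-01
53,9.080370e-01
54,8.822097e-01
55,8.575709e-01
56,8.340458e-01
57,8.115656e-01
58,7.900666e-01
59,7.694902e-01
60,7.497822e-01
61,7.361384e-01
62,7.229588e-01
63,7.102204e-01
64,6.979017e-01
65,6.859829e-01
66,6.744449e-01
67,6.632702e-01
68,6.524421e-01
69,6.419450e-01
70,6.317642e-01
71,6.218859e-01
72,6.122970e-01
73,6.029852e-01
74,5.939388e-01
75,5.851469e-01
76,5.765990e-01
77,5.682852e-01
78,5.601964e-01
79,5.523235e-01
80,5.446582e-01
81,5.395541e-01
82,5.345595e-01
83,5.296709e-01
84,5.248847e-01
85,5.201977e-01
86,5.156066e-01
87,5.111084e-01
88,5.067002e-01
89,5.023791e-01
90,4.981426e-01
91,4.939881e-01
92,4.899130e-01
93,4.859151e-01
94,4.819920e-01
95,4.781416e-01
96,4.743618e-01
97,4.706506e-01
98,4.670061e-01
99,4.634263e-01
100,4.599096e-01
101,4.575192e-01
102,4.551646e-01
103,4.528449e-01
104,4.505593e-01
105,4.483070e-01
106,4.460870e-01
107,4.438988e-01
108,4.417415e-01
109,4.396144e-01
110,4.375169e-01
111,4.354482e-01
112,4.334077e-01
113,4.313948e-01
114,4.294088e-01
115,4.274492e-01
116,4.255154e-01
117,4.236069e-01
118,4.217230e-01
119,4.198633e-01
120,4.180273e-01
121,4.162144e-01
122,4.144242e-01
123,4.126563e-01
124,4.109101e-01
125,4.091852e-01
126,4.074813e-01
127,4.057978e-01
128,4.041344e-01
129,4.024906e-01
130,4.008662e-01
131,3.992607e-01
132,3.976738e-01
133,3.961051e-01
134,3.945542e-01
135,3.930209e-01
136,3.915048e-01
137,3.900056e-01
138,3.885230e-01
139,3.870566e-01
140,3.856063e-01
141,3.841716e-01
142,3.827524e-01
143,3.813483e-01
144,3.799591e-01
145,3.785845e-01
146,3.772242e-01
147,3.758781e-01
148,3.745459e-01
149,3.732274e-01
150,3.719222e-01
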