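# material: copper
# density_g_cm3: 8.96
energy_keV,mu_per_cm
1,9.470720e+04
2,1.929984e+04
3,6.709248e+03
4,3.111808e+03
5,1.701504e+03
6,1.065344e+03
7,6.878238e+02
8,4.708480e+02
9,2.480688e+03
10,1.934464e+03
11,1.504250e+03
12,1.195614e+03
13,9.679422e+02
14,7.959942e+02
15,6.634880e+02
16,5.564066e+02
17,4.716145e+02
18,4.035408e+02
19,3.482163e+02
20,3.027584e+02
21,2.642809e+02
22,2.321571e+02
23,2.051165e+02
24,1.821832e+02
25,1.625992e+02
26,1.457693e+02
27,1.312214e+02
28,1.185780e+02
29,1.075344e+02
30,9.784320e+01
31,8.922312e+01
32,8.160109e+01
33,7.483555e+01
34,6.880850e+01
35,6.342105e+01
36,5.858984e+01
37,5.424430e+01
38,5.032438e+01
39,4.677879e+01
40,4.356352e+01
41,4.067066e+01
42,3.803283e+01
43,3.562225e+01
44,3.341472e+01
45,3.138909e+01
46,2.952681e+01
47,2.781158e+01
48,2.622902e+01
49,2.476641e+01
50,2.341248e+01
51,2.218726e+01
52,2.104812e+01
53,1.998753e+01
54,1.899873e+01
55,1.807566e+01
56,1.721289e+01
57,1.640549e+01
58,1.564903e+01
59,1.493951e+01
60,1.427328e+01
61,1.368218e+01
62,1.312458e+01
63,1.259810e+01
64,1.210053e+01
65,1.162988e+01
66,1.118430e+01
67,1.076212e+01
68,1.036178e+01
69,9.981852e+00
70,9.621027e+00
71,9.278089e+00
72,8.951918e+00
73,8.641478e+00
74,8.345811e+00
75,8.064027e+00
76,7.795304e+00
77,7.538874e+00
78,7.294027e+00
79,7.060101e+00
80,6.836480e+00
81,6.645288e+00
82,6.461691e+00
83,6.285300e+00
84,6.115752e+00
85,5.952703e+00
86,5.795833e+00
87,5.644840e+00
88,5.499439e+00
89,5.359363e+00
90,5.224361e+00
91,5.094196e+00
92,4.968644e+00
93,4.847493e+00
94,4.730546e+00
95,4.617613e+00
96,4.508517e+00
97,4.403089e+00
98,4.301170e+00
99,4.202609e+00
100,4.107264e+00
101,4.034694e+00
102,3.964102e+00
103,3.895416e+00
104,3.828567e+00
105,3.763489e+00
106,3.700118e+00
107,3.638394e+00
108,3.578259e+00
109,3.519659e+00
110,3.462541e+00
111,3.406854e+00
112,3.352551e+00
113,3.299584e+00
114,3.247909e+00
115,3.197485e+00
116,3.148270e+00
117,3.100225e+00
118,3.053313e+00
119,3.007498e+00
120,2.962745e+00
121,2.919021e+00
122,2.876295e+00
123,2.834535e+00
124,2.793712e+00
125,2.753798e+00
126,2.714765e+00
127,2.676588e+00
128,2.639241e+00
129,2.602699e+00
130,2.566940e+00
131,2.531940e+00
132,2.497679e+00
133,2.464134e+00
134,2.431286e+00
135,2.399116e+00
136,2.367604e+00
137,2.336732e+00
138,2.306482e+00
139,2.276839e+00
140,2.247785e+00
141,2.219305e+00
142,2.191382e+00
143,2.164004e+00
144,2.137155e+00
145,2.110821e+00
146,2.084989e+00
147,2.059647e+00
148,2.034781e+00
149,2.010380e+00
150,1.986432e+00
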