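# material: titanium
# density_g_cm3: 4.506
energy_keV,mu_per_cm
1,2.644571e+04
2,4.442916e+03
3,1.497344e+03
4,6.835602e+02
5,3.048337e+03
6,1.947944e+03
7,1.296770e+03
8,9.115638e+02
9,6.630928e+02
10,4.988142e+02
11,3.827320e+02
12,3.005161e+02
13,2.405760e+02
14,1.957944e+02
15,1.616302e+02
16,1.345702e+02
17,1.132924e+02
18,9.632219e+01
19,8.261584e+01
20,7.142010e+01
21,6.212034e+01
22,5.438339e+01
23,4.789244e+01
24,4.240503e+01
25,3.773336e+01
26,3.373044e+01
27,3.028007e+01
28,2.728954e+01
29,2.468428e+01
30,2.240383e+01
31,2.043032e+01
32,1.868529e+01
33,1.713632e+01
34,1.575641e+01
35,1.452293e+01
36,1.341678e+01
37,1.242182e+01
38,1.152430e+01
39,1.071248e+01
40,9.976284e+00
41,9.333661e+00
42,8.746455e+00
43,8.208735e+00
44,7.715319e+00
45,7.261671e+00
46,6.843807e+00
47,6.458214e+00
48,6.101792e+00
49,5.771793e+00
50,5.465778e+00
51,5.199665e+00
52,4.951305e+00
53,4.719205e+00
54,4.502024e+00
55,4.298553e+00
56,4.107699e+00
57,3.928475e+00
58,3.759988e+00
59,3.601424e+00
60,3.452047e+00
61,3.327999e+00
62,3.210319e+00
63,3.098584e+00
64,2.992407e+00
65,2.891431e+00
66,2.795327e+00
67,2.703792e+00
68,2.616544e+00
69,2.533325e+00
70,2.453893e+00
71,2.378026e+00
72,2.305517e+00
73,2.236174e+00
74,2.169818e+00
75,2.106282e+00
76,2.045412e+00
77,1.987063e+00
78,1.931099e+00
79,1.877395e+00
80,1.825831e+00
81,1.785800e+00
82,1.747122e+00
83,1.709736e+00
84,1.673583e+00
85,1.638609e+00
86,1.604762e+00
87,1.571993e+00
88,1.540257e+00
89,1.509510e+00
90,1.479709e+00
91,1.450816e+00
92,1.422795e+00
93,1.395608e+00
94,1.369224e+00
95,1.343610e+00
96,1.318735e+00
97,1.294572e+00
98,1.271093e+00
99,1.248271e+00
100,1.226083e+00
101,1.211105e+00
102,1.196456e+00
103,1.182124e+00
104,1.168100e+00
105,1.154374e+00
106,1.140938e+00
107,1.127781e+00
108,1.114897e+00
109,1.102276e+00
110,1.089912e+00
111,1.077797e+00
112,1.065923e+00
113,1.054283e+00
114,1.042872e+00
115,1.031682e+00
116,1.020707e+00
117,1.009942e+00
118,9.993810e-01
119,9.890179e-01
120,9.788476e-01
121,9.688650e-01
122,9.590651e-01
123,9.494431e-01
124,9.399944e-01
125,9.307145e-01
126,9.215991e-01
127,9.126440e-01
128,9.038451e-01
129,8.951985e-01
130,8.867004e-01
131,8.783473e-01
132,8.701354e-01
133,8.620614e-01
134,8.541220e-01
135,8.463139e-01
136,8.386341e-01
137,8.310794e-01
138,8.236470e-01
139,8.163340e-01
140,8.091377e-01
141,8.020553e-01
142,7.950843e-01
143,7.882222e-01
144,7.814666e-01
145,7.748150e-01
146,7.682651e-01
147,7.618148e-01
148,7.554618e-01
149,7.492040e-01
150,7.430394e-01
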