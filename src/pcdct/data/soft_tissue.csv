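# material: soft_tissue
# density_g_cm3: 1.06
energy_keV,mu_per_cm
1,4.322680e+03
2,6.543380e+02
3,2.044740e+02
4,8.774680e+01
5,4.513480e+01
6,2.611840e+01
7,1.642653e+01
8,1.099220e+01
9,7.735173e+00
10,5.648740e+00
11,4.302088e+00
12,3.355097e+00
13,2.669184e+00
14,2.159814e+00
15,1.773380e+00
16,1.506899e+00
17,1.293169e+00
18,1.119501e+00
19,9.767437e-01
20,8.581760e-01
21,7.824209e-01
22,7.164271e-01
23,6.585746e-01
24,6.075674e-01
25,5.623586e-01
26,5.220949e-01
27,4.860752e-01
28,4.537186e-01
29,4.245410e-01
30,3.981360e-01
31,3.831585e-01
32,3.691937e-01
33,3.561446e-01
34,3.439259e-01
35,3.324628e-01
36,3.216888e-01
37,3.115450e-01
38,3.019791e-01
39,2.929440e-01
40,2.843980e-01
41,2.791722e-01
42,2.741649e-01
43,2.693622e-01
44,2.647511e-01
45,2.603199e-01
46,2.560579e-01
47,2.519551e-01
48,2.480024e-01
49,2.441913e-01
50,2.405140e-01
51,2.379903e-01
52,2.355413e-01
53,2.331634e-01
54,2.308534e-01
55,2.286080e-01
56,2.264243e-01
57,2.242995e-01
58,2.222312e-01
59,2.202168e-01
60,2.182540e-01
61,2.168280e-01
62,2.154343e-01
63,2.140716e-01
64,2.127389e-01
65,2.114348e-01
66,2.101585e-01
67,2.089090e-01
68,2.076852e-01
69,2.064863e-01
70,2.053114e-01
71,2.041597e-01
72,2.030304e-01
73,2.019229e-01
74,2.008363e-01
75,1.997701e-01
76,1.987235e-01
77,1.976960e-01
78,1.966869e-01
79,1.956958e-01
80,1.947220e-01
81,1.939280e-01
82,1.931469e-01
83,1.923784e-01
84,1.916220e-01
85,1.908776e-01
86,1.901447e-01
87,1.894230e-01
88,1.887123e-01
89,1.880122e-01
90,1.873225e-01
91,1.866429e-01
92,1.859732e-01
93,1.853130e-01
94,1.846623e-01
95,1.840206e-01
96,1.833879e-01
97,1.827639e-01
98,1.821484e-01
99,1.815411e-01
100,1.809420e-01
101,1.803836e-01
102,1.798324e-01
103,1.792883e-01
104,1.787510e-01
105,1.782205e-01
106,1.776965e-01
107,1.771790e-01
108,1.766678e-01
109,1.761627e-01
110,1.756637e-01
111,1.751706e-01
112,1.746833e-01
113,1.742017e-01
114,1.737256e-01
115,1.732549e-01
116,1.727896e-01
117,1.723295e-01
118,1.718746e-01
119,1.714246e-01
120,1.709796e-01
121,1.705394e-01
122,1.701040e-01
123,1.696732e-01
124,1.692470e-01
125,1.688253e-01
126,1.684079e-01
127,1.679949e-01
128,1.675861e-01
129,1.671815e-01
130,1.667810e-01
131,1.663845e-01
132,1.659919e-01
133,1.656033e-01
134,1.652184e-01
135,1.648373e-01
136,1.644598e-01
137,1.640860e-01
138,1.637158e-01
139,1.633490e-01
140,1.629857e-01
141,1.626258e-01
142,1.622692e-01
143,1.619158e-01
144,1.615657e-01
145,1.612188e-01
146,1.608750e-01
147,1.605342e-01
148,1.601965e-01
149,1.598618e-01
150,1.595300e-01
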