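# material: bone
# density_g_cm3: 1.92
energy_keV,mu_per_cm
1,7.257600e+03
2,1.132800e+03
3,5.299200e+02
4,3.072000e+02
5,2.016000e+02
6,1.440000e+02
7,1.078117e+02
8,8.390400e+01
9,6.696958e+01
10,5.473920e+01
11,4.177837e+01
12,3.264540e+01
13,2.601792e+01
14,2.108774e+01
15,1.734144e+01
16,1.444625e+01
17,1.216847e+01
18,1.035089e+01
19,8.882166e+00
20,7.681920e+00
21,6.729031e+00
22,5.930776e+00
23,5.256645e+00
24,4.683132e+00
25,4.191917e+00
26,3.768569e+00
27,3.401618e+00
28,3.081860e+00
29,2.801849e+00
30,2.555520e+00
31,2.361392e+00
32,2.187491e+00
33,2.031173e+00
34,1.890205e+00
35,1.762691e+00
36,1.647018e+00
37,1.541800e+00
38,1.445848e+00
39,1.358131e+00
40,1.277760e+00
41,1.215646e+00
42,1.157941e+00
43,1.104238e+00
44,1.054176e+00
45,1.007434e+00
46,9.637245e-01
47,9.227913e-01
48,8.844045e-01
49,8.483574e-01
50,8.144640e-01
51,7.885015e-01
52,7.638469e-01
53,7.404112e-01
54,7.181126e-01
55,6.968766e-01
56,6.766344e-01
57,6.573230e-01
58,6.388845e-01
59,6.212653e-01
60,6.044160e-01
61,5.925456e-01
62,5.810957e-01
63,5.700450e-01
64,5.593735e-01
65,5.490627e-01
66,5.390950e-01
67,5.294542e-01
68,5.201248e-01
69,5.110924e-01
70,5.023435e-01
71,4.938653e-01
72,4.856458e-01
73,4.776736e-01
74,4.699382e-01
75,4.624293e-01
76,4.551375e-01
77,4.480538e-01
78,4.411696e-01
79,4.344769e-01
80,4.279680e-01
81,4.236144e-01
82,4.193576e-01
83,4.151945e-01
84,4.111218e-01
85,4.071365e-01
86,4.032359e-01
87,3.994170e-01
88,3.956773e-01
89,3.920144e-01
90,3.884257e-01
91,3.849089e-01
92,3.814619e-01
93,3.780826e-01
94,3.747688e-01
95,3.715187e-01
96,3.683304e-01
97,3.652021e-01
98,3.621320e-01
99,3.591185e-01
100,3.561600e-01
101,3.541915e-01
102,3.522531e-01
103,3.503441e-01
104,3.484638e-01
105,3.466113e-01
106,3.447862e-01
107,3.429877e-01
108,3.412151e-01
109,3.394679e-01
110,3.377455e-01
111,3.360473e-01
112,3.343728e-01
113,3.327213e-01
114,3.310925e-01
115,3.294858e-01
116,3.279006e-01
117,3.263367e-01
118,3.247933e-01
119,3.232703e-01
120,3.217670e-01
121,3.202831e-01
122,3.188181e-01
123,3.173718e-01
124,3.159436e-01
125,3.145333e-01
126,3.131404e-01
127,3.117646e-01
128,3.104056e-01
129,3.090630e-01
130,3.077366e-01
131,3.064259e-01
132,3.051307e-01
133,3.038507e-01
134,3.025856e-01
135,3.013351e-01
136,3.000989e-01
137,2.988769e-01
138,2.976686e-01
139,2.964739e-01
140,2.952925e-01
141,2.941241e-01
142,2.929686e-01
143,2.918257e-01
144,2.906952e-01
145,2.895768e-01
146,2.884704e-01
147,2.873757e-01
148,2.862925e-01
149,2.852207e-01
150,2.841600e-01
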