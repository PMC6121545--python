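age,q_all,cvd_fatality
0,2.714433158601537e-05,0.1
1,2.9849464220577104e-05,0.1
2,3.282417882843891e-05,0.1
3,3.6095339872255217e-05,0.1
4,3.969248872714992e-05,0.1
5,4.364811038004568e-05,0.1
6,4.799792669374359e-05,0.1
7,5.2781218876973846e-05,0.1
8,5.804118206798048e-05,0.1
9,6.382531522630686e-05,0.1
10,7.0185849847193e-05,0.1
11,7.718022135838609e-05,0.1
12,8.487158744552303e-05,0.1
13,9.332939797179751e-05,0.1
14,0.00010263002162147483,0.1
15,0.00011285743490474509,0.1
16,0.00012410397971851506,0.1
17,0.00013647119627513415,0.1
18,0.0001500707388816247,0.1
19,0.00016502538279195011,0.1
20,0.00018147013117075783,0.1
21,0.00019955343209587806,0.1
22,0.00021943851650640944,0.1
23,0.00024130486908235937,0.1
24,0.00026534984521331406,0.1
25,0.00029179044851623814,0.1
26,0.00032086528477426324,0.1
27,0.0003528367097295204,0.1
28,0.0003879931898641553,0.1
29,0.00042665189717727703,0.1
30,0.00046916156100762496,0.1
31,0.0005159056021981634,0.1
32,0.0005673055773489644,0.1
33,0.0006238249635887039,0.1
34,0.0006859733172313032,0.1
35,0.0007543108428870182,0.1
36,0.0008294534131018105,0.1
37,0.0009120780824140029,0.1
38,0.0010029291438844457,0.1
39,0.001102824780690459,0.1
40,0.0012126643703067597,0.1
41,0.0013334365041606233,0.1
42,0.0014662277914651023,0.1
43,0.0016122325222434064,0.1
44,0.0017727632713759878,0.1
45,0.0019492625328710877,0.1
46,0.002143315481495267,0.1
47,0.0023566639674295065,0.1
48,0.0025912218587617053,0.1
49,0.002849091856389707,0.1
50,0.0031325839163065528,0.1
51,0.0034442354252479657,0.1
52,0.0037868332872952326,0.1
53,0.004163438091185245,0.1
54,0.004577410540722804,0.1
55,0.005032440343727851,0.1
56,0.005532577768218694,0.1
57,0.006082268087878928,0.1
58,0.006686389151999039,0.1
59,0.0073502923277262155,0.1
60,0.008079847074174196,0.1
61,0.008881489418218869,0.1
62,0.009762274609973698,0.1
63,0.010729934241195171,0.1
64,0.011792938111177764,0.1
65,0.012960561120839986,0.1
66,0.014242955465122664,0.1
67,0.015651228374693793,0.1
68,0.017197525628008692,0.1
69,0.0188951210113254,0.1
70,0.020758511844077066,0.1
71,0.022803520606203498,0.1
72,0.025047402598066038,0.1
73,0.027508959427037905,0.1
74,0.03020865794147154,0.1
75,0.03316875401516517,0.1
76,0.03641342031525319,0.1
77,0.039968876853969215,0.1
78,0.043863522719078785,0.1
79,0.048128066886791276,0.1
80,0.052795655431269406,0.1
81,0.05790199174208788,0.1
82,0.06348544553007973,0.1
83,0.06958714542771183,0.1
84,0.07625104885789868,0.1
85,0.08352398154228324,0.1
86,0.09145563753733044,0.1
87,0.10009852902078675,0.1
88,0.1095078732078113,0.1
89,0.11974140177398374,0.1
90,0.1308590760382552,0.1
91,0.14292268897414706,0.1
92,0.15599533296613088,0.1
93,0.17014071024615496,0.1
94,0.18542226132156936,0.1
95,0.20190208569384804,0.1
96,0.21963962909814938,0.1
97,0.2386901127860278,0.1
98,0.2591026835436009,0.1
99,0.2809182688010958,0.1
100,0.30416713005525,0.1
101,0.3288661206710827,0.1
102,0.3550156717548726,0.1
103,0.3825965529414742,0.1
104,0.41156648418755415,0.1
105,0.44185671023367223,0.1
106,0.47336869094382417,0.1
107,0.5059711070406623,0.1
108,0.5394974294194818,0.1
109,0.5737443472817033,0.1
110,1.0,0.1
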