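label	x	y	z
PreCG.L	-48.71	31.59	13.74
PreCG.R	48.71	31.59	13.74
SFGdor.L	-21.78	-62.21	34.10
SFGdor.R	21.78	-62.21	34.10
ORBsup.L	-21.79	-35.50	41.85
ORBsup.R	21.79	-35.50	41.85
MFG.L	-31.37	-51.50	38.87
MFG.R	31.37	-51.50	38.87
ORBmid.L	-26.90	-15.91	19.42
ORBmid.R	26.90	-15.91	19.42
IFGoperc.L	-32.85	-13.20	7.10
IFGoperc.R	32.85	-13.20	7.10
IFGtriang.L	-26.69	-40.72	-5.46
IFGtriang.R	26.69	-40.72	-5.46
ORBinf.L	-33.60	8.69	-12.27
ORBinf.R	33.60	8.69	-12.27
ROL.L	-40.62	-62.06	-19.81
ROL.R	40.62	-62.06	-19.81
SMA.L	-4.33	35.60	54.33
SMA.R	4.33	35.60	54.33
OLF.L	-7.32	-22.99	-25.00
OLF.R	7.32	-22.99	-25.00
SFGmed.L	-7.46	-44.05	0.67
SFGmed.R	7.46	-44.05	0.67
ORBsupmed.L	-5.04	36.63	-37.75
ORBsupmed.R	5.04	36.63	-37.75
REC.L	-4.70	26.10	16.49
REC.R	4.70	26.10	16.49
INS.L	-40.11	-64.43	17.96
INS.R	40.11	-64.43	17.96
ACG.L	-7.07	-42.53	13.40
ACG.R	7.07	-42.53	13.40
DCG.L	-10.49	-69.64	45.13
DCG.R	10.49	-69.64	45.13
PCG.L	-4.09	50.13	-1.45
PCG.R	4.09	50.13	-1.45
HIP.L	-56.47	50.69	42.77
HIP.R	56.47	50.69	42.77
PHG.L	-42.99	-60.34	-7.68
PHG.R	42.99	-60.34	-7.68
AMYG.L	-42.51	39.15	16.68
AMYG.R	42.51	39.15	16.68
CAL.L	-5.92	-32.27	52.70
CAL.R	5.92	-32.27	52.70
CUN.L	-4.18	-79.43	30.53
CUN.R	4.18	-79.43	30.53
LING.L	-30.86	-3.41	18.47
LING.R	30.86	-3.41	18.47
SOG.L	-21.09	-17.86	-9.94
SOG.R	21.09	-17.86	-9.94
MOG.L	-56.29	-57.65	56.23
MOG.R	56.29	-57.65	56.23
IOG.L	-18.42	34.19	-17.54
IOG.R	18.42	34.19	-17.54
FFG.L	-23.15	55.00	16.00
FFG.R	23.15	55.00	16.00
PoCG.L	-50.30	-51.82	30.30
PoCG.R	50.30	-51.82	30.30
SPG.L	-41.91	19.58	42.78
SPG.R	41.91	19.58	42.78
IPL.L	-27.30	-55.95	11.99
IPL.R	27.30	-55.95	11.99
SMG.L	-52.76	-59.65	-32.83
SMG.R	52.76	-59.65	-32.83
ANG.L	-52.96	46.83	30.99
ANG.R	52.96	46.83	30.99
PCUN.L	-11.06	-64.60	32.43
PCUN.R	11.06	-64.60	32.43
PCL.L	-7.79	-55.11	-5.08
PCL.R	7.79	-55.11	-5.08
CAU.L	-8.23	8.16	31.52
CAU.R	8.23	8.16	31.52
PUT.L	-54.84	-23.92	40.33
PUT.R	54.84	-23.92	40.33
PAL.L	-36.17	3.32	30.68
PAL.R	36.17	3.32	30.68
THA.L	-10.13	-52.88	58.96
THA.R	10.13	-52.88	58.96
HES.L	-41.46	0.85	48.33
HES.R	41.46	0.85	48.33
STG.L	-23.48	-3.06	41.75
STG.R	23.48	-3.06	41.75
TPOsup.L	-40.39	-3.26	-29.76
TPOsup.R	40.39	-3.26	-29.76
MTG.L	-50.01	20.53	-4.55
MTG.R	50.01	20.53	-4.55
TPOmid.L	-25.39	-64.65	-16.13
TPOmid.R	25.39	-64.65	-16.13
ITG.L	-43.54	-28.09	-33.13
ITG.R	43.54	-28.09	-33.13
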