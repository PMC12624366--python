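name	x	y
Fp1	-0.024055	0.074034
AF7	-0.045755	0.062977
AF3	-0.028623	0.061383
F1	-0.018533	0.045870
F3	-0.036303	0.044830
F5	-0.051604	0.044858
F7	-0.062977	0.045755
FT7	-0.074034	0.024055
FC5	-0.061995	0.023798
FC3	-0.043681	0.023226
FC1	-0.023263	0.023263
C1	-0.023950	-0.000000
C3	-0.045971	-0.000000
C5	-0.064350	-0.000000
T7	-0.077844	-0.000000
TP7	-0.074034	-0.024055
CP5	-0.061995	-0.023798
CP3	-0.043681	-0.023226
CP1	-0.023263	-0.023263
P1	-0.018533	-0.045870
P3	-0.036303	-0.044830
P5	-0.051604	-0.044858
P7	-0.062977	-0.045755
P9	-0.069656	-0.050608
PO7	-0.045755	-0.062977
PO3	-0.028623	-0.061383
O1	-0.024055	-0.074034
Iz	0.000000	-0.086099
Oz	0.000000	-0.077844
POz	0.000000	-0.064350
Pz	0.000000	-0.045971
CPz	0.000000	-0.023950
Fpz	0.000000	0.077844
Fp2	0.024055	0.074034
AF8	0.045755	0.062977
AF4	0.028623	0.061383
AFz	0.000000	0.064350
Fz	0.000000	0.045971
F2	0.018533	0.045870
F4	0.036303	0.044830
F6	0.051604	0.044858
F8	0.062977	0.045755
FT8	0.074034	0.024055
FC6	0.061995	0.023798
FC4	0.043681	0.023226
FC2	0.023263	0.023263
FCz	0.000000	0.023950
Cz	0.000000	0.000000
C2	0.023950	0.000000
C4	0.045971	0.000000
C6	0.064350	0.000000
T8	0.077844	0.000000
TP8	0.074034	-0.024055
CP6	0.061995	-0.023798
CP4	0.043681	-0.023226
CP2	0.023263	-0.023263
P2	0.018533	-0.045870
P4	0.036303	-0.044830
P6	0.051604	-0.044858
P8	0.062977	-0.045755
P10	0.069656	-0.050608
PO8	0.045755	-0.062977
PO4	0.028623	-0.061383
O2	0.024055	-0.074034
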