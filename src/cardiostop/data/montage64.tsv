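label	x_cm	y_cm	z_cm
Fp1	-2.6450	8.1406	2.7812
Fp2	2.6450	8.1406	2.7812
AF7	-5.0312	6.9248	2.7812
AF3	-2.6486	7.4787	4.2491
AFz	0.0000	7.2812	5.2901
AF4	2.6486	7.4787	4.2491
AF8	5.0312	6.9248	2.7812
F7	-6.9248	5.0312	2.7812
F5	-5.5686	5.5778	4.3450
F3	-3.8972	5.8087	5.6630
F1	-2.0054	5.7110	6.6606
Fz	0.0000	5.2901	7.2812
F2	2.0054	5.7110	6.6606
F4	3.8972	5.8087	5.6630
F6	5.5686	5.5778	4.3450
F8	6.9248	5.0312	2.7812
FT9	-8.5595	2.7812	0.0000
FT7	-8.1406	2.6450	2.7812
FC5	-6.8082	3.0852	5.0130
FC3	-4.8917	3.2606	6.8147
FC1	-2.5555	3.1563	8.0316
FCz	0.0000	2.7812	8.5595
FC2	2.5555	3.1563	8.0316
FC4	4.8917	3.2606	6.8147
FC6	6.8082	3.0852	5.0130
FT8	8.1406	2.6450	2.7812
FT10	8.5595	2.7812	0.0000
T7	-8.5595	0.0000	2.7812
C5	-7.2812	0.0000	5.2901
C3	-5.2901	0.0000	7.2812
C1	-2.7812	0.0000	8.5595
Cz	0.0000	0.0000	9.0000
C2	2.7812	0.0000	8.5595
C4	5.2901	0.0000	7.2812
C6	7.2812	0.0000	5.2901
T8	8.5595	0.0000	2.7812
TP9	-8.5595	-2.7812	0.0000
TP7	-8.1406	-2.6450	2.7812
CP5	-6.8082	-3.0852	5.0130
CP3	-4.8917	-3.2606	6.8147
CP1	-2.5555	-3.1563	8.0316
CPz	-0.0000	-2.7812	8.5595
CP2	2.5555	-3.1563	8.0316
CP4	4.8917	-3.2606	6.8147
CP6	6.8082	-3.0852	5.0130
TP8	8.1406	-2.6450	2.7812
TP10	8.5595	-2.7812	0.0000
P7	-6.9248	-5.0312	2.7812
P5	-5.5686	-5.5778	4.3450
P3	-3.8972	-5.8087	5.6630
P1	-2.0054	-5.7110	6.6606
Pz	-0.0000	-5.2901	7.2812
P2	2.0054	-5.7110	6.6606
P4	3.8972	-5.8087	5.6630
P6	5.5686	-5.5778	4.3450
P8	6.9248	-5.0312	2.7812
PO7	-5.0312	-6.9248	2.7812
PO3	-2.6486	-7.4787	4.2491
POz	-0.0000	-7.2812	5.2901
PO4	2.6486	-7.4787	4.2491
PO8	5.0312	-6.9248	2.7812
O1	-2.6450	-8.1406	2.7812
Oz	-0.0000	-8.5595	2.7812
O2	2.6450	-8.1406	2.7812
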