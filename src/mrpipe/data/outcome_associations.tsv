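outcome	rsid	gene	or	ci_low	ci_high	pval	proxy
nonsubtyped_IS	rs1801133	MTHFR	1.02	1.00	1.04	0.352
nonsubtyped_IS	rs2275565	MTR	1.01	0.99	1.04	0.211
nonsubtyped_IS	rs9369898	MUT	1.03	1.01	1.05	0.001
nonsubtyped_IS	rs7130284	NOX4	1.02	0.99	1.06	0.237
nonsubtyped_IS	rs154657	DPEP1	1.01	0.99	1.02	0.604
nonsubtyped_IS	rs234709	CBS	1.00	0.98	1.02	0.782
nonsubtyped_IS	rs4660306	MMACHC	0.99	0.97	1.01	0.315
nonsubtyped_IS	rs548987	SLC17A3	1.01	0.98	1.03	0.670
nonsubtyped_IS	rs42648	GTPB10	0.98	0.97	1.00	0.076
nonsubtyped_IS	rs1801222	CUBN	1.02	1.00	1.04	0.051
nonsubtyped_IS	rs2251468	HNF1A	1.01	0.99	1.03	0.423
nonsubtyped_IS	rs838133	FUT2	0.99	0.97	1.01	0.398
nonsubtyped_IS	rs12780845	CUBN	0.99	0.97	1.01	0.460
LAA	rs1801133	MTHFR	1.00	0.95	1.06	0.945
LAA	rs2275565	MTR	1.02	0.96	1.08	0.508
LAA	rs9369898	MUT	1.02	0.97	1.07	0.400
LAA	rs7130284	NOX4	1.00	0.91	1.10	0.941
LAA	rs154657	DPEP1	1.06	1.00	1.12	0.043
LAA	rs234709	CBS	1.02	0.96	1.07	0.582
LAA	rs4660306	MMACHC	1.00	0.95	1.05	0.889
LAA	rs548987	SLC17A3	1.08	1.01	1.17	0.034
LAA	rs42648	GTPB10	1.00	0.95	1.05	0.972
LAA	rs1801222	CUBN	1.01	0.96	1.07	0.628
LAA	rs2251468	HNF1A	1.01	0.96	1.06	0.728
LAA	rs838133	FUT2	0.96	0.91	1.02	0.180
LAA	rs12780845	CUBN	1.03	0.98	1.09	0.219
SAO	rs1801133	MTHFR	1.09	1.05	1.13	8.37e-6
SAO	rs2275565	MTR	1.00	0.96	1.04	0.990
SAO	rs9369898	MUT	1.06	1.02	1.09	8.32e-4
SAO	rs7130284	NOX4	1.02	0.97	1.07	0.483
SAO	rs154657	DPEP1	0.98	0.94	1.03	0.381
SAO	rs234709	CBS	1.00	0.96	1.04	0.939
SAO	rs4660306	MMACHC	0.99	0.96	1.04	0.790
SAO	rs548987	SLC17A3	1.06	1.01	1.11	0.020
SAO	rs42648	GTPB10	0.99	0.95	1.02	0.443
SAO	rs1801222	CUBN	1.04	1.00	1.08	0.031
SAO	rs2251468	HNF1A	0.97	0.94	1.01	0.120
SAO	rs838133	FUT2	0.95	0.91	0.99	0.022
SAO	rs12780845	CUBN	0.99	0.96	1.03	0.675
CE	rs1801133	MTHFR	1.00	0.96	1.04	0.928
CE	rs2275565	MTR	1.05	1.01	1.09	0.018
CE	rs9369898	MUT	1.01	0.98	1.05	0.419
CE	rs7130284	NOX4	0.99	0.94	1.05	0.839
CE	rs154657	DPEP1	1.00	0.96	1.04	0.894
CE	rs234709	CBS	0.98	0.94	1.02	0.305
CE	rs4660306	MMACHC	1.02	0.98	1.05	0.409
CE	rs548987	SLC17A3	0.96	0.91	1.01	0.134
CE	rs42648	GTPB10	1.00	0.97	1.04	0.984
CE	rs1801222	CUBN	1.03	0.99	1.07	0.667
CE	rs2251468	HNF1A	1.01	0.97	1.04	0.682
CE	rs838133	FUT2	1.03	0.99	1.07	0.147
CE	rs12780845	CUBN	1.01	0.97	1.05	0.560
TIA	rs1801133	MTHFR	1.00	1.00	1.00	0.930
TIA	rs2275565	MTR	NA	NA	NA	NA
TIA	rs9369898	MUT	1.00	1.00	1.00	0.056
TIA	rs7130284	NOX4	NA	NA	NA	NA
TIA	rs154657	DPEP1	1.00	1.00	1.00	0.230
TIA	rs234709	CBS	1.00	1.00	1.00	1.000
TIA	rs4660306	MMACHC	1.00	1.00	1.00	0.140
TIA	rs548987	SLC17A3	NA	NA	NA	NA
TIA	rs42648	GTPB10	1.00	1.00	1.00	0.900
TIA	rs1801222	CUBN	1.00	1.00	1.00	0.430
TIA	rs2251468	HNF1A	1.00	1.00	1.00	0.840
TIA	rs838133	FUT2	1.00	1.00	1.00	0.260
TIA	rs12780845	CUBN	1.00	1.00	1.00	1.000
MS	rs1801133	MTHFR	NA	NA	NA	NA
MS	rs2275565	MTR	0.96	0.92	1.00	0.059	rs10158822
MS	rs9369898	MUT	NA	NA	NA	NA
MS	rs7130284	NOX4	0.98	0.92	1.04	0.528	rs11018628
MS	rs154657	DPEP1	1.01	0.98	1.04	0.616	rs460879
MS	rs234709	CBS	NA	NA	NA	NA
MS	rs4660306	MMACHC	NA	NA	NA	NA
MS	rs548987	SLC17A3	1.04	0.99	1.09	0.088	rs501220
MS	rs42648	GTPB10	NA	NA	NA	NA
MS	rs1801222	CUBN	NA	NA	NA	NA
MS	rs2251468	HNF1A	1.00	0.96	1.03	0.870	rs2244608
MS	rs838133	FUT2	NA	NA	NA	NA
MS	rs12780845	CUBN	1.02	0.98	1.05	0.303	rs10490958
AD	rs1801133	MTHFR	1.01	0.98	1.04	0.352
AD	rs2275565	MTR	1.00	0.97	1.04	0.970
AD	rs9369898	MUT	1.02	0.99	1.05	0.260
AD	rs7130284	NOX4	0.97	0.92	1.02	0.269
AD	rs154657	DPEP1	1.01	0.98	1.04	0.550
AD	rs234709	CBS	1.00	0.97	1.03	0.944
AD	rs4660306	MMACHC	1.01	0.98	1.04	0.394
AD	rs548987	SLC17A3	0.98	0.94	1.02	0.325
AD	rs42648	GTPB10	0.99	0.96	1.02	0.390
AD	rs1801222	CUBN	1.00	0.97	1.03	0.895
AD	rs2251468	HNF1A	1.01	0.98	1.04	0.606
AD	rs838133	FUT2	0.98	0.95	1.01	0.196
AD	rs12780845	CUBN	0.99	0.96	1.02	0.377
PD	rs1801133	MTHFR	1.01	0.97	1.04	0.698
PD	rs2275565	MTR	1.01	0.97	1.05	0.591
PD	rs9369898	MUT	1.00	0.96	1.03	0.882
PD	rs7130284	NOX4	0.97	0.89	1.06	0.511
PD	rs154657	DPEP1	1.00	0.97	1.04	0.987
PD	rs234709	CBS	1.01	0.97	1.05	0.730
PD	rs4660306	MMACHC	1.02	0.98	1.06	0.253
PD	rs548987	SLC17A3	1.01	0.95	1.06	0.846
PD	rs42648	GTPB10	0.98	0.95	1.02	0.343
PD	rs1801222	CUBN	1.01	0.97	1.05	0.587
PD	rs2251468	HNF1A	0.99	0.96	1.02	0.526
PD	rs838133	FUT2	1.02	0.98	1.06	0.301
PD	rs12780845	CUBN	0.99	0.96	1.03	0.765
ALS	rs1801133	MTHFR	1.02	0.99	1.05	0.123
ALS	rs2275565	MTR	0.98	0.95	1.01	0.165
ALS	rs9369898	MUT	1.00	0.98	1.03	0.767
ALS	rs7130284	NOX4	0.96	0.92	1.02	0.176
ALS	rs154657	DPEP1	1.02	0.99	1.04	0.263
ALS	rs234709	CBS	1.00	0.98	1.03	0.837
ALS	rs4660306	MMACHC	1.02	1.00	1.05	0.103
ALS	rs548987	SLC17A3	1.03	0.99	1.07	0.212
ALS	rs42648	GTPB10	0.98	0.95	1.00	0.087
ALS	rs1801222	CUBN	1.02	0.99	1.05	0.183
ALS	rs2251468	HNF1A	0.98	0.95	1.01	0.189
ALS	rs838133	FUT2	1.02	0.99	1.05	0.266
ALS	rs12780845	CUBN	1.01	0.98	1.04	0.616
FTD	rs1801133	MTHFR	NA	NA	NA	NA
FTD	rs2275565	MTR	NA	NA	NA	NA
FTD	rs9369898	MUT	0.94	0.82	1.08	0.356	rs2501968
FTD	rs7130284	NOX4	1.25	0.96	1.64	0.099	rs10501705
FTD	rs154657	DPEP1	1.13	0.99	1.29	0.080	rs460879
FTD	rs234709	CBS	NA	NA	NA	NA
FTD	rs4660306	MMACHC	1.04	0.90	1.20	0.588	rs2991966
FTD	rs548987	SLC17A3	NA	NA	NA	NA
FTD	rs42648	GTPB10	1.03	0.90	1.18	0.710	rs42659
FTD	rs1801222	CUBN	NA	NA	NA	NA
FTD	rs2251468	HNF1A	NA	NA	NA	NA
FTD	rs838133	FUT2	NA	NA	NA	NA
FTD	rs12780845	CUBN	1.04	0.90	1.20	0.595	rs7095324
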