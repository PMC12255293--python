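# nn_params v1: unified DNA nearest-neighbor parameters, 1 M NaCl reference
# wc: SantaLucia & Hicks 2004 Watson-Crick stacks; mismatch: Allawi/SantaLucia/Peyret single internal mismatches
# stack key: top dinucleotide 5'->3' / bottom dinucleotide 3'->5'
category	stack	dH_kcal_mol	dS_cal_mol_K	dG37_kcal_mol
init	init	0.00	0.00	0.0000
init	init_A/T	2.30	4.10	1.0284
init	init_G/C	0.10	-2.80	0.9684
init	init_oneG/C	0.00	0.00	0.0000
init	init_allA/T	0.00	0.00	0.0000
init	init_5T/A	0.00	0.00	0.0000
init	sym	0.00	-1.40	0.4342
wc	AA/TT	-7.90	-22.20	-1.0147
wc	AT/TA	-7.20	-20.40	-0.8729
wc	TA/AT	-7.20	-21.30	-0.5938
wc	CA/GT	-8.50	-22.70	-1.4596
wc	GT/CA	-8.40	-22.40	-1.4526
wc	CT/GA	-7.80	-21.00	-1.2869
wc	GA/CT	-8.20	-22.20	-1.3147
wc	CG/GC	-10.60	-27.20	-2.1639
wc	GC/CG	-9.80	-24.40	-2.2323
wc	GG/CC	-8.00	-19.90	-1.8280
mismatch	AG/TT	1.00	0.90	0.7209
mismatch	AT/TG	-2.50	-8.30	0.0742
mismatch	CG/GT	-4.10	-11.70	-0.4712
mismatch	CT/GG	-2.80	-8.00	-0.3188
mismatch	GG/CT	3.30	10.40	0.0744
mismatch	GG/TT	5.80	16.30	0.7446
mismatch	GT/CG	-4.40	-12.30	-0.5852
mismatch	GT/TG	4.10	9.50	1.1536
mismatch	TG/AT	-0.10	-1.70	0.4273
mismatch	TG/GT	-1.40	-6.20	0.5229
mismatch	TT/AG	-1.30	-5.30	0.3438
mismatch	AA/TG	-0.60	-2.30	0.1133
mismatch	AG/TA	-0.70	-2.30	0.0133
mismatch	CA/GG	-0.70	-2.30	0.0133
mismatch	CG/GA	-4.00	-13.20	0.0940
mismatch	GA/CG	-0.60	-1.00	-0.2898
mismatch	GG/CA	0.50	3.20	-0.4925
mismatch	TA/AG	0.70	0.70	0.4829
mismatch	TG/AA	3.00	7.40	0.7049
mismatch	AC/TT	0.70	0.20	0.6380
mismatch	AT/TC	-1.20	-6.20	0.7229
mismatch	CC/GT	-0.80	-4.50	0.5957
mismatch	CT/GC	-1.50	-6.10	0.3919
mismatch	GC/CT	2.30	5.40	0.6252
mismatch	GT/CC	5.20	13.50	1.0130
mismatch	TC/AT	1.20	0.70	0.9829
mismatch	TT/AC	1.00	0.70	0.7829
mismatch	AA/TC	2.30	4.60	0.8733
mismatch	AC/TA	5.30	14.60	0.7718
mismatch	CA/GC	1.90	3.70	0.7524
mismatch	CC/GA	0.60	-0.60	0.7861
mismatch	GA/CC	5.20	14.20	0.7959
mismatch	GC/CA	-0.70	-3.80	0.4786
mismatch	TA/AC	3.40	8.00	0.9188
mismatch	TC/AA	7.60	20.20	1.3350
mismatch	AA/TA	1.20	1.70	0.6727
mismatch	CA/GA	-0.90	-4.20	0.4026
mismatch	GA/CA	-2.90	-9.80	0.1395
mismatch	TA/AA	4.70	12.90	0.6991
mismatch	AC/TC	0.00	-4.40	1.3647
mismatch	CC/GC	-1.50	-7.20	0.7331
mismatch	GC/CC	3.60	8.90	0.8397
mismatch	TC/AC	6.10	16.40	1.0135
mismatch	AG/TG	-3.10	-9.50	-0.1536
mismatch	CG/GG	-4.90	-15.30	-0.1547
mismatch	GG/CG	-6.00	-15.80	-1.0996
mismatch	TG/AG	1.60	3.60	0.4835
mismatch	AT/TT	-2.70	-10.80	0.6496
mismatch	CT/GT	-5.00	-15.80	-0.0996
mismatch	GT/CT	-2.20	-8.40	0.4053
mismatch	TT/AT	0.20	-1.50	0.6652
mismatch	AI/TC	-8.90	-25.50	-0.9912
mismatch	TI/AC	-5.90	-17.40	-0.5034
mismatch	AC/TI	-8.80	-25.40	-0.9222
mismatch	TC/AI	-4.90	-13.90	-0.5889
mismatch	CI/GC	-5.40	-13.70	-1.1509
mismatch	GI/CC	-6.80	-19.10	-0.8761
mismatch	CC/GI	-8.30	-23.80	-0.9184
mismatch	GC/CI	-5.00	-12.60	-1.0921
mismatch	AI/TA	-8.30	-25.00	-0.5463
mismatch	TI/AA	-3.40	-11.20	0.0737
mismatch	AA/TI	-0.70	-2.60	0.1064
mismatch	TA/AI	-1.30	-4.60	0.1267
mismatch	CI/GA	2.60	8.90	-0.1603
mismatch	GI/CA	-7.80	-21.10	-1.2558
mismatch	CA/GI	-7.00	-20.00	-0.7970
mismatch	GA/CI	-7.60	-20.20	-1.3350
mismatch	AI/TT	0.49	-0.70	0.7071
mismatch	TI/AT	-6.50	-22.00	0.3233
mismatch	AT/TI	-5.60	-18.70	0.1998
mismatch	TT/AI	-0.80	-4.30	0.5336
mismatch	CI/GT	-1.00	-2.40	-0.2556
mismatch	GI/CT	-3.50	-10.60	-0.2124
mismatch	CT/GI	0.10	-1.00	0.4102
mismatch	GT/CI	-4.30	-12.10	-0.5472
mismatch	AI/TG	-4.90	-15.80	0.0004
mismatch	TI/AG	-1.90	-8.50	0.7363
mismatch	AG/TI	0.10	-1.80	0.6583
mismatch	TG/AI	1.00	1.00	0.6899
mismatch	CI/GG	7.10	21.30	0.4938
mismatch	GI/CG	-1.10	-3.20	-0.1075
mismatch	CG/GI	5.80	16.90	0.5585
mismatch	GG/CI	-7.60	-22.00	-0.7767
mismatch	AI/TI	-3.30	-11.90	0.3908
mismatch	TI/AI	0.10	-2.30	0.8133
mismatch	CI/GI	1.30	3.00	0.3696
mismatch	GI/CI	-0.50	-1.30	-0.0968
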