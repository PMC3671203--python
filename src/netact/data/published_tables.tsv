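# Published k-means 2x2 contingency tables (module-activity feature set) for two
# breast-cancer and two ovarian-cancer cohorts, with the p-values printed in the
# original report.  Counts are cluster-1 / cluster-2 tallies per category.
# `verified` marks rows whose printed p-value is reproduced from the printed
# counts by a Yates-corrected chi-square test to 3 significant figures; the
# ovarian_2 stage row is internally inconsistent in print (no corrected or
# uncorrected chi-square on its counts yields the printed p) and is flagged.
dataset	annotation	category_a	category_b	a1	a2	b1	b2	printed_p	verified
breast_1	ER	neg	pos	19	33	43	18	6.14E-04	true
breast_1	HER2	neg	pos	46	39	16	12	9.52E-01	true
breast_1	grade	low	high	28	18	34	33	3.84E-01	true
breast_2	ER	neg	pos	29	24	44	48	5.31E-01	true
breast_2	HER2	neg	pos	53	54	20	18	8.89E-01	true
breast_2	grade	low	high	30	35	43	37	4.58E-01	true
ovarian_1	type	malignant	LMP	117	144	11	6	1.80E-01	true
ovarian_1	stage	high	low	100	137	28	13	3.43E-03	true
ovarian_1	grade	high	low	118	141	10	9	7.20E-01	true
ovarian_2	type	malignant	LMP	28	30	16	9	2.81E-01	true
ovarian_2	stage	high	low	34	30	10	9	8.23E-01	false
ovarian_2	grade	high	low	29	29	15	10	5.50E-01	true
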