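subgenome	chromosome	length_bp	gap_count	gap_length_bp
A	A.mon-A01	118283061	1961	12923146
A	A.mon-A02	84409872	1598	13652890
A	A.mon-A03	123011103	2089	18448429
A	A.mon-A04	106244467	2020	15031534
A	A.mon-A05	123320146	1950	15552662
A	A.mon-A06	98474784	1770	11764791
A	A.mon-A07	72108480	1299	7250302
A	A.mon-A08	39681652	442	1898702
A	A.mon-A09	107717523	1889	11324084
A	A.mon-A10	100634791	1847	13895555
A	Un-chr	61870352	422	7811614
B	A.mon-B01	140073190	2773	17354378
B	A.mon-B02	124915013	2271	14941271
B	A.mon-B03	160549902	2512	18727668
B	A.mon-B04	147957427	2521	16939677
B	A.mon-B05	121568645	2396	14347666
B	A.mon-B06	154488041	2644	22222939
B	A.mon-B07	136067974	2462	15804193
B	A.mon-B08	138850997	2492	17429178
B	A.mon-B09	163848611	2991	16573361
B	A.mon-B10	147468805	2693	18369757
B	Un-chr	49370401	428	7142698
unknown	-	103005886	972	16282706
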