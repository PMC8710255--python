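# qseqid	sseqid	pident	length	qstart	qend	sstart	send	evalue	bitscore	qframe
Contig_1	Reference_1::psaA	92.0	100	101	400	1	100	1e-55	210.0	+2
Contig_1	Reference_1::psaB	90.0	117	350	700	1	117	1e-50	195.0	-1
Contig_1	Reference_1::psbA	88.0	66	801	1000	10	75	1e-40	150.0	+2
Contig_1	Reference_1::psbB	85.0	66	1101	1300	5	70	1e-35	140.0	+2
Contig_1	Reference_1::psbC	83.0	66	1401	1600	1	66	1e-30	120.0	-3
Contig_2	Reference_1::atpA	91.0	66	101	300	1	66	1e-45	180.0	+2
Contig_2	Reference_1::atpB	90.0	66	401	600	1	66	1e-44	175.0	+2
Contig_2	Reference_1::atpI	89.0	66	701	900	1	66	1e-41	160.0	-2
Contig_2	Reference_1::petA	88.0	66	1001	1200	1	66	1e-39	155.0	+2
Contig_2	Reference_1::petB	95.0	100	1301	1600	1	100	1e-60	220.0	+2
Contig_2	Reference_1::rbcL	93.0	100	1350	1650	1	100	1e-52	200.0	+3
Contig_2	Reference_1::rpl2	92.0	100	1400	1700	1	100	1e-48	190.0	-1
Contig_2	Reference_1::psbD	61.0	100	1450	1750	1	100	1e-20	90.0	+2
Contig_2	Reference_2::psaA	80.0	66	101	300	1	66	1e-33	130.0	+2
Contig_2	Reference_2::psbA	79.0	66	501	700	1	66	1e-31	125.0	+2
Contig_2	Reference_2::rbcL	76.0	66	901	1100	1	66	1e-27	110.0	-1
Contig_1	Reference_3::psaA	84.0	66	101	300	1	66	1e-42	170.0	+2
Contig_1	Reference_3::psbA	84.0	66	501	700	1	66	1e-41	165.0	+2
Contig_1	Reference_3::atpA	82.0	66	901	1100	1	66	1e-38	150.0	+3
Contig_1	Reference_3::rbcL	81.0	66	1301	1500	1	66	1e-36	145.0	+2
Contig_2	Reference_3::petB	72.0	66	201	400	1	66	1e-22	100.0	+2
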