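# regsp gene search report | stage=sorted
# hsp source: fixture
>Contig_1 [reference Reference_1] genes=5
gene=psaA
qstart=101 qend=400 alen=100 bitscore=210 evalue=1e-55 frame=+2
gene=psaB
qstart=350 qend=700 alen=117 bitscore=195 evalue=1e-50 frame=-1
gene=psbA
qstart=801 qend=1000 alen=66 bitscore=150 evalue=1e-40 frame=+2
gene=psbB
qstart=1101 qend=1300 alen=66 bitscore=140 evalue=1e-35 frame=+2
gene=psbC
qstart=1401 qend=1600 alen=66 bitscore=120 evalue=1e-30 frame=-3

>Contig_2 [reference Reference_1] genes=7
gene=petB
qstart=1301 qend=1600 alen=100 bitscore=220 evalue=1e-60 frame=+2
gene=rbcL
qstart=1350 qend=1650 alen=100 bitscore=200 evalue=1e-52 frame=+3
gene=rpl2
qstart=1400 qend=1700 alen=100 bitscore=190 evalue=1e-48 frame=-1
gene=atpA
qstart=101 qend=300 alen=66 bitscore=180 evalue=1e-45 frame=+2
gene=atpB
qstart=401 qend=600 alen=66 bitscore=175 evalue=1e-44 frame=+2
gene=atpI
qstart=701 qend=900 alen=66 bitscore=160 evalue=1e-41 frame=-2
gene=petA
qstart=1001 qend=1200 alen=66 bitscore=155 evalue=1e-39 frame=+2

>Contig_2 [reference Reference_2] genes=3
gene=psaA
qstart=101 qend=300 alen=66 bitscore=130 evalue=1e-33 frame=+2
gene=psbA
qstart=501 qend=700 alen=66 bitscore=125 evalue=1e-31 frame=+2
gene=rbcL
qstart=901 qend=1100 alen=66 bitscore=110 evalue=1e-27 frame=-1

>Contig_1 [reference Reference_3] genes=4
gene=psaA
qstart=101 qend=300 alen=66 bitscore=170 evalue=1e-42 frame=+2
gene=psbA
qstart=501 qend=700 alen=66 bitscore=165 evalue=1e-41 frame=+2
gene=atpA
qstart=901 qend=1100 alen=66 bitscore=150 evalue=1e-38 frame=+3
gene=rbcL
qstart=1301 qend=1500 alen=66 bitscore=145 evalue=1e-36 frame=+2

>Contig_2 [reference Reference_3] genes=1
gene=petB
qstart=201 qend=400 alen=66 bitscore=100 evalue=1e-22 frame=+2
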