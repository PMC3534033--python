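gene	members	egra_twintron	note
atpE	Maen.1,Egra.1	1
atpF	Maen.1,Egra.2	0
atpI	Maen.1,Egra.6	0
chlI	Maen.1,Egra.1	0
petB	Maen.1,Egra.1	1
psaC	Maen.1,Egra.1	0
psaC	Maen.2,Egra.2	0
psbB	Maen.1,Egra.2	0
psbC	Maen.1,Egra.2	1
psbC	Maen.2,Egra.4,Evir.1,Egym.1	1
psbK	Maen.1,Egra.2	1
psbT	Maen.1,Egra.1	1
rpl12	Maen.1,Egra.1,Elon.1	0
rpl14	Maen.1,Egra.1,Elon.1	0
rpl16	Maen.2,Egra.3,Elon.3	1
rpoC1	Maen.1,Egra.1,Elon.1	1
rpoC1	Maen.2,Egra.2,Elon.2	0
rpoC1	Maen.3,Egra.3,Elon.3	1
rpoC1	Maen.4,Egra.4,Elon.4	0
rpoC1	Maen.6,Elon.7	0
rpoC1	Maen.7,Egra.8,Elon.8	0
rpoC1	Maen.8,Egra.9,Elon.9	0
rpoC1	Maen.9,Egra.11,Elon.11	1
rps2	Maen.1,Egra.1,Elon.1	0
rps2	Maen.2,Egra.2,Elon.2	0
rps2	Maen.3,Egra.3,Elon.3	0
rps3	Maen.1,Egra.1,Elon.1	1
rps3	Maen.2,Egra.2,Elon.2	0
rps8	Maen.1,Egra.2,Elon.2	0
rps8	Maen.2,Egra.3,Elon.3	0
rps9	Maen.1,Egra.3	0
rps9	Maen.2,Egra.5,Elon.4	0
rps9	Maen.3,Egra.6,Elon.5	0
rps11	Maen.1,Egra.1,Elon.1	0
rps11	Maen.2,Egra.2,Elon.2	0
rps14	Maen.1,Egra.1,Elon.1	0
rps18	Maen.1,Egra.1	0
rps18	Maen.2,Egra.2,Egym.1	1	possibly_unrelated_Egym
rps19	Maen.1,Egra.1,Elon.1	0
tufA	Maen.1,Egra.1,Elon.1	0
ycf4	Maen.1,Egra.1	0
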