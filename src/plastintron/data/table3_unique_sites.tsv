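site_id	note
atpB.Maen.1
atpE.Maen.2
orf240.Maen.1
psbD.Maen.1
psbD.Maen.2
rbcL.Maen.1
rpl2.Maen.1
rpl14.Maen.2
rpl16.Maen.1
rpl23.Maen.1
rpoB.Maen.1	ambiguous_near_rpoB.Evir.1
rpoC1.Maen.5
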