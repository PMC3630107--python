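# Tissue-selective induction patterns of ten negative regulators across three
# HSF1-dependent reporters: phsp70::gfp (intestine, muscle), pckb-2::gfp
# (intestine only), phsp-16.2::gfp (intestine, muscle). 1 = induction.
gene	description	hsp70_I	hsp70_M	ckb2_I	hsp16_I	hsp16_M
hsp-1	HSP70	1	1	1	1	0
daf-21	HSP90	1	1	1	0	1
cct-1	CCT/TRiC	0	1	0	0	1
pas-4	Proteasome	1	0	1	0	0
let-607	Transcription Factor	1	0	1	0	0
F38A1.8	SRP receptor alpha	1	0	1	1	0
hsp-6	HSP70 (mito)	1	0	1	0	0
C53A5.6	E3 ubiquitin ligase	1	0	1	0	0
dars-1	tRNA Synthetase	1	0	1	0	0
pyp-1	NuRF	1	0	1	1	0
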