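# Negative regulators of the heat shock response and tissue-selective
# phsp70::gfp reporter induction. S = spermatheca, I = intestine, M = muscle;
# 1 = induction, 0 = no induction.
cosmid	gene	description	S	I	M
F26D10.3	hsp-1	HSP70 Chaperone	1	1	1
C47E8.5	daf-21	HSP90 Chaperone	1	1	1
T05C12.7	cct-1	CCT/TRiC Chaperone	0	0	1
T21B10.7	cct-2	CCT/TRiC Chaperone	0	0	1
F54A3.3	cct-3	CCT/TRiC Chaperone	0	0	1
K01C8.10	cct-4	CCT/TRiC Chaperone	0	0	1
C07G2.3	cct-5	CCT/TRiC Chaperone	0	0	1
F01F1.8	cct-6	CCT/TRiC Chaperone	0	0	1
T10B5.5	cct-7	CCT/TRiC Chaperone	0	0	1
Y55F3AR.3	cct-8	CCT/TRiC Chaperone	0	0	1
R05F9.10	sgt-1	TPR cochaperone	0	0	1
F30H5.1	unc-45	TPR cochaperone	0	0	1
T01B7.4	cyn-11	Cyclophilin cochaperone	0	0	1
C36B1.4	pas-4	Proteasome 20S subunit	1	1	0
F25H2.9	pas-5	Proteasome 20S subunit	1	1	0
CD4.6	pas-6	Proteasome 20S subunit	1	1	0
C47B2.4	pbs-2	Proteasome 20S subunit	1	1	0
Y38A8.2	pbs-3	Proteasome 20S subunit	1	1	0
T20F5.2	pbs-4	Proteasome 20S subunit	1	1	0
K05C4.1	pbs-5	Proteasome 20S subunit	1	1	0
C02F5.9	pbs-6	Proteasome 20S subunit	1	1	0
F39H11.5	pbs-7	Proteasome 20S subunit	1	1	0
C52E4.4	rpt-1	Proteasome 19S subunit	1	1	0
F23F12.6	rpt-3	Proteasome 19S subunit	1	1	0
F23F1.8	rpt-4	Proteasome 19S subunit	1	1	0
F56H1.4	rpt-5	Proteasome 19S subunit	1	1	0
Y49E10.1	rpt-6	Proteasome 19S subunit	1	1	0
T22D1.9	rpn-1	Proteasome 19S subunit	1	1	0
C23G10.4	rpn-2	Proteasome 19S subunit	1	1	0
F57B9.10	rpn-6	Proteasome 19S subunit	1	1	0
F49C12.8	rpn-7	Proteasome 19S subunit	1	1	0
R12E2.3	rpn-8	Proteasome 19S subunit	1	1	0
K07D4.3	rpn-11	Proteasome 19S subunit	1	1	0
F57B10.1	let-607	Transcription Factor (ER)	1	1	0
C15H9.6	hsp-3	HSP70 Chaperone (ER)	1	1	0
F38A1.8		SRP receptor alpha subunit	1	1	0
R186.3		SRP receptor beta subunit	1	1	0
F55C5.8		SRP subunit	1	1	0
F08D12.1		SRP subunit	0	1	0
F25G6.8		SRP subunit	0	1	0
F38E11.5		COPI beta' subunit	0	1	0
T14G10.5		COPI gamma subunit	0	1	0
T24H7.2		HSP70 Chaperone (ER)	0	1	0
C37H5.8	hsp-6	HSP70 Chaperone (mito)	0	1	0
T09B4.9		TIM44 subunit (mito)	0	1	0
C47E12.5	uba-1	E1 ubiquitin ligase	0	1	0
F52C6.3	phi-32	Ubiquitin	0	1	0
C53A5.6		E3 ubiquitin ligase	0	1	0
B0464.1	dars-1	Asp tRNA Synthetase	0	1	0
W04A4.5		Integrator subunit	0	1	0
C47E12.4	pyp-1	NuRF subunit	0	1	0
R12B2.5	mdt-15	Mediator subunit	0	1	0
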