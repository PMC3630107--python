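# Positive regulators of the heat shock response: screen hits whose knockdown
# blocks heat-shock induction of the phsp70::gfp reporter.
cosmid	gene	description
ZK328.2	eftu-2	EF-2 like
C26C6.5	dcp-66	NuRD subunit
F09D1.1	F09D1.1	USP39
T08A11.2	phi-11	Splicing Factor 3B, subunit 1
T13H5.4	phi-8	Splicing Factor 3A, subunit 3
T28D9.10	snr-3	SNRPD1
Y53C10A.12	hsf-1	Heat Shock Factor
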