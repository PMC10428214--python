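protein	ligand	ki_nM	ki_err_nM
WT	TMP	4.2	0.5
WT	4DTMP	5.1	1.0
L28R	TMP	65.0	7.5
L28R	4DTMP	34.3	2.9
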