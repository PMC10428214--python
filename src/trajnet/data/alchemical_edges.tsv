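protein	transformation	dg_kcal_mol	dg_err_kcal_mol
WT	TMP->4DTMP	-3.2	0.3
L28R	TMP->4DTMP	-3.4	0.4
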