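pdb_id	protein_name	n_sites	n_correct	null_p
2GLS	glutamine synthetase (E. coli)	15	13	0.5
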