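label	rise	twist	symmetry
VLP_r	43.2	13.78	8
VLP_h	5.88	-48.11	1
VLP_h_RNA	3.97	-40.96	1
VLP_dC40_r	43.29	15.04	8
VLP_dC40_h_RNA	4.05	-41.05	1
VLP_dC60_h	4.65	-46.36	1
VLP_dC79_h	4.70	-46.47	1
trCP_H2T	39.30	-3.59	8
VLP_T43C_D136C	4.01	-41.00	1
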