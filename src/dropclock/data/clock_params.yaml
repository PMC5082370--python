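# Calibrated default parameters of the stochastic clock network.
# Units: rates 1/h (k_WCC, k_inact: 1/(molecule*h)); K_* in molecules;
# n_* dimensionless Hill exponents; init_* molecule counts.
# Calibration (fixed seed): deterministic mirror tuned to a 21.0 h limit
# cycle; ccg-2 mRNA mean ~129 molecules/cell; CCG-2 protein mean ~264.
K_act: 30.0
K_rep: 80.0
n_act: 2.0
n_rep: 6.0
k_gene_on: 1.0098957788791265
k_gene_off: 0.25247394471978163
k_tx_frq: 50.49478894395633
d_mrna_frq: 0.37871091707967247
k_tl_frq: 0.7574218341593449
d_FRQ: 0.31559243089972705
k_tx_wc1: 50.49478894395633
d_mrna_wc1: 0.37871091707967247
k_tl_wc1: 0.7574218341593449
d_WC1: 0.31559243089972705
k_WC2: 31.559243089972703
d_WC2: 0.31559243089972705
k_WCC: 0.0037871091707967247
d_WCC: 0.37871091707967247
k_inact: 0.0006311848617994541
k_tx_ccg2: 183.35754850088182
d_mrna_ccg2: 0.4418294032596179
k_tl_ccg2: 0.6311848617994541
d_CCG2: 0.3080182125581336
init_frq_mrna: 41
init_FRQ: 99
init_wc1_mrna: 35
init_WC1: 49
init_WC2: 65
init_WCC: 24
init_ccg2_mrna: 129
init_CCG2: 264
_log_scale:
- k_tx_frq
- k_tx_wc1
- k_tx_ccg2
- d_mrna_frq
- d_mrna_wc1
- d_mrna_ccg2
- k_tl_frq
- k_tl_wc1
- k_tl_ccg2
- d_FRQ
- d_WC1
- d_WC2
- d_WCC
- d_CCG2
- k_WC2
- k_WCC
- k_inact
- k_gene_on
- k_gene_off
- K_act
- K_rep
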