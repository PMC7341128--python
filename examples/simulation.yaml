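# F2 simulation experiment at reduced scale (full scale: 50 families,
# 5 scenarios x 3 architectures, cdmean_iters 3000)
experiment: simulation
seed: 5
output_dir: results/simulation
map: {n_markers: 356, n_linkage_groups: 19, length_cm: 150}
panels: {n_a: 300, n_b: 300, n_subpops: 3, fst: 0.25, divergence: 0.3}
families: {n_families: 10, n_f1: 50, n_f2: 216}
trait:
  scenarios: [S.QTN, D.QTN.Msi]
  architectures: [A20D0E0]
model: {q_pcs: 7, subset_size: 200, cdmean_iters: 3000}
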