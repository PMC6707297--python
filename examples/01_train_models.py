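"""Train prior-informed expression models on a small simulated tissue.

Simulates a 30-gene panel, estimates SNP priors from the panel's own eQTL
scan plus the planted epigenomic annotation, maps them to penalty factors,
and trains the weighted elastic net against the uniform-penalty baseline on
shared cross-validation folds.
"""

import numpy as np

import epitwas as et
from epitwas.pipeline import panel_prior_table

cfg = et.SimulationConfig(n_samples=500, annotation_enrichment=5.0, seed=7)
panel = et.simulate_gene_panel(cfg, 30, seed=7, level=1.0)

priors, model, _ = panel_prior_table(panel, seed=7)
print(f"annotation weight gamma = {model.gamma[0]:.2f} "
      f"(planted log-odds = {np.log(cfg.annotation_enrichment):.2f}), "
      f"EM iterations = {model.n_iter}")

rescaler = et.BezierRescaler(w_min=0.1, x1=0.5)
pmap = {g: grp["prior"].to_numpy() for g, grp in priors.groupby("gene_id")}

deltas = []
for g in panel:
    v = et.bezier_penalty(rescaler, pmap[g["gene_id"]])
    _, perf_w = et.nested_cv_train(g["G"].dosages, g["y"], v, seed=1)
    _, perf_u = et.nested_cv_train(g["G"].dosages, g["y"],
                                   np.ones(g["G"].n_snps), seed=1)
    deltas.append(perf_w.r2_cv - perf_u.r2_cv)

rep = et.compare_methods(np.array(deltas), np.zeros(len(deltas)))
print(f"mean delta R2_CV (prior-informed - uniform) = {np.mean(deltas):+.4f}")
print(f"genes improved/worsened = {rep['n_pos']}/{rep['n_neg']}, "
      f"one-sided sign test p = {rep['sign_p']:.3g}")
# A positive mean delta with a small sign-test p says the epigenome-informed
# penalties systematically improve cross-validated prediction accuracy.
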