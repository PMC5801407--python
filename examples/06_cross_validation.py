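"""Cross-validation designs: what limits predictive ability?

LOO keeps maximal training size and relatedness; LFO removes all lines
sharing a parent with the validation family; LSO predicts one breeding
cycle from the other; k-fold varies training size only.  Predictive
ability is corr(corrected phenotype, GEBV); the bias slope should sit
near 1.
"""

from granos import design_matrix, plan_folds, profile_config, qc_filter, \
    run_cv, simulate_population

cfg = profile_config("tiny", seed=7)
g, pheno, truth, _ = simulate_population(cfg)
g, _ = qc_filter(g)
X, _ = design_matrix(pheno.set_factor)

schemes = {
    "loo": dict(),
    "lfo": dict(pedigree=pheno),
    "lso": dict(set_factor=pheno.set_factor),
    "kfold": dict(k=5, seed=1),
}
print(f"{'scheme':<8}{'r':>7}{'slope':>8}{'h_max':>8}")
for scheme, kw in schemes.items():
    plan = plan_folds(scheme, g.line_ids, **kw)
    res = run_cv(plan, "gblup", pheno.y, X, g, min_train=5)
    print(f"{scheme:<8}{res.predictive_ability:>7.2f}"
          f"{res.bias_slope:>8.2f}{res.h_max:>8.2f}")
# Expect r(LOO) >= r(LFO) >= r(LSO): losing relatives from the training
# set costs more accuracy than losing training lines per se.
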