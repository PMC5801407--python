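"""Marker QC, the VanRaden relationship matrix, PCA and genetic distances.

QC drops over-missing then low-MAF markers; G = Z2 Z2'/(2 sum p(1-p)) on the
centered 1/0/-1 coding; PCA of G summarizes family/set structure; the
modified Rogers' distance puts pairwise divergence on a [0, 1] scale.
"""

from granos import (
    pca_g,
    profile_config,
    qc_filter,
    rogers_distance,
    simulate_population,
    vanraden_g,
)

cfg = profile_config("tiny", seed=7)
g, pheno, truth, _ = simulate_population(cfg)

g_qc, report = qc_filter(g, maf_min=0.01, miss_max=0.10)
print(f"QC: {report.n_input} markers in, {report.n_dropped_missing} dropped "
      f"for missingness, {report.n_dropped_maf} for MAF, {report.n_kept} kept")

K = vanraden_g(g_qc)
print(f"G-matrix: {K.n_lines} lines, avg diagonal d(G) = {K.avg_diag:.3f} "
      f"(inbred lines push the diagonal toward 2)")

scores, shares = pca_g(K)
print(f"PC1/PC2 variance shares: {shares[0]:.1%} / {shares[1]:.1%} "
      f"(sets overlap, so PC1 stays well under 50%)")

D, summ = rogers_distance(g_qc, set_factor=pheno.set_factor)
print("modified Rogers' distance:",
      {k: round(v, 3) for k, v in summ.items()})
# Within-set means just below the between-set mean mirror two related
# breeding cycles drawn from a shared parent pool.
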