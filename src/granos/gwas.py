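"""Single-marker mixed-model GWAS with LOCO correction and genomic control.

Each SNP i is tested in y = Xb + w_i a_i + u + e, where w_i is the marker's
1/0/-1 coding (heterozygotes and missing calls contribute 0) and the
polygenic term u ~ N(0, G_loco s2g) uses the relationship matrix built from
every chromosome except the tested SNP's (unmapped SNPs fall back to the
full-genome matrix, flagged in the output).  Null variance components are
estimated once per chromosome and reused across that chromosome's SNPs;
an exact per-SNP REML refit is available for verification.

The Wald statistic chi2 = (a_hat / SE)^2 feeds the genomic inflation factor
lambda_IF = median(chi2) / median(Chi2_1); if lambda_IF > 1 every statistic
is divided by it before p-values are recomputed (genomic control).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import reml_fit
from .io import MISSING, UNMAPPED, GenotypeMatrix, GranosError
from .kinship import KinshipMatrix

logger = logging.getLogger("granos")

#: median of the chi-squared distribution with one degree of freedom
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, df=1))


def bonferroni(alpha: float, m_tests: int) -> float:
    """Genome-wide per-test significance threshold alpha / m."""
    if m_tests < 1:
        raise GranosError("m_tests must be at least 1")
    return alpha / m_tests


def genomic_control(chi2: np.ndarray) -> tuple[float, np.ndarray]:
    """Inflation factor and corrected p-values.

    lambda_IF = median(chi2)/median(Chi2_1); statistics are divided by
    lambda_IF only when it exceeds 1, then p-values are recomputed from
    Chi2_1.
    """
    chi2 = np.asarray(chi2, dtype=float)
    finite = chi2[np.isfinite(chi2)]
    if finite.size == 0:
        raise GranosError("no finite chi-squared statistics")
    lam = float(np.median(finite) / CHI2_1_MEDIAN)
    corrected = chi2 / lam if lam > 1 else chi2
    p_gc = stats.chi2.sf(corrected, df=1)
    return lam, p_gc


def scan(
    y: np.ndarray,
    X: np.ndarray,
    g: GenotypeMatrix,
    loco_gs: dict[str, KinshipMatrix],
    exact: bool = False,
    higher_is_better: bool = True,
) -> pd.DataFrame:
    """Mixed-model association scan over every SNP in ``g``.

    Returns a frame with columns snp_id, chrom, a_hat, se_a, chi2, p_raw,
    p_gc, var_explained, advantageous_allele_freq, unmapped_correction; the
    frame's ``attrs`` carry ``lambda_if`` and the full-scan sigma_g2.
    Monomorphic SNPs get NA rows.
    """
    y = np.asarray(y, dtype=float)
    n, m = g.n_lines, g.m
    chroms_present = sorted(set(g.chrom))
    for c in chroms_present:
        key = c if c in loco_gs else None
        if key is None and c != UNMAPPED:
            raise GranosError(f"no LOCO kinship matrix for chromosome {c}")
    if UNMAPPED in chroms_present and UNMAPPED not in loco_gs:
        raise GranosError("unmapped SNPs present but no full-genome matrix "
                          "under the 'unmapped' key")

    W = g.dosage.astype(float) - 1.0
    W[g.dosage == MISSING] = 0.0

    a_hat = np.full(m, np.nan)
    se_a = np.full(m, np.nan)
    sg2_by_chrom: dict[str, float] = {}
    for c in chroms_present:
        idx = np.where(g.chrom == c)[0]
        K = loco_gs[c]
        fit0 = reml_fit(y, X, K, compute_se=False)
        sg2_by_chrom[c] = fit0.sigma_g2
        if exact:
            for j in idx:
                w = W[:, [j]]
                if np.ptp(w) == 0:
                    continue
                Xa = np.hstack([X, w])
                if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
                    continue
                fitj = reml_fit(y, Xa, K, compute_se=False)
                a, s = _gls_marker(
                    y, X, w[:, 0], K, fitj.sigma_g2, fitj.sigma_e2
                )
                a_hat[j], se_a[j] = a, s
        else:
            a_sub, s_sub = _gls_markers_vectorized(
                y, X, W[:, idx], K, fit0.sigma_g2, fit0.sigma_e2
            )
            a_hat[idx], se_a[idx] = a_sub, s_sub

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (a_hat / se_a) ** 2
    p_raw = stats.chi2.sf(chi2, df=1)
    lam, p_gc_full = genomic_control(chi2)

    # variance explained relative to the full-genome additive variance
    full_key = UNMAPPED if UNMAPPED in loco_gs else None
    if full_key is not None:
        sg2_full = sg2_by_chrom.get(UNMAPPED)
        if sg2_full is None:
            sg2_full = reml_fit(y, X, loco_gs[full_key], compute_se=False).sigma_g2
    else:
        sg2_full = float(np.mean(list(sg2_by_chrom.values())))
    p_freq = g.counted_freq()
    var_exp = variance_explained(a_hat, p_freq, sg2_full) if sg2_full > 0 \
        else np.full(m, np.nan)

    adv_freq = np.where(
        (a_hat > 0) == bool(higher_is_better), p_freq, 1.0 - p_freq
    )
    adv_freq[~np.isfinite(a_hat)] = np.nan

    res = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chrom": g.chrom,
            "a_hat": a_hat,
            "se_a": se_a,
            "chi2": chi2,
            "p_raw": p_raw,
            "p_gc": p_gc_full,
            "var_explained": var_exp,
            "advantageous_allele_freq": adv_freq,
            "unmapped_correction": g.chrom == UNMAPPED,
        }
    )
    n_mono = int((~np.isfinite(a_hat)).sum())
    if n_mono:
        logger.info("scan produced %d NA rows (monomorphic/aliased SNPs)", n_mono)
    res.attrs["lambda_if"] = lam
    res.attrs["sigma_g2_full"] = sg2_full
    res.attrs["sigma_g2_by_chrom"] = sg2_by_chrom
    return res


def _whiten(K: KinshipMatrix, sg2: float, se2: float):
    d, U = np.linalg.eigh(K.G)
    d = np.clip(d, 0.0, None)
    v = sg2 * d + se2
    return U, 1.0 / np.sqrt(v)


def _gls_markers_vectorized(y, X, Wsub, K, sg2, se2):
    """GLS slope and SE for each column of Wsub under V = sg2 G + se2 I."""
    U, s = _whiten(K, sg2, se2)
    yt = (U.T @ y) * s
    Xt = (U.T @ X) * s[:, None]
    Wt = (U.T @ Wsub) * s[:, None]
    # residualize on the fixed effects (whitened projection)
    Q, _ = np.linalg.qr(Xt)
    yr = yt - Q @ (Q.T @ yt)
    Wr = Wt - Q @ (Q.T @ Wt)
    denom = np.sum(Wr * Wr, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (Wr.T @ yr) / denom
        se = np.where(denom > 1e-12, 1.0 / np.sqrt(denom), np.nan)
    a[denom <= 1e-12] = np.nan
    return a, se


def _gls_marker(y, X, w, K, sg2, se2):
    a, se = _gls_markers_vectorized(y, X, w[:, None], K, sg2, se2)
    return float(a[0]), float(se[0])


def variance_explained(
    a_hat: np.ndarray, p: np.ndarray, sigma_g2: float
) -> np.ndarray:
    """Fraction of additive genetic variance at a marker: 2p(1-p)a^2 / s2g.

    Values above 1 are clipped with a warning (estimation noise can push a
    single-marker estimate past the total).
    """
    if sigma_g2 <= 0:
        raise GranosError("sigma_g2 must be positive")
    frac = 2.0 * p * (1.0 - p) * np.asarray(a_hat, dtype=float) ** 2 / sigma_g2
    if np.nanmax(frac, initial=0.0) > 1.0:
        logger.warning("variance_explained clipped at 1 for some SNPs")
    return np.clip(frac, None, 1.0)


def genotype_class_means(
    y: np.ndarray, g: GenotypeMatrix, snp_ids
) -> pd.DataFrame:
    """Phenotype means per homozygous genotype class for the given SNPs.

    Single SNPs produce per-SNP rows (classes 0 and 2 plus a separate het
    row); with several SNPs the joint homozygous classes are also listed.
    Empty classes get NaN means with count 0.
    """
    y = np.asarray(y, dtype=float)
    idx = g.snp_index(snp_ids)
    rows = []
    for j, sid in zip(idx, snp_ids):
        d = g.dosage[:, j]
        for label, mask in (
            ("0", d == 0), ("2", d == 2), ("het", d == 1),
        ):
            sel = y[mask]
            rows.append(
                {"snp_id": sid, "class": label,
                 "mean": float(sel.mean()) if sel.size else np.nan,
                 "n_lines": int(sel.size)}
            )
    if len(idx) > 1:
        D = g.dosage[:, idx]
        homo = (D != 1).all(axis=1) & (D != MISSING).all(axis=1)
        joint = ["/".join(str(int(v)) for v in D[i]) for i in range(len(y))]
        joint = np.asarray(joint, dtype=object)
        for combo in sorted(set(joint[homo])):
            mask = homo & (joint == combo)
            sel = y[mask]
            rows.append(
                {"snp_id": "+".join(map(str, snp_ids)), "class": combo,
                 "mean": float(sel.mean()) if sel.size else np.nan,
                 "n_lines": int(sel.size)}
            )
    return pd.DataFrame(rows)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional alternative to Bonferroni)."""
    from statsmodels.stats.multitest import multipletests

    finite = np.isfinite(p)
    out = np.full_like(np.asarray(p, dtype=float), np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out
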