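"""Marker QC, VanRaden genomic relationship matrices, distances and PCA.

The relationship matrix follows VanRaden's first method,

    G = Z2 Z2' / (2 * sum_i p_i (1 - p_i)),

where Z2 = M - P, M holds marker alleles coded 1/0/-1 with missing calls set
to 0, and P's columns are 2(p_i - 0.5) with p_i the counted-allele
frequency.  Leave-one-chromosome-out (LOCO) matrices omit one chromosome's
markers entirely; they feed the structure correction of the GWAS so the
tested SNP's chromosome does not enter the polygenic term twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix, GranosError, ValidationError


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix with its average diagonal.

    ``excluded_chrom`` records which chromosome's markers were omitted
    (None for the full-genome matrix); ``marker_count_used`` the number of
    markers that contributed.
    """

    line_ids: np.ndarray
    G: np.ndarray
    avg_diag: float
    excluded_chrom: str | None = None
    marker_count_used: int = 0

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValidationError("kinship matrix is not symmetric")

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]

    def subset(self, idx: np.ndarray) -> "KinshipMatrix":
        """Submatrix for the given line indices (avg_diag recomputed)."""
        G = self.G[np.ix_(idx, idx)]
        return KinshipMatrix(
            np.asarray(self.line_ids)[idx], G, float(np.diag(G).mean()),
            self.excluded_chrom, self.marker_count_used,
        )


@dataclass
class QcReport:
    n_input: int
    n_dropped_missing: int
    n_dropped_maf: int
    n_kept: int


def qc_filter(
    g: GenotypeMatrix, maf_min: float = 0.01, miss_max: float = 0.10
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop over-missing markers, then low-MAF markers among the survivors.

    The sequential order makes the two dropped counts disjoint: a marker
    failing both filters is charged to the missingness filter only.
    """
    miss_frac = g.missing_mask.mean(axis=0)
    keep1 = miss_frac <= miss_max
    n_missing = int((~keep1).sum())
    g1 = g.subset_snps(keep1)
    maf = g1.compute_maf()
    keep2 = np.nan_to_num(maf, nan=-1.0) >= maf_min
    n_maf = int((~keep2).sum())
    g2 = g1.subset_snps(keep2)
    if g2.m == 0:
        raise GranosError("QC removed every marker")
    report = QcReport(g.m, n_missing, n_maf, g2.m)
    return g2, report


def center_code(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Centered 1/0/-1 coding Z2 = M - P (missing -> 0 in M).

    ``freqs`` lets a caller reuse counted-allele frequencies computed on a
    reference line set (e.g. the full analysis set) when coding a subset;
    by default frequencies come from ``g`` itself.  With no missing calls a
    column of Z2 has mean exactly 0.
    """
    M = g.dosage.astype(float) - 1.0
    M[g.dosage == MISSING] = 0.0
    p = g.counted_freq() if freqs is None else np.asarray(freqs, dtype=float)
    P = 2.0 * (p - 0.5)
    return M - P[None, :]


def vanraden_denominator(freqs: np.ndarray) -> float:
    return float(2.0 * np.sum(freqs * (1.0 - freqs)))


def vanraden_g(
    g: GenotypeMatrix,
    exclude_chrom: str | None = None,
    freqs: np.ndarray | None = None,
) -> KinshipMatrix:
    """VanRaden method-one G over the included markers.

    ``exclude_chrom`` omits that chromosome's markers entirely (LOCO).
    """
    if exclude_chrom is not None:
        keep = g.chrom != exclude_chrom
        g_used = g.subset_snps(keep)
        if freqs is not None:
            freqs = np.asarray(freqs)[keep]
    else:
        g_used = g
    if g_used.m < 2:
        raise GranosError("need at least two markers for a G-matrix")
    p = g_used.counted_freq() if freqs is None else np.asarray(freqs, dtype=float)
    denom = vanraden_denominator(p)
    if denom <= 0:
        raise GranosError("all included markers are monomorphic")
    Z2 = center_code(g_used, freqs=p)
    G = (Z2 @ Z2.T) / denom
    G = 0.5 * (G + G.T)
    return KinshipMatrix(
        g.line_ids.copy(), G, float(np.diag(G).mean()),
        excluded_chrom=exclude_chrom, marker_count_used=g_used.m,
    )


def loco_matrices(
    g: GenotypeMatrix, freqs: np.ndarray | None = None
) -> dict[str, KinshipMatrix]:
    """One leave-one-chromosome-out G per chromosome present in ``g``.

    Unmapped markers always stay in; the ``unmapped`` key (present when the
    matrix has unmapped markers) maps to the full-genome G, since an unknown
    chromosome cannot be excluded.
    """
    from .io import UNMAPPED

    out: dict[str, KinshipMatrix] = {}
    for c in sorted(set(g.chrom)):
        if c == UNMAPPED:
            continue
        out[c] = vanraden_g(g, exclude_chrom=c, freqs=freqs)
    if (g.chrom == UNMAPPED).any():
        out[UNMAPPED] = vanraden_g(g, freqs=freqs)
    return out


def rogers_distance(
    g: GenotypeMatrix,
    scaling: str = "reif",
    set_factor: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Modified Rogers' distance matrix between lines.

    Default ("reif") normalization ranges over [0, 1]: per-line per-SNP
    allele frequencies are dosage/2, so

        MRD(a, b) = sqrt( sum_j (p_aj - p_bj)^2 / m ),

    equivalently the Euclidean distance on the 1/0/-1 coding divided by
    2*sqrt(m).  ``scaling="literal"`` divides the Euclidean distance by 2*m
    instead (an alternative normalization retained for comparison).
    Missing calls enter as 0 in the +-1 coding, i.e. frequency 1/2.

    Returns the distance matrix and summaries (max; with ``set_factor``,
    mean within each set and mean between sets).
    """
    if g.n_lines < 2:
        raise ValidationError("need at least two lines for distances")
    M = g.dosage.astype(float) - 1.0
    M[g.dosage == MISSING] = 0.0
    sq = np.sum(M * M, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)
    np.fill_diagonal(d2, 0.0)
    euclid = np.sqrt(np.clip(d2, 0.0, None))
    if scaling == "reif":
        D = euclid / (2.0 * np.sqrt(g.m))
    elif scaling == "literal":
        D = euclid / (2.0 * g.m)
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")
    iu = np.triu_indices(g.n_lines, k=1)
    summaries: dict = {"max": float(D[iu].max())}
    if set_factor is not None:
        set_factor = np.asarray(set_factor)
        same = set_factor[:, None] == set_factor[None, :]
        for lev in sorted(set(set_factor)):
            mask = (set_factor[:, None] == lev) & (set_factor[None, :] == lev)
            vals = D[mask & ~np.eye(g.n_lines, dtype=bool)]
            summaries[f"mean_within_{lev}"] = float(vals.mean()) if vals.size else np.nan
        between = D[~same]
        summaries["mean_between"] = float(between.mean()) if between.size else np.nan
    return D, summaries


def pca_g(K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of G: per-line component scores and variance shares.

    Components are sorted by descending eigenvalue; each eigenvector's sign
    is fixed so its largest-magnitude loading is positive; scores are
    eigenvectors scaled by sqrt(eigenvalue) (negative eigenvalues are
    clipped to zero for scaling and shares).
    """
    if not np.isfinite(K.G).all():
        raise GranosError("kinship matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh(K.G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    lam = np.clip(vals, 0.0, None)
    scores = vecs * np.sqrt(lam)[None, :]
    total = lam.sum()
    shares = lam / total if total > 0 else np.full_like(lam, np.nan)
    return scores, shares


def heterozygosity(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Per-line fraction of non-missing calls that are heterozygous.

    Lines with all calls missing get NaN; the population mean ignores them.
    """
    non_missing = (~g.missing_mask).sum(axis=1)
    hets = (g.dosage == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(non_missing > 0, hets / non_missing, np.nan)
    return frac, float(np.nanmean(frac))
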