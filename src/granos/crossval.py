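"""Cross-validation schemes and prediction metrics.

Four fold constructions:

* LOO  -- each line predicted from all the others (maximal training set and
  relatedness);
* LFO  -- leave-(half-sib)-family-out: one validation unit per crossing
  parent; the training set excludes every line sharing a parent with any
  validation line, so training and validation have no parents in common;
* LSO  -- leave-set-out: each breeding-cycle set predicted from the other;
* k-fold -- seeded random partition into k near-equal folds.

Predictive ability is the Pearson correlation between fixed-effect-corrected
phenotypes and GEBVs; dispersion bias is the slope of the regression of
corrected phenotypes on GEBVs (expectation 1).  Corrections use the
training-fold fixed-effect estimates by default (no leakage from validation
phenotypes); full-data correction is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import heritability, predict_unphenotyped, reml_fit
from .io import GenotypeMatrix, GranosError, PhenotypeTable
from .kinship import vanraden_g
from . import powerlasso

logger = logging.getLogger("granos")

SCHEMES = ("loo", "lfo", "lso", "kfold")


@dataclass
class FoldUnit:
    name: str
    val_idx: np.ndarray
    train_idx: np.ndarray


@dataclass
class FoldPlan:
    scheme: str
    units: list[FoldUnit]
    line_ids: np.ndarray
    k: int | None = None
    seed: int | None = None
    family_key: dict | None = None  # line -> retained LFO unit name

    def __post_init__(self):
        for unit in self.units:
            if np.intersect1d(unit.val_idx, unit.train_idx).size:
                raise GranosError(
                    f"fold {unit.name}: validation and training overlap"
                )


@dataclass
class CvResult:
    scheme: str
    predictions: pd.DataFrame  # line, fold, gebv, y_corr
    predictive_ability: float
    bias_slope: float
    bias_se: float
    h_max: float
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_skipped_folds: int = 0


def plan_folds(
    scheme: str,
    lines: np.ndarray,
    pedigree: PhenotypeTable | None = None,
    set_factor: np.ndarray | None = None,
    k: int | None = None,
    seed: int | None = None,
    family_unit: str = "halfsib",
) -> FoldPlan:
    """Build the validation/training index sets for a CV scheme.

    ``family_unit`` governs LFO: ``halfsib`` (default) makes one validation
    unit per crossing parent (a line is validated in its mother's and its
    father's unit; the retained prediction comes from the mother's);
    ``fullsib`` makes one unit per cross.  Either way the training set
    excludes every line sharing a parent with any validation line.
    """
    lines = np.asarray([str(x) for x in lines], dtype=object)
    n = len(lines)
    all_idx = np.arange(n)
    units: list[FoldUnit] = []
    family_key = None

    if scheme == "loo":
        units = [
            FoldUnit(str(lines[i]), np.asarray([i]), np.delete(all_idx, i))
            for i in range(n)
        ]
    elif scheme == "lfo":
        if pedigree is None or not pedigree.has_pedigree:
            raise GranosError("LFO needs mother/father ids for every line")
        ped = pedigree.subset_lines(lines)
        mother, father = ped.mother_id, ped.father_id
        family_key = {}
        if family_unit == "halfsib":
            # one unit per crossing parent; a line appears in two units
            keys = sorted(set(mother) | set(father))
            in_unit = lambda key: (mother == key) | (father == key)
            for i in range(n):
                family_key[str(lines[i])] = str(mother[i])
        elif family_unit == "fullsib":
            # one unit per cross; each line appears in exactly one unit
            crosses = [f"{m}x{f}" for m, f in zip(mother, father)]
            crosses_arr = np.asarray(crosses, dtype=object)
            keys = sorted(set(crosses))
            in_unit = lambda key: crosses_arr == key
            for i in range(n):
                family_key[str(lines[i])] = crosses[i]
        else:
            raise GranosError(f"unknown family_unit {family_unit!r}")
        for key in keys:
            val = np.where(in_unit(key))[0]
            val_parents = set(mother[val]) | set(father[val])
            train = np.asarray(
                [i for i in all_idx
                 if mother[i] not in val_parents and father[i] not in val_parents],
                dtype=int,
            )
            if train.size == 0:
                raise GranosError(
                    f"LFO unit {key!r} leaves no training lines"
                )
            units.append(FoldUnit(str(key), val, train))
    elif scheme == "lso":
        if set_factor is None:
            raise GranosError("LSO needs the set factor")
        set_factor = np.asarray(set_factor)
        levels = sorted(set(set_factor))
        if len(levels) < 2:
            raise GranosError("LSO needs at least two set levels")
        for lev in levels:
            val = np.where(set_factor == lev)[0]
            train = np.where(set_factor != lev)[0]
            units.append(FoldUnit(str(lev), val, train))
    elif scheme == "kfold":
        if k is None or k < 2:
            raise GranosError("kfold needs k >= 2")
        if k > n:
            raise GranosError(f"k={k} exceeds the number of lines ({n})")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for f, val in enumerate(folds):
            train = np.asarray(sorted(set(all_idx) - set(val)), dtype=int)
            units.append(FoldUnit(f"fold{f + 1}", np.sort(val), train))
    else:
        raise GranosError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    return FoldPlan(scheme, units, lines, k=k, seed=seed,
                    family_key=family_key)


def _drop_aliased(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    X = np.atleast_2d(X)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, list(range(X.shape[1]))
    from scipy.linalg import qr

    _, _, piv = qr(X, pivoting=True, mode="economic")
    keep = sorted(piv[:rank])
    return X[:, keep], keep


def run_cv(
    plan: FoldPlan,
    predictor_spec: str,
    y: np.ndarray,
    X: np.ndarray,
    g: GenotypeMatrix,
    refit_per_fold: bool = True,
    correction: str = "train",
    chain_cfg: "powerlasso.ChainConfig | None" = None,
    seed: int = 0,
    min_train: int = 10,
    average_parents: bool = False,
) -> CvResult:
    """Fold-wise fit/predict and pooled metrics.

    ``predictor_spec``: ``gblup`` (REML + conditional-mean BLUP) or
    ``power_lasso`` (posterior-mean SNP effects applied to the validation
    coding).  Marker frequencies for the relationship matrix are computed
    once on the full line set and reused across folds, mirroring a single
    G built for the whole panel.  In LFO, a line validated in several
    parent-keyed units keeps the prediction from its mother's unit
    (``average_parents`` averages the mother- and father-keyed ones).
    """
    if predictor_spec not in ("gblup", "power_lasso"):
        raise GranosError(f"unknown predictor {predictor_spec!r}")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)

    K_full = vanraden_g(g)
    full_fit = reml_fit(y, X, K_full, compute_se=False)
    h_max = float(np.sqrt(heritability(full_fit, K_full)))
    Z3 = powerlasso.design_Z3(g) if predictor_spec == "power_lasso" else None

    gebv_by_line: dict[str, list[tuple[str, float]]] = {}
    ycorr_by_line: dict[str, list[tuple[str, float]]] = {}
    fold_rows = []
    n_skipped = 0
    if not refit_per_fold:
        base_sg2, base_se2 = full_fit.sigma_g2, full_fit.sigma_e2

    for fold_i, unit in enumerate(plan.units):
        tr, va = unit.train_idx, unit.val_idx
        if len(tr) < min_train:
            logger.warning("fold %s skipped: only %d training lines",
                           unit.name, len(tr))
            n_skipped += 1
            continue
        X_tr, kept = _drop_aliased(X[tr])
        try:
            if predictor_spec == "gblup":
                K_tr = K_full.subset(tr)
                fit_tr = reml_fit(y[tr], X_tr, K_tr, compute_se=False)
                if not refit_per_fold:
                    fit_tr = _refit_with_components(
                        y[tr], X_tr, K_tr, base_sg2, base_se2
                    )
                gebv_val = predict_unphenotyped(fit_tr, K_full, tr, va)
                b_hat, b_cols = fit_tr.b_hat, kept
                sg2, se2 = fit_tr.sigma_g2, fit_tr.sigma_e2
            else:
                child_seed = (int(seed) * 7_919 + fold_i) % (2**31)
                fit_tr = powerlasso.fit(
                    y[tr], X_tr, Z3[tr], beta_shape=1.0,
                    chain_cfg=chain_cfg, seed=child_seed,
                )
                gebv_val = Z3[va] @ fit_tr.post_u
                b_hat, b_cols = fit_tr.post_b, kept
                sg2, se2 = fit_tr.additive_var, fit_tr.post_sigma_e2
        except GranosError as exc:
            logger.warning("fold %s failed: %s", unit.name, exc)
            n_skipped += 1
            continue

        if correction == "train":
            y_corr_val = y[va] - X[np.ix_(va, b_cols)] @ b_hat
        elif correction == "full":
            y_corr_val = full_fit._corrected_y[va]
        else:
            raise GranosError(f"unknown correction {correction!r}")

        for i, line_i in enumerate(va):
            lid = str(plan.line_ids[line_i])
            gebv_by_line.setdefault(lid, []).append((unit.name, float(gebv_val[i])))
            ycorr_by_line.setdefault(lid, []).append(
                (unit.name, float(y_corr_val[i]))
            )
        fold_rows.append(
            {"fold": unit.name, "n_train": len(tr), "n_val": len(va),
             "sigma_g2": sg2, "sigma_e2": se2}
        )

    rows = []
    for lid, entries in gebv_by_line.items():
        if plan.family_key is not None:
            keyed = [e for e in entries if e[0] == plan.family_key[lid]]
            if average_parents or not keyed:
                chosen = float(np.mean([v for _, v in entries]))
                fold_name = "averaged" if len(entries) > 1 else entries[0][0]
            else:
                fold_name, chosen = keyed[0]
            yc_entries = dict(ycorr_by_line[lid])
            yc = yc_entries.get(fold_name, next(iter(yc_entries.values())))
        else:
            fold_name, chosen = entries[0]
            yc = ycorr_by_line[lid][0][1]
        rows.append({"line": lid, "fold": fold_name, "gebv": chosen,
                     "y_corr": yc})
    pred = pd.DataFrame(rows)
    if pred.empty:
        raise GranosError("no fold produced predictions")
    valid = pred.dropna()
    gebv = valid["gebv"].to_numpy()
    y_corr_all = valid["y_corr"].to_numpy()
    if np.var(gebv) == 0:
        # e.g. every fold at the zero-genetic-variance boundary
        logger.warning("constant GEBVs across folds; metrics undefined")
        r, slope, se = float("nan"), float("nan"), float("nan")
    else:
        r = predictive_ability(y_corr_all, gebv)
        slope, se = bias_slope(y_corr_all, gebv)
    return CvResult(
        scheme=plan.scheme, predictions=pred, predictive_ability=r,
        bias_slope=slope, bias_se=se, h_max=h_max,
        per_fold=pd.DataFrame(fold_rows), n_skipped_folds=n_skipped,
    )


def _refit_with_components(y, X, K, sg2, se2):
    """BLUE/BLUP at fixed variance components (reuse of full-data estimates)."""
    n = len(y)
    V = sg2 * K.G + se2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ (Vinv @ y))
    r = y - X @ beta
    u = sg2 * K.G @ (Vinv @ r)
    from .gblup import MixedModelFit

    fit = MixedModelFit(
        sigma_g2=sg2, sigma_e2=se2, se_sigma_g2=np.nan, se_sigma_e2=np.nan,
        b_hat=beta, b_names=list(range(X.shape[1])), u_hat=u,
        pev=np.full(n, np.nan), h2=np.nan, loglik=np.nan, converged=True,
        n_iter=0, line_ids=np.asarray(K.line_ids),
    )
    fit._corrected_y = r
    fit._X = X
    return fit


def predictive_ability(y_corr: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation of corrected phenotypes with GEBVs (NaN if a
    vector is constant)."""
    y_corr = np.asarray(y_corr, float)
    gebv = np.asarray(gebv, float)
    if len(y_corr) != len(gebv):
        raise GranosError("length mismatch between phenotypes and GEBVs")
    if len(y_corr) < 3:
        raise GranosError("need at least three pairs for a correlation")
    if np.std(y_corr) == 0 or np.std(gebv) == 0:
        return float("nan")
    return float(np.corrcoef(y_corr, gebv)[0, 1])


def bias_slope(y_corr: np.ndarray, gebv: np.ndarray) -> tuple[float, float]:
    """OLS slope of corrected phenotypes on GEBVs with its standard error."""
    y_corr = np.asarray(y_corr, float)
    gebv = np.asarray(gebv, float)
    if np.var(gebv) == 0:
        raise GranosError("constant GEBVs: slope undefined")
    x = gebv - gebv.mean()
    yc = y_corr - y_corr.mean()
    sxx = float(x @ x)
    slope = float(x @ yc) / sxx
    n = len(yc)
    resid = yc - slope * x
    se = float(np.sqrt((resid @ resid) / max(n - 2, 1) / sxx))
    return slope, se
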