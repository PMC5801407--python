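"""Few-marker panels: selection, joint re-estimation, and 5-fold evaluation.

Panels of the 3 or 10 "best" SNPs per trait are chosen either by
single-marker GWAS significance (at most one SNP per chromosome, so several
markers tagging one QTL are not all picked) or by the magnitude of the
Power-Lasso posterior effects (no chromosome constraint).  Panel effects are
either kept from the single-marker scan, re-estimated jointly as random
effects in a panel-only SNP-BLUP (common variance by REML), or re-estimated
by a panel-only Power-Lasso chain.  Evaluation mimics genomic prediction
with few markers: selection and estimation happen inside each training fold
of a seeded 5-fold split, and predictions for the held-out fold are scored
like any other genomic prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossval import FoldPlan, bias_slope, plan_folds, predictive_ability, _drop_aliased
from .gblup import reml_fit
from .gwas import scan
from .io import MISSING, GenotypeMatrix, GranosError
from .kinship import KinshipMatrix, loco_matrices
from . import powerlasso

logger = logging.getLogger("granos")

SELECTORS = ("single_marker", "power_lasso")
REESTIMATORS = ("single_marker", "snp_blup", "power_lasso")


@dataclass
class MarkerPanel:
    trait: str
    selector: str
    size: int
    snp_ids: np.ndarray
    chrom: np.ndarray
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    coding: dict[str, str] = field(default_factory=dict)  # method -> w|z3
    intercepts: dict[str, tuple] = field(default_factory=dict)


def select_panel(
    source: pd.DataFrame,
    size: int,
    selector: str,
    trait: str = "",
    one_per_chrom: bool | None = None,
) -> MarkerPanel:
    """Pick the best markers from a scan table or posterior-effect table.

    ``single_marker`` expects columns snp_id/chrom/p_gc/a_hat and ranks by
    ascending p with the one-per-chromosome constraint; ``power_lasso``
    expects snp_id/chrom/effect and ranks by descending |effect| without the
    constraint (it can be switched on via ``one_per_chrom``).  Ties keep the
    original SNP order.  Fewer candidates than ``size`` yield a smaller
    panel with a warning.
    """
    if selector not in SELECTORS:
        raise GranosError(f"unknown selector {selector!r}")
    df = source.reset_index(drop=True).copy()
    df["_order"] = np.arange(len(df))
    if selector == "single_marker":
        constrain = True if one_per_chrom is None else one_per_chrom
        df = df[np.isfinite(df["p_gc"])]
        ranked = df.sort_values(["p_gc", "_order"], kind="stable")
        eff_col = "a_hat"
    else:
        constrain = False if one_per_chrom is None else one_per_chrom
        df = df[np.isfinite(df["effect"])]
        ranked = df.assign(_mag=-df["effect"].abs()).sort_values(
            ["_mag", "_order"], kind="stable"
        )
        eff_col = "effect"
    chosen = []
    seen_chrom: set = set()
    for _, row in ranked.iterrows():
        if constrain and row["chrom"] in seen_chrom:
            continue
        chosen.append(row)
        seen_chrom.add(row["chrom"])
        if len(chosen) == size:
            break
    if len(chosen) < size:
        logger.warning("panel has only %d of %d requested SNPs",
                       len(chosen), size)
    sel = pd.DataFrame(chosen)
    panel = MarkerPanel(
        trait=trait, selector=selector, size=size,
        snp_ids=sel["snp_id"].to_numpy() if len(sel) else np.asarray([], dtype=object),
        chrom=sel["chrom"].to_numpy() if len(sel) else np.asarray([], dtype=object),
    )
    if len(sel):
        panel.effects["single_marker" if selector == "single_marker"
                      else "power_lasso_full"] = sel[eff_col].to_numpy()
        panel.coding["single_marker"] = "w"
        panel.coding["power_lasso_full"] = "z3"
    return panel


def _panel_w(g: GenotypeMatrix, snp_ids) -> np.ndarray:
    idx = g.snp_index(snp_ids)
    W = g.dosage[:, idx].astype(float) - 1.0
    W[g.dosage[:, idx] == MISSING] = 0.0
    return W


def _panel_z3(g: GenotypeMatrix, snp_ids) -> np.ndarray:
    idx = g.snp_index(snp_ids)
    Z = g.dosage[:, idx].astype(float)
    Z[g.dosage[:, idx] == MISSING] = 0.0
    return Z


def reestimate_effects(
    panel: MarkerPanel,
    y_train: np.ndarray,
    X_train: np.ndarray,
    g_train: GenotypeMatrix,
    method: str,
    chain_cfg: "powerlasso.ChainConfig | None" = None,
    seed: int = 0,
) -> MarkerPanel:
    """Attach effect estimates under ``method`` to the panel.

    ``single_marker`` keeps the per-SNP scan estimates; ``snp_blup`` fits
    the panel jointly as random effects with a common variance estimated by
    REML (duplicated columns split an effect equally); ``power_lasso`` runs
    a panel-only chain.
    """
    if method not in REESTIMATORS:
        raise GranosError(f"unknown re-estimation method {method!r}")
    if len(panel.snp_ids) == 0:
        panel.effects[method] = np.asarray([])
        return panel
    if method == "single_marker":
        if "single_marker" not in panel.effects:
            raise GranosError(
                "single_marker re-estimation needs scan-based selection"
            )
        return panel
    y_train = np.asarray(y_train, float)
    X_train, _ = _drop_aliased(X_train)
    if method == "snp_blup":
        W = _panel_w(g_train, panel.snp_ids)
        K = KinshipMatrix(
            g_train.line_ids.copy(), W @ W.T,
            float(np.mean(np.sum(W * W, axis=1))),
            marker_count_used=W.shape[1],
        )
        fit = reml_fit(y_train, X_train, K, compute_se=False)
        n = len(y_train)
        V = fit.sigma_g2 * K.G + fit.sigma_e2 * np.eye(n)
        a_hat = fit.sigma_g2 * (W.T @ np.linalg.solve(V, fit._corrected_y))
        panel.effects["snp_blup"] = a_hat
        panel.coding["snp_blup"] = "w"
    else:
        Z = _panel_z3(g_train, panel.snp_ids)
        fit = powerlasso.fit(
            y_train, X_train, Z, beta_shape=1.0, chain_cfg=chain_cfg,
            seed=seed,
        )
        panel.effects["power_lasso"] = fit.post_u
        panel.coding["power_lasso"] = "z3"
    return panel


def panel_predict(
    panel: MarkerPanel, g: GenotypeMatrix, method: str
) -> np.ndarray:
    """Breeding values as the coding-weighted sum of panel effects."""
    eff = panel.effects.get(method)
    if eff is None and method == "single_marker":
        eff = panel.effects.get("single_marker")
    if eff is None and method == "power_lasso_full":
        eff = panel.effects.get("power_lasso_full")
    if eff is None:
        raise GranosError(f"panel has no effects for method {method!r}")
    if len(eff) == 0:
        return np.zeros(g.n_lines)
    coding = panel.coding.get(method, "w")
    M = _panel_z3(g, panel.snp_ids) if coding == "z3" else _panel_w(
        g, panel.snp_ids
    )
    return M @ np.asarray(eff, float)


def evaluate_panel_cv(
    y: np.ndarray,
    X: np.ndarray,
    g: GenotypeMatrix,
    selector: str,
    size: int,
    reestimation: str,
    k: int = 5,
    seed: int = 0,
    loco_gs: dict[str, KinshipMatrix] | None = None,
    chain_cfg: "powerlasso.ChainConfig | None" = None,
    plan: FoldPlan | None = None,
    beta_shape: float = 1.0,
):
    """Seeded k-fold evaluation of few-SNP prediction.

    Selection, re-estimation and the fixed-effect correction all happen
    strictly inside each training fold.  Pass the same ``plan`` (or seed)
    across selector/re-estimation combinations to keep comparisons paired.
    Returns (CvResult-like metrics dict, per-fold panel table).
    """
    from .crossval import CvResult

    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if plan is None:
        plan = plan_folds("kfold", g.line_ids, k=k, seed=seed)
    if loco_gs is None and selector == "single_marker":
        loco_gs = loco_matrices(g)

    rows, panel_rows = [], []
    for fold_i, unit in enumerate(plan.units):
        tr, va = unit.train_idx, unit.val_idx
        g_tr = g.subset_lines(g.line_ids[tr])
        X_tr, kept = _drop_aliased(X[tr])
        child_seed = (int(seed) * 65_537 + fold_i) % (2**31)

        if selector == "single_marker":
            loco_tr = {c: K.subset(tr) for c, K in loco_gs.items()}
            res = scan(y[tr], X_tr, g_tr, loco_tr)
            panel = select_panel(res, size, "single_marker")
        else:
            Z3_tr = powerlasso.design_Z3(g_tr)
            fit_full = powerlasso.fit(
                y[tr], X_tr, Z3_tr, beta_shape=beta_shape,
                chain_cfg=chain_cfg, seed=child_seed,
            )
            src = pd.DataFrame(
                {"snp_id": g.snp_ids, "chrom": g.chrom,
                 "effect": fit_full.post_u}
            )
            panel = select_panel(src, size, "power_lasso")
            panel.coding["power_lasso_full"] = "z3"

        panel = reestimate_effects(
            panel, y[tr], X[tr], g_tr, reestimation,
            chain_cfg=chain_cfg, seed=child_seed,
        )
        method = reestimation
        if reestimation == "single_marker" and selector == "power_lasso":
            # no scan estimates exist; fall back to the full-model posterior
            method = "power_lasso_full"

        g_va = g.subset_lines(g.line_ids[va])
        pred = panel_predict(panel, g_va, method)

        # training-only fixed-effect correction (OLS on the training fold)
        b_ols, *_ = np.linalg.lstsq(X_tr, y[tr], rcond=None)
        y_corr_val = y[va] - X[np.ix_(va, kept)] @ b_ols

        for i, line_i in enumerate(va):
            rows.append(
                {"line": str(g.line_ids[line_i]), "fold": unit.name,
                 "gebv": float(pred[i]), "y_corr": float(y_corr_val[i])}
            )
        for sid, ch in zip(panel.snp_ids, panel.chrom):
            panel_rows.append({"fold": unit.name, "snp_id": sid, "chrom": ch})

    pred_df = pd.DataFrame(rows)
    gebv = pred_df["gebv"].to_numpy()
    ycorr = pred_df["y_corr"].to_numpy()
    if np.std(gebv) == 0:
        r, slope, se = float("nan"), float("nan"), float("nan")
    else:
        r = predictive_ability(ycorr, gebv)
        slope, se = bias_slope(ycorr, gebv)
    result = CvResult(
        scheme=f"kfold{plan.k or len(plan.units)}-top{size}-{selector}-{reestimation}",
        predictions=pred_df, predictive_ability=r, bias_slope=slope,
        bias_se=se, h_max=float("nan"),
    )
    return result, pd.DataFrame(panel_rows)
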