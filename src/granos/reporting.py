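"""Machine-readable result tables and the run manifest.

Outputs mirror the standard surfaces of a genomic-prediction study: a
variance-component table (trait x model with sigma_g^2 +- SE, sigma_e^2 +-
SE, h^2), cross-validation grids (trait x scheme of predictive abilities
and of bias slopes), and per-SNP tables for Manhattan/Q-Q-style plots.  The
manifest records inputs, seeds, thresholds and content digests so every
report cell traces to an artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    version: str = ""

    def add_input(self, name: str, path) -> None:
        self.inputs[name] = {"path": str(path), "sha256": _digest(path)}

    def add_output(self, name: str, path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _digest(path)}

    def time_stage(self, name: str, seconds: float) -> None:
        self.timings[name] = round(seconds, 3)

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "version": self.version or __version__,
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config": self.config,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings": self.timings,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def variance_table(fits: dict) -> pd.DataFrame:
    """Trait x model table of variance components, SEs and heritability.

    ``fits`` maps (trait, model) -> an object exposing sigma_g2/sigma_e2
    (+ their SEs when available) and h2: a REML ``MixedModelFit`` or a
    ``PowerLassoFit`` (additive_var / post_sigma_e2 / h2_bayes).
    """
    rows = []
    for (trait, model), fit in fits.items():
        if hasattr(fit, "sigma_g2"):
            rows.append(
                {"trait": trait, "model": model,
                 "sigma_g2": fit.sigma_g2, "se_sigma_g2": fit.se_sigma_g2,
                 "sigma_e2": fit.sigma_e2, "se_sigma_e2": fit.se_sigma_e2,
                 "h2": fit.h2}
            )
        else:
            rows.append(
                {"trait": trait, "model": model,
                 "sigma_g2": fit.additive_var, "se_sigma_g2": np.nan,
                 "sigma_e2": fit.post_sigma_e2,
                 "se_sigma_e2": fit.sd_sigma_e2, "h2": fit.h2_bayes}
            )
    cols = ["trait", "model", "sigma_g2", "se_sigma_g2", "sigma_e2",
            "se_sigma_e2", "h2"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["trait", "model"]).reset_index(drop=True)


def cv_grid(results: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait x scheme grids of predictive ability and of bias slope +- SE.

    ``results`` maps (trait, scheme) -> CvResult.  Missing cells are NaN;
    insertion order does not matter.  The ability grid carries the h
    reference (square root of full-data genomic h^2) as its first column.
    """
    traits = sorted({t for t, _ in results})
    schemes = sorted({s for _, s in results})
    r_grid = pd.DataFrame(index=traits, columns=["h"] + schemes, dtype=float)
    b_grid = pd.DataFrame(
        index=traits,
        columns=[c for s in schemes for c in (s, f"{s}_se")],
        dtype=float,
    )
    for (trait, scheme), res in results.items():
        r_grid.loc[trait, scheme] = res.predictive_ability
        r_grid.loc[trait, "h"] = res.h_max
        b_grid.loc[trait, scheme] = res.bias_slope
        b_grid.loc[trait, f"{scheme}_se"] = res.bias_se
    return r_grid, b_grid


def manhattan_table(scan_result: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready per-SNP table: chromosome, order, -log10 p before/after
    genomic control."""
    out = scan_result[["snp_id", "chrom"]].copy()
    out["neglog10_p_raw"] = -np.log10(scan_result["p_raw"])
    out["neglog10_p_gc"] = -np.log10(scan_result["p_gc"])
    return out


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10(p) quantiles for a Q-Q plot."""
    finite = np.asarray(p_values, float)
    p = np.sort(finite[np.isfinite(finite)])  # ascending p
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    # i-th smallest p pairs with i-th smallest null quantile
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p)}
    )
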