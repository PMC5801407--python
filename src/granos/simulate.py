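"""Synthetic breeding populations for testing the whole pipeline.

The generator emulates an advanced winter-wheat line-breeding design:
inbred founder lines crossed in biparental families, single-seed descent
selfing to F6, two breeding-cycle "sets", a skewed marker distribution over
the 21 chromosomes (D-genome markers are scarce), and additive traits that
range from fully polygenic to "few large QTL + polygenic background".

Defaults reproduce the shape of the study population this pipeline targets:
635 F6 lines in 159 full-sib families (sizes 1..33) from 96 founders, 10,802
SNPs, ~2.5% residual line heterozygosity and a shared set/year fixed effect.

Randomness flows from a single integer seed through named streams so each
stage (founders, crossing, phenotypes, missingness) is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CHROMOSOMES,
    MISSING,
    UNMAPPED,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
    write_dosage_tsv,
    write_phenotypes,
    write_vcf,
)

# marker counts per chromosome in the emulated 15K-array panel after QC;
# the remainder of the 10,802 markers is the unmapped bin
CHROM_SNP_COUNTS: dict[str, int] = {
    "1A": 474, "2A": 474, "3A": 489, "4A": 319, "5A": 559, "6A": 557, "7A": 657,
    "1B": 736, "2B": 713, "3B": 692, "4B": 355, "5B": 797, "6B": 685, "7B": 565,
    "1D": 269, "2D": 217, "3D": 123, "4D": 49, "5D": 133, "6D": 128, "7D": 114,
    UNMAPPED: 1697,
}

# full-sib family-size distribution of the emulated population:
# {family size: number of families}; 159 families, 635 lines in total
FAMILY_SIZE_TABLE: dict[int, int] = {
    1: 39, 2: 27, 3: 21, 4: 29, 5: 9, 6: 10, 7: 5, 8: 5,
    9: 3, 10: 2, 11: 3, 12: 2, 13: 1, 15: 1, 18: 1, 33: 1,
}


def _default_family_sizes() -> list[int]:
    sizes: list[int] = []
    for size, count in FAMILY_SIZE_TABLE.items():
        sizes.extend([size] * count)
    return sizes


def _default_chrom_weights() -> dict[str, float]:
    total = sum(CHROM_SNP_COUNTS.values())
    return {c: k / total for c, k in CHROM_SNP_COUNTS.items()}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic population.

    ``maf_dist`` is the founder allele-frequency law, a callable
    ``(rng, size) -> frequencies``; the default Beta(1/2, 1/2) produces the
    U-shaped frequency spectrum typical of array SNPs in elite germplasm.
    ``n_self_gens`` counts selfing generations after the F1 (5 for F6 lines),
    giving an expected Mendelian residual heterozygosity of
    ``0.5**n_self_gens`` at parent-divergent loci.  ``target_het`` optionally
    tops heterozygosity up to a realistic array-level rate (see
    :func:`simulate_cross_to_f6`); ``None`` disables it.
    """

    n_founders: int = 96
    n_families: int = 159
    family_sizes: list[int] = field(default_factory=_default_family_sizes)
    n_sets: int = 2
    m: int = 10_802
    chrom_weights: dict[str, float] = field(default_factory=_default_chrom_weights)
    maf_dist: object = None  # callable (rng, size) -> freqs; default Beta(.5,.5)
    n_self_gens: int = 5
    n_qtl: int = 3
    qtl_var_share: float = 0.189
    qtl_chroms: tuple[str, ...] | None = None
    h2: float = 0.80
    set_effect_sd: float = 0.5
    target_het: float | None = 0.025
    miss_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.qtl_var_share <= 1:
            raise ValidationError("qtl_var_share must lie in [0, 1]")
        if not 0 <= self.h2 < 1:
            raise ValidationError("h2 must lie in [0, 1); 0 means no signal")
        w = sum(self.chrom_weights.values())
        if abs(w - 1.0) > 1e-8:
            raise ValidationError("chrom_weights must sum to 1")
        if self.maf_dist is None:
            self.maf_dist = lambda rng, size: rng.beta(0.5, 0.5, size=size)

    def stream(self, name: str) -> np.random.Generator:
        """Named RNG stream derived from the master seed."""
        streams = {"founders": 0, "cross": 1, "phenotype": 2, "missing": 3,
                   "sets": 4, "het": 5}
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed),
                                   spawn_key=(streams[name],))
        )


@dataclass
class SimTruth:
    """Ground truth behind a simulated trait, for parameter-recovery tests."""

    qtl_ids: np.ndarray
    snp_effects: np.ndarray  # per SNP, trait units per (dosage - 1) unit
    sigma_g2: float
    sigma_e2: float
    set_effects: dict[str, float]
    tbv: np.ndarray  # per line true breeding value


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(cfg: SimConfig) -> GenotypeMatrix:
    """Fully inbred founder lines drawn SNP-wise from the founder MAF law.

    Each founder is homozygous everywhere (dosage 0 or 2).  Markers are
    conditioned on being polymorphic among the sampled founders, emulating
    the ascertainment of array SNPs.  Chromosome assignment is multinomial
    with ``chrom_weights``.
    """
    labels = [c for c in list(CHROMOSOMES) + [UNMAPPED]
              if cfg.chrom_weights.get(c, 0.0) > 0]
    if cfg.m < len(labels):
        raise ValidationError(
            f"m={cfg.m} below the number of chromosomes with positive weight"
        )
    rng = cfg.stream("founders")
    weights = np.array([cfg.chrom_weights[c] for c in labels])
    counts = rng.multinomial(cfg.m, weights / weights.sum())
    chrom = np.repeat(labels, counts)
    pos_order = np.concatenate([np.arange(k) for k in counts])

    p = cfg.maf_dist(rng, cfg.m)
    dosage = 2 * (rng.random((cfg.n_founders, cfg.m)) < p).astype(np.int8)
    # ascertainment: redraw monomorphic columns until polymorphic
    for _ in range(200):
        mono = (dosage == dosage[0]).all(axis=0)
        if not mono.any():
            break
        k = int(mono.sum())
        p[mono] = cfg.maf_dist(rng, k)
        dosage[:, mono] = 2 * (
            rng.random((cfg.n_founders, k)) < p[mono]
        ).astype(np.int8)
    founder_ids = [f"P{i + 1:03d}" for i in range(cfg.n_founders)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(cfg.m)]
    return GenotypeMatrix.from_dosage(
        founder_ids, snp_ids, dosage, chrom=chrom, pos_order=pos_order
    )


# ---------------------------------------------------------------------------
# crossing and selfing
# ---------------------------------------------------------------------------

def simulate_cross_to_f6(
    founders: GenotypeMatrix, cfg: SimConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Biparental families selfed to F6 by single-seed descent.

    For each family two distinct founders are drawn; the F1 is heterozygous
    at parent-divergent loci; each line then descends through
    ``n_self_gens`` generations of independent Mendelian selfing per locus
    (no within-chromosome linkage -- the downstream analyses never use
    genetic distances).  With ``target_het`` set, additional heterozygous
    calls are retained at parent-divergent loci so the population mean
    matches array-level residual heterozygosity, which in real F6 material
    exceeds the pure-selfing expectation (outcrossing, seed admixture and
    scoring artifacts); the top-up keeps every call Mendelian-attainable.

    Returns the F6 genotype matrix and a pedigree frame with columns
    ``line, mother, father, family, set``.
    """
    sizes = list(cfg.family_sizes)
    if sum(sizes) == 0:
        raise ValidationError("family sizes sum to zero")
    if founders.n_lines < 2:
        raise ValidationError("need at least two founders to cross")
    rng = cfg.stream("cross")
    n_fam = len(sizes)
    parents = np.array(
        [rng.choice(founders.n_lines, size=2, replace=False) for _ in range(n_fam)]
    )

    n_lines = int(sum(sizes))
    m = founders.m
    dosage = np.empty((n_lines, m), dtype=np.int8)
    mother, father, family = [], [], []
    row = 0
    p_het = 0.5 ** cfg.n_self_gens
    for fam, (size, (pa, pb)) in enumerate(zip(sizes, parents)):
        da, db = founders.dosage[pa], founders.dosage[pb]
        divergent = da != db  # F1 heterozygous here, homozygous elsewhere
        base = np.where(divergent, 1, da)
        for _ in range(size):
            u = rng.random(m)
            line = base.copy()
            het = divergent
            # terminal state of the selfing chain at initially-het loci:
            # still het w.p. 0.5^g, else fixed to either homozygote equally
            line[het & (u >= p_het) & (u < p_het + (1 - p_het) / 2)] = 0
            line[het & (u >= p_het + (1 - p_het) / 2)] = 2
            line[het & (u < p_het)] = 1
            dosage[row] = line
            mother.append(founders.line_ids[pa])
            father.append(founders.line_ids[pb])
            family.append(f"fam{fam + 1:03d}")
            row += 1

    if cfg.target_het is not None:
        _top_up_heterozygosity(dosage, founders, parents, sizes, cfg)

    line_ids = [f"L{i + 1:04d}" for i in range(n_lines)]
    sets = _assign_sets(sizes, cfg)
    pedigree = pd.DataFrame(
        {"line": line_ids, "mother": mother, "father": father,
         "family": family, "set": sets}
    )
    g = GenotypeMatrix(
        line_ids, founders.snp_ids.copy(), dosage, founders.chrom.copy(),
        founders.pos_order.copy(),
    )
    return g, pedigree


def _top_up_heterozygosity(dosage, founders, parents, sizes, cfg) -> None:
    """Retain extra hets at divergent loci to reach ``cfg.target_het``."""
    rng = cfg.stream("het")
    m = founders.m
    p_het = 0.5 ** cfg.n_self_gens
    div_rows = np.repeat(
        [
            (founders.dosage[pa] != founders.dosage[pb])
            for pa, pb in parents
        ],
        sizes,
        axis=0,
    )
    mean_div = div_rows.mean()
    if mean_div <= 0:
        return
    # solve: p_het + (1 - p_het) * r = target / mean_div   (per divergent locus)
    r = (cfg.target_het / mean_div - p_het) / (1 - p_het)
    if r <= 0:
        return
    flip = div_rows & (dosage != 1) & (rng.random(dosage.shape) < min(r, 1.0))
    dosage[flip] = 1


def _assign_sets(sizes: list[int], cfg: SimConfig) -> list[str]:
    """Assign whole families to breeding-cycle sets, balancing line counts."""
    rng = cfg.stream("sets")
    n_fam = len(sizes)
    order = rng.permutation(n_fam)
    total = sum(sizes)
    targets = [round(total * (i + 1) / cfg.n_sets) for i in range(cfg.n_sets)]
    fam_set = [0] * n_fam
    cum, s = 0, 0
    for fam in order:
        if s < cfg.n_sets - 1 and cum >= targets[s]:
            s += 1
        fam_set[fam] = s
        cum += sizes[fam]
    labels = [f"set{2014 + i}" for i in range(cfg.n_sets)]
    return [labels[fam_set[fam]] for fam, size in enumerate(sizes)
            for _ in range(size)]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimConfig, pedigree: pd.DataFrame | None = None
) -> tuple[PhenotypeTable, SimTruth]:
    """Additive trait: y = mu + set effect + sum_j w_j u_j + e.

    ``n_qtl`` SNPs carry large effects accounting for ``qtl_var_share`` of
    the additive variance; every other SNP carries a small Gaussian effect.
    Components are rescaled to their realized variances so var(tbv) = ``h2``
    and var(e) = 1 - ``h2`` (trait units are arbitrary).  ``h2 = 0`` yields a
    pure-noise trait.  Genotypes enter through the (dosage - 1) coding with
    missing set to 0, matching the downstream analyses.
    """
    if g.n_lines == 0:
        raise ValidationError("empty genotype matrix")
    rng = cfg.stream("phenotype")
    n, m = g.n_lines, g.m
    W = g.dosage.astype(float) - 1.0
    W[g.dosage == MISSING] = 0.0

    u = np.zeros(m)
    qtl_ids = np.asarray([], dtype=object)
    sigma_g2 = float(cfg.h2)
    sigma_e2 = 1.0 - sigma_g2
    tbv = np.zeros(n)
    if cfg.h2 > 0:
        candidates = np.arange(m)
        if cfg.qtl_chroms is not None:
            candidates = candidates[np.isin(g.chrom, cfg.qtl_chroms)]
        n_qtl = min(cfg.n_qtl, len(candidates))
        qtl_idx = rng.choice(candidates, size=n_qtl, replace=False) \
            if n_qtl else np.asarray([], dtype=int)
        qtl_ids = g.snp_ids[qtl_idx]
        share = cfg.qtl_var_share if n_qtl else 0.0

        u_poly = rng.standard_normal(m)
        u_poly[qtl_idx] = 0.0
        tbv_poly = W @ u_poly
        v_poly = tbv_poly.var()
        if v_poly > 0:
            scale_p = np.sqrt(sigma_g2 * (1 - share) / v_poly)
        else:
            scale_p = 0.0
        u_poly *= scale_p
        tbv = tbv_poly * scale_p

        if n_qtl:
            u_qtl = np.zeros(m)
            u_qtl[qtl_idx] = rng.standard_normal(n_qtl) + np.sign(
                rng.standard_normal(n_qtl)
            )  # shifted away from 0 so every planted QTL is sizeable
            tbv_qtl = W @ u_qtl
            v_qtl = tbv_qtl.var()
            if v_qtl > 0:
                scale_q = np.sqrt(sigma_g2 * share / v_qtl)
                u_qtl *= scale_q
                tbv = tbv + tbv_qtl * scale_q
        else:
            u_qtl = np.zeros(m)
        u = u_poly + u_qtl

    e = rng.standard_normal(n) * np.sqrt(sigma_e2)

    if pedigree is not None:
        set_factor = pedigree["set"].to_numpy()
        mother = pedigree["mother"].to_numpy()
        father = pedigree["father"].to_numpy()
    else:
        set_factor = np.asarray(
            [f"set{2014 + (i * cfg.n_sets) // n}" for i in range(n)]
        )
        mother = father = None
    levels = sorted(set(set_factor))
    set_effects = {
        lev: float(rng.standard_normal() * cfg.set_effect_sd) for lev in levels
    }
    y = tbv + e + np.asarray([set_effects[s] for s in set_factor])

    pheno = PhenotypeTable(
        g.line_ids.copy(), "sim_trait", y, set_factor, mother, father
    )
    truth = SimTruth(qtl_ids, u, sigma_g2, sigma_e2, set_effects, tbv)
    return pheno, truth


def inject_missing(g: GenotypeMatrix, rate: float,
                   rng: np.random.Generator) -> GenotypeMatrix:
    """Set a uniform random fraction of calls to missing and re-cache MAF."""
    dosage = g.dosage.copy()
    dosage[rng.random(dosage.shape) < rate] = MISSING
    return GenotypeMatrix(
        g.line_ids.copy(), g.snp_ids.copy(), dosage, g.chrom.copy(),
        g.pos_order.copy(), flipped=g.flipped.copy(),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

PROFILES = ("tiny", "paperlike", "null")


def profile_config(profile_tag: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study profiles: ``tiny`` (50 x 200), ``paperlike``
    (635 x 10,802), ``null`` (no genetic signal, tiny-sized)."""
    if profile_tag == "paperlike":
        cfg = SimConfig(seed=seed, **overrides)
    elif profile_tag == "tiny":
        defaults = dict(
            n_founders=12, n_families=12,
            family_sizes=[4] * 10 + [5] * 2, m=200, n_qtl=2, seed=seed,
        )
        defaults.update(overrides)
        cfg = SimConfig(**defaults)
    elif profile_tag == "null":
        defaults = dict(
            n_founders=12, n_families=12,
            family_sizes=[4] * 10 + [5] * 2, m=200, n_qtl=0,
            qtl_var_share=0.0, h2=0.0, seed=seed,
        )
        defaults.update(overrides)
        cfg = SimConfig(**defaults)
    else:
        raise ValidationError(f"unknown profile {profile_tag!r}")
    return cfg


def simulate_population(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth, pd.DataFrame]:
    """Founders -> F6 cross -> phenotypes -> observed (missingness-injected)
    genotypes.  Phenotypes derive from the complete genotypes; missing calls
    are an observation-level artifact."""
    founders = simulate_founders(cfg)
    g, pedigree = simulate_cross_to_f6(founders, cfg)
    pheno, truth = simulate_phenotypes(g, cfg, pedigree)
    if cfg.miss_rate > 0:
        g = inject_missing(g, cfg.miss_rate, cfg.stream("missing"))
    return g, pheno, truth, pedigree


def make_fixture(profile_tag: str, seed: int, out_dir) -> dict:
    """Write a complete on-disk fixture bundle, deterministic per seed.

    Produces ``genotypes.tsv``, ``genotypes.vcf``, ``phenotypes.tsv`` and
    ``truth.json`` under ``out_dir``; returns the paths.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = profile_config(profile_tag, seed=seed)
    g, pheno, truth, pedigree = simulate_population(cfg)
    paths = {
        "genotypes_tsv": out / "genotypes.tsv",
        "genotypes_vcf": out / "genotypes.vcf",
        "phenotypes_tsv": out / "phenotypes.tsv",
        "truth_json": out / "truth.json",
    }
    write_dosage_tsv(g, paths["genotypes_tsv"])
    write_vcf(g, paths["genotypes_vcf"])
    write_phenotypes({pheno.trait_name: pheno}, paths["phenotypes_tsv"])
    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "profile": profile_tag,
                "seed": seed,
                "qtl_ids": list(truth.qtl_ids),
                "snp_effects": truth.snp_effects.tolist(),
                "sigma_g2": truth.sigma_g2,
                "sigma_e2": truth.sigma_e2,
                "set_effects": truth.set_effects,
                "tbv": truth.tbv.tolist(),
            },
            fh,
        )
    return {k: str(v) for k, v in paths.items()}
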