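"""Data model and file I/O for genotypes, phenotypes and pedigree.

Genotypes are stored as minor-allele dosages in {0, 1, 2} with an explicit
missing sentinel.  At load time the counted allele is re-oriented to the
minor allele (frequency <= 0.5); the original alt/ref orientation is kept in
``flipped`` so effect signs remain reportable in either convention.
Missing calls are never imputed here -- the set-missing-to-zero convention
lives inside the matrix-coding step of the kinship module.

Supported formats: VCF (biallelic records; multiallelic records are skipped
and counted) and a dosage TSV dialect with header
``snp_id  chrom  order  <line...>`` and cells 0/1/2/NA.  Phenotypes and
pedigree travel in a single TSV with columns
``line  set  [mother  father]  <trait...>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("granos")

#: sentinel for a missing dosage call in the int8 matrix
MISSING: int = -1

#: the 21 bread-wheat chromosome labels plus the unmapped bin
CHROMOSOMES: tuple[str, ...] = tuple(
    f"{num}{genome}" for genome in "ABD" for num in range(1, 8)
)
UNMAPPED: str = "unmapped"
VALID_CHROM_LABELS = frozenset(CHROMOSOMES) | {UNMAPPED}


class GranosError(Exception):
    """Base error for this package."""


class ParseError(GranosError):
    """A file could not be parsed; the message names the offending record."""


class ValidationError(GranosError):
    """Input violated a data-model invariant."""


def _as_str_array(values) -> np.ndarray:
    return np.asarray([str(v) for v in values], dtype=object)


@dataclass
class GenotypeMatrix:
    """Lines x SNPs minor-allele dosage matrix with chromosome map.

    Attributes
    ----------
    line_ids, snp_ids : object arrays of unique identifiers (case sensitive).
    dosage : ``(n_lines, m)`` int8 matrix, entries in {0, 1, 2, MISSING}.
    chrom : per-SNP chromosome label (``1A``..``7D`` or ``unmapped``).
    pos_order : per-SNP opaque ordering key within chromosome.
    maf : cached per-SNP minor-allele frequency in [0, 0.5].
    flipped : True where the counted allele is the original alt/second allele
        complement, i.e. dosages were re-oriented at load time.
    """

    line_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray
    chrom: np.ndarray
    pos_order: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: True when ``maf`` was deliberately carried over from a larger line
    #: set (fold subsetting reuses full-panel frequencies); validation then
    #: skips the cache-consistency check.
    maf_frozen: bool = False

    def __post_init__(self):
        self.line_ids = _as_str_array(self.line_ids)
        self.snp_ids = _as_str_array(self.snp_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.chrom = _as_str_array(self.chrom)
        self.pos_order = np.asarray(self.pos_order)
        if self.flipped is None:
            self.flipped = np.zeros(self.m, dtype=bool)
        if self.maf is None:
            self.maf = self.compute_maf()
        else:
            self.maf = np.asarray(self.maf, dtype=float)
        self.validate()

    # -- basic shape ------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def m(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_lines, m) mask, True where the call is missing."""
        return self.dosage == MISSING

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dosage(
        cls,
        line_ids,
        snp_ids,
        dosage,
        chrom=None,
        pos_order=None,
        orient_minor: bool = True,
    ) -> "GenotypeMatrix":
        """Build from an arbitrary-orientation dosage matrix.

        With ``orient_minor`` (default) columns whose counted-allele
        frequency exceeds 0.5 are flipped (``2 - dosage``) so cached ``maf``
        is the frequency of the counted allele.
        """
        dosage = np.array(dosage, dtype=float)
        dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
        m = dosage.shape[1]
        if chrom is None:
            chrom = [UNMAPPED] * m
        if pos_order is None:
            pos_order = np.arange(m)
        flipped = np.zeros(m, dtype=bool)
        if orient_minor:
            freq = _allele_freq(dosage)
            flip = freq > 0.5
            if flip.any():
                cols = dosage[:, flip]
                cols = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
                dosage = dosage.copy()
                dosage[:, flip] = cols
                flipped = flip
        return cls(line_ids, snp_ids, dosage, chrom, pos_order, flipped=flipped)

    def compute_maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from non-missing dosages."""
        f = _allele_freq(self.dosage)
        return np.minimum(f, 1.0 - f)

    def counted_freq(self) -> np.ndarray:
        """Frequency of the counted allele (equals ``maf`` after loading
        with minor orientation; may exceed 0.5 after line subsetting)."""
        return _allele_freq(self.dosage)

    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.line_ids) != n or len(self.snp_ids) != m:
            raise ValidationError("dosage shape does not match id lengths")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate snp_ids")
        if len(set(self.line_ids)) != n:
            raise ValidationError("duplicate line_ids")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of range at line {self.line_ids[i]!r}, "
                f"snp {self.snp_ids[j]!r}: {self.dosage[i, j]}"
            )
        unknown = set(self.chrom) - VALID_CHROM_LABELS
        if unknown:
            raise ValidationError(f"unknown chromosome labels: {sorted(unknown)}")
        if not self.maf_frozen:
            recomputed = self.compute_maf()
            if not np.allclose(recomputed, self.maf, atol=1e-12, equal_nan=True):
                raise ValidationError("cached MAF disagrees with dosages")

    # -- subsetting -------------------------------------------------------
    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        """Restrict to the given lines in the given order (MAF cache kept)."""
        idx = _index_of(self.line_ids, line_ids, what="line")
        return replace(
            self,
            line_ids=self.line_ids[idx],
            dosage=self.dosage[idx, :],
            maf=self.maf.copy(),
            flipped=self.flipped.copy(),
            maf_frozen=True,
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Restrict to SNPs selected by boolean mask or index array."""
        keep = np.asarray(keep)
        return replace(
            self,
            snp_ids=self.snp_ids[keep],
            dosage=self.dosage[:, keep],
            chrom=self.chrom[keep],
            pos_order=self.pos_order[keep],
            maf=self.maf[keep],
            flipped=self.flipped[keep],
        )

    def snp_index(self, snp_ids) -> np.ndarray:
        return _index_of(self.snp_ids, snp_ids, what="snp")

    def refresh_maf(self) -> "GenotypeMatrix":
        """Recompute the MAF cache (after line subsetting, when wanted)."""
        return replace(self, maf=self.compute_maf(), maf_frozen=False)


def _allele_freq(dosage: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per column ignoring MISSING (NaN if all missing)."""
    present = dosage != MISSING
    counts = present.sum(axis=0)
    sums = np.where(present, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / (2.0 * counts), np.nan)


def _index_of(universe: np.ndarray, wanted, what: str) -> np.ndarray:
    pos = {v: i for i, v in enumerate(universe)}
    try:
        return np.asarray([pos[str(w)] for w in wanted], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"unknown {what} id: {exc.args[0]!r}") from None


@dataclass
class PhenotypeTable:
    """Per-line records for one trait plus the set/year factor and pedigree.

    ``y`` may contain NaN (missing phenotype, retained but flagged).
    ``mother_id``/``father_id`` entries may be ``None`` when the pedigree is
    unknown; fold schemes that need it refuse explicitly.
    """

    line_ids: np.ndarray
    trait_name: str
    y: np.ndarray
    set_factor: np.ndarray
    mother_id: np.ndarray = None  # type: ignore[assignment]
    father_id: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.line_ids = _as_str_array(self.line_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.set_factor = _as_str_array(self.set_factor)
        n = len(self.line_ids)
        if self.mother_id is None:
            self.mother_id = np.asarray([None] * n, dtype=object)
        else:
            self.mother_id = np.asarray(self.mother_id, dtype=object)
        if self.father_id is None:
            self.father_id = np.asarray([None] * n, dtype=object)
        else:
            self.father_id = np.asarray(self.father_id, dtype=object)
        if len(set(self.line_ids)) != n:
            raise ValidationError("duplicate line ids in phenotype table")
        if not (len(self.y) == len(self.set_factor) == n):
            raise ValidationError("phenotype column lengths disagree")
        if len(set(self.set_factor)) < 1:
            raise ValidationError("set factor needs at least one level")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def has_pedigree(self) -> bool:
        return all(v is not None for v in self.mother_id) and all(
            v is not None for v in self.father_id
        )

    def subset_lines(self, line_ids) -> "PhenotypeTable":
        idx = _index_of(self.line_ids, line_ids, what="line")
        return PhenotypeTable(
            self.line_ids[idx],
            self.trait_name,
            self.y[idx],
            self.set_factor[idx],
            self.mother_id[idx],
            self.father_id[idx],
        )


@dataclass
class AnalysisConfig:
    """Thresholds and sampler controls shared across the pipeline.

    Defaults follow the study design this pipeline reproduces: SNPs with
    MAF < 1% or > 10% missing calls are discarded, genome-wide significance
    is Bonferroni at alpha = 0.05, and the Power Lasso shape grid spans
    0.2..1.0 (DIC picks the winner per trait).
    """

    maf_min: float = 0.01
    miss_max: float = 0.10
    alpha: float = 0.05
    beta_grid: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    chain_length: int = 100_000
    burn_in: int = 30_000
    thin: int = 10
    seed: int = 1
    k: int = 5

    def __post_init__(self):
        if not 0 <= self.maf_min < 0.5:
            raise ValidationError("maf_min must be in [0, 0.5)")
        if not 0 < self.miss_max <= 1:
            raise ValidationError("miss_max must be in (0, 1]")
        if not self.burn_in < self.chain_length:
            raise ValidationError("burn_in must be below chain_length")


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format_tag: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``dosage_tsv``.

    Heterozygous calls map to dosage 1; half-missing diploid VCF calls are
    treated as missing.  In a VCF, records that are not biallelic SNPs are
    skipped and the skip count logged.
    """
    if format_tag == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format_tag == "vcf":
        return _read_vcf(path)
    raise ValidationError(f"unknown genotype format: {format_tag!r}")


def _read_dosage_tsv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse dosage TSV {path}: {exc}") from exc
    required = ["snp_id", "chrom", "order"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"dosage TSV {path} must start with columns {required}, "
            f"got {list(df.columns[:3])}"
        )
    line_cols = list(df.columns[3:])
    if not line_cols:
        raise ParseError(f"dosage TSV {path} has no line columns")
    cells = df[line_cols].astype(object).where(
        ~df[line_cols].isna(), "NA"
    ).astype(str).to_numpy()
    dosage = np.full(cells.shape, MISSING, dtype=np.int8)
    accepted = {"NA": MISSING}
    for code in (0, 1, 2):  # integer and float renderings both accepted
        accepted[str(code)] = code
        accepted[f"{code}.0"] = code
    for value, code in accepted.items():
        dosage[cells == value] = code
    known = np.isin(cells, list(accepted))
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise ValidationError(
            f"dosage TSV {path}: entry {cells[i, j]!r} at snp "
            f"{df['snp_id'].iloc[i]!r}, line {line_cols[j]!r} is not 0/1/2/NA"
        )
    return GenotypeMatrix.from_dosage(
        line_cols,
        df["snp_id"].to_numpy(),
        dosage.T,
        chrom=df["chrom"].to_numpy(),
        pos_order=df["order"].to_numpy(),
    )


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise GranosError("VCF support needs the cyvcf2 package") from exc
    vcf = VCF(str(path))
    lines = list(vcf.samples)
    snp_ids, chroms, orders, rows = [], [], [], []
    skipped = 0
    for order, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gts = np.asarray(rec.genotype.array())[:, :2]
        row = np.where((gts < 0).any(axis=1), MISSING, gts.clip(0).sum(axis=1))
        snp_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM if rec.CHROM in VALID_CHROM_LABELS else UNMAPPED)
        orders.append(rec.POS)
        rows.append(row.astype(np.int8))
    if skipped:
        logger.info("skipped %d non-biallelic records in %s", skipped, path)
    if not rows:
        raise ParseError(f"no biallelic SNP records in {path}")
    g = GenotypeMatrix.from_dosage(
        lines, snp_ids, np.asarray(rows, dtype=np.int8).T, chrom=chroms,
        pos_order=orders,
    )
    g.n_skipped_records = skipped
    return g


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        {"snp_id": g.snp_ids, "chrom": g.chrom, "order": g.pos_order}
    )
    cells = g.dosage.T.astype(object)
    cells[g.dosage.T == MISSING] = "NA"
    for j, line in enumerate(g.line_ids):
        df[line] = cells[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT calls (counted allele as ALT)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in CHROMOSOMES:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(f"##contig=<ID={UNMAPPED}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.line_ids) + "\n"
        )
        for j in range(g.m):
            calls = "\t".join(gt_map[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{g.chrom[j]}\t{int(g.pos_order[j]) + 1}\t{g.snp_ids[j]}"
                f"\tA\tB\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# phenotype I/O
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> dict[str, PhenotypeTable]:
    """Read a phenotype/pedigree TSV into one table per trait column.

    Expected columns: ``line``, ``set``, optional ``mother``/``father``,
    then one column per trait.  Rows with a missing phenotype are retained
    with NaN.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"line": str, "set": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"phenotype file {path} is empty") from None
    if df.empty:
        raise ParseError(f"phenotype file {path} has no rows")
    for col in ("line", "set"):
        if col not in df.columns:
            raise ParseError(f"phenotype file {path} lacks column {col!r}")
    if df["line"].duplicated().any():
        dup = df["line"][df["line"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate line id {dup!r} in {path}")
    if df["set"].isna().any():
        raise ValidationError(f"missing set label in {path}")
    has_ped = "mother" in df.columns and "father" in df.columns
    mother = df["mother"].astype(object).to_numpy() if has_ped else None
    father = df["father"].astype(object).to_numpy() if has_ped else None
    meta = {"line", "set", "mother", "father"}
    traits = [c for c in df.columns if c not in meta]
    if not traits:
        raise ParseError(f"phenotype file {path} has no trait columns")
    out = {}
    for trait in traits:
        out[trait] = PhenotypeTable(
            df["line"].to_numpy(),
            trait,
            pd.to_numeric(df[trait], errors="coerce").to_numpy(),
            df["set"].to_numpy(),
            mother,
            father,
        )
    return out


def write_phenotypes(tables: dict[str, PhenotypeTable], path) -> None:
    first = next(iter(tables.values()))
    df = pd.DataFrame({"line": first.line_ids, "set": first.set_factor})
    if first.has_pedigree:
        df["mother"] = first.mother_id
        df["father"] = first.father_id
    for trait, tab in tables.items():
        if list(tab.line_ids) != list(first.line_ids):
            raise ValidationError("trait tables have mismatched line order")
        df[trait] = tab.y
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_lines(
    g: GenotypeMatrix, p: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both objects to the common lines, identical order.

    The order is the genotype matrix's order restricted to the
    intersection.  Dropped ids are logged on both sides.
    """
    common = set(g.line_ids) & set(p.line_ids)
    if not common:
        raise ValidationError("genotype and phenotype line ids are disjoint")
    keep = [lid for lid in g.line_ids if lid in common]
    dropped_g = [lid for lid in g.line_ids if lid not in common]
    dropped_p = [lid for lid in p.line_ids if lid not in common]
    if dropped_g or dropped_p:
        logger.info(
            "align_lines dropped %d genotype-only and %d phenotype-only lines",
            len(dropped_g), len(dropped_p),
        )
    return g.subset_lines(keep), p.subset_lines(keep)


def design_matrix(set_factor: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment contrasts for the set/year factor.

    Reference level is the alphabetically first set; a single-level factor
    yields the intercept only.
    """
    levels = sorted(set(set_factor))
    n = len(set_factor)
    X = np.ones((n, len(levels)))
    names = ["intercept"]
    for k, lev in enumerate(levels[1:], start=1):
        X[:, k] = (np.asarray(set_factor) == lev).astype(float)
        names.append(f"set[{lev}]")
    return X, names
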