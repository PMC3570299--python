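"""Variant catalogue: the glycaemic-trait SNP panel and allele-orientation logic.

The packaged catalogue transcribes the study panel of 38 SNPs associated with
fasting glucose and/or type 2 diabetes (plus one obesity variant): dbSNP id,
gene, major/minor alleles, cohort and CEU reference minor-allele frequencies,
which allele raises the trait (risk orientation), score weights, and the LD
proxy relationships for the two substituted variants.

Genotypes are coded throughout as minor-allele counts in {0, 1, 2}; a single
sentinel (:data:`MISSING`) marks missing calls, distinct from 0 because a zero
count is a valid genotype. ``orient_to_risk`` converts minor-allele counts to
risk-allele counts, the coding the weighted scores are defined on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "RiskOrientation",
    "VariantRecord",
    "GenotypeMatrix",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "catalog_frame",
    "orient_to_risk",
    "resolve_proxies",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_vcf",
]

#: Sentinel for a missing genotype call (kept negative so {0,1,2} stay valid counts).
MISSING: int = -1

_CATALOG_COLUMNS = [
    "rsid", "gene", "major", "minor", "maf_mothers", "maf_children", "maf_ceu",
    "risk_orientation", "traits", "fg_weight", "t2d_weight",
    "proxy_rsid", "proxy_r2", "alias", "notes",
]
_MANDATORY_COLUMNS = _CATALOG_COLUMNS[:9]

_VALID_TRAITS = {"fasting_glucose", "t2d", "obesity"}
_NUCLEOTIDES = set("ACGT")


class RiskOrientation(str, Enum):
    """Which allele at a SNP raises the trait."""

    MAJOR = "major"
    MINOR = "minor"


class CatalogError(ValueError):
    """Raised when a catalogue file violates the panel's validity rules."""


@dataclass(frozen=True)
class VariantRecord:
    """One catalogued SNP with its panel metadata and score weights."""

    rsid: str
    gene: str
    major_allele: str
    minor_allele: str
    maf_mothers: float | None  # None for child-only SNPs (not typed in mothers)
    maf_children: float
    maf_ceu: float | None
    risk_orientation: RiskOrientation
    trait_tags: frozenset[str]
    fg_weight: float | None = None
    t2d_weight: float | None = None
    proxy_of: tuple[str, float] | None = None  # (index rsid, r^2) for substituted SNPs
    alias: str | None = None
    notes: str = ""

    @property
    def mother_typed(self) -> bool:
        return self.maf_mothers is not None

    def maf(self, source: str) -> float:
        """Minor-allele frequency in the requested cohort ('mothers'|'children')."""
        if source == "children":
            return self.maf_children
        if source == "mothers":
            if self.maf_mothers is None:
                raise ValueError(f"{self.rsid} was not typed in mothers")
            return self.maf_mothers
        raise ValueError(f"unknown MAF source {source!r}")

    def risk_allele_frequency(self, source: str = "children") -> float:
        """Frequency of the trait-raising allele in the requested cohort."""
        p = self.maf(source)
        return p if self.risk_orientation is RiskOrientation.MINOR else 1.0 - p


def _validate_record(rec: VariantRecord, row: int) -> None:
    where = f"catalogue row {row} ({rec.rsid})"
    for label, f in (("maf_mothers", rec.maf_mothers),
                     ("maf_children", rec.maf_children)):
        if f is None:
            continue
        if not (0.0 < f <= 0.5):
            raise CatalogError(f"{where}: {label}={f} outside (0, 0.5]")
    # the reference column reports the frequency of the cohort-defined minor
    # allele in the reference panel, which can exceed 0.5 where the minor
    # allele differs between populations; stored as printed
    if rec.maf_ceu is not None and not (0.0 < rec.maf_ceu < 1.0):
        raise CatalogError(f"{where}: maf_ceu={rec.maf_ceu} outside (0, 1)")
    if rec.major_allele not in _NUCLEOTIDES or rec.minor_allele not in _NUCLEOTIDES:
        raise CatalogError(f"{where}: alleles must be single nucleotides")
    if rec.major_allele == rec.minor_allele:
        raise CatalogError(f"{where}: major and minor alleles identical")
    if not rec.trait_tags <= _VALID_TRAITS:
        raise CatalogError(f"{where}: unknown trait tags {rec.trait_tags - _VALID_TRAITS}")
    for label, w in (("fg_weight", rec.fg_weight), ("t2d_weight", rec.t2d_weight)):
        if w is not None and not w > 0:
            raise CatalogError(f"{where}: {label}={w} must be strictly positive")
    if rec.proxy_of is not None and not (0.0 <= rec.proxy_of[1] <= 1.0):
        raise CatalogError(f"{where}: proxy r^2 {rec.proxy_of[1]} outside [0, 1]")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def load_catalog(path: str | Path | None = None) -> list[VariantRecord]:
    """Read the variant catalogue (the packaged panel when *path* is None).

    Returns the validated records in file order. Raises :class:`CatalogError`
    naming the offending row on any invariant violation (frequency out of
    range, duplicate rsid, missing mandatory column).
    """
    if path is None:
        with resources.as_file(
            resources.files("duoscore.data").joinpath("variant_catalog.tsv")
        ) as p:
            return load_catalog(p)
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str}, keep_default_na=True)
    missing_cols = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CatalogError(f"catalogue is missing mandatory columns: {missing_cols}")
    for opt in _CATALOG_COLUMNS[9:]:
        if opt not in df.columns:
            df[opt] = np.nan
    dupes = df["rsid"][df["rsid"].duplicated()].tolist()
    if dupes:
        raise CatalogError(f"duplicate rsids in catalogue: {dupes}")

    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            orientation = RiskOrientation(str(row.risk_orientation))
        except ValueError:
            raise CatalogError(
                f"catalogue row {i} ({row.rsid}): risk_orientation "
                f"{row.risk_orientation!r} not in {{major, minor}}"
            ) from None
        proxy_rsid = None if pd.isna(row.proxy_rsid) else str(row.proxy_rsid)
        proxy = (proxy_rsid, float(row.proxy_r2)) if proxy_rsid else None
        rec = VariantRecord(
            rsid=str(row.rsid),
            gene=str(row.gene),
            major_allele=str(row.major),
            minor_allele=str(row.minor),
            maf_mothers=_opt_float(row.maf_mothers),
            maf_children=float(row.maf_children),
            maf_ceu=_opt_float(row.maf_ceu),
            risk_orientation=orientation,
            trait_tags=frozenset(str(row.traits).split(",")) if pd.notna(row.traits) else frozenset(),
            fg_weight=_opt_float(row.fg_weight),
            t2d_weight=_opt_float(row.t2d_weight),
            proxy_of=proxy,
            alias=None if pd.isna(row.alias) else str(row.alias),
            notes="" if pd.isna(row.notes) else str(row.notes),
        )
        _validate_record(rec, i)
        records.append(rec)
    return records


def catalog_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabular view of the catalogue (one row per SNP, file column order)."""
    rows = []
    for r in records:
        rows.append({
            "rsid": r.rsid, "gene": r.gene, "major": r.major_allele,
            "minor": r.minor_allele, "maf_mothers": r.maf_mothers,
            "maf_children": r.maf_children, "maf_ceu": r.maf_ceu,
            "risk_orientation": r.risk_orientation.value,
            "traits": ",".join(sorted(r.trait_tags)) if r.trait_tags else np.nan,
            "fg_weight": r.fg_weight, "t2d_weight": r.t2d_weight,
            "proxy_rsid": r.proxy_of[0] if r.proxy_of else np.nan,
            "proxy_r2": r.proxy_of[1] if r.proxy_of else np.nan,
            "alias": r.alias if r.alias else np.nan,
            "notes": r.notes if r.notes else np.nan,
        })
    return pd.DataFrame(rows, columns=_CATALOG_COLUMNS)


def write_catalog(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as the tab-separated catalogue format read by load_catalog."""
    catalog_frame(records).to_csv(path, sep="\t", index=False)


def orient_to_risk(count_minor, orientation: RiskOrientation | str):
    """Convert minor-allele count(s) to risk-allele count(s).

    Identity when the minor allele is the risk allele; the additive complement
    ``2 - g`` when the major allele is. The missing sentinel propagates.
    Accepts scalars or numpy arrays.
    """
    orientation = RiskOrientation(orientation)
    arr = np.asarray(count_minor)
    if not np.isin(arr, (0, 1, 2, MISSING)).all():
        raise ValueError("genotype counts must be in {0, 1, 2} or the missing sentinel")
    if orientation is RiskOrientation.MINOR:
        out = arr.copy()
    else:
        out = np.where(arr == MISSING, MISSING, 2 - arr)
    if np.isscalar(count_minor) or arr.ndim == 0:
        return int(out)
    return out


def resolve_proxies(
    records: Sequence[VariantRecord], r2_floor: float = 0.5
) -> tuple[list[VariantRecord], list[dict]]:
    """Audit LD-proxy substitutions, returning (records, audit list).

    Each proxy record carries the linked index variant's literature weight
    unchanged; the audit lists (proxy rsid, index rsid, r^2, weights carried).
    A proxy whose r^2 falls below *r2_floor* triggers a warning but the
    substitution is still applied — the study itself accepted one at r^2=0.8.
    """
    audit: list[dict] = []
    for rec in records:
        if rec.proxy_of is None:
            continue
        index_rsid, r2 = rec.proxy_of
        if r2 < r2_floor:
            warnings.warn(
                f"proxy {rec.rsid} for {index_rsid} has r^2={r2} below floor {r2_floor}; "
                "substituted weight retained",
                stacklevel=2,
            )
        audit.append({
            "proxy": rec.rsid,
            "index": index_rsid,
            "r2": r2,
            "fg_weight": rec.fg_weight,
            "t2d_weight": rec.t2d_weight,
        })
    return list(records), audit


@dataclass
class GenotypeMatrix:
    """Individuals x variants matrix of minor-allele counts with missing sentinel.

    ``counts`` is int8, shape (n_individuals, n_variants); entries are 0, 1, 2
    or :data:`MISSING`.
    """

    individual_ids: list[str]
    variant_ids: list[str]
    counts: np.ndarray
    _col: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, m = self.counts.shape
        if n != len(self.individual_ids) or m != len(self.variant_ids):
            raise ValueError("genotype matrix dimensions do not match id lists")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant ids")
        if not np.isin(self.counts, (0, 1, 2, MISSING)).all():
            raise ValueError("entries must be 0, 1, 2 or the missing sentinel")
        self._col = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def column(self, rsid: str) -> np.ndarray:
        try:
            return self.counts[:, self._col[rsid]]
        except KeyError:
            raise KeyError(f"variant {rsid} not in genotype matrix") from None

    def subset_variants(self, rsids: Iterable[str]) -> "GenotypeMatrix":
        rsids = list(rsids)
        idx = [self._col[r] for r in rsids]
        return GenotypeMatrix(list(self.individual_ids), rsids, self.counts[:, idx])

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        idx = [pos[s] for s in ids]
        return GenotypeMatrix(ids, list(self.variant_ids), self.counts[idx, :])

    def with_column(self, rsid: str, column: np.ndarray) -> "GenotypeMatrix":
        if rsid in self._col:
            raise ValueError(f"variant {rsid} already present")
        return GenotypeMatrix(
            list(self.individual_ids),
            self.variant_ids + [rsid],
            np.column_stack([self.counts, np.asarray(column, dtype=np.int8)]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosage table with NA for missing (rows=individuals, cols=rsids)."""
        df = pd.DataFrame(
            self.counts.astype(float), index=self.individual_ids, columns=self.variant_ids
        )
        return df.mask(df == MISSING)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        counts = df.to_numpy(dtype=float)
        counts = np.where(np.isnan(counts), MISSING, counts).astype(np.int8)
        return cls([str(i) for i in df.index], [str(c) for c in df.columns], counts)


def read_dosage_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a tab-separated dosage table (rows=individuals, columns=rsids, NA=missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix.from_frame(df)


def write_dosage_matrix(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.to_frame()
    # keep integer formatting for non-missing entries
    df.to_csv(path, sep="\t", index_label="id", float_format="%.0f", na_rep="NA")


def read_vcf(path: str | Path, records: Sequence[VariantRecord]) -> GenotypeMatrix:
    """Convert VCF GT fields to minor-allele counts using catalogue allele labels.

    Requires cyvcf2. Sites are matched by ID against the catalogue (aliases
    honoured); the minor-allele count is the ALT dosage when ALT equals the
    catalogue minor allele, and its complement when REF does.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    by_id: dict[str, VariantRecord] = {}
    for rec in records:
        by_id[rec.rsid] = rec
        if rec.alias:
            by_id[rec.alias] = rec

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for site in vcf:
        rec = by_id.get(site.ID)
        if rec is None or not site.ALT:
            continue
        alt = site.ALT[0]
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 gt_types order 0,1,3,2)
        dosage = np.array([sum(a > 0 for a in g[:2]) if g[0] >= 0 else MISSING
                           for g in site.genotypes], dtype=np.int8)
        if alt == rec.minor_allele and site.REF == rec.major_allele:
            counts = dosage
        elif alt == rec.major_allele and site.REF == rec.minor_allele:
            counts = np.where(dosage == MISSING, MISSING, 2 - dosage).astype(np.int8)
        else:
            raise CatalogError(
                f"VCF alleles {site.REF}/{alt} at {site.ID} do not match catalogue "
                f"{rec.major_allele}/{rec.minor_allele}"
            )
        columns[rec.rsid] = counts
    rsids = [r.rsid for r in records if r.rsid in columns]
    counts = np.column_stack([columns[r] for r in rsids]) if rsids else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples, rsids, counts)
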