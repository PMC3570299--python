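"""Weighted genetic risk scores for fasting glucose (FGGRS) and type 2 diabetes (T2DGRS).

A score is ``(sum_i w_i * g_i / W) * K`` where ``g_i`` is the risk-allele count
at SNP i (0/1/2), ``w_i`` the literature per-allele effect, ``W`` the
denominator constant and ``K`` the SNP count, so a complete-data score lives in
``[0, 2K]`` "weighted allele" units. The FGGRS uses 16 fasting-glucose variants
with W = 0.474; the T2DGRS uses 22 diabetes variants with the published
denominator W = 2.86 even though its printed weights sum to 2.89 — pass
``consistent_denominator=True`` to substitute the true sum.

Missing genotypes are handled by an explicit policy:

``complete_case``
    individuals with any missing term get a missing (NaN) score;
``zero_fill``
    missing terms contribute nothing (biases the score toward 0);
``renormalize``
    W is replaced per-individual by the sum of weights at non-missing terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    MISSING,
    GenotypeMatrix,
    RiskOrientation,
    VariantRecord,
    orient_to_risk,
)

__all__ = [
    "Trait",
    "MissingPolicy",
    "ScoreDefinition",
    "ScoreVector",
    "build_definition",
    "compute_score",
    "analytic_score_moments",
    "score_summary",
    "FG_DENOMINATOR",
    "T2D_DENOMINATOR_PRINTED",
]

#: Published denominator constants (total effect size, as printed).
FG_DENOMINATOR = 0.474
T2D_DENOMINATOR_PRINTED = 2.86


class Trait(str, Enum):
    FASTING_GLUCOSE = "fasting_glucose"
    T2D = "t2d"


class MissingPolicy(str, Enum):
    COMPLETE_CASE = "complete_case"
    ZERO_FILL = "zero_fill"
    RENORMALIZE = "renormalize"


@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered weighted term list with its denominator and scale constants."""

    name: str
    terms: tuple[tuple[str, float], ...]  # (rsid, weight)
    denominator: float  # W: total-effect constant
    scale: int  # K: SNP-count multiplier
    missing_policy: MissingPolicy = MissingPolicy.ZERO_FILL
    weight_sum: float = field(default=float("nan"))  # audit: actual sum of term weights

    def __post_init__(self) -> None:
        if self.scale != len(self.terms):
            raise ValueError("scale K must equal the number of terms")
        if not self.denominator > 0:
            raise ValueError("denominator W must be positive")
        if any(w <= 0 for _, w in self.terms):
            raise ValueError("score weights must be strictly positive")
        if np.isnan(self.weight_sum):
            object.__setattr__(self, "weight_sum", float(sum(w for _, w in self.terms)))

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.terms)

    def audit(self) -> dict:
        return {
            "name": self.name,
            "n_terms": len(self.terms),
            "denominator_W": self.denominator,
            "scale_K": self.scale,
            "weight_sum": round(self.weight_sum, 10),
            "missing_policy": self.missing_policy.value,
            "terms": [{"rsid": r, "weight": w} for r, w in self.terms],
        }


@dataclass
class ScoreVector:
    """Per-individual score values plus the count of contributing SNPs."""

    individual_ids: list[str]
    values: np.ndarray  # float, NaN = missing under complete_case
    n_contributing: np.ndarray  # int, non-missing terms per individual
    definition: ScoreDefinition

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.individual_ids, name=self.definition.name)


# rsids excluded from the scores although present (or aliased) in the panel:
# the LD-duplicate per pair with the smaller effect, the child-only ADIPOQ trio,
# the low-maternal-n CDC123/CAMK1D SNP, the Pima-only COX2 SNP and the FTO
# obesity variant.
_EXCLUDED_RSIDS = frozenset({
    "rs12255372", "rs2237892",  # LD duplicates of rs7903146 / rs2237895
    "rs1501299", "rs17300539", "rs266729",  # ADIPOQ, children only
    "rs12779790", "rs20417", "rs9939609",
})

# Printed score formulas, in printed term order.
_FG_TERMS: tuple[tuple[str, float], ...] = (
    ("rs560887", 0.075), ("rs10830963", 0.067), ("rs1799884", 0.062),
    ("rs2191349", 0.03), ("rs780094", 0.029), ("rs2877716", 0.027),
    ("rs13266634", 0.027), ("rs7903146", 0.023), ("rs10885122", 0.022),
    ("rs7944584", 0.021), ("rs11920090", 0.02), ("rs7034200", 0.018),
    ("rs174550", 0.017), ("rs11605924", 0.015), ("rs340874", 0.013),
    ("rs11071657", 0.008),
)
_T2D_TERMS: tuple[tuple[str, float], ...] = (
    ("rs4607103", 0.09), ("rs10946398", 0.15), ("rs10811661", 0.23),
    ("rs1111875", 0.16), ("rs757210", 0.1), ("rs4402960", 0.16),
    ("rs864745", 0.1), ("rs5219", 0.15), ("rs2237895", 0.22),
    ("rs10923931", 0.12), ("rs1801282", 0.17), ("rs7578597", 0.14),
    ("rs7961581", 0.09), ("rs10010131", 0.1), ("rs2877716", 0.11),
    ("rs2191349", 0.06), ("rs1799884", 0.07), ("rs780094", 0.06),
    ("rs10830963", 0.09), ("rs340874", 0.07), ("rs13266634", 0.14),
    ("rs7903146", 0.31),
)


def build_definition(
    catalog: Sequence[VariantRecord],
    trait: Trait | str,
    policy: MissingPolicy | str = MissingPolicy.ZERO_FILL,
    consistent_denominator: bool = False,
) -> ScoreDefinition:
    """Assemble the published score definition for a trait against a catalogue.

    The 16-term FGGRS (W=0.474) or the 22-term T2DGRS (published W=2.86;
    *consistent_denominator* substitutes the actual weight sum 2.89). Every
    term rsid must exist in the catalogue and carry the matching weight;
    missing rsids raise a hard error listing them.
    """
    trait = Trait(trait)
    policy = MissingPolicy(policy)
    by_rsid = {rec.rsid: rec for rec in catalog}

    if trait is Trait.FASTING_GLUCOSE:
        terms, name, denom = _FG_TERMS, "FGGRS", FG_DENOMINATOR
        weight_of = lambda rec: rec.fg_weight  # noqa: E731
    else:
        terms, name, denom = _T2D_TERMS, "T2DGRS", T2D_DENOMINATOR_PRINTED
        weight_of = lambda rec: rec.t2d_weight  # noqa: E731

    absent = [r for r, _ in terms if r not in by_rsid]
    if absent:
        raise KeyError(f"catalogue lacks required score SNPs: {absent}")
    for rsid, w in terms:
        cat_w = weight_of(by_rsid[rsid])
        if cat_w is None or abs(cat_w - w) > 1e-12:
            raise ValueError(
                f"catalogue weight for {rsid} ({cat_w}) disagrees with the "
                f"published {name} term ({w})"
            )
        if rsid in _EXCLUDED_RSIDS:
            raise ValueError(f"{rsid} is an excluded variant and cannot enter {name}")

    if consistent_denominator:
        denom = float(sum(w for _, w in terms))
    return ScoreDefinition(
        name=name, terms=terms, denominator=denom, scale=len(terms),
        missing_policy=policy,
    )


def compute_score(
    genotypes: GenotypeMatrix,
    definition: ScoreDefinition,
    catalog: Sequence[VariantRecord],
) -> ScoreVector:
    """Score each individual: ``(sum_i w_i g_i / W) * K`` on risk-allele counts.

    *genotypes* holds minor-allele counts; orientation to risk-allele counts is
    applied internally from the catalogue's risk_orientation. Missing terms are
    handled per the definition's missing_policy.
    """
    by_rsid = {rec.rsid: rec for rec in catalog}
    n = genotypes.n_individuals
    K, W = definition.scale, definition.denominator

    weighted = np.zeros(n)  # sum of w_i * g_i over non-missing terms
    weight_avail = np.zeros(n)  # sum of w_i over non-missing terms
    n_contrib = np.zeros(n, dtype=int)

    for rsid, w in definition.terms:
        rec = by_rsid.get(rsid)
        if rec is None:
            raise KeyError(f"catalogue lacks {rsid}")
        g_minor = genotypes.column(rsid)
        g_risk = orient_to_risk(g_minor, rec.risk_orientation)
        ok = g_risk != MISSING
        weighted[ok] += w * g_risk[ok]
        weight_avail[ok] += w
        n_contrib += ok.astype(int)

    policy = definition.missing_policy
    if policy is MissingPolicy.COMPLETE_CASE:
        values = np.where(n_contrib == K, weighted / W * K, np.nan)
    elif policy is MissingPolicy.ZERO_FILL:
        values = weighted / W * K
    else:  # renormalize: per-individual denominator = available weight
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(weight_avail > 0, weighted / weight_avail * K, np.nan)
    return ScoreVector(list(genotypes.individual_ids), values, n_contrib, definition)


def analytic_score_moments(
    definition: ScoreDefinition,
    catalog: Sequence[VariantRecord],
    maf_source: str = "children",
) -> tuple[float, float]:
    """Closed-form (mean, variance) of the score under HWE with independent SNPs.

    With risk-allele frequency ``p_i``, a risk-allele count has mean ``2 p_i``
    and variance ``2 p_i (1 - p_i)``, so

        mean = (K/W) * sum_i w_i * 2 p_i
        var  = (K/W)^2 * sum_i w_i^2 * 2 p_i (1 - p_i).
    """
    by_rsid = {rec.rsid: rec for rec in catalog}
    K, W = definition.scale, definition.denominator
    mean = 0.0
    var = 0.0
    for rsid, w in definition.terms:
        p = by_rsid[rsid].risk_allele_frequency(maf_source)
        mean += w * 2.0 * p
        var += w * w * 2.0 * p * (1.0 - p)
    factor = K / W
    return factor * mean, factor * factor * var


def score_summary(scores: ScoreVector) -> dict:
    """Descriptive summary: n, mean, sd, range, skewness and excess kurtosis."""
    values = scores.values[~np.isnan(scores.values)]
    if values.size == 0:
        raise ValueError("all scores are missing; nothing to summarise")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {
        "name": scores.definition.name,
        "n": int(values.size),
        "n_missing": int(np.isnan(scores.values).sum()),
        "mean": float(np.mean(values)),
        "sd": sd,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "skewness": float(stats.skew(values)) if values.size > 2 and sd > 0 else 0.0,
        "excess_kurtosis": (float(stats.kurtosis(values))
                            if values.size > 3 and sd > 0 else 0.0),
    }
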