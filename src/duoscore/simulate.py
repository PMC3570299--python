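"""Synthetic mother-child duo cohorts with the structure the analysis assumes.

The generator emulates a population birth cohort genotyped on the glycaemic
SNP panel: founder (maternal) genotypes in Hardy-Weinberg proportions at the
catalogued minor-allele frequencies, children produced by Mendelian
transmission (one maternal allele sampled uniformly, one paternal allele drawn
from the population), optional LD-proxy columns at a target r², phenotypes
generated from configurable score → trait linear models calibrated to the
cohort's published summary statistics (fasting glucose 4.95 ± 0.39 mmol/l,
HbA1c 4.91 ± 0.31 %, IQ 104.4 ± 16.4), a Bernoulli-logistic maternal
diabetes/glycosuria exposure, completely-at-random genotype missingness, and
an optional two-subpopulation structure with a panel of unlinked background
SNPs for principal-component adjustment.

Everything is driven by one seeded generator in a fixed order, so a config
with the same seed regenerates the cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .catalog import MISSING, GenotypeMatrix, VariantRecord, load_catalog
from .scores import MissingPolicy, Trait, analytic_score_moments, build_definition, compute_score

__all__ = [
    "TraitModel",
    "IQModel",
    "DiabetesModel",
    "StructureConfig",
    "SimulationConfig",
    "DuoCohort",
    "CONFOUNDER_COLUMNS",
    "BREASTFEEDING_LEVELS",
    "DIABETES_CATEGORIES",
    "simulate_mother_genotypes",
    "transmit_to_child",
    "add_ld_proxy",
    "simulate_phenotypes",
    "inject_missingness",
    "generate_cohort",
]

BREASTFEEDING_LEVELS = ("never", "lt_3m", "3_to_5m", "ge_6m")
DIABETES_CATEGORIES = ("none", "pre_existing", "gestational", "glycosuria")

#: The fifteen covariables entering the confounder scan.
CONFOUNDER_COLUMNS = [
    "maternal_education", "social_class", "parity", "breastfeeding",
    "smoking", "alcohol_before", "alcohol_during", "iron_supplementation",
    "gestational_age", "birthweight", "maternal_age",
    "interpregnancy_interval", "infection", "age", "sex",
]


@dataclass
class TraitModel:
    """Linear model for a continuous child glycaemic trait.

    ``trait = intercept + beta * (child FGGRS - analytic mean)
            + sex_effect * 1[male] + N(0, residual_sd^2)``
    """

    intercept: float
    per_weighted_allele: float
    residual_sd: float
    sex_effect: float = 0.0


@dataclass
class IQModel:
    """Child IQ model with separate maternal and offspring score effects.

    Scores are centred at their analytic HWE means, so ``mean`` is the
    population mean under the null. ``score_trait`` selects which score
    (fasting-glucose or diabetes) carries the maternal/offspring effects.
    ``maternal_diabetes_effect`` is the group shift for children of
    diabetic/glycosuric mothers. ``confounder_effects`` maps phenotype-table
    column names to additive per-unit effects (opt-in scenario knobs).
    """

    mean: float = 104.4
    sd: float = 16.4
    maternal_effect: float = 0.0
    offspring_effect: float = 0.0
    score_trait: str = "t2d"
    maternal_diabetes_effect: float = 0.0
    confounder_effects: dict = field(default_factory=dict)


@dataclass
class DiabetesModel:
    """Maternal diabetes/glycosuria exposure: Bernoulli(logistic(a + g*score))."""

    prevalence: float = 0.05
    per_weighted_allele_logodds: float = 0.0
    # split of the affected group across the three exclusive affected categories
    category_split: tuple[float, float, float] = (0.10, 0.35, 0.55)


@dataclass
class StructureConfig:
    n_subpops: int = 1
    maf_divergence: float = 0.2
    n_background_snps: int = 200


@dataclass
class SimulationConfig:
    seed: int = 0
    n_duos: int = 1000
    maf_source: str = "children"
    fg_model: TraitModel = field(default_factory=lambda: TraitModel(4.95, 0.02, 0.39))
    hba1c_model: TraitModel = field(default_factory=lambda: TraitModel(4.91, 0.02, 0.31))
    iq_model: IQModel = field(default_factory=IQModel)
    diabetes_model: DiabetesModel = field(default_factory=DiabetesModel)
    missing_rate: float = 0.0
    structure: StructureConfig = field(default_factory=StructureConfig)
    ld_proxies: list = field(default_factory=list)  # (rsid, r2) pairs

    def __post_init__(self) -> None:
        for label, frac in (("missing_rate", self.missing_rate),
                            ("prevalence", self.diabetes_model.prevalence)):
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{label}={frac} outside [0, 1)")
        for label, sd in (("fg residual_sd", self.fg_model.residual_sd),
                          ("hba1c residual_sd", self.hba1c_model.residual_sd),
                          ("iq sd", self.iq_model.sd)):
            if not sd > 0:
                raise ValueError(f"{label} must be > 0")
        for m in (self.fg_model, self.hba1c_model, self.iq_model, self.diabetes_model):
            for v in asdict(m).values():
                if isinstance(v, (int, float)) and not np.isfinite(v):
                    raise ValueError("non-finite parameter in simulation config")
        if self.n_duos < 0:
            raise ValueError("n_duos must be >= 0")
        if self.maf_source not in ("mothers", "children"):
            raise ValueError("maf_source must be 'mothers' or 'children'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "fg_model" in d:
            d["fg_model"] = TraitModel(**d["fg_model"])
        if "hba1c_model" in d:
            d["hba1c_model"] = TraitModel(**d["hba1c_model"])
        if "iq_model" in d:
            d["iq_model"] = IQModel(**d["iq_model"])
        if "diabetes_model" in d:
            dm = dict(d["diabetes_model"])
            if "category_split" in dm:
                dm["category_split"] = tuple(dm["category_split"])
            d["diabetes_model"] = DiabetesModel(**dm)
        if "structure" in d:
            d["structure"] = StructureConfig(**d["structure"])
        if "ld_proxies" in d:
            d["ld_proxies"] = [tuple(p) for p in d["ld_proxies"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DuoCohort:
    """Paired maternal/child genotypes, phenotypes and the generating truth."""

    mothers: GenotypeMatrix
    children: GenotypeMatrix
    families: pd.DataFrame  # family_id, mother_id, child_id
    phenotypes: pd.DataFrame  # indexed by family_id
    truth: dict
    mothers_background: GenotypeMatrix | None = None
    children_background: GenotypeMatrix | None = None

    def __post_init__(self) -> None:
        if self.families["mother_id"].duplicated().any() or \
           self.families["child_id"].duplicated().any():
            raise ValueError("each child must pair with exactly one mother")
        if self.mothers.variant_ids != self.children.variant_ids:
            raise ValueError("mother and child matrices must share the variant panel")

    @property
    def n_duos(self) -> int:
        return len(self.families)

    def write(self, outdir: str | Path) -> None:
        """Write dosage matrices, phenotype table and truth record as text files."""
        from .catalog import write_dosage_matrix

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dosage_matrix(self.mothers, outdir / "mothers.tsv")
        write_dosage_matrix(self.children, outdir / "children.tsv")
        if self.mothers_background is not None:
            write_dosage_matrix(self.mothers_background, outdir / "mothers_background.tsv")
        if self.children_background is not None:
            write_dosage_matrix(self.children_background, outdir / "children_background.tsv")
        self.families.to_csv(outdir / "families.tsv", sep="\t", index=False)
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index_label="family_id")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# genotype generation


def _subpop_freqs(p: np.ndarray, structure: StructureConfig) -> np.ndarray:
    """Per-subpopulation allele frequencies: p shifted by +/- maf_divergence."""
    k = structure.n_subpops
    if k <= 1:
        return p[None, :]
    offsets = np.linspace(-structure.maf_divergence, structure.maf_divergence, k)
    return np.clip(p[None, :] + offsets[:, None], 0.01, 0.5)


def _draw_hwe(freqs: np.ndarray, subpop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """HWE genotypes: minor-allele count = Binomial(2, p_subpop) per entry."""
    p = freqs[subpop, :]  # (n, m)
    return rng.binomial(2, p).astype(np.int8)


def panel_frequencies(catalog: Sequence[VariantRecord], maf_source: str) -> tuple[list[str], np.ndarray]:
    """(rsids, minor-allele frequencies) for the SNPs typed in the chosen cohort."""
    recs = [r for r in catalog if maf_source == "children" or r.mother_typed]
    return [r.rsid for r in recs], np.array([r.maf(maf_source) for r in recs])


def simulate_mother_genotypes(
    config: SimulationConfig,
    catalog: Sequence[VariantRecord],
    rng: np.random.Generator | None = None,
    subpop: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Founder genotypes in HWE at the catalogued MAFs (per-subpopulation if structured)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rsids, p = panel_frequencies(catalog, config.maf_source)
    n = config.n_duos
    if subpop is None:
        subpop = np.zeros(n, dtype=int)
    freqs = _subpop_freqs(p, config.structure)
    counts = _draw_hwe(freqs, subpop, rng)
    if ids is None:
        ids = [f"M{i:06d}" for i in range(n)]
    return GenotypeMatrix(list(ids), rsids, counts)


def transmit_to_child(
    mother_genotypes: GenotypeMatrix,
    config: SimulationConfig,
    catalog: Sequence[VariantRecord],
    rng: np.random.Generator | None = None,
    subpop: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
    freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Mendelian transmission: one maternal allele (uniform) + one paternal
    population allele ~ Bernoulli(p) on the minor allele.

    The expected child MAF equals the population MAF and the mother-child
    genotype correlation is the additive parent-offspring value 1/2.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    g_m = mother_genotypes.counts
    if (g_m == MISSING).any():
        raise ValueError("maternal panel must be complete for transmission")
    n, m = g_m.shape
    if freqs is None:
        by_rsid = {r.rsid: r for r in catalog}
        p = np.array([by_rsid[v].maf(config.maf_source) for v in mother_genotypes.variant_ids])
        freqs = _subpop_freqs(p, config.structure)
    if subpop is None:
        subpop = np.zeros(n, dtype=int)
    # maternal transmitted allele: P(minor) = g_m / 2
    maternal = rng.random((n, m)) < (g_m / 2.0)
    paternal = rng.random((n, m)) < freqs[subpop, :]
    counts = (maternal.astype(np.int8) + paternal.astype(np.int8))
    if ids is None:
        ids = [f"C{i:06d}" for i in range(n)]
    return GenotypeMatrix(list(ids), mother_genotypes.variant_ids + [], counts)  # copy ids list


def add_ld_proxy(
    genotypes: GenotypeMatrix,
    rsid: str,
    r2: float,
    freq: float,
    rng: np.random.Generator,
    proxy_rsid: str | None = None,
) -> GenotypeMatrix:
    """Append a proxy column in LD with *rsid* at squared allelic correlation *r2*.

    Haplotype-level copy scheme for an equal-frequency pair: each of the two
    proxy alleles copies the corresponding index allele with probability
    sqrt(r2), otherwise it is an independent Bernoulli(freq) draw, giving
    allelic correlation sqrt(r2) and hence r² as requested.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must be in [0, 1]")
    g = genotypes.column(rsid)
    if (g == MISSING).any():
        raise ValueError("index column must be complete to synthesise a proxy")
    n = g.shape[0]
    s = np.sqrt(r2)
    # reconstruct the two index alleles per individual (order exchangeable)
    a1 = np.where(g == 2, 1, np.where(g == 1, 1, 0))
    a2 = np.where(g == 2, 1, 0)
    proxy = np.zeros(n, dtype=np.int8)
    for allele in (a1, a2):
        copy = rng.random(n) < s
        indep = rng.random(n) < freq
        proxy += np.where(copy, allele, indep).astype(np.int8)
    name = proxy_rsid or f"{rsid}_proxy"
    return genotypes.with_column(name, proxy)


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Set each entry to missing independently with probability *rate* (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0, 1)")
    if rate == 0.0:
        return genotypes
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(genotypes.counts.shape) < rate
    counts = np.where(mask, MISSING, genotypes.counts).astype(np.int8)
    return GenotypeMatrix(list(genotypes.individual_ids), list(genotypes.variant_ids), counts)


# ---------------------------------------------------------------------------
# phenotypes


def _centered_scores(
    mothers: GenotypeMatrix,
    children: GenotypeMatrix,
    config: SimulationConfig,
    catalog: Sequence[VariantRecord],
) -> dict:
    """Complete-data FGGRS/T2DGRS for both generations, centred at analytic means."""
    out = {}
    for trait in (Trait.FASTING_GLUCOSE, Trait.T2D):
        d = build_definition(catalog, trait, MissingPolicy.COMPLETE_CASE)
        mean, var = analytic_score_moments(d, catalog, config.maf_source)
        out[trait.value] = {
            "definition": d,
            "analytic_mean": mean,
            "analytic_var": var,
            "mother": compute_score(mothers, d, catalog).values - mean,
            "child": compute_score(children, d, catalog).values - mean,
        }
    return out


def _solve_alpha(prevalence: float, gamma: float, z: np.ndarray) -> float:
    """Intercept making mean(logistic(alpha + gamma z)) equal the target prevalence."""
    if gamma == 0.0 or z.size == 0:
        return float(logit(prevalence))
    f = lambda a: float(np.mean(expit(a + gamma * z))) - prevalence  # noqa: E731
    lo, hi = logit(prevalence) - 20.0, logit(prevalence) + 20.0
    return float(brentq(f, lo, hi))


def simulate_phenotypes(
    mothers: GenotypeMatrix,
    children: GenotypeMatrix,
    config: SimulationConfig,
    catalog: Sequence[VariantRecord],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Phenotype table for a duo cohort plus the truth record.

    Uses the complete (pre-missingness) genotypes. Continuous traits follow
    the configured linear models on centred scores; the maternal
    diabetes/glycosuria exposure is Bernoulli-logistic on the centred maternal
    T2DGRS with the intercept solved to hit the configured prevalence.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n = mothers.n_individuals
    scores = _centered_scores(mothers, children, config, catalog)
    fg_child = scores["fasting_glucose"]["child"]
    iq_trait = Trait(config.iq_model.score_trait).value
    iq_mother_score = scores[iq_trait]["mother"]
    iq_child_score = scores[iq_trait]["child"]
    t2d_mother = scores["t2d"]["mother"]

    # demographic and confounder columns (distributions chosen to look like a
    # European birth cohort; effects on outcomes are all opt-in)
    sex = np.where(rng.random(n) < 0.499, "male", "female")
    age = rng.normal(8.583, 0.275, n)  # years: 8y7m +/- 3.3 months
    pheno = pd.DataFrame({
        "sex": sex,
        "age": age,
        "maternal_education": rng.integers(1, 6, n),
        "social_class": rng.integers(1, 6, n),
        "parity": rng.poisson(0.9, n),
        "breastfeeding": rng.choice(BREASTFEEDING_LEVELS, n, p=(0.25, 0.25, 0.2, 0.3)),
        "smoking": rng.binomial(1, 0.25, n),
        "alcohol_before": rng.binomial(1, 0.5, n),
        "alcohol_during": rng.binomial(1, 0.3, n),
        "iron_supplementation": rng.binomial(1, 0.4, n),
        "gestational_age": rng.normal(39.5, 1.9, n),
        "birthweight": rng.normal(3400.0, 550.0, n),
        "maternal_age": rng.normal(28.0, 5.0, n),
        "interpregnancy_interval": rng.gamma(2.0, 18.0, n),
        "infection": rng.binomial(1, 0.15, n),
    })

    male = (sex == "male").astype(float)
    fg_m, hb_m, iq_m, dm = config.fg_model, config.hba1c_model, config.iq_model, config.diabetes_model

    pheno["fasting_glucose"] = (
        fg_m.intercept + fg_m.per_weighted_allele * fg_child
        + fg_m.sex_effect * male + rng.normal(0.0, fg_m.residual_sd, n)
    )
    pheno["hba1c"] = (
        hb_m.intercept + hb_m.per_weighted_allele * scores["fasting_glucose"]["child"]
        + hb_m.sex_effect * male + rng.normal(0.0, hb_m.residual_sd, n)
    )

    alpha = _solve_alpha(dm.prevalence, dm.per_weighted_allele_logodds, t2d_mother)
    p_affected = expit(alpha + dm.per_weighted_allele_logodds * t2d_mother)
    affected = rng.random(n) < p_affected
    split = np.asarray(dm.category_split, dtype=float)
    split = split / split.sum()
    cat_draw = rng.choice(DIABETES_CATEGORIES[1:], n, p=split)
    pheno["maternal_diabetes_category"] = np.where(affected, cat_draw, "none")
    pheno["maternal_diabetes_glycosuria"] = affected.astype(int)

    iq = (
        iq_m.mean + iq_m.maternal_effect * iq_mother_score
        + iq_m.offspring_effect * iq_child_score
        + iq_m.maternal_diabetes_effect * affected.astype(float)
        + rng.normal(0.0, iq_m.sd, n)
    )
    for col, beta in iq_m.confounder_effects.items():
        x = pheno[col]
        if x.dtype == object:
            raise ValueError(f"confounder effect on categorical column {col!r} not supported")
        iq = iq + beta * x.to_numpy(dtype=float)
    pheno["iq"] = iq

    truth = {
        "config": config.to_dict(),
        "alpha_diabetes": alpha,
        "analytic_means": {t: scores[t]["analytic_mean"] for t in scores},
        "analytic_vars": {t: scores[t]["analytic_var"] for t in scores},
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# end-to-end


def generate_cohort(config: SimulationConfig, catalog: Sequence[VariantRecord] | None = None) -> DuoCohort:
    """Generate a full duo cohort: genotypes, transmission, background panel,
    phenotypes, LD proxies and missingness, deterministically from the seed."""
    catalog = load_catalog() if catalog is None else catalog
    rng = np.random.default_rng(config.seed)
    n = config.n_duos
    k_sub = max(config.structure.n_subpops, 1)
    subpop = rng.integers(0, k_sub, n) if k_sub > 1 else np.zeros(n, dtype=int)

    mother_ids = [f"M{i:06d}" for i in range(n)]
    child_ids = [f"C{i:06d}" for i in range(n)]
    family_ids = [f"F{i:06d}" for i in range(n)]

    mothers = simulate_mother_genotypes(config, catalog, rng=rng, subpop=subpop, ids=mother_ids)
    children = transmit_to_child(mothers, config, catalog, rng=rng, subpop=subpop, ids=child_ids)

    # background panel for PC estimation (unlinked biallelic markers)
    m_bg = config.structure.n_background_snps
    mothers_bg = children_bg = None
    if m_bg > 0:
        base = rng.uniform(0.1, 0.5, m_bg)
        bg_freqs = _subpop_freqs(base, config.structure)
        bg_ids = [f"bg{j:04d}" for j in range(m_bg)]
        mothers_bg = GenotypeMatrix(mother_ids, bg_ids, _draw_hwe(bg_freqs, subpop, rng))
        maternal = rng.random((n, m_bg)) < (mothers_bg.counts / 2.0)
        paternal = rng.random((n, m_bg)) < bg_freqs[subpop, :]
        children_bg = GenotypeMatrix(
            child_ids, bg_ids, (maternal.astype(np.int8) + paternal.astype(np.int8))
        )

    pheno, truth = simulate_phenotypes(mothers, children, config, catalog, rng=rng)
    pheno.index = pd.Index(family_ids, name="family_id")
    pheno.insert(0, "mother_id", mother_ids)
    pheno.insert(1, "child_id", child_ids)
    pheno["subpop"] = subpop

    by_rsid = {r.rsid: r for r in catalog}
    for rsid, r2 in config.ld_proxies:
        freq = by_rsid[rsid].maf(config.maf_source) if rsid in by_rsid else 0.3
        mothers = add_ld_proxy(mothers, rsid, r2, freq, rng)
        children = add_ld_proxy(children, rsid, r2, freq, rng)

    if config.missing_rate > 0:
        mothers = inject_missingness(mothers, config.missing_rate, rng)
        children = inject_missingness(children, config.missing_rate, rng)

    families = pd.DataFrame(
        {"family_id": family_ids, "mother_id": mother_ids, "child_id": child_ids}
    )
    return DuoCohort(
        mothers=mothers, children=children, families=families, phenotypes=pheno,
        truth=truth, mothers_background=mothers_bg, children_background=children_bg,
    )
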