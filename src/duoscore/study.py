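"""End-to-end duo study: a model object over a cohort, and its fitted report.

:class:`DuoStudy` is built from a :class:`~duoscore.simulate.DuoCohort` (loaded
from files or generated synthetically) plus a :class:`StudyConfig`; ``fit()``
runs the full analysis — genotype QC, score construction, instrument
validation (score → fasting glucose / HbA1c), offspring and maternal
score → IQ regressions with mutual adjustment, the maternal
diabetes/glycosuria contrast, and the genotype × confounder scan — and
returns a :class:`StudyResult` whose ``summary()`` renders the tables and
whose ``to_dict()/to_json()`` give the machine-readable report.

The maternal-score regressions adjusted for the offspring score are the
design's causal contrast: because a child inherits half its alleles from the
mother, mother-child scores correlate at ~0.5 and an unadjusted maternal
coefficient absorbs any offspring genetic effect; conditioning on the child's
own score isolates the intrauterine pathway.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import qc
from .catalog import GenotypeMatrix, VariantRecord, load_catalog
from .scores import (
    MissingPolicy,
    Trait,
    analytic_score_moments,
    build_definition,
    compute_score,
    score_summary,
)
from .simulate import CONFOUNDER_COLUMNS, DuoCohort, SimulationConfig, generate_cohort

__all__ = [
    "FlowLedger",
    "StudyConfig",
    "DuoStudy",
    "StudyResult",
    "apply_inclusion_filters",
    "replicate_study",
    "validate_report",
    "COVARIATE_PRESETS",
]

#: Named covariate sets used across the report tables.
COVARIATE_PRESETS = {
    "age_sex": ["age", "sex"],
    "maternal_diabetes_full": [
        "age", "sex", "maternal_age", "birthweight", "gestational_age", "breastfeeding",
    ],
}


@dataclass
class FlowLedger:
    """Ordered participant-accounting entries: (stage, n remaining, n excluded, reason)."""

    entries: list = field(default_factory=list)

    def add(self, stage: str, n_remaining: int, n_excluded: int, reason: str = "") -> None:
        if self.entries and n_remaining > self.entries[-1]["n_remaining"]:
            raise ValueError("participant counts must be non-increasing across stages")
        if self.entries and self.entries[-1]["n_remaining"] - n_excluded != n_remaining:
            raise ValueError("exclusions do not sum consistently")
        self.entries.append({
            "stage": stage, "n_remaining": int(n_remaining),
            "n_excluded": int(n_excluded), "reason": reason,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def apply_inclusion_filters(cohort: DuoCohort, filters: list[dict]) -> tuple[DuoCohort, FlowLedger]:
    """Apply declared inclusion filters in order, recording each in a ledger.

    Each filter is a mapping with a ``column`` (in the phenotype table), an
    optional ``label``, and one criterion: ``present: true`` (non-missing),
    ``equals``, ``min`` or ``max``. Idempotent on an already-filtered cohort.
    """
    ledger = FlowLedger()
    pheno = cohort.phenotypes
    ledger.add("enrolled", len(pheno), 0)
    keep = pd.Series(True, index=pheno.index)
    for spec in filters:
        col = spec["column"]
        if col not in pheno.columns:
            raise KeyError(f"filter references unknown column {col!r}")
        x = pheno[col]
        if spec.get("present"):
            crit = x.notna()
            label = spec.get("label", f"{col} present")
        elif "equals" in spec:
            crit = x == spec["equals"]
            label = spec.get("label", f"{col} == {spec['equals']}")
        elif "min" in spec:
            crit = x >= spec["min"]
            label = spec.get("label", f"{col} >= {spec['min']}")
        elif "max" in spec:
            crit = x <= spec["max"]
            label = spec.get("label", f"{col} <= {spec['max']}")
        else:
            raise ValueError(f"filter on {col!r} has no criterion")
        new_keep = keep & crit.fillna(False)
        ledger.add(label, int(new_keep.sum()), int(keep.sum() - new_keep.sum()),
                   reason=f"excluded by {label}")
        keep = new_keep

    idx = pheno.index[keep]
    pheno_f = pheno.loc[idx]
    fam_f = cohort.families.set_index("family_id").loc[idx].reset_index()
    sub = DuoCohort(
        mothers=cohort.mothers.subset_individuals(fam_f["mother_id"]),
        children=cohort.children.subset_individuals(fam_f["child_id"]),
        families=fam_f,
        phenotypes=pheno_f,
        truth=cohort.truth,
        mothers_background=(cohort.mothers_background.subset_individuals(fam_f["mother_id"])
                            if cohort.mothers_background is not None else None),
        children_background=(cohort.children_background.subset_individuals(fam_f["child_id"])
                             if cohort.children_background is not None else None),
    )
    return sub, ledger


@dataclass
class StudyConfig:
    """Knobs for one study run (everything else comes from the cohort itself)."""

    k_pcs: int = 10
    alpha: float = 0.05
    missing_policy: str = "zero_fill"
    consistent_denominator: bool = False
    filters: list = field(default_factory=list)
    confounders: list = field(default_factory=lambda: list(CONFOUNDER_COLUMNS))
    include_confounder_scan: bool = True
    include_hwe: bool = True
    include_pcs: bool = True


def _rows(results: list[assoc.RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.summary_row() for r in results])


def _fmt_table(df: pd.DataFrame, title: str) -> str:
    with pd.option_context("display.width", 120, "display.max_columns", 20,
                           "display.float_format", lambda v: f"{v:.4g}"):
        return f"== {title} ==\n{df.to_string(index=False)}\n"


class DuoStudy:
    """The full mother-offspring score analysis as a fittable model object."""

    def __init__(
        self,
        cohort: DuoCohort,
        config: StudyConfig | None = None,
        catalog: list[VariantRecord] | None = None,
    ):
        self.cohort = cohort
        self.config = config or StudyConfig()
        self.catalog = load_catalog() if catalog is None else catalog

    @classmethod
    def from_simulation(
        cls,
        sim_config: SimulationConfig,
        study_config: StudyConfig | None = None,
        catalog: list[VariantRecord] | None = None,
    ) -> "DuoStudy":
        catalog = load_catalog() if catalog is None else catalog
        return cls(generate_cohort(sim_config, catalog), study_config, catalog)

    # -- pieces -------------------------------------------------------------

    def _pcs(self, background: GenotypeMatrix | None, ids: list[str]) -> pd.DataFrame | None:
        cfg = self.config
        if not cfg.include_pcs or background is None or background.n_variants == 0:
            return None
        k = min(cfg.k_pcs, background.n_individuals - 1, background.n_variants)
        if k < cfg.k_pcs:
            warnings.warn(f"background panel supports only {k} PCs (requested {cfg.k_pcs})")
        if k < 1:
            return None
        res = qc.compute_pcs(background, k)
        return res.to_frame().loc[ids].reset_index(drop=True)

    def _scores(self) -> dict:
        cfg = self.config
        out = {}
        for trait in (Trait.FASTING_GLUCOSE, Trait.T2D):
            d = build_definition(
                self.catalog, trait, MissingPolicy(cfg.missing_policy),
                consistent_denominator=cfg.consistent_denominator,
            )
            out[trait.value] = {
                "definition": d,
                "mother": compute_score(self.cohort.mothers, d, self.catalog),
                "child": compute_score(self.cohort.children, d, self.catalog),
                "analytic_moments": analytic_score_moments(d, self.catalog, "children"),
            }
        return out

    # -- fit ----------------------------------------------------------------

    def fit(self) -> "StudyResult":
        cfg = self.config
        cohort, ledger = apply_inclusion_filters(self.cohort, cfg.filters)
        pheno = cohort.phenotypes.reset_index()
        catalog_rsids = {r.rsid for r in self.catalog}

        # QC section
        hwe_mothers = hwe_children = None
        if cfg.include_hwe:
            hwe_mothers = qc.hwe_table(cohort.mothers)
            hwe_children = qc.hwe_table(cohort.children)
        freq_rows = []
        by_rsid = {r.rsid: r for r in self.catalog}
        for rsid in cohort.children.variant_ids:
            if rsid not in catalog_rsids:
                continue
            rec = by_rsid[rsid]
            freq_rows.append({
                "rsid": rsid,
                "maf_observed_children": qc.allele_frequency(cohort.children.column(rsid)),
                "maf_catalog_children": rec.maf_children,
                "maf_ceu": rec.maf_ceu,
            })
        freq_comparison = pd.DataFrame(freq_rows)

        scores = self._scores()
        score_summaries = {
            f"{t}_{who}": score_summary(scores[t][who])
            for t in scores for who in ("mother", "child")
        }

        child_pcs = self._pcs(cohort.children_background, list(cohort.families["child_id"]))
        mother_pcs = self._pcs(cohort.mothers_background, list(cohort.families["mother_id"]))

        fg_child = scores["fasting_glucose"]["child"].to_series().reset_index(drop=True)
        t2_child = scores["t2d"]["child"].to_series().reset_index(drop=True)
        fg_mother = scores["fasting_glucose"]["mother"].to_series().reset_index(drop=True)
        t2_mother = scores["t2d"]["mother"].to_series().reset_index(drop=True)

        # Instrument validation: child score vs fasting glucose and HbA1c,
        # unadjusted and PC-adjusted
        instrument = []
        for outcome in ("fasting_glucose", "hba1c"):
            y = pheno[outcome]
            for name, s in (("FGGRS", fg_child), ("T2DGRS", t2_child)):
                instrument.append(assoc.ols_fit(y, s, None, outcome, name))
                if child_pcs is not None:
                    instrument.append(assoc.ols_fit(y, s, child_pcs, outcome, name))

        # Offspring exposures vs IQ: glycaemic traits (age+sex adjusted) and
        # child scores (unadjusted / PC-adjusted)
        iq = pheno["iq"]
        offspring_iq = []
        agesex = pheno[COVARIATE_PRESETS["age_sex"]]
        for label in ("fasting_glucose", "hba1c"):
            offspring_iq.append(assoc.ols_fit(iq, pheno[label], None, "iq", label))
            offspring_iq.append(assoc.ols_fit(iq, pheno[label], agesex, "iq", label))
        for name, s in (("FGGRS", fg_child), ("T2DGRS", t2_child)):
            offspring_iq.append(assoc.ols_fit(iq, s, None, "iq", name))
            if child_pcs is not None:
                offspring_iq.append(assoc.ols_fit(iq, s, child_pcs, "iq", name))

        # Maternal scores vs child IQ, mutually adjusted (the duo contrast)
        maternal_iq = []
        for name, sm_, sc_ in (("FGGRS", fg_mother, fg_child), ("T2DGRS", t2_mother, t2_child)):
            pair = assoc.maternal_effect_fit(iq, sm_, sc_, mother_pcs, "iq", f"maternal_{name}")
            maternal_iq.extend([pair["unadjusted"], pair["adjusted"]])

        # Maternal diabetes/glycosuria contrast with the full covariate preset
        diabetes_contrast = assoc.ols_fit(
            iq, pheno["maternal_diabetes_glycosuria"],
            pheno[COVARIATE_PRESETS["maternal_diabetes_full"]],
            "iq", "maternal_diabetes_glycosuria",
        )

        scan = None
        if cfg.include_confounder_scan:
            child_dosages = cohort.children.to_frame().reset_index(drop=True)
            child_dosages = child_dosages[[c for c in child_dosages.columns if c in catalog_rsids]]
            scan = assoc.confounder_scan(child_dosages, pheno[cfg.confounders], cfg.alpha)

        n_panel = len([c for c in cohort.children.variant_ids if c in catalog_rsids])
        bonf_exact, bonf_display = qc.bonferroni_threshold(cfg.alpha, max(n_panel, 1))

        return StudyResult(
            study=self,
            flow_ledger=ledger,
            hwe_mothers=hwe_mothers,
            hwe_children=hwe_children,
            freq_comparison=freq_comparison,
            score_summaries=score_summaries,
            instrument_table=_rows(instrument),
            offspring_iq_table=_rows(offspring_iq),
            maternal_iq_table=_rows(maternal_iq),
            diabetes_contrast=diabetes_contrast,
            confounder_scan=scan,
            bonferroni={"alpha": cfg.alpha, "n_tests": n_panel,
                        "exact": bonf_exact, "display": bonf_display},
        )


@dataclass
class StudyResult:
    """Fitted study report: every table the analysis produces, with its n."""

    study: DuoStudy
    flow_ledger: FlowLedger
    hwe_mothers: pd.DataFrame | None
    hwe_children: pd.DataFrame | None
    freq_comparison: pd.DataFrame
    score_summaries: dict
    instrument_table: pd.DataFrame
    offspring_iq_table: pd.DataFrame
    maternal_iq_table: pd.DataFrame
    diabetes_contrast: assoc.RegressionResult
    confounder_scan: assoc.ScanResult | None
    bonferroni: dict

    def to_dict(self) -> dict:
        d = {
            "flow_ledger": self.flow_ledger.entries,
            "qc": {
                "hwe_mothers": (self.hwe_mothers.to_dict("records")
                                if self.hwe_mothers is not None else None),
                "hwe_children": (self.hwe_children.to_dict("records")
                                 if self.hwe_children is not None else None),
                "freq_comparison": self.freq_comparison.to_dict("records"),
                "bonferroni": self.bonferroni,
            },
            "score_summaries": self.score_summaries,
            "instrument_table": self.instrument_table.to_dict("records"),
            "offspring_iq_table": self.offspring_iq_table.to_dict("records"),
            "maternal_iq_table": self.maternal_iq_table.to_dict("records"),
            "diabetes_contrast": self.diabetes_contrast.summary_row(),
            "confounder_scan": None,
        }
        if self.confounder_scan is not None:
            s = self.confounder_scan
            d["confounder_scan"] = {
                "n_tests": s.n_tests, "alpha": s.alpha,
                "expected_nominal": s.expected_nominal,
                "observed_nominal": s.observed_nominal,
                "observed_fraction": s.observed_fraction,
                "n_untestable": len(s.untestable),
            }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        parts = [_fmt_table(self.flow_ledger.to_frame(), "Participant flow")]
        if self.hwe_children is not None:
            flagged = self.hwe_children[self.hwe_children["flagged"]]
            parts.append(
                f"== HWE (children) == {len(flagged)}/{len(self.hwe_children)} SNPs "
                f"flagged at p <= {qc.HWE_FLAG_P}\n"
            )
        if self.hwe_mothers is not None:
            flagged = self.hwe_mothers[self.hwe_mothers["flagged"]]
            parts.append(
                f"== HWE (mothers) == {len(flagged)}/{len(self.hwe_mothers)} SNPs "
                f"flagged at p <= {qc.HWE_FLAG_P}\n"
            )
        ss = pd.DataFrame(self.score_summaries).T
        parts.append(_fmt_table(ss.reset_index(names="score"), "Score summaries"))
        parts.append(_fmt_table(self.instrument_table,
                                "Instrument validation: score vs glycaemic trait"))
        parts.append(_fmt_table(self.offspring_iq_table, "Offspring exposures vs IQ"))
        parts.append(_fmt_table(self.maternal_iq_table,
                                "Maternal scores vs offspring IQ (duo contrast)"))
        dc = self.diabetes_contrast
        parts.append(
            f"== Maternal diabetes/glycosuria vs IQ == beta {dc.beta:.2f} "
            f"(95% CI {dc.ci95[0]:.2f}, {dc.ci95[1]:.2f}; p {dc.p_value:.3g}; n {dc.n})\n"
        )
        if self.confounder_scan is not None:
            s = self.confounder_scan
            parts.append(
                f"== Confounder scan == {s.observed_nominal} nominal associations "
                f"observed vs {s.expected_nominal} expected in {s.n_tests} tests "
                f"({100 * s.observed_fraction:.1f}%)\n"
            )
        return "\n".join(parts)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


# ---------------------------------------------------------------------------
# replication harness


def replicate_study(
    sim_config: SimulationConfig,
    n_replicates: int,
    study_config: StudyConfig | None = None,
    catalog: list[VariantRecord] | None = None,
) -> dict:
    """Monte-Carlo harness: refit the study across seeds and summarise recovery.

    For each key contrast (instrument fg/hba1c, adjusted and unadjusted
    maternal T2DGRS → IQ, diabetes contrast) returns the mean estimate,
    empirical SE of the estimates, mean model SE, empirical 95% CI coverage of
    the generating value, and the nominal rejection rate.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    catalog = load_catalog() if catalog is None else catalog
    study_config = study_config or StudyConfig(
        include_confounder_scan=False, include_hwe=False, include_pcs=False
    )
    truths = {
        "fggrs_fasting_glucose": sim_config.fg_model.per_weighted_allele,
        "fggrs_hba1c": sim_config.hba1c_model.per_weighted_allele,
        "maternal_t2dgrs_iq_adjusted": sim_config.iq_model.maternal_effect,
        "maternal_t2dgrs_iq_unadjusted": None,  # biased under offspring effects by design
        "diabetes_contrast_iq": sim_config.iq_model.maternal_diabetes_effect,
    }
    draws: dict[str, list[tuple[float, float, float]]] = {k: [] for k in truths}

    base = dict(sim_config.to_dict())
    for i in range(n_replicates):
        base["seed"] = sim_config.seed + i
        cfg = SimulationConfig.from_dict(base)
        result = DuoStudy.from_simulation(cfg, study_config, catalog).fit()

        inst = result.instrument_table
        fg_row = inst[(inst.exposure == "FGGRS") & (inst.outcome == "fasting_glucose")
                      & (inst.covariates == "")].iloc[0]
        hb_row = inst[(inst.exposure == "FGGRS") & (inst.outcome == "hba1c")
                      & (inst.covariates == "")].iloc[0]
        mat = result.maternal_iq_table
        t2_rows = mat[mat.exposure == "maternal_T2DGRS"]
        unadj = t2_rows[t2_rows.covariates == ""].iloc[0]
        adj = t2_rows[t2_rows.covariates != ""].iloc[0]
        dc = result.diabetes_contrast

        for key, row in (("fggrs_fasting_glucose", fg_row), ("fggrs_hba1c", hb_row),
                         ("maternal_t2dgrs_iq_adjusted", adj),
                         ("maternal_t2dgrs_iq_unadjusted", unadj)):
            draws[key].append((float(row.beta), float(row.se), float(row.p_value)))
        draws["diabetes_contrast_iq"].append((dc.beta, dc.se, dc.p_value))

    out = {}
    for key, vals in draws.items():
        betas = np.array([v[0] for v in vals])
        ses = np.array([v[1] for v in vals])
        ps = np.array([v[2] for v in vals])
        truth = truths[key]
        entry = {
            "n_replicates": n_replicates,
            "mean_estimate": float(betas.mean()),
            "empirical_se": float(betas.std(ddof=1)),
            "mean_model_se": float(ses.mean()),
            "rejection_rate": float((ps < 0.05).mean()),
            "truth": truth,
        }
        if truth is not None:
            cover = (betas - 1.96 * ses <= truth) & (truth <= betas + 1.96 * ses)
            entry["coverage_95"] = float(cover.mean())
        out[key] = entry
    return out


# ---------------------------------------------------------------------------
# report schema


def validate_report(report: dict, schema: dict | None = None, _path: str = "$") -> None:
    """Validate a report dict against the shipped structural schema.

    Supports the subset of JSON Schema the shipped file uses: ``type``,
    ``required`` and ``properties``. Raises ValueError naming the first
    offending path.
    """
    if schema is None:
        text = resources.files("duoscore.data").joinpath("study_report.schema.json").read_text()
        schema = json.loads(text)
    t = schema.get("type")
    type_map = {"object": dict, "array": list, "string": str, "number": (int, float),
                "integer": (int, np.integer), "boolean": bool}
    if t is not None and report is not None:
        expected = type_map[t]
        if not isinstance(report, expected):
            raise ValueError(f"{_path}: expected {t}, got {type(report).__name__}")
    if t == "object" and report is not None:
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{_path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{_path}.{key}")
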