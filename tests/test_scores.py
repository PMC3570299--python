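"""Score definitions, computation, missingness policies and analytic moments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duoscore.catalog import MISSING, GenotypeMatrix, RiskOrientation, VariantRecord
from duoscore.scores import (
    FG_DENOMINATOR,
    T2D_DENOMINATOR_PRINTED,
    MissingPolicy,
    ScoreDefinition,
    Trait,
    analytic_score_moments,
    build_definition,
    compute_score,
    score_summary,
)

EXCLUDED = {"rs12255372", "rs2237892", "rs1501299", "rs17300539", "rs266729",
            "rs12779790", "rs20417", "rs9939609"}


class TestBuildDefinition:
    def test_fggrs_terms_and_denominator(self, fg_def):
        assert fg_def.scale == 16
        assert len(fg_def.terms) == 16
        assert fg_def.denominator == FG_DENOMINATOR
        assert fg_def.weight_sum == pytest.approx(0.474, abs=1e-12)

    def test_t2dgrs_printed_vs_consistent_denominator(self, catalog, t2d_def):
        assert t2d_def.scale == 22
        assert t2d_def.denominator == T2D_DENOMINATOR_PRINTED
        assert t2d_def.weight_sum == pytest.approx(2.89, abs=1e-12)
        alt = build_definition(catalog, Trait.T2D, consistent_denominator=True)
        assert alt.denominator == pytest.approx(2.89, abs=1e-12)

    def test_excluded_variants_never_appear(self, fg_def, t2d_def):
        assert not (set(fg_def.rsids) | set(t2d_def.rsids)) & EXCLUDED

    def test_eight_shared_snps(self, fg_def, t2d_def):
        assert len(set(fg_def.rsids) & set(t2d_def.rsids)) == 8

    def test_missing_snp_is_hard_error(self, catalog):
        pruned = [r for r in catalog if r.rsid != "rs560887"]
        with pytest.raises(KeyError, match="rs560887"):
            build_definition(pruned, Trait.FASTING_GLUCOSE)

    def test_scale_must_match_terms(self):
        with pytest.raises(ValueError, match="K must equal"):
            ScoreDefinition("x", (("rs1", 0.1),), denominator=0.1, scale=2)


def _matrix_from_risk_counts(definition, catalog, risk_counts):
    """Build a genotype matrix whose risk-allele counts are as requested."""
    by_rsid = {r.rsid: r for r in catalog}
    cols = []
    for rsid in definition.rsids:
        g_risk = np.asarray(risk_counts[rsid], dtype=np.int8)
        if by_rsid[rsid].risk_orientation is RiskOrientation.MAJOR:
            g_minor = np.where(g_risk == MISSING, MISSING, 2 - g_risk)
        else:
            g_minor = g_risk
        cols.append(g_minor.astype(np.int8))
    n = len(cols[0])
    return GenotypeMatrix([f"i{k}" for k in range(n)], list(definition.rsids),
                          np.column_stack(cols))


class TestComputeScore:
    def test_all_risk_homozygotes_hit_upper_bound(self, fg_def, catalog):
        gm = _matrix_from_risk_counts(fg_def, catalog,
                                      {r: [2] for r in fg_def.rsids})
        assert compute_score(gm, fg_def, catalog).values[0] == pytest.approx(32.0)

    def test_all_heterozygotes_at_midpoint(self, fg_def, catalog):
        gm = _matrix_from_risk_counts(fg_def, catalog,
                                      {r: [1] for r in fg_def.rsids})
        assert compute_score(gm, fg_def, catalog).values[0] == pytest.approx(16.0)

    def test_single_term_arithmetic(self, fg_def, catalog):
        counts = {r: [0] for r in fg_def.rsids}
        counts["rs560887"] = [2]
        gm = _matrix_from_risk_counts(fg_def, catalog, counts)
        # (2 * 0.075 / 0.474) * 16 = 5.063 to 4 significant figures
        assert compute_score(gm, fg_def, catalog).values[0] == pytest.approx(
            5.063, abs=5e-4)

    def test_missing_policies(self, fg_def, catalog):
        counts = {r: [1, 1] for r in fg_def.rsids}
        counts["rs560887"] = [MISSING, 1]
        gm = _matrix_from_risk_counts(fg_def, catalog, counts)

        cc = compute_score(
            gm,
            ScoreDefinition(fg_def.name, fg_def.terms, fg_def.denominator,
                            fg_def.scale, MissingPolicy.COMPLETE_CASE),
            catalog,
        )
        assert np.isnan(cc.values[0]) and cc.values[1] == pytest.approx(16.0)

        zf = compute_score(gm, ScoreDefinition(fg_def.name, fg_def.terms,
                                               fg_def.denominator, fg_def.scale,
                                               MissingPolicy.ZERO_FILL), catalog)
        expected = (sum(w for r, w in fg_def.terms if r != "rs560887") / 0.474) * 16
        assert zf.values[0] == pytest.approx(expected)

        rn = compute_score(gm, ScoreDefinition(fg_def.name, fg_def.terms,
                                               fg_def.denominator, fg_def.scale,
                                               MissingPolicy.RENORMALIZE), catalog)
        assert rn.values[0] == pytest.approx(16.0)  # all observed terms are hets
        assert rn.values[1] == pytest.approx(16.0)

    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    @settings(deadline=None, max_examples=20)
    def test_bounds_under_every_policy(self, fg_def, catalog, seed):
        rng = np.random.default_rng(seed)
        counts = {r: rng.choice([0, 1, 2, MISSING], size=5, p=[0.3, 0.3, 0.3, 0.1])
                  for r in fg_def.rsids}
        gm = _matrix_from_risk_counts(fg_def, catalog, counts)
        for policy in MissingPolicy:
            d = ScoreDefinition(fg_def.name, fg_def.terms, fg_def.denominator,
                                fg_def.scale, policy)
            v = compute_score(gm, d, catalog).values
            v = v[~np.isnan(v)]
            assert ((v >= 0) & (v <= 2 * fg_def.scale)).all()

    def test_policies_agree_on_complete_rows(self, fg_def, catalog, rng):
        counts = {r: rng.choice([0, 1, 2], size=50) for r in fg_def.rsids}
        gm = _matrix_from_risk_counts(fg_def, catalog, counts)
        vals = {}
        for policy in MissingPolicy:
            d = ScoreDefinition(fg_def.name, fg_def.terms, fg_def.denominator,
                                fg_def.scale, policy)
            vals[policy] = compute_score(gm, d, catalog).values
        np.testing.assert_allclose(vals[MissingPolicy.ZERO_FILL],
                                   vals[MissingPolicy.COMPLETE_CASE])
        np.testing.assert_allclose(vals[MissingPolicy.RENORMALIZE],
                                   vals[MissingPolicy.COMPLETE_CASE])

    def test_orientation_invariance(self, fg_def, catalog, rng):
        """Flipping a record's allele labels and its coding leaves scores unchanged."""
        counts = {r: rng.choice([0, 1, 2], size=30) for r in fg_def.rsids}
        gm = _matrix_from_risk_counts(fg_def, catalog, counts)
        base = compute_score(gm, fg_def, catalog).values

        flipped_catalog = []
        for rec in catalog:
            if rec.rsid == "rs560887":
                rec = VariantRecord(
                    rsid=rec.rsid, gene=rec.gene,
                    major_allele=rec.minor_allele, minor_allele=rec.major_allele,
                    maf_mothers=rec.maf_mothers, maf_children=rec.maf_children,
                    maf_ceu=rec.maf_ceu,
                    risk_orientation=(RiskOrientation.MINOR
                                      if rec.risk_orientation is RiskOrientation.MAJOR
                                      else RiskOrientation.MAJOR),
                    trait_tags=rec.trait_tags, fg_weight=rec.fg_weight,
                    t2d_weight=rec.t2d_weight, proxy_of=rec.proxy_of,
                )
            flipped_catalog.append(rec)
        flipped_counts = gm.counts.copy()
        j = gm.variant_ids.index("rs560887")
        flipped_counts[:, j] = 2 - flipped_counts[:, j]
        gm2 = GenotypeMatrix(list(gm.individual_ids), list(gm.variant_ids), flipped_counts)
        flipped = compute_score(gm2, fg_def, flipped_catalog).values
        np.testing.assert_allclose(flipped, base)


class TestAnalyticMoments:
    def test_enumeration_oracle(self, fg_def, catalog):
        """Closed form must match direct enumeration over HWE genotype probabilities."""
        by_rsid = {r.rsid: r for r in catalog}
        mean = var = 0.0
        K, W = fg_def.scale, fg_def.denominator
        for rsid, w in fg_def.terms:
            p = by_rsid[rsid].risk_allele_frequency("children")
            probs = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p ** 2}
            e = sum(g * q for g, q in probs.items())
            e2 = sum(g * g * q for g, q in probs.items())
            mean += w * e
            var += w * w * (e2 - e * e)
        expected = (K / W * mean, (K / W) ** 2 * var)
        assert analytic_score_moments(fg_def, catalog, "children") == pytest.approx(expected)

    def test_children_fggrs_mean_matches_reported_distribution(self, fg_def, catalog):
        """The HWE expectation reproduces the published observed mean (~17.1)."""
        mean, _ = analytic_score_moments(fg_def, catalog, "children")
        assert mean == pytest.approx(17.12, abs=0.01)

    def test_children_t2dgrs_mean_matches_reported_distribution(self, t2d_def, catalog):
        mean, _ = analytic_score_moments(t2d_def, catalog, "children")
        assert mean == pytest.approx(22.6, abs=0.05)

    def test_symmetric_frequencies_give_mean_K(self, fg_def, catalog):
        half = [VariantRecord(
            rsid=r.rsid, gene=r.gene, major_allele=r.major_allele,
            minor_allele=r.minor_allele, maf_mothers=0.5, maf_children=0.5,
            maf_ceu=r.maf_ceu, risk_orientation=r.risk_orientation,
            trait_tags=r.trait_tags, fg_weight=r.fg_weight, t2d_weight=r.t2d_weight,
        ) for r in catalog]
        mean, _ = analytic_score_moments(fg_def, half, "children")
        assert mean == pytest.approx(fg_def.scale)

    def test_degenerate_limit(self, fg_def, catalog):
        """Risk-allele frequency -> 1 drives the mean to 2K and variance to 0."""
        # make every term SNP major-risk with a vanishing MAF, so p -> 1
        fixed = [VariantRecord(
            rsid=r.rsid, gene=r.gene, major_allele=r.major_allele,
            minor_allele=r.minor_allele, maf_mothers=r.maf_mothers,
            maf_children=1e-9, maf_ceu=r.maf_ceu,
            risk_orientation=RiskOrientation.MAJOR,
            trait_tags=r.trait_tags, fg_weight=r.fg_weight, t2d_weight=r.t2d_weight,
        ) for r in catalog]
        mean, var = analytic_score_moments(fg_def, fixed, "children")
        limit = 2 * fg_def.scale * fg_def.weight_sum / fg_def.denominator
        assert mean == pytest.approx(limit, rel=1e-6)
        assert var == pytest.approx(0.0, abs=1e-6)


class TestScoreSummary:
    def test_constant_vector(self, fg_def, catalog):
        gm = _matrix_from_risk_counts(fg_def, catalog, {r: [1, 1, 1] for r in fg_def.rsids})
        s = score_summary(compute_score(gm, fg_def, catalog))
        assert s["mean"] == pytest.approx(16.0)
        assert s["sd"] == 0.0
        assert s["min"] == pytest.approx(16.0)
        assert s["max"] == pytest.approx(16.0)

    def test_all_missing_errors(self, fg_def, catalog):
        gm = _matrix_from_risk_counts(fg_def, catalog,
                                      {r: [MISSING] for r in fg_def.rsids})
        d = ScoreDefinition(fg_def.name, fg_def.terms, fg_def.denominator,
                            fg_def.scale, MissingPolicy.COMPLETE_CASE)
        with pytest.raises(ValueError, match="all scores are missing"):
            score_summary(compute_score(gm, d, catalog))
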