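"""Weighted risk-allele-score pipeline on synthetic cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

from msrisk.association import (
    DEFAULT_BINS_5,
    DEFAULT_BINS_6,
    a_priori_risk,
    binned_or_vs_prior,
    cohort_auc,
    per_snp_association,
    weighted_scores,
)
from msrisk.cohort import CohortSpec, generate_cohort
from msrisk.panels import Panel, VariantSpec, builtin_panel
from msrisk.simulate import UndefinedAUCError

HLA = "rs3135388"


def _toy_cohort(n_cases, n_controls, genotypes=None, rsid="rs1"):
    n = n_cases + n_controls
    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "status": [1] * n_cases + [0] * n_controls,
            "age": np.linspace(30, 60, n),
            "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        }
    )
    if genotypes is None:
        genotypes = np.zeros(n, dtype=int)
    frame[rsid] = pd.array(genotypes, dtype="Int64")
    return frame


class TestAPrioriRisk:
    def test_study_sized_cohort_prints_49_percent(self):
        cohort = _toy_cohort(564, 581)
        risk = a_priori_risk(cohort)
        assert risk == pytest.approx(564 / 1145)
        assert f"{risk:.0%}" == "49%"

    def test_balanced_cohort(self):
        assert a_priori_risk(_toy_cohort(50, 50)) == pytest.approx(0.5)

    def test_all_cases(self):
        assert a_priori_risk(_toy_cohort(10, 0)) == pytest.approx(1.0)

    def test_incomplete_subjects_excluded(self):
        cohort = _toy_cohort(10, 10)
        cohort.loc[cohort.index[:5], "rs1"] = pd.NA  # five cases incomplete
        assert a_priori_risk(cohort) == pytest.approx(5 / 15)


class TestWeightedScores:
    def test_zero_alleles_zero_score(self, complete_cohort, panel_empirical_6):
        scores = weighted_scores(complete_cohort, panel_empirical_6)
        zero = scores[scores.risk_allele_count == 0]
        assert (zero.weighted_score == 0).all()

    def test_hla_homozygote_weight(self):
        panel = builtin_panel("panel_empirical_6")
        cohort = _toy_cohort(1, 1, rsid=HLA, genotypes=[2, 0])
        for v in panel.variants:
            if v.rsid != HLA:
                cohort[v.rsid] = pd.array([0, 0], dtype="Int64")
        scores = weighted_scores(cohort, panel)
        assert scores.weighted_score.iloc[0] == pytest.approx(
            2 * math.log(2.53), abs=1e-12
        )

    def test_one_score_per_complete_subject(self, complete_cohort, panel_empirical_6):
        scores = weighted_scores(complete_cohort, panel_empirical_6)
        assert len(scores) == len(complete_cohort)

    def test_raw_or_weighting_flag(self, complete_cohort, panel_empirical_6):
        log_w = weighted_scores(complete_cohort, panel_empirical_6)
        raw_w = weighted_scores(complete_cohort, panel_empirical_6, weight="raw_or")
        assert not np.allclose(log_w.weighted_score, raw_w.weighted_score)


class TestPerSnpAssociation:
    def test_recovers_generative_hla_or(self, default_cohort):
        assoc = {a.rsid: a for a in per_snp_association(default_cohort)}
        hla = assoc[HLA]
        assert hla.ci_low < 2.53 < hla.ci_high
        assert hla.significant_bonferroni

    def test_null_cohort_coverage_single(self):
        null_panel = Panel(
            "null", tuple(
                VariantSpec("G", f"rs{i}", "1", "A", 0.3, 1.0) for i in range(6)
            )
        )
        cohort = generate_cohort(CohortSpec(panel=null_panel, seed=8,
                                            n_cases=300, n_controls=300))
        assoc = per_snp_association(cohort, adjust="none")
        covered = sum(a.ci_low < 1.0 < a.ci_high for a in assoc)
        assert covered >= 5  # expect ~5.7 of 6 at nominal 95%

    def test_monomorphic_variant_flagged(self):
        cohort = _toy_cohort(10, 10, genotypes=np.zeros(20, dtype=int))
        (assoc,) = per_snp_association(cohort)
        assert assoc.flagged == "monomorphic"
        assert np.isnan(assoc.per_allele_or)

    def test_adjustment_changes_little_without_confounding(self, default_cohort):
        crude = {a.rsid: a.per_allele_or for a in
                 per_snp_association(default_cohort, adjust="none")}
        adj = {a.rsid: a.per_allele_or for a in
               per_snp_association(default_cohort, adjust="age_sex")}
        for rsid in crude:
            assert adj[rsid] == pytest.approx(crude[rsid], rel=0.15)


class TestBinnedOr:
    def test_deviation_coding_identity(self, complete_cohort, panel_empirical_6):
        """Bin-size-weighted mean of fitted bin log-odds equals the model
        reference exactly (the sum-to-zero constraint)."""
        scores = weighted_scores(complete_cohort, panel_empirical_6)
        bin_ors = binned_or_vs_prior(scores, adjust="none")
        sizes = np.array([b.n_cases + b.n_controls for b in bin_ors], dtype=float)
        # crude saturated model: fitted bin log-odds are the empirical ones
        logodds = np.array(
            [math.log(b.n_cases / b.n_controls) for b in bin_ors]
        )
        # reconstruct the model deviations: beta_b = logodds_b - intercept
        intercept = (sizes * logodds).sum() / sizes.sum()
        deviations = logodds - intercept
        assert (sizes * deviations).sum() == pytest.approx(0.0, abs=1e-9)

    def test_reference_bin_or_near_one(self):
        # a bin with the overall case fraction sits at the reference
        counts = np.array([0] * 100 + [1] * 100)
        status = np.array([1] * 50 + [0] * 50 + [1] * 50 + [0] * 50)
        scores = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(200)],
                "status": status,
                "age": np.linspace(20, 80, 200),
                "sex": ["F", "M"] * 100,
                "risk_allele_count": counts,
                "weighted_score": counts * 0.5,
            }
        )
        out = binned_or_vs_prior(scores, bins=((0, 0), (1, 1)), adjust="none")
        for b in out:
            assert b.or_vs_prior == pytest.approx(1.0, abs=1e-9)
            assert b.ci_low < 1.0 < b.ci_high

    def test_gradient_direction(self, complete_cohort, panel_empirical_6):
        """Top allele-count bin enriched for cases, bottom bin depleted."""
        scores = weighted_scores(complete_cohort, panel_empirical_6)
        out = binned_or_vs_prior(scores, bins=DEFAULT_BINS_6)
        assert out[-1].or_vs_prior > 1.2
        assert out[0].or_vs_prior < 0.8
        assert all(b.ci_low < b.or_vs_prior < b.ci_high for b in out)

    def test_excluding_hla_flattens_gradient(self, complete_cohort):
        """Without the strongest variant the top-bin OR moves toward 1."""
        panel = builtin_panel("panel_empirical_6")
        with_hla = binned_or_vs_prior(
            weighted_scores(complete_cohort, panel), bins=DEFAULT_BINS_6
        )
        without = binned_or_vs_prior(
            weighted_scores(complete_cohort, panel.drop([HLA])),
            bins=DEFAULT_BINS_5,
        )
        assert without[-1].or_vs_prior < with_hla[-1].or_vs_prior

    def test_uncovered_counts_rejected(self, complete_cohort, panel_empirical_6):
        scores = weighted_scores(complete_cohort, panel_empirical_6)
        with pytest.raises(ValueError, match="cover"):
            binned_or_vs_prior(scores, bins=((0, 1),))


class TestCohortAuc:
    def test_null_panel_near_half(self):
        null_panel = Panel(
            "null", tuple(
                VariantSpec("G", f"rs{i}", "1", "A", 0.4, 1.0) for i in range(4)
            )
        )
        cohort = generate_cohort(CohortSpec(panel=null_panel, seed=3,
                                            missing_rate=0.0))
        scores = weighted_scores(cohort, null_panel)
        # all weights ln(1)=0: scores all tie, AUC exactly 1/2
        assert cohort_auc(scores) == pytest.approx(0.5, abs=1e-12)

    def test_perfect_separation(self):
        scores = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "status": [1, 1, 0, 0],
                "age": [40.0] * 4,
                "sex": ["F"] * 4,
                "risk_allele_count": [4, 3, 1, 0],
                "weighted_score": [4.0, 3.0, 1.0, 0.0],
            }
        )
        assert cohort_auc(scores) == pytest.approx(1.0)

    def test_single_class_raises(self):
        scores = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "status": [1, 1],
                "age": [40.0, 41.0],
                "sex": ["F", "M"],
                "risk_allele_count": [2, 3],
                "weighted_score": [1.0, 2.0],
            }
        )
        with pytest.raises(UndefinedAUCError):
            cohort_auc(scores)

    def test_realistic_cohort_auc_range(self, complete_cohort, panel_empirical_6):
        scores = weighted_scores(complete_cohort, panel_empirical_6)
        assert 0.55 < cohort_auc(scores) < 0.75
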