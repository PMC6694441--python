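"""ROI-level ANOVA, post-hoc contrasts and clinical-score correlations."""

import numpy as np
import pytest
from scipy import stats

from taunet.cohort import CohortTable, SubjectRecord
from taunet.regional import (anova_regions, correlate_csf_pet,
                             correlate_with_score, posthoc_contrasts)
from taunet.simulate import SimulationConfig, generate_cohort

from conftest import small_config
import oracles


class TestAnova:
    def test_location_invariance(self, small_cohort):
        cohort, _ = small_cohort
        shifted = CohortTable(cohort.atlas, cohort.subjects,
                              cohort.values + 17.3)
        a = anova_regions(cohort)
        b = anova_regions(shifted)
        np.testing.assert_allclose(a["F"], b["F"], rtol=1e-9)

    def test_matches_sum_of_squares_oracle(self, small_cohort):
        cohort, _ = small_cohort
        # overwrite one region with small integers for an exact hand check
        rng = np.random.default_rng(0)
        cohort = CohortTable(cohort.atlas, cohort.subjects,
                             cohort.values.copy())
        cohort.values[:, 0] = rng.integers(0, 10, cohort.n_subjects)
        groups = cohort.meta("group")
        samples = [cohort.values[groups == g, 0]
                   for g in ("A4-T-", "A4+T+", "A4+T-", "A4-T+")]
        res = anova_regions(cohort)
        assert res.loc[0, "F"] == pytest.approx(
            oracles.anova_f_by_sums_of_squares(samples), abs=1e-12)

    def test_two_group_f_equals_t_squared(self):
        cfg = small_config(group_sizes={"A4-T-": 12, "A4+T+": 10})
        cohort, _ = generate_cohort(cfg, seed=1)
        res = anova_regions(cohort)
        groups = cohort.meta("group")
        for j in (0, 30, 89):
            t = oracles.pooled_t(cohort.values[groups == "A4-T-", j],
                                 cohort.values[groups == "A4+T+", j])
            assert res.loc[j, "F"] == pytest.approx(t ** 2, rel=1e-9)

    def test_planted_elevation_recovered(self, atlas):
        cfg = SimulationConfig(effect_size=1.0)
        cohort, truth = generate_cohort(cfg, seed=30)
        res = anova_regions(cohort, adjust_covariates=True)
        planted = truth.effect_regions["A4+T+"]
        flagged = set(res.loc[res["significant"], "region"])
        assert len(flagged & set(planted)) >= 7

    def test_degenerate_region_excluded(self, small_cohort):
        cohort, _ = small_cohort
        cohort = CohortTable(cohort.atlas, cohort.subjects, cohort.values.copy())
        cohort.values[:, 5] = 2.0
        res = anova_regions(cohort)
        assert bool(res.loc[5, "degenerate"])
        assert np.isnan(res.loc[5, "p_adj"])


class TestPosthoc:
    def test_identical_comparison_group_gives_zero_t(self, atlas, rng):
        base = [SubjectRecord(id=f"a{i}", group="A4-T-", age=70 + i, sex=i % 2,
                              diagnosis="NC") for i in range(8)]
        clones = [SubjectRecord(id=f"b{i}", group="A4+T-", age=70 + i, sex=i % 2,
                                diagnosis="NC") for i in range(8)]
        vals = rng.normal(size=(8, len(atlas)))
        cohort = CohortTable(atlas, base + clones, np.vstack([vals, vals]))
        out = posthoc_contrasts(cohort, "A4-T-",
                                restrict_to=list(atlas.names[:10]))
        df = out["A4+T-"]
        np.testing.assert_allclose(df["t"], 0.0, atol=1e-12)
        assert not df["significant"].any()

    def test_matches_pooled_t_oracle(self):
        cfg = small_config(group_sizes={"A4-T-": 12, "A4+T+": 10})
        cohort, _ = generate_cohort(cfg, seed=2)
        out = posthoc_contrasts(cohort, "A4-T-",
                                restrict_to=[cohort.atlas.names[3]])
        groups = cohort.meta("group")
        expected = oracles.pooled_t(cohort.values[groups == "A4+T+", 3],
                                    cohort.values[groups == "A4-T-", 3])
        assert out["A4+T+"].loc[0, "t"] == pytest.approx(expected, rel=1e-9)

    def test_planted_elevation_specific_to_planted_group(self):
        hits, false_hits = 0, 0
        n_seeds = 5
        for seed in range(n_seeds):
            cohort, truth = generate_cohort(SimulationConfig(), seed=100 + seed)
            out = posthoc_contrasts(cohort, "A4-T-", adjust_covariates=True)
            planted = set(truth.effect_regions["A4+T+"])
            hits += len(planted & set(
                out["A4+T+"].loc[out["A4+T+"]["significant"], "region"]))
            for g in ("A4+T-", "A4-T+"):
                false_hits += int(out[g]["significant"].sum())
        assert hits >= 0.8 * n_seeds * 10      # most planted regions, per seed
        assert false_hits <= 0.1 * n_seeds * 10  # rarely in unaffected groups


class TestScoreCorrelation:
    def test_score_equal_to_region_gives_unit_r(self, atlas, rng):
        vals = rng.normal(size=(10, len(atlas)))
        subs = [SubjectRecord(id=f"s{i}", group="A4+T+", age=float(vals[i, 0]),
                              sex=0, diagnosis="MCI") for i in range(10)]
        cohort = CohortTable(atlas, subs, vals)
        df = correlate_with_score(cohort, [atlas.names[0]], "age", "A4+T+")
        assert df.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_score_rejected(self, atlas, rng):
        vals = rng.normal(size=(6, len(atlas)))
        subs = [SubjectRecord(id=f"s{i}", group="A4+T+", age=70.0, sex=0,
                              diagnosis="MCI", faq=5) for i in range(6)]
        cohort = CohortTable(atlas, subs, vals)
        with pytest.raises(ValueError, match="constant"):
            correlate_with_score(cohort, [atlas.names[0]], "faq", "A4+T+")

    def test_missing_scores_dropped_pairwise(self, atlas, rng):
        vals = rng.normal(size=(8, len(atlas)))
        subs = [SubjectRecord(id=f"s{i}", group="A4+T+", age=70.0, sex=0,
                              diagnosis="MCI", faq=None if i < 2 else i)
                for i in range(8)]
        cohort = CohortTable(atlas, subs, vals)
        df = correlate_with_score(cohort, [atlas.names[0]], "faq", "A4+T+")
        assert df.loc[0, "n"] == 6

    def test_independent_score_rejects_at_nominal_rate(self, atlas):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=30)
            score = rng.normal(size=30)
            _, p = stats.pearsonr(x, score)
            rejections += p < 0.05
        # direct null calibration of the Pearson p-value at the group size used
        assert 0.02 <= rejections / reps <= 0.09

    def test_planted_faq_coupling_recovers_positive_r(self):
        positives = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort, truth = generate_cohort(SimulationConfig(), seed=200 + seed)
            df = correlate_with_score(cohort,
                                      list(truth.effect_regions["A4+T+"]),
                                      "faq", "A4+T+")
            positives += bool((df["r"] > 0).all())
        assert positives >= 0.9 * n_seeds


class TestCsfCorrelation:
    def test_proportional_ttau_gives_unit_global_r(self, atlas, rng):
        vals = rng.normal(1.5, 0.2, size=(12, len(atlas)))
        gm = vals.mean(axis=1)
        ttau = 600.0 + 30.0 * (gm - gm.mean()) / gm.std()
        subs = [SubjectRecord(id=f"s{i}", group="A4+T+", age=70.0, sex=0,
                              diagnosis="MCI", csf_ttau=float(ttau[i]))
                for i in range(12)]
        cohort = CohortTable(atlas, subs, vals)
        df = correlate_csf_pet(cohort, "A4+T+")
        assert df.loc[df["region"] == "GLOBAL_MEAN", "r"].iloc[0] == \
            pytest.approx(1.0, abs=1e-12)

    def test_planted_csf_regions_rank_top_two(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort, truth = generate_cohort(SimulationConfig(), seed=300 + seed)
            df = correlate_csf_pet(cohort, truth.csf_group)
            df = df[df["region"] != "GLOBAL_MEAN"]
            top2 = set(df.reindex(df["r"].abs().sort_values().index)
                       .tail(2)["region"])
            hits += top2 == set(truth.csf_regions)
        assert hits >= 0.8 * n_seeds
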