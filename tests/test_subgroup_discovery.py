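import itertools

import numpy as np
import pytest
from scipy import stats

from psycohort import subgroup_discovery as sd
from psycohort.synthetic_cohort import GeneratorConfig, generate_cohort, preset


def make_sample(n, n_members, seed, member_r=0.9, member_resp=0.95, bg_resp=0.35):
    """Hand-built analysis sample with a planted linear member subset."""
    rng = np.random.default_rng(seed)
    score = rng.uniform(10, 70, n)
    igm = np.exp(rng.normal(0, 0.4, n))
    member = np.zeros(n, dtype=bool)
    member[rng.choice(n, n_members, replace=False)] = True
    if n_members:
        g = score[member]
        noise_sd = 0.02 * np.std(g) * np.sqrt(1 / member_r**2 - 1)
        igm[member] = 1.0 + 0.02 * g + rng.normal(0, noise_sd, n_members)
    p_resp = np.where(member, member_resp, bg_resp)
    resp = np.where(
        rng.random(n) < p_resp,
        "responder",
        np.where(rng.random(n) < 0.4, "partial", "non_responder"),
    )
    features = rng.uniform(0, 1, (n, 9))
    features[member, 0] = rng.uniform(0.7, 1.0, n_members)
    return (
        sd.AnalysisSample(
            diagnosis="F2",
            patient_ids=tuple(f"P{i:03d}" for i in range(n)),
            features=features,
            igm=igm,
            score=score,
            response=resp,
        ),
        member,
    )


class TestSubgroupStatistics:
    def test_variance_identity(self):
        sample, member = make_sample(40, 12, seed=1)
        r, p, fp, var = sd.subgroup_statistics(
            member, sample.igm, sample.score, sample.response
        )
        assert var == pytest.approx(100.0 * r**2, abs=1e-12)

    def test_exact_linear_members(self):
        igm = np.arange(10, dtype=float)
        score = 3.0 + 2.0 * igm
        resp = np.array(["responder"] * 10)
        r, p, fp, var = sd.subgroup_statistics(
            np.ones(10, dtype=bool), igm, score, resp
        )
        assert r == pytest.approx(1.0)
        assert p < 1e-12
        assert fp == 0.0

    def test_fp_rate_counts_non_responders(self):
        igm = np.linspace(1, 2, 18)
        score = 10 + 30 * igm + np.linspace(-1, 1, 18)
        resp = np.array(["responder"] * 17 + ["non_responder"])
        _, _, fp, _ = sd.subgroup_statistics(
            np.ones(18, dtype=bool), igm, score, resp
        )
        assert fp == pytest.approx(1 / 18)

    def test_too_few_members(self):
        with pytest.raises(ValueError, match="at least 5"):
            sd.subgroup_statistics(
                np.arange(4), np.ones(10), np.ones(10), np.array(["responder"] * 10)
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sd.subgroup_statistics(
                np.arange(6),
                np.full(10, 1.5),
                np.arange(10, dtype=float),
                np.array(["responder"] * 10),
            )

    def test_pvalue_matches_scipy(self):
        sample, member = make_sample(50, 15, seed=3)
        r, p, _, _ = sd.subgroup_statistics(
            member, sample.igm, sample.score, sample.response
        )
        r_sp, p_sp = stats.pearsonr(sample.igm[member], sample.score[member])
        assert r == pytest.approx(r_sp)
        assert p == pytest.approx(p_sp, rel=1e-9)


def test_variance_explained_helper():
    assert sd.variance_explained_pct(0.746) == pytest.approx(55.65, abs=0.01)


class TestExcludeIncomplete:
    def test_f2_exclusion_report(self):
        cohort = generate_cohort(GeneratorConfig(n_f3=0, n_f2=84, seed=2))
        ids = cohort.patients["patient_id"].iloc[:4]
        cohort.patients.loc[
            cohort.patients["patient_id"].isin(ids), "dim_delusions"
        ] = np.nan
        sample, report = sd.exclude_incomplete(cohort, "F2")
        assert sample.n == 80
        assert report["n_excluded"] == 4
        assert report["excluded_pct"] == 4.8

    def test_f3_exclusion_report(self):
        cohort = generate_cohort(GeneratorConfig(n_f3=195, n_f2=0, seed=2))
        ids = cohort.patients["patient_id"].iloc[:16]
        cohort.patients.loc[cohort.patients["patient_id"].isin(ids), "igm"] = np.nan
        sample, report = sd.exclude_incomplete(cohort, "F3")
        assert sample.n == 179
        assert report["n_excluded"] == 16
        assert report["excluded_pct"] == 8.2

    def test_no_missing_data_keeps_everyone(self, small_cohort):
        sample, report = sd.exclude_incomplete(small_cohort, "F2")
        assert sample.n == report["n_total"]
        assert report["n_excluded"] == 0

    def test_dropouts_excluded(self):
        cohort = generate_cohort(GeneratorConfig(n_f3=0, n_f2=30, seed=4))
        pid = cohort.patients["patient_id"].iloc[0]
        mask = (cohort.assessments["patient_id"] == pid) & (
            cohort.assessments["day"] > 3
        )
        cohort.assessments = cohort.assessments[~mask]
        sample, report = sd.exclude_incomplete(cohort, "F2")
        assert report["n_excluded"] == 1
        assert pid not in sample.patient_ids

    def test_features_scaled_to_unit_interval(self, small_cohort):
        sample, _ = sd.exclude_incomplete(small_cohort, "F3")
        assert sample.features.min() >= 0.0
        assert sample.features.max() <= 1.0


def brute_force_best(sample, cfg):
    """Independent exhaustive oracle: best feasible subset size (None if
    infeasible everywhere), using scipy's pearsonr directly."""
    best_size = None
    for size in range(cfg.min_size, sample.n + 1):
        for combo in itertools.combinations(range(sample.n), size):
            idx = np.asarray(combo)
            x, y = sample.igm[idx], sample.score[idx]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            fp = np.mean(sample.response[idx] == "non_responder")
            if r > 0 and p < cfg.min_r_pvalue and fp <= cfg.max_fp_rate:
                best_size = size
    return best_size


class TestSearchTinyExact:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_enumeration(self, seed):
        sample, _ = make_sample(12, 6, seed=seed)
        cfg = sd.SearchConfig(min_size=5, seed=seed)
        model = sd.search(sample, cfg)
        oracle = brute_force_best(sample, cfg)
        if oracle is None:
            assert not model.found
        else:
            assert model.found and model.size == oracle

    def test_infeasible_constraints_yield_no_solution(self):
        sample, _ = make_sample(12, 0, seed=5, bg_resp=0.0)
        model = sd.search(sample, sd.SearchConfig(min_size=5, seed=0))
        assert not model.found

    def test_min_size_above_n(self):
        sample, _ = make_sample(8, 4, seed=0)
        model = sd.search(sample, sd.SearchConfig(min_size=20))
        assert not model.found


class TestSearchFull:
    def test_recovery_single_seed(self):
        cohort = generate_cohort(preset("paper-f2", seed=1))
        sample, _ = sd.exclude_incomplete(cohort, "F2")
        truth = cohort.truth.set_index("patient_id")["in_subgroup"]
        true_ids = [p for p in sample.patient_ids if truth[p] == 1]
        model = sd.search(sample, sd.SearchConfig(seed=1))
        assert model.found
        assert sd.jaccard(model.member_ids, true_ids) >= 0.6
        assert model.net is not None

    def test_feasibility_recheck_independent(self):
        cohort = generate_cohort(preset("paper-f2", seed=2))
        sample, _ = sd.exclude_incomplete(cohort, "F2")
        cfg = sd.SearchConfig(seed=2)
        model = sd.search(sample, cfg)
        assert model.found
        idx = [sample.patient_ids.index(p) for p in model.member_ids]
        r, p = stats.pearsonr(sample.igm[idx], sample.score[idx])
        fp = np.mean(sample.response[idx] == "non_responder")
        assert r > 0 and p < cfg.min_r_pvalue and fp <= cfg.max_fp_rate
        assert model.r == pytest.approx(r)
        assert model.fraction == round(len(idx) / sample.n, 3)

    def test_monotone_in_fp_ceiling(self):
        cohort = generate_cohort(preset("paper-f2", seed=3))
        sample, _ = sd.exclude_incomplete(cohort, "F2")
        sizes = []
        for ceiling in (0.06, 0.125, 0.25):
            model = sd.search(
                sample, sd.SearchConfig(seed=3, max_fp_rate=ceiling)
            )
            sizes.append(model.size)
        assert sizes == sorted(sizes)

    def test_deterministic(self):
        cohort = generate_cohort(preset("paper-f2", seed=4))
        sample, _ = sd.exclude_incomplete(cohort, "F2")
        m1 = sd.search(sample, sd.SearchConfig(seed=4))
        m2 = sd.search(sample, sd.SearchConfig(seed=4))
        assert m1.member_ids == m2.member_ids
        assert m1.r == m2.r


class TestCutoffBaseline:
    def test_feature_planted_membership_beats_cutoff(self):
        cohort = generate_cohort(preset("paper-f2", seed=6))
        sample, _ = sd.exclude_incomplete(cohort, "F2")
        cfg = sd.SearchConfig(seed=6)
        nn_model = sd.search(sample, cfg)
        cut_model = sd.cutoff_baseline(sample, cfg)
        assert nn_model.found
        nn_size = nn_model.size
        cut_size = cut_model.size if cut_model.found else 0
        assert cut_size < nn_size

    def test_igm_threshold_planted_membership_matched_by_cutoff(self):
        cohort = generate_cohort(preset("igm-cutoff-f2", seed=7))
        sample, _ = sd.exclude_incomplete(cohort, "F2")
        truth = cohort.truth.set_index("patient_id")["in_subgroup"]
        true_ids = [p for p in sample.patient_ids if truth[p] == 1]
        cut_model = sd.cutoff_baseline(sample, sd.SearchConfig(seed=7))
        assert cut_model.found
        assert cut_model.igm_threshold is not None
        assert sd.jaccard(cut_model.member_ids, true_ids) >= 0.8

    def test_constant_igm_has_no_feasible_cutoff(self):
        sample, _ = make_sample(40, 10, seed=8)
        sample.igm[:] = 1.5
        model = sd.cutoff_baseline(sample, sd.SearchConfig(seed=8))
        assert not model.found


class TestEvaluate:
    def test_reported_fractions(self):
        sample, member = make_sample(80, 18, seed=9, member_resp=1.0)
        model = sd._build_model(sample, np.flatnonzero(member), sd.SearchConfig())
        report = sd.evaluate(model, sample)
        assert report["subgroup_pct"] == 22.5
        assert report["n_members"] == 18
        assert len(report["scatter"]) == 80
        assert report["scatter"]["member"].sum() == 18

    def test_f3_fraction(self):
        sample, member = make_sample(179, 35, seed=10, member_resp=1.0)
        model = sd._build_model(sample, np.flatnonzero(member), sd.SearchConfig())
        report = sd.evaluate(model, sample)
        assert report["subgroup_pct"] == 19.6

    def test_no_solution_report(self):
        sample, _ = make_sample(30, 8, seed=11)
        report = sd.evaluate(sd._no_solution("F2"), sample)
        assert report["found"] is False
        assert "scatter" in report


def test_permutation_pvalue_sane():
    rng = np.random.default_rng(0)
    x = rng.normal(size=15)
    y = 0.9 * x + 0.3 * rng.normal(size=15)
    p_perm = sd.permutation_pvalue(x, y, n_perm=2000, seed=1)
    _, p_t = stats.pearsonr(x, y)
    assert p_perm < 0.01
    x2 = rng.normal(size=15)
    assert sd.permutation_pvalue(x2, y, n_perm=500, seed=2) > 0.05


def test_jaccard():
    assert sd.jaccard([1, 2], [1, 2]) == 1.0
    assert sd.jaccard([1, 2], [3, 4]) == 0.0
    assert sd.jaccard([], []) == 1.0
    assert sd.jaccard([1, 2, 3], [2, 3, 4]) == pytest.approx(0.5)
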