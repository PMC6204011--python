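import warnings

import numpy as np
import pytest

from cstdyn.dmm import CSTAssignment
from cstdyn.temporal import (
    classify_pattern,
    fit_occurrence_surface,
    fit_single_index,
    occurrence_logistic_test,
    sequence_index_summary,
)
from cstdyn.types import VisitSample


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(0)
    n = 400
    return {
        "wol": rng.uniform(0, 60, n),
        "gab": rng.uniform(23, 42, n),
        "subj": [f"S{i % 40}" for i in range(n)],
        "rng": rng,
        "n": n,
    }


class TestOccurrenceSurface:
    def test_constant_outcome_flat_surface(self, design):
        fit = fit_occurrence_surface(np.full(design["n"], 0.3),
                                     design["wol"], design["gab"],
                                     design["subj"])
        w, g = np.meshgrid(np.linspace(5, 55, 15), np.linspace(25, 40, 15))
        assert np.abs(fit.predict(w.ravel(), g.ravel()) - 0.3).max() < 0.02

    def test_wol_only_truth_flat_in_gab(self, design):
        rng = np.random.default_rng(1)
        truth = 1 / (1 + np.exp(-(0.5 * design["wol"] - 10)))
        y = truth + rng.normal(0, 0.05, design["n"])
        fit = fit_occurrence_surface(y, design["wol"], design["gab"],
                                     design["subj"])
        gab_grid = np.linspace(25, 40, 40)
        for w in (10.0, 20.0, 30.0):
            vals = fit.predict(np.full(40, w), gab_grid)
            assert vals.max() - vals.min() < 0.05
        # and it does vary along WOL
        along = fit.predict(np.linspace(5, 40, 40), np.full(40, 32.0))
        assert along.max() - along.min() > 0.5

    def test_interpolates_representable_truth_without_noise(self, design):
        y = 0.2 + 0.01 * design["wol"] + 1e-4 * design["wol"] ** 2
        fit = fit_occurrence_surface(y, design["wol"], design["gab"],
                                     design["subj"])
        pred = fit.predict(design["wol"][:80], design["gab"][:80])
        assert np.abs(pred - y[:80]).max() < 1e-6

    def test_minimum_data_requirements(self):
        with pytest.raises(ValueError):
            fit_occurrence_surface(np.zeros(10), np.arange(10.0),
                                   np.full(10, 30.0), ["s"] * 10)


def _synthetic_cohort(weights, seed):
    from cstdyn.synth import SiteSpec, SynthConfig, simulate_cohort

    mid = 20.0 if weights == (1.0, 0.0) else 50.0
    cfg = SynthConfig(
        n_preterm=14, n_fullterm=16, n_shared_otus=4,
        sites={"gut": SiteSpec(n_otus=12, k=2, index_weights=[weights] * 2,
                               midpoints=[mid, mid], slopes=[-0.3, 0.3])},
        seed=seed)
    subjects, samples, _, truth = simulate_cohort(cfg)
    subj_of = {s.subject_id: s for s in subjects}
    gut = [v for v in samples if v.site == "gut"]
    labels = truth.labels[truth.labels.site == "gut"].true_cst.to_numpy()
    return {
        "y": (labels == 2).astype(float),
        "wol": np.array([v.wol for v in gut]),
        "gab": np.array([subj_of[v.subject_id].ga_birth for v in gut]),
        "subj": [v.subject_id for v in gut],
        "subj_of": subj_of,
    }


class TestSingleIndex:
    def test_wol_only_truth_recovers_small_theta(self):
        d = _synthetic_cohort((1.0, 0.0), seed=11)
        fit = fit_single_index(d["y"], d["wol"], d["gab"], d["subj"])
        assert abs(np.degrees(fit.theta)) < 20
        assert fit.log2_ratio < -1

    def test_pma_truth_recovers_diagonal(self):
        d = _synthetic_cohort((1.0, 1.0), seed=12)
        fit = fit_single_index(d["y"], d["wol"], d["gab"], d["subj"])
        assert abs(np.degrees(fit.theta) - 45) < 10
        assert abs(fit.log2_ratio) < 1

    def test_optimum_beats_grid_anchors(self):
        d = _synthetic_cohort((1.0, 1.0), seed=13)
        fit = fit_single_index(d["y"], d["wol"], d["gab"], d["subj"])
        from cstdyn.temporal import _index_fit

        for deg in (0.0, 45.0, 89.0):
            anchor = _index_fit(d["y"], d["wol"], d["gab"], d["subj"],
                                np.radians(deg), fit.ndim)[0].gcv
            assert fit.criterion <= anchor + 1e-9


class TestOccurrenceLogistic:
    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 400
        for _ in range(reps):
            gab = rng.uniform(23, 42, 200)
            occ = rng.random(200) < 0.4
            p, _ = occurrence_logistic_test(occ, gab)
            rejections += p <= 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_separation_flagged_significant(self):
        gab = np.linspace(23, 42, 60)
        occ = gab > 37
        p, separated = occurrence_logistic_test(occ, gab)
        assert separated and p < 0.05

    def test_degenerate_all_occur(self):
        p, separated = occurrence_logistic_test(np.ones(30), np.linspace(23, 42, 30))
        assert p == 1.0 and not separated


class TestClassifyPattern:
    @pytest.mark.parametrize("a,b,p,expected", [
        (1.0, 1.0, 0.2, "convergent"),       # log2 ratio 0
        (1.0, 0.2, 0.5, "chronological"),    # log2 0.2 = -2.32, p n.s.
        (1.0, 0.2, 0.01, "idiosyncratic"),   # same ratio, significant occ test
        (1.0, 4.0, 0.5, "idiosyncratic"),    # log2 4 = 2 > 1
        (1.0, -0.3, 0.5, "chronological"),   # b <= 0 branch
        (1.0, -0.3, 0.01, "idiosyncratic"),
        (0.0, 1.0, 0.5, "idiosyncratic"),    # no WOL dependence
    ])
    def test_binning_rule(self, a, b, p, expected):
        assert classify_pattern(a, b, p).pattern == expected

    def test_classes_partition_domain(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.uniform(0, 1)
            b = rng.uniform(-1, 1)
            if a == 0 and b == 0:
                continue
            p = rng.random()
            res = classify_pattern(a, b, p)
            assert res.pattern in {"chronological", "convergent",
                                   "idiosyncratic"}

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(0.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            classify_pattern(-0.5, 1.0, 0.5)


class TestSequenceIndex:
    @staticmethod
    def _assignment(sample_ids, labels):
        k = max(labels)
        post = np.eye(k)[np.array(labels) - 1]
        return CSTAssignment(sample_ids=list(sample_ids), posterior=post,
                             map_label=np.array(labels),
                             canonical_map=np.arange(1, k + 1))

    def test_single_sample_floored_week(self):
        asg = self._assignment(["x"], [3])
        samples = [VisitSample("x", "P0", "gut", wol=10.0, pma=39.6)]
        seq = sequence_index_summary(asg, samples)
        assert seq.to_dict("records") == [
            {"subject_id": "P0", "site": "gut", "pma_week": 39, "cst": 3}]

    def test_midpoint_split(self):
        asg = self._assignment(["x", "y"], [1, 2])
        samples = [VisitSample("x", "P0", "gut", wol=0.0, pma=30.0),
                   VisitSample("y", "P0", "gut", wol=4.0, pma=34.0)]
        seq = sequence_index_summary(asg, samples).set_index("pma_week").cst
        assert seq.loc[[30, 31]].tolist() == [1, 1]
        assert seq.loc[[32, 33, 34]].tolist() == [2, 2, 2]

    def test_empty_subject_empty_sequence(self):
        asg = self._assignment(["x"], [1])
        assert sequence_index_summary(asg, []).empty

    def test_duplicate_week_later_wins(self):
        asg = self._assignment(["x", "y"], [1, 2])
        samples = [VisitSample("x", "P0", "gut", wol=0.0, pma=30.2),
                   VisitSample("y", "P0", "gut", wol=0.5, pma=30.7)]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            seq = sequence_index_summary(asg, samples)
        assert any("duplicate" in str(w.message) for w in caught)
        assert seq.cst.tolist() == [2]
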