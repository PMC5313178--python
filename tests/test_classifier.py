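"""Decision statistic, threshold calibration, EER accuracy and predictions."""

import numpy as np
import pytest

from keyfusion import (
    PipelineConfig,
    Volume,
    calibrate_threshold,
    eer_accuracy,
    predict_label,
)
from keyfusion.classify import (
    CohortData,
    SubjectData,
    TrainedModel,
    _confusion,
    fit_on_subjects,
    ls_sum_cached,
)
from keyfusion.keypoints import FeatureSet
from keyfusion.scoring import KeypointModel

from conftest import make_record


def brute_force_best(scores, labels, objective, grid=None):
    """Oracle: exhaustive threshold search on a fine grid."""
    vals = np.asarray(list(scores.values()))
    if grid is None:
        grid = np.linspace(vals.min() - 1, vals.max() + 1, 4001)
    best = min(objective(*_confusion(scores, labels, t)) for t in grid)
    return best


class TestLsSum:
    """LS_sum arithmetic through a hand-constructed cohort cache."""

    @staticmethod
    def cohort_with_votes(vote_specs):
        """Build a CohortData + TrainedModel where keypoint i votes
        patient/healthy with the given (score, vote) pairs for subject s0."""
        cfg = PipelineConfig()
        template_fs = FeatureSet(
            "t", "template", [make_record() for _ in vote_specs]
        )
        vol = Volume(np.ones((16, 16, 16)), "s0", "patient")
        data = CohortData(
            template_volume=vol,
            template_fs=template_fs,
            subjects={"s0": SubjectData(vol, FeatureSet("s0", "patient"), "patient")},
            matches=[{"s0": make_record()} if matched else {}
                     for (_, _, matched) in vote_specs],
            config=cfg,
        )
        theta = np.zeros(128)
        theta[0] = 1.0
        data._theta_cache[("hog", 16)] = [
            {"s0": theta} if matched else {} for (_, _, matched) in vote_specs
        ]
        models = []
        for i, (score, vote_patient, _) in enumerate(vote_specs):
            w = np.zeros(128)
            w[0] = 1.0 if vote_patient else -1.0
            models.append(
                KeypointModel(i, score, w, 0.0, "hog", 16)
            )
        trained = TrainedModel(
            keypoint_models=models,
            template_records={i: template_fs.records[i] for i in range(len(models))},
            threshold=0.0,
            config=cfg,
        )
        return data, trained

    def test_signed_sum(self):
        data, model = self.cohort_with_votes(
            [(0.3, True, True), (0.2, False, True)]
        )
        assert ls_sum_cached(data, model, "s0") == pytest.approx(0.1)

    def test_unmatched_keypoints_contribute_zero(self):
        data, model = self.cohort_with_votes(
            [(0.3, True, False), (0.2, False, False)]
        )
        assert ls_sum_cached(data, model, "s0") == 0.0

    def test_all_patient_votes_sum_scores(self):
        data, model = self.cohort_with_votes(
            [(0.3, True, True), (0.25, True, True), (0.1, True, True)]
        )
        assert ls_sum_cached(data, model, "s0") == pytest.approx(0.65)


class TestThresholdCalibration:
    def test_separable_scores_gap_midpoint(self):
        scores = {"c1": -0.8, "c2": -0.4, "p1": 0.6, "p2": 1.0}
        labels = {"c1": "control", "c2": "control", "p1": "patient", "p2": "patient"}
        t = calibrate_threshold(scores, labels)
        assert t == pytest.approx(0.1)  # midpoint of the gap, closest to 0
        assert _confusion(scores, labels, t)[1:3] == (0, 2)  # fp=0, tn=2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_objective(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = {f"s{i}": float(rng.normal()) for i in range(n)}
        labels = {
            f"s{i}": "patient" if i < n // 2 else "control" for i in range(n)
        }
        if len(set(labels.values())) < 2:
            pytest.skip("degenerate split")
        t = calibrate_threshold(scores, labels)
        achieved = abs(
            _confusion(scores, labels, t)[3] - _confusion(scores, labels, t)[1]
        )
        oracle = brute_force_best(
            scores, labels, lambda tp, fp, tn, fn: abs(fn - fp)
        )
        assert achieved == oracle

    def test_all_scores_equal_degenerate(self):
        scores = {"p1": 0.5, "p2": 0.5, "p3": 0.5, "c1": 0.5}
        labels = {"p1": "patient", "p2": "patient", "p3": "patient", "c1": "control"}
        t = calibrate_threshold(scores, labels)
        tp, fp, tn, fn = _confusion(scores, labels, t)
        assert abs(fn - fp) == min(3, 1)  # best attainable: min(#patients, #controls)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            calibrate_threshold({"a": 0.1}, {"a": "patient"})


class TestPredictLabel:
    def test_strict_inequality_at_boundary(self):
        assert predict_label(0.5, 0.5) == "control"
        assert predict_label(0.5 + 1e-9, 0.5) == "patient"

    def test_minus_infinity_sentinel(self):
        assert predict_label(-1e9, -np.inf) == "patient"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        counts = [
            int(np.sum(scores > t)) for t in np.linspace(-3, 3, 25)
        ]
        assert counts == sorted(counts, reverse=True)


class TestEerAccuracy:
    def test_perfectly_separable_is_100(self):
        scores = {"c1": -1.0, "c2": -0.5, "p1": 0.5, "p2": 2.0}
        labels = {"c1": "control", "c2": "control", "p1": "patient", "p2": "patient"}
        assert eer_accuracy(scores, labels) == 100.0

    def test_anti_separated_at_most_50(self):
        scores = {"p1": -2.0, "p2": -1.0, "c1": 1.0, "c2": 2.0}
        labels = {"p1": "patient", "p2": "patient", "c1": "control", "c2": "control"}
        assert eer_accuracy(scores, labels) <= 50.0

    def test_identical_scores_degenerate(self):
        scores = {"p1": 0.0, "p2": 0.0, "c1": 0.0}
        labels = {"p1": "patient", "p2": "patient", "c1": "control"}
        acc = eer_accuracy(scores, labels)
        assert acc in (100.0 * 2 / 3, 100.0 * 1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_label_swap_antisymmetry(self, seed):
        """Negating scores and swapping labels leaves EER accuracy unchanged."""
        rng = np.random.default_rng(seed)
        scores = {f"s{i}": float(rng.normal()) for i in range(12)}
        labels = {f"s{i}": "patient" if i % 2 else "control" for i in range(12)}
        swapped = {
            k: ("control" if v == "patient" else "patient") for k, v in labels.items()
        }
        neg = {k: -v for k, v in scores.items()}
        assert eer_accuracy(scores, labels) == pytest.approx(
            eer_accuracy(neg, swapped)
        )


class TestNoLeakage:
    def test_fit_ignores_held_out_subject(self):
        """Perturbing a held-out subject's cached descriptors does not change
        the model fitted on the remaining subjects."""
        rng = np.random.default_rng(0)
        cfg = PipelineConfig(top_k=2)
        n = 8
        sids = [f"p{i}" for i in range(n // 2)] + [f"c{i}" for i in range(n // 2)]
        template_fs = FeatureSet("t", "template", [make_record(), make_record()])
        vol = Volume(np.ones((16, 16, 16)), "t", "template")
        subjects = {
            s: SubjectData(
                Volume(np.ones((16, 16, 16)), s, "patient" if s[0] == "p" else "control"),
                FeatureSet(s, "patient" if s[0] == "p" else "control"),
                "patient" if s[0] == "p" else "control",
            )
            for s in sids
        }

        def thetas():
            out = []
            for _ in range(2):
                row = {}
                for s in sids:
                    v = rng.normal(size=128)
                    shift = 0.5 if s[0] == "p" else -0.5
                    v[0] += shift
                    row[s] = v / np.linalg.norm(v)
                out.append(row)
            return out

        cache = thetas()
        data = CohortData(vol, template_fs, subjects,
                          [dict.fromkeys(sids, make_record()) for _ in range(2)], cfg)
        data._theta_cache[("hog", 16)] = cache
        train = [s for s in sids if s != "p0"]
        m1 = fit_on_subjects(data, train, cfg)
        # corrupt the held-out subject's descriptors
        for row in cache:
            row["p0"] = -row["p0"]
        m2 = fit_on_subjects(data, train, cfg)
        assert m1.threshold == m2.threshold
        for a, b in zip(m1.keypoint_models, m2.keypoint_models):
            assert a.score == b.score
            np.testing.assert_array_equal(a.weight, b.weight)
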