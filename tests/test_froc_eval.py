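import numpy as np
import pytest

from pulmo3d.froc_eval import (FP_LEVELS, SizeStrata, cpm_score,
                               froc_sensitivities, match_candidates,
                               specificity, stratified_cpm)
from pulmo3d.io_formats import Candidate, NoduleAnnotation


def cand(x, y, z, d=6.0, score=0.5, uid="s"):
    return Candidate(center_world=(x, y, z), diameter_mm=d, score=score,
                     seriesuid=uid)


def truth(x, y, z, d=6.0):
    return NoduleAnnotation(center_world=(x, y, z), diameter_mm=d)


def froc_oracle(cands_by_scan, truths_by_scan, fp_levels=FP_LEVELS):
    """Brute force: re-match at every candidate-score threshold."""
    scores = sorted({c.score for cs in cands_by_scan.values() for c in cs},
                    reverse=True)
    n_truths = sum(len(t) for t in truths_by_scan.values())
    n_scans = len(truths_by_scan)
    points = [(0, 0.0)]  # (fp_count, sensitivity) at threshold above max
    for t in scores:
        tp = fp = 0
        for uid, truths in truths_by_scan.items():
            kept = [c for c in cands_by_scan.get(uid, []) if c.score >= t]
            hit = [False] * len(truths)
            for c in kept:
                hits = [i for i, tr in enumerate(truths)
                        if np.linalg.norm(np.subtract(c.center_world,
                                                      tr.center_world))
                        < tr.diameter_mm / 2]
                if hits:
                    for i in hits:
                        hit[i] = True
                else:
                    fp += 1
            tp += sum(hit)
        points.append((fp, tp / n_truths if n_truths else 0.0))
    out = []
    for level in fp_levels:
        ok = [s for f, s in points if f <= level * n_scans + 1e-9]
        out.append(max(ok) if ok else 0.0)
    return tuple(out)


class TestMatching:
    def test_candidate_at_truth_center_is_tp(self):
        m = match_candidates({"s": [cand(0, 0, 0)]},
                             {"s": [truth(0, 0, 0, d=6)]})
        assert m.candidate_status["s"] == ["TP"]
        assert m.truth_best_score["s"] == [0.5]

    def test_far_candidate_is_fp(self):
        m = match_candidates({"s": [cand(10, 0, 0)]},
                             {"s": [truth(0, 0, 0, d=6)]})
        assert m.candidate_status["s"] == ["FP"]
        assert np.isnan(m.truth_best_score["s"][0])

    def test_double_hit_second_ignored(self):
        m = match_candidates(
            {"s": [cand(0, 0, 0, score=0.9), cand(1, 0, 0, score=0.4)]},
            {"s": [truth(0, 0, 0, d=8)]})
        assert sorted(m.candidate_status["s"]) == ["TP", "ignored"]
        assert m.truth_best_score["s"] == [0.9]

    def test_unknown_scan_id_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            match_candidates({"ghost": [cand(0, 0, 0)]}, {"s": []})

    def test_partition_and_truth_accounting(self, rng):
        cands = {"a": [cand(*rng.uniform(-20, 20, 3), score=float(s))
                       for s in rng.uniform(0, 1, 12)]}
        truths = {"a": [truth(*rng.uniform(-20, 20, 3), d=10)
                        for _ in range(4)]}
        m = match_candidates(cands, truths)
        statuses = m.candidate_status["a"]
        assert len(statuses) == 12
        assert set(statuses) <= {"TP", "FP", "ignored"}
        n_tp = statuses.count("TP")
        n_detected = sum(not np.isnan(s) for s in m.truth_best_score["a"])
        assert n_tp == n_detected  # TP + FN == number of truths


class TestFROC:
    def test_no_candidates_all_zero(self):
        m = match_candidates({}, {"a": [truth(0, 0, 0)], "b": []})
        res = froc_sensitivities(m)
        assert res.sensitivities == (0.0,) * 7
        assert res.cpm == 0.0

    def test_sensitivity_non_decreasing_in_level(self, rng):
        cands = {"a": [cand(*rng.uniform(-30, 30, 3), score=float(s))
                       for s in rng.uniform(0, 1, 20)]}
        truths = {"a": [truth(*rng.uniform(-30, 30, 3), d=12)
                        for _ in range(5)]}
        res = froc_sensitivities(match_candidates(cands, truths))
        assert all(a <= b for a, b in zip(res.sensitivities,
                                          res.sensitivities[1:]))

    def test_matches_brute_force_sweep(self, rng):
        for trial in range(30):
            n_scans = int(rng.integers(2, 6))
            cands, truths = {}, {}
            for i in range(n_scans):
                uid = f"s{i}"
                truths[uid] = [truth(*rng.uniform(-30, 30, 3),
                                     d=float(rng.uniform(4, 14)))
                               for _ in range(int(rng.integers(0, 4)))]
                cands[uid] = [cand(*rng.uniform(-30, 30, 3),
                                   score=float(rng.uniform(0, 1)), uid=uid)
                              for _ in range(int(rng.integers(0, 12)))]
            m = match_candidates(cands, truths)
            if m.n_truths == 0:
                continue
            got = froc_sensitivities(m).sensitivities
            want = froc_oracle(cands, truths)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zero_scans_rejected(self):
        m = match_candidates({}, {})
        with pytest.raises(ValueError):
            froc_sensitivities(m)

    def test_interpolated_reading_bounds_step_reading(self, rng):
        cands = {"a": [cand(*rng.uniform(-30, 30, 3), score=float(s))
                       for s in rng.uniform(0, 1, 15)]}
        truths = {"a": [truth(*rng.uniform(-30, 30, 3), d=12)
                        for _ in range(4)]}
        m = match_candidates(cands, truths)
        step = froc_sensitivities(m).sensitivities
        lin = froc_sensitivities(m, interpolate=True).sensitivities
        assert all(b >= a - 1e-12 for a, b in zip(step, lin))
        assert all(0.0 <= v <= 1.0 for v in lin)


class TestCPM:
    @pytest.mark.parametrize("sens,expected", [
        ((0.848, 0.876, 0.905, 0.933, 0.943, 0.957, 0.970), 0.919),
        ((0.906, 0.923, 0.948, 0.981, 0.981, 0.981, 0.981), 0.957),
    ])
    def test_reference_rows(self, sens, expected):
        assert round(cpm_score(sens), 3) == expected

    def test_constant_mean(self):
        assert cpm_score((0.4,) * 7) == pytest.approx(0.4)

    def test_arity_enforced(self):
        with pytest.raises(ValueError):
            cpm_score((0.5,) * 6)


class TestStrata:
    def test_boundaries(self):
        strata = SizeStrata()
        assert strata.stratum(4.9) == "small"
        assert strata.stratum(5.0) == "medium"   # 5 mm belongs to medium
        assert strata.stratum(10.0) == "medium"
        assert strata.stratum(10.1) == "large"

    def test_all_medium_equals_overall(self):
        cands = {"a": [cand(0, 0, 0, score=0.9),
                       cand(50, 50, 50, score=0.3)]}
        truths = {"a": [truth(0, 0, 0, d=8)]}
        m = match_candidates(cands, truths)
        per = stratified_cpm(m)
        assert per["small"] is None and per["large"] is None
        assert per["medium"] == pytest.approx(froc_sensitivities(m).cpm)

    def test_per_stratum_equals_restricted_sweep(self, rng):
        truths = {"a": [truth(0, 0, 0, d=4), truth(20, 0, 0, d=7),
                        truth(0, 20, 0, d=12)]}
        cands = {"a": [cand(0, 0, 0, score=0.9),
                       cand(20, 0, 0.5, score=0.6),
                       cand(40, 40, 40, score=0.7),
                       cand(0, 20, 1, score=0.2)]}
        m = match_candidates(cands, truths)
        per = stratified_cpm(m)
        # restricted oracle: only this stratum's truths count, FPs global
        for name, d in [("small", 4), ("medium", 7), ("large", 12)]:
            sub_truth = {"a": [t for t in truths["a"]
                               if SizeStrata().stratum(t.diameter_mm) == name]}
            fp_scores = [0.7]  # the one global FP
            sens = []
            for level in FP_LEVELS:
                allowed = int(level * 1 + 1e-9)
                thr = -np.inf if len(fp_scores) <= allowed else \
                    np.nextafter(sorted(fp_scores)[-(allowed + 1)], np.inf)
                mm = match_candidates(cands, truths)
                best = [s for s in mm.truth_best_score["a"]]
                scores = [b for t, b in zip(truths["a"], best)
                          if SizeStrata().stratum(t.diameter_mm) == name]
                sens.append(sum(1 for s in scores
                                if not np.isnan(s) and s >= thr)
                            / len(scores))
            assert per[name] == pytest.approx(float(np.mean(sens)))


def test_specificity_definition():
    assert specificity(tn=90, fp=10) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        specificity(0, 0)
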