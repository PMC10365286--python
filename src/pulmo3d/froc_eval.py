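"""FROC analysis: candidate-to-truth matching, sensitivities at fixed
false-positive rates, the competition performance metric (CPM), and
size-stratified CPMs.

Matching follows the LUNA16 convention: a candidate hits a nodule if the
Euclidean distance between their centres is below the nodule radius; the
highest-scoring hit per nodule is the true positive, further hits on the
same nodule are ignored (neither TP nor FP), and candidates hitting nothing
are false positives. Sensitivity at a false-positive level L is the best
sensitivity achievable at any score threshold whose FP/scan does not exceed
L (step-function reading, no interpolation unless requested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Candidate, NoduleAnnotation

FP_LEVELS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

TP, FP, IGNORED = "TP", "FP", "ignored"


@dataclass
class SizeStrata:
    """Diameter partition: small [3,5) mm, medium [5,10] mm, large (10,inf)."""

    small_max: float = 5.0
    medium_max: float = 10.0

    def stratum(self, diameter_mm: float) -> str:
        if diameter_mm < self.small_max:
            return "small"
        if diameter_mm <= self.medium_max:
            return "medium"
        return "large"


@dataclass
class MatchResult:
    candidate_status: dict[str, list[str]]       # per scan, per candidate
    truth_best_score: dict[str, list[float]]     # NaN where the truth is missed
    truth_diameters: dict[str, list[float]]
    n_scans: int

    @property
    def n_truths(self) -> int:
        return sum(len(v) for v in self.truth_best_score.values())

    @property
    def fp_scores(self) -> np.ndarray:
        out = []
        for uid, statuses in self.candidate_status.items():
            out.extend(s for s, st in zip(self._scores[uid], statuses)
                       if st == FP)
        return np.sort(np.asarray(out, dtype=np.float64))

    _scores: dict[str, list[float]] = field(default_factory=dict, repr=False)


@dataclass
class FROCResult:
    fp_levels: tuple[float, ...]
    sensitivities: tuple[float, ...]
    cpm: float
    strata_cpm: dict[str, float | None] | None = None


def match_candidates(candidates: dict[str, list[Candidate]],
                     truths: dict[str, list[NoduleAnnotation]]) -> MatchResult:
    """Match detections to ground truth per scan.

    ``truths`` must carry every scan identifier (possibly with an empty
    list); unknown scan ids among the candidates are an error.
    """
    unknown = sorted(set(candidates) - set(truths))
    if unknown:
        raise ValueError(f"candidates reference unknown scan id(s): {unknown}")
    status: dict[str, list[str]] = {}
    best: dict[str, list[float]] = {}
    diams: dict[str, list[float]] = {}
    scores: dict[str, list[float]] = {}
    for uid, anns in truths.items():
        cands = candidates.get(uid, [])
        scores[uid] = [c.score for c in cands]
        diams[uid] = [a.diameter_mm for a in anns]
        centers = np.asarray([a.center_world for a in anns], dtype=np.float64)
        radii = np.asarray([a.diameter_mm / 2 for a in anns])
        st = []
        hit_of = []  # indices of truths each candidate hits
        for c in cands:
            if len(anns):
                dist = np.linalg.norm(centers - np.asarray(c.center_world), axis=1)
                hits = np.flatnonzero(dist < radii)
            else:
                hits = np.empty(0, dtype=int)
            hit_of.append(hits)
            st.append(FP if hits.size == 0 else IGNORED)
        truth_best = np.full(len(anns), np.nan)
        for t in range(len(anns)):
            hitters = [i for i, hits in enumerate(hit_of) if t in hits]
            if hitters:
                # highest score wins; ties resolved by input order
                winner = max(hitters, key=lambda i: (cands[i].score, -i))
                truth_best[t] = cands[winner].score
                st[winner] = TP
        status[uid] = st
        best[uid] = truth_best.tolist()
    result = MatchResult(candidate_status=status, truth_best_score=best,
                         truth_diameters=diams, n_scans=len(truths))
    result._scores = scores
    return result


def _sensitivity_at_levels(truth_scores: np.ndarray, fp_scores: np.ndarray,
                           n_truths: int, n_scans: int, fp_levels,
                           interpolate: bool = False) -> tuple:
    """Best sensitivity per FP/scan level over all score thresholds.

    ``interpolate`` switches from the step-function reading to linear
    interpolation between the operating points of the FROC curve.
    """
    if n_scans <= 0:
        raise ValueError("need at least one scan")
    if n_truths == 0:
        return tuple(0.0 for _ in fp_levels)
    detected = np.sort(truth_scores[~np.isnan(truth_scores)])
    fp_sorted = np.sort(fp_scores)
    if interpolate:
        thresholds = np.unique(np.concatenate([detected, fp_sorted]))[::-1]
        xs = [0.0]
        ys = [0.0]
        for t in thresholds:
            xs.append(np.count_nonzero(fp_sorted >= t) / n_scans)
            ys.append(np.count_nonzero(detected >= t) / n_truths)
        xs, ys = np.asarray(xs), np.asarray(ys)
        order = np.argsort(xs, kind="stable")
        return tuple(float(v) for v in
                     np.interp(fp_levels, xs[order], ys[order]))
    sens = []
    for level in fp_levels:
        max_fp = level * n_scans + 1e-9
        # threshold t: fp(t) = #{fp >= t}; as t decreases both fp and tp grow.
        # the best qualifying t is the smallest with fp(t) <= max_fp.
        k = int(np.floor(max_fp))           # allowed FP count
        if fp_sorted.size <= k:
            t = -np.inf                      # keep everything
        else:
            # keep the k highest-scoring FPs: threshold just above the next one
            t = np.nextafter(fp_sorted[-(k + 1)], np.inf)
        tp = np.count_nonzero(detected >= t)
        sens.append(tp / n_truths)
    return tuple(float(s) for s in sens)


def froc_sensitivities(match: MatchResult, n_scans: int | None = None,
                       fp_levels=FP_LEVELS,
                       interpolate: bool = False) -> FROCResult:
    """FROC sensitivities at the configured FP/scan levels, plus their CPM."""
    n_scans = match.n_scans if n_scans is None else n_scans
    truth_scores = np.asarray(
        [s for v in match.truth_best_score.values() for s in v], dtype=np.float64)
    sens = _sensitivity_at_levels(truth_scores, match.fp_scores,
                                  match.n_truths, n_scans, fp_levels,
                                  interpolate=interpolate)
    cpm = cpm_score(sens) if len(sens) == 7 else float(np.mean(sens)) if sens else 0.0
    return FROCResult(fp_levels=tuple(fp_levels), sensitivities=sens, cpm=cpm)


def cpm_score(sensitivities) -> float:
    """Competition performance metric: the mean of the seven sensitivities."""
    values = np.asarray(list(sensitivities), dtype=np.float64)
    if values.shape != (7,):
        raise ValueError(f"expected exactly 7 sensitivities, got {values.shape}")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("sensitivities must lie in [0, 1]")
    return float(values.mean())


def stratified_cpm(match: MatchResult, strata: SizeStrata | None = None,
                   fp_levels=FP_LEVELS) -> dict[str, float | None]:
    """Per-size-stratum CPM.

    Sensitivity in a stratum counts only that stratum's nodules, while the
    FP/scan axis uses all false positives. An empty stratum yields ``None``.
    """
    strata = strata or SizeStrata()
    fp_scores = match.fp_scores
    by_stratum: dict[str, list[float]] = {"small": [], "medium": [], "large": []}
    for uid in match.truth_best_score:
        for score, d in zip(match.truth_best_score[uid],
                            match.truth_diameters[uid]):
            by_stratum[strata.stratum(d)].append(score)
    out: dict[str, float | None] = {}
    for name, scores_list in by_stratum.items():
        if not scores_list:
            out[name] = None
            continue
        sens = _sensitivity_at_levels(np.asarray(scores_list), fp_scores,
                                      len(scores_list), match.n_scans, fp_levels)
        out[name] = float(np.mean(sens))
    return out


def specificity(tn: int, fp: int) -> float:
    """TN / (TN + FP) over candidate-level decisions."""
    if tn + fp == 0:
        raise ValueError("no negative decisions to evaluate")
    return tn / (tn + fp)
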