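"""Benchmark evaluation protocol.

Given disruption scores for riboSNitch and non-riboSNitch windows this
module implements the evaluation used to compare predictors:

* control matching — for a riboSNitch category of size n, pick the n
  non-riboSNitches whose PARS comparisons most confidently showed *no*
  structure change, ranked by the average of the FDR-adjusted P-values
  over the applicable trio comparisons;
* ROC curves swept over all distinct scores, AUC as the Mann–Whitney
  statistic with ties counted one half;
* AUC standard deviation via DeLong's structural-components estimator,
  95% confidence intervals as AUC ± 1.96·s, and one-tailed DeLong tests
  between two ROC curves (paired via window-id overlap, or unpaired);
* the curve's "best" operating point: the point closest to the top-left
  corner in (1 − specificity, sensitivity) space;
* the n% tails opt-out strategy: combine both score sets, find the
  thresholds delimiting the middle (100 − n)% of the combined
  distribution, and keep only scores at or beyond them before re-running
  the ROC analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ScoreSet",
    "ROCResult",
    "TailThresholds",
    "match_controls",
    "roc",
    "delong_sd",
    "delong_compare",
    "tail_thresholds",
    "apply_tails",
    "run_benchmark",
    "benjamini_hochberg",
    "BenchmarkRow",
]

CATEGORY_ORDER = ("probed", "validated", "symmetric", "asymmetric", "all")


@dataclass
class ScoreSet:
    """Labelled disruption scores for one metric (and category slice).

    ``positives`` are riboSNitch windows, ``negatives`` matched
    non-riboSNitches; each entry is (window_id, score).
    """

    positives: List[Tuple[str, float]]
    negatives: List[Tuple[str, float]]
    metric: str = ""
    category: str = "all"

    def __post_init__(self):
        for side in (self.positives, self.negatives):
            for _, s in side:
                if not math.isfinite(s):
                    raise ValueError("scores must be finite")

    @property
    def pos_scores(self) -> np.ndarray:
        return np.array([s for _, s in self.positives], dtype=float)

    @property
    def neg_scores(self) -> np.ndarray:
        return np.array([s for _, s in self.negatives], dtype=float)


@dataclass
class ROCResult:
    """ROC curve with AUC, DeLong sd, 95% CI, and best operating point.

    ``points`` are (threshold, sensitivity, specificity); a score is
    called positive when it is >= threshold.  ``ci95`` keeps the raw
    AUC ± 1.96 s values (clipping to [0, 1] is a display concern).
    """

    points: List[Tuple[float, float, float]]
    auc: float
    auc_sd: float
    ci95: Tuple[float, float]
    best_point: Tuple[float, float, float]

    @property
    def ci95_clipped(self) -> Tuple[float, float]:
        lo, hi = self.ci95
        return (max(lo, 0.0), min(hi, 1.0))


@dataclass
class TailThresholds:
    """Score thresholds delimiting the middle (100 − n)% of the combined
    riboSNitch + non-riboSNitch score distribution."""

    n_percent: float
    theta_low: float
    theta_high: float

    def __post_init__(self):
        if self.theta_low > self.theta_high:
            raise ValueError("theta_low must be <= theta_high")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg FDR adjustment (for inputs supplied as raw P)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * n / rank_from_top)
        adj[idx] = running
    return adj


def match_controls(candidates: Sequence, n: int, ascending: bool = False) -> List:
    """Top-n non-riboSNitch controls by mean FDR-adjusted P-value.

    Candidates must expose ``mean_fdr_p`` (attribute, callable, or key
    "mean_fdr_p") and an identifier.  Default ranking is descending mean
    adjusted P — the candidates whose PARS comparisons were most
    confidently unchanged first; pass ``ascending=True`` to invert.  Ties
    break deterministically on the identifier.  Requesting more than the
    pool returns the whole pool with a warning.
    """
    if n < 0:
        raise ValueError("n must be >= 0")

    def mean_p(c) -> float:
        v = getattr(c, "mean_fdr_p", None)
        if callable(v):
            v = v()
        if v is None and isinstance(c, Mapping):
            v = c["mean_fdr_p"]
        if v is None:
            raise ValueError(f"candidate {ident(c)!r} lacks mean_fdr_p")
        return float(v)

    def ident(c) -> str:
        for attr in ("window_id", "snv_id", "id"):
            v = getattr(c, attr, None)
            if v is None and isinstance(c, Mapping):
                v = c.get(attr)
            if v is not None:
                return str(v)
        return repr(c)

    if n > len(candidates):
        warnings.warn(
            f"requested {n} controls but only {len(candidates)} candidates; "
            "returning all",
            stacklevel=2,
        )
        n = len(candidates)
    sign = 1.0 if ascending else -1.0
    ranked = sorted(candidates, key=lambda c: (sign * mean_p(c), ident(c)))
    return list(ranked[:n])


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann–Whitney statistic, ties counted one half."""
    combined = np.concatenate([pos, neg])
    ranks = rankdata(combined)  # midranks
    m, n = len(pos), len(neg)
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def roc(scores: ScoreSet) -> ROCResult:
    """ROC over all distinct score thresholds, with DeLong CI.

    A window is called a riboSNitch when its score >= threshold.  The
    sweep runs from a threshold above every score (sens 0, spec 1) down
    through each distinct score.  The best point minimises the Euclidean
    distance to the top-left corner (FPR 0, TPR 1); ties go to the lowest
    threshold.
    """
    pos = scores.pos_scores
    neg = scores.neg_scores
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs at least one positive and one negative score")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points: List[Tuple[float, float, float]] = [
        (float(thresholds[0]) + 1.0, 0.0, 1.0)
    ]
    for t in thresholds:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        points.append((float(t), sens, spec))

    auc = _auc_mann_whitney(pos, neg)
    try:
        sd = delong_sd(scores)
    except ValueError:
        sd = float("nan")
    ci = (auc - 1.96 * sd, auc + 1.96 * sd)

    best = None
    best_d2 = math.inf
    for t, sens, spec in points:
        d2 = (1.0 - spec) ** 2 + (1.0 - sens) ** 2
        # ties -> lowest threshold; sweep is descending, so <= keeps the last
        if d2 < best_d2 or (d2 == best_d2 and t < best[0]):
            best_d2 = d2
            best = (t, sens, spec)
    return ROCResult(points=points, auc=auc, auc_sd=sd, ci95=ci, best_point=best)


def _placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks.

    v10[i] = fraction of negatives a positive beats (ties half);
    v01[j] = fraction of positives a negative is beaten by.
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = rankdata(combined)
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    return v10, v01


def delong_sd(scores: ScoreSet) -> float:
    """Standard deviation of the AUC by DeLong's estimator.

    s^2 = var(v10)/m + var(v01)/n with sample variances; requires at
    least two scores on each side.  Rank-based, hence invariant under
    strictly increasing transforms of the scores; zero under perfect
    separation.
    """
    pos = scores.pos_scores
    neg = scores.neg_scores
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("DeLong variance needs >= 2 scores per side")
    v10, v01 = _placements(pos, neg)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    return float(math.sqrt(max(var, 0.0)))


def delong_compare(
    a: ScoreSet,
    b: ScoreSet,
    alternative: str = "greater",
    paired: Optional[bool] = None,
) -> Dict[str, float]:
    """One-tailed DeLong test comparing two ROC curves.

    ``alternative="greater"`` tests AUC(a) > AUC(b).  Pairing is chosen
    automatically: when the two score sets cover exactly the same window
    ids on both sides, placement-value covariances are used; otherwise
    the variance of the difference is the sum of the two DeLong
    variances.  Returns auc_a, auc_b, z and the one-tailed P-value.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")

    ids_a = ([i for i, _ in a.positives], [i for i, _ in a.negatives])
    ids_b = ([i for i, _ in b.positives], [i for i, _ in b.negatives])
    if paired is None:
        paired = ids_a[0] == ids_b[0] and ids_a[1] == ids_b[1] and len(ids_a[0]) > 0

    auc_a = _auc_mann_whitney(a.pos_scores, a.neg_scores)
    auc_b = _auc_mann_whitney(b.pos_scores, b.neg_scores)

    if paired:
        va10, va01 = _placements(a.pos_scores, a.neg_scores)
        vb10, vb01 = _placements(b.pos_scores, b.neg_scores)
        m, n = len(va10), len(va01)
        if m < 2 or n < 2:
            raise ValueError("DeLong comparison needs >= 2 scores per side")
        s10 = np.cov(np.stack([va10, vb10]), ddof=1)
        s01 = np.cov(np.stack([va01, vb01]), ddof=1)
        var = (
            (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        )
    else:
        var = delong_sd(a) ** 2 + delong_sd(b) ** 2

    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    if alternative == "greater":
        p = float(norm.sf(z))
    else:
        p = float(norm.cdf(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p_value": p,
            "paired": bool(paired)}


def tail_thresholds(all_scores: Sequence[float], n_percent: float) -> TailThresholds:
    """Thresholds marking the middle (100 − n)% of the combined scores.

    The tail mass is split symmetrically: theta_low is the empirical
    n/2 % quantile and theta_high the (100 − n/2) % quantile, with linear
    interpolation between order statistics.
    """
    if not 0 < n_percent <= 100:
        raise ValueError("n_percent must be in (0, 100]")
    x = np.asarray(list(all_scores), dtype=float)
    if x.size == 0:
        raise ValueError("no scores supplied")
    half = n_percent / 200.0
    lo = float(np.quantile(x, half, method="linear"))
    hi = float(np.quantile(x, 1.0 - half, method="linear"))
    return TailThresholds(n_percent=float(n_percent), theta_low=lo, theta_high=hi)


def apply_tails(scores: ScoreSet, th: TailThresholds) -> ScoreSet:
    """Keep only scores at or beyond the tail thresholds, per side.

    Retention is inclusive at the thresholds (score <= theta_low or
    score >= theta_high), so degenerate score multisets — e.g. the
    zero-heavy distributions MFE distances produce — retain all tied
    values.  Labels are untouched; the middle of the distribution opts
    out of prediction.  n = 100 is the identity.
    """
    keep = lambda s: s <= th.theta_low or s >= th.theta_high
    out = ScoreSet(
        positives=[(i, s) for i, s in scores.positives if keep(s)],
        negatives=[(i, s) for i, s in scores.negatives if keep(s)],
        metric=scores.metric,
        category=f"{scores.category},{th.n_percent:g}% tails",
    )
    if not out.positives or not out.negatives:
        warnings.warn(
            f"{th.n_percent:g}% tails filtering left an empty side "
            f"(pos {len(out.positives)}, neg {len(out.negatives)}); "
            "downstream ROC will fail",
            stacklevel=2,
        )
    return out


@dataclass
class BenchmarkRow:
    """One line of the benchmark report."""

    metric: str
    category: str
    n_pos: int
    n_neg: int
    auc: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    best_threshold: Optional[float] = None
    best_sens: Optional[float] = None
    best_spec: Optional[float] = None
    note: str = ""
    roc_points: Optional[List[Tuple[float, float, float]]] = field(
        default=None, repr=False
    )


def _roc_row(metric: str, category: str, ss: ScoreSet,
             keep_points: bool = False) -> BenchmarkRow:
    n_pos, n_neg = len(ss.positives), len(ss.negatives)
    if n_pos < 2 or n_neg < 2:
        return BenchmarkRow(metric, category, n_pos, n_neg,
                            note="NA: fewer than 2 windows per side")
    r = roc(ss)
    t, sens, spec = r.best_point
    return BenchmarkRow(
        metric, category, n_pos, n_neg,
        auc=r.auc, ci_low=r.ci95[0], ci_high=r.ci95[1],
        best_threshold=t, best_sens=sens, best_spec=spec,
        roc_points=r.points if keep_points else None,
    )


def run_benchmark(
    windows: Sequence,
    scores: Mapping[str, Mapping[str, float]],
    tails: Sequence[float] = (25.0, 5.0),
    ribosnitch_subsets: Sequence[float] = (),
    keep_roc_points: bool = False,
    match_ascending: bool = False,
) -> List[BenchmarkRow]:
    """Full evaluation: per metric, ROC per category plus tails rows.

    *windows* are labelled :class:`~ribobench.windows.SequenceWindow`
    objects (with ``mean_fdr_p`` populated for control matching); *scores*
    maps metric -> {window_id -> score}.  For each riboSNitch category a
    size-matched non-riboSNitch control set is selected, then ROC/AUC/CI
    and the best point are computed.  Tails rows re-analyse the "all"
    score set after n% tails filtering.  ``ribosnitch_subsets`` adds the
    lowest-mean-adjusted-P riboSNitch subset analysis (e.g. (25, 5) for
    the top quartile / top 5% most significant riboSNitches, each with
    freshly matched controls).  Categories with fewer than two windows a
    side are reported as NA rows, never dropped silently.
    """
    positives = [w for w in windows if w.label == "riboSNitch"]
    negatives = [w for w in windows if w.label == "non-riboSNitch"]
    rows: List[BenchmarkRow] = []

    for metric, smap in scores.items():
        def score_of(w):
            return float(smap[w.window_id])

        def scoreset(pos_w, neg_w, category) -> ScoreSet:
            return ScoreSet(
                positives=[(w.window_id, score_of(w)) for w in pos_w],
                negatives=[(w.window_id, score_of(w)) for w in neg_w],
                metric=metric,
                category=category,
            )

        all_ss = None
        for category in CATEGORY_ORDER:
            if category == "all":
                pos_w = positives
            else:
                pos_w = [w for w in positives if category in w.categories]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                neg_w = match_controls(negatives, len(pos_w),
                                       ascending=match_ascending)
            ss = scoreset(pos_w, neg_w, category)
            if category == "all":
                all_ss = ss
            rows.append(_roc_row(metric, category, ss, keep_roc_points))

        if all_ss is not None and all_ss.positives and all_ss.negatives:
            combined = np.concatenate([all_ss.pos_scores, all_ss.neg_scores])
            for n_pct in tails:
                th = tail_thresholds(combined, n_pct)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    filtered = apply_tails(all_ss, th)
                rows.append(
                    _roc_row(metric, f"{n_pct:g}% tails", filtered, keep_roc_points)
                )
            for pct in ribosnitch_subsets:
                k = max(int(round(len(positives) * pct / 100.0)), 0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sub_pos = match_controls(positives, k, ascending=True)
                    neg_w = match_controls(negatives, len(sub_pos),
                                           ascending=match_ascending)
                rows.append(
                    _roc_row(
                        metric,
                        f"top {pct:g}% riboSNitches",
                        scoreset(sub_pos, neg_w, f"top {pct:g}%"),
                        keep_roc_points,
                    )
                )
    return rows
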