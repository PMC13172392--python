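"""Paired-comparison statistics for the two tissue-detection arms.

Covers pixel-level sensitivity/precision, exact (Clopper–Pearson)
binomial confidence intervals for failure rates, McNemar's test on the
discordant-pair counts, quadratic weighted kappa for ordinal grade
agreement with percentile-bootstrap confidence intervals, the 2x2
paired detection-failure accounting, and the discordance summary of
slides graded differently under the two masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .core import InvalidSpecError, TissueMask

GRADE_CATEGORIES = tuple(range(6))  # 0 benign, 1..5 ISUP


# ---------------------------------------------------------------------------
# Pixel metrics


@dataclass(frozen=True)
class PixelMetrics:
    slide_id: str
    sensitivity: float          # nan when the truth has no tissue
    precision: float            # nan when the prediction is empty
    undefined_precision_flag: bool


def pixel_metrics(pred: TissueMask, truth: TissueMask) -> PixelMetrics:
    """Sensitivity TP/(TP+FN) and precision TP/(TP+FP) of a mask pair.

    An empty prediction leaves precision undefined: the flag is set and
    the slide is excluded from precision aggregation by the caller.
    """
    if pred.raster.shape != truth.raster.shape:
        raise InvalidSpecError("mask dims differ")
    if not np.isclose(pred.mpp, truth.mpp):
        raise InvalidSpecError("mask mpp differ")
    p, t = pred.raster, truth.raster
    tp = int(np.sum(p & t))
    fn = int(np.sum(~p & t))
    fp = int(np.sum(p & ~t))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    empty_pred = tp + fp == 0
    prec = float("nan") if empty_pred else tp / (tp + fp)
    return PixelMetrics(pred.slide_id, sens, prec, empty_pred)


# ---------------------------------------------------------------------------
# Exact binomial CI


@dataclass(frozen=True)
class BinomialCI:
    k: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def rate(self) -> float:
        return self.k / self.n


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Two-sided exact binomial (Clopper–Pearson) interval for k/n."""
    if not 0 <= k <= n or n <= 0:
        raise InvalidSpecError("need 0 <= k <= n, n > 0")
    lower, upper = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    return BinomialCI(k, n, level, float(lower), float(upper))


# ---------------------------------------------------------------------------
# McNemar


def mcnemar_exact(b: int, c: int, mode: str = "exact") -> float:
    """McNemar's test from the two discordant-pair counts.

    ``exact`` (default): two-sided binomial test of b successes in b+c
    trials at p = 1/2, capped at 1.  ``chi2``: chi-square statistic with
    continuity correction.  b = c = 0 gives p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise InvalidSpecError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if mode == "exact":
        p = 2.0 * sps.binom.cdf(min(b, c), n, 0.5)
        return float(min(p, 1.0))
    if mode == "chi2":
        stat = (abs(b - c) - 1.0) ** 2 / n
        return float(sps.chi2.sf(stat, df=1))
    raise InvalidSpecError(f"unknown McNemar mode {mode!r}")


# ---------------------------------------------------------------------------
# Quadratic weighted kappa


def quadratic_weighted_kappa(
    ref_grades: Sequence[int],
    pred_grades: Sequence[int],
    categories: Sequence[int] = GRADE_CATEGORIES,
) -> float:
    """Cohen's kappa with quadratic (squared-distance) disagreement weights.

    kappa = 1 - sum(w * O) / sum(w * E), with w_ij = (i - j)^2, O the
    observed contingency table and E the outer product of its marginals
    divided by n.  Two identical constant vectors have zero expected
    disagreement and return 1 by convention.
    """
    ref = np.asarray(ref_grades)
    pred = np.asarray(pred_grades)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise InvalidSpecError("grade vectors must be 1-D and equal length")
    if ref.size < 2:
        raise InvalidSpecError("need at least 2 cases")
    cats = np.asarray(categories)
    if not (np.isin(ref, cats).all() and np.isin(pred, cats).all()):
        raise InvalidSpecError("grades outside the category set")

    k = cats.size
    cat_index = {c: i for i, c in enumerate(cats.tolist())}
    ri = np.array([cat_index[v] for v in ref.tolist()])
    pi = np.array([cat_index[v] for v in pred.tolist()])
    obs = np.zeros((k, k))
    np.add.at(obs, (ri, pi), 1.0)
    expect = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / ref.size
    w = (np.arange(k)[:, None] - np.arange(k)[None, :]) ** 2
    denom = float(np.sum(w * expect))
    if denom == 0.0:
        return 1.0
    return float(1.0 - np.sum(w * obs) / denom)


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass(frozen=True)
class KappaResult:
    point: float
    ci: tuple[float, float]
    replicates: int
    seed: int
    aggregation_unit: str = "slide"
    n_redrawn: int = 0


def bootstrap_ci(
    statistic_fn: Callable[[np.ndarray], float],
    cases: Sequence,
    replicates: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_redraws: int = 100_000,
) -> tuple[tuple[float, float], int]:
    """Percentile bootstrap interval of a statistic over resampled cases.

    ``statistic_fn`` receives an index-resampled array of ``cases``.  A
    replicate on which the statistic is undefined (raises or returns
    NaN) is redrawn; the number of redraws is returned alongside the
    interval.
    """
    arr = np.asarray(cases, dtype=object) if not isinstance(cases, np.ndarray) else cases
    n = len(arr)
    if n == 0:
        raise InvalidSpecError("cases must be non-empty")
    rng = np.random.default_rng(seed)
    values = []
    redraws = 0
    while len(values) < replicates:
        idx = rng.integers(0, n, n)
        try:
            v = float(statistic_fn(arr[idx]))
        except (ValueError, ZeroDivisionError, InvalidSpecError):
            v = float("nan")
        if np.isnan(v):
            redraws += 1
            if redraws > max_redraws:
                raise InvalidSpecError("statistic undefined on too many replicates")
            continue
        values.append(v)
    alpha = 1.0 - level
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(lo), float(hi)), redraws


def kappa_with_ci(
    ref_grades: Sequence[int],
    pred_grades: Sequence[int],
    replicates: int = 1000,
    seed: int = 0,
    aggregation_unit: str = "slide",
    categories: Sequence[int] = GRADE_CATEGORIES,
) -> KappaResult:
    """QWK point estimate with a 1000-replicate percentile bootstrap CI."""
    ref = np.asarray(ref_grades)
    pred = np.asarray(pred_grades)
    point = quadratic_weighted_kappa(ref, pred, categories)
    pairs = np.arange(ref.size)

    def stat(idx_cases: np.ndarray) -> float:
        idx = idx_cases.astype(int)
        return quadratic_weighted_kappa(ref[idx], pred[idx], categories)

    ci, redraws = bootstrap_ci(stat, pairs, replicates, seed)
    ci = (min(ci[0], point), max(ci[1], point))
    return KappaResult(point, ci, replicates, seed, aggregation_unit, redraws)


# ---------------------------------------------------------------------------
# Paired failure analysis


@dataclass(frozen=True)
class PairedFailureTable:
    a_only: int
    b_only: int
    both: int
    total: int

    @property
    def a_failures(self) -> int:
        return self.a_only + self.both

    @property
    def b_failures(self) -> int:
        return self.b_only + self.both

    @property
    def excluded(self) -> int:
        return self.a_only + self.b_only + self.both

    def validate(self) -> None:
        if min(self.a_only, self.b_only, self.both, self.total) < 0:
            raise InvalidSpecError("counts must be non-negative")
        if self.excluded > self.total:
            raise InvalidSpecError("failures exceed total slides")


@dataclass(frozen=True)
class FailureAnalysis:
    table: PairedFailureTable
    a_ci: BinomialCI
    b_ci: BinomialCI
    mcnemar_p: float


def paired_failure_analysis(
    failures_a: Mapping[str, bool], failures_b: Mapping[str, bool], level: float = 0.95
) -> FailureAnalysis:
    """Tally per-slide detection failures of two methods over one slide set."""
    if set(failures_a) != set(failures_b):
        raise InvalidSpecError("slide sets differ between methods")
    a_only = sum(failures_a[s] and not failures_b[s] for s in failures_a)
    b_only = sum(failures_b[s] and not failures_a[s] for s in failures_a)
    both = sum(failures_a[s] and failures_b[s] for s in failures_a)
    table = PairedFailureTable(a_only, b_only, both, len(failures_a))
    table.validate()
    return failure_analysis_from_counts(table, level)


def failure_analysis_from_counts(
    table: PairedFailureTable, level: float = 0.95
) -> FailureAnalysis:
    """Failure rates, exact CIs, and McNemar p from a 2x2 paired table."""
    table.validate()
    return FailureAnalysis(
        table,
        clopper_pearson(table.a_failures, table.total, level),
        clopper_pearson(table.b_failures, table.total, level),
        mcnemar_exact(table.a_only, table.b_only),
    )


# ---------------------------------------------------------------------------
# Discordance summary


@dataclass(frozen=True)
class DiscordanceSummary:
    n_total: int
    n_discordant: int
    n_malignant: int
    n_malignant_discordant: int
    a_correct_only: int
    b_correct_only: int
    neither_correct: int
    confusion: np.ndarray       # 6x6, A-prediction x B-prediction, diagonal zero

    @property
    def discordant_share(self) -> float:
        return self.n_discordant / self.n_total if self.n_total else float("nan")

    @property
    def malignant_discordant_share(self) -> float:
        return (self.n_malignant_discordant / self.n_malignant
                if self.n_malignant else float("nan"))


def discordance(
    preds_a: Sequence[int], preds_b: Sequence[int], ref_grades: Sequence[int]
) -> DiscordanceSummary:
    """Slides graded differently under the two masks, and who was right.

    Direction counts (A right / B right / neither) are taken over
    malignant (reference grade >= 1) discordant slides; the confusion
    matrix covers all discordant slides regardless of label.
    """
    a = np.asarray(preds_a)
    b = np.asarray(preds_b)
    ref = np.asarray(ref_grades)
    if not (a.shape == b.shape == ref.shape) or a.ndim != 1:
        raise InvalidSpecError("grade vectors must be 1-D and aligned")
    k = len(GRADE_CATEGORIES)
    for v in (a, b, ref):
        if v.size and not np.isin(v, GRADE_CATEGORIES).all():
            raise InvalidSpecError("grades must be in 0..5")
    disc = a != b
    malignant = ref >= 1
    md = disc & malignant
    a_right = int(np.sum(md & (a == ref)))
    b_right = int(np.sum(md & (b == ref)))
    neither = int(np.sum(md & (a != ref) & (b != ref)))
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (a[disc], b[disc]), 1)
    return DiscordanceSummary(
        n_total=int(a.size),
        n_discordant=int(disc.sum()),
        n_malignant=int(malignant.sum()),
        n_malignant_discordant=int(md.sum()),
        a_correct_only=a_right,
        b_correct_only=b_right,
        neither_correct=neither,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Binary screening metrics


def binary_screen_metrics(
    ref_malignant: Sequence[bool], pred_malignant: Sequence[bool]
) -> tuple[float, float]:
    """(sensitivity, specificity) for malignant-vs-benign screening.

    Cohorts without positives leave sensitivity NaN; without negatives,
    specificity NaN — mirroring the N/A entries reported for all-
    malignant cohorts.
    """
    ref = np.asarray(ref_malignant, bool)
    pred = np.asarray(pred_malignant, bool)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise InvalidSpecError("vectors must be 1-D and aligned")
    pos = int(ref.sum())
    neg = int((~ref).sum())
    sens = float(np.sum(pred & ref) / pos) if pos else float("nan")
    spec = float(np.sum(~pred & ~ref) / neg) if neg else float("nan")
    return sens, spec
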