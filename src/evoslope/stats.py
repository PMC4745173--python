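"""Resampling significance, two-sample comparison and threshold metrics.

Two resampling nulls accompany the global slope of a sequence:

* **multinomial bootstrap** — iid sequences of the same (truncated) length
  with letter probabilities equal to the observed base proportions; the
  achieved significance level (ASL) is the fraction of null slopes at or
  below the observed one (left tail, tie-inclusive);
* **permutation test** — random shuffles of the observed residues, so the
  base counts are preserved exactly; the empirical p-value is defined the
  same way.

Exon/intron separation is summarised by a confusion table at a slope
threshold (predicted exon <=> slope > threshold), the usual derived
metrics (sensitivity, specificity, accuracy, Matthews correlation), and
the threshold maximising the Youden index J = sens + spec - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .encoding import DEFAULT_REPRESENTATIVES, NucleotideSequence, as_sequence
from .regions import composition_stats
from .spectra import SpectralSlope, global_slope
from . import simulate


class DegenerateVarianceError(ValueError):
    """Both samples constant: the t statistic is undefined."""


class UndefinedMetricError(ValueError):
    """A confusion-table marginal is zero."""


class DegenerateBandwidthError(ValueError):
    """All KDE input values identical."""


@dataclass(frozen=True)
class ResamplingResult:
    observed: SpectralSlope
    null_slopes: np.ndarray
    asl: float
    n_replicates: int
    seed: int | None
    n_nonfinite_null: int

    def as_dict(self) -> dict:
        return {
            "observed_slope": self.observed.s,
            "used_length": self.observed.used_length,
            "asl": self.asl,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "n_nonfinite_null": self.n_nonfinite_null,
            "log_base": self.observed.log_base,
        }


def achieved_significance(observed: float, null_slopes: np.ndarray) -> float:
    """Left-tail, tie-inclusive ASL: #(null <= observed) / #null.

    Non-finite null slopes stay in the denominator; NaN comparisons are
    False, so missing nulls can never enter the numerator.
    """
    null_slopes = np.asarray(null_slopes, dtype=float)
    if null_slopes.size == 0:
        raise ValueError("need at least one null replicate")
    with np.errstate(invalid="ignore"):
        return float(np.count_nonzero(null_slopes <= observed) / null_slopes.size)


def _resample(
    seq: NucleotideSequence | str,
    n: int,
    seed: int | None,
    mode: str,
    log_base: str,
    representatives: tuple[str, str, str],
    code: str,
    kind: str,
) -> ResamplingResult:
    s = as_sequence(seq)
    observed = global_slope(
        s, mode=mode, code=code, representatives=representatives, log_base=log_base
    )
    used = observed.used_length or len(s)
    rng = np.random.default_rng(seed)
    if kind == "bootstrap":
        comp = composition_stats(s)
        probs = tuple(comp.proportions[b] for b in "ACGT")
    else:
        prefix = np.frombuffer(s.residues[:used].encode("ascii"), dtype=np.uint8)
    nulls = np.empty(n)
    for i in range(n):
        if kind == "bootstrap":
            null_seq = simulate.random_dna(used, probs, seed=rng)
        else:
            null_seq = NucleotideSequence(
                f"{s.id}|perm{i}", rng.permutation(prefix).tobytes().decode("ascii")
            )
        nulls[i] = global_slope(
            null_seq,
            mode=mode,
            code=code,
            representatives=representatives,
            log_base=log_base,
        ).s
    return ResamplingResult(
        observed=observed,
        null_slopes=nulls,
        asl=achieved_significance(observed.s, nulls),
        n_replicates=n,
        seed=seed,
        n_nonfinite_null=int(np.count_nonzero(~np.isfinite(nulls))),
    )


def bootstrap_asl(
    seq: NucleotideSequence | str,
    n: int = 10_000,
    seed: int | None = None,
    mode: str = "invariant",
    log_base: str = "e",
    representatives: tuple[str, str, str] = DEFAULT_REPRESENTATIVES,
    code: str = "ACGT",
) -> ResamplingResult:
    """Parametric (multinomial) bootstrap ASL for one sequence.

    Null sequences are iid draws of the truncated length with the
    observed base proportions of the full sequence — composition matched
    in expectation, not exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return _resample(seq, n, seed, mode, log_base, representatives, code, "bootstrap")


def permutation_test(
    seq: NucleotideSequence | str,
    n: int = 20_000,
    seed: int | None = None,
    mode: str = "invariant",
    log_base: str = "e",
    representatives: tuple[str, str, str] = DEFAULT_REPRESENTATIVES,
    code: str = "ACGT",
) -> ResamplingResult:
    """Permutation-test empirical p-value for one sequence.

    Null sequences are shuffles of the (truncated) observed residues, so
    base counts are preserved exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return _resample(seq, n, seed, mode, log_base, representatives, code, "permutation")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample t-test (pooled variance by default; Welch on request)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateVarianceError("both samples are constant")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    if welch:
        nx, ny = x.size, y.size
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    else:
        df = x.size + y.size - 2
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts at a slope threshold; positive class = exon = slope above."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float | None
    j: float
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


def confusion_at(
    threshold: float,
    exon_slopes: Sequence[float],
    intron_slopes: Sequence[float],
) -> ConfusionCounts:
    """Confusion counts for the rule "predict exon iff slope > threshold"."""
    ex = np.asarray(exon_slopes, dtype=float)
    inx = np.asarray(intron_slopes, dtype=float)
    if not (np.isfinite(ex).all() and np.isfinite(inx).all()):
        raise ValueError("confusion counts require finite slopes only")
    return ConfusionCounts(
        tp=int(np.count_nonzero(ex > threshold)),
        fn=int(np.count_nonzero(ex <= threshold)),
        fp=int(np.count_nonzero(inx > threshold)),
        tn=int(np.count_nonzero(inx <= threshold)),
    )


def metrics_from_confusion(
    c: ConfusionCounts, threshold: float | None = None
) -> ThresholdMetrics:
    """Sensitivity, specificity, accuracy, MCC and J from a confusion table."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError(f"zero class marginal in {c}")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    denom = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    # MCC of an all-one-way prediction is conventionally 0
    mcc = (c.tp * c.tn - c.fp * c.fn) / denom if denom else 0.0
    return ThresholdMetrics(
        threshold=threshold,
        j=sens + spec - 1,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        mcc=mcc,
    )


def youden_threshold(
    exon_slopes: Sequence[float], intron_slopes: Sequence[float]
) -> ThresholdMetrics:
    """Threshold s* maximising the Youden index J = sens + spec - 1.

    Candidates are the midpoints between consecutive distinct pooled
    slopes plus one sentinel below the minimum and one above the maximum;
    ties in J break toward the smallest threshold.
    """
    ex = np.asarray(exon_slopes, dtype=float)
    inx = np.asarray(intron_slopes, dtype=float)
    if ex.size == 0 or inx.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(ex).all() and np.isfinite(inx).all()):
        raise ValueError("threshold search requires finite slopes only")
    pooled = np.unique(np.concatenate([ex, inx]))
    grid = np.concatenate(
        [[pooled[0] - 1.0], (pooled[:-1] + pooled[1:]) / 2.0, [pooled[-1] + 1.0]]
    )
    best: ThresholdMetrics | None = None
    for t in grid:  # ascending, strict improvement => smallest-threshold tie-break
        m = metrics_from_confusion(confusion_at(t, ex, inx), threshold=float(t))
        if best is None or m.j > best.j + 1e-12:
            best = m
    assert best is not None
    return best


def kde_1d(
    values: Sequence[float], n_points: int = 100, extend: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density with Silverman bandwidth on a uniform grid.

    The grid has ``n_points`` points covering the data range (optionally
    padded by ``extend`` times the range on each side, e.g. for checking
    normalisation).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise DegenerateBandwidthError("all values identical")
    kde = sps.gaussian_kde(v, bw_method="silverman")
    pad = extend * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_points)
    return grid, kde(grid)
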