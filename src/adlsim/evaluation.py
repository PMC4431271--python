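"""Dataset similarity via interval-binned sensor frequencies and Fisher's
exact test.

Two timestamped sensor-event datasets covering the same number of days are
compared sensor by sensor.  The day is cut into fixed intervals (default
five minutes, small compared with typical activity durations) and the
activations of each sensor are counted per interval, day k of one dataset
aligned with day k of the other at matching clock time.  The two count
vectors form a 2×K contingency table (intervals empty in both datasets are
dropped) and the null hypothesis — both datasets arise from the same
behaviour, i.e. follow a similar sensor frequency distribution — is scored
with a two-sided Fisher exact test.  Counts per interval are mostly zero
or one, which rules out the chi-squared approximation.  The unweighted
mean of the per-sensor p-values is the similarity score: identical
distributions give 1, and values above the usual 0.05/0.1 thresholds mean
the null cannot be rejected.

The test p-value is the total multivariate-hypergeometric probability of
all tables with the observed margins that are no more probable than the
observed table (with the customary ``1 + 1e-7`` tie multiplier).  Tables
whose margin-compatible family is small are enumerated exactly; larger
families fall back to seeded Monte-Carlo sampling with fixed margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from math import log1p
from typing import Iterable

import numpy as np
from scipy.special import gammaln

from .simulator import LabelledDataset

__all__ = [
    "BinningSpec",
    "SensorHistogram",
    "ContingencyTable",
    "ComparisonReport",
    "bin_events",
    "build_contingency",
    "fisher_exact",
    "compare_datasets",
]

#: relative tie tolerance for "no more probable than observed"
_TIE_EPS = 1e-7


@dataclass(frozen=True)
class BinningSpec:
    """Interval binning of a multi-day period."""

    period_days: int
    interval_s: int = 300

    def __post_init__(self) -> None:
        if self.interval_s <= 0 or 86400 % self.interval_s != 0:
            raise ValueError("interval_s must be positive and divide 86400")
        if self.period_days < 1:
            raise ValueError("period_days must be >= 1")

    @property
    def bins_per_day(self) -> int:
        return 86400 // self.interval_s

    @property
    def n_bins(self) -> int:
        return self.period_days * self.bins_per_day


@dataclass
class SensorHistogram:
    """Per-interval activation counts of one sensor, days concatenated."""

    sensor_name: str
    counts: np.ndarray


def bin_events(
    ds: LabelledDataset, spec: BinningSpec, period_start: date | None = None
) -> dict[str, SensorHistogram]:
    """Count each sensor's activations per interval.

    An event at in-day second ``t`` of day ``d`` lands in bin
    ``d * bins_per_day + t // interval_s``.  ``period_start`` defaults to
    the dataset's first day; an event outside the period is an error.
    """
    start = ds.span[0] if period_start is None else period_start
    hists: dict[str, SensorHistogram] = {}
    for ev in ds.events:
        day_idx = (ev.timestamp.date() - start).days
        if not 0 <= day_idx < spec.period_days:
            raise ValueError(
                f"event at {ev.timestamp.isoformat()} lies outside the "
                f"{spec.period_days}-day period starting {start.isoformat()}"
            )
        t = ev.timestamp.hour * 3600 + ev.timestamp.minute * 60 + ev.timestamp.second
        b = day_idx * spec.bins_per_day + t // spec.interval_s
        if ev.sensor_name not in hists:
            hists[ev.sensor_name] = SensorHistogram(
                ev.sensor_name, np.zeros(spec.n_bins, dtype=np.int64)
            )
        hists[ev.sensor_name].counts[b] += 1
    return hists


@dataclass
class ContingencyTable:
    """2×K non-negative integer counts, rows = the two datasets."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2 or self.counts.shape[1] < 1:
            raise ValueError("contingency table must be 2 x K with K >= 1")
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be non-negative")


def build_contingency(hA: SensorHistogram, hB: SensorHistogram) -> ContingencyTable:
    """Stack two equal-length histograms and drop intervals empty in both."""
    a = np.asarray(hA.counts, dtype=np.int64)
    b = np.asarray(hB.counts, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("histograms must have equal length")
    keep = (a + b) > 0
    if not keep.any():
        raise ValueError(
            f"sensor {hA.sensor_name!r}: no activations in either dataset"
        )
    return ContingencyTable(np.vstack([a[keep], b[keep]]))


# ---------------------------------------------------------------------------
# Fisher's exact test for 2 x K tables
# ---------------------------------------------------------------------------


def _log_table_prob_terms(col_sums: np.ndarray, row0: int, total: int) -> float:
    # log of the constant denominator log C(N, r0)
    return float(gammaln(total + 1) - gammaln(row0 + 1) - gammaln(total - row0 + 1))


def _log_prob_first_row(a: np.ndarray, col_sums: np.ndarray, log_denom: float) -> np.ndarray:
    """Log multivariate-hypergeometric probability of first-row vector(s) a."""
    a = np.atleast_2d(a)
    terms = (
        gammaln(col_sums + 1)
        - gammaln(a + 1)
        - gammaln(col_sums - a + 1)
    )
    return terms.sum(axis=1) - log_denom


def n_margin_tables_bound(table: ContingencyTable) -> int:
    """Cheap over-estimate of the number of margin-compatible tables:
    the product over columns of (column total + 1)."""
    col_sums = table.counts.sum(axis=0)
    bound = 1
    for c in col_sums:
        bound *= int(c) + 1
        if bound > 10**15:
            return 10**15
    return bound


def _enumerate_exact(
    col_sums: np.ndarray, row0: int, log_p_obs: float, log_denom: float
) -> float:
    """Sum Pr(T) over all margin-compatible tables with
    Pr(T) <= Pr(obs)·(1+eps), by depth-first search over the first row."""
    K = len(col_sums)
    suffix = np.concatenate([np.cumsum(col_sums[::-1])[::-1], [0]])
    threshold = log_p_obs + log1p(_TIE_EPS)
    log_choose = [
        gammaln(c + 1) - gammaln(np.arange(c + 1) + 1) - gammaln(c - np.arange(c + 1) + 1)
        for c in col_sums
    ]
    total_p = 0.0

    # stack of (column index, remaining row-0 mass, accumulated log prob)
    stack = [(0, row0, -log_denom)]
    while stack:
        j, rem, acc = stack.pop()
        if j == K:
            if acc <= threshold:
                total_p += float(np.exp(acc))
            continue
        lo = max(0, rem - int(suffix[j + 1]))
        hi = min(int(col_sums[j]), rem)
        for a in range(lo, hi + 1):
            stack.append((j + 1, rem - a, acc + float(log_choose[j][a])))
    return min(total_p, 1.0)


def fisher_exact(
    table: ContingencyTable,
    seed: int = 0,
    max_tables: int = 10**6,
    n_mc: int = 10**4,
) -> float:
    """Two-sided Fisher exact p-value for a 2×K contingency table.

    Exact enumeration when the margin-compatible family is no larger than
    ``max_tables`` (by the :func:`n_margin_tables_bound` over-estimate);
    otherwise seeded Monte-Carlo with fixed margins, where
    ``p = (1 + #{Pr(T*) <= Pr(obs)}) / (n_mc + 1)``.
    """
    counts = table.counts
    # all-zero columns fix their cell values and carry no information
    counts = counts[:, counts.sum(axis=0) > 0]
    row_sums = counts.sum(axis=1)
    if counts.shape[1] == 0 or (row_sums == 0).any():
        raise ValueError("degenerate margins: a row sums to zero (or the table is empty)")
    col_sums = counts.sum(axis=0)

    total = int(counts.sum())
    row0 = int(row_sums[0])
    log_denom = _log_table_prob_terms(col_sums, row0, total)
    log_p_obs = float(_log_prob_first_row(counts[0], col_sums, log_denom)[0])

    if n_margin_tables_bound(table) <= max_tables:
        return _enumerate_exact(col_sums, row0, log_p_obs, log_denom)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col_sums, row0, size=n_mc)
    log_p = _log_prob_first_row(draws, col_sums, log_denom)
    hits = int(np.count_nonzero(log_p <= log_p_obs + log1p(_TIE_EPS)))
    return (1 + hits) / (n_mc + 1)


def uses_exact_mode(table: ContingencyTable, max_tables: int = 10**6) -> bool:
    """Whether :func:`fisher_exact` would enumerate this table exactly."""
    return n_margin_tables_bound(table) <= max_tables


# ---------------------------------------------------------------------------
# the report
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Per-sensor Fisher p-values and their unweighted mean.

    Sensors present in only one dataset get ``None`` and are excluded from
    the mean.  ``modes`` records whether each p-value came from exact
    enumeration or Monte-Carlo sampling.
    """

    p_values: dict[str, float | None]
    mean_p: float
    binning: BinningSpec
    modes: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def aggregate(p_values: Iterable[float]) -> float:
        """Unweighted arithmetic mean of p-values."""
        vals = list(p_values)
        if not vals:
            raise ValueError("no p-values to aggregate")
        return float(sum(vals) / len(vals))

    def to_dict(self) -> dict:
        return {
            "interval_s": self.binning.interval_s,
            "period_days": self.binning.period_days,
            "p_values": self.p_values,
            "modes": self.modes,
            "mean_p": self.mean_p,
        }


def compare_datasets(
    dsA: LabelledDataset,
    dsB: LabelledDataset,
    spec: BinningSpec,
    sensors: list[str] | None = None,
    seed: int = 0,
    max_tables: int = 10**6,
    n_mc: int = 10**4,
) -> ComparisonReport:
    """Compare two datasets sensor by sensor; day k aligns with day k.

    For every sensor present in both datasets the pipeline is
    bin → contingency → Fisher; ``mean_p`` is the unweighted mean over
    those sensors.  A ``sensors`` list restricts the comparison.
    """
    hA = bin_events(dsA, spec)
    hB = bin_events(dsB, spec)
    if sensors is None:
        names = sorted(set(hA) | set(hB))
    else:
        names = list(sensors)

    p_values: dict[str, float | None] = {}
    modes: dict[str, str] = {}
    for name in names:
        if name not in hA or name not in hB:
            warnings.warn(
                f"sensor {name!r} present in only one dataset; excluded from mean_p",
                stacklevel=2,
            )
            p_values[name] = None
            continue
        tab = build_contingency(hA[name], hB[name])
        p_values[name] = fisher_exact(tab, seed=seed, max_tables=max_tables, n_mc=n_mc)
        modes[name] = "exact" if uses_exact_mode(tab, max_tables) else "monte-carlo"

    defined = [p for p in p_values.values() if p is not None]
    if not defined:
        raise ValueError("no sensor is present in both datasets")
    return ComparisonReport(
        p_values=p_values,
        mean_p=ComparisonReport.aggregate(defined),
        binning=spec,
        modes=modes,
    )
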