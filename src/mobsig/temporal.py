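"""Temporal disruption analysis between two observation periods.

Quantifies how a city's mobility changed between a baseline period and
a comparison period (e.g. pre-pandemic vs pandemic months):

* per-destination relative differences of signature fractions,
  (f_a - f_b) / f_a, plus destinations lost and gained;
* signature-length change (the number of destinations reached);
* flow-weighted outgoing trip-distance samples, their means, and a
  two-sample Kolmogorov-Smirnov comparison of the distance
  distributions (each trip counts as one observation; the weighted
  empirical CDFs are computed without materializing the expansion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .core import DistanceTable, ODMatrix
from .signatures import compute_signature


@dataclass
class PeriodComparison:
    """Signature change of one city between two periods."""

    city_id: str
    period_a: str
    period_b: str
    length_a: int
    length_b: int
    #: destination -> (fraction_a - fraction_b) / fraction_a, for
    #: destinations present in both periods
    relative_differences: dict[str, float]
    lost: tuple[str, ...]    # present in a, absent in b
    gained: tuple[str, ...]  # absent in a, present in b


def compare_periods(od_a: ODMatrix, od_b: ODMatrix, city_id: str) -> PeriodComparison:
    """Compare one city's signatures across two preprocessed matrices.

    Relative differences are matched by destination identity (not by
    rank).  A city absent from one period has an empty signature there;
    all its destinations then appear as lost or gained.
    """

    def _sig_map(od: ODMatrix) -> dict[str, float]:
        if city_id not in od.city_ids():
            return {}
        return compute_signature(od, city_id).as_mapping()

    fa = _sig_map(od_a)
    fb = _sig_map(od_b)
    common = set(fa) & set(fb)
    rel = {d: (fa[d] - fb[d]) / fa[d] for d in sorted(common)}
    lost = tuple(sorted(set(fa) - set(fb)))
    gained = tuple(sorted(set(fb) - set(fa)))
    return PeriodComparison(city_id, od_a.period, od_b.period,
                            len(fa), len(fb), rel, lost, gained)


@dataclass
class DistanceSample:
    """Flow-weighted multiset of one city's outgoing trip distances.

    ``distances[k]`` occurs with multiplicity ``counts[k]`` (one
    observation per trip).  ``mean`` is the flow-weighted average
    distance, ``None`` for a city with no outgoing flow.
    """

    city_id: str
    period: str
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n(self) -> float:
        """Total number of trips (observations)."""
        return float(self.counts.sum()) if len(self.counts) else 0.0

    @property
    def mean(self) -> float | None:
        if self.n == 0:
            return None
        return float((self.distances * self.counts).sum() / self.counts.sum())


def distance_sample(od: ODMatrix, dist: DistanceTable, city_id: str) -> DistanceSample:
    """Outgoing trip-distance sample of one city.

    Each directed flow contributes its great-circle distance with
    multiplicity equal to the trip count.
    """
    out = od.outgoing(city_id)
    if not out:
        return DistanceSample(city_id, od.period)
    pairs = sorted((dist.distance(city_id, d), v) for d, v in out.items())
    ds = np.array([p[0] for p in pairs])
    cs = np.array([p[1] for p in pairs], dtype=float)
    return DistanceSample(city_id, od.period, ds, cs)


def _weighted_ecdf_on(points: np.ndarray, distances: np.ndarray,
                      counts: np.ndarray) -> np.ndarray:
    """ECDF of a weighted sample evaluated at sorted ``points``."""
    order = np.argsort(distances)
    d_sorted = distances[order]
    cum = np.cumsum(counts[order])
    total = cum[-1]
    idx = np.searchsorted(d_sorted, points, side="right")
    return np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0) / total


def ks_two_sample(sample_a: DistanceSample, sample_b: DistanceSample) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on weighted distance samples.

    D is the supremum over the pooled support of the absolute
    difference of the two flow-weighted empirical CDFs.  The p-value is
    asymptotic, from the Kolmogorov distribution evaluated at
    sqrt(n_eff) * D with effective size n_eff = n_a n_b / (n_a + n_b) —
    appropriate in the large-sample regime of monthly OD data.
    """
    if sample_a.n == 0 or sample_b.n == 0:
        raise ValueError("KS test requires two non-empty samples")
    pooled = np.unique(np.concatenate([sample_a.distances, sample_b.distances]))
    ecdf_a = _weighted_ecdf_on(pooled, sample_a.distances, sample_a.counts)
    ecdf_b = _weighted_ecdf_on(pooled, sample_b.distances, sample_b.counts)
    d_stat = float(np.max(np.abs(ecdf_a - ecdf_b)))
    n_eff = sample_a.n * sample_b.n / (sample_a.n + sample_b.n)
    p_value = float(special.kolmogorov(np.sqrt(n_eff) * d_stat))
    return d_stat, p_value


def distance_histogram(sample: DistanceSample, bins) -> pd.DataFrame:
    """Flow-weighted density histogram of trip distances.

    Returns a frame with columns ``bin_left``, ``bin_right``,
    ``density`` (normalized so the histogram integrates to 1).
    """
    if sample.n == 0:
        raise ValueError("cannot histogram an empty sample")
    density, edges = np.histogram(sample.distances, bins=bins,
                                  weights=sample.counts, density=True)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "density": density,
    })


# ---------------------------------------------------------------------
# delimited-text output
# ---------------------------------------------------------------------

PERIOD_COLUMNS = ["city_id", "period_a", "period_b", "length_a", "length_b",
                  "n_lost", "n_gained", "mean_relative_difference"]


def write_period_comparisons(comparisons, path, sep: str = ",") -> None:
    rows = []
    for c in comparisons:
        rel = list(c.relative_differences.values())
        mean_rd = sum(rel) / len(rel) if rel else ""
        rows.append((c.city_id, c.period_a, c.period_b, c.length_a, c.length_b,
                     len(c.lost), len(c.gained), mean_rd))
    pd.DataFrame(rows, columns=PERIOD_COLUMNS).to_csv(
        path, sep=sep, index=False, lineterminator="\n")


def write_ks_table(rows, path, sep: str = ",") -> None:
    """Write a K-S table with columns city_id, D, p_value."""
    pd.DataFrame(rows, columns=["city_id", "D", "p_value"]).to_csv(
        path, sep=sep, index=False, lineterminator="\n")
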