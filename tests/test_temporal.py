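import numpy as np
import pytest
from scipy import stats

from mobsig import (
    DistanceSample, compare_periods, distance_histogram, distance_sample,
    ks_two_sample, pairwise_distances, perturb_lockdown, preprocess,
)
from mobsig.synthetic import SyntheticSpec, generate_city_system, generate_od
from conftest import make_od


def sample_from(values, city="A", period="p"):
    vals, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    return DistanceSample(city, period, vals, counts.astype(float))


def brute_force_ks(values_a, values_b):
    """Exhaustive max ECDF difference over pooled evaluation points."""
    a = sorted(values_a)
    b = sorted(values_b)
    points = sorted(set(a) | set(b))
    best = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


# --------------------------------------------------------- compare_periods

def test_compare_periods_identity():
    od = preprocess(make_od("a", A_B=60, A_C=30, A_D=10), 0)
    pc = compare_periods(od, od, "A")
    assert pc.length_a == pc.length_b == 3
    assert all(v == 0.0 for v in pc.relative_differences.values())
    assert pc.lost == () and pc.gained == ()


def test_compare_periods_scale_invariance():
    od_a = make_od("a", A_B=60, A_C=30, A_D=10)
    od_b = make_od("b", A_B=30, A_C=15, A_D=5)
    pc = compare_periods(od_a, od_b, "A")
    assert all(abs(v) < 1e-15 for v in pc.relative_differences.values())
    assert pc.length_a == pc.length_b


def test_compare_periods_lost_and_gained():
    od_a = make_od("a", A_B=60, A_C=30, A_D=10)
    od_b = make_od("b", A_B=60, A_C=30, A_E=10)
    pc = compare_periods(od_a, od_b, "A")
    assert pc.length_b == pc.length_a
    assert pc.lost == ("D",)
    assert pc.gained == ("E",)
    # fractions of shared destinations changed identically here
    assert set(pc.relative_differences) == {"B", "C"}


def test_compare_periods_city_absent_from_one_period():
    od_a = make_od("a", A_B=60, A_C=40)
    od_b = make_od("b", B_C=10)
    pc = compare_periods(od_a, od_b, "A")
    assert pc.length_b == 0
    assert pc.lost == ("B", "C")
    assert pc.relative_differences == {}


# --------------------------------------------------------- distance samples

def test_distance_sample_counts_and_mean(toy_cities, toy_dist):
    od = make_od(A_B=3)
    s = distance_sample(od, toy_dist, "A")
    d_ab = toy_dist.distance("A", "B")
    assert s.n == 3
    assert s.mean == pytest.approx(d_ab)
    od2 = make_od(A_B=1, A_C=1)
    s2 = distance_sample(od2, toy_dist, "A")
    assert s2.mean == pytest.approx(
        (toy_dist.distance("A", "B") + toy_dist.distance("A", "C")) / 2)


def test_distance_sample_weight_invariance(toy_cities, toy_dist):
    od = make_od(A_B=3, A_C=5, A_D=2)
    od2 = make_od(A_B=6, A_C=10, A_D=4)
    assert distance_sample(od, toy_dist, "A").mean == pytest.approx(
        distance_sample(od2, toy_dist, "A").mean, rel=1e-14)


def test_distance_sample_empty(toy_cities, toy_dist):
    s = distance_sample(make_od(B_A=5), toy_dist, "A")
    assert s.n == 0 and s.mean is None


# -------------------------------------------------------------------- K-S

def test_ks_identity_and_disjoint():
    s = sample_from([1, 2, 3])
    d, p = ks_two_sample(s, s)
    assert d == 0.0 and p == pytest.approx(1.0)
    d2, _ = ks_two_sample(sample_from([1, 1]), sample_from([100, 100]))
    assert d2 == 1.0


def test_ks_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(25):
        a = rng.integers(0, 15, size=rng.integers(2, 12)).tolist()
        b = rng.integers(0, 15, size=rng.integers(2, 12)).tolist()
        d, _ = ks_two_sample(sample_from(a), sample_from(b))
        assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)


def test_ks_statistic_matches_scipy_and_pvalue_matches_series():
    rng = np.random.default_rng(3)
    a = rng.exponential(50, 40).round(1)
    b = rng.exponential(80, 60).round(1)
    d, p = ks_two_sample(sample_from(a), sample_from(b))
    assert d == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)
    # independent evaluation of the Kolmogorov survival series
    # Q(x) = 2 * sum_k (-1)^(k-1) exp(-2 k^2 x^2)
    x = np.sqrt(len(a) * len(b) / (len(a) + len(b))) * d
    series = 2 * sum((-1) ** (k - 1) * np.exp(-2 * k * k * x * x)
                     for k in range(1, 200))
    assert p == pytest.approx(series, rel=1e-9)


def test_ks_symmetry_and_monotone_invariance():
    a, b = [1, 4, 4, 9], [2, 2, 16]
    d_ab, _ = ks_two_sample(sample_from(a), sample_from(b))
    d_ba, _ = ks_two_sample(sample_from(b), sample_from(a))
    assert d_ab == d_ba
    d_sq, _ = ks_two_sample(sample_from([x ** 2 for x in a]),
                            sample_from([x ** 2 for x in b]))
    assert d_sq == d_ab


def test_ks_rejects_empty():
    with pytest.raises(ValueError):
        ks_two_sample(sample_from([1]), DistanceSample("x", "p"))


# ------------------------------------------------------------ histograms

def test_distance_histogram_density_normalized():
    s = sample_from([10, 10, 10, 30, 50, 50])
    h = distance_histogram(s, bins=4)
    widths = h["bin_right"] - h["bin_left"]
    assert float((h["density"] * widths).sum()) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        distance_histogram(DistanceSample("x", "p"), bins=4)


# --------------------------------------------- lockdown perturbation pattern

def test_lockdown_reduces_distance_and_increases_ks():
    spec = SyntheticSpec(seed=9, n_cities=25, total_trips=300_000.0)
    cities, dist = generate_city_system(spec)
    od = generate_od(spec, cities, dist)
    baseline = distance_sample(od, dist, cities.ids[0])
    prev_d = 0.0
    prev_mean = baseline.mean
    for phi in (0.8, 0.5, 0.2):
        pert = perturb_lockdown(od, dist, phi, 100.0)
        s = distance_sample(pert, dist, cities.ids[0])
        d, _ = ks_two_sample(baseline, s)
        assert s.mean < prev_mean       # stronger suppression, shorter trips
        assert d > prev_d               # and larger distribution shift
        prev_d, prev_mean = d, s.mean


def test_lockdown_censoring_shortens_signatures():
    spec = SyntheticSpec(seed=9, n_cities=25, total_trips=300_000.0)
    cities, dist = generate_city_system(spec)
    od = preprocess(generate_od(spec, cities, dist), 20)
    pert = preprocess(perturb_lockdown(od, dist, 0.5, 100.0), 20)
    lengths = [(len(od.outgoing(c)), len(pert.outgoing(c))) for c in cities.ids]
    assert all(b <= a for a, b in lengths)
    assert sum(b for _, b in lengths) < sum(a for a, _ in lengths)
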