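import numpy as np
import pytest

from mobsig import (
    CalibrationError, City, CitySet, ConvergenceError, GravityModel,
    ModelError, ODMatrix, RadiationModel, gravity_calibrate,
    gravity_generate, model_signatures, pairwise_distances,
    radiation_generate,
)
from mobsig.synthetic import SyntheticSpec, generate_city_system, generate_od


def brute_force_ipf(dist, row, col, beta, n_iter=20000, tol=1e-12):
    """Independent Furness balancing written with explicit loops."""
    n = len(row)
    k = [[0.0 if i == j else np.exp(-beta * dist[i][j]) for j in range(n)]
         for i in range(n)]
    a = [1.0] * n
    b = [1.0] * n
    for _ in range(n_iter):
        for i in range(n):
            s = sum(k[i][j] * b[j] * col[j] for j in range(n))
            a[i] = 1.0 / s
        for j in range(n):
            s = sum(k[i][j] * a[i] * row[i] for i in range(n))
            b[j] = 1.0 / s
        T = [[a[i] * row[i] * k[i][j] * b[j] * col[j] for j in range(n)]
             for i in range(n)]
        err = max(
            max(abs(sum(T[i]) - row[i]) / row[i] for i in range(n)),
            max(abs(sum(T[i][j] for i in range(n)) - col[j]) / col[j] for j in range(n)),
        )
        if err < tol:
            return T
    raise AssertionError("oracle IPF did not converge")


def line_cities(populations, spacing_deg=0.2):
    """Cities on a meridian with given populations."""
    return CitySet([
        City(f"L{i}", f"L{i}", 60.0 + i * spacing_deg, 25.0, p)
        for i, p in enumerate(populations)
    ])


# ---------------------------------------------------------------- gravity

def test_gravity_two_city_margins_force_solution():
    cities = line_cities([100, 100])
    dist = pairwise_distances(cities)
    od = gravity_generate(cities, dist, ({"L0": 50.0, "L1": 50.0},
                                         {"L0": 50.0, "L1": 50.0}), beta=0.05)
    assert od.flow("L0", "L1") == pytest.approx(50.0, rel=1e-9)
    assert od.flow("L1", "L0") == pytest.approx(50.0, rel=1e-9)


def test_gravity_margins_reproduced(toy_cities, toy_dist):
    row = {"A": 1000.0, "B": 400.0, "C": 250.0, "D": 80.0}
    col = {"A": 500.0, "B": 700.0, "C": 330.0, "D": 200.0}
    od = gravity_generate(toy_cities, toy_dist, (row, col), beta=0.02)
    for cid, want in row.items():
        assert od.total_outgoing(cid) == pytest.approx(want, rel=1e-6)
    for cid, want in col.items():
        assert od.col_sums[cid] == pytest.approx(want, rel=1e-6)
    assert all(o != d for o, d, _ in od.pairs())


def test_gravity_matches_brute_force_oracle(toy_cities, toy_dist):
    row = [800.0, 300.0, 200.0, 100.0]
    col = [450.0, 500.0, 280.0, 170.0]
    od = gravity_generate(toy_cities, toy_dist, (row, col), beta=0.05)
    oracle = brute_force_ipf(toy_dist.matrix.tolist(), row, col, beta=0.05)
    ids = toy_cities.ids
    for i, o in enumerate(ids):
        for j, d in enumerate(ids):
            assert od.flow(o, d) == pytest.approx(oracle[i][j], rel=1e-6, abs=1e-9)


def test_gravity_zero_margin_city_has_no_flows(toy_cities, toy_dist):
    row = {"A": 100.0, "B": 50.0, "C": 0.0, "D": 30.0}
    col = {"A": 60.0, "B": 70.0, "C": 50.0, "D": 0.0}
    od = gravity_generate(toy_cities, toy_dist, (row, col), beta=0.01)
    assert od.total_outgoing("C") == 0.0
    assert od.col_sums.get("D", 0.0) == 0.0


def test_gravity_beta_to_zero_is_distance_independent():
    rng = np.random.default_rng(2)
    cities = CitySet([
        City(f"c{i}", f"c{i}", float(rng.uniform(60, 65)),
             float(rng.uniform(22, 30)), 10)
        for i in range(6)
    ])
    dist = pairwise_distances(cities)
    uniform = [100.0] * 6
    od = gravity_generate(cities, dist, (uniform, uniform), beta=1e-12)
    flows = [v for _, _, v in od.pairs()]
    assert max(flows) / min(flows) == pytest.approx(1.0, rel=1e-6)


def test_gravity_nonconvergence_raises_with_diagnostics(toy_cities, toy_dist):
    row = {"A": 1000.0, "B": 400.0, "C": 250.0, "D": 80.0}
    col = {"A": 500.0, "B": 700.0, "C": 330.0, "D": 200.0}
    with pytest.raises(ConvergenceError) as exc:
        gravity_generate(toy_cities, toy_dist, (row, col), beta=0.02, max_iter=1)
    assert exc.value.iterations == 1
    assert exc.value.max_rel_error > 0


def test_gravity_rejects_bad_margins(toy_cities, toy_dist):
    with pytest.raises(ValueError, match="differ"):
        gravity_generate(toy_cities, toy_dist,
                         ([1.0, 1, 1, 1], [2.0, 1, 1, 1]), beta=0.1)
    with pytest.raises(ValueError, match="beta"):
        gravity_generate(toy_cities, toy_dist,
                         ([1.0, 1, 1, 1], [1.0, 1, 1, 1]), beta=-0.1)
    # a dominant city whose production cannot fit elsewhere (diagonal is zero)
    with pytest.raises(ValueError, match="infeasible"):
        gravity_generate(toy_cities, toy_dist,
                         ([10.0, 1, 1, 1], [10.0, 1, 1, 1]), beta=0.1)


# ------------------------------------------------------------ calibration

def test_calibration_recovers_beta_noiseless():
    spec = SyntheticSpec(seed=21, n_cities=30, total_trips=500_000.0, beta=0.03)
    cities, dist = generate_city_system(spec)
    od = generate_od(spec, cities, dist)
    fit = gravity_calibrate(od, cities, dist)
    assert fit.calibrated
    assert fit.beta == pytest.approx(0.03, abs=1e-4)
    # generated matrix reproduces the observed mean trip distance
    assert fit.mean_trip_distance == pytest.approx(
        sum(v * dist.distance(o, d) for o, d, v in od.pairs()) / od.total, rel=1e-5)


def test_calibration_degenerate_two_city_matrix():
    cities = line_cities([100, 100])
    dist = pairwise_distances(cities)
    od = ODMatrix("p", {("L0", "L1"): 40.0, ("L1", "L0"): 40.0})
    # margins force the flows for any beta: mean distance is insensitive
    with pytest.raises(CalibrationError):
        gravity_calibrate(od, cities, dist)


def test_calibration_requires_observed():
    cities = line_cities([100, 100, 100])
    dist = pairwise_distances(cities)
    model = GravityModel(cities, dist, [10.0, 10, 10], [10.0, 10, 10])
    with pytest.raises(ValueError, match="observed"):
        model.fit()


def test_gravity_results_summary_mentions_fit():
    spec = SyntheticSpec(seed=21, n_cities=12, total_trips=50_000.0)
    cities, dist = generate_city_system(spec)
    od = generate_od(spec, cities, dist)
    res = GravityModel.from_od(od, cities, dist).fit(beta=0.03)
    text = res.summary()
    assert "beta" in text and "0.03" in text
    assert "fixed" in text
    kv = res.to_keyvalue()
    assert "beta = 0.03" in kv


# --------------------------------------------------------------- radiation

def test_radiation_three_city_line_hand_computed():
    # populations 100 each; from L0 the near destination is L1, far is L2
    cities = line_cities([100, 100, 100])
    dist = pairwise_distances(cities)
    od = radiation_generate(cities, dist, {"L0": 1000.0})
    # T = T_i/(1-m/M) * m*m/((m+s)(2m+s)); s=0 near, s=100 far
    assert od.flow("L0", "L1") == pytest.approx(750.0, rel=1e-12)
    assert od.flow("L0", "L2") == pytest.approx(250.0, rel=1e-12)
    assert od.flow("L1", "L0") == 0.0


def test_radiation_conserves_outgoing_totals():
    spec = SyntheticSpec(seed=4, n_cities=40)
    cities, dist = generate_city_system(spec)
    totals = {cid: float(1000 + 10 * i) for i, cid in enumerate(cities.ids)}
    od = radiation_generate(cities, dist, totals)
    for cid, want in totals.items():
        assert od.total_outgoing(cid) == pytest.approx(want, rel=1e-9)


def test_radiation_monotone_on_homogeneous_line():
    cities = line_cities([50] * 8)
    dist = pairwise_distances(cities)
    od = radiation_generate(cities, dist, {"L0": 1000.0})
    flows = [od.flow("L0", f"L{j}") for j in range(1, 8)]
    assert all(a >= b for a, b in zip(flows, flows[1:]))


def test_radiation_equidistant_tie_break_by_id():
    # L1 and L2 equidistant from the middle city; ordering falls back to id
    cities = CitySet([
        City("M", "mid", 60.0, 25.0, 100),
        City("A", "south", 59.5, 25.0, 200),
        City("B", "north", 60.5, 25.0, 300),
    ])
    dist = pairwise_distances(cities)
    assert dist.distance("M", "A") == pytest.approx(dist.distance("M", "B"), rel=1e-9)
    od = radiation_generate(cities, dist, {"M": 100.0})
    # A sorts before B: s=0 for A, s=pop(A) for B
    m, ma, mb, M = 100, 200, 300, 600
    corr = 1 / (1 - m / M)
    t_a = 100 * corr * m * ma / ((m + 0) * (m + ma + 0))
    t_b = 100 * corr * m * mb / ((m + ma) * (m + mb + ma))
    assert od.flow("M", "A") == pytest.approx(t_a, rel=1e-12)
    assert od.flow("M", "B") == pytest.approx(t_b, rel=1e-12)


def test_radiation_single_city_undefined():
    cities = CitySet([City("A", "a", 60.0, 25.0, 100)])
    dist = pairwise_distances(cities)
    with pytest.raises(ModelError):
        RadiationModel(cities, dist, {"A": 10.0}).generate()


# --------------------------------------------------------- model signatures

def test_model_signatures_threshold_censors_real_flows():
    cities = line_cities([100, 100, 100])
    dist = pairwise_distances(cities)
    od = ODMatrix("m", {("L0", "L1"): 19.4, ("L0", "L2"): 30.0, ("L1", "L0"): 25.0})
    sigs = model_signatures(od, threshold=20)
    assert sigs["L0"].destinations == ("L2",)
    assert sigs["L0"].fractions.tolist() == [1.0]  # renormalized over survivors
    sigs0 = model_signatures(od, threshold=0)
    assert sigs0["L0"].length == 2
    assert abs(sigs0["L0"].fractions.sum() - 1.0) < 1e-12
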