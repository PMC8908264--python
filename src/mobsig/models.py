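"""Collective mobility models: doubly-constrained gravity and radiation.

Gravity
-------
The doubly-constrained gravity model with exponential deterrence places

    T_ij = A_i n_i+  B_j n_+j  exp(-beta d_ij),   T_ii = 0,

where n_i+ / n_+j are the observed production (outgoing) and attraction
(incoming) margins and the balancing factors A_i, B_j are determined by
iterative proportional fitting (Furness balancing) so that both margin
constraints hold:  sum_j T_ij = n_i+  and  sum_i T_ij = n_+j.

The deterrence rate beta (1/km) is calibrated Hyman-style: bisection
finds the beta whose generated flow-weighted mean trip distance matches
the observed one.

Radiation
---------
The parameter-free radiation model with finite-size correction places

    T_ij = T_i * 1/(1 - m_i/M) * m_i m_j / ((m_i + s_ij)(m_i + m_j + s_ij)),

where m_i are city populations (opportunities), M their total, T_i the
number of travellers leaving i, and s_ij the population of cities
strictly closer to i than j (origin and destination excluded).  With a
total order on destinations by (distance, id), the sum over j
telescopes and outgoing flows conserve T_i exactly.

Both models expose a statsmodels-style surface (``GravityModel.fit()``
returns a :class:`GravityResults`) plus plain functions
(:func:`gravity_generate`, :func:`gravity_calibrate`,
:func:`radiation_generate`, :func:`model_signatures`).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .core import CitySet, DistanceTable, ODMatrix, preprocess, DEFAULT_THRESHOLD
from .exceptions import CalibrationError, ConvergenceError, ModelError
from .signatures import MobilitySignature, all_signatures

__all__ = [
    "GravityModel", "GravityResults", "RadiationModel", "RadiationResults",
    "gravity_generate", "gravity_calibrate", "radiation_generate",
    "model_signatures",
]

IPF_TOL = 1e-8
IPF_MAX_ITER = 10_000
CALIBRATION_BRACKET = (1e-6, 10.0)
CALIBRATION_REL_TOL = 1e-6


def _margins_to_array(margins, cities: CitySet) -> np.ndarray:
    """Accept a mapping id -> value or a sequence in set order."""
    if isinstance(margins, Mapping):
        return np.array([float(margins.get(cid, 0.0)) for cid in cities.ids])
    arr = np.asarray(margins, dtype=float)
    if arr.shape != (len(cities),):
        raise ValueError(f"margins length {arr.shape} does not match {len(cities)} cities")
    return arr.copy()


def _ipf(kernel: np.ndarray, row: np.ndarray, col: np.ndarray,
         tol: float = IPF_TOL, max_iter: int = IPF_MAX_ITER):
    """Furness balancing of ``T = diag(a*row) @ kernel @ diag(b*col)``.

    Returns (T, a, b, iterations, max_rel_error).  Rows/columns with a
    zero margin are fixed at zero flow and excluded from the error.
    """
    n = kernel.shape[0]
    active_r = row > 0
    active_c = col > 0
    a = np.ones(n)
    b = np.ones(n)
    a[~active_r] = 0.0
    b[~active_c] = 0.0

    def margin_error(T: np.ndarray) -> float:
        errs = [0.0]
        if active_r.any():
            errs.append(float(np.max(np.abs(T.sum(axis=1)[active_r] - row[active_r]) / row[active_r])))
        if active_c.any():
            errs.append(float(np.max(np.abs(T.sum(axis=0)[active_c] - col[active_c]) / col[active_c])))
        err = np.max(errs)
        if not np.isfinite(err):
            raise ConvergenceError(
                "numerical overflow in balancing factors (deterrence too strong "
                "for the margin structure)", iterations=it, max_rel_error=float("inf"))
        return float(err)

    err = np.inf
    it = 0
    check_every = 10  # margin check costs a full matrix product
    with np.errstate(over="raise", invalid="raise"):
        try:
            for it in range(1, max_iter + 1):
                denom_r = kernel @ (b * col)
                bad = active_r & (denom_r <= 0)
                if bad.any():
                    raise ConvergenceError(
                        "infeasible margins: a row with positive production reaches no "
                        "destination with positive attraction",
                        iterations=it, max_rel_error=float("inf"))
                a[active_r] = 1.0 / denom_r[active_r]
                denom_c = kernel.T @ (a * row)
                bad = active_c & (denom_c <= 0)
                if bad.any():
                    raise ConvergenceError(
                        "infeasible margins: a column with positive attraction is reached "
                        "by no origin with positive production",
                        iterations=it, max_rel_error=float("inf"))
                b[active_c] = 1.0 / denom_c[active_c]
                if it % check_every == 0 or it == max_iter:
                    T = (a * row)[:, None] * kernel * (b * col)[None, :]
                    err = margin_error(T)
                    if err < tol:
                        return T, a, b, it, err
        except FloatingPointError:
            raise ConvergenceError(
                "numerical overflow in balancing factors (deterrence too strong "
                "for the margin structure)",
                iterations=it, max_rel_error=float("inf")) from None
    raise ConvergenceError(
        f"IPF did not converge in {max_iter} iterations (max relative margin "
        f"error {err:.3e} > {tol:.1e})",
        iterations=it, max_rel_error=err)


def _check_margins(row: np.ndarray, col: np.ndarray) -> None:
    if (row < 0).any() or (col < 0).any():
        raise ValueError("margins must be non-negative")
    tr, tc = row.sum(), col.sum()
    if tr <= 0:
        raise ValueError("total production margin must be positive")
    if abs(tr - tc) > 1e-9 * max(tr, tc):
        raise ValueError(f"production total {tr!r} and attraction total {tc!r} differ")
    # zero diagonal: city i's production must fit in the other cities'
    # attraction, and vice versa (margins of any real matrix satisfy this)
    bad = row > tc - col + 1e-9 * tc
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"infeasible margins with a zero diagonal: production {row[i]!r} of "
            f"city index {i} exceeds the attraction {tc - col[i]!r} available elsewhere")
    bad = col > tr - row + 1e-9 * tr
    if bad.any():
        j = int(np.argmax(bad))
        raise ValueError(
            f"infeasible margins with a zero diagonal: attraction {col[j]!r} of "
            f"city index {j} exceeds the production {tr - row[j]!r} available elsewhere")


class GravityResults:
    """Fitted doubly-constrained gravity model.

    Attributes
    ----------
    beta : float
        Exponential deterrence rate (1/km).
    balancing_production, balancing_attraction : dict
        Balancing factors A_i and B_j keyed by city id (zero-margin
        cities carry factor 0).
    od : ODMatrix
        Generated real-valued flow matrix satisfying both margins.
    iterations, max_rel_margin_error : convergence diagnostics.
    calibrated : whether beta was estimated from the observed matrix.
    """

    def __init__(self, model, beta, a, b, od, iterations, max_rel_margin_error,
                 calibrated, n_objective_evals=0):
        self.model = model
        self.beta = float(beta)
        ids = model.cities.ids
        self.balancing_production = dict(zip(ids, a))
        self.balancing_attraction = dict(zip(ids, b))
        self.od = od
        self.iterations = iterations
        self.max_rel_margin_error = max_rel_margin_error
        self.calibrated = calibrated
        self.n_objective_evals = n_objective_evals

    @property
    def mean_trip_distance(self) -> float:
        """Flow-weighted mean trip distance (km) of the generated matrix."""
        return _mean_trip_distance(self.od, self.model.distances)

    def signatures(self, threshold: float = DEFAULT_THRESHOLD) -> dict[str, MobilitySignature]:
        return model_signatures(self.od, threshold=threshold, cities=self.model.cities)

    def summary(self) -> str:
        lines = [
            "Doubly-constrained gravity model",
            "================================",
            f"cities:                   {len(self.model.cities)}",
            f"beta (1/km):              {self.beta:.6g}" + ("  (calibrated)" if self.calibrated else "  (fixed)"),
            f"total flow:               {self.od.total:.6g}",
            f"mean trip distance (km):  {self.mean_trip_distance:.6g}",
            f"IPF iterations:           {self.iterations}",
            f"max rel margin error:     {self.max_rel_margin_error:.3e}",
        ]
        return "\n".join(lines)

    def to_keyvalue(self) -> str:
        """Small key = value serialization of the fit."""
        return "\n".join([
            f"beta = {self.beta!r}",
            f"calibrated = {self.calibrated}",
            f"iterations = {self.iterations}",
            f"max_rel_margin_error = {self.max_rel_margin_error!r}",
        ]) + "\n"


class GravityModel:
    """Doubly-constrained gravity model with exponential deterrence.

    Parameters
    ----------
    cities, distances : the city system.
    production, attraction : margins n_i+ and n_+j (mapping id -> value
        or sequence in set order) with equal grand totals.
    observed : optional preprocessed ODMatrix; required for calibration.
    """

    def __init__(self, cities: CitySet, distances: DistanceTable,
                 production, attraction, observed: ODMatrix | None = None):
        self.cities = cities
        self.distances = distances
        self.production = _margins_to_array(production, cities)
        self.attraction = _margins_to_array(attraction, cities)
        _check_margins(self.production, self.attraction)
        self.observed = observed

    @classmethod
    def from_od(cls, od: ODMatrix, cities: CitySet,
                distances: DistanceTable | None = None) -> "GravityModel":
        """Build the model from an observed (preprocessed) matrix,
        taking both margins from it."""
        from .core import pairwise_distances
        if distances is None:
            distances = pairwise_distances(cities)
        return cls(cities, distances, od.row_sums, od.col_sums, observed=od)

    def _kernel(self, beta: float) -> np.ndarray:
        # IPF is invariant to row scalings of the kernel (absorbed into
        # A_i), so measure each row's distances from its nearest
        # neighbour; this keeps exp() from underflowing a whole row to
        # zero at strong deterrence.
        d = self.distances.matrix.astype(float).copy()
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        k = np.exp(-beta * (d - nearest[:, None]))
        np.fill_diagonal(k, 0.0)
        return k

    def generate(self, beta: float, period: str = "gravity",
                 tol: float = IPF_TOL, max_iter: int = IPF_MAX_ITER):
        if beta <= 0:
            raise ValueError(f"beta must be positive, got {beta}")
        T, a, b, it, err = _ipf(self._kernel(beta), self.production,
                                self.attraction, tol=tol, max_iter=max_iter)
        od = ODMatrix.from_dense(period, self.cities, T)
        return od, a, b, it, err

    def fit(self, beta: float | None = None, period: str = "gravity",
            tol: float = IPF_TOL, max_iter: int = IPF_MAX_ITER,
            bracket: tuple[float, float] = CALIBRATION_BRACKET,
            rel_tol: float = CALIBRATION_REL_TOL) -> GravityResults:
        """Fit the model; calibrate beta when it is not supplied.

        Calibration matches the generated flow-weighted mean trip
        distance to the observed one by bisection over ``bracket``.
        """
        n_evals = 0
        calibrated = False
        if beta is None:
            if self.observed is None:
                raise ValueError("calibration requires an observed OD matrix "
                                 "(construct with from_od or pass observed=)")
            beta, n_evals = self._calibrate_beta(bracket, rel_tol, tol, max_iter)
            calibrated = True
        od, a, b, it, err = self.generate(beta, period=period, tol=tol, max_iter=max_iter)
        return GravityResults(self, beta, a, b, od, it, err, calibrated, n_evals)

    def _calibrate_beta(self, bracket, rel_tol, tol, max_iter) -> tuple[float, int]:
        obs = self.observed
        pairs = [(o, d, v) for o, d, v in obs.pairs() if o != d]
        dists = {self.distances.distance(o, d) for o, d, _v in pairs}
        if len(dists) < 2:
            raise CalibrationError(
                "observed matrix has fewer than two distinct trip distances; "
                "mean distance carries no information about beta",
                bracket=bracket)
        target = _mean_trip_distance(obs, self.distances)
        n_evals = 0
        # probes need the mean only, not fully polished margins; a trial
        # beta whose IPF is too slow (or overflows) is treated as
        # over-strong deterrence and the bracket moves down
        probe_iter = min(max_iter, 3000)

        def mean_at(beta: float, budget: int) -> float:
            nonlocal n_evals
            n_evals += 1
            od, *_ = self.generate(beta, tol=tol, max_iter=budget)
            return _mean_trip_distance(od, self.distances)

        lo, hi = bracket
        m_lo = mean_at(lo, max_iter)            # mean is decreasing in beta
        if target > m_lo * (1.0 + rel_tol):
            raise CalibrationError(
                f"observed mean trip distance {target:.6g} km exceeds the "
                f"maximum {m_lo:.6g} km achievable at beta = {lo:g}",
                bracket=bracket, achievable=(None, m_lo))
        if abs(m_lo - target) <= rel_tol * target:
            return lo, n_evals
        last_mean = m_lo
        for _ in range(200):
            beta = 0.5 * (lo + hi)
            try:
                m = mean_at(beta, probe_iter)
            except (ConvergenceError, ValueError):
                hi = beta
                continue
            if abs(m - target) <= rel_tol * target:
                return beta, n_evals
            if m > target:
                lo = beta      # need stronger deterrence
            else:
                hi = beta
            if hi - lo < 1e-13:
                break
            if abs(m - last_mean) <= 1e-12 * max(target, 1.0) and abs(m - target) > rel_tol * target:
                # bracket moves but the mean does not: margins pin the flows
                raise CalibrationError(
                    "generated mean trip distance is insensitive to beta; "
                    "margins determine the flows",
                    bracket=bracket, achievable=(m, m_lo))
            last_mean = m
        raise CalibrationError(
            f"no beta in {bracket} reproduces the observed mean trip distance "
            f"{target:.6g} km within relative tolerance {rel_tol:g}",
            bracket=bracket, achievable=(last_mean, m_lo))


def _mean_trip_distance(od: ODMatrix, dist: DistanceTable) -> float:
    num = 0.0
    den = 0.0
    for o, d, v in od.pairs():
        if o == d:
            continue
        num += v * dist.distance(o, d)
        den += v
    if den == 0:
        raise ValueError("matrix has no off-diagonal flow")
    return num / den


class RadiationResults:
    """Generated radiation-model flows (the model has no free parameter)."""

    def __init__(self, model, od: ODMatrix):
        self.model = model
        self.od = od

    @property
    def mean_trip_distance(self) -> float:
        return _mean_trip_distance(self.od, self.model.distances)

    def signatures(self, threshold: float = DEFAULT_THRESHOLD) -> dict[str, MobilitySignature]:
        return model_signatures(self.od, threshold=threshold, cities=self.model.cities)

    def summary(self) -> str:
        return "\n".join([
            "Radiation model (finite-size corrected)",
            "=======================================",
            f"cities:                   {len(self.model.cities)}",
            f"total population M:       {self.model.cities.total_population}",
            f"total flow:               {self.od.total:.6g}",
            f"mean trip distance (km):  {self.mean_trip_distance:.6g}",
        ])


class RadiationModel:
    """Radiation model driven by populations and per-origin trip totals."""

    def __init__(self, cities: CitySet, distances: DistanceTable, outgoing_totals):
        self.cities = cities
        self.distances = distances
        self.outgoing_totals = _margins_to_array(outgoing_totals, cities)
        if (self.outgoing_totals < 0).any():
            raise ValueError("outgoing totals must be non-negative")

    @classmethod
    def from_od(cls, od: ODMatrix, cities: CitySet,
                distances: DistanceTable | None = None) -> "RadiationModel":
        from .core import pairwise_distances
        if distances is None:
            distances = pairwise_distances(cities)
        return cls(cities, distances, od.row_sums)

    def fit(self, period: str = "radiation") -> RadiationResults:
        return RadiationResults(self, self.generate(period=period))

    def generate(self, period: str = "radiation") -> ODMatrix:
        cities = self.cities
        ids = np.array(cities.ids)
        pop = cities.populations
        M = float(cities.total_population)
        n = len(cities)
        T = np.zeros((n, n))
        for i in range(n):
            Ti = self.outgoing_totals[i]
            if Ti == 0:
                continue
            mi = pop[i]
            if mi >= M:
                raise ModelError(
                    f"radiation model undefined: city {ids[i]!r} holds the entire "
                    "population (m_i = M)")
            drow = self.distances.matrix[i]
            others = np.delete(np.arange(n), i)
            # total order by (distance, id) makes s_ij unambiguous at ties
            order = others[np.lexsort((ids[others], drow[others]))]
            m_sorted = pop[order]
            s = np.concatenate(([0.0], np.cumsum(m_sorted)[:-1]))
            flows = (Ti / (1.0 - mi / M)
                     * mi * m_sorted / ((mi + s) * (mi + m_sorted + s)))
            T[i, order] = flows
        return ODMatrix.from_dense(period, cities, T)


# ---------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------

def gravity_generate(cities: CitySet, dist: DistanceTable,
                     margins: tuple, beta: float, *,
                     period: str = "gravity",
                     tol: float = IPF_TOL, max_iter: int = IPF_MAX_ITER) -> ODMatrix:
    """Generate doubly-constrained gravity flows for fixed beta.

    ``margins`` is the pair (production n_i+, attraction n_+j); each may
    be a mapping id -> value or a sequence in city-set order.
    """
    production, attraction = margins
    model = GravityModel(cities, dist, production, attraction)
    od, *_ = model.generate(beta, period=period, tol=tol, max_iter=max_iter)
    return od


def gravity_calibrate(od_observed: ODMatrix, cities: CitySet,
                      dist: DistanceTable, **fit_kwargs) -> GravityResults:
    """Calibrate beta against an observed matrix and return the fit."""
    model = GravityModel(cities, dist, od_observed.row_sums,
                         od_observed.col_sums, observed=od_observed)
    return model.fit(beta=None, **fit_kwargs)


def radiation_generate(cities: CitySet, dist: DistanceTable,
                       outgoing_totals, *, period: str = "radiation") -> ODMatrix:
    """Generate radiation-model flows conserving each origin's total."""
    return RadiationModel(cities, dist, outgoing_totals).generate(period=period)


def model_signatures(od_model: ODMatrix, threshold: float = DEFAULT_THRESHOLD,
                     cities: CitySet | None = None) -> dict[str, MobilitySignature]:
    """Censor model flows like the empirical data, then build signatures.

    Model flows are real-valued; the same strict below-threshold removal
    used for empirical matrices is applied before normalizing.
    """
    censored = preprocess(od_model, threshold=threshold)
    return all_signatures(censored, cities)
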