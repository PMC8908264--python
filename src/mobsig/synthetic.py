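"""Synthetic country generator.

The operator-provided OD data the method was designed for (aggregated
mobile-phone trip counts between municipalities) is proprietary, so
this module fabricates structurally similar inputs: a Finland-like
rectangle of cities with heavy-tailed populations, flows drawn from a
gravity or radiation kernel with optional Poisson count noise, privacy
censoring of small flows, and a "lockdown" perturbation that suppresses
long-distance trips.

All randomness flows from a single integer seed through numpy's PCG64
generator (128-bit state); a fixed seed reproduces every output
byte-stably across platforms.  Independent streams for the city system,
the count noise and the perturbation are derived from the seed with
fixed stream tags, so e.g. regenerating the OD does not disturb the
city layout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .core import (City, CitySet, DistanceTable, ODMatrix,
                   pairwise_distances, preprocess)
from .models import gravity_generate, radiation_generate

#: km per degree of latitude (and of longitude at the equator)
_KM_PER_DEG = 111.32

# southern edge and central meridian of the default synthetic country
_LAT0 = 59.8
_LON0 = 26.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic country and its flows.

    Defaults mirror the reference setting: 310 cities on a 1000 x 600 km
    rectangle, log-normal populations, 3.4 million daily trips, and a
    20-trip privacy threshold (applied only when requested).
    """

    seed: int
    n_cities: int = 310
    extent_ns_km: float = 1000.0
    extent_ew_km: float = 600.0
    layout: str = "uniform"            # "uniform" | "clustered"
    population_law: str = "lognormal"  # "lognormal" | "zipf"
    pop_mu: float = 9.0
    pop_sigma: float = 1.2
    zipf_exponent: float = 2.0
    kernel: str = "gravity"            # "gravity" | "radiation"
    beta: float = 0.03                 # 1/km, gravity deterrence rate
    total_trips: float = 3_400_000.0   # daily trips country-wide
    noise: str = "none"                # "none" | "poisson"
    threshold: float | None = None     # censoring applied after generation
    phi: float = 0.5                   # long-distance suppression factor
    d_knee_km: float = 100.0           # distance above which phi applies

    def __post_init__(self) -> None:
        if self.n_cities < 2:
            raise ValueError("n_cities must be at least 2")
        if self.layout not in ("uniform", "clustered"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.population_law not in ("lognormal", "zipf"):
            raise ValueError(f"unknown population law {self.population_law!r}")
        if self.population_law == "lognormal" and self.pop_sigma <= 0:
            raise ValueError("pop_sigma must be positive")
        if self.population_law == "zipf" and self.zipf_exponent <= 1:
            raise ValueError("zipf_exponent must exceed 1")
        if self.kernel not in ("gravity", "radiation"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.total_trips <= 0:
            raise ValueError("total_trips must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")

    # -- plain-text config round-trip ----------------------------------
    def to_config(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items() if v is not None]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path) -> "SyntheticSpec":
        fields = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
        if "seed" not in fields:
            raise ValueError(f"{path}: synthetic config must state a seed")
        typed = {}
        for key, value in fields.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}: unknown key {key!r}")
            if key in ("seed", "n_cities"):
                typed[key] = int(value)
            elif key in ("layout", "population_law", "kernel", "noise"):
                typed[key] = value
            elif key == "threshold":
                typed[key] = None if value.lower() == "none" else float(value)
            else:
                typed[key] = float(value)
        return cls(**typed)


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # fixed stream tags keep the city system, count noise and
    # perturbation independent but all reproducible from one seed
    return np.random.default_rng([int(spec.seed), stream])


def generate_city_system(spec: SyntheticSpec) -> tuple[CitySet, DistanceTable]:
    """Reproducible city coordinates and heavy-tailed populations,
    together with the pairwise distance table."""
    cities = generate_cities(spec)
    return cities, pairwise_distances(cities)


def generate_cities(spec: SyntheticSpec) -> CitySet:
    """The city set alone (no O(n^2) distance table)."""
    rng = _rng(spec, 1)
    ns, ew = spec.extent_ns_km, spec.extent_ew_km
    if spec.layout == "uniform":
        y = rng.uniform(0.0, ns, spec.n_cities)
        x = rng.uniform(0.0, ew, spec.n_cities)
    else:
        n_clusters = max(2, spec.n_cities // 60)
        cy = rng.uniform(0.0, ns, n_clusters)
        cx = rng.uniform(0.0, ew, n_clusters)
        member = rng.integers(0, n_clusters, spec.n_cities)
        y = np.clip(cy[member] + rng.normal(0.0, 50.0, spec.n_cities), 0.0, ns)
        x = np.clip(cx[member] + rng.normal(0.0, 50.0, spec.n_cities), 0.0, ew)

    if spec.population_law == "lognormal":
        pops = rng.lognormal(spec.pop_mu, spec.pop_sigma, spec.n_cities)
    else:
        pops = rng.zipf(spec.zipf_exponent, spec.n_cities).astype(float)
    pops = np.maximum(1, np.rint(pops)).astype(int)

    lat_mid = _LAT0 + 0.5 * ns / _KM_PER_DEG
    km_per_deg_lon = _KM_PER_DEG * np.cos(np.radians(lat_mid))
    width = int(len(str(spec.n_cities)))
    cities = CitySet(
        City(
            id=f"C{idx:0{width}d}",
            name=f"city-{idx}",
            lat=_LAT0 + float(y[idx]) / _KM_PER_DEG,
            lon=_LON0 + (float(x[idx]) - ew / 2.0) / km_per_deg_lon,
            population=int(pops[idx]),
        )
        for idx in range(spec.n_cities)
    )
    return cities


def generate_od(spec: SyntheticSpec, cities: CitySet, dist: DistanceTable,
                period: str = "baseline") -> ODMatrix:
    """Flows from the configured kernel, noised and censored per spec.

    Production and attraction margins are proportional to city
    population and sum to ``total_trips`` (the radiation kernel uses the
    production margin as each origin's T_i).
    """
    pop = cities.populations
    margins = spec.total_trips * pop / pop.sum()
    if spec.kernel == "gravity":
        od = gravity_generate(cities, dist, (margins, margins), spec.beta,
                              period=period)
    else:
        od = radiation_generate(cities, dist, margins, period=period)
    if spec.noise == "poisson":
        dense = od.to_dense(cities)
        dense = _rng(spec, 2).poisson(dense).astype(float)
        od = ODMatrix.from_dense(period, cities, dense)
    if spec.threshold is not None:
        od = preprocess(od, threshold=spec.threshold)
    return od


def perturb_lockdown(od: ODMatrix, dist: DistanceTable, phi: float,
                     d_knee_km: float, rng: np.random.Generator | None = None,
                     period: str | None = None) -> ODMatrix:
    """Suppress long-distance flows by a factor phi.

    Flows over distances strictly greater than ``d_knee_km`` are scaled
    by phi; flows at or below the knee are untouched.  With ``rng``
    given, the scaled flows are re-drawn as Poisson counts (so a
    perturbed integer matrix stays integer); phi = 1 is always the
    identity.
    """
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must lie in [0, 1]")
    if period is None:
        period = f"{od.period}-lockdown"
    if phi == 1.0:
        return ODMatrix(period, dict(((o, d), v) for o, d, v in od.pairs()))
    flows: dict[tuple[str, str], float] = {}
    for o, d, v in sorted(od.pairs()):   # sorted: rng draws are order-stable
        if o != d and dist.distance(o, d) > d_knee_km:
            v = v * phi
            if rng is not None:
                v = float(rng.poisson(v))
        flows[(o, d)] = v
    return ODMatrix(period, flows)


def generate_dataset(spec: SyntheticSpec):
    """Convenience: city system plus baseline and lockdown matrices.

    The lockdown matrix is the baseline perturbed with the spec's phi
    and distance knee (re-drawn as Poisson counts when the spec's noise
    model is "poisson"), then censored with the spec's threshold.
    Returns ``(cities, dist, od_baseline, od_lockdown)``.
    """
    cities, dist = generate_city_system(spec)
    base_spec = replace(spec, threshold=None)
    od_base = generate_od(base_spec, cities, dist, period="baseline")
    rng = _rng(spec, 3) if spec.noise == "poisson" else None
    od_lock = perturb_lockdown(od_base, dist, spec.phi, spec.d_knee_km,
                               rng=rng, period="lockdown")
    if spec.threshold is not None:
        od_base = preprocess(od_base, threshold=spec.threshold)
        od_lock = preprocess(od_lock, threshold=spec.threshold)
    return cities, dist, od_base, od_lock
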