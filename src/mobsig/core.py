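"""Domain types and I/O for origin-destination (OD) mobility data.

The analysis operates on three objects: a :class:`CitySet` of region
nodes (centroid coordinates and resident population), an
:class:`ODMatrix` of directed trip counts per observation period, and a
:class:`DistanceTable` of great-circle centroid distances.  Raw OD
tables are preprocessed by discarding within-city flows (the diagonal)
and censoring flows below a privacy threshold (20 trips in typical
operator feeds) before any signature is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError

#: Mean Earth radius in kilometres (IUGG).
EARTH_RADIUS_KM = 6371.0088

#: Default privacy-censoring threshold: flows strictly below this many
#: trips are removed during preprocessing.
DEFAULT_THRESHOLD = 20


@dataclass(frozen=True)
class City:
    """A region node: identifier, display name, centroid, population.

    The population is the mass term of the flow models (residents of
    the city, used as the number of opportunities it offers).
    """

    id: str
    name: str
    lat: float
    lon: float
    population: int

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise FormatError(f"city {self.id!r}: latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise FormatError(f"city {self.id!r}: longitude {self.lon} outside [-180, 180]")
        if self.population < 1:
            raise FormatError(f"city {self.id!r}: population must be >= 1, got {self.population}")


class CitySet:
    """An ordered collection of cities with unique identifiers."""

    def __init__(self, cities: Iterable[City]):
        self._cities: list[City] = list(cities)
        self._index: dict[str, int] = {}
        for pos, c in enumerate(self._cities):
            if c.id in self._index:
                raise FormatError(f"duplicate city id {c.id!r}")
            self._index[c.id] = pos
        self.total_population: int = sum(c.population for c in self._cities)

    def __len__(self) -> int:
        return len(self._cities)

    def __iter__(self) -> Iterator[City]:
        return iter(self._cities)

    def __contains__(self, city_id: str) -> bool:
        return city_id in self._index

    def __getitem__(self, city_id: str) -> City:
        return self._cities[self._index[city_id]]

    def index(self, city_id: str) -> int:
        """Position of a city in the set's fixed ordering."""
        return self._index[city_id]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._cities]

    @property
    def populations(self) -> np.ndarray:
        """Populations as a float array in set order."""
        return np.array([c.population for c in self._cities], dtype=float)


class ODMatrix:
    """Directed trip counts between cities for one observation period.

    Flows are stored sparsely: an absent (origin, destination) pair
    means zero flow.  Margins (row sums ``n_i+`` = total outgoing, and
    column sums ``n_+j`` = total incoming) are recomputed from the
    stored flows on demand, so they always agree with a brute-force sum.
    """

    def __init__(self, period: str, flows: Mapping[tuple[str, str], float]):
        self.period = period
        self._flows: dict[tuple[str, str], float] = {}
        for (o, d), v in flows.items():
            v = float(v)
            if v < 0:
                raise FormatError(f"negative flow {v} for pair ({o!r}, {d!r})")
            if v > 0:
                self._flows[(o, d)] = v
        self._by_origin: dict[str, dict[str, float]] | None = None

    # -- accessors ----------------------------------------------------
    def flow(self, origin: str, destination: str) -> float:
        return self._flows.get((origin, destination), 0.0)

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for (o, d), v in self._flows.items():
            yield o, d, v

    def _origin_index(self) -> dict[str, dict[str, float]]:
        # flows are immutable after construction, so build once
        if self._by_origin is None:
            by_origin: dict[str, dict[str, float]] = {}
            for (o, d), v in self._flows.items():
                by_origin.setdefault(o, {})[d] = v
            self._by_origin = by_origin
        return self._by_origin

    def outgoing(self, origin: str) -> dict[str, float]:
        """Destination -> flow mapping for one origin."""
        return dict(self._origin_index().get(origin, {}))

    def total_outgoing(self, origin: str) -> float:
        return sum(self._origin_index().get(origin, {}).values())

    @property
    def row_sums(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (o, _d), v in self._flows.items():
            out[o] = out.get(o, 0.0) + v
        return out

    @property
    def col_sums(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (_o, d), v in self._flows.items():
            out[d] = out.get(d, 0.0) + v
        return out

    @property
    def total(self) -> float:
        return sum(self._flows.values())

    @property
    def n_flows(self) -> int:
        return len(self._flows)

    def origins(self) -> set[str]:
        return {o for (o, _d) in self._flows}

    def city_ids(self) -> set[str]:
        """All ids appearing as origin or destination."""
        ids: set[str] = set()
        for o, d in self._flows:
            ids.add(o)
            ids.add(d)
        return ids

    # -- dense interop ------------------------------------------------
    def to_dense(self, cities: CitySet) -> np.ndarray:
        """Flows as an (n, n) array in the city set's order.

        Raises ``KeyError`` if the matrix references an unknown city.
        """
        n = len(cities)
        mat = np.zeros((n, n))
        for (o, d), v in self._flows.items():
            mat[cities.index(o), cities.index(d)] = v
        return mat

    @classmethod
    def from_dense(cls, period: str, cities: CitySet, mat: np.ndarray) -> "ODMatrix":
        ids = cities.ids
        flows = {
            (ids[i], ids[j]): mat[i, j]
            for i, j in zip(*np.nonzero(mat))
        }
        return cls(period, flows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ODMatrix):
            return NotImplemented
        return self.period == other.period and self._flows == other._flows

    def __repr__(self) -> str:
        return f"ODMatrix(period={self.period!r}, n_flows={self.n_flows}, total={self.total:g})"


class DistanceTable:
    """Symmetric great-circle distances (km) between city centroids."""

    def __init__(self, cities: CitySet, matrix: np.ndarray):
        n = len(cities)
        if matrix.shape != (n, n):
            raise ValueError(f"distance matrix shape {matrix.shape} does not match {n} cities")
        self._cities = cities
        self.matrix = matrix

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self._cities.index(a), self._cities.index(b)])

    def __call__(self, a: str, b: str) -> float:
        return self.distance(a, b)

    @property
    def ids(self) -> list[str]:
        return self._cities.ids

    def index(self, city_id: str) -> int:
        return self._cities.index(city_id)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float,
                 radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two points in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(a)))


def pairwise_distances(cities: CitySet) -> DistanceTable:
    """Great-circle (haversine) distances between every pair of centroids."""
    lat = np.radians([c.lat for c in cities])
    lon = np.radians([c.lon for c in cities])
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2.0) ** 2
    mat = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(mat, 0.0)
    return DistanceTable(cities, mat)


def preprocess(od: ODMatrix, threshold: float = DEFAULT_THRESHOLD) -> ODMatrix:
    """Remove within-city flows and censor flows below a threshold.

    Diagonal entries (origin == destination) are set to zero and every
    flow strictly smaller than ``threshold`` is dropped; a flow exactly
    equal to the threshold survives.  Margins of the returned matrix are
    recomputed from the surviving flows.  Idempotent.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    kept = {
        (o, d): v
        for (o, d), v in od._flows.items()
        if o != d and v >= threshold
    }
    return ODMatrix(od.period, kept)


# ---------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------

CITY_COLUMNS = ["id", "name", "lat", "lon", "population"]
FLOW_COLUMNS = ["origin", "destination", "period", "trips"]


def read_cities(path, sep: str = ",") -> CitySet:
    """Read a city table (columns id, name, lat, lon, population)."""
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "name": str})
    missing = [c for c in CITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    cities = []
    for row in df.itertuples(index=True):
        try:
            pop_f = float(row.population)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-numeric population {row.population!r} in row {row.Index}"
            ) from None
        if not pop_f.is_integer():
            raise FormatError(
                f"{path}: population {row.population!r} in row {row.Index} is not an integer"
            )
        cities.append(
            City(id=str(row.id), name=str(row.name), lat=float(row.lat),
                 lon=float(row.lon), population=int(pop_f))
        )
    return CitySet(cities)


def write_cities(cities: CitySet, path, sep: str = ",") -> None:
    df = pd.DataFrame(
        [(c.id, c.name, c.lat, c.lon, c.population) for c in cities],
        columns=CITY_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_flows(path, cities: CitySet | None = None, sep: str = ",") -> list[ODMatrix]:
    """Read a long-format flow table into one ODMatrix per period.

    Rows sharing (origin, destination, period) are summed.  If a
    ``CitySet`` is supplied, references to unknown cities are rejected.
    Matrices are returned sorted by period label.
    """
    df = pd.read_csv(path, sep=sep, dtype={"origin": str, "destination": str, "period": str})
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    trips = pd.to_numeric(df["trips"], errors="coerce")
    if trips.isna().any():
        bad = int(trips.isna().idxmax())
        raise FormatError(f"{path}: non-numeric trips value in row {bad}")
    if (trips < 0).any():
        bad = int((trips < 0).idxmax())
        raise FormatError(f"{path}: negative trips value in row {bad}")
    if cities is not None:
        known = set(cities.ids)
        unknown = (set(df["origin"]) | set(df["destination"])) - known
        if unknown:
            raise FormatError(f"{path}: unknown city id(s) {sorted(unknown)[:5]}")
    df = df.assign(trips=trips)
    grouped = df.groupby(["period", "origin", "destination"], sort=True)["trips"].sum()
    matrices = []
    for period, sub in grouped.groupby(level="period", sort=True):
        flows = {(o, d): v for (_p, o, d), v in sub.items()}
        matrices.append(ODMatrix(str(period), flows))
    return matrices


def write_flows(matrices: Iterable[ODMatrix], path, sep: str = ",") -> None:
    """Write matrices in the long flow format, byte-stably ordered."""
    rows = []
    for od in matrices:
        for o, d, v in sorted(od.pairs()):
            rows.append((o, d, od.period, v))
    rows.sort(key=lambda r: (r[2], r[0], r[1]))
    df = pd.DataFrame(rows, columns=FLOW_COLUMNS)
    # keep integer counts integer-looking
    if (df["trips"] % 1 == 0).all():
        df["trips"] = df["trips"].astype("int64")
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")
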