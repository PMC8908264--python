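"""Mobility signatures and their Jensen-Shannon divergence.

A city's *mobility signature* is the vector of its outgoing-flow
fractions T_ij / T_i, sorted from the most to the least visited
destination.  It plays the role of an egocentric "social signature" for
a city embedded in the country-wide mobility network: a steep signature
means a few dominant destinations, a flat one a uniform spread.

Signatures are compared with the Jensen-Shannon divergence,

    JSD(p, q) = H((p + q) / 2) - (H(p) + H(q)) / 2,

with Shannon entropies H in bits (base-2 logarithm), so JSD lies in
[0, 1].  Signatures of different lengths are compared as rank
distributions: the shorter fraction vector is zero-padded to the length
of the longer one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CitySet, ODMatrix
from .exceptions import FormatError

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MobilitySignature:
    """Rank-ordered outgoing-flow distribution of one city.

    ``fractions[r]`` is the share of the city's outgoing trips going to
    ``destinations[r]``; fractions are positive, non-increasing in rank
    and sum to one.  An empty signature (length 0) represents a city
    with no outgoing flows.
    """

    city_id: str
    destinations: tuple[str, ...]
    fractions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        if len(fr) != len(self.destinations):
            raise ValueError("destinations and fractions must have equal length")
        if len(fr) == 0:
            return
        if np.any(fr <= 0):
            raise ValueError("signature fractions must be strictly positive")
        if np.any(np.diff(fr) > 0):
            raise ValueError("signature fractions must be non-increasing in rank")
        if abs(fr.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"signature fractions sum to {fr.sum()!r}, not 1")

    def __len__(self) -> int:
        return len(self.destinations)

    @property
    def length(self) -> int:
        """Number of destinations k_i."""
        return len(self.destinations)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.destinations, self.fractions))


def compute_signature(od: ODMatrix, city_id: str,
                      cities: CitySet | None = None) -> MobilitySignature:
    """Signature of one city from a (preprocessed) OD matrix.

    Destinations are sorted by descending flow; ties are broken by
    ascending destination id.  A city with no outgoing flows yields an
    empty signature.  If ``cities`` is given, an id outside the set
    raises ``KeyError``; otherwise an id absent from the matrix
    entirely (as origin or destination) raises ``KeyError``.
    """
    if cities is not None:
        if city_id not in cities:
            raise KeyError(f"unknown city id {city_id!r}")
    elif city_id not in od.city_ids():
        raise KeyError(f"city id {city_id!r} not present in OD matrix")
    out = od.outgoing(city_id)
    if not out:
        return MobilitySignature(city_id, ())
    total = sum(out.values())
    ranked = sorted(out.items(), key=lambda kv: (-kv[1], kv[0]))
    dests = tuple(d for d, _v in ranked)
    fractions = np.array([v for _d, v in ranked]) / total
    return MobilitySignature(city_id, dests, fractions)


def signature_length(sig: MobilitySignature) -> int:
    """Number of destinations k_i in a signature."""
    return sig.length


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0 * log 0 := 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _padded(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    pa = np.asarray(a, dtype=float)
    pb = np.asarray(b, dtype=float)
    k = max(len(pa), len(pb))
    return (np.pad(pa, (0, k - len(pa))), np.pad(pb, (0, k - len(pb))))


def jsd_vectors(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon divergence (base 2) of two probability vectors.

    Vectors of unequal length are zero-padded to the common length.
    The result is clipped to [0, 1] against floating-point round-off.
    """
    pa, pb = _padded(p, q)
    if len(pa) == 0 or (pa.sum() == 0 and pb.sum() == 0):
        raise ValueError("JSD undefined for two empty distributions")
    m = 0.5 * (pa + pb)
    val = _entropy_bits(m) - 0.5 * (_entropy_bits(pa) + _entropy_bits(pb))
    return float(min(1.0, max(0.0, val)))


def jsd(sig_a: MobilitySignature, sig_b: MobilitySignature) -> float:
    """JSD between two signatures, compared as rank distributions.

    The fraction vectors are aligned by rank (not destination identity)
    and the shorter is zero-padded; 0 means identical rank profiles,
    1 maximal dissimilarity.  Raises ``ValueError`` if both signatures
    are empty.
    """
    if sig_a.length == 0 and sig_b.length == 0:
        raise ValueError("JSD undefined: both signatures are empty")
    return jsd_vectors(sig_a.fractions, sig_b.fractions)


def all_signatures(od: ODMatrix, cities: CitySet | None = None) -> dict[str, MobilitySignature]:
    """Signatures for every city (of ``cities`` if given, else every
    origin appearing in the matrix)."""
    ids = cities.ids if cities is not None else sorted(od.origins())
    return {cid: compute_signature(od, cid, cities) for cid in ids}


# ---------------------------------------------------------------------
# delimited-text round-trip
# ---------------------------------------------------------------------

SIGNATURE_COLUMNS = ["city_id", "rank", "destination", "fraction"]


def write_signatures(signatures: Mapping[str, MobilitySignature], path, sep: str = ",") -> None:
    rows = []
    for cid in sorted(signatures):
        sig = signatures[cid]
        for rank, (dest, frac) in enumerate(zip(sig.destinations, sig.fractions), start=1):
            rows.append((cid, rank, dest, repr(float(frac))))
    df = pd.DataFrame(rows, columns=SIGNATURE_COLUMNS)
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_signatures(path, sep: str = ",") -> dict[str, MobilitySignature]:
    df = pd.read_csv(path, sep=sep, dtype={"city_id": str, "destination": str},
                     float_precision="round_trip")
    missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out: dict[str, MobilitySignature] = {}
    for cid, sub in df.groupby("city_id", sort=True):
        sub = sub.sort_values("rank")
        out[str(cid)] = MobilitySignature(
            str(cid),
            tuple(sub["destination"]),
            sub["fraction"].to_numpy(dtype=float),
        )
    return out
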