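"""Empirical-versus-model signature comparison.

For each city the Jensen-Shannon divergence between its empirical
signature and the signature generated by each mobility model (gravity,
radiation) is computed; the model with the smaller divergence is the
better description of that city's outgoing-flow profile.  Summaries
report mean divergences, the share of cities per better-model group,
and the population make-up of the groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import CitySet, DistanceTable, ODMatrix, pairwise_distances, DEFAULT_THRESHOLD
from .exceptions import CalibrationError
from .models import GravityResults, gravity_calibrate, model_signatures, radiation_generate
from .signatures import MobilitySignature, all_signatures, jsd

GRAVITY = "gravity"
RADIATION = "radiation"
TIE = "tie"


@dataclass(frozen=True)
class ComparisonRecord:
    """Per-city model comparison.

    A ``None`` divergence means that model produced no surviving flows
    for the city after censoring (the ``*_empty`` flag is then set);
    such cities are excluded from that model's mean and from the share
    denominators.
    """

    city_id: str
    population: int
    jsd_gravity: float | None
    jsd_radiation: float | None
    better_model: str | None

    @property
    def gravity_empty(self) -> bool:
        return self.jsd_gravity is None

    @property
    def radiation_empty(self) -> bool:
        return self.jsd_radiation is None


def compare_city(sig_emp: MobilitySignature,
                 sig_grav: MobilitySignature | None,
                 sig_rad: MobilitySignature | None,
                 population: int = 0) -> ComparisonRecord:
    """Compare one city's empirical signature with both model signatures.

    The empirical signature must be non-empty.  An empty (or missing)
    model signature yields a ``None`` divergence for that model; the
    better-model label is the argmin over the divergences that exist,
    ``"tie"`` on exact equality, ``None`` when both models are empty.
    """
    if sig_emp.length == 0:
        raise ValueError(f"empirical signature for {sig_emp.city_id!r} is empty")

    def _jsd_or_none(sig_model):
        if sig_model is None or sig_model.length == 0:
            return None
        return jsd(sig_emp, sig_model)

    jg = _jsd_or_none(sig_grav)
    jr = _jsd_or_none(sig_rad)
    if jg is None and jr is None:
        better = None
    elif jg is None:
        better = RADIATION
    elif jr is None:
        better = GRAVITY
    elif jg < jr:
        better = GRAVITY
    elif jr < jg:
        better = RADIATION
    else:
        better = TIE
    return ComparisonRecord(sig_emp.city_id, population, jg, jr, better)


@dataclass
class ComparisonSummary:
    """Aggregate of per-city comparison records."""

    n_cities: int
    n_complete: int                 # records where both models produced flows
    mean_jsd_gravity: float | None  # over records with a gravity JSD
    mean_jsd_radiation: float | None
    share_gravity: float | None     # of complete records
    share_radiation: float | None
    share_tie: float | None
    mean_jsd_gravity_in_gravity_group: float | None
    mean_jsd_radiation_in_radiation_group: float | None
    n_gravity_empty: int
    n_radiation_empty: int
    populations_by_group: dict[str, list[int]]

    def as_text(self) -> str:
        def fmt(x, pct=False):
            if x is None:
                return "n/a"
            return f"{100 * x:.1f}%" if pct else f"{x:.4f}"
        return "\n".join([
            "Model comparison summary",
            "========================",
            f"cities compared:              {self.n_cities}",
            f"complete (both models):       {self.n_complete}",
            f"mean JSD gravity:             {fmt(self.mean_jsd_gravity)}",
            f"mean JSD radiation:           {fmt(self.mean_jsd_radiation)}",
            f"gravity better:               {fmt(self.share_gravity, pct=True)}",
            f"radiation better:             {fmt(self.share_radiation, pct=True)}",
            f"ties:                         {fmt(self.share_tie, pct=True)}",
            f"mean JSD gravity | gravity-better:     {fmt(self.mean_jsd_gravity_in_gravity_group)}",
            f"mean JSD radiation | radiation-better: {fmt(self.mean_jsd_radiation_in_radiation_group)}",
            f"cities with empty gravity signature:   {self.n_gravity_empty}",
            f"cities with empty radiation signature: {self.n_radiation_empty}",
        ])


def _mean(values: Sequence[float]) -> float | None:
    vals = list(values)
    return sum(vals) / len(vals) if vals else None


def summarize(records: Iterable[ComparisonRecord]) -> ComparisonSummary:
    """Aggregate comparison records into means, shares and group
    population lists (for population-vs-model plots)."""
    records = list(records)
    if not records:
        raise ValueError("no comparison records to summarize")
    with_g = [r for r in records if r.jsd_gravity is not None]
    with_r = [r for r in records if r.jsd_radiation is not None]
    complete = [r for r in records if r.jsd_gravity is not None and r.jsd_radiation is not None]
    n_complete = len(complete)
    grav_group = [r for r in complete if r.better_model == GRAVITY]
    rad_group = [r for r in complete if r.better_model == RADIATION]
    tie_group = [r for r in complete if r.better_model == TIE]
    pops = {
        GRAVITY: [r.population for r in grav_group],
        RADIATION: [r.population for r in rad_group],
        TIE: [r.population for r in tie_group],
    }
    return ComparisonSummary(
        n_cities=len(records),
        n_complete=n_complete,
        mean_jsd_gravity=_mean([r.jsd_gravity for r in with_g]),
        mean_jsd_radiation=_mean([r.jsd_radiation for r in with_r]),
        share_gravity=len(grav_group) / n_complete if n_complete else None,
        share_radiation=len(rad_group) / n_complete if n_complete else None,
        share_tie=len(tie_group) / n_complete if n_complete else None,
        mean_jsd_gravity_in_gravity_group=_mean([r.jsd_gravity for r in grav_group]),
        mean_jsd_radiation_in_radiation_group=_mean([r.jsd_radiation for r in rad_group]),
        n_gravity_empty=len(records) - len(with_g),
        n_radiation_empty=len(records) - len(with_r),
        populations_by_group=pops,
    )


def compare_models(od_emp: ODMatrix, cities: CitySet,
                   dist: DistanceTable | None = None,
                   threshold: float = DEFAULT_THRESHOLD,
                   beta: float | None = None):
    """End-to-end comparison pipeline for one empirical period.

    Fits the gravity model (calibrating beta unless supplied) and the
    radiation model from the empirical matrix's margins, censors both
    model matrices with the same threshold as the data, and compares
    signatures city by city.

    Returns ``(records, summary, gravity_results, radiation_od)``;
    ``gravity_results`` is ``None`` if calibration failed (the
    comparison then proceeds with radiation alone).
    """
    if dist is None:
        dist = pairwise_distances(cities)
    gravity_results: GravityResults | None = None
    sigs_grav: dict[str, MobilitySignature] = {}
    try:
        if beta is None:
            gravity_results = gravity_calibrate(od_emp, cities, dist)
        else:
            from .models import GravityModel
            model = GravityModel(cities, dist, od_emp.row_sums, od_emp.col_sums, observed=od_emp)
            gravity_results = model.fit(beta=beta)
        sigs_grav = model_signatures(gravity_results.od, threshold=threshold, cities=cities)
    except CalibrationError:
        gravity_results = None

    od_rad = radiation_generate(cities, dist, od_emp.row_sums)
    sigs_rad = model_signatures(od_rad, threshold=threshold, cities=cities)
    sigs_emp = all_signatures(od_emp, cities)

    records = []
    for cid in cities.ids:
        sig_emp = sigs_emp[cid]
        if sig_emp.length == 0:
            continue
        records.append(compare_city(
            sig_emp, sigs_grav.get(cid), sigs_rad.get(cid),
            population=cities[cid].population))
    return records, summarize(records), gravity_results, od_rad


# ---------------------------------------------------------------------
# delimited-text output
# ---------------------------------------------------------------------

RECORD_COLUMNS = ["city_id", "population", "jsd_gravity", "jsd_radiation", "better_model"]


def write_records(records: Iterable[ComparisonRecord], path, sep: str = ",") -> None:
    df = pd.DataFrame(
        [(r.city_id, r.population,
          "" if r.jsd_gravity is None else repr(r.jsd_gravity),
          "" if r.jsd_radiation is None else repr(r.jsd_radiation),
          r.better_model or "") for r in records],
        columns=RECORD_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_records(path, sep: str = ",") -> list[ComparisonRecord]:
    df = pd.read_csv(path, sep=sep, dtype={"city_id": str, "better_model": str})
    out = []
    for row in df.itertuples(index=False):
        jg = None if pd.isna(row.jsd_gravity) else float(row.jsd_gravity)
        jr = None if pd.isna(row.jsd_radiation) else float(row.jsd_radiation)
        better = None if (not isinstance(row.better_model, str) or not row.better_model) else row.better_model
        out.append(ComparisonRecord(str(row.city_id), int(row.population), jg, jr, better))
    return out
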