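"""Reading, validation and writing of nest and insect-trap tables.

Three delimited-text (CSV) schemas are used throughout:

``nests.csv``
    Long format, one row per nest per *observed* day:
    ``nest_id, pair_id, year, renest, day, code``.
    ``code`` is 1 (nest observed alive), 0 (observed failed) or the literal
    ``NA`` / empty (checked but state not determined).  Days on which a nest
    was not checked may simply be absent.  ``day`` is an integer day-of-season
    (1-based, per calendar year); converting calendar dates to day indices is
    the caller's responsibility.

``nest_coords.csv``
    ``nest_id, x, y`` with planar coordinates in the same projected units as
    the trap coordinates.

``traps.csv``
    ``trap_id, x, y, year, day, taxon, count, active``.  ``active`` is 1 when
    the trap was operating that day; ``count`` must be present exactly when
    ``active`` is 1.  Days with no row for a trap are treated the same as
    ``active = 0`` rows.

Nests incubated full term without hatching are encoded by the data preparer
as failed on incubation day 30; the reader performs no such inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "EncounterHistory",
    "TrapCountTable",
    "NestSite",
    "read_encounter_histories",
    "write_encounter_histories",
    "read_trap_counts",
    "write_trap_counts",
    "read_nest_sites",
    "write_nest_sites",
    "fill_known_zeros",
]


class ValidationError(ValueError):
    """Raised when an input table violates the documented schema."""


MISSING_CODES = {"na", "nan", ""}


@dataclass
class EncounterHistory:
    """Daily encounter record for one nest.

    ``days`` are strictly increasing integer days-of-season; ``codes`` holds
    1.0 (alive), 0.0 (failed) or NaN (not determined) aligned with ``days``.
    The first coded day is the detection day and must be alive; at most one
    failure is allowed and nothing may be observed alive after it.
    """

    nest_id: str
    pair_id: str
    year: int
    renest: int
    days: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.codes = np.asarray(self.codes, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.nest_id
        if self.renest not in (0, 1):
            raise ValidationError(f"nest {n}: renest must be 0 or 1, got {self.renest}")
        if len(self.days) != len(self.codes) or len(self.days) == 0:
            raise ValidationError(f"nest {n}: empty or misaligned day/code vectors")
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError(f"nest {n}: day indices must be strictly increasing")
        if self.days[0] < 1:
            raise ValidationError(f"nest {n}: day indices are 1-based")
        obs = self.codes[~np.isnan(self.codes)]
        if not np.isin(obs, (0.0, 1.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0))][0]
            raise ValidationError(f"nest {n}: encounter code {bad!r} not in {{0, 1, NA}}")
        first = self.codes[~np.isnan(self.codes)]
        if first.size == 0 or np.isnan(self.codes[0]) or self.codes[0] != 1.0:
            raise ValidationError(f"nest {n}: first coded day must be an alive (1) record")
        dead = np.flatnonzero(self.codes == 0.0)
        if dead.size > 1:
            raise ValidationError(f"nest {n}: more than one failure (0) record")
        if dead.size == 1 and np.any(self.codes[dead[0] + 1 :] == 1.0):
            raise ValidationError(f"nest {n}: alive (1) record after a failure (0)")

    # -- convenience -------------------------------------------------------
    @property
    def detection_day(self) -> int:
        return int(self.days[0])

    @property
    def failed(self) -> bool:
        return bool(np.any(self.codes == 0.0))

    @property
    def last_alive_day(self) -> int:
        return int(self.days[np.flatnonzero(self.codes == 1.0)[-1]])

    @property
    def failure_day(self) -> int | None:
        """Day on which the nest was first observed failed, or None."""
        idx = np.flatnonzero(self.codes == 0.0)
        return int(self.days[idx[0]]) if idx.size else None


@dataclass
class NestSite:
    """Planar coordinates of one nest."""

    nest_id: str
    x: float
    y: float


@dataclass
class TrapCountTable:
    """Per-trap, per-day, per-taxon insect counts with an activity mask.

    Thin wrapper around a tidy DataFrame with columns
    ``trap_id, x, y, year, day, taxon, count, active``.  ``count`` is NaN
    exactly where ``active == 0``.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ["trap_id", "x", "y", "year", "day", "taxon", "count", "active"]

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in self.COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"trap table missing columns: {missing}")
        t = t[self.COLUMNS]
        t["count"] = pd.to_numeric(t["count"], errors="coerce")
        for c in ("year", "day", "active"):
            t[c] = t[c].astype(int)
        self.table = t.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        dup = t.duplicated(subset=["trap_id", "year", "day", "taxon"])
        if dup.any():
            raise ValidationError(
                f"duplicate (trap, year, day, taxon) rows, first at row {int(np.flatnonzero(dup)[0])}"
            )
        if not t["active"].isin((0, 1)).all():
            raise ValidationError("active must be 0 or 1")
        inactive_with_count = (t["active"] == 0) & t["count"].notna()
        if inactive_with_count.any():
            row = int(np.flatnonzero(inactive_with_count)[0])
            raise ValidationError(f"row {row}: count recorded for an inactive trap-day")
        active_missing = (t["active"] == 1) & t["count"].isna()
        if active_missing.any():
            row = int(np.flatnonzero(active_missing)[0])
            raise ValidationError(f"row {row}: active trap-day without a count")
        if (t["count"].dropna() < 0).any():
            raise ValidationError("negative insect count")
        coords = t.groupby("trap_id")[["x", "y"]].nunique()
        bad = coords[(coords > 1).any(axis=1)]
        if len(bad):
            raise ValidationError(f"trap {bad.index[0]!r}: coordinates vary across days")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.table["taxon"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.table["year"].unique())

    def trap_coords(self, year: int | None = None) -> pd.DataFrame:
        t = self.table if year is None else self.table[self.table["year"] == year]
        return t.groupby("trap_id")[["x", "y"]].first()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_code(value, row: int) -> float:
    s = str(value).strip().lower()
    if s in MISSING_CODES:
        return np.nan
    try:
        v = float(s)
    except ValueError:
        raise ValidationError(f"row {row}: malformed encounter code {value!r}") from None
    if v not in (0.0, 1.0):
        raise ValidationError(f"row {row}: encounter code {value!r} not in {{0, 1, NA}}")
    return v


def read_encounter_histories(path, dialect: dict | None = None) -> list[EncounterHistory]:
    """Read ``nests.csv`` and return one validated history per nest.

    ``dialect`` optionally maps the canonical column names
    (nest_id, pair_id, year, renest, day, code) to the file's own headers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    required = ["nest_id", "pair_id", "year", "renest", "day", "code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"nest table missing columns: {missing}")
    if len(df) == 0:
        warnings.warn("empty nest table", stacklevel=2)
        logger.warning("empty nest table at %s", path)
        return []
    codes = np.array([_parse_code(v, i) for i, v in enumerate(df["code"])])
    df = df.assign(_code=codes, day=df["day"].astype(int), year=df["year"].astype(int),
                   renest=df["renest"].astype(int))
    out = []
    for nest_id, g in df.groupby("nest_id", sort=False):
        g = g.sort_values("day")
        if g["pair_id"].nunique() > 1 or g["year"].nunique() > 1 or g["renest"].nunique() > 1:
            raise ValidationError(f"nest {nest_id}: inconsistent pair/year/renest metadata")
        out.append(
            EncounterHistory(
                nest_id=str(nest_id),
                pair_id=str(g["pair_id"].iloc[0]),
                year=int(g["year"].iloc[0]),
                renest=int(g["renest"].iloc[0]),
                days=g["day"].to_numpy(),
                codes=g["_code"].to_numpy(),
            )
        )
    return out


def write_encounter_histories(histories: list[EncounterHistory], path) -> None:
    rows = []
    for h in histories:
        for d, c in zip(h.days, h.codes):
            rows.append(
                dict(nest_id=h.nest_id, pair_id=h.pair_id, year=h.year,
                     renest=h.renest, day=int(d), code="NA" if np.isnan(c) else int(c))
            )
    pd.DataFrame(rows, columns=["nest_id", "pair_id", "year", "renest", "day", "code"]).to_csv(
        path, index=False
    )


def read_trap_counts(path) -> TrapCountTable:
    """Read and validate ``traps.csv``."""
    df = pd.read_csv(path)
    return TrapCountTable(df)


def write_trap_counts(counts: TrapCountTable, path) -> None:
    counts.table.to_csv(path, index=False)


def read_nest_sites(path) -> list[NestSite]:
    df = pd.read_csv(path)
    missing = [c for c in ("nest_id", "x", "y") if c not in df.columns]
    if missing:
        raise ValidationError(f"nest coordinate table missing columns: {missing}")
    if df["nest_id"].duplicated().any():
        dup = df["nest_id"][df["nest_id"].duplicated()].iloc[0]
        raise ValidationError(f"nest {dup!r}: more than one coordinate pair")
    return [NestSite(str(r.nest_id), float(r.x), float(r.y)) for r in df.itertuples()]


def write_nest_sites(sites: list[NestSite], path) -> None:
    pd.DataFrame([vars(s) for s in sites], columns=["nest_id", "x", "y"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# known-zero filling
# ---------------------------------------------------------------------------

def fill_known_zeros(
    counts: TrapCountTable,
    emergence_windows: dict[tuple[str, int], tuple[int, int]],
    season_days: dict[int, int] | None = None,
) -> TrapCountTable:
    """Fill in observed zero counts on days outside a taxon's activity window.

    ``emergence_windows`` maps ``(taxon, year)`` to ``(first_day, last_day)``
    of known adult activity.  Days before the first emergence or after the
    last activity are set to an observed count of 0 at every trap operated
    that year; all other missing days remain missing.  Taxa or years with no
    window are left untouched.  ``season_days`` optionally gives the last
    day-of-season per year (defaults to the largest day present per year) and
    windows outside ``[1, season]`` raise an error.
    """
    t = counts.table
    frames = [t]
    for year in counts.years:
        ty = t[t["year"] == year]
        season = (season_days or {}).get(year, int(ty["day"].max()))
        traps = ty.groupby("trap_id")[["x", "y"]].first()
        for taxon in counts.taxa:
            window = emergence_windows.get((taxon, year))
            if window is None:
                continue
            first, last = window
            if first < 1 or last > season or first > last:
                raise ValidationError(
                    f"window {window} for ({taxon!r}, {year}) outside season 1..{season}"
                )
            outside = [d for d in range(1, season + 1) if d < first or d > last]
            if not outside:
                continue
            have = ty[ty["taxon"] == taxon]
            observed = set(zip(have.loc[have["active"] == 1, "trap_id"], have.loc[have["active"] == 1, "day"]))
            rows = []
            for trap_id, (x, y) in traps.iterrows():
                for d in outside:
                    if (trap_id, d) not in observed:
                        rows.append(dict(trap_id=trap_id, x=x, y=y, year=year, day=d,
                                         taxon=taxon, count=0.0, active=1))
            if rows:
                frames.append(pd.DataFrame(rows))
    merged = pd.concat(frames, ignore_index=True)
    # an explicit inactive row may coexist with a filled zero: drop the inactive one
    merged = merged.sort_values("active", ascending=False)
    merged = merged.drop_duplicates(subset=["trap_id", "year", "day", "taxon"], keep="first")
    merged = merged.sort_values(["year", "taxon", "trap_id", "day"]).reset_index(drop=True)
    return TrapCountTable(merged)
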