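"""Canonical event data model and I/O.

The raw material of a home-cage operant experiment is three linked event
tables -- corner visits, nose pokes, and licks -- plus an animal roster.
This module defines the in-memory representation (:class:`EventDataset`),
parses/writes tab-delimited exports, persists everything to a single-file
SQLite store, and slices a recording into 24-h analysis days.

Conventions
-----------
* Timestamps are seconds since protocol start (``t0``), stored as float64
  with at least millisecond resolution.
* A day boundary is ``t0 + k*86400``; events are assigned to days by the
  *entry time* of their visit, so a visit is never split across days.
* Licks are stored as burst events carrying a count (``n_licks``); total
  licks is the sum of counts.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1
DAY_SECONDS = 86400.0

GENOTYPES = ("NonTg", "TG")
SIDES = ("left", "right")
CORNERS = (1, 2, 3, 4)

VISIT_COLUMNS = ["visit_id", "animal_id", "corner", "t_start", "t_end"]
POKE_COLUMNS = ["visit_id", "side", "t"]
LICK_COLUMNS = ["visit_id", "t", "n_licks"]
ROSTER_COLUMNS = ["animal_id", "genotype", "cage_id"]
ROSTER_OPTIONAL = ["status", "removal_day"]


class FormatError(ValueError):
    """A file or table does not have the documented shape."""


class IntegrityError(ValueError):
    """Tables violate a referential or structural invariant."""


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing required column(s) {missing}")


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class EventDataset:
    """The three event tables plus the animal roster.

    Attributes
    ----------
    animals
        Roster: ``animal_id, genotype, cage_id, status, removal_day``.
    visits
        ``visit_id, animal_id, corner, t_start, t_end``.
    pokes
        ``visit_id, side, t``.
    licks
        ``visit_id, t, n_licks``.
    t0
        Protocol start, seconds (all event times are >= t0).
    lights_on, lights_off
        Clock hours of the light phase; ``t0`` coincides with lights-on.
    """

    animals: pd.DataFrame
    visits: pd.DataFrame
    pokes: pd.DataFrame
    licks: pd.DataFrame
    t0: float = 0.0
    lights_on: float = 6.0
    lights_off: float = 18.0

    # ------------------------------------------------------------------
    def validate(self) -> "EventDataset":
        """Coerce dtypes, sort canonically, and enforce all invariants.

        Returns self (mutated in place) for chaining; raises
        :class:`FormatError` / :class:`IntegrityError` on violation.
        """
        _require_columns(self.animals, ROSTER_COLUMNS, "roster")
        _require_columns(self.visits, VISIT_COLUMNS, "visits")
        _require_columns(self.pokes, POKE_COLUMNS, "pokes")
        _require_columns(self.licks, LICK_COLUMNS, "licks")

        roster = self.animals.copy()
        if "status" not in roster.columns:
            roster["status"] = "active"
        if "removal_day" not in roster.columns:
            roster["removal_day"] = np.nan
        roster["animal_id"] = roster["animal_id"].astype(str)
        roster["genotype"] = roster["genotype"].astype(str)
        roster["cage_id"] = roster["cage_id"].astype(str)
        roster["status"] = roster["status"].astype(str)
        roster["removal_day"] = pd.to_numeric(roster["removal_day"], errors="coerce").astype(float)
        if roster["animal_id"].duplicated().any():
            dupes = roster.loc[roster["animal_id"].duplicated(), "animal_id"].tolist()
            raise IntegrityError(f"duplicate animal_id in roster: {dupes}")
        bad_geno = set(roster["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise FormatError(f"unknown genotype value(s): {sorted(bad_geno)}")
        bad_status = set(roster["status"]) - {"active", "removed"}
        if bad_status:
            raise FormatError(f"unknown status value(s): {sorted(bad_status)}")
        removed = roster["status"] == "removed"
        if (removed & roster["removal_day"].isna()).any():
            raise IntegrityError("removed animal without removal_day")
        if (~removed & roster["removal_day"].notna()).any():
            raise IntegrityError("removal_day set on an active animal")
        roster = roster.sort_values("animal_id", kind="stable").reset_index(drop=True)

        visits = self.visits.copy()
        visits["visit_id"] = pd.to_numeric(visits["visit_id"]).astype(np.int64)
        visits["animal_id"] = visits["animal_id"].astype(str)
        visits["corner"] = pd.to_numeric(visits["corner"]).astype(np.int64)
        visits["t_start"] = pd.to_numeric(visits["t_start"]).astype(float)
        visits["t_end"] = pd.to_numeric(visits["t_end"]).astype(float)
        if visits["visit_id"].duplicated().any():
            raise IntegrityError("duplicate visit_id")
        if not visits["corner"].isin(CORNERS).all():
            bad = visits.loc[~visits["corner"].isin(CORNERS), "visit_id"].tolist()
            raise IntegrityError(f"corner outside 1..4 in visits {bad}")
        if (visits["t_start"] >= visits["t_end"]).any():
            bad = visits.loc[visits["t_start"] >= visits["t_end"], "visit_id"].tolist()
            raise IntegrityError(f"t_start >= t_end in visits {bad}")
        if (visits["t_start"] < self.t0).any():
            raise IntegrityError("visit before protocol start t0")
        unknown = set(visits["animal_id"]) - set(roster["animal_id"])
        if unknown:
            raise IntegrityError(f"visits reference unknown animal(s): {sorted(unknown)}")
        visits = visits.sort_values(["t_start", "visit_id"], kind="stable").reset_index(drop=True)
        # per-animal non-overlap
        for animal_id, grp in visits.groupby("animal_id", sort=False):
            starts = grp["t_start"].to_numpy()
            ends = grp["t_end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise IntegrityError(f"overlapping visits for animal {animal_id}")

        span = visits.set_index("visit_id")[["t_start", "t_end"]]

        pokes = self.pokes.copy()
        pokes["visit_id"] = pd.to_numeric(pokes["visit_id"]).astype(np.int64) if len(pokes) else pokes["visit_id"].astype(np.int64)
        pokes["side"] = pokes["side"].astype(str)
        pokes["t"] = pd.to_numeric(pokes["t"]).astype(float)
        bad_side = set(pokes["side"]) - set(SIDES)
        if bad_side:
            raise FormatError(f"unknown poke side value(s): {sorted(bad_side)}")
        self._check_child(pokes, span, "pokes")

        licks = self.licks.copy()
        licks["visit_id"] = pd.to_numeric(licks["visit_id"]).astype(np.int64) if len(licks) else licks["visit_id"].astype(np.int64)
        licks["t"] = pd.to_numeric(licks["t"]).astype(float)
        licks["n_licks"] = pd.to_numeric(licks["n_licks"]).astype(np.int64) if len(licks) else licks["n_licks"].astype(np.int64)
        if (licks["n_licks"] < 1).any():
            raise IntegrityError("lick burst with n_licks < 1")
        self._check_child(licks, span, "licks")

        self.animals = roster[ROSTER_COLUMNS + ROSTER_OPTIONAL]
        self.visits = visits[VISIT_COLUMNS]
        self.pokes = pokes.sort_values(["t", "visit_id"], kind="stable").reset_index(drop=True)[POKE_COLUMNS]
        self.licks = licks.sort_values(["t", "visit_id"], kind="stable").reset_index(drop=True)[LICK_COLUMNS]
        return self

    @staticmethod
    def _check_child(child: pd.DataFrame, span: pd.DataFrame, name: str) -> None:
        if child.empty:
            return
        orphan = ~child["visit_id"].isin(span.index)
        if orphan.any():
            rows = child.index[orphan].tolist()
            ids = child.loc[orphan, "visit_id"].unique().tolist()
            raise IntegrityError(f"{name}: rows {rows} reference unknown visit_id(s) {ids}")
        joined = child.join(span, on="visit_id")
        out = (joined["t"] < joined["t_start"]) | (joined["t"] > joined["t_end"])
        if out.any():
            raise IntegrityError(f"{name}: rows {child.index[out].tolist()} fall outside their visit")

    # ------------------------------------------------------------------
    def equals(self, other: "EventDataset") -> bool:
        return (
            self.animals.reset_index(drop=True).equals(other.animals.reset_index(drop=True))
            and self.visits.reset_index(drop=True).equals(other.visits.reset_index(drop=True))
            and self.pokes.reset_index(drop=True).equals(other.pokes.reset_index(drop=True))
            and self.licks.reset_index(drop=True).equals(other.licks.reset_index(drop=True))
            and self.t0 == other.t0
            and self.lights_on == other.lights_on
            and self.lights_off == other.lights_off
        )

    def active_animals(self) -> pd.DataFrame:
        return self.animals

    def copy(self) -> "EventDataset":
        return replace(
            self,
            animals=self.animals.copy(),
            visits=self.visits.copy(),
            pokes=self.pokes.copy(),
            licks=self.licks.copy(),
        )

    @property
    def n_days(self) -> int:
        """Number of whole days spanned by the recording (by visit entry)."""
        if self.visits.empty:
            return 0
        last = self.visits["t_start"].max()
        return int(np.floor((last - self.t0) / DAY_SECONDS)) + 1


@dataclass
class DaySlice:
    """All events of one 24-h analysis day (views, not copies)."""

    day_index: int
    t_lo: float
    t_hi: float
    visits: pd.DataFrame
    pokes: pd.DataFrame
    licks: pd.DataFrame

    def for_animal(self, animal_id: str) -> "DaySlice":
        v = self.visits[self.visits["animal_id"] == animal_id]
        ids = set(v["visit_id"])
        return DaySlice(
            self.day_index,
            self.t_lo,
            self.t_hi,
            v,
            self.pokes[self.pokes["visit_id"].isin(ids)],
            self.licks[self.licks["visit_id"].isin(ids)],
        )


def visit_day_index(t_start: np.ndarray | float, t0: float) -> np.ndarray | int:
    """1-based day index of a visit entry time."""
    d = np.floor((np.asarray(t_start, dtype=float) - t0) / DAY_SECONDS).astype(np.int64) + 1
    return d if d.ndim else int(d)


def slice_by_day(dataset: EventDataset, n_days: int | None = None) -> list[DaySlice]:
    """Partition a dataset into 24-h slices anchored at ``t0``.

    Pokes and licks inherit the slice of their parent visit, so a visit
    straddling a boundary stays atomic (entry-time rule).
    """
    if dataset.visits.empty and not n_days:
        raise ValueError("cannot slice an empty dataset without an explicit n_days")
    if not dataset.visits.empty and (dataset.visits["t_start"] < dataset.t0).any():
        raise IntegrityError("visit before t0")
    vdays = visit_day_index(dataset.visits["t_start"].to_numpy(), dataset.t0) if len(dataset.visits) else np.array([], dtype=np.int64)
    total = int(n_days) if n_days else int(vdays.max())
    day_of_visit = pd.Series(vdays, index=dataset.visits["visit_id"].to_numpy()) if len(dataset.visits) else pd.Series(dtype=np.int64)
    pdays = day_of_visit.reindex(dataset.pokes["visit_id"]).to_numpy() if len(dataset.pokes) else np.array([])
    ldays = day_of_visit.reindex(dataset.licks["visit_id"]).to_numpy() if len(dataset.licks) else np.array([])
    out = []
    for d in range(1, total + 1):
        out.append(
            DaySlice(
                day_index=d,
                t_lo=dataset.t0 + (d - 1) * DAY_SECONDS,
                t_hi=dataset.t0 + d * DAY_SECONDS,
                visits=dataset.visits[vdays == d] if len(dataset.visits) else dataset.visits,
                pokes=dataset.pokes[pdays == d] if len(dataset.pokes) else dataset.pokes,
                licks=dataset.licks[ldays == d] if len(dataset.licks) else dataset.licks,
            )
        )
    return out


# ----------------------------------------------------------------------
# Tab-delimited export I/O
# ----------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty and not list(df.columns):
        df = _empty(required)
    _require_columns(df, required, name)
    return df


def parse_event_export(
    visit_path: str | Path,
    poke_path: str | Path,
    lick_path: str | Path,
    roster_path: str | Path,
    t0: float = 0.0,
    lights_on: float = 6.0,
    lights_off: float = 18.0,
) -> EventDataset:
    """Read the four tab-delimited tables and return a validated dataset."""
    return EventDataset(
        animals=_read_tsv(roster_path, ROSTER_COLUMNS, "roster"),
        visits=_read_tsv(visit_path, VISIT_COLUMNS, "visits"),
        pokes=_read_tsv(poke_path, POKE_COLUMNS, "pokes"),
        licks=_read_tsv(lick_path, LICK_COLUMNS, "licks"),
        t0=t0,
        lights_on=lights_on,
        lights_off=lights_off,
    ).validate()


def write_event_export(dataset: EventDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset back to visits/pokes/licks/roster TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": out / "visits.tsv",
        "pokes": out / "pokes.tsv",
        "licks": out / "licks.tsv",
        "roster": out / "roster.tsv",
    }
    dataset.visits.to_csv(paths["visits"], sep="\t", index=False)
    dataset.pokes.to_csv(paths["pokes"], sep="\t", index=False)
    dataset.licks.to_csv(paths["licks"], sep="\t", index=False)
    dataset.animals.to_csv(paths["roster"], sep="\t", index=False)
    return paths


# ----------------------------------------------------------------------
# Single-file relational store
# ----------------------------------------------------------------------

def write_store(dataset: EventDataset, path: str | Path) -> Path:
    """Persist the dataset as a single SQLite file (one table per input)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        dataset.animals.to_sql("animals", con, index=False)
        dataset.visits.to_sql("visits", con, index=False)
        dataset.pokes.to_sql("pokes", con, index=False)
        dataset.licks.to_sql("licks", con, index=False)
        meta = pd.DataFrame(
            {
                "key": ["t0", "lights_on", "lights_off", "schema_version"],
                "value": [dataset.t0, dataset.lights_on, dataset.lights_off, float(SCHEMA_VERSION)],
            }
        )
        meta.to_sql("meta", con, index=False)
        con.commit()
    finally:
        con.close()
    return path


def read_store(path: str | Path) -> EventDataset:
    """Load a dataset from a SQLite store written by :func:`write_store`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        try:
            meta = pd.read_sql("SELECT key, value FROM meta", con).set_index("key")["value"]
            animals = pd.read_sql("SELECT * FROM animals", con)
            visits = pd.read_sql("SELECT * FROM visits", con)
            pokes = pd.read_sql("SELECT * FROM pokes", con)
            licks = pd.read_sql("SELECT * FROM licks", con)
        except (pd.errors.DatabaseError, sqlite3.DatabaseError) as exc:
            raise FormatError(f"corrupt or foreign store at {path}: {exc}") from exc
    finally:
        con.close()
    return EventDataset(
        animals=animals,
        visits=visits,
        pokes=pokes,
        licks=licks,
        t0=float(meta["t0"]),
        lights_on=float(meta["lights_on"]),
        lights_off=float(meta["lights_off"]),
    ).validate()


def write_daily_csvs(dataset: EventDataset, out_dir: str | Path, n_days: int | None = None) -> list[Path]:
    """One CSV of visits per day, mirroring per-day spreadsheet exports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sl in slice_by_day(dataset, n_days=n_days):
        p = out / f"day_{sl.day_index:02d}_visits.csv"
        sl.visits.to_csv(p, index=False)
        paths.append(p)
    return paths
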