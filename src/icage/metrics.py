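"""Per-mouse, per-day dependent variables.

Every variable is computed per animal per 24-h protocol day, exactly as
defined for each phase:

* ``total_visits`` / ``total_licks`` -- all phases.
* ``visits_with_poke`` / ``visits_with_lick`` -- nose-poke adaptation on.
* ``visits_during_water_access`` -- restricted-water phases (membership
  by visit entry time).
* place preference: ``assigned_visits``, ``assigned_visits_with_lick``,
  ``pct_correct_pp = assigned_visits_with_lick / total_visits * 100``.
* reaction time: ``trials`` and %abandoned/%premature/%correct, overall
  and stratified by pre-cue duration.
* avoidance/extinction: ``assigned_visits_with_poke`` at the puff corner.

Percentages with a zero denominator are missing (NaN), never 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import Outcome
from .events import DaySlice, EventDataset, slice_by_day
from .schedule import CornerAssignment, Phase, PhaseSpec, Protocol, RT_PHASES, WaterWindow

COUNT_COLUMNS = [
    "total_visits", "total_licks", "visits_with_poke", "visits_with_lick",
    "visits_during_water_access", "assigned_visits", "assigned_visits_with_lick",
    "assigned_visits_with_poke", "trials",
]
PCT_COLUMNS = ["pct_correct_pp", "pct_abandoned", "pct_premature", "pct_correct"]


def _d_tag(d: float) -> str:
    return str(int(d)) if float(d).is_integer() else str(d).replace(".", "_")


def per_d_columns(precue_set: tuple[float, ...]) -> list[str]:
    cols = []
    for d in precue_set:
        tag = _d_tag(d)
        cols += [f"trials_d{tag}", f"pct_abandoned_d{tag}", f"pct_premature_d{tag}", f"pct_correct_d{tag}"]
    return cols


def daily_counts(
    day_slice: DaySlice,
    water_window: WaterWindow,
    t0: float = 0.0,
    t0_clock: float = 6.0,
) -> dict[str, float]:
    """Visit/poke/lick counts for one animal-day slice."""
    visits = day_slice.visits
    pokes = day_slice.pokes
    licks = day_slice.licks
    with_poke = pokes["visit_id"].unique() if len(pokes) else []
    with_lick = licks["visit_id"].unique() if len(licks) else []
    if water_window.kind == "restricted" and len(visits):
        in_win = visits["t_start"].map(lambda t: water_window.contains(t, t0, t0_clock))
        n_water = int(in_win.sum())
    else:
        n_water = int(len(visits)) if water_window.kind == "unrestricted" else 0
    return {
        "total_visits": int(len(visits)),
        "total_licks": int(licks["n_licks"].sum()) if len(licks) else 0,
        "visits_with_poke": int(visits["visit_id"].isin(with_poke).sum()),
        "visits_with_lick": int(visits["visit_id"].isin(with_lick).sum()),
        "visits_during_water_access": n_water,
    }


def place_preference_metrics(day_slice: DaySlice, assigned_corner: int) -> dict[str, float]:
    """Assigned-corner counts and the place-preference %Correct.

    %Correct = assigned visits with >=1 lick / total visits (all corners)
    * 100, undefined (NaN) when there are no visits.
    """
    visits = day_slice.visits
    licks = day_slice.licks
    with_lick = set(licks["visit_id"]) if len(licks) else set()
    assigned = visits[visits["corner"] == assigned_corner]
    n_assigned_lick = int(assigned["visit_id"].isin(with_lick).sum())
    total = len(visits)
    return {
        "assigned_visits": int(len(assigned)),
        "assigned_visits_with_lick": n_assigned_lick,
        "pct_correct_pp": (100.0 * n_assigned_lick / total) if total else np.nan,
    }


def rt_metrics(trial_table: pd.DataFrame, precue_set: tuple[float, ...]) -> dict[str, float]:
    """Trial-outcome percentages, overall and per pre-cue duration.

    ``trial_table`` holds the trials of one animal-day. Strata with zero
    trials get NaN percentages.
    """
    bad = set(trial_table["precue"]) - set(float(d) for d in precue_set)
    if bad:
        raise ValueError(f"trial pre-cue value(s) {sorted(bad)} outside the phase set {precue_set}")

    def pct_block(df: pd.DataFrame) -> tuple[int, float, float, float]:
        n = len(df)
        if n == 0:
            return 0, np.nan, np.nan, np.nan
        counts = df["outcome"].value_counts()
        return (
            n,
            100.0 * counts.get(Outcome.ABANDONED.value, 0) / n,
            100.0 * counts.get(Outcome.PREMATURE.value, 0) / n,
            100.0 * counts.get(Outcome.CORRECT.value, 0) / n,
        )

    n, ab, pr, co = pct_block(trial_table)
    out = {"trials": n, "pct_abandoned": ab, "pct_premature": pr, "pct_correct": co}
    for d in precue_set:
        tag = _d_tag(d)
        nd, abd, prd, cod = pct_block(trial_table[trial_table["precue"] == float(d)])
        out[f"trials_d{tag}"] = nd
        out[f"pct_abandoned_d{tag}"] = abd
        out[f"pct_premature_d{tag}"] = prd
        out[f"pct_correct_d{tag}"] = cod
    return out


def avoidance_metrics(day_slice: DaySlice, assigned_corner: int) -> dict[str, float]:
    """Puff-corner visit counts for the avoidance and extinction days."""
    visits = day_slice.visits
    pokes = day_slice.pokes
    with_poke = set(pokes["visit_id"]) if len(pokes) else set()
    assigned = visits[visits["corner"] == assigned_corner]
    return {
        "assigned_visits": int(len(assigned)),
        "assigned_visits_with_poke": int(assigned["visit_id"].isin(with_poke).sum()),
    }


# ----------------------------------------------------------------------

def build_metric_table(
    dataset: EventDataset,
    protocol: Protocol,
    assignment: CornerAssignment | None,
    trial_table: pd.DataFrame | None = None,
    days: list[int] | None = None,
) -> pd.DataFrame:
    """Assemble the wide animal x day dependent-variable table.

    One row per active animal per protocol day (the home-cage delay day
    is skipped; removed animals contribute only days before removal).
    """
    all_d: set[float] = set()
    for ph in protocol.phases:
        if ph.precue_set:
            all_d.update(ph.precue_set)
    d_cols = per_d_columns(tuple(sorted(all_d)))

    day_list = days if days is not None else [
        d for d in protocol.day_range if protocol.phase_for_day(d).name != Phase.HOME_CAGE_DELAY
    ]
    slices = {sl.day_index: sl for sl in slice_by_day(dataset, n_days=protocol.n_days)}
    roster = dataset.animals
    geno_of = dict(zip(roster["animal_id"], roster["genotype"]))
    removal = dict(zip(roster["animal_id"], roster["removal_day"]))

    if trial_table is None:
        trial_table = pd.DataFrame(columns=["animal_id", "day", "precue", "outcome"])
    trial_groups = dict(tuple(trial_table.groupby(["animal_id", "day"]))) if len(trial_table) else {}

    rows = []
    for day in day_list:
        phase = protocol.phase_for_day(day)
        if phase.name == Phase.HOME_CAGE_DELAY:
            continue
        sl = slices[day]
        for animal_id in roster["animal_id"]:
            rd = removal[animal_id]
            if not np.isnan(rd) and day >= rd:
                continue
            asl = sl.for_animal(animal_id)
            row: dict[str, object] = {
                "animal_id": animal_id,
                "genotype": geno_of[animal_id],
                "day": day,
                "phase": phase.name.value,
            }
            row.update(daily_counts(asl, phase.water, protocol.t0, protocol.t0_clock))
            if phase.name in (Phase.PP, Phase.REVERSAL):
                row.update(place_preference_metrics(asl, assignment.corner_for_phase(animal_id, phase.name)))
            if phase.name in RT_PHASES:
                tg = trial_groups.get((animal_id, day))
                if tg is None:
                    tg = trial_table.iloc[0:0]
                row.update(rt_metrics(tg, phase.precue_set))
            if phase.name in (Phase.AVOIDANCE, Phase.EXTINCTION) and assignment is not None:
                row.update(avoidance_metrics(asl, assignment.reversal(animal_id)))
            rows.append(row)

    columns = (["animal_id", "genotype", "day", "phase"] + COUNT_COLUMNS + PCT_COLUMNS + d_cols)
    table = pd.DataFrame(rows)
    for c in columns:
        if c not in table.columns:
            table[c] = np.nan
    return table[columns].reset_index(drop=True)


def rt_metric_table(trial_table: pd.DataFrame, roster: pd.DataFrame, precue_set: tuple[float, ...]) -> pd.DataFrame:
    """Fast RT-only metric table straight from a trial table.

    Used by simulation studies that only need the reaction-time DVs;
    yields the same ``trials``/percentage columns as
    :func:`build_metric_table` for the covered animal-days.
    """
    rows = []
    geno_of = dict(zip(roster["animal_id"], roster["genotype"]))
    for (animal_id, day), grp in trial_table.groupby(["animal_id", "day"]):
        row = {"animal_id": animal_id, "genotype": geno_of[str(animal_id)], "day": int(day)}
        row.update(rt_metrics(grp, precue_set))
        rows.append(row)
    return pd.DataFrame(rows)


def to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide table to (animal_id, genotype, phase, day, variable, value)."""
    return table.melt(
        id_vars=["animal_id", "genotype", "phase", "day"],
        var_name="variable",
        value_name="value",
    ).dropna(subset=["value"]).reset_index(drop=True)
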