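"""Proximity-logger contact-log ingestion and bout assembly.

Collar-mounted proximity loggers record, for each animal, the start time and
duration of every episode during which another collar was within detection
range.  The two collars of a dyad log the same physical contact with slightly
different start and end times (radio shadowing is not symmetric), short
spurious detections occur at the edge of the range, and a logger-level
"separation time" means that detections separated by less than a threshold
belong to one social contact bout.

This module turns raw directional logger records into symmetric dyadic
contact bouts assigned to experimental phases:

1. :func:`trim_pre_experiment` — drop records from before the animals were
   placed in their plots (negative times relative to the experiment origin);
2. :func:`filter_short_contacts` — drop spurious detections of at most
   ``min_contact_duration`` seconds (default 1 s);
3. :func:`symmetrize_reciprocal` — union the two loggers' intervals per dyad:
   a contact starts when *either* logger sees it and ends when *either*
   logger last maintains it;
4. :func:`assemble_bouts` — merge consecutive intervals of a dyad separated
   by less than ``separation_time`` (default 30 s) into single bouts;
5. :func:`assign_phases` — attach phase labels, splitting bouts that straddle
   a phase boundary so per-phase contact durations are conserved.

Collections are plain :class:`pandas.DataFrame` objects with the column
schemas given by :data:`RECORD_COLUMNS`, :data:`INTERVAL_COLUMNS` and
:data:`BOUT_COLUMNS`.  All times are real-valued seconds from the experiment
origin; calendar parsing happens only in :func:`read_contact_log`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAY_SECONDS = 86400.0

#: Schema of raw directional logger records.
RECORD_COLUMNS = ["group_id", "logger_animal", "partner_animal", "start_s", "duration_s"]
#: Schema of symmetric dyadic contact intervals (dyad in canonical order, a < b).
INTERVAL_COLUMNS = ["group_id", "animal_a", "animal_b", "start_s", "end_s"]
#: Schema of assembled contact bouts (phase is NA until :func:`assign_phases`).
BOUT_COLUMNS = INTERVAL_COLUMNS + ["phase"]

ROSTER_COLUMNS = ["group_id", "animal_id", "role"]
ROLES = ("resident", "unfamiliar")


class ContactLogError(ValueError):
    """Malformed contact-log input (parse failure, naming the offending line)."""


class ValidationError(ValueError):
    """Contact-log content violating roster or record invariants."""


@dataclass(frozen=True)
class Phase:
    """One experimental phase covering whole days ``first_day``..``last_day`` (1-based, inclusive)."""

    label: str
    first_day: int
    last_day: int

    def __post_init__(self) -> None:
        if self.last_day < self.first_day or self.first_day < 1:
            raise ValueError(f"phase {self.label!r}: invalid day range "
                             f"{self.first_day}..{self.last_day}")

    @property
    def start_s(self) -> float:
        return (self.first_day - 1) * DAY_SECONDS

    @property
    def end_s(self) -> float:
        return self.last_day * DAY_SECONDS

    @property
    def n_days(self) -> int:
        return self.last_day - self.first_day + 1


#: Phases of the disturbance experiment: 6 pre-introduction days, then two
#: 6-day windows after the unfamiliar animal is introduced.
DEFAULT_PHASES = (Phase("1", 1, 6), Phase("2a", 7, 12), Phase("2b", 13, 18))


@dataclass
class StudyDesign:
    """Replicated group design: ``n_groups`` networks of ``residents_per_group`` animals.

    Parameters
    ----------
    n_groups
        Number of replicated networks (groups), ``n_g`` in the design formulas.
    residents_per_group
        Resident animals per group, ``n_n`` (the unfamiliar animal is extra).
    phases
        Ordered, contiguous, non-overlapping day ranges.
    separation_time
        Seconds; logger detections of a dyad separated by *less* than this
        belong to one bout.
    min_contact_duration
        Seconds; directional records of at most this duration are discarded
        as spurious.
    experiment_start
        Optional ISO-8601 timestamp of the experiment origin, used only when
        reading logs whose start column is a datetime.
    """

    n_groups: int = 6
    residents_per_group: int = 5
    phases: tuple[Phase, ...] = DEFAULT_PHASES
    separation_time: float = 30.0
    min_contact_duration: float = 1.0
    experiment_start: str | None = None
    boundary_policy: str = "split"  # or "start": assign straddling bouts by start time

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.residents_per_group < 1:
            raise ValueError("counts must be >= 1")
        if self.separation_time <= 0:
            raise ValueError("separation_time must be > 0")
        if self.min_contact_duration < 0:
            raise ValueError("min_contact_duration must be >= 0")
        if self.boundary_policy not in ("split", "start"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")
        self.phases = tuple(p if isinstance(p, Phase) else Phase(*p) for p in self.phases)
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if nxt.first_day != prev.last_day + 1:
                raise ValueError("phase day ranges must be contiguous and non-overlapping")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def phase_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.phases)

    @property
    def days_per_phase(self) -> int:
        days = {p.n_days for p in self.phases}
        if len(days) != 1:
            raise ValueError("phases have unequal lengths; use Phase.n_days per phase")
        return days.pop()

    def phase_of(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        if "phases" in d:
            d["phases"] = tuple(
                Phase(str(p["label"]), int(p["first_day"]), int(p["last_day"]))
                if isinstance(p, dict) else Phase(*p)
                for p in d["phases"]
            )
        return cls(**d)


def read_roster(path) -> pd.DataFrame:
    """Read the animal roster CSV (``group_id,animal_id,role``)."""
    roster = pd.read_csv(path, dtype=str)
    missing = set(ROSTER_COLUMNS) - set(roster.columns)
    if missing:
        raise ContactLogError(f"roster {path}: missing columns {sorted(missing)}")
    bad = set(roster["role"]) - set(ROLES)
    if bad:
        raise ValidationError(f"roster {path}: unknown roles {sorted(bad)}")
    if roster["animal_id"].duplicated().any():
        dup = roster.loc[roster["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValidationError(f"roster {path}: duplicate animal_id {dup!r}")
    return roster[ROSTER_COLUMNS]


def _parse_start_column(raw: pd.DataFrame, design: StudyDesign, path) -> pd.Series:
    if "start_s" in raw.columns:
        start = pd.to_numeric(raw["start_s"], errors="coerce")
    elif "start_time" in raw.columns:
        if design.experiment_start is None:
            raise ContactLogError(
                f"{path}: datetime start column requires design.experiment_start")
        origin = pd.Timestamp(design.experiment_start)
        parsed = pd.to_datetime(raw["start_time"], errors="coerce", format="ISO8601")
        start = (parsed - origin).dt.total_seconds()
    else:
        raise ContactLogError(f"{path}: need a 'start_s' or 'start_time' column")
    if start.isna().any():
        line = int(start.index[start.isna()][0]) + 2  # header is line 1
        raise ContactLogError(f"{path}: unparseable start value at line {line}")
    return start.astype(float)


def read_contact_log(path, design: StudyDesign, roster: pd.DataFrame) -> pd.DataFrame:
    """Read and validate a raw proximity-logger CSV.

    Expected header ``group_id,logger_animal,partner_animal,start_s,duration_s``
    (UTF-8, ``.`` decimal separator).  A ``start_time`` ISO-8601 column may
    replace ``start_s`` when ``design.experiment_start`` is set.

    Every record is checked against the roster: both animals listed, both in
    the record's group, distinct from each other, non-negative duration.
    Row order is preserved.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    needed = {"group_id", "logger_animal", "partner_animal", "duration_s"}
    missing = needed - set(raw.columns)
    if missing:
        raise ContactLogError(f"{path}: missing columns {sorted(missing)}")
    start = _parse_start_column(raw, design, path)
    duration = pd.to_numeric(raw["duration_s"], errors="coerce")
    if duration.isna().any():
        line = int(duration.index[duration.isna()][0]) + 2
        raise ContactLogError(f"{path}: unparseable duration at line {line}")

    records = pd.DataFrame({
        "group_id": raw["group_id"].astype(str),
        "logger_animal": raw["logger_animal"].astype(str),
        "partner_animal": raw["partner_animal"].astype(str),
        "start_s": start.to_numpy(),
        "duration_s": duration.to_numpy(dtype=float),
    })
    validate_records(records, roster, source=str(path))
    return records


def validate_records(records: pd.DataFrame, roster: pd.DataFrame, source: str = "records") -> None:
    """Raise :class:`ValidationError` on roster or invariant violations."""
    self_contact = records["logger_animal"] == records["partner_animal"]
    if self_contact.any():
        line = int(records.index[self_contact][0]) + 2
        raise ValidationError(f"{source}: logger_animal equals partner_animal at line {line}")
    if (records["duration_s"] < 0).any():
        line = int(records.index[records["duration_s"] < 0][0]) + 2
        raise ValidationError(f"{source}: negative duration at line {line}")
    if not np.isfinite(records["start_s"].to_numpy() + records["duration_s"].to_numpy()).all():
        raise ValidationError(f"{source}: non-finite start or duration")
    group_of = dict(zip(roster["animal_id"], roster["group_id"]))
    for col in ("logger_animal", "partner_animal"):
        unknown = ~records[col].isin(group_of)
        if unknown.any():
            bad = records.loc[unknown, col].iloc[0]
            raise ValidationError(f"{source}: animal {bad!r} not in roster")
        wrong = records[col].map(group_of) != records["group_id"]
        if wrong.any():
            bad = records.loc[wrong, col].iloc[0]
            raise ValidationError(f"{source}: animal {bad!r} recorded outside its roster group")
    a = records["logger_animal"].map(group_of)
    b = records["partner_animal"].map(group_of)
    if (a != b).any():
        i = records.index[(a != b)][0]
        raise ValidationError(
            f"{source}: cross-group dyad "
            f"({records.at[i, 'logger_animal']!r}, {records.at[i, 'partner_animal']!r})")


def trim_pre_experiment(records: pd.DataFrame, design: StudyDesign | None = None) -> pd.DataFrame:
    """Drop records that start before the experiment origin (``start_s < 0``).

    Records exactly at time 0 are retained.
    """
    kept = records[records["start_s"] >= 0].reset_index(drop=True)
    logger.info("trim_pre_experiment: dropped %d of %d records", len(records) - len(kept), len(records))
    return kept


def filter_short_contacts(records: pd.DataFrame, min_contact_duration: float = 1.0) -> pd.DataFrame:
    """Drop directional records of duration <= ``min_contact_duration`` seconds.

    The threshold is inclusive ("1 second or less"): a 1.0-s record is removed
    at the default threshold.
    """
    if min_contact_duration < 0:
        raise ValueError("min_contact_duration must be >= 0")
    kept = records[records["duration_s"] > min_contact_duration].reset_index(drop=True)
    logger.info("filter_short_contacts: dropped %d of %d records", len(records) - len(kept), len(records))
    return kept


def _dyad_sweep_merge(df: pd.DataFrame, gap: float) -> pd.DataFrame:
    """Merge intervals per (group, dyad) whenever start - previous end < ``gap``.

    ``gap = 0`` gives the interval union (overlapping or touching intervals
    coalesce); ``gap = separation_time`` gives bout assembly.  Single global
    sweep: each dyad's times are shifted onto a private segment of the time
    axis so one pass over the sorted array handles all dyads.
    """
    if df.empty:
        return df.copy()
    keys = df["group_id"].str.cat([df["animal_a"], df["animal_b"]], sep="\x1f")
    codes, _ = pd.factorize(keys, sort=True)
    span = float(df["end_s"].max()) + gap + 1.0
    offset = codes * span
    order = np.lexsort((df["start_s"].to_numpy(), codes))
    start = df["start_s"].to_numpy()[order] + offset[order]
    end = df["end_s"].to_numpy()[order] + offset[order]
    run_end = np.maximum.accumulate(end)
    # a new merged interval begins where the gap to everything before is >= gap
    new_run = np.ones(len(start), dtype=bool)
    new_run[1:] = start[1:] - run_end[:-1] >= gap if gap > 0 else start[1:] > run_end[:-1]
    first = np.flatnonzero(new_run)
    merged_start = start[first]
    merged_end = np.maximum.reduceat(end, first)
    rows = df.iloc[order[first]]
    out = pd.DataFrame({
        "group_id": rows["group_id"].to_numpy(),
        "animal_a": rows["animal_a"].to_numpy(),
        "animal_b": rows["animal_b"].to_numpy(),
        "start_s": merged_start - offset[order[first]],
        "end_s": merged_end - offset[order[first]],
    })
    return out.reset_index(drop=True)


def symmetrize_reciprocal(records: pd.DataFrame) -> pd.DataFrame:
    """Union the directional intervals of each dyad's two loggers.

    A contact interval starts when either logger records contact and ends when
    either logger last holds it: per unordered dyad the output is the union of
    all ``[start, start + duration)`` intervals from both loggers, with
    overlapping or end-to-start touching intervals coalesced.  Output intervals
    are pairwise disjoint per dyad and sorted by (group, dyad, start); the
    result does not depend on input record order.
    """
    if records.empty:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    la = records["logger_animal"].to_numpy()
    pa = records["partner_animal"].to_numpy()
    swap = la > pa
    intervals = pd.DataFrame({
        "group_id": records["group_id"].to_numpy(),
        "animal_a": np.where(swap, pa, la),
        "animal_b": np.where(swap, la, pa),
        "start_s": records["start_s"].to_numpy(),
        "end_s": records["start_s"].to_numpy() + records["duration_s"].to_numpy(),
    })
    intervals = intervals[intervals["end_s"] > intervals["start_s"]]
    return _dyad_sweep_merge(intervals, gap=0.0)


def assemble_bouts(intervals: pd.DataFrame, separation_time: float = 30.0) -> pd.DataFrame:
    """Merge per-dyad intervals separated by less than ``separation_time`` into bouts.

    Two contacts less than ``separation_time`` seconds apart form one bout; a
    gap of exactly ``separation_time`` (or more) keeps them separate.  Merging
    is exhaustive, so the operation is idempotent.  The returned frame carries
    an unset ``phase`` column.
    """
    if separation_time <= 0:
        raise ValueError("separation_time must be > 0")
    if intervals.empty:
        return pd.DataFrame(columns=BOUT_COLUMNS)
    bouts = _dyad_sweep_merge(intervals[INTERVAL_COLUMNS], gap=float(separation_time))
    bouts["phase"] = pd.NA
    return bouts


def assign_phases(bouts: pd.DataFrame, design: StudyDesign, policy: str | None = None) -> pd.DataFrame:
    """Attach phase labels to bouts.

    With ``policy="split"`` (default) a bout straddling a phase boundary is cut
    at the boundary into one fragment per phase, so summed per-phase durations
    equal the unsplit total.  With ``policy="start"`` each bout is assigned
    the phase containing its start time.  Bouts falling entirely outside all
    phases are dropped (the count is logged).
    """
    policy = design.boundary_policy if policy is None else policy
    if policy not in ("split", "start"):
        raise ValueError(f"unknown boundary policy {policy!r}")
    if bouts.empty:
        return pd.DataFrame(columns=BOUT_COLUMNS)
    pieces = []
    if policy == "split":
        for phase in design.phases:
            lo = np.maximum(bouts["start_s"].to_numpy(), phase.start_s)
            hi = np.minimum(bouts["end_s"].to_numpy(), phase.end_s)
            inside = lo < hi
            if inside.any():
                frag = bouts.loc[inside, INTERVAL_COLUMNS].copy()
                frag["start_s"] = lo[inside]
                frag["end_s"] = hi[inside]
                frag["phase"] = phase.label
                pieces.append(frag)
    else:
        for phase in design.phases:
            s = bouts["start_s"].to_numpy()
            inside = (s >= phase.start_s) & (s < phase.end_s)
            if inside.any():
                frag = bouts.loc[inside, INTERVAL_COLUMNS].copy()
                frag["phase"] = phase.label
                pieces.append(frag)
    window_lo = design.phases[0].start_s
    window_hi = design.phases[-1].end_s
    outside = (bouts["end_s"].to_numpy() <= window_lo) | (bouts["start_s"].to_numpy() >= window_hi)
    if outside.any():
        logger.info("assign_phases: dropped %d bouts outside all phases", int(outside.sum()))
    if not pieces:
        return pd.DataFrame(columns=BOUT_COLUMNS)
    out = pd.concat(pieces, ignore_index=True)
    out = out.sort_values(["group_id", "animal_a", "animal_b", "start_s"],
                          kind="mergesort").reset_index(drop=True)
    logger.info("assign_phases: %d bouts -> %d phase fragments (policy=%s)",
                len(bouts), len(out), policy)
    return out[BOUT_COLUMNS]


@dataclass
class PreprocessResult:
    """Assembled, phase-assigned bouts plus per-step drop accounting."""

    bouts: pd.DataFrame
    counts: dict = field(default_factory=dict)


def preprocess(records: pd.DataFrame, design: StudyDesign,
               roster: pd.DataFrame | None = None) -> PreprocessResult:
    """Run the full preprocessing chain on raw directional records.

    trim → short-contact filter → reciprocal union → bout assembly → phase
    assignment, with the thresholds and boundary policy from ``design``.
    """
    if roster is not None:
        validate_records(records, roster)
    n0 = len(records)
    trimmed = trim_pre_experiment(records, design)
    filtered = filter_short_contacts(trimmed, design.min_contact_duration)
    intervals = symmetrize_reciprocal(filtered)
    bouts = assemble_bouts(intervals, design.separation_time)
    assigned = assign_phases(bouts, design)
    counts = {
        "records_in": n0,
        "dropped_pre_experiment": n0 - len(trimmed),
        "dropped_short": len(trimmed) - len(filtered),
        "intervals": len(intervals),
        "bouts": len(bouts),
        "bouts_assigned": len(assigned),
    }
    return PreprocessResult(bouts=assigned, counts=counts)
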