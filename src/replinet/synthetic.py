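"""Synthetic data generation at two levels.

The cattle contact data this package was built around are not publicly
deposited, so the package carries its own generators:

* **Metric level** (:func:`simulate_metrics`) — draws per-animal per-phase
  response values directly from the mixed model
  ``y = mu + phase + G + GP + A(G) + e`` with specified variance components
  on the log10 scale.  This gives exact distributional control and is the
  surface on which the statistical modules (ANOVA decomposition, component
  estimation, phase test) are validated by parameter recovery.

* **Event level** (:func:`simulate_contact_logs`) — simulates raw two-logger
  proximity records: per-dyad Poisson bout processes with log-normal bout
  durations, independently jittered start/end times per logger, per-logger
  missed detections, and spurious sub-second detections.  The true
  (noise-free) bout list is returned alongside so the preprocessing chain
  can be checked against ground truth.

:func:`exemplar_study_dataset` bundles the event level into a full study: six
groups of five residents over three 6-day phases, with one unfamiliar animal
joining each group at the start of phase 2a, contact frequency dropping and
mean bout duration rising after the disturbance, and variance components of
the magnitude estimated in the original cattle study.

All randomness flows through explicit ``numpy.random.Generator`` seeds; no
global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contact_log import (BOUT_COLUMNS, RECORD_COLUMNS, ROSTER_COLUMNS, DAY_SECONDS,
                          Phase, StudyDesign, assemble_bouts, assign_phases,
                          symmetrize_reciprocal)

# Variance-component magnitudes (log10^2 scale) of the cattle study's contact
# frequency metric; group and animal components were not published, so the
# defaults use values of the same order.
DEFAULT_SIGMA2_GROUP = 0.005
DEFAULT_SIGMA2_ANIMAL = 0.010
DEFAULT_SIGMA2_GROUP_PHASE = 0.0047
DEFAULT_SIGMA2_RESIDUAL = 0.0129

# Contact-frequency phase means of the cattle study (contacts/cow/day
# 360.4, 254.3, 228.6) expressed as zero-sum log10 offsets around their mean.
_FREQ_LOG10 = np.log10([360.4, 254.3, 228.6])
DEFAULT_MU = float(_FREQ_LOG10.mean())
DEFAULT_PHASE_EFFECTS = tuple(float(v) for v in _FREQ_LOG10 - _FREQ_LOG10.mean())


@dataclass
class MetricSimParams:
    """Parameters of the metric-level simulator (log10 scale throughout)."""

    mu: float = DEFAULT_MU
    phase_effects: tuple[float, ...] = DEFAULT_PHASE_EFFECTS
    sigma2_group: float = DEFAULT_SIGMA2_GROUP
    sigma2_animal: float = DEFAULT_SIGMA2_ANIMAL
    sigma2_group_phase: float = DEFAULT_SIGMA2_GROUP_PHASE
    sigma2_residual: float = DEFAULT_SIGMA2_RESIDUAL
    n_g: int = 6
    n_n: int = 5
    n_p: int = 3

    def __post_init__(self) -> None:
        for name in ("sigma2_group", "sigma2_animal", "sigma2_group_phase", "sigma2_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.phase_effects) != self.n_p:
            raise ValueError("need one phase effect per phase")
        if abs(sum(self.phase_effects)) > 1e-9:
            raise ValueError("phase effects must sum to 0 (identifiability convention)")


@dataclass
class SimulatedMetrics:
    """Metric-level draw: the log10 response grid and a long-format table."""

    y: np.ndarray                      # (n_g, n_n, n_p), log10 scale
    frame: pd.DataFrame                # group_id, animal, phase, value_log10, value
    params: MetricSimParams


def simulate_metrics(params: MetricSimParams, seed) -> SimulatedMetrics:
    """Draw one balanced dataset from the mixed model.

    ``y[g,a,p] = mu + phase_p + G_g + GP_gp + A_a(g) + e_gap`` with
    independent normal effects at the stated variances; the long table also
    carries the back-transformed value ``10**y``.  Deterministic for a given
    seed (PCG64 via :func:`numpy.random.default_rng`).
    """
    rng = np.random.default_rng(seed)
    p = params
    G = rng.normal(0.0, math.sqrt(p.sigma2_group), size=p.n_g)
    A = rng.normal(0.0, math.sqrt(p.sigma2_animal), size=(p.n_g, p.n_n))
    GP = rng.normal(0.0, math.sqrt(p.sigma2_group_phase), size=(p.n_g, p.n_p))
    e = rng.normal(0.0, math.sqrt(p.sigma2_residual), size=(p.n_g, p.n_n, p.n_p))
    y = (p.mu + np.asarray(p.phase_effects)[None, None, :]
         + G[:, None, None] + GP[:, None, :] + A[:, :, None] + e)
    groups = [f"g{i + 1}" for i in range(p.n_g)]
    phases = ["1", "2a", "2b"][:p.n_p] if p.n_p <= 3 else [str(i + 1) for i in range(p.n_p)]
    idx = pd.MultiIndex.from_product(
        [groups, [f"c{j + 1}" for j in range(p.n_n)], phases],
        names=["group_id", "animal_short", "phase"])
    frame = pd.DataFrame(index=idx).reset_index()
    frame["animal"] = frame["group_id"] + frame["animal_short"]
    frame["value_log10"] = y.ravel()
    frame["value"] = 10.0 ** frame["value_log10"]
    frame = frame[["group_id", "animal", "phase", "value_log10", "value"]]
    return SimulatedMetrics(y=y, frame=frame, params=p)


@dataclass
class EventSimParams:
    """Parameters of the raw two-logger event simulator.

    The per-dyad bout rate on the log10 scale is
    ``log10(rate) = log10(base_rate_per_day * phase_multiplier) + G_g + GP_gp + D_d``
    with normal group, group-by-phase and dyad effects at the stated SDs.
    Bout durations are log-normal with a per-phase median and a common
    log-scale shape.  Each true bout is reported by up to two loggers, each
    with independent Gaussian start/end jitter and an independent miss
    probability; spurious directional detections of at most 1 s are added as
    a Poisson stream per dyad-day.

    Defaults are calibrated loosely to the cattle study's magnitudes:
    ~360 contacts per cow per day before the disturbance (4 resident
    partners -> 90 bouts/dyad/day) falling afterwards, and mean bout
    durations near 54/73/68 s across the three phases.
    """

    base_rate_per_day: float = 90.0
    phase_rate_multipliers: tuple[float, ...] = (1.0, 254.3 / 360.4, 228.6 / 360.4)
    unfamiliar_rate_factor: float = 0.5
    sd_log10_group: float = 0.05
    sd_log10_group_phase: float = 0.07
    sd_log10_dyad: float = 0.10
    # median = mean / exp(sigma^2/2); targets means 53.5/73.1/68.2 s at shape 0.8
    median_duration_s: tuple[float, ...] = (38.8, 53.1, 49.5)
    duration_sigma: float = 0.8
    jitter_sd_s: float = 5.0
    miss_prob: float = 0.05
    spurious_per_dyad_day: float = 2.0
    spurious_max_s: float = 1.0

    def __post_init__(self) -> None:
        if self.base_rate_per_day <= 0 or any(m < 0 for m in self.phase_rate_multipliers):
            raise ValueError("rates must be positive")
        if self.jitter_sd_s < 0:
            raise ValueError("jitter SD must be >= 0")
        if not 0 <= self.miss_prob < 1:
            raise ValueError("miss probability must be in [0, 1)")


def make_roster(design: StudyDesign, with_unfamiliar: bool = True) -> pd.DataFrame:
    """Roster for a simulated study: residents ``g<i>c<j>``, unfamiliar ``g<i>u1``."""
    rows = []
    for g in range(1, design.n_groups + 1):
        gid = f"g{g}"
        for a in range(1, design.residents_per_group + 1):
            rows.append({"group_id": gid, "animal_id": f"{gid}c{a}", "role": "resident"})
        if with_unfamiliar:
            rows.append({"group_id": gid, "animal_id": f"{gid}u1", "role": "unfamiliar"})
    return pd.DataFrame(rows, columns=ROSTER_COLUMNS)


def _dyads(roster: pd.DataFrame, group_id: str) -> list[tuple[str, str, bool]]:
    sub = roster[roster["group_id"] == group_id]
    animals = sorted(sub["animal_id"])
    role = dict(zip(sub["animal_id"], sub["role"]))
    out = []
    for i, a in enumerate(animals):
        for b in animals[i + 1:]:
            out.append((a, b, role[a] == "unfamiliar" or role[b] == "unfamiliar"))
    return out


@dataclass
class SimulatedContacts:
    """Event-level draw: raw logger records plus the ground-truth bout list."""

    records: pd.DataFrame              # RECORD_COLUMNS schema, shuffled row order
    truth_bouts: pd.DataFrame          # BOUT_COLUMNS schema, phase-assigned
    roster: pd.DataFrame
    design: StudyDesign
    params: EventSimParams


def simulate_contact_logs(params: EventSimParams, design: StudyDesign, seed,
                          unfamiliar_from_phase: int = 1) -> SimulatedContacts:
    """Simulate raw two-logger records for a full study.

    Unfamiliar-dyad contacts start at phase index ``unfamiliar_from_phase``
    (0-based; default 1, i.e. the second phase).  The ground truth is the
    noise-free event stream after reciprocal union, bout assembly and phase
    assignment — what an ideal pair of loggers would yield.
    """
    rng = np.random.default_rng(seed)
    roster = make_roster(design, with_unfamiliar=unfamiliar_from_phase < design.n_phases)
    log10_base = math.log10(params.base_rate_per_day)
    events = []
    for g in range(design.n_groups):
        gid = f"g{g + 1}"
        g_eff = rng.normal(0.0, params.sd_log10_group)
        gp_eff = rng.normal(0.0, params.sd_log10_group_phase, size=design.n_phases)
        for a, b, has_unfamiliar in _dyads(roster, gid):
            d_eff = rng.normal(0.0, params.sd_log10_dyad)
            for p_idx, phase in enumerate(design.phases):
                if has_unfamiliar and p_idx < unfamiliar_from_phase:
                    continue
                mult = params.phase_rate_multipliers[p_idx]
                factor = params.unfamiliar_rate_factor if has_unfamiliar else 1.0
                if mult * factor <= 0:
                    continue
                rate = 10.0 ** (log10_base + math.log10(mult * factor)
                                + g_eff + gp_eff[p_idx] + d_eff)
                n = rng.poisson(rate * phase.n_days)
                if n == 0:
                    continue
                starts = np.sort(rng.uniform(phase.start_s, phase.end_s, size=n))
                durs = rng.lognormal(math.log(params.median_duration_s[p_idx]),
                                     params.duration_sigma, size=n)
                events.append(pd.DataFrame({
                    "group_id": gid, "animal_a": a, "animal_b": b,
                    "start_s": starts, "end_s": starts + durs,
                }))
    true_events = (pd.concat(events, ignore_index=True) if events
                   else pd.DataFrame(columns=["group_id", "animal_a", "animal_b",
                                              "start_s", "end_s"]))

    # ground truth: ideal loggers -> union, bout assembly, phase split
    truth = assemble_bouts(
        symmetrize_reciprocal(pd.DataFrame({
            "group_id": true_events["group_id"],
            "logger_animal": true_events["animal_a"],
            "partner_animal": true_events["animal_b"],
            "start_s": true_events["start_s"],
            "duration_s": true_events["end_s"] - true_events["start_s"],
        })), design.separation_time)
    truth = assign_phases(truth, design)

    # two directional records per true event, jittered and possibly dropped
    record_frames = []
    for logger_col, partner_col in ((0, 1), (1, 0)):
        n = len(true_events)
        start = true_events["start_s"].to_numpy() + rng.normal(0, params.jitter_sd_s, n)
        end = true_events["end_s"].to_numpy() + rng.normal(0, params.jitter_sd_s, n)
        keep = (rng.uniform(size=n) >= params.miss_prob) & (end > start)
        ab = true_events[["animal_a", "animal_b"]].to_numpy()
        record_frames.append(pd.DataFrame({
            "group_id": true_events["group_id"].to_numpy()[keep],
            "logger_animal": ab[keep, logger_col],
            "partner_animal": ab[keep, partner_col],
            "start_s": start[keep],
            "duration_s": (end - start)[keep],
        }))

    # spurious sub-second detections, one directional record each
    if params.spurious_per_dyad_day > 0:
        span_days = sum(p.n_days for p in design.phases)
        spur = []
        for g in range(design.n_groups):
            gid = f"g{g + 1}"
            for a, b, _ in _dyads(roster, gid):
                n = rng.poisson(params.spurious_per_dyad_day * span_days)
                if n == 0:
                    continue
                t = rng.uniform(0.0, span_days * DAY_SECONDS, size=n)
                direction = rng.uniform(size=n) < 0.5
                spur.append(pd.DataFrame({
                    "group_id": gid,
                    "logger_animal": np.where(direction, a, b),
                    "partner_animal": np.where(direction, b, a),
                    "start_s": t,
                    "duration_s": rng.uniform(0.1, params.spurious_max_s, size=n),
                }))
        record_frames += spur

    record_frames = [f for f in record_frames if len(f)]
    records = (pd.concat(record_frames, ignore_index=True) if record_frames
               else pd.DataFrame(columns=RECORD_COLUMNS))
    records = records.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(2 ** 31))).reset_index(drop=True)[RECORD_COLUMNS]
    return SimulatedContacts(records=records, truth_bouts=truth[BOUT_COLUMNS],
                             roster=roster, design=design, params=params)


@dataclass
class StudyBundle:
    """A complete simulated study ready for the full pipeline."""

    records: pd.DataFrame
    roster: pd.DataFrame
    truth_bouts: pd.DataFrame
    design: StudyDesign
    params: EventSimParams
    paths: dict = field(default_factory=dict)


def exemplar_study_dataset(seed, out_dir=None, scale: float = 1.0) -> StudyBundle:
    """Simulate the full replicated disturbance study.

    Six groups of five residents, one unfamiliar animal per group from the
    second phase, three 6-day phases, contact frequency dropping and bout
    duration rising after the disturbance.  ``scale`` multiplies the base
    contact rate (< 1 gives a lighter dataset with the same structure).
    When ``out_dir`` is given, writes ``contacts.csv``, ``roster.csv``,
    ``truth_bouts.csv`` and ``config.yaml`` in the pipeline's CSV dialects.
    """
    design = StudyDesign()
    params = EventSimParams(base_rate_per_day=90.0 * scale)
    sim = simulate_contact_logs(params, design, seed, unfamiliar_from_phase=1)
    bundle = StudyBundle(records=sim.records, roster=sim.roster,
                             truth_bouts=sim.truth_bouts, design=design, params=params)
    if out_dir is not None:
        import pathlib
        import yaml
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.paths = {
            "contacts": str(out / "contacts.csv"),
            "roster": str(out / "roster.csv"),
            "truth_bouts": str(out / "truth_bouts.csv"),
            "config": str(out / "config.yaml"),
        }
        sim.records.to_csv(bundle.paths["contacts"], index=False)
        sim.roster.to_csv(bundle.paths["roster"], index=False)
        sim.truth_bouts.to_csv(bundle.paths["truth_bouts"], index=False)
        cfg = {
            "design": {
                "n_groups": design.n_groups,
                "residents_per_group": design.residents_per_group,
                "phases": [{"label": p.label, "first_day": p.first_day,
                            "last_day": p.last_day} for p in design.phases],
                "separation_time": design.separation_time,
                "min_contact_duration": design.min_contact_duration,
                "boundary_policy": design.boundary_policy,
            },
        }
        with open(bundle.paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
    return bundle


def metrics_sim_defaults_for(metric: str = "freq_per_day") -> MetricSimParams:
    """Metric-level parameter sets with the published component magnitudes."""
    table2 = {
        "freq_per_day": (0.0047, 0.0129),
        "mean_dur": (0.0060, 0.0094),
        "total_dur_per_day": (0.0130, 0.0041),
        "degree": (0.0055, 0.0042),
    }
    mus = {"freq_per_day": _FREQ_LOG10, "degree": np.log10([2460.4, 1766.0, 1671.1]),
           "mean_dur": np.log10([53.5, 73.1, 68.2]),
           "total_dur_per_day": np.log10([19229.9, 18534.3, 15558.7])}
    s2_gp, s2_e = table2[metric]
    logm = mus[metric]
    return MetricSimParams(
        mu=float(logm.mean()),
        phase_effects=tuple(float(v) for v in logm - logm.mean()),
        sigma2_group_phase=s2_gp, sigma2_residual=s2_e)


def null_params(base: MetricSimParams | None = None) -> MetricSimParams:
    """The same model with all phase effects removed (for type-I error checks)."""
    base = base or MetricSimParams()
    return replace(base, phase_effects=tuple(0.0 for _ in range(base.n_p)))
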