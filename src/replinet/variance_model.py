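"""Balanced mixed-model analysis of per-animal per-phase contact metrics.

The experimental treatment (phase) is applied to whole groups, so the unit of
replication is the group and animals are subsamples.  On the log10 scale the
model for metric value :math:`y_{gap}` of animal *a* in group *g* during
phase *p* is

.. math::

    y_{gap} = \\mu + \\pi_p + G_g + (G\\pi)_{gp} + A_{a(g)} + e_{gap},

with fixed phase effects :math:`\\pi_p` and independent normal random effects
for group (:math:`\\sigma^2_G`), group-by-phase (:math:`\\sigma^2_{GP}`,
between-group variation in the *change* of behaviour), animal within group
(:math:`\\sigma^2_A`), and residual (:math:`\\sigma^2_e`, within-group
variation in the change of behaviour).

For a complete balanced table the REML estimates (when interior) coincide
with the classical expected-mean-square solutions, so this module estimates
components in closed form from the balanced ANOVA decomposition:

* :math:`\\hat\\sigma^2_e = MS_{res}`
* :math:`\\hat\\sigma^2_{GP} = (MS_{G\\times P} - MS_{res}) / n_n`
* :math:`\\hat\\sigma^2_A = (MS_{A(G)} - MS_{res}) / n_p`
* :math:`\\hat\\sigma^2_G = (MS_G - MS_{G\\times P} - MS_{A(G)} + MS_{res}) / (n_n n_p)`

The phase effect is tested with :math:`F = MS_{phase} / MS_{G\\times P}` on
:math:`(n_p-1, (n_g-1)(n_p-1))` degrees of freedom, with Wald statistic
:math:`W = (n_p-1)F`.  Pairwise phase differences use the standard error of
a difference from the design formula
:math:`\\mathrm{SED} = \\sqrt{2\\sigma^2_{GP}/n_g + 2\\sigma^2_e/(n_g n_n)}`.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats

from .design_power import predicted_sed

logger = logging.getLogger(__name__)

STRATA = ("groups", "animals_within_groups", "phase", "group_by_phase", "residual")


class UnbalancedDataError(ValueError):
    """Raised when the closed-form path receives an incomplete/unbalanced table.

    The balanced decomposition is only valid for complete tables; unbalanced
    data need a general iterative REML fit, which is outside this module's
    core path (a generic REML cross-check harness lives in the test suite).
    """


@dataclass
class ResponseTable:
    """log10-scale responses on a complete (n_g, n_n, n_p) grid."""

    y: np.ndarray
    groups: tuple[str, ...]
    animals: tuple[tuple[str, ...], ...]  # per group
    phases: tuple[str, ...]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 3:
            raise ValueError("response table must be (n_g, n_n, n_p)")
        if not np.isfinite(self.y).all():
            raise UnbalancedDataError("response table has missing or non-finite cells")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.y.shape


@dataclass
class AnovaTable:
    """Balanced five-stratum ANOVA: df, SS and MS per stratum."""

    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]
    n_g: int
    n_n: int
    n_p: int

    @property
    def total_ss(self) -> float:
        return sum(self.ss.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"df": self.df, "ss": self.ss, "ms": self.ms}).loc[list(STRATA)]


@dataclass
class VarianceComponents:
    """Estimated variance components on the log10 scale."""

    sigma2_group: float
    sigma2_animal: float
    sigma2_group_phase: float
    sigma2_residual: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class PhaseTest:
    wald_W: float
    F_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass
class PhaseEffectResult:
    """Phase fixed-effect summary: overall test, pairwise contrasts, back-transformed means."""

    phase_labels: tuple[str, ...]
    phase_means: np.ndarray            # log10 scale
    test: PhaseTest
    pairwise: pd.DataFrame             # phase_i, phase_j, difference, sed, t, df, p
    backtransformed: pd.DataFrame      # phase, mean, lower95, upper95 (original scale)
    max_mean_difference: float         # max |pairwise difference|, log10 scale


def log10_transform(values, offset: float = 0.0) -> np.ndarray:
    """Base-10 log transform with an optional additive offset.

    Raises on non-positive values when ``offset`` is 0, naming the first
    offending flat index.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    arr = np.asarray(values, dtype=float)
    shifted = arr + offset
    bad = ~(shifted > 0)
    if bad.any():
        idx = int(np.flatnonzero(bad.ravel())[0])
        raise ValueError(
            f"non-positive value {arr.ravel()[idx]!r} at flat index {idx}; "
            "use a positive offset or exclude zero-metric animals")
    return np.log10(shifted)


def response_table(metrics: pd.DataFrame, metric: str, offset: float = 0.0,
                   drop_zero: bool = False) -> ResponseTable:
    """Pivot a long metrics table into a complete balanced log10 grid.

    ``drop_zero`` excludes zero-valued animal-phase rows (with a warning)
    before the transform; if that breaks balance an
    :class:`UnbalancedDataError` is raised.
    """
    if metric not in metrics.columns:
        raise KeyError(metric)
    tab = metrics[["group_id", "animal", "phase", metric]].copy()
    if drop_zero:
        zero = tab[metric] <= 0
        if zero.any():
            dropped = tab.loc[zero, ["animal", "phase"]].to_records(index=False).tolist()
            warnings.warn(f"dropping {int(zero.sum())} zero-metric cells: {dropped[:5]}")
            tab = tab[~zero]
    wide = tab.pivot_table(index=["group_id", "animal"], columns="phase",
                           values=metric, aggfunc="first", sort=True)
    if wide.isna().any().any():
        raise UnbalancedDataError(
            "incomplete animal-by-phase table; the closed-form path needs balanced "
            "data — fit unbalanced data with a general REML tool instead")
    groups = tuple(dict.fromkeys(wide.index.get_level_values(0)))
    animals = tuple(tuple(a for g2, a in wide.index if g2 == g) for g in groups)
    n_per_group = {len(a) for a in animals}
    if len(n_per_group) != 1:
        raise UnbalancedDataError("groups have unequal numbers of animals")
    phases = tuple(wide.columns)
    try:
        y = log10_transform(wide.to_numpy(), offset)
    except ValueError as err:
        bad = np.flatnonzero(~((wide.to_numpy() + offset) > 0).ravel())
        if bad.size:
            r, c = divmod(int(bad[0]), len(phases))
            raise ValueError(f"non-positive {metric!r} for animal "
                             f"{wide.index[r][1]!r} in phase {phases[c]!r}") from err
        raise
    n_g, n_n = len(groups), n_per_group.pop()
    return ResponseTable(y.reshape(n_g, n_n, len(phases)), groups, animals, phases)


def anova_decompose(y) -> AnovaTable:
    """Balanced five-stratum decomposition of a (n_g, n_n, n_p) response array.

    Strata: groups (df ``n_g-1``), animals within groups (``n_g(n_n-1)``),
    phase (``n_p-1``), group-by-phase (``(n_g-1)(n_p-1)``) and residual
    (``n_g(n_n-1)(n_p-1)``); sums of squares add to the total corrected SS.
    """
    if isinstance(y, ResponseTable):
        y = y.y
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise UnbalancedDataError("expected a complete (n_g, n_n, n_p) array")
    if not np.isfinite(y).all():
        raise UnbalancedDataError("missing cells; the closed-form path needs balanced data")
    n_g, n_n, n_p = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))           # group means
    m_ga = y.mean(axis=2)               # animal means
    m_p = y.mean(axis=(0, 1))           # phase means
    m_gp = y.mean(axis=1)               # group-by-phase cell means

    ss = {
        "groups": n_n * n_p * float(((m_g - grand) ** 2).sum()),
        "animals_within_groups": n_p * float(((m_ga - m_g[:, None]) ** 2).sum()),
        "phase": n_g * n_n * float(((m_p - grand) ** 2).sum()),
        "group_by_phase": n_n * float(
            ((m_gp - m_g[:, None] - m_p[None, :] + grand) ** 2).sum()),
        "residual": float(
            ((y - m_ga[:, :, None] - m_gp[:, None, :] + m_g[:, None, None]) ** 2).sum()),
    }
    df = {
        "groups": n_g - 1,
        "animals_within_groups": n_g * (n_n - 1),
        "phase": n_p - 1,
        "group_by_phase": (n_g - 1) * (n_p - 1),
        "residual": n_g * (n_n - 1) * (n_p - 1),
    }
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}
    return AnovaTable(df=df, ss=ss, ms=ms, n_g=n_g, n_n=n_n, n_p=n_p)


def estimate_components(anova: AnovaTable, constrain_nonneg: bool = False) -> VarianceComponents:
    """Closed-form component estimates by equating mean squares to expectations.

    Identical to REML for balanced data when all estimates are positive.
    Negative estimates are returned as-is unless ``constrain_nonneg``, which
    truncates them to 0 with a warning.
    """
    ms, n_n, n_p = anova.ms, anova.n_n, anova.n_p
    s2_e = ms["residual"]
    s2_gp = (ms["group_by_phase"] - s2_e) / n_n
    s2_a = (ms["animals_within_groups"] - s2_e) / n_p
    s2_g = (ms["groups"] - ms["group_by_phase"] - ms["animals_within_groups"] + s2_e) / (n_n * n_p)
    comps = VarianceComponents(s2_g, s2_a, s2_gp, s2_e)
    if constrain_nonneg:
        for name in ("sigma2_group", "sigma2_animal", "sigma2_group_phase"):
            if getattr(comps, name) < 0:
                warnings.warn(f"{name} estimate negative; truncated to 0")
                setattr(comps, name, 0.0)
    return comps


def phase_test(anova: AnovaTable) -> PhaseTest:
    """F-test of the phase fixed effect against the group-by-phase stratum.

    ``F = MS_phase / MS_group_by_phase`` on ``(n_p-1, (n_g-1)(n_p-1))`` df;
    the Wald statistic is ``W = (n_p-1) F``.
    """
    ms_gp = anova.ms["group_by_phase"]
    if not ms_gp > 0:
        raise ZeroDivisionError(
            "group-by-phase mean square is zero; the phase F-test is degenerate")
    df_num = anova.df["phase"]
    df_den = anova.df["group_by_phase"]
    F = anova.ms["phase"] / ms_gp
    p = float(stats.f.sf(F, df_num, df_den))
    return PhaseTest(wald_W=df_num * F, F_stat=F, df_num=df_num, df_den=df_den, p_value=p)


def pairwise_phases(y, components: VarianceComponents,
                    phase_labels: tuple[str, ...] | None = None,
                    bonferroni: bool = False) -> pd.DataFrame:
    """Pairwise phase-mean differences with SED-based t-tests.

    The SED comes from the design formula with the estimated group-by-phase
    and residual components; t-tests use ``(n_g-1)(n_p-1)`` df.  P-values are
    unadjusted unless ``bonferroni``.
    """
    if isinstance(y, ResponseTable):
        phase_labels = phase_labels or y.phases
        y = y.y
    y = np.asarray(y, dtype=float)
    n_g, n_n, n_p = y.shape
    labels = tuple(phase_labels) if phase_labels else tuple(str(i + 1) for i in range(n_p))
    means = y.mean(axis=(0, 1))
    sed = predicted_sed(max(components.sigma2_group_phase, 0.0),
                        max(components.sigma2_residual, 0.0), n_g, n_n)
    df = (n_g - 1) * (n_p - 1)
    n_tests = n_p * (n_p - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(n_p), 2):
        diff = float(means[i] - means[j])
        if sed > 0:
            t = diff / sed
            p = float(2 * stats.t.sf(abs(t), df))
        else:
            t = math.inf if diff else 0.0
            p = 0.0 if diff else 1.0
        if bonferroni:
            p = min(1.0, p * n_tests)
        rows.append({"phase_i": labels[i], "phase_j": labels[j], "difference": diff,
                     "sed": sed, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def phase_mean_se(components: VarianceComponents, n_g: int, n_n: int) -> float:
    """Standard error of one marginal phase mean under the full random-effects model."""
    return math.sqrt(
        (max(components.sigma2_group, 0.0) + max(components.sigma2_group_phase, 0.0)) / n_g
        + (max(components.sigma2_animal, 0.0) + max(components.sigma2_residual, 0.0)) / (n_g * n_n))


def backtransform(means, ses, df: int) -> pd.DataFrame:
    """Back-transform log10 means and 95% limits to the original scale.

    ``mean = 10**m`` with limits ``10**(m ± t_{0.975,df} SE)``; the interval
    is asymmetric on the original scale and always brackets the mean.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    ses = np.broadcast_to(np.asarray(ses, dtype=float), means.shape)
    tcrit = float(stats.t.ppf(0.975, df))
    return pd.DataFrame({
        "mean": 10.0 ** means,
        "lower95": 10.0 ** (means - tcrit * ses),
        "upper95": 10.0 ** (means + tcrit * ses),
    })


def fit_phase_effect(table: ResponseTable, constrain_nonneg: bool = False,
                     ) -> tuple[AnovaTable, VarianceComponents, PhaseEffectResult]:
    """Full analysis of one metric: ANOVA, components, phase test and summaries."""
    anova = anova_decompose(table)
    comps = estimate_components(anova, constrain_nonneg=constrain_nonneg)
    test = phase_test(anova)
    pairwise = pairwise_phases(table, comps)
    n_g, n_n, _ = table.shape
    means = table.y.mean(axis=(0, 1))
    se = phase_mean_se(comps, n_g, n_n)
    bt = backtransform(means, se, test.df_den)
    bt.insert(0, "phase", list(table.phases))
    result = PhaseEffectResult(
        phase_labels=table.phases, phase_means=means, test=test, pairwise=pairwise,
        backtransformed=bt,
        max_mean_difference=float(np.abs(pairwise["difference"]).max()) if len(pairwise) else 0.0)
    return anova, comps, result


@dataclass
class MetricFit:
    metric: str
    anova: AnovaTable
    components: VarianceComponents
    phase_effect: PhaseEffectResult


def fit_metrics_table(metrics: pd.DataFrame, metric_names=None, offset: float = 0.0,
                      constrain_nonneg: bool = False, drop_zero: bool = False,
                      ) -> dict[str, MetricFit]:
    """Fit the mixed model to each response metric of a long metrics table."""
    from .network_metrics import METRIC_NAMES
    fits = {}
    for metric in (metric_names or METRIC_NAMES):
        table = response_table(metrics, metric, offset=offset, drop_zero=drop_zero)
        anova, comps, effect = fit_phase_effect(table, constrain_nonneg=constrain_nonneg)
        fits[metric] = MetricFit(metric, anova, comps, effect)
    return fits


def fit_to_dict(fit: MetricFit) -> dict:
    """JSON-ready report of one metric's fit."""
    eff = fit.phase_effect
    return {
        "metric": fit.metric,
        "anova": {"df": fit.anova.df, "ss": fit.anova.ss, "ms": fit.anova.ms},
        "variance_components": fit.components.as_dict(),
        "phase_test": asdict(eff.test),
        "phase_means_log10": dict(zip(eff.phase_labels, map(float, eff.phase_means))),
        "pairwise": eff.pairwise.to_dict(orient="records"),
        "backtransformed": eff.backtransformed.to_dict(orient="records"),
        "max_mean_difference": eff.max_mean_difference,
    }


def report_json(fits: dict[str, MetricFit], indent: int = 2) -> str:
    return json.dumps({m: fit_to_dict(f) for m, f in fits.items()}, indent=indent)


def report_text(fits: dict[str, MetricFit]) -> str:
    """Human-readable model report."""
    lines = []
    for metric, fit in fits.items():
        eff = fit.phase_effect
        c = fit.components
        lines.append(f"== {metric} ==")
        lines.append(fit.anova.to_frame().to_string(float_format=lambda v: f"{v:.6g}"))
        lines.append(
            f"components: group={c.sigma2_group:.5f} animal={c.sigma2_animal:.5f} "
            f"group_phase={c.sigma2_group_phase:.5f} residual={c.sigma2_residual:.5f}")
        t = eff.test
        lines.append(f"phase effect: W={t.wald_W:.2f} F[{t.df_num},{t.df_den}]={t.F_stat:.2f} "
                     f"P={t.p_value:.3g}")
        for _, r in eff.pairwise.iterrows():
            lines.append(f"  {r['phase_i']} vs {r['phase_j']}: diff={r['difference']:+.4f} "
                         f"SED={r['sed']:.4f} t={r['t']:.2f} P={r['p']:.3g}")
        bt = eff.backtransformed
        for _, r in bt.iterrows():
            lines.append(f"  phase {r['phase']}: mean={r['mean']:.1f} "
                         f"({r['lower95']:.1f}-{r['upper95']:.1f})")
        lines.append("")
    return "\n".join(lines)
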