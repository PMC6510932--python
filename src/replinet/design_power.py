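"""Replication-design prediction: SED, LSD and detectability under re-design.

Given the two variance components that govern a difference between phase
means — the group-by-phase component :math:`\\sigma^2_{gp}` (between-group
variation in the change of behaviour) and the residual component
:math:`\\sigma^2_e` (within-group variation in the change) — the standard
error of the difference between two phase means in a design with
:math:`n_g` groups of :math:`n_n` animals is

.. math::

    \\mathrm{SED} = \\sqrt{\\frac{2\\sigma^2_{gp}}{n_g}
                          + \\frac{2\\sigma^2_e}{n_g n_n}}

and the least significant difference at the 5% level is
:math:`\\mathrm{LSD} = t_{0.975,\\nu} \\cdot \\mathrm{SED}` with
:math:`\\nu = (n_g-1)(n_p-1)` residual degrees of freedom from the
group-by-phase stratum.  A phase effect of a given size is declarable at the
5% level only when the observed maximum difference between phase means
exceeds the LSD, so tabulating SED/LSD over candidate ``(n_g, n_n)`` designs
shows how replication at the group level, versus group size, buys power.

Three standard scenario families are provided: vary the number of networks
at fixed group size, vary group size at a fixed number of networks, and vary
both with the total number of animals held fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

SCENARIO_FAMILIES = ("vary_replicates", "vary_group_size", "fixed_total")


@dataclass(frozen=True)
class DesignScenario:
    """One candidate design: ``n_g`` networks of ``n_n`` individuals, ``n_p`` phases."""

    n_g: int
    n_n: int
    n_p: int = 3
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_g < 2 or self.n_n < 2 or self.n_p < 2:
            raise ValueError("need n_g >= 2, n_n >= 2, n_p >= 2")


@dataclass
class DesignPrediction:
    """SED/LSD prediction for one scenario, with the 5%-level detectability flag."""

    n_g: int
    n_n: int
    sed: float
    df: int
    t_crit: float
    lsd: float
    detectable: bool | None  # None when no observed max difference was supplied
    label: str = ""


@dataclass
class ContributionBreakdown:
    """The two variance terms of the SED and their percentage split.

    ``c_gp = 2 sigma2_gp / n_g`` and ``c_e = 2 sigma2_e / (n_g n_n)`` are the
    between-group and within-group contributions to the squared SED;
    percentages sum to 100.
    """

    c_gp: float
    c_e: float
    pct_gp: float
    pct_e: float


def predicted_sed(sigma2_group_phase: float, sigma2_residual: float,
                  n_g: int, n_n: int) -> float:
    """Standard error of a difference between two phase means."""
    if sigma2_group_phase < 0 or sigma2_residual < 0:
        raise ValueError("variance components must be >= 0 (truncate or reject negatives)")
    if n_g < 1 or n_n < 1:
        raise ValueError("n_g and n_n must be >= 1")
    return math.sqrt(2.0 * sigma2_group_phase / n_g + 2.0 * sigma2_residual / (n_g * n_n))


def stratum_df(n_g: int, n_p: int = 3) -> int:
    """Residual degrees of freedom of the group-by-phase stratum, ``(n_g-1)(n_p-1)``."""
    if n_g < 2:
        raise ValueError("n_g must be >= 2: no between-group replication otherwise")
    if n_p < 2:
        raise ValueError("n_p must be >= 2")
    return (n_g - 1) * (n_p - 1)


def t_critical(df: int) -> float:
    """Two-sided 5% t critical value, ``t_{0.975, df}``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(0.975, df))


def lsd(sed: float, df: int) -> float:
    """Least significant difference at the 5% level, ``t_{0.975,df} * SED``."""
    if sed < 0:
        raise ValueError("sed must be >= 0")
    return t_critical(df) * sed


def contribution(sigma2_group_phase: float, sigma2_residual: float,
                 n_g: int, n_n: int) -> ContributionBreakdown:
    """Split the squared SED into its between- and within-group terms."""
    if sigma2_group_phase < 0 or sigma2_residual < 0:
        raise ValueError("variance components must be >= 0")
    c_gp = 2.0 * sigma2_group_phase / n_g
    c_e = 2.0 * sigma2_residual / (n_g * n_n)
    total = c_gp + c_e
    if total == 0:
        raise ZeroDivisionError("both variance components are zero; percentages undefined")
    return ContributionBreakdown(c_gp=c_gp, c_e=c_e,
                                 pct_gp=100.0 * c_gp / total, pct_e=100.0 * c_e / total)


def scenario_families(n_p: int = 3, total: int = 30,
                      families=SCENARIO_FAMILIES) -> list[DesignScenario]:
    """The three standard scenario families.

    * ``vary_replicates`` — 3..7 networks of 5 individuals;
    * ``vary_group_size`` — 6 networks of 3..7 individuals;
    * ``fixed_total`` — every ``(n_g, n_n)`` with ``n_g * n_n == total``,
      ``n_g >= 2`` and ``n_n >= 3``, in order of decreasing ``n_g``
      (for total 30: 10x3, 6x5, 5x6, 3x10, 2x15).
    """
    scenarios: list[DesignScenario] = []
    if "vary_replicates" in families:
        scenarios += [DesignScenario(g, 5, n_p, "vary_replicates") for g in range(7, 2, -1)]
    if "vary_group_size" in families:
        scenarios += [DesignScenario(6, n, n_p, "vary_group_size") for n in range(7, 2, -1)]
    if "fixed_total" in families:
        fixed = [DesignScenario(g, total // g, n_p, "fixed_total")
                 for g in range(total, 1, -1)
                 if total % g == 0 and g >= 2 and total // g >= 3]
        if not fixed:
            warnings.warn(f"no (n_g, n_n) split of total={total} meets n_g >= 2, n_n >= 3")
        scenarios += fixed
    return scenarios


def _component_pair(components) -> tuple[float, float]:
    if hasattr(components, "sigma2_group_phase"):
        return float(components.sigma2_group_phase), float(components.sigma2_residual)
    s2_gp, s2_e = components
    return float(s2_gp), float(s2_e)


def scenario_table(components, scenarios, max_mean_difference: float | None = None,
                   ) -> pd.DataFrame:
    """Predicted SED/LSD table over scenarios.

    ``components`` is either a fitted :class:`~replinet.variance_model.VarianceComponents`
    or a ``(sigma2_group_phase, sigma2_residual)`` pair (e.g. published
    values).  Full-precision values are carried in ``sed``/``t_crit``/``lsd``;
    ``*_2dp`` columns give the 2-decimal reporting form.  ``detectable`` is
    the strict comparison ``max_mean_difference > lsd`` (Y/N in rendering),
    or missing when no observed maximum difference is supplied.
    """
    s2_gp, s2_e = _component_pair(components)
    rows = []
    for sc in scenarios:
        sed_val = predicted_sed(s2_gp, s2_e, sc.n_g, sc.n_n)
        df = stratum_df(sc.n_g, sc.n_p)
        t = t_critical(df)
        lsd_val = t * sed_val
        rows.append({
            "label": sc.label, "n_g": sc.n_g, "n_n": sc.n_n,
            "sed": sed_val, "df": df, "t_crit": t, "lsd": lsd_val,
            "sed_2dp": round(sed_val, 2), "t_crit_2dp": round(t, 2),
            "lsd_2dp": round(lsd_val, 2),
            "detectable": (max_mean_difference > lsd_val)
            if max_mean_difference is not None else pd.NA,
        })
    return pd.DataFrame(rows)


def render_markdown(table: pd.DataFrame, behaviour: str = "") -> str:
    """Markdown rendering with the conventional column layout."""
    lines = []
    if behaviour:
        lines.append(f"**Behaviour: {behaviour}**\n")
    lines.append("| No of networks | No individuals per network | SED | Residual df | "
                 "t stat (5%) | Predicted LSD | Observed max mean difference > predicted LSD |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in table.iterrows():
        flag = "" if pd.isna(r["detectable"]) else ("Y" if r["detectable"] else "N")
        lines.append(f"| {r['n_g']} | {r['n_n']} | {r['sed_2dp']:.2f} | {r['df']} | "
                     f"{r['t_crit_2dp']:.2f} | {r['lsd_2dp']:.2f} | {flag} |")
    return "\n".join(lines)
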