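"""Culture physiology: growth, quotas, production rates and two-sample tests.

Implements the standard batch-culture arithmetic for coccolithophore
physiology experiments: specific growth rate from exponential-phase cell
densities, generations of growth, per-cell elemental quotas (POC, PON,
CaCO3) and their production rates, nutrient-utilization percentages, coccolith
morphometric summaries and unpaired (pooled-variance) t-tests between
treatments.  Group statistics are carried as (mean, sd, n) triples so tests
can be run directly from published summary tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "TTestResult",
    "growth_rate",
    "generations",
    "production_rate",
    "caco3_quota_from_icp",
    "nutrient_utilization",
    "pooled_t_test",
    "morphometry_summary",
    "summarize_culture",
]

#: oceanic molar Ca/Na ratio used for the residual-seawater calcium blank
CA_NA_SEAWATER = 0.0219


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± sample sd of n replicate measurements."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 replicates")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def growth_rate(c0: float, c1: float, dt: float) -> float:
    """Specific growth rate µ = ln(C1/C0)/Δt (day⁻¹) over the exponential phase."""
    if c0 <= 0 or c1 <= 0:
        raise ValueError("cell densities must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return math.log(c1 / c0) / dt


def generations(n0: float, n1: float) -> float:
    """Number of generations g = log2(N1/N0) between inoculation and harvest."""
    if n0 <= 0 or n1 <= 0:
        raise ValueError("cell densities must be positive")
    return math.log2(n1 / n0)


def production_rate(quota: float, mu: float) -> float:
    """Cellular production rate = quota × µ (pmol cell⁻¹ day⁻¹).

    For a cell pool at steady quota in exponential growth, the per-cell
    synthesis rate is the quota times the specific growth rate.
    """
    if quota < 0 or mu < 0:
        raise ValueError("quota and mu must be non-negative")
    return quota * mu


def caco3_quota_from_icp(
    ca_total: float,
    na_measured: float,
    ca_na_seawater: float = CA_NA_SEAWATER,
    cells_on_filter: float = 1,
) -> float:
    """CaCO3 quota (pmol cell⁻¹) from ICP-OES Ca with a Na-based seawater blank.

    Residual seawater on the filter contributes Ca in proportion to measured
    Na; the corrected coccolith Ca maps 1:1 onto CaCO3.  A correction
    exceeding the measured Ca marks a blank-dominated sample and floors the
    quota at zero (with a logged warning).
    """
    if min(ca_total, na_measured, ca_na_seawater) < 0 or cells_on_filter <= 0:
        raise ValueError("inputs must be non-negative; cells_on_filter positive")
    corrected = ca_total - na_measured * ca_na_seawater
    if corrected < 0:
        logger.warning(
            "seawater Ca blank (%.3g µmol) exceeds measured Ca (%.3g µmol); "
            "blank-dominated sample, quota floored at 0",
            na_measured * ca_na_seawater,
            ca_total,
        )
        return 0.0
    return corrected * 1e6 / cells_on_filter


def nutrient_utilization(initial: float, final: float) -> float:
    """Percent of a dissolved nutrient pool consumed over the incubation."""
    if initial <= 0:
        raise ValueError("initial concentration must be positive")
    return 100.0 * (initial - final) / initial


def pooled_t_test(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Unpaired equal-variance (pooled) two-sample t-test from summaries.

    df = n1 + n2 - 2; two-sided p from the t distribution.  Zero pooled
    variance with unequal means yields an infinite t (p = 0).
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    diff = g1.mean - g2.mean
    if se == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return TTestResult(t=t, df=df, p=1.0 if diff == 0 else 0.0)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p)


def morphometry_summary(measurements) -> GroupSummary:
    """Mean, sample sd (n-1 denominator) and n of a list of measurements."""
    x = np.asarray(list(measurements), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 measurements")
    return GroupSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def summarize_culture(
    culture: pd.DataFrame,
    quotas: pd.DataFrame | None = None,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-condition growth and production summary from daily counts.

    ``culture`` needs columns ``condition, replicate, day, cell_density``
    (``coccosphere_volume`` optional).  µ is fitted per replicate over
    ``window`` (default: full observed span) from the first/last densities,
    g over the same span.  ``quotas`` (columns ``condition, replicate,
    analyte, quota``) adds mean quotas and production = quota × µ.
    """
    rows = []
    for (cond, rep), grp in culture.groupby(["condition", "replicate"]):
        grp = grp.sort_values("day")
        if window is not None:
            grp = grp[(grp["day"] >= window[0]) & (grp["day"] <= window[1])]
        if len(grp) < 2:
            raise ValueError(f"condition {cond!r} replicate {rep!r}: need >= 2 days")
        first, last = grp.iloc[0], grp.iloc[-1]
        mu = growth_rate(first["cell_density"], last["cell_density"], last["day"] - first["day"])
        g = generations(first["cell_density"], last["cell_density"])
        row = {"condition": cond, "replicate": rep, "mu": mu, "generations": g}
        if "coccosphere_volume" in grp.columns:
            row["coccosphere_volume_final"] = float(last["coccosphere_volume"])
        if quotas is not None:
            sub = quotas[(quotas["condition"] == cond) & (quotas["replicate"] == rep)]
            for analyte, agrp in sub.groupby("analyte"):
                q = float(agrp["quota"].mean())
                row[f"quota_{analyte}"] = q
                row[f"production_{analyte}"] = production_rate(q, mu)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["condition", "replicate"]).reset_index(drop=True)
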