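"""First-order mercury methylation/demethylation kinetics.

The tracer model is the coupled two-compartment linear system

    d[MMHg]/dt = k_m [Hg(II)] - k_d [MMHg]

applied independently to each enriched-isotope pool: the methylation tracer
starts as pure inorganic 200Hg(II) and is followed through its product
MM200Hg, while the demethylation tracer starts as pure MM198Hg and is
followed through its loss.  Because incubations yield a single time point,
rate constants are estimated with the simplified (no back-reaction)
inversions

    k_m = -ln(1 - [MM200Hg]_t / [200Hg(II)]_0) / t
    k_d = -ln([MM198Hg]_t / [MM198Hg]_0) / t

Concentrations are in ng/L, time in days, rate constants in 1/day.

``TracerKineticsModel`` wraps a table of replicate incubations and
``fit()`` returns a ``TracerKineticsResults`` with per-replicate estimates,
per-site mean/SE summaries and between-site ANOVA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KineticParams",
    "TracerSpike",
    "TracerIncubation",
    "RateEstimate",
    "RateSummary",
    "simulate_coupled_tracers",
    "simulate_simplified_tracers",
    "estimate_km",
    "estimate_kd",
    "summarize_site_rates",
    "compare_sites_anova",
    "TracerKineticsModel",
    "TracerKineticsResults",
]


@dataclass(frozen=True)
class KineticParams:
    """Methylation (km) and demethylation (kd) rate constants, 1/day."""

    km: float
    kd: float

    def __post_init__(self) -> None:
        if self.km < 0 or self.kd < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass(frozen=True)
class TracerSpike:
    """Initial enriched-isotope additions, ng/L.

    ihg200_0 is the added inorganic 200Hg(II); mmhg198_0 the added MM198Hg.
    """

    ihg200_0: float
    mmhg198_0: float

    def __post_init__(self) -> None:
        if self.ihg200_0 <= 0 or self.mmhg198_0 <= 0:
            raise ValueError("spike concentrations must be positive")


@dataclass(frozen=True)
class TracerIncubation:
    """A single replicate incubation measured at one time point.

    ``censored`` marks an MM200Hg measurement recorded as below the
    detection limit (the stored value then equals the reported bound).
    """

    site_id: str
    replicate_id: str
    spike: TracerSpike
    mmhg200_t: float
    mmhg198_t: float
    t: float
    lod_mmhg: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("incubation time must be positive")
        if self.mmhg200_t < 0 or self.mmhg198_t < 0:
            raise ValueError("concentrations must be non-negative")
        if self.lod_mmhg <= 0:
            raise ValueError("detection limit must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """One replicate's rate-constant estimate, or a non-detect."""

    value: float | None
    kind: Literal["methylation", "demethylation"]
    replicate_id: str
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected and (self.value is None or self.value < 0):
            raise ValueError("detected estimate needs a non-negative value")


@dataclass(frozen=True)
class RateSummary:
    """Per-site mean and standard error over detected replicates."""

    site_id: str
    mean: float | None
    se: float | None
    n_detected: int
    n_total: int


def _check_time(t: float) -> None:
    if t < 0:
        raise ValueError("negative incubation time")


def _pool_solution(total: float, b0: float, km: float, kd: float, t: float) -> float:
    """MMHg compartment of one tracer pool at time t (closed form).

    The coupled system is linear with conserved total A+B; the MMHg
    compartment relaxes exponentially to its equilibrium total*km/(km+kd)
    at rate km+kd.
    """
    s = km + kd
    if s == 0.0:
        return b0
    b_eq = total * km / s
    return b_eq + (b0 - b_eq) * math.exp(-s * t)


def simulate_coupled_tracers(
    params: KineticParams, spike: TracerSpike, t: float
) -> tuple[float, float, float, float]:
    """Forward-simulate both tracer pools under the coupled model.

    Returns ``(mmhg200_t, ihg200_t, mmhg198_t, ihg198_t)``.  Mass is
    conserved exactly within each isotope pool.
    """
    _check_time(t)
    mm200 = _pool_solution(spike.ihg200_0, 0.0, params.km, params.kd, t)
    mm198 = _pool_solution(spike.mmhg198_0, spike.mmhg198_0, params.km, params.kd, t)
    return mm200, spike.ihg200_0 - mm200, mm198, spike.mmhg198_0 - mm198


def simulate_simplified_tracers(
    params: KineticParams, spike: TracerSpike, t: float
) -> tuple[float, float]:
    """Forward maps matching the single-time-point estimators exactly.

    Product formation ignores demethylation of newly formed MM200Hg and
    tracer loss ignores remethylation:
    ``mmhg200_t = ihg200_0 (1 - exp(-km t))``,
    ``mmhg198_t = mmhg198_0 exp(-kd t)``.
    """
    _check_time(t)
    mm200 = spike.ihg200_0 * -math.expm1(-params.km * t)
    mm198 = spike.mmhg198_0 * math.exp(-params.kd * t)
    return mm200, mm198


def estimate_km(inc: TracerIncubation) -> RateEstimate:
    """Methylation rate constant from one incubation.

    Measurements at or below the MMHg detection limit (or flagged censored)
    yield a non-detect.  A product concentration reaching the spike is
    physically impossible under the model and raises.
    """
    ratio = inc.mmhg200_t / inc.spike.ihg200_0
    if ratio >= 1.0:
        raise ValueError(
            f"MM200Hg ({inc.mmhg200_t}) >= spiked 200Hg(II) "
            f"({inc.spike.ihg200_0}): logarithm undefined"
        )
    if inc.censored or inc.mmhg200_t <= inc.lod_mmhg:
        return RateEstimate(None, "methylation", inc.replicate_id, detected=False)
    value = -math.log1p(-ratio) / inc.t
    return RateEstimate(value, "methylation", inc.replicate_id)


def estimate_kd(inc: TracerIncubation) -> RateEstimate:
    """Demethylation rate constant from one incubation.

    An apparent MMHg gain (measured above the spike) would imply a negative
    rate; it is clamped to zero with a warning since the decay model cannot
    represent it.
    """
    if inc.mmhg198_t <= 0:
        raise ValueError("MM198Hg at time t must be positive to estimate kd")
    value = -math.log(inc.mmhg198_t / inc.spike.mmhg198_0) / inc.t
    if value < 0:
        warnings.warn(
            f"replicate {inc.replicate_id}: apparent MM198Hg gain; kd clamped to 0",
            stacklevel=2,
        )
        value = 0.0
    return RateEstimate(value, "demethylation", inc.replicate_id)


def summarize_site_rates(
    estimates: list[RateEstimate],
    site_id: str,
    include_nondetect_as_zero: bool = False,
) -> RateSummary:
    """Mean and standard error (sd/sqrt(n)) of a site's replicate rates.

    By default only detected replicates enter the mean; alternatively
    non-detects can be counted as zeros.
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    n_total = len(estimates)
    if include_nondetect_as_zero:
        values = [e.value if e.detected else 0.0 for e in estimates]
    else:
        values = [e.value for e in estimates if e.detected]
    n_detected = sum(e.detected for e in estimates)
    if not values:
        return RateSummary(site_id, None, None, 0, n_total)
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return RateSummary(site_id, mean, se, n_detected, n_total)


def compare_sites_anova(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> tuple[float, float, dict[tuple[str, str], float]]:
    """One-way ANOVA across sites with Tukey HSD pairwise comparisons.

    Groups with fewer than two values are excluded with a warning; at least
    two usable groups are required.  Returns ``(F, p, pairwise_p)`` where
    ``pairwise_p`` maps site pairs to Tukey HSD p-values.
    """
    usable: dict[str, list[float]] = {}
    for site, values in groups.items():
        if len(values) < 2:
            warnings.warn(
                f"site {site!r} has < 2 detected values; excluded from ANOVA",
                stacklevel=2,
            )
        else:
            usable[site] = list(values)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 values")
    names = list(usable)
    samples = [usable[s] for s in names]
    f_stat, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pairwise = {
        (names[i], names[j]): float(tukey.pvalue[i, j])
        for i, j in combinations(range(len(names)), 2)
    }
    return float(f_stat), float(p), pairwise


# ---------------------------------------------------------------------------
# model / results interface


class TracerKineticsModel:
    """Tracer-incubation kinetics model over a table of replicates.

    Parameters
    ----------
    incubations
        Replicate incubations, typically three per site.
    """

    def __init__(self, incubations: list[TracerIncubation]):
        if not incubations:
            raise ValueError("no incubations supplied")
        self.incubations = list(incubations)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TracerKineticsModel":
        """Build from a table with columns site_id, replicate_id, ihg200_0,
        mmhg198_0, mmhg200_t, mmhg198_t, t_days, lod_mmhg (and optionally
        mmhg200_censored)."""
        required = {
            "site_id",
            "replicate_id",
            "ihg200_0",
            "mmhg198_0",
            "mmhg200_t",
            "mmhg198_t",
            "t_days",
            "lod_mmhg",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tracer table missing columns: {sorted(missing)}")
        incs = []
        for row in df.itertuples(index=False):
            incs.append(
                TracerIncubation(
                    site_id=str(row.site_id),
                    replicate_id=str(row.replicate_id),
                    spike=TracerSpike(float(row.ihg200_0), float(row.mmhg198_0)),
                    mmhg200_t=float(row.mmhg200_t),
                    mmhg198_t=float(row.mmhg198_t),
                    t=float(row.t_days),
                    lod_mmhg=float(row.lod_mmhg),
                    censored=bool(getattr(row, "mmhg200_censored", False)),
                )
            )
        return cls(incs)

    def simulate(
        self, params_by_site: dict[str, KineticParams], mode: str = "coupled"
    ) -> pd.DataFrame:
        """Forward-simulate noise-free measurements for this design."""
        rows = []
        for inc in self.incubations:
            p = params_by_site[inc.site_id]
            if mode == "coupled":
                mm200, _, mm198, _ = simulate_coupled_tracers(p, inc.spike, inc.t)
            elif mode == "simplified":
                mm200, mm198 = simulate_simplified_tracers(p, inc.spike, inc.t)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            rows.append(
                {
                    "site_id": inc.site_id,
                    "replicate_id": inc.replicate_id,
                    "mmhg200_t": mm200,
                    "mmhg198_t": mm198,
                }
            )
        return pd.DataFrame(rows)

    def fit(
        self, include_nondetect_as_zero: bool = False, alpha: float = 0.05
    ) -> "TracerKineticsResults":
        """Estimate km and kd per replicate and summarize per site."""
        rows = []
        km_by_site: dict[str, list[RateEstimate]] = {}
        kd_by_site: dict[str, list[RateEstimate]] = {}
        for inc in self.incubations:
            km = estimate_km(inc)
            kd = estimate_kd(inc)
            km_by_site.setdefault(inc.site_id, []).append(km)
            kd_by_site.setdefault(inc.site_id, []).append(kd)
            rows.append(
                {
                    "site_id": inc.site_id,
                    "replicate_id": inc.replicate_id,
                    "km": km.value if km.detected else np.nan,
                    "km_detected": km.detected,
                    "kd": kd.value,
                }
            )
        estimates = pd.DataFrame(rows)
        summaries = {
            "km": [
                summarize_site_rates(v, s, include_nondetect_as_zero)
                for s, v in km_by_site.items()
            ],
            "kd": [
                summarize_site_rates(v, s, include_nondetect_as_zero)
                for s, v in kd_by_site.items()
            ],
        }
        anova: dict[str, tuple | None] = {}
        for kind, by_site in (("km", km_by_site), ("kd", kd_by_site)):
            groups = {
                s: [e.value for e in ests if e.detected]
                for s, ests in by_site.items()
            }
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    anova[kind] = compare_sites_anova(groups, alpha=alpha)
            except ValueError:
                anova[kind] = None
        return TracerKineticsResults(self, estimates, summaries, anova)


@dataclass
class TracerKineticsResults:
    """Fitted rate constants with replicate detail, site summaries and ANOVA."""

    model: TracerKineticsModel
    estimates: pd.DataFrame
    summaries: dict[str, list[RateSummary]] = field(repr=False)
    anova: dict[str, tuple | None] = field(repr=False)

    def site_table(self) -> pd.DataFrame:
        rows = []
        for kind, summary_list in self.summaries.items():
            for s in summary_list:
                rows.append(
                    {
                        "site_id": s.site_id,
                        "rate": kind,
                        "mean_per_day": s.mean,
                        "se_per_day": s.se,
                        "n_detected": s.n_detected,
                        "n_total": s.n_total,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["Tracer kinetics fit", "=" * 19, ""]
        table = self.site_table()
        lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        for kind in ("km", "kd"):
            res = self.anova.get(kind)
            if res is None:
                lines.append(f"\n{kind}: ANOVA not computed (fewer than 2 usable sites)")
            else:
                f_stat, p, pairwise = res
                lines.append(f"\n{kind}: one-way ANOVA F = {f_stat:.3g}, p = {p:.3g}")
                for (a, b), pv in pairwise.items():
                    lines.append(f"  Tukey HSD {a} vs {b}: p = {pv:.3g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of site means with SE error bars (one panel per rate)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(8, 3.5))
        for axis, kind in zip(np.ravel(ax), ("km", "kd")):
            summ = [s for s in self.summaries[kind] if s.mean is not None]
            sites = [s.site_id for s in summ]
            means = [s.mean for s in summ]
            ses = [s.se for s in summ]
            axis.bar(sites, means, yerr=ses, capsize=3)
            axis.set_ylabel(f"{kind} (1/day)")
        return ax
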