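"""Derived pharmacokinetic quantities and structure-activity correlations.

From a fitted kinetic model this module derives the exposure metrics used to
compare particles: area under the concentration-time curve (AUC, 0-24 h by
default), elimination half-life, peak concentration and time of peak.  Across
particles it computes the dose-normalised i.p./i.v. AUC ratio (absolute
bioavailability of the intraperitoneal route), ROI-to-heart concentration
ratios (heart as the plasma surrogate), and the power-law dependence of AUC
on particle core diameter, AUC = lambda * size^b, fitted by ordinary least
squares on log-log scale.  Group comparisons use one-way ANOVA with Tukey HSD
post-hoc pairs and unpaired t-tests at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .fitting import ConcentrationSeries, ModelFit
from .models import (
    ContractError,
    DomainError,
    KineticParams,
    ModelVariant,
    auc_closed_form,
    eval_variant,
    half_life,
    time_of_peak,
)

__all__ = [
    "PKSummary",
    "PowerLawSAR",
    "BioavailabilityResult",
    "GroupComparisonReport",
    "summarize_fit",
    "total_excreted_series",
    "bioavailability_fraction",
    "roi_to_heart_ratio",
    "power_law_fit",
    "compare_groups",
]


@dataclass
class PKSummary:
    """Derived PK quantities for one fitted subject x ROI curve.

    ``t_half`` and ``k_out`` are absent for the uptake-only variant (no
    elimination phase within the study window); ``k_in`` is absent for the
    washout variant.  For uptake-only curves the asymptote is reported as
    C_max with t_max set to the AUC horizon (the observable maximum within
    the window), with a note recording why.
    """

    subject_id: str
    roi: str
    variant: ModelVariant
    AUC_0_24: float
    t_half: Optional[float]
    k_in: Optional[float]
    k_out: Optional[float]
    C_max: float
    t_max: Optional[float]
    A: float
    horizon: float = 24.0
    notes: str = ""


@dataclass
class PowerLawSAR:
    """Power-law structure-activity fit AUC = lambda * size^exponent.

    ``exponent`` is the signed slope of the log-log regression (negative for
    systemic circulation and source-like organs, positive for sink-like
    organs); ``n`` is its magnitude as conventionally reported.
    """

    organ_class: str
    lam: float
    exponent: float
    n: float
    se_exponent: float
    r_squared: float
    n_points: int

    def exponent_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the signed exponent."""
        dof = self.n_points - 2
        if dof <= 0:
            return (-math.inf, math.inf)
        tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
        return (self.exponent - tcrit * self.se_exponent,
                self.exponent + tcrit * self.se_exponent)


@dataclass
class BioavailabilityResult:
    """Dose-normalised i.p./i.v. AUC ratio for one particle, in percent."""

    particle_id: str
    F: float
    auc_ip: float
    auc_iv: float
    dose_ip: float = 1.0
    dose_iv: float = 1.0


def summarize_fit(fit: ModelFit, horizon: float = 24.0) -> PKSummary:
    """Derive AUC, half-life, C_max and t_max from a converged fit."""
    if not fit.converged:
        raise ContractError("cannot summarise an unconverged fit")
    v, p = fit.variant, fit.params
    series = fit.series
    subject = series.subject_id if series is not None else ""
    roi = series.roi if series is not None else ""
    auc = auc_closed_form(v, p, T=horizon)
    notes = ""

    if v is ModelVariant.MONO_DECAY:
        k_out = p.get("k_out")
        summary = PKSummary(subject, roi, v, auc, half_life(k_out), None,
                            k_out, C_max=p.get("A"), t_max=0.0, A=p.get("A"),
                            horizon=horizon)
    elif v is ModelVariant.DOUBLE_EXP:
        k_in, k_out = p.get("k_in"), p.get("k_out")
        t_max = time_of_peak(k_in, k_out)
        c_max = float(eval_variant(v, p, t_max))
        summary = PKSummary(subject, roi, v, auc, half_life(k_out), k_in,
                            k_out, C_max=c_max, t_max=t_max, A=p.get("A"),
                            horizon=horizon)
    elif v is ModelVariant.UPTAKE_ONLY:
        notes = ("no elimination phase within the study window: t_half and "
                 "k_out absent; C_max reported as the asymptote A, t_max as "
                 "the horizon")
        summary = PKSummary(subject, roi, v, auc, None, p.get("k_in"), None,
                            C_max=p.get("A"), t_max=horizon, A=p.get("A"),
                            horizon=horizon, notes=notes)
    elif v is ModelVariant.EXCRETION:
        notes = ("cumulative excretion curve: amplitude is the total excreted "
                 "fraction U_t, rate is k_u reported in the k_in slot")
        summary = PKSummary(subject, roi, v, auc, None, p.get("k_u"), None,
                            C_max=p.get("U_t"), t_max=horizon, A=p.get("U_t"),
                            horizon=horizon, notes=notes)
    else:  # pragma: no cover
        raise ContractError(f"unknown variant {v!r}")
    return summary


def total_excreted_series(whole_body: ConcentrationSeries) -> ConcentrationSeries:
    """Cumulative excreted activity: 100 %ID minus whole-body activity.

    Whole-body retention starts at the full injected dose; whatever has left
    the body (renal plus hepatobiliary routes combined) is the complement.
    """
    if whole_body.value_kind != "activity":
        raise ContractError("whole-body series must carry value_kind='activity'")
    if np.any(whole_body.values > 100.0):
        raise DomainError("whole-body activity exceeds the injected dose "
                          "(values must be <= 100 %ID)")
    return ConcentrationSeries(
        subject_id=whole_body.subject_id, group_id=whole_body.group_id,
        roi="total_excretion", route=whole_body.route,
        times=whole_body.times.copy(), values=100.0 - whole_body.values,
        value_kind="activity", excluded=whole_body.excluded,
        exclusion_reason=whole_body.exclusion_reason)


def bioavailability_fraction(auc_ip: float, auc_iv: float,
                             dose_ip: float = 1.0, dose_iv: float = 1.0) -> float:
    """Absolute bioavailability of the i.p. route, percent.

    F = 100 * (AUC_ip / dose_ip) / (AUC_iv / dose_iv); the i.v. route is
    100% bioavailable by definition.  Doses default to 1 because %ID-scaled
    data are already dose-normalised.
    """
    for name, val in (("auc_ip", auc_ip), ("auc_iv", auc_iv),
                      ("dose_ip", dose_ip), ("dose_iv", dose_iv)):
        if val <= 0:
            raise DomainError(f"{name} must be > 0, got {val}")
    return 100.0 * (auc_ip / dose_ip) / (auc_iv / dose_iv)


def roi_to_heart_ratio(roi_series: ConcentrationSeries,
                       heart_series: ConcentrationSeries
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Element-wise ROI / heart concentration ratio over time.

    The heart ROI stands in for plasma; for source-like organs the ratio is
    approximately constant over time (blood-pool coupling), while sink-like
    organs show an increasing ratio.  Returns ``(times, ratio, undefined)``
    where ``undefined`` flags points with zero heart concentration (ratio NaN
    there).
    """
    if roi_series.subject_id != heart_series.subject_id:
        raise ContractError("ROI and heart series must come from one subject")
    if (len(roi_series) != len(heart_series)
            or not np.allclose(roi_series.times, heart_series.times)):
        raise ContractError("ROI and heart series must share the time grid")
    heart = heart_series.values
    undefined = heart <= 0
    ratio = np.full_like(heart, np.nan, dtype=float)
    ratio[~undefined] = roi_series.values[~undefined] / heart[~undefined]
    return roi_series.times.copy(), ratio, undefined


def power_law_fit(sizes: Sequence[float], aucs: Sequence[float],
                  organ_class: str = "", method: str = "loglog_ols"
                  ) -> PowerLawSAR:
    """Fit AUC = lambda * size^b across a particle panel.

    Default: ordinary least squares of log AUC on log size (exact for
    noise-free power laws, and the natural scale for multiplicative noise).
    ``method='nls'`` refits on the original scale by nonlinear least squares
    for sensitivity analysis, seeded from the log-log estimates.
    """
    sizes = np.asarray(sizes, dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    if sizes.shape != aucs.shape or sizes.ndim != 1:
        raise ContractError("sizes and aucs must be 1-D and equal length")
    if len(sizes) < 3:
        raise ContractError("power-law fit needs >= 3 (size, AUC) pairs")
    if np.any(sizes <= 0) or np.any(aucs <= 0):
        raise ContractError("sizes and AUCs must all be positive")

    x, y = np.log(sizes), np.log(aucs)
    n_pts = len(x)
    slope, intercept, r_value, _, se_slope = stats.linregress(x, y)
    lam, b, se_b = math.exp(intercept), float(slope), float(se_slope)
    r2 = float(r_value ** 2)

    if method == "nls":
        from scipy.optimize import curve_fit
        popt, pcov = curve_fit(lambda s, lam_, b_: lam_ * s ** b_, sizes, aucs,
                               p0=[lam, b], maxfev=10000)
        lam, b = float(popt[0]), float(popt[1])
        se_b = float(math.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.nan
        resid = aucs - lam * sizes ** b
        ss_tot = float(np.sum((aucs - aucs.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        r2 = min(max(r2, 0.0), 1.0)
    elif method != "loglog_ols":
        raise ContractError(f"unknown method {method!r}")

    return PowerLawSAR(organ_class=organ_class, lam=lam, exponent=b, n=abs(b),
                       se_exponent=se_b, r_squared=r2, n_points=n_pts)


@dataclass
class GroupComparisonReport:
    """One-way ANOVA, Tukey HSD pairs and requested unpaired t-tests."""

    anova_F: float
    anova_p: float
    group_names: tuple[str, ...]
    tukey: list[dict] = field(default_factory=list)
    t_tests: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    refusals: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "anova": {"F": self.anova_F, "p": self.anova_p,
                      "groups": list(self.group_names)},
            "tukey": self.tukey,
            "t_tests": self.t_tests,
            "alpha": self.alpha,
            "refusals": self.refusals,
        }


def compare_groups(groups: dict[str, Sequence[float]],
                   t_test_pairs: Optional[Sequence[tuple[str, str]]] = None,
                   alpha: float = 0.05) -> GroupComparisonReport:
    """Compare a fitted parameter across particle groups.

    One-way ANOVA across all groups, Tukey honest-significant-difference
    adjusted pairwise comparisons, and unpaired two-sample t-tests for any
    requested pairs.  Degenerate inputs (n < 2, or all groups constant) are
    refused per affected test rather than returning misleading statistics.
    """
    names = tuple(groups.keys())
    if len(names) < 2:
        raise ContractError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    refusals = []
    for k, arr in arrays.items():
        if len(arr) < 2:
            raise ContractError(f"group {k!r} has n < 2")

    if all(np.var(arr) == 0 for arr in arrays.values()):
        refusals.append("ANOVA refused: zero variance in every group")
        F, p = math.nan, math.nan
        tukey_rows: list[dict] = []
    else:
        F, p = stats.f_oneway(*arrays.values())
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[k] * len(arrays[k]) for k in names])
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey_rows = []
        for row in res.summary().data[1:]:
            tukey_rows.append({
                "group1": str(row[0]), "group2": str(row[1]),
                "meandiff": float(row[2]), "p_adj": float(row[3]),
                "lower": float(row[4]), "upper": float(row[5]),
                "reject": bool(row[6]),
            })

    t_rows = []
    for a, b in (t_test_pairs or []):
        xa, xb = arrays[a], arrays[b]
        if np.var(xa) == 0 and np.var(xb) == 0:
            if np.allclose(xa.mean(), xb.mean()):
                t_rows.append({"group1": a, "group2": b, "t": 0.0, "p": 1.0,
                               "significant": False})
            else:
                refusals.append(
                    f"t-test refused for ({a}, {b}): zero variance in both groups")
            continue
        t_stat, p_val = stats.ttest_ind(xa, xb)
        t_rows.append({"group1": a, "group2": b, "t": float(t_stat),
                       "p": float(p_val), "significant": bool(p_val < alpha)})

    return GroupComparisonReport(anova_F=float(F), anova_p=float(p),
                                 group_names=names, tukey=tukey_rows,
                                 t_tests=t_rows, alpha=alpha,
                                 refusals=refusals)
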