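"""Per-subject nonlinear least-squares fitting and model-variant selection.

Each subject x ROI concentration-time series is fit by one member of the
kinetic model family (:mod:`nanopk.models`).  Which member applies is decided
by the ROI's physiological class and the route of administration:

* heart, source-like organs and kidneys: mono-exponential washout after an
  i.v. bolus; full double exponential after i.p. dosing (absorption phase
  visible);
* sink-like organs after i.p. dosing: saturating uptake, except lymph nodes,
  which drain the peritoneum directly and show a clear elimination phase
  (double exponential);
* sink-like organs after i.v. dosing: data-driven - washout model when the
  group-mean concentration declines from the first to the last imaging time,
  saturating uptake otherwise (liver vs spleen differ in practice);
* whole-body-derived cumulative excretion: the saturating excretion model.

Estimation is Levenberg-Marquardt least squares (via lmfit) under positivity
bounds and the labelling convention k_in > k_out, with a deterministic
jittered-restart policy for robustness.  Three-point designs make the
double exponential exactly identified (zero degrees of freedom): the fit
interpolates, standard errors are suppressed and the fit is flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import lmfit
import numpy as np

from .models import (
    ContractError,
    DomainError,
    KineticParams,
    ModelVariant,
    RATE_GAP_TOL,
    eval_variant,
    time_of_peak,
)

__all__ = [
    "ConcentrationSeries",
    "ROITaxonomy",
    "ModelFit",
    "GroupParameterSummary",
    "FitError",
    "GuessError",
    "select_variant",
    "initial_guesses",
    "fit_series",
    "fit_group",
]


class FitError(RuntimeError):
    """Nonlinear regression failed to converge after bounded restarts."""

    def __init__(self, message: str, best: Optional["ModelFit"] = None):
        super().__init__(message)
        self.best = best  # best candidate found, for post-mortem


class GuessError(ValueError):
    """No usable starting values could be derived from the data."""


@dataclass
class ConcentrationSeries:
    """One subject x ROI time course of dose-normalised measurements.

    ``values`` are %ID/g for tissue ROIs (``value_kind='concentration'``) and
    %ID for bladder / whole-body / excretion series (``value_kind='activity'``).
    """

    subject_id: str
    group_id: str
    roi: str
    route: str  # 'iv' | 'ip'
    times: np.ndarray
    values: np.ndarray
    value_kind: str = "concentration"
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.route not in ("iv", "ip"):
            raise ContractError(f"route must be 'iv' or 'ip', got {self.route!r}")
        if self.value_kind not in ("concentration", "activity"):
            raise ContractError(f"bad value_kind {self.value_kind!r}")
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ContractError("times and values must be 1-D and equal length")
        if len(self.times) and (np.any(np.diff(self.times) <= 0)
                                or np.any(self.times < 0)):
            raise ContractError("times must be strictly increasing and >= 0")
        if np.any(self.values < 0):
            raise ContractError("values must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


# ROI physiological classes.  Source-like organs lack microvascular traps
# (particles transit with blood); sink-like organs (MPS-rich, fenestrated)
# sequester particles; kidneys are handled like source-like organs for model
# selection but kept distinct because excretion mechanisms differ.
ROI_CLASSES = ("heart", "source_like", "sink_like", "kidney", "bladder",
               "whole_body")

DEFAULT_ROI_CLASS_MAP: dict[str, str] = {
    "heart": "heart",
    "lungs": "source_like",
    "aorta": "source_like",
    "muscle": "source_like",
    "brain": "source_like",
    "bone": "source_like",
    "liver": "sink_like",
    "spleen": "sink_like",
    "lymph_nodes": "sink_like",
    "kidneys": "kidney",
    "bladder": "bladder",
    "whole_body": "whole_body",
}


@dataclass
class ROITaxonomy:
    """Mapping from ROI name to physiological class, with overrides."""

    mapping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ROI_CLASS_MAP))

    def __post_init__(self) -> None:
        for roi, cls in self.mapping.items():
            if cls not in ROI_CLASSES:
                raise ContractError(f"unknown ROI class {cls!r} for {roi!r}")

    def class_of(self, roi: str) -> str:
        try:
            return self.mapping[roi]
        except KeyError:
            raise ContractError(f"ROI {roi!r} not in taxonomy") from None

    def with_overrides(self, overrides: dict[str, str]) -> "ROITaxonomy":
        merged = dict(self.mapping)
        merged.update(overrides)
        return ROITaxonomy(merged)


@dataclass
class ModelFit:
    """Result of fitting one variant to one series."""

    variant: ModelVariant
    params: KineticParams
    standard_errors: dict[str, Optional[float]]
    residuals: np.ndarray
    rss: float
    dof: int
    converged: bool
    aicc: Optional[float]
    n_obs: int
    series: Optional[ConcentrationSeries] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def interpolating(self) -> bool:
        return self.dof == 0


@dataclass
class GroupParameterSummary:
    """Mean +/- s.d. of one fitted parameter across subjects of a group."""

    group_id: str
    roi: str
    parameter: str
    mean: float
    sd: float
    n: int
    excluded_subjects: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# variant selection
# ---------------------------------------------------------------------------

#: ROIs in the sink-like class that drain the peritoneal cavity directly and
#: therefore show an elimination phase after i.p. dosing.
LYMPHATIC_ROIS = frozenset({"lymph_nodes"})


def select_variant(roi_class: str, route: str,
                   series: ConcentrationSeries | Sequence[ConcentrationSeries],
                   override: Optional[ModelVariant] = None) -> ModelVariant:
    """Choose the model variant for an ROI class / route combination.

    ``series`` may be a single series or all series of the group; the group
    is only consulted for the data-driven sink-like i.v. rule (washout model
    when the group-mean value at the last time is below the group-mean at the
    first time).  Bladder data are never modelled.
    """
    if override is not None:
        return ModelVariant(override)
    if roi_class not in ROI_CLASSES:
        raise ContractError(f"unknown ROI class {roi_class!r}")
    if roi_class == "bladder":
        raise ContractError("no kinetic model is fitted to bladder data")
    if route not in ("iv", "ip"):
        raise ContractError(f"route must be 'iv' or 'ip', got {route!r}")

    group = [series] if isinstance(series, ConcentrationSeries) else list(series)
    if not group:
        raise ContractError("at least one series is required")

    if roi_class == "whole_body":
        return ModelVariant.EXCRETION
    if roi_class in ("heart", "source_like", "kidney"):
        return ModelVariant.MONO_DECAY if route == "iv" else ModelVariant.DOUBLE_EXP
    # sink-like
    if route == "ip":
        roi = group[0].roi
        if roi in LYMPHATIC_ROIS:
            return ModelVariant.DOUBLE_EXP
        return ModelVariant.UPTAKE_ONLY
    first = float(np.mean([s.values[0] for s in group]))
    last = float(np.mean([s.values[-1] for s in group]))
    return ModelVariant.MONO_DECAY if last < first else ModelVariant.UPTAKE_ONLY


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _loglinear(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Intercept exp(a) and decay rate -b of a log-linear regression."""
    mask = values > 0
    if mask.sum() < 2:
        raise GuessError("need >= 2 positive values for a log-linear guess")
    slope, intercept = np.polyfit(times[mask], np.log(values[mask]), 1)
    return math.exp(intercept), -slope


def initial_guesses(series: ConcentrationSeries,
                    variant: ModelVariant) -> KineticParams:
    """Heuristic starting values for the nonlinear fit.

    Washout: back-extrapolated log-linear intercept and slope.  Saturating
    forms: amplitude 5% above the observed maximum, rate from the first time
    the curve reaches half its maximum.  Double exponential: terminal slope
    for k_out, uptake rate from the observed peak time, amplitude rescaled by
    the theoretical peak fraction.
    """
    t, v = series.times, series.values
    if len(series) < 2:
        raise GuessError("need at least 2 observations")
    vmax = float(v.max())
    if vmax <= 0:
        raise GuessError("all-zero series: no kinetic signal to initialise from")

    def _half_rise_rate() -> float:
        idx = np.nonzero(v >= vmax / 2.0)[0][0]
        t_half = max(float(t[idx]), 1e-3)
        return math.log(2.0) / t_half

    if variant is ModelVariant.MONO_DECAY:
        A, k = _loglinear(t, v)
        if k <= 0:  # non-declining data; nudge to a slow decay
            k = 1e-3
        return KineticParams(A=A, k_out=k)

    if variant is ModelVariant.UPTAKE_ONLY:
        return KineticParams(A=1.05 * vmax, k_in=_half_rise_rate())

    if variant is ModelVariant.EXCRETION:
        return KineticParams(U_t=min(1.05 * vmax, 100.0), k_u=_half_rise_rate())

    if variant is ModelVariant.DOUBLE_EXP:
        # terminal two points give the elimination rate
        if v[-1] > 0 and v[-2] > 0 and v[-2] > v[-1]:
            k_out = (math.log(v[-2]) - math.log(v[-1])) / (t[-1] - t[-2])
        else:
            k_out = 0.05
        k_out = max(k_out, 1e-3)
        t_peak_obs = max(float(t[int(np.argmax(v))]), 1e-2)
        k_in = max(5.0 * k_out, 1.0 / t_peak_obs)
        if k_in - k_out < 10 * RATE_GAP_TOL:
            k_in = k_out * 5.0
        t_star = time_of_peak(k_in, k_out)
        peak_fraction = (math.exp(-k_out * t_star) - math.exp(-k_in * t_star))
        A = vmax / max(peak_fraction, 1e-6)
        return KineticParams(A=A, k_in=k_in, k_out=k_out)

    raise ContractError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# least-squares estimation
# ---------------------------------------------------------------------------

_POS = 1e-12  # positivity floor for bounded parameters

#: Deterministic restart policy: up to 20 jittered restarts, log-uniform
#: factors in [0.2, 5], drawn from this fixed seed so fits are reproducible.
N_RESTARTS = 20
_RESTART_SEED = 734265011


def _build_params(variant: ModelVariant, g: KineticParams,
                  ut_max: Optional[float] = None) -> lmfit.Parameters:
    p = lmfit.Parameters()
    if variant is ModelVariant.MONO_DECAY:
        p.add("A", value=g.get("A"), min=_POS)
        p.add("k_out", value=g.get("k_out"), min=_POS)
    elif variant is ModelVariant.UPTAKE_ONLY:
        p.add("A", value=g.get("A"), min=_POS)
        p.add("k_in", value=g.get("k_in"), min=_POS)
    elif variant is ModelVariant.EXCRETION:
        # U_t <= 100 %ID is enforced lazily: the unbounded fit keeps the
        # normalised problem identical under data rescaling, and the bound
        # is only imposed when the unconstrained optimum violates it
        if ut_max is None:
            p.add("U_t", value=g.get("U_t"), min=_POS)
        else:
            p.add("U_t", value=min(g.get("U_t"), ut_max), min=_POS, max=ut_max)
        p.add("k_u", value=g.get("k_u"), min=_POS)
    elif variant is ModelVariant.DOUBLE_EXP:
        # enforce k_in > k_out by fitting the positive gap dk = k_in - k_out
        p.add("A", value=g.get("A"), min=_POS)
        p.add("k_out", value=g.get("k_out"), min=_POS)
        p.add("dk", value=max(g.get("k_in") - g.get("k_out"), 1e-6),
              min=RATE_GAP_TOL)
        p.add("k_in", expr="k_out + dk")
    else:
        raise ContractError(f"unknown variant {variant!r}")
    return p


def _params_from_lmfit(variant: ModelVariant, p: lmfit.Parameters) -> KineticParams:
    kw = {name: float(p[name].value) for name in variant.param_names}
    return KineticParams(**kw)


def _weight_vector(values: np.ndarray, weights: Optional[str]) -> np.ndarray:
    if weights is None or weights == "none":
        return np.ones_like(values)
    if weights == "1/value^2":
        floor = max(float(np.max(values)) * 1e-6, 1e-12)
        return 1.0 / np.maximum(values, floor)
    raise ContractError(f"unknown weighting scheme {weights!r}")


def fit_series(series: ConcentrationSeries, variant: ModelVariant,
               weights: Optional[str] = None,
               guesses: Optional[KineticParams] = None) -> ModelFit:
    """Levenberg-Marquardt fit of ``variant`` to one series.

    Standard errors come from the local curvature (covariance of the LM
    solution) when dof > 0; at dof = 0 the fit interpolates the data and
    standard errors are reported as unavailable rather than zero.
    """
    n_par = variant.n_params
    if len(series) < n_par:
        raise ContractError(
            f"{variant.value} needs >= {n_par} observations, got {len(series)}"
        )
    if series.excluded:
        raise ContractError(
            f"series {series.subject_id}/{series.roi} is excluded "
            f"({series.exclusion_reason or 'no reason recorded'})"
        )
    g = guesses if guesses is not None else initial_guesses(series, variant)
    t, v_raw = series.times, series.values

    # Normalise by the data maximum: the amplitude parameter is linear in the
    # data, so fitting in normalised units makes the estimate exactly
    # scale-equivariant (absolute bounds would otherwise break homogeneity).
    vscale = float(v_raw.max()) if v_raw.max() > 0 else 1.0
    v = v_raw / vscale
    amp_name = "U_t" if variant is ModelVariant.EXCRETION else "A"
    g_scaled = KineticParams(**{
        name: (g.get(name) / vscale if name == amp_name else g.get(name))
        for name in variant.param_names})
    w = _weight_vector(v, weights)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        kp = _params_from_lmfit(variant, p)
        try:
            model = np.asarray(eval_variant(variant, kp, t), dtype=float)
        except DomainError:
            return np.full_like(v, 1e6)
        return (model - v) * w

    rng = np.random.default_rng(_RESTART_SEED)
    free_names = [name for name in variant.param_names if name != "k_in"] \
        if variant is ModelVariant.DOUBLE_EXP else list(variant.param_names)
    if variant is ModelVariant.DOUBLE_EXP:
        free_names.append("dk")

    attempts = [{}]  # first attempt: unjittered guesses
    for _ in range(N_RESTARTS):
        attempts.append({name: math.exp(rng.uniform(math.log(0.2), math.log(5.0)))
                         for name in free_names})
    tol_rss = 1e-24 * len(v)  # "good enough" early stop (normalised units)

    def _search(base: lmfit.Parameters):
        best = None
        for jitter in attempts:
            p = base.copy()
            for name, factor in jitter.items():
                raw = base[name].value * factor
                lo, hi = p[name].min, p[name].max
                p[name].set(value=min(max(raw, lo + _POS), hi if hi else raw))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = lmfit.minimize(residual, p, method="leastsq",
                                         ftol=1e-13, xtol=1e-13)
                except Exception:
                    continue
            rss = float(np.sum(res.residual ** 2))
            if best is None or rss < best[1]:
                best = (res, rss)
            if res.success and (rss <= tol_rss or jitter == {}):
                break
        return best

    best = _search(_build_params(variant, g_scaled, ut_max=None))
    if (best is not None and variant is ModelVariant.EXCRETION
            and float(best[0].params["U_t"].value) * vscale > 100.0):
        # unconstrained optimum excretes more than the dose: impose the bound
        best = _search(_build_params(variant, g_scaled, ut_max=100.0 / vscale))

    if best is None:
        raise FitError(
            f"all {len(attempts)} fit attempts failed for "
            f"{series.subject_id}/{series.roi} ({variant.value})"
        )
    res, rss = best
    params = _params_from_lmfit(variant, res.params)
    # undo the data normalisation: amplitude and rss are homogeneous in scale
    amp_scaled = {amp_name: params.get(amp_name) * vscale}
    params = KineticParams(**{**params.as_dict(variant), **amp_scaled})
    rss *= vscale ** 2
    dof = len(series) - n_par
    notes: list[str] = []
    if dof == 0:
        notes.append("dof=0: exactly identified fit interpolates the data; "
                     "standard errors unavailable")
    stderr: dict[str, Optional[float]] = {}
    for name in variant.param_names:
        se = res.params[name].stderr if dof > 0 else None
        if se is not None and name == amp_name:
            se = se * vscale
        stderr[name] = float(se) if se is not None else None

    aicc = None
    if dof > 0:
        n = len(series)
        k = n_par
        # Gaussian log-likelihood AIC with small-sample correction
        aic = n * math.log(max(rss / n, 1e-300)) + 2 * k
        if n - k - 1 > 0:
            aicc = aic + 2 * k * (k + 1) / (n - k - 1)

    converged = bool(res.success)
    try:
        params.validate(variant)
    except DomainError as exc:
        converged = False
        notes.append(f"parameter constraints violated at optimum: {exc}")

    fit = ModelFit(variant=variant, params=params, standard_errors=stderr,
                   residuals=np.asarray(res.residual, dtype=float) * vscale,
                   rss=rss,
                   dof=dof, converged=converged, aicc=aicc, n_obs=len(series),
                   series=series, warnings=notes)
    if not converged:
        raise FitError(
            f"fit did not converge for {series.subject_id}/{series.roi} "
            f"({variant.value}) after {len(attempts)} attempts", best=fit)
    return fit


# ---------------------------------------------------------------------------
# group-level fitting
# ---------------------------------------------------------------------------

def fit_group(series_list: Iterable[ConcentrationSeries],
              variant: Optional[ModelVariant] = None,
              mode: str = "per_subject",
              weights: Optional[str] = None,
              taxonomy: Optional[ROITaxonomy] = None,
              ) -> tuple[list[GroupParameterSummary], list[ModelFit]]:
    """Fit every subject of one group x ROI x route and summarise parameters.

    ``per_subject`` (default): one fit per subject, mean +/- s.d. across
    subjects, matching how group tables report fitted parameters.
    ``pooled``: a single fit to the union of all points.
    Excluded subjects never enter fits; they are reported in the summary.
    """
    series_list = list(series_list)
    if not series_list:
        raise ContractError("empty group")
    if mode not in ("per_subject", "pooled"):
        raise ContractError(f"mode must be 'per_subject' or 'pooled', got {mode!r}")
    rois = {s.roi for s in series_list}
    routes = {s.route for s in series_list}
    groups = {s.group_id for s in series_list}
    if len(rois) > 1 or len(routes) > 1 or len(groups) > 1:
        raise ContractError(
            f"fit_group requires a single group/ROI/route; got groups={groups}, "
            f"rois={rois}, routes={routes}")
    roi, route, group_id = rois.pop(), routes.pop(), groups.pop()

    excluded = tuple(sorted(s.subject_id for s in series_list if s.excluded))
    active = [s for s in series_list if not s.excluded]
    if not active:
        raise ContractError(f"all subjects of group {group_id} are excluded")

    if variant is None:
        tax = taxonomy or ROITaxonomy()
        variant = select_variant(tax.class_of(roi), route, active)

    if mode == "pooled":
        order = np.argsort(np.concatenate([s.times for s in active]),
                           kind="stable")
        times = np.concatenate([s.times for s in active])[order]
        values = np.concatenate([s.values for s in active])[order]
        # collapse duplicate times by epsilon-offsets is unnecessary: the fit
        # only needs (t, y) pairs, so bypass the strict-monotonicity check by
        # fitting a synthetic series built from the first subject's metadata
        pooled = ConcentrationSeries.__new__(ConcentrationSeries)
        pooled.subject_id = "pooled"
        pooled.group_id = group_id
        pooled.roi = roi
        pooled.route = route
        pooled.times = times
        pooled.values = values
        pooled.value_kind = active[0].value_kind
        pooled.excluded = False
        pooled.exclusion_reason = ""
        fits = [fit_series(pooled, variant, weights=weights)]
    else:
        fits = [fit_series(s, variant, weights=weights) for s in active]

    summaries = []
    for name in variant.param_names:
        vals = np.array([f.params.get(name) for f in fits], dtype=float)
        summaries.append(GroupParameterSummary(
            group_id=group_id, roi=roi, parameter=name,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            n=len(fits), excluded_subjects=excluded))
    return summaries, fits
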