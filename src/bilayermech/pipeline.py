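"""From a raw voltage-clamp trace to elastic constants.

The measurement protocol applies a square-wave potential (2 s on, 2 s off,
amplitudes stepping by ±25 mV up to ±200 mV) across a free-standing planar
bilayer while capacitance and area are recorded simultaneously.  The
pipeline stages are:

1. :func:`segment_steps` -- split the trace into on-steps (one per applied
   level) and off-periods.
2. :func:`estimate_state` -- zero-field reference state (C0, A0, d0, C_m, V0)
   from off-periods and low-field samples.
3. :func:`summarize_step` -- steady-state averages per step, the field
   thickness d_psi, and the constant-volume capacitance.
4. :func:`fit_alpha` -- ordinary least squares of constant-volume
   capacitance on psi**2; alpha = slope / (slope_factor * C0).
5. :func:`estimate_moduli` -- the constant-volume Young's modulus
   E = C_m/(alpha d0), the legacy single-volume estimator from the thinning
   slope, and the thin-plate conversion to K_A and k_c.
6. :func:`bootstrap_uncertainty` -- residual-resampling confidence
   intervals for alpha, E and k_c.

:func:`run_analysis` composes all stages into an :class:`AnalysisReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from . import model
from .errors import ConfigurationError, DataError, FitError, PipelineError

__all__ = [
    "ElectroTrace",
    "Segment",
    "Segmentation",
    "StepSummary",
    "MembraneState",
    "AlphaFit",
    "ElasticityResult",
    "AnalysisConfig",
    "AnalysisReport",
    "segment_steps",
    "summarize_step",
    "estimate_state",
    "fit_alpha",
    "estimate_moduli",
    "bootstrap_uncertainty",
    "run_analysis",
]


@dataclass
class ElectroTrace:
    """Sampled time series of applied potential, capacitance and area.

    All channels are SI: seconds, volts, farads, square meters.  ``metadata``
    carries free-form condition labels (lipid, asymmetry factor ``x_factor``,
    ``dielectric_constant``).
    """

    time: np.ndarray
    potential: np.ndarray
    capacitance: np.ndarray
    area: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        self.capacitance = np.asarray(self.capacitance, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        n = self.time.size
        for name in ("potential", "capacitance", "area"):
            if getattr(self, name).size != n:
                raise DataError(f"channel {name!r} has length "
                                f"{getattr(self, name).size}, expected {n}")
        if n == 0:
            raise DataError("empty trace")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if np.any(self.capacitance <= 0):
            raise DataError("all capacitance samples must be positive")
        if np.any(self.area <= 0):
            raise DataError("all area samples must be positive")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dielectric_constant(self) -> float:
        return float(self.metadata.get(
            "dielectric_constant", model.DEFAULT_DIELECTRIC_CONSTANT))


@dataclass(frozen=True)
class Segment:
    """A maximal run of samples at one applied level; ``stop`` is exclusive."""

    level: float
    start: int
    stop: int

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class Segmentation:
    on: tuple
    off: tuple


@dataclass(frozen=True)
class MembraneState:
    """Zero-field reference quantities of a bilayer.

    Derived per the plate-capacitor relations: ``d0 = eps0 eps_r A0 / C0``,
    ``C_m = C0 / A0``, ``V0 = A0 * d0``.
    """

    zero_field_capacitance: float
    zero_field_area: float
    zero_field_thickness: float
    specific_capacitance: float
    zero_field_volume: float
    dielectric_constant: float = model.DEFAULT_DIELECTRIC_CONSTANT

    @classmethod
    def from_reference(cls, capacitance: float, area: float,
                       dielectric_constant: float = model.DEFAULT_DIELECTRIC_CONSTANT
                       ) -> "MembraneState":
        d0 = model.thickness_from_capacitance(capacitance, area,
                                              dielectric_constant)
        return cls(
            zero_field_capacitance=capacitance,
            zero_field_area=area,
            zero_field_thickness=d0,
            specific_capacitance=capacitance / area,
            zero_field_volume=area * d0,
            dielectric_constant=dielectric_constant,
        )


@dataclass(frozen=True)
class StepSummary:
    """Steady-state aggregates for one applied-voltage step."""

    potential: float
    mean_capacitance: float
    mean_area: float
    thickness: float
    constant_volume_capacitance: float
    measured_volume: float
    n_samples: int


@dataclass(frozen=True)
class AlphaFit:
    """Result of regressing constant-volume capacitance on psi**2.

    ``alpha = slope / (slope_factor * C0)``.  ``branch_asymmetry`` is the
    relative difference of alpha fitted on positive-only vs negative-only
    steps; ``None`` when only one sign is present.
    ``intercept_relative_deviation`` compares the free intercept with the
    measured C0 -- a baseline-consistency diagnostic.
    """

    alpha: float
    alpha_se: float
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    branch_asymmetry: float | None
    intercept_relative_deviation: float
    slope_factor: float
    n_points: int


@dataclass(frozen=True)
class ElasticityResult:
    """Elastic constants with diagnostics.

    ``young_modulus_constant_volume`` uses the constant-volume capacitance
    route; ``young_modulus_legacy`` the single-volume thinning-slope route
    (``None`` when no compression was measurable).  ``volume_growth_ratio``
    is max measured volume over V0 -- values > 1 quantify the
    disproportionate area growth that motivates the correction.
    """

    alpha: float
    alpha_se: float
    young_modulus_constant_volume: float
    young_modulus_legacy: float | None
    area_expansion_modulus: float
    bending_rigidity: float
    branch_asymmetry: float | None
    fit_r_squared: float
    volume_growth_ratio: float
    poisson_ratio: float
    alpha_interval: tuple | None = None
    young_modulus_interval: tuple | None = None
    bending_rigidity_interval: tuple | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis chain (all SI).

    ``settle_fraction`` is the trailing fraction of each on-step averaged as
    steady state.  ``level_tolerance`` and ``level_floor`` control step
    detection; ``min_duration`` discards runt segments.  Bootstrap runs when
    ``bootstrap_replicates`` > 0.
    """

    settle_fraction: float = 0.5
    level_tolerance: float = 2e-3
    level_floor: float = 5e-3
    min_duration: float = 0.5
    slope_factor: float = model.DEFAULT_SLOPE_FACTOR
    poisson_ratio: float = model.DEFAULT_POISSON_RATIO
    bootstrap_replicates: int = 0
    seed: int = 0
    detrend_baseline: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.settle_fraction <= 1:
            raise ConfigurationError(
                f"settle_fraction must be in (0, 1], got {self.settle_fraction}")
        if self.level_floor <= 0 or self.level_tolerance <= 0:
            raise ConfigurationError("level_floor and level_tolerance must be positive")


def segment_steps(
    trace: ElectroTrace,
    protocol_hint=None,
    level_tolerance: float = 2e-3,
    level_floor: float = 5e-3,
    min_duration: float = 0.5,
) -> Segmentation:
    """Split a trace into on-steps and off-periods.

    A segment boundary is placed wherever the potential jumps by more than
    ``level_tolerance``.  Segments whose level magnitude is below
    ``level_floor`` are off-periods (baseline); on-segments shorter than
    ``min_duration`` seconds are discarded.  When a protocol hint is given,
    each on-level is snapped to the nearest hinted amplitude within
    ``level_tolerance``.

    Raises
    ------
    PipelineError
        If no on-segments are detected.
    """
    p = trace.potential
    boundaries = np.flatnonzero(np.abs(np.diff(p)) > level_tolerance) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [p.size]))

    hint_levels = None
    if protocol_hint is not None:
        hint_levels = np.asarray(protocol_hint.amplitudes, dtype=float)

    on, off = [], []
    for s, e in zip(starts, stops):
        level = float(np.median(p[s:e]))
        if abs(level) < level_floor:
            off.append(Segment(0.0, int(s), int(e)))
            continue
        duration = float(trace.time[e - 1] - trace.time[s])
        if duration < min_duration:
            continue
        if hint_levels is not None:
            k = int(np.argmin(np.abs(hint_levels - level)))
            if abs(hint_levels[k] - level) <= level_tolerance:
                level = float(hint_levels[k])
        on.append(Segment(level, int(s), int(e)))

    if not on:
        raise PipelineError("no voltage steps found")
    return Segmentation(on=tuple(on), off=tuple(off))


def estimate_state(
    trace: ElectroTrace,
    level_floor: float = 5e-3,
    detrend: bool = False,
) -> MembraneState:
    """Zero-field reference state from off-periods and low-field samples.

    All samples with ``|psi| <= level_floor`` qualify (this captures both the
    off-periods and the 1 mV reference step of the standard protocol).  C0
    and A0 are their means; d0, C_m and V0 follow from the plate-capacitor
    relations.  With ``detrend``, a linear drift in the baseline capacitance
    is removed by evaluating an OLS line at the trace midpoint.
    """
    mask = np.abs(trace.potential) <= level_floor
    if not np.any(mask):
        raise PipelineError("no zero/low-field samples for state estimation")
    c = trace.capacitance[mask]
    a = trace.area[mask]
    if detrend and c.size > 2:
        t = trace.time[mask]
        coef = np.polyfit(t, c, 1)
        c0 = float(np.polyval(coef, 0.5 * (trace.time[0] + trace.time[-1])))
    else:
        c0 = float(np.mean(c))
    a0 = float(np.mean(a))
    if c0 <= 0 or a0 <= 0:
        raise DataError("non-positive baseline capacitance or area")
    return MembraneState.from_reference(c0, a0, trace.dielectric_constant)


def summarize_step(
    trace: ElectroTrace,
    segment: Segment,
    state: MembraneState,
    settle_fraction: float = 0.5,
) -> StepSummary:
    """Steady-state aggregates over the trailing ``settle_fraction`` of a step.

    Averages potential, capacitance and area; derives the field thickness
    d_psi from the plate-capacitor relation and the constant-volume
    capacitance from the state's V0.
    """
    if not (0 <= segment.start < segment.stop <= len(trace)):
        raise DataError(f"segment [{segment.start}, {segment.stop}) outside trace")
    n = segment.n_samples
    k = max(1, int(np.ceil(n * settle_fraction)))
    sl = slice(segment.stop - k, segment.stop)
    c = float(np.mean(trace.capacitance[sl]))
    a = float(np.mean(trace.area[sl]))
    psi = float(np.mean(trace.potential[sl]))
    if c <= 0 or a <= 0:
        raise DataError("averaged capacitance or area non-positive")
    d = model.thickness_from_capacitance(c, a, state.dielectric_constant)
    ccv = model.constant_volume_capacitance(
        state.zero_field_volume, d, state.dielectric_constant)
    return StepSummary(
        potential=psi,
        mean_capacitance=c,
        mean_area=a,
        thickness=d,
        constant_volume_capacitance=ccv,
        measured_volume=a * d,
        n_samples=k,
    )


def _ols(x: np.ndarray, y: np.ndarray):
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        se = res.bse[1] if np.isfinite(res.bse[1]) else 0.0
        r2 = float(res.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0
    return float(slope), float(se), float(intercept), r2


def fit_alpha(
    steps: Sequence[StepSummary],
    state: MembraneState,
    slope_factor: float = model.DEFAULT_SLOPE_FACTOR,
) -> AlphaFit:
    """OLS of constant-volume capacitance on psi**2, pooled over both signs.

    ``alpha = m / (slope_factor * C0)`` where ``m`` is the fitted slope.
    Per-sign fits yield the branch-asymmetry diagnostic
    ``|alpha+ - alpha-| / mean`` when both signs are present.  A negative
    slope is reported as-is (alpha <= 0); downstream moduli are then
    undefined.
    """
    psi = np.array([s.potential for s in steps], dtype=float)
    y = np.array([s.constant_volume_capacitance for s in steps], dtype=float)
    x = psi**2
    if np.unique(x).size < 2:
        raise FitError("need at least 2 distinct psi^2 values to fit alpha")
    m, m_se, intercept, r2 = _ols(x, y)
    c0 = state.zero_field_capacitance
    alpha = model.alpha_from_slope(m, c0, slope_factor)
    alpha_se = abs(m_se) / (slope_factor * c0)

    asym = None
    pos, neg = psi > 0, psi < 0
    if np.unique(x[pos]).size >= 2 and np.unique(x[neg]).size >= 2:
        m_p = _ols(x[pos], y[pos])[0]
        m_n = _ols(x[neg], y[neg])[0]
        a_p = model.alpha_from_slope(m_p, c0, slope_factor)
        a_n = model.alpha_from_slope(m_n, c0, slope_factor)
        mean = 0.5 * (a_p + a_n)
        asym = abs(a_p - a_n) / abs(mean) if mean != 0 else float("inf")

    return AlphaFit(
        alpha=float(alpha),
        alpha_se=float(alpha_se),
        slope=m,
        slope_se=m_se,
        intercept=intercept,
        r_squared=r2,
        branch_asymmetry=asym,
        intercept_relative_deviation=(intercept - c0) / c0,
        slope_factor=slope_factor,
        n_points=len(steps),
    )


def estimate_moduli(
    steps: Sequence[StepSummary],
    state: MembraneState,
    fit: AlphaFit,
    poisson_ratio: float = model.DEFAULT_POISSON_RATIO,
) -> ElasticityResult:
    """Elastic constants from the fitted voltage dependence.

    The constant-volume Young's modulus is ``C_m / (alpha d0)``; the legacy
    estimator regresses the thickness decrease ``d0 - d_psi`` on psi**2 and
    evaluates ``E = C_m / (2 s)`` from that slope ``s`` (reported ``None``
    when no thinning is measurable).  K_A and k_c follow from thin-plate
    theory evaluated at the zero-field thickness.

    Raises
    ------
    PipelineError
        If the fitted alpha is not positive (capacitance did not increase
        with voltage; moduli undefined).
    """
    if fit.alpha <= 0:
        raise PipelineError(
            "moduli undefined: fitted alpha <= 0 "
            "(no voltage-dependent capacitance increase)")
    cm = state.specific_capacitance
    d0 = state.zero_field_thickness
    e_cv = model.young_modulus_alvarez(cm, fit.alpha, d0)

    psi2 = np.array([s.potential for s in steps], dtype=float) ** 2
    dd = d0 - np.array([s.thickness for s in steps], dtype=float)
    e_legacy = None
    if np.any(dd > 0) and np.unique(psi2).size >= 2:
        s_thin = _ols(psi2, dd)[0]
        if s_thin > 0:
            e_legacy = float(cm / (2.0 * s_thin))

    ka = model.area_expansion_modulus(e_cv, d0, poisson_ratio)
    kc = model.bending_rigidity(ka, d0, poisson_ratio)
    volumes = np.array([s.measured_volume for s in steps], dtype=float)
    return ElasticityResult(
        alpha=fit.alpha,
        alpha_se=fit.alpha_se,
        young_modulus_constant_volume=float(e_cv),
        young_modulus_legacy=e_legacy,
        area_expansion_modulus=float(ka),
        bending_rigidity=float(kc),
        branch_asymmetry=fit.branch_asymmetry,
        fit_r_squared=fit.r_squared,
        volume_growth_ratio=float(np.max(volumes) / state.zero_field_volume),
        poisson_ratio=poisson_ratio,
    )


def bootstrap_uncertainty(
    steps: Sequence[StepSummary],
    state: MembraneState,
    n_replicates: int = 1000,
    seed: int = 0,
    slope_factor: float = model.DEFAULT_SLOPE_FACTOR,
    poisson_ratio: float = model.DEFAULT_POISSON_RATIO,
) -> dict:
    """Residual-resampling bootstrap of the capacitance-vs-psi**2 regression.

    Residuals from the pooled OLS fit are rescaled by sqrt(n/(n-2)) to
    compensate the degrees of freedom absorbed by the fit, resampled with
    replacement onto the fitted line, and the full alpha -> E -> k_c chain
    re-evaluated per replicate.  Returns percentile 95% intervals, keyed
    ``alpha``, ``young_modulus``, ``bending_rigidity``.  Deterministic for a
    fixed seed.
    """
    if n_replicates < 50:
        raise ConfigurationError(
            f"bootstrap needs at least 50 replicates, got {n_replicates}")
    psi2 = np.array([s.potential for s in steps], dtype=float) ** 2
    y = np.array([s.constant_volume_capacitance for s in steps], dtype=float)
    n = y.size
    if np.unique(psi2).size < 2:
        raise FitError("need at least 2 distinct psi^2 values to bootstrap")
    X = np.column_stack([np.ones(n), psi2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    resid = (y - yhat) * np.sqrt(n / (n - 2))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_replicates, n))
    ystar = yhat[None, :] + resid[idx]
    # closed-form OLS slope per replicate
    xc = psi2 - psi2.mean()
    sxx = float(np.sum(xc**2))
    slopes = (ystar - ystar.mean(axis=1, keepdims=True)) @ xc / sxx

    c0 = state.zero_field_capacitance
    alphas = slopes / (slope_factor * c0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(alphas > 0,
                     state.specific_capacitance
                     / (alphas * state.zero_field_thickness),
                     np.nan)
    d0 = state.zero_field_thickness
    kc = e * d0**3 / (24.0 * (1.0 - poisson_ratio) * (1.0 + poisson_ratio))

    def interval(v):
        lo, hi = np.nanpercentile(v, [2.5, 97.5])
        return (float(lo), float(hi))

    return {
        "alpha": interval(alphas),
        "young_modulus": interval(e),
        "bending_rigidity": interval(kc),
        "n_replicates": n_replicates,
        "seed": seed,
    }


@dataclass
class AnalysisReport:
    """Full analysis output: state, per-step table, fit, moduli, intervals."""

    state: MembraneState
    steps: tuple
    fit: AlphaFit
    result: ElasticityResult
    config: AnalysisConfig
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean({
            "metadata": dict(self.metadata),
            "state": asdict(self.state),
            "steps": [asdict(s) for s in self.steps],
            "fit": asdict(self.fit),
            "result": asdict(self.result),
            "config": asdict(self.config),
        })

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (PipelineError, DataError, FitError) as err:
                if not str(err).startswith(f"[{name}]"):
                    err.args = (f"[{name}] {err}",)
                raise
        return wrapped
    return deco


def run_analysis(
    trace: ElectroTrace,
    config: AnalysisConfig | None = None,
    protocol_hint=None,
) -> AnalysisReport:
    """End-to-end composition of all pipeline stages.

    Deterministic for fixed inputs and config; stage failures propagate with
    the stage name prefixed to the error message.
    """
    cfg = config or AnalysisConfig()
    seg = _stage("segment_steps")(segment_steps)(
        trace, protocol_hint,
        level_tolerance=cfg.level_tolerance,
        level_floor=cfg.level_floor,
        min_duration=cfg.min_duration,
    )
    state = _stage("estimate_state")(estimate_state)(
        trace, level_floor=cfg.level_floor, detrend=cfg.detrend_baseline)
    steps = tuple(
        _stage("summarize_step")(summarize_step)(
            trace, s, state, cfg.settle_fraction)
        for s in seg.on
    )
    fit = _stage("fit_alpha")(fit_alpha)(steps, state, cfg.slope_factor)
    result = _stage("estimate_moduli")(estimate_moduli)(
        steps, state, fit, cfg.poisson_ratio)
    if cfg.bootstrap_replicates > 0:
        ci = bootstrap_uncertainty(
            steps, state,
            n_replicates=cfg.bootstrap_replicates,
            seed=cfg.seed,
            slope_factor=cfg.slope_factor,
            poisson_ratio=cfg.poisson_ratio,
        )
        result = ElasticityResult(
            **{**asdict(result),
               "alpha_interval": tuple(ci["alpha"]),
               "young_modulus_interval": tuple(ci["young_modulus"]),
               "bending_rigidity_interval": tuple(ci["bending_rigidity"])})
    return AnalysisReport(
        state=state, steps=steps, fit=fit, result=result, config=cfg,
        metadata=dict(trace.metadata),
    )
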