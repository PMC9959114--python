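"""Forward simulator for planar-bilayer electrostriction traces.

Generates (time, potential, capacitance, area) traces that are the exact
inverse of the analysis chain: given a target Young's modulus E and
zero-field thickness d0, the voltage dependence constant is
``alpha = C_m / (E d0)`` and each applied potential psi thins the film to

.. math:: d_\\psi = d_0 (1 + s\\,\\alpha\\,\\psi^2)^{-1/2}

(with ``s`` the slope factor), so that the constant-volume capacitance is
exactly linear in psi**2 and the pipeline provably recovers the generator
parameters.  Area growth is modeled quadratically,
``A_psi = A0 (1 + gamma psi**2)``, mirroring the capacitance law; gamma
above ``s*alpha/2`` yields net volume growth with field strength -- the
disproportionate-area regime the constant-volume correction exists for.
An exact volume-conserving mode (``conserve_volume``) sets
``A_psi = A0 d0 / d_psi`` instead.

Measurement noise is multiplicative Gaussian, applied independently to the
capacitance and area channels, seeded and reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import model
from .errors import ConfigurationError, DomainError, FormatError
from .pipeline import ElectroTrace

__all__ = [
    "VoltageProtocol",
    "SimulationParams",
    "build_protocol",
    "simulate_trace",
    "write_trace",
    "read_trace",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = ("time_s", "potential_V", "capacitance_F", "area_m2")


@dataclass(frozen=True)
class VoltageProtocol:
    """Square-wave schedule of applied potentials.

    ``amplitudes`` are the signed on-levels in V, applied in order, each for
    ``on_duration`` seconds followed by ``off_duration`` seconds at 0 V.
    """

    amplitudes: tuple
    on_duration: float = 2.0
    off_duration: float = 2.0
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        if not self.amplitudes:
            raise ConfigurationError("protocol needs at least one amplitude")
        if self.on_duration <= 0 or self.off_duration < 0:
            raise ConfigurationError("on_duration must be > 0, off_duration >= 0")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")


@dataclass(frozen=True)
class SimulationParams:
    """Physical and noise parameters of the forward model.

    ``area_growth`` is gamma in the quadratic area law A0(1 + gamma psi**2),
    in V^-2; ``conserve_volume`` overrides it with the exact
    volume-conserving area response.  Noise levels are relative standard
    deviations of multiplicative Gaussian noise.  ``settle_tau`` > 0 adds a
    first-order exponential approach to each step's steady state (seconds);
    0 means instantaneous response.
    """

    zero_field_thickness: float = 2.69e-9
    zero_field_area: float = 6.36e-7
    dielectric_constant: float = model.DEFAULT_DIELECTRIC_CONSTANT
    young_modulus: float = 1.757e7
    poisson_ratio: float = model.DEFAULT_POISSON_RATIO
    slope_factor: float = model.DEFAULT_SLOPE_FACTOR
    area_growth: float | None = None
    conserve_volume: bool = False
    capacitance_noise: float = 0.0
    area_noise: float = 0.0
    settle_tau: float = 0.0
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("zero_field_thickness", "zero_field_area",
                     "dielectric_constant", "young_modulus", "slope_factor"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.capacitance_noise < 0 or self.area_noise < 0:
            raise DomainError("noise levels must be >= 0")
        if self.area_growth is not None and self.area_growth < 0:
            raise DomainError("area_growth must be >= 0")

    @property
    def specific_capacitance(self) -> float:
        """C_m = eps0 eps_r / d0, in F/m^2."""
        return (model.VACUUM_PERMITTIVITY * self.dielectric_constant
                / self.zero_field_thickness)

    @property
    def alpha(self) -> float:
        """Voltage-dependence constant implied by the target modulus, V^-2."""
        return self.specific_capacitance / (
            self.young_modulus * self.zero_field_thickness)

    @property
    def gamma(self) -> float:
        """Effective quadratic area-growth coefficient (default 2*alpha)."""
        return 2.0 * self.alpha if self.area_growth is None else self.area_growth

    @property
    def bending_rigidity(self) -> float:
        ka = model.area_expansion_modulus(
            self.young_modulus, self.zero_field_thickness, self.poisson_ratio)
        return float(model.bending_rigidity(
            ka, self.zero_field_thickness, self.poisson_ratio))


def build_protocol(
    step: float = 0.025,
    max_level: float = 0.200,
    include_reference: bool = True,
    signs: str = "both",
    on_duration: float = 2.0,
    off_duration: float = 2.0,
    sample_rate: float = 1000.0,
) -> VoltageProtocol:
    """Standard square-wave ramp: ±25 mV increments up to ±200 mV.

    Amplitudes are interleaved in sign at each magnitude (+, -), optionally
    preceded by a ±1 mV reference level.  ``signs`` may be ``"both"``,
    ``"positive"`` or ``"negative"``.
    """
    if not 0 < step <= max_level:
        raise ConfigurationError(
            f"step must satisfy 0 < step <= max_level, got step={step}, "
            f"max_level={max_level}")
    if signs not in ("both", "positive", "negative"):
        raise ConfigurationError(f"signs must be both/positive/negative, got {signs!r}")
    sign_values = {"both": (1.0, -1.0), "positive": (1.0,), "negative": (-1.0,)}[signs]
    amplitudes: list[float] = []
    if include_reference:
        amplitudes.extend(s * 1e-3 for s in sign_values)
    n = int(np.floor(max_level / step + 1e-12))
    for k in range(1, n + 1):
        amplitudes.extend(s * k * step for s in sign_values)
    return VoltageProtocol(
        amplitudes=tuple(amplitudes),
        on_duration=on_duration,
        off_duration=off_duration,
        sample_rate=sample_rate,
    )


def _response(psi: float, params: SimulationParams) -> tuple[float, float]:
    """Steady-state (thickness, area) at applied potential psi."""
    d0, a0 = params.zero_field_thickness, params.zero_field_area
    if psi == 0.0:
        return d0, a0
    x = params.slope_factor * params.alpha * psi**2
    d = d0 / np.sqrt(1.0 + x)
    if params.conserve_volume:
        a = a0 * d0 / d
    else:
        a = a0 * (1.0 + params.gamma * psi**2)
    return float(d), float(a)


def simulate_trace(
    params: SimulationParams,
    protocol: VoltageProtocol | None = None,
) -> ElectroTrace:
    """Generate an :class:`~bilayermech.pipeline.ElectroTrace`.

    Each protocol amplitude contributes an on-block followed by an off-block
    at 0 V; samples carry the steady-state thickness/area response (or a
    first-order approach to it when ``settle_tau`` > 0), converted to
    capacitance via the plate-capacitor relation, with seeded multiplicative
    Gaussian noise on the capacitance and area channels.
    """
    proto = protocol or build_protocol()
    dt = 1.0 / proto.sample_rate
    n_on = max(1, int(round(proto.on_duration * proto.sample_rate)))
    n_off = int(round(proto.off_duration * proto.sample_rate))
    d0, a0 = params.zero_field_thickness, params.zero_field_area

    pot, thick, area = [], [], []
    d_prev, a_prev = d0, a0
    for amp in proto.amplitudes:
        for psi, n in ((amp, n_on), (0.0, n_off)):
            if n == 0:
                continue
            d_t, a_t = _response(psi, params)
            if params.settle_tau > 0:
                t_rel = np.arange(1, n + 1) * dt
                w = np.exp(-t_rel / params.settle_tau)
                d_block = d_t + (d_prev - d_t) * w
                a_block = a_t + (a_prev - a_t) * w
            else:
                d_block = np.full(n, d_t)
                a_block = np.full(n, a_t)
            pot.append(np.full(n, psi))
            thick.append(d_block)
            area.append(a_block)
            d_prev, a_prev = float(d_block[-1]), float(a_block[-1])

    potential = np.concatenate(pot)
    d = np.concatenate(thick)
    a = np.concatenate(area)
    time = np.arange(potential.size) * dt
    cap = model.VACUUM_PERMITTIVITY * params.dielectric_constant * a / d

    if params.capacitance_noise > 0 or params.area_noise > 0:
        rng = np.random.default_rng(params.seed)
        if params.capacitance_noise > 0:
            cap = cap * (1.0 + params.capacitance_noise
                         * rng.standard_normal(cap.size))
        if params.area_noise > 0:
            a = a * (1.0 + params.area_noise * rng.standard_normal(a.size))

    metadata = {"dielectric_constant": params.dielectric_constant,
                **params.metadata}
    return ElectroTrace(time=time, potential=potential, capacitance=cap,
                        area=a, metadata=metadata)


def write_trace(path, trace: ElectroTrace) -> None:
    """Write a trace as CSV with ``#``-prefixed ``key=value`` metadata lines.

    Channels are printed with 12 significant digits so that
    ``read_trace(write_trace(...))`` is an identity to full precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        for key, value in trace.metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        df = pd.DataFrame({
            "time_s": trace.time,
            "potential_V": trace.potential,
            "capacitance_F": trace.capacitance,
            "area_m2": trace.area,
        })
        df.to_csv(fh, header=False, index=False,
                  float_format="%.12g", lineterminator="\n")


def _parse_metadata_value(raw: str):
    try:
        return float(raw)
    except ValueError:
        return raw


def read_trace(path) -> ElectroTrace:
    """Read a trace CSV written by :func:`write_trace`.

    Raises :class:`~bilayermech.errors.FormatError` (with a line number) on
    a malformed header, a missing column, or a non-numeric cell.
    """
    path = Path(path)
    metadata: dict = {}
    with path.open() as fh:
        lines = fh.readlines()
    header_idx = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = _parse_metadata_value(value.strip())
            continue
        header_idx = i
        break
    if header_idx is None:
        raise FormatError(f"{path}: no header line found")
    header = [h.strip() for h in lines[header_idx].split(",")]
    missing = [c for c in TRACE_COLUMNS if c not in header]
    if missing:
        raise FormatError(
            f"{path}:{header_idx + 1}: missing column(s) {', '.join(missing)}")
    try:
        df = pd.read_csv(io.StringIO("".join(lines[header_idx:])))
        data = {c: df[c].to_numpy(dtype=float) for c in TRACE_COLUMNS}
    except (ValueError, TypeError):
        # locate the offending cell for a useful error message
        for j, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
            for cell in line.strip().split(","):
                if cell:
                    try:
                        float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{j}: non-numeric cell {cell!r}") from None
        raise FormatError(f"{path}: could not parse numeric data") from None
    return ElectroTrace(metadata=metadata, time=data["time_s"],
                        potential=data["potential_V"],
                        capacitance=data["capacitance_F"],
                        area=data["area_m2"])


def params_with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Copy ``params`` with a different noise seed."""
    return replace(params, seed=seed)
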