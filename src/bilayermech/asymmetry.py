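"""Calcium-asymmetry bookkeeping and batch condition analysis.

An asymmetric ionic environment is created by adding small aliquots of a
concentrated CaCl2 stock to the top chamber of the bilayer cell while the
bottom chamber stays at its initial concentration.  Assuming perfect
mixing, ``n`` aliquots of volume ``V_a`` and concentration ``c_stock`` into
a chamber of volume ``V`` at ``c_init`` give

.. math:: c_n = (c_\\mathrm{init} V + n V_a c_\\mathrm{stock}) / (V + n V_a)

The asymmetry factor ``x`` is the top/bottom concentration ratio.
:func:`run_series` batch-analyzes a manifest of traces recorded at
different ``x`` and tabulates thickness and bending rigidity against it,
with percent changes relative to the symmetric (x = 1) condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, FormatError
from .pipeline import AnalysisConfig, run_analysis
from .synthetic import read_trace

__all__ = [
    "AsymmetrySchedule",
    "ConditionResult",
    "concentration_after_additions",
    "asymmetry_factor",
    "run_series",
    "read_manifest",
]

MANIFEST_COLUMNS = ("trace_path", "lipid", "x_factor")


@dataclass(frozen=True)
class AsymmetrySchedule:
    """Aliquot-addition schedule for the top chamber.

    Volumes in liters, concentrations in mM.  The bottom chamber is held at
    ``bottom_concentration`` throughout.
    """

    chamber_volume: float
    aliquot_volume: float = 50e-6
    stock_concentration: float = 200.0
    initial_concentration: float = 2.0
    bottom_concentration: float = 2.0
    n_additions: int = 0

    def __post_init__(self) -> None:
        for name in ("chamber_volume", "aliquot_volume", "stock_concentration",
                     "initial_concentration", "bottom_concentration"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.n_additions < 0:
            raise DomainError("n_additions must be >= 0")


@dataclass(frozen=True)
class ConditionResult:
    """One analyzed condition: asymmetry factor, thickness, rigidity."""

    x_factor: float
    lipid: str
    thickness: float
    bending_rigidity: float
    bending_rigidity_interval: tuple | None = None


def concentration_after_additions(schedule: AsymmetrySchedule) -> float:
    """Top-chamber concentration (mM) after ``n_additions`` aliquots.

    Perfect-mixing dilution; monotone increasing in the number of additions
    and bounded above by the stock concentration.
    """
    v = schedule.chamber_volume
    va = schedule.aliquot_volume * schedule.n_additions
    return (schedule.initial_concentration * v
            + schedule.stock_concentration * va) / (v + va)


def asymmetry_factor(top: float, bottom: float) -> float:
    """Calcium asymmetry factor ``x`` = top / bottom concentration."""
    if top <= 0 or bottom <= 0:
        raise DomainError(
            f"concentrations must be positive, got top={top}, bottom={bottom}")
    return top / bottom


def read_manifest(path) -> pd.DataFrame:
    """Read a series manifest CSV (``trace_path,lipid,x_factor``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:
        raise FormatError(f"{path}: {err}") from err
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def run_series(
    entries,
    config: AnalysisConfig | None = None,
    schedule: AsymmetrySchedule | None = None,
    base_dir=None,
) -> pd.DataFrame:
    """Analyze a series of traces recorded at different asymmetry factors.

    Parameters
    ----------
    entries:
        Iterable of ``(trace_path, lipid, x_factor)`` tuples, a manifest
        DataFrame, or a path to a manifest CSV.  ``x_factor`` may be NaN, in
        which case it is taken from the trace metadata or, failing that,
        computed from ``schedule``.
    config:
        Analysis configuration applied to every trace.
    schedule:
        Optional dilution schedule used to fill in missing x values
        (``n_additions`` is taken as the 0-based position of the trace in
        the series).
    base_dir:
        Directory against which relative trace paths are resolved.

    Returns
    -------
    pandas.DataFrame
        One row per condition, ordered by ``x_factor``, with columns
        ``x_factor, lipid, thickness_m, bending_rigidity_J`` and, when more
        than one row is present, percent changes relative to the row with
        the smallest x (the symmetric reference).  The output is invariant
        to the input file order.

    Raises
    ------
    ConfigurationError
        If traces carry mixed lipid labels (explicit grouping required).
    """
    if isinstance(entries, (str, Path)):
        entries = read_manifest(entries)
    if isinstance(entries, pd.DataFrame):
        records = list(entries[list(MANIFEST_COLUMNS)].itertuples(index=False))
    else:
        records = [tuple(e) for e in entries]

    rows = []
    for i, (trace_path, lipid, x) in enumerate(records):
        p = Path(trace_path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        trace = read_trace(p)
        if x is None or (isinstance(x, float) and np.isnan(x)):
            if "x_factor" in trace.metadata:
                x = float(trace.metadata["x_factor"])
            elif schedule is not None:
                from dataclasses import replace
                top = concentration_after_additions(
                    replace(schedule, n_additions=i))
                x = asymmetry_factor(top, schedule.bottom_concentration)
            else:
                raise ConfigurationError(
                    f"{p}: no x_factor in manifest, metadata or schedule")
        lipid = str(lipid) if lipid is not None else str(
            trace.metadata.get("lipid", ""))
        report = run_analysis(trace, config)
        interval = report.result.bending_rigidity_interval
        rows.append(ConditionResult(
            x_factor=float(x),
            lipid=lipid,
            thickness=report.state.zero_field_thickness,
            bending_rigidity=report.result.bending_rigidity,
            bending_rigidity_interval=interval,
        ))

    lipids = {r.lipid for r in rows}
    if len(lipids) > 1:
        raise ConfigurationError(
            f"mixed lipid labels {sorted(lipids)}; analyze each lipid series "
            "separately")

    rows.sort(key=lambda r: r.x_factor)
    df = pd.DataFrame({
        "x_factor": [r.x_factor for r in rows],
        "lipid": [r.lipid for r in rows],
        "thickness_m": [r.thickness for r in rows],
        "bending_rigidity_J": [r.bending_rigidity for r in rows],
    })
    if any(r.bending_rigidity_interval for r in rows):
        df["bending_rigidity_ci_low_J"] = [
            r.bending_rigidity_interval[0] if r.bending_rigidity_interval
            else np.nan for r in rows]
        df["bending_rigidity_ci_high_J"] = [
            r.bending_rigidity_interval[1] if r.bending_rigidity_interval
            else np.nan for r in rows]
    if len(df) > 1:
        ref = df.iloc[0]
        df["thickness_pct_change"] = 100.0 * (
            df["thickness_m"] / ref["thickness_m"] - 1.0)
        df["bending_rigidity_pct_change"] = 100.0 * (
            df["bending_rigidity_J"] / ref["bending_rigidity_J"] - 1.0)
    return df
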