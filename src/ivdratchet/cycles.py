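"""Per-cycle metrics for stress-controlled cyclic compression records.

Segments a stress–strain time series into load cycles and extracts, per
cycle: valley and peak strain, ratcheting strain (their mean), strain range,
and the loading-branch secant compression stiffness in N/mm.

Conventions
-----------
* Compression is positive for both stress and strain.
* Cycle indexing is 1-based ("the 400th cycle" is ``cycle == 400``).
* The valley strain of a cycle is taken at the commanded stress-valley
  sample that opens the cycle (not the global strain minimum within it),
  which is robust to the hysteresis-loop shape; the peak strain is taken at
  the sample of maximum commanded stress within the cycle.
* The ratcheting strain rate is the per-cycle increment dε_r/dN, computed
  with central finite differences (one-sided at the ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .synthetic import LoadingProtocol, SpecimenGeometry, StressStrainSeries

__all__ = [
    "CycleSummary",
    "RatchetingCurve",
    "SegmentationError",
    "DegenerateCycleError",
    "segment_cycles",
    "ratcheting_strain",
    "ratcheting_rate",
    "compression_stiffness",
    "cycle_summaries",
    "build_ratcheting_curve",
    "curve_from_summaries",
    "write_summaries",
    "read_summaries",
]

SUMMARY_COLUMNS = [
    "cycle",
    "strain_min",
    "strain_max",
    "ratcheting_strain",
    "strain_range",
    "stiffness_N_per_mm",
]


class SegmentationError(ValueError):
    """The series cannot be segmented with the given protocol."""


class DegenerateCycleError(ValueError):
    """A cycle has no usable loading branch (zero displacement span)."""


@dataclass(frozen=True)
class CycleSummary:
    """Metrics of one load cycle.

    Attributes
    ----------
    cycle_index : int
        1-based cycle number N.
    strain_min, strain_max : float
        Valley and peak strain of the cycle (dimensionless, compression
        positive).
    ratcheting_strain : float
        (strain_min + strain_max) / 2.
    strain_range : float
        strain_max - strain_min.
    stiffness : float or None
        Loading-branch secant stiffness in N/mm; ``None`` when no specimen
        geometry was supplied.
    """

    cycle_index: int
    strain_min: float
    strain_max: float
    ratcheting_strain: float
    strain_range: float
    stiffness: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cycle_index < 1:
            raise ValueError("cycle_index must be >= 1")
        if not (
            self.strain_min - 1e-12
            <= self.ratcheting_strain
            <= self.strain_max + 1e-12
        ):
            raise ValueError("ratcheting strain must lie between valley and peak")
        if self.strain_range < -1e-12:
            raise ValueError("strain_range must be non-negative")


@dataclass
class RatchetingCurve:
    """Ratcheting strain and its per-cycle rate as functions of cycle number.

    Carries the condition metadata (stress variation Δσ in MPa, stress rate
    in MPa/s, spinal segment label, replicate id) so that downstream fitting
    and statistics can group curves by condition. ``stiffness`` is optional
    and aligned with ``cycle_indices`` when present.
    """

    cycle_indices: np.ndarray
    ratcheting_strain: np.ndarray
    ratcheting_rate: np.ndarray
    stress_variation: Optional[float] = None
    stress_rate: Optional[float] = None
    segment: Optional[str] = None
    replicate: Optional[int] = None
    stiffness: Optional[np.ndarray] = field(default=None, repr=False)
    strain_range: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cycle_indices = np.asarray(self.cycle_indices)
        self.ratcheting_strain = np.asarray(self.ratcheting_strain, dtype=float)
        self.ratcheting_rate = np.asarray(self.ratcheting_rate, dtype=float)
        n = len(self.cycle_indices)
        if len(self.ratcheting_strain) != n or len(self.ratcheting_rate) != n:
            raise ValueError("curve arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.cycle_indices) > 0):
            raise ValueError("cycle_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cycle_indices)

    def at_cycle(self, cycle: int) -> float:
        """Ratcheting strain at a given 1-based cycle number."""
        idx = np.flatnonzero(self.cycle_indices == cycle)
        if idx.size == 0:
            raise KeyError(f"cycle {cycle} not present in curve")
        return float(self.ratcheting_strain[idx[0]])

    def stiffness_at_cycle(self, cycle: int) -> float:
        if self.stiffness is None:
            raise ValueError("curve carries no stiffness channel")
        idx = np.flatnonzero(self.cycle_indices == cycle)
        if idx.size == 0:
            raise KeyError(f"cycle {cycle} not present in curve")
        return float(np.asarray(self.stiffness)[idx[0]])


def segment_cycles(
    series: "StressStrainSeries",
    protocol: "LoadingProtocol",
    *,
    valley_tol_frac: float = 0.05,
) -> list[tuple[int, int]]:
    """Split a record into complete cycles, valley to valley.

    Boundaries are placed on the commanded-stress time grid at integer
    multiples of the protocol period from the first sample; a trailing
    partial cycle is discarded.

    Parameters
    ----------
    series : StressStrainSeries
    protocol : LoadingProtocol
        Supplies the cycle period and the valley stress level.
    valley_tol_frac : float
        Stress tolerance at cycle boundaries, as a fraction of Δσ. A
        boundary sample whose stress is further than this from the commanded
        valley indicates a series/protocol mismatch.

    Returns
    -------
    list of (start, end) sample-index pairs, end inclusive.
    """
    time = np.asarray(series.time, dtype=float)
    stress = np.asarray(series.stress, dtype=float)
    if time.size < 2:
        raise SegmentationError("series too short to segment")
    period = protocol.period
    dt = float(np.median(np.diff(time)))
    span = time[-1] - time[0]
    n_complete = int(np.floor(span / period + 1e-9))
    if n_complete < 1:
        raise SegmentationError(
            f"series covers {span:.3g}s, less than one protocol period {period:.3g}s"
        )
    boundaries = []
    for k in range(n_complete + 1):
        target = time[0] + k * period
        idx = int(np.searchsorted(time, target))
        # pick the nearest of the two candidate samples
        if idx >= time.size or (
            idx > 0 and target - time[idx - 1] <= time[idx] - target
        ):
            idx -= 1
        if abs(time[idx] - target) > 0.5 * dt + 1e-9:
            raise SegmentationError(
                "sampling grid inconsistent with the protocol period "
                f"(no sample within dt/2 of t={target:.6g}s)"
            )
        if abs(stress[idx] - protocol.stress_valley) > valley_tol_frac * protocol.stress_variation:
            raise SegmentationError(
                f"stress at cycle boundary t={time[idx]:.6g}s is "
                f"{stress[idx]:.4g} MPa, not the commanded valley "
                f"{protocol.stress_valley:.4g} MPa"
            )
        boundaries.append(idx)
    return [(boundaries[k], boundaries[k + 1]) for k in range(n_complete)]


def ratcheting_strain(strain_min, strain_max):
    """Mean of valley and peak strain of a cycle, (ε_min + ε_max) / 2."""
    smin = np.asarray(strain_min, dtype=float)
    smax = np.asarray(strain_max, dtype=float)
    if np.any(smin > smax):
        raise ValueError("strain_min must not exceed strain_max")
    out = 0.5 * (smin + smax)
    if out.ndim == 0:
        return float(out)
    return out


def ratcheting_rate(values, cycle_indices=None):
    """Per-cycle ratcheting strain rate dε_r/dN.

    Central finite differences in the interior, one-sided at the ends;
    the result has the same length as the input.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("ratcheting rate needs at least two cycles")
    if cycle_indices is None:
        return np.gradient(y)
    return np.gradient(y, np.asarray(cycle_indices, dtype=float))


def compression_stiffness(stress, strain, geometry: "SpecimenGeometry") -> float:
    """Loading-branch secant stiffness of one cycle, in N/mm.

    Force is stress times disc area (MPa·mm² = N) and displacement is strain
    times disc height, so the secant (F_peak − F_valley)/(d_peak − d_valley)
    is evaluated between the cycle-opening valley sample and the sample of
    maximum stress.
    """
    stress = np.asarray(stress, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if stress.size < 2:
        raise DegenerateCycleError("cycle must contain at least two samples")
    peak = int(np.argmax(stress))
    d_span = (strain[peak] - strain[0]) * geometry.height
    if abs(d_span) < 1e-15:
        raise DegenerateCycleError("zero displacement span over the loading branch")
    f_span = (stress[peak] - stress[0]) * geometry.area
    return float(f_span / d_span)


def cycle_summaries(
    series: "StressStrainSeries",
    protocol: "LoadingProtocol",
    geometry: Optional["SpecimenGeometry"] = None,
) -> pd.DataFrame:
    """Per-cycle metric table with the columns of ``SUMMARY_COLUMNS``."""
    segments = segment_cycles(series, protocol)
    stress = np.asarray(series.stress, dtype=float)
    strain = np.asarray(series.strain, dtype=float)
    rows = []
    for n, (s, e) in enumerate(segments, start=1):
        peak = s + int(np.argmax(stress[s : e + 1]))
        smin = float(strain[s])
        smax = float(strain[peak])
        stiff = np.nan
        if geometry is not None:
            stiff = compression_stiffness(
                stress[s : e + 1], strain[s : e + 1], geometry
            )
        rows.append(
            (n, smin, smax, ratcheting_strain(smin, smax), smax - smin, stiff)
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def build_ratcheting_curve(
    series: "StressStrainSeries",
    protocol: "LoadingProtocol",
    geometry: Optional["SpecimenGeometry"] = None,
) -> RatchetingCurve:
    """Segment a record and assemble its ratcheting curve (ε_r and dε_r/dN)."""
    table = cycle_summaries(series, protocol, geometry)
    meta = getattr(series, "metadata", {}) or {}
    stiffness = None
    if geometry is not None:
        stiffness = table["stiffness_N_per_mm"].to_numpy()
    return RatchetingCurve(
        cycle_indices=table["cycle"].to_numpy(),
        ratcheting_strain=table["ratcheting_strain"].to_numpy(),
        ratcheting_rate=ratcheting_rate(
            table["ratcheting_strain"].to_numpy(), table["cycle"].to_numpy()
        ),
        stress_variation=protocol.stress_variation,
        stress_rate=protocol.stress_rate,
        segment=meta.get("segment"),
        replicate=meta.get("replicate"),
        stiffness=stiffness,
        strain_range=table["strain_range"].to_numpy(),
    )


def curve_from_summaries(table: pd.DataFrame, metadata: Optional[dict] = None) -> RatchetingCurve:
    """Rebuild a RatchetingCurve from a per-cycle summary table."""
    meta = metadata or {}
    cycles = table["cycle"].to_numpy()
    eps_r = table["ratcheting_strain"].to_numpy()
    stiffness = None
    if "stiffness_N_per_mm" in table and not table["stiffness_N_per_mm"].isna().all():
        stiffness = table["stiffness_N_per_mm"].to_numpy()
    return RatchetingCurve(
        cycle_indices=cycles,
        ratcheting_strain=eps_r,
        ratcheting_rate=ratcheting_rate(eps_r, cycles),
        stress_variation=meta.get("stress_variation"),
        stress_rate=meta.get("stress_rate"),
        segment=meta.get("segment"),
        replicate=meta.get("replicate"),
        stiffness=stiffness,
        strain_range=table["strain_range"].to_numpy()
        if "strain_range" in table
        else None,
    )


def write_summaries(table: pd.DataFrame, path) -> None:
    """Write a per-cycle summary table as CSV (strain dimensionless, stiffness N/mm)."""
    table.to_csv(path, index=False, float_format="%.12g")


def read_summaries(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS[:5] if c not in table.columns]
    if missing:
        raise ValueError(f"summary file {path} lacks columns {missing}")
    return table
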