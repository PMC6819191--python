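"""Synthetic stress-controlled cyclic-compression test records.

Emulates uniaxial ratcheting tests on intervertebral disc specimens: a
triangular stress command (valley 0 MPa, peak = stress variation Δσ), a
strain response with a rate- and amplitude-dependent secant modulus, a
cycle-by-cycle ratcheting drift following the saturating evolution law of
:mod:`ivdratchet.model`, a hysteresis opening, and optional Gaussian
measurement noise. Compression is positive for both stress and strain in
every array and file written here.

The generated records reproduce the qualitative structure of real disc
tests: hysteresis loops densify with cycle number and remain unclosed,
ratcheting strain rises sharply then grows quasi-steadily, larger stress
variations ratchet more, faster stress rates ratchet less but appear
stiffer, and caudal (L6–7) segments ratchet less than L5–6.

The strain model of one record is::

    strain(t) = stress(t)/E + drift(N(t)) + hysteresis(t) + noise

* ``E = elastic_modulus_ref · (rate/0.59)^rate_stiffening_exponent
  · (Δσ/1.18)^amplitude_stiffening_exponent`` — a per-condition secant
  modulus (reference rate 0.59 MPa/s, reference amplitude 1.18 MPa).
* ``drift`` is the ratcheting evolution law scaled by ``segment_factor``
  and by ``(rate/0.59)^(-drift_rate_exponent)``, interpolated piecewise-
  linearly between per-cycle knots placed so that the mean of the valley
  and peak strain of cycle N equals exactly ``X_r(N) + Δσ/(2E)``.
* ``hysteresis`` is a half-sine per branch (``w·sin(2π·phase)``, positive
  on loading), which opens the loop while vanishing at valley and peak.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .model import URMKParams, evaluate

__all__ = [
    "REFERENCE_STRESS_RATE",
    "REFERENCE_STRESS_VARIATION",
    "MIN_SAMPLES_PER_RAMP",
    "DEFAULT_SEGMENT_FACTORS",
    "ProtocolError",
    "ResolutionError",
    "LoadingProtocol",
    "SpecimenGeometry",
    "SyntheticSpecimenParams",
    "StressStrainSeries",
    "Condition",
    "build_protocol",
    "generate_response",
    "generate_cohort",
    "area_from_dims",
    "table1_conditions",
    "segment_comparison_conditions",
    "protocol_from_metadata",
]

#: Reference stress rate for rate-dependence terms (MPa/s): central rate of
#: the loading matrix.
REFERENCE_STRESS_RATE = 0.59

#: Reference stress variation for the amplitude-stiffening term (MPa).
REFERENCE_STRESS_VARIATION = 1.18

MIN_SAMPLES_PER_RAMP = 20

#: Default drift scale per spinal segment; L6-7 ratchets less than L5-6.
DEFAULT_SEGMENT_FACTORS: Mapping[str, float] = {"L5-6": 1.0, "L6-7": 0.8}


class ProtocolError(ValueError):
    """Invalid loading-protocol specification."""


class ResolutionError(ProtocolError):
    """Sampling too coarse to resolve the loading ramps."""


@dataclass(frozen=True)
class LoadingProtocol:
    """Commanded triangular stress waveform of one stress-controlled test.

    Attributes
    ----------
    stress_variation : float
        Peak-to-valley stress amplitude Δσ in MPa (> 0).
    stress_rate : float
        Magnitude of dσ/dt on each ramp, MPa/s (> 0).
    n_cycles : int
        Number of commanded cycles (>= 1).
    stress_valley : float
        Valley stress in MPa (0 in the disc tests).
    samples_per_ramp : int
        Samples on each loading/unloading ramp (>= 20); the grid contains
        every valley and peak exactly, so per-cycle extrema are sampled.
    """

    stress_variation: float
    stress_rate: float
    n_cycles: int
    stress_valley: float = 0.0
    samples_per_ramp: int = 25

    def __post_init__(self) -> None:
        if self.stress_variation <= 0:
            raise ProtocolError("stress_variation must be > 0")
        if self.stress_rate <= 0:
            raise ProtocolError("stress_rate must be > 0")
        if self.n_cycles < 1:
            raise ProtocolError("n_cycles must be >= 1")
        if self.samples_per_ramp < MIN_SAMPLES_PER_RAMP:
            raise ResolutionError(
                f"each ramp must contain >= {MIN_SAMPLES_PER_RAMP} samples "
                f"(got {self.samples_per_ramp})"
            )

    @property
    def ramp_duration(self) -> float:
        """Duration of one loading (or unloading) ramp, s."""
        return self.stress_variation / self.stress_rate

    @property
    def period(self) -> float:
        """Cycle period 2·Δσ/rate, s."""
        return 2.0 * self.ramp_duration

    @property
    def dt(self) -> float:
        return self.ramp_duration / self.samples_per_ramp

    @property
    def sampling_rate(self) -> float:
        """Effective sampling rate, Hz."""
        return 1.0 / self.dt

    @property
    def n_samples(self) -> int:
        """Total samples including the terminal valley."""
        return 2 * self.samples_per_ramp * self.n_cycles + 1

    @property
    def peak_stress(self) -> float:
        return self.stress_valley + self.stress_variation

    def waveform(self) -> tuple[np.ndarray, np.ndarray]:
        """Sampled commanded waveform (time in s, stress in MPa)."""
        m = self.samples_per_ramp
        i = np.arange(self.n_samples)
        pos = i % (2 * m)
        tri = np.where(pos <= m, pos / m, (2 * m - pos) / m)
        # terminal sample closes the last cycle at the valley
        tri[-1] = 0.0
        return i * self.dt, self.stress_valley + self.stress_variation * tri

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_protocol(
    stress_variation: float,
    stress_rate: float,
    n_cycles: int,
    sampling_rate: Optional[float] = None,
) -> LoadingProtocol:
    """Validated triangular-wave protocol.

    When ``sampling_rate`` (Hz) is given, the grid is snapped to the nearest
    integer number of samples per ramp so that valleys and peaks fall on
    samples; fewer than 20 samples per ramp raises :class:`ResolutionError`.
    Without it, 25 samples per ramp are used.
    """
    if stress_variation <= 0 or stress_rate <= 0 or n_cycles < 1:
        raise ProtocolError(
            "stress_variation, stress_rate must be positive and n_cycles >= 1"
        )
    if sampling_rate is None:
        spr = 25
    else:
        if sampling_rate <= 0:
            raise ProtocolError("sampling_rate must be > 0")
        spr = int(round(sampling_rate * stress_variation / stress_rate))
        if spr < MIN_SAMPLES_PER_RAMP:
            raise ResolutionError(
                f"sampling_rate {sampling_rate} Hz yields {spr} samples per "
                f"ramp; >= {MIN_SAMPLES_PER_RAMP} required"
            )
    return LoadingProtocol(
        stress_variation=float(stress_variation),
        stress_rate=float(stress_rate),
        n_cycles=int(n_cycles),
        samples_per_ramp=spr,
    )


def area_from_dims(length: float, width: float, k: float = 1.01) -> float:
    """Elliptic disc area (π/4)·length·width scaled by the coefficient k.

    Lengths in mm, area in mm². The coefficient k (≈ 1.01) corrects the
    ideal-ellipse area to the measured cross-section.
    """
    if length <= 0 or width <= 0 or k <= 0:
        raise ValueError("length, width and k must be positive")
    return float(np.pi / 4.0 * length * width * k)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Disc cross-section area S (mm²) and height h (mm).

    May be built from measured length/width via the elliptic-area formula
    or given the area directly. Typical ovine lumbar values are
    S ≈ 394 mm², h ≈ 3.98 mm.
    """

    height: float
    area: Optional[float] = None
    length: Optional[float] = None
    width: Optional[float] = None
    area_coefficient: float = 1.01

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.area_coefficient <= 0:
            raise ValueError("area_coefficient must be positive")
        if self.area is None:
            if self.length is None or self.width is None:
                raise ValueError("give either area or both length and width")
            object.__setattr__(
                self,
                "area",
                area_from_dims(self.length, self.width, self.area_coefficient),
            )
        else:
            if self.area <= 0:
                raise ValueError("area must be positive")
            if self.length is not None and self.width is not None:
                expected = area_from_dims(
                    self.length, self.width, self.area_coefficient
                )
                if abs(expected - self.area) > 1e-6 * expected:
                    raise ValueError(
                        f"area {self.area} mm² inconsistent with dimensions "
                        f"({expected:.6g} mm² expected)"
                    )

    @classmethod
    def typical(cls) -> "SpecimenGeometry":
        """Typical ovine lumbar disc: S = 394 mm², h = 3.98 mm."""
        return cls(height=3.98, area=394.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SyntheticSpecimenParams:
    """Material parameters of one synthetic disc specimen.

    Attributes
    ----------
    elastic_modulus_ref : float
        Secant modulus (MPa) at the reference rate 0.59 MPa/s and reference
        amplitude 1.18 MPa.
    rate_stiffening_exponent : float
        Power-law exponent of modulus on stress rate (>= 0): faster loading
        appears stiffer.
    amplitude_stiffening_exponent : float
        Power-law exponent of modulus on stress variation (>= 0): larger
        amplitudes engage a stiffer secant response.
    drift_params : URMKParams
        Constitutive parameters governing the ratcheting drift.
    drift_rate_exponent : float
        Attenuates the drift as (rate/0.59)^(-exponent) (>= 0): faster
        loading ratchets less.
    segment_factor : float
        Multiplicative drift scale in (0, 1]; < 1 for more ratcheting-
        resistant segments (L6-7).
    hysteresis_width : float
        Strain amplitude of the half-sine loop opening (>= 0).
    noise_sd : float
        Standard deviation of additive Gaussian strain noise (>= 0); the
        stress channel is commanded and noise-free.
    seed : int
        Seed of the noise generator; with ``noise_sd = 0`` the record is
        bit-reproducible regardless.
    """

    elastic_modulus_ref: float = 5.0
    rate_stiffening_exponent: float = 0.1
    amplitude_stiffening_exponent: float = 0.15
    drift_params: URMKParams = field(default_factory=URMKParams)
    drift_rate_exponent: float = 0.3
    segment_factor: float = 1.0
    hysteresis_width: float = 0.004
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elastic_modulus_ref <= 0:
            raise ValueError("elastic_modulus_ref must be > 0")
        for name in (
            "rate_stiffening_exponent",
            "amplitude_stiffening_exponent",
            "drift_rate_exponent",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.segment_factor <= 1.0):
            raise ValueError("segment_factor must lie in (0, 1]")
        if self.hysteresis_width < 0:
            raise ValueError("hysteresis_width must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def modulus(self, protocol: LoadingProtocol) -> float:
        """Per-condition secant modulus E(rate, Δσ), MPa."""
        return (
            self.elastic_modulus_ref
            * (protocol.stress_rate / REFERENCE_STRESS_RATE)
            ** self.rate_stiffening_exponent
            * (protocol.stress_variation / REFERENCE_STRESS_VARIATION)
            ** self.amplitude_stiffening_exponent
        )

    def drift_scale(self, protocol: LoadingProtocol) -> float:
        """Dimensionless multiplier on the ratcheting drift."""
        return self.segment_factor * (
            protocol.stress_rate / REFERENCE_STRESS_RATE
        ) ** (-self.drift_rate_exponent)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_params"] = dataclasses.asdict(self.drift_params)
        return d


@dataclass
class StressStrainSeries:
    """One sampled test record: time (s), stress (MPa), strain (—).

    Compression positive throughout. ``metadata`` holds the protocol, the
    specimen parameters, the segment label, the replicate id and the seed.
    """

    time: np.ndarray
    stress: np.ndarray
    strain: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if not (self.time.size == self.stress.size == self.strain.size):
            raise ValueError("time, stress and strain must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_csv(self, path) -> None:
        """Write `time_s,stress_MPa,strain` CSV plus a JSON metadata sidecar.

        Compression is positive for both stress and strain.
        """
        path = Path(path)
        pd.DataFrame(
            {"time_s": self.time, "stress_MPa": self.stress, "strain": self.strain}
        ).to_csv(path, index=False, float_format="%.12g")
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(
            json.dumps(
                {"convention": "compression positive", **self.metadata},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_csv(cls, path) -> "StressStrainSeries":
        path = Path(path)
        table = pd.read_csv(path)
        for col in ("time_s", "stress_MPa", "strain"):
            if col not in table.columns:
                raise ValueError(f"{path} lacks column {col!r}")
        if table.empty:
            raise ValueError(f"{path} contains no samples")
        metadata = {}
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            metadata = json.loads(sidecar.read_text())
        return cls(
            time=table["time_s"].to_numpy(),
            stress=table["stress_MPa"].to_numpy(),
            strain=table["strain"].to_numpy(),
            metadata=metadata,
        )


def protocol_from_metadata(metadata: Mapping) -> LoadingProtocol:
    """Rebuild the loading protocol from a series metadata sidecar."""
    proto = metadata.get("protocol")
    if proto is None:
        raise ValueError("metadata carries no protocol entry")
    return LoadingProtocol(**proto)


# --------------------------------------------------------------------------
# response generation
# --------------------------------------------------------------------------


def _drift_knots(protocol: LoadingProtocol, params: SyntheticSpecimenParams) -> np.ndarray:
    """Drift values at each commanded valley and peak.

    Knots are placed so that the mean of the cycle-N valley and peak drift
    equals exactly X_r(N): valley_N = X_N − ΔX_N/2 and peak_N = X_N + ΔX_N/2
    with ΔX_N = X_{N+1} − X_N. Because the evolution increments decrease
    with N, the knot sequence is monotone and each loop stays unclosed.
    """
    n = protocol.n_cycles
    scale = params.drift_scale(protocol)
    X = scale * np.asarray(
        evaluate(np.arange(1, n + 3), protocol.peak_stress, params.drift_params),
        dtype=float,
    )
    knots = np.empty(2 * n + 1)
    knots[0::2] = 1.5 * X[: n + 1] - 0.5 * X[1 : n + 2]  # valleys of cycles 1..n+1
    knots[1::2] = 0.5 * (X[:n] + X[1 : n + 1])  # peaks of cycles 1..n
    return knots


def generate_response(
    protocol: LoadingProtocol,
    params: SyntheticSpecimenParams,
    segment: str = "L5-6",
    replicate: int = 0,
) -> StressStrainSeries:
    """Simulate one stress-controlled cyclic compression record.

    The per-cycle ratcheting strain of the output equals
    ``drift(N) + Δσ/(2·E)`` exactly (to rounding), the stress channel
    reproduces the commanded waveform, and with ``noise_sd = 0`` the output
    is bit-reproducible for a fixed seed.
    """
    if not isinstance(protocol, LoadingProtocol):
        raise ProtocolError("protocol must be a LoadingProtocol")
    m = protocol.samples_per_ramp
    time, stress = protocol.waveform()
    E = params.modulus(protocol)
    elastic = stress / E

    knots = _drift_knots(protocol, params)
    half_pos = np.arange(protocol.n_samples) / m  # in half-period units
    drift = np.interp(half_pos, np.arange(knots.size, dtype=float), knots)

    phase = (np.arange(protocol.n_samples) % (2 * m)) / (2 * m)
    phase[-1] = 0.0
    hysteresis = params.hysteresis_width * np.sin(2.0 * np.pi * phase)

    strain = elastic + drift + hysteresis
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        strain = strain + rng.normal(0.0, params.noise_sd, size=strain.size)

    return StressStrainSeries(
        time=time,
        stress=stress,
        strain=strain,
        metadata={
            "protocol": protocol.to_dict(),
            "specimen_params": params.to_dict(),
            "segment": segment,
            "replicate": int(replicate),
            "seed": int(params.seed),
            "stress_variation": protocol.stress_variation,
            "stress_rate": protocol.stress_rate,
            "secant_modulus_MPa": E,
        },
    )


class Condition(NamedTuple):
    """One cohort cell: a protocol, a spinal segment label, replicates."""

    protocol: LoadingProtocol
    segment: str = "L5-6"
    n_replicates: int = 3


def generate_cohort(
    conditions: Sequence[Condition],
    base_params: SyntheticSpecimenParams = SyntheticSpecimenParams(),
    seed: int = 0,
    modulus_jitter_sd: float = 0.03,
    drift_jitter_sd: float = 0.08,
    segment_factors: Mapping[str, float] = DEFAULT_SEGMENT_FACTORS,
) -> list[StressStrainSeries]:
    """Simulate a cohort of replicated tests across loading conditions.

    Replicate-level inter-specimen variability is log-normal on the secant
    modulus (sd ``modulus_jitter_sd`` in log space) and on the drift
    amplitude (sd ``drift_jitter_sd``); both default to modest matched-
    specimen levels and may be set to 0 for identical replicates. Per-series
    seeds derive deterministically from ``(seed, condition index, replicate
    index)``, so a cohort is fully reproducible. Segment labels map to drift
    scales through ``segment_factors`` (unlisted labels get 1.0).
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    out = []
    for ci, cond in enumerate(conditions):
        if cond.n_replicates < 1:
            raise ValueError("each condition needs at least one replicate")
        factor = float(segment_factors.get(cond.segment, 1.0))
        for ri in range(cond.n_replicates):
            ss = np.random.SeedSequence((int(seed), ci, ri))
            rng = np.random.default_rng(ss)
            mod_f = float(np.exp(rng.normal(0.0, modulus_jitter_sd))) if modulus_jitter_sd > 0 else 1.0
            drift_f = float(np.exp(rng.normal(0.0, drift_jitter_sd))) if drift_jitter_sd > 0 else 1.0
            params = dataclasses.replace(
                base_params,
                elastic_modulus_ref=base_params.elastic_modulus_ref * mod_f,
                drift_params=dataclasses.replace(
                    base_params.drift_params,
                    K=base_params.drift_params.K * drift_f,
                ),
                segment_factor=factor,
                seed=int(ss.generate_state(1)[0] % 2**31),
            )
            series = generate_response(cond.protocol, params, cond.segment, ri)
            series.metadata["condition_index"] = ci
            out.append(series)
    return out


# --------------------------------------------------------------------------
# standard condition matrices
# --------------------------------------------------------------------------

#: (specimen region, stress variation MPa, stress rate MPa/s) rows of the
#: disc ratcheting loading matrix.
LOADING_MATRIX = (
    ("L1-L4", 0.59, 0.13),
    ("L1-L4", 0.59, 0.4),
    ("L1-L4", 0.59, 1.18),
    ("L4-L7", 0.59, 0.59),
    ("L4-L7", 0.88, 0.59),
    ("L4-L7", 1.18, 0.59),
    ("L4-L7", 1.76, 0.59),
    ("L1-L4", 1.76, 0.4),
    ("L1-L4", 1.76, 0.59),
    ("L1-L4", 1.76, 1.18),
)


def table1_conditions(
    n_cycles: int = 400,
    n_replicates: int = 3,
    sampling_rate: Optional[float] = None,
) -> list[Condition]:
    """The ten-condition loading matrix of the disc ratcheting study."""
    return [
        Condition(
            build_protocol(ds, rate, n_cycles, sampling_rate), region, n_replicates
        )
        for region, ds, rate in LOADING_MATRIX
    ]


def segment_comparison_conditions(
    n_cycles: int = 400,
    n_replicates: int = 3,
    stress_variations: Sequence[float] = (0.59, 1.18, 1.76),
    stress_rate: float = 0.59,
) -> list[Condition]:
    """L5-6 vs L6-7 comparison cells at several stress variations."""
    out = []
    for segment in ("L5-6", "L6-7"):
        for ds in stress_variations:
            out.append(
                Condition(
                    build_protocol(ds, stress_rate, n_cycles), segment, n_replicates
                )
            )
    return out
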