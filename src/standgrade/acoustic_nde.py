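"""Time-of-flight acoustics: raw hit series to tree velocity and dynamic MOE.

A standing-tree acoustic tool times a hammer-induced stress wave between two
probes inserted in the stem.  Each measurement is a series of eight hits;
the instrument averages them after deducting the constant transit time
through the metal probe tips, and the probe separation is measured
ultrasonically between the sensors, so the sensor-to-tip offsets are
deducted from the raw distance.  Velocity is then simply distance over
time, and the one-dimensional wave equation V = sqrt(MOE_D / rho) links it
to dynamic stiffness given green density.

Velocities are carried in km·s⁻¹ (numerically equal to mm/µs); the wave
equation operates in SI with explicit converters.  Note kN·mm⁻² ≡ GPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

#: Default QC threshold: relative spread of the middle four corrected times,
#: nominally ~2% on a ~300 µs time of flight.
DEFAULT_QC_THRESHOLD = 0.02

N_HITS = 8

KMS_TO_MS = 1_000.0  # km/s -> m/s
PA_TO_KN_MM2 = 1e-9  # N/m² -> kN/mm² (= GPa)


@dataclass(frozen=True)
class HitSeries:
    """One eight-hit acoustic measurement at a probe depth and direction.

    Parameters
    ----------
    raw_times_us : eight raw elapsed times in µs, each including the probe-tip
        transit constant.
    probe_constant_us : constant stress-wave transit time through the metal
        probe tips, deducted from every raw time.
    raw_distance_mm : ultrasonically measured sensor-to-sensor distance.
    sensor_offsets_mm : distance from each ultrasonic sensor to its probe tip;
        their sum is deducted from the raw distance.
    depth_cm : probe insertion depth (1.5 or 3.0 cm by convention).
    direction : cardinal direction label of the measurement face.
    """

    raw_times_us: tuple[float, ...]
    probe_constant_us: float
    raw_distance_mm: float
    sensor_offsets_mm: tuple[float, ...] = (0.0, 0.0)
    depth_cm: float = 3.0
    direction: str = "south"

    def __post_init__(self) -> None:
        if len(self.raw_times_us) != N_HITS:
            raise ValueError(f"expected {N_HITS} raw times, got {len(self.raw_times_us)}")
        if any(t <= self.probe_constant_us for t in self.raw_times_us):
            raise ValueError("raw time not greater than probe-tip constant")
        if self.corrected_distance_mm <= 0:
            raise ValueError("corrected probe distance must be positive")

    @property
    def corrected_times_us(self) -> tuple[float, ...]:
        return tuple(t - self.probe_constant_us for t in self.raw_times_us)

    @property
    def corrected_distance_mm(self) -> float:
        return self.raw_distance_mm - sum(self.sensor_offsets_mm)


@dataclass(frozen=True)
class AcousticReading:
    """A processed velocity reading with its quality-control verdict."""

    velocity_kms: float
    qc_statistic: float
    qc_pass: bool
    depth_cm: float
    direction: str


class TreeVelocity(NamedTuple):
    velocity_kms: float
    n_readings: int
    depth_cm: float


def velocity_from_hits(
    hits: HitSeries, qc_threshold: float = DEFAULT_QC_THRESHOLD
) -> AcousticReading:
    """Average the eight per-hit velocities and score measurement spread.

    Per-hit velocity is corrected distance over corrected time; the reading
    velocity is the mean of the eight.  The QC statistic is the range of the
    middle four corrected times (after sorting) divided by their mean; the
    reading passes iff it does not exceed ``qc_threshold``.
    """
    times = np.asarray(hits.corrected_times_us, dtype=float)
    if np.any(times <= 0):
        raise ValueError("corrected hit time must be positive")
    d = hits.corrected_distance_mm
    velocities = d / times  # mm/µs == km/s
    mid4 = np.sort(times)[2:6]
    qc = float((mid4.max() - mid4.min()) / mid4.mean())
    return AcousticReading(
        velocity_kms=float(velocities.mean()),
        qc_statistic=qc,
        qc_pass=qc <= qc_threshold,
        depth_cm=hits.depth_cm,
        direction=hits.direction,
    )


def dynamic_moe(velocity_ms: float, green_density: float) -> float:
    """Dynamic MOE (N·m⁻²) from the one-dimensional wave equation, ρ·V².

    ``velocity_ms`` in m·s⁻¹, ``green_density`` in kg·m⁻³.
    """
    if velocity_ms <= 0:
        raise ValueError("velocity must be positive")
    if green_density <= 0:
        raise ValueError("green density must be positive")
    return green_density * velocity_ms**2


def velocity_from_moe(moe_d: float, green_density: float) -> float:
    """Inverse of :func:`dynamic_moe`: V = √(MOE_D/ρ), in m·s⁻¹."""
    if moe_d <= 0:
        raise ValueError("dynamic MOE must be positive")
    if green_density <= 0:
        raise ValueError("green density must be positive")
    return math.sqrt(moe_d / green_density)


def tree_velocity(
    readings: Iterable[AcousticReading], depth_cm: float = 3.0
) -> TreeVelocity:
    """Tree-level velocity: mean of QC-passing readings at one probe depth.

    Readings at other depths and readings failing QC are excluded; the count
    of readings actually used is reported alongside the mean.
    """
    used = [r.velocity_kms for r in readings if r.qc_pass and r.depth_cm == depth_cm]
    if not used:
        raise ValueError(f"no usable acoustic reading at depth {depth_cm} cm")
    return TreeVelocity(float(np.mean(used)), len(used), depth_cm)


def kn_mm2_from_velocity(velocity_kms: float, green_density: float) -> float:
    """Convenience: dynamic MOE in kN·mm⁻² (GPa) from velocity in km·s⁻¹."""
    return dynamic_moe(velocity_kms * KMS_TO_MS, green_density) * PA_TO_KN_MM2
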