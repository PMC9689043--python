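"""Linear-array model: excitation pulse, subaperture sweep, focal delays.

The probe is a 32-element linear array on the bottom (skin-side) face of
the muscle slab.  Acquisition sweeps a 5-element transmit subaperture one
element at a time, giving n_elements - 5 + 1 scan lines (28 for the
default array).  Each transmit applies per-element delays so the five
wavelets arrive simultaneously at a 10 mm focus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArraySpec",
    "PulseSpec",
    "DelayLaw",
    "SweepPlan",
    "SourceTerm",
    "pulse_waveform",
    "sweep_plan",
    "focal_delays",
    "element_drive",
]

MUSCLE_REFERENCE_VELOCITY = 1570.0


@dataclass(frozen=True)
class ArraySpec:
    """Element layout; the array is centered at x = 0 on the face y = 0."""

    n_elements: int = 32
    pitch: float = 0.05 / 32          # elements span the 50 mm aperture
    element_width_fraction: float = 0.8
    face_y: float = 0.0

    @property
    def element_width(self) -> float:
        return self.element_width_fraction * self.pitch

    @property
    def element_centers(self) -> np.ndarray:
        idx = np.arange(self.n_elements)
        return (idx - (self.n_elements - 1) / 2.0) * self.pitch

    @property
    def element_spans(self) -> np.ndarray:
        """(n_elements, 2) lateral extents [x_lo, x_hi] of each element."""
        c = self.element_centers
        half = self.element_width / 2.0
        return np.stack([c - half, c + half], axis=1)

    @classmethod
    def spanning(cls, width: float, n_elements: int = 32, **kw) -> "ArraySpec":
        return cls(n_elements=n_elements, pitch=width / n_elements, **kw)


@dataclass(frozen=True)
class PulseSpec:
    """Gaussian-windowed sine burst, peak-normalized to unit amplitude.

    Default envelope sigma of 1.5 cycles gives roughly a three-cycle
    pulse.  ``duration`` spans +-3 sigma about the envelope center.
    """

    f0: float = 2.0e6
    envelope_sigma: float | None = None
    duration: float | None = None

    @property
    def sigma(self) -> float:
        return self.envelope_sigma if self.envelope_sigma is not None else 1.5 / self.f0

    @property
    def total_duration(self) -> float:
        return self.duration if self.duration is not None else 6.0 * self.sigma

    @property
    def center_time(self) -> float:
        return self.total_duration / 2.0

    def sample(self, dt: float) -> np.ndarray:
        t = np.arange(0.0, self.total_duration + dt / 2, dt)
        return pulse_waveform(t, self)


def pulse_waveform(t: np.ndarray, spec: PulseSpec) -> np.ndarray:
    """sin(2 pi f0 (t - tc)) * exp(-(t - tc)^2 / (2 sigma^2)), peak = 1."""
    sigma = spec.sigma
    if sigma <= 0:
        raise ValueError("envelope sigma must be positive")
    if spec.total_duration < 6.0 * sigma - 1e-15:
        raise ValueError("duration must cover at least 6 sigma")
    t = np.asarray(t, dtype=float)
    tc = spec.center_time
    w = np.sin(2.0 * np.pi * spec.f0 * (t - tc)) * np.exp(-((t - tc) ** 2) / (2.0 * sigma**2))
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


@dataclass(frozen=True)
class SweepPlan:
    """Ordered sliding subaperture windows over the element indices."""

    n_elements: int
    aperture_size: int = 5
    step: int = 1

    @property
    def n_positions(self) -> int:
        return (self.n_elements - self.aperture_size) // self.step + 1

    @property
    def positions(self) -> list[range]:
        return [
            range(s, s + self.aperture_size)
            for s in range(0, self.n_elements - self.aperture_size + 1, self.step)
        ]


def sweep_plan(n_elements: int, aperture_size: int = 5, step: int = 1) -> SweepPlan:
    if aperture_size > n_elements:
        raise ValueError("aperture cannot exceed the element count")
    if (n_elements - aperture_size) % step != 0:
        raise ValueError("sweep step does not tile the array evenly")
    return SweepPlan(n_elements=n_elements, aperture_size=aperture_size, step=step)


@dataclass(frozen=True)
class DelayLaw:
    """Per-element transmit gates A in {0, 1} and delays B (s)."""

    gates: np.ndarray
    delays: np.ndarray


def focal_delays(
    x_positions: np.ndarray,
    focus_depth: float = 0.010,
    c_ref: float = MUSCLE_REFERENCE_VELOCITY,
) -> np.ndarray:
    """Delays equalizing arrival at the on-axis focus.

    With path_i = sqrt(focus_depth^2 + (x_i - x_center)^2), element i is
    delayed by (max_j path_j - path_i) / c_ref: the outermost elements
    (longest paths) fire first, the center element last, and all wavelets
    meet at the focus simultaneously.
    """
    if focus_depth <= 0:
        raise ValueError("focus depth must be positive")
    x = np.asarray(x_positions, dtype=float)
    xc = x.mean()
    paths = np.hypot(focus_depth, x - xc)
    return (paths.max() - paths) / c_ref


@dataclass(frozen=True)
class SourceTerm:
    """One driven element: waveform samples at uniform dt, delayed onset."""

    element_index: int
    waveform: np.ndarray
    dt: float
    onset_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_delay < 0:
            raise ValueError("onset delay must be non-negative")
        if not np.isfinite(self.waveform).all():
            raise ValueError("waveform must be finite")


def element_drive(
    sweep_index: int,
    plan: SweepPlan,
    array: ArraySpec,
    pulse: PulseSpec,
    dt: float,
    focus_depth: float = 0.010,
    c_ref: float = MUSCLE_REFERENCE_VELOCITY,
) -> list[SourceTerm]:
    """Source terms for one sweep position: the shared pulse, gated to the
    5-element window and shifted by each element's focal delay."""
    positions = plan.positions
    if not 0 <= sweep_index < len(positions):
        raise IndexError(f"sweep index {sweep_index} outside plan of {len(positions)}")
    window = positions[sweep_index]
    centers = array.element_centers
    delays = focal_delays(centers[list(window)], focus_depth=focus_depth, c_ref=c_ref)
    waveform = pulse.sample(dt)
    return [
        SourceTerm(element_index=e, waveform=waveform, dt=dt, onset_delay=d)
        for e, d in zip(window, delays)
    ]
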