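"""B-scan formation from RF traces.

The chain mirrors a classic research scanner backend: per-trace
logarithmic amplification, Hilbert envelope detection, fixed-focus
receive delay-and-sum over the 5-element subaperture, lateral
interpolation, and log-scale display normalization.  The default order
applies the log amplifier *before* envelope detection — the chain this
simulator models; the conventional order (beamform -> envelope -> log)
is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .dataset import RFDataset
from .probe import focal_delays

__all__ = [
    "BScanImage",
    "log_amplify",
    "envelope",
    "beamform_line",
    "compose_bscan",
]


@dataclass
class BScanImage:
    """Log-envelope image, depth x lateral, normalized to 0 dB peak."""

    intensity: np.ndarray          # dB, in [-dynamic_range, 0]
    depth_axis: np.ndarray         # m, depth = c_ref * t / 2
    lateral_axis: np.ndarray       # m
    dynamic_range: float

    @property
    def linear(self) -> np.ndarray:
        """Amplitude on a linear scale (1.0 at the image peak)."""
        return 10.0 ** (self.intensity / 20.0)

    def save_npz(self, path) -> None:
        np.savez(
            path,
            intensity=self.intensity,
            depth_axis=self.depth_axis,
            lateral_axis=self.lateral_axis,
            dynamic_range=self.dynamic_range,
        )

    @classmethod
    def load_npz(cls, path) -> "BScanImage":
        d = np.load(path)
        return cls(
            intensity=d["intensity"],
            depth_axis=d["depth_axis"],
            lateral_axis=d["lateral_axis"],
            dynamic_range=float(d["dynamic_range"]),
        )

    def save_png(self, path) -> None:
        from PIL import Image

        gray = (self.intensity + self.dynamic_range) / self.dynamic_range
        img = (np.clip(gray, 0.0, 1.0) * 255).astype(np.uint8)
        # rows = depth (top of image = shallow), columns = lateral
        Image.fromarray(img, mode="L").save(path)


def log_amplify(x: np.ndarray, x_ref: float | None = None) -> np.ndarray:
    """Sign-preserving logarithmic compression.

    y = sign(x) log10(1 + |x| / x_ref).  The reference defaults to the
    peak magnitude divided by 1000, i.e. a 60 dB compression window; an
    all-zero input passes through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("log amplifier requires finite samples")
    if x_ref is None:
        peak = np.abs(x).max()
        if peak == 0.0:
            return x.copy()
        x_ref = peak / 1.0e3
    return np.sign(x) * np.log10(1.0 + np.abs(x) / x_ref)


def envelope(trace: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert-transform envelope)."""
    return np.abs(hilbert(np.asarray(trace, dtype=float), axis=axis))


def _shift_advance(trace: np.ndarray, advance: float, dt: float) -> np.ndarray:
    """Advance a trace in time (fractional-sample, linear interpolation),
    zero-filling past the end."""
    n = len(trace)
    t = np.arange(n) * dt
    return np.interp(t + advance, t, trace, left=0.0, right=0.0)


def beamform_line(traces: np.ndarray, delays: np.ndarray, dt: float) -> np.ndarray:
    """Fixed-focus delay-and-sum: advance each trace by its receive delay
    and sum coherently.

    The delays come from the same focal geometry as transmit, so an echo
    from the focus aligns across the subaperture and adds constructively.
    """
    traces = np.asarray(traces, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if traces.shape[0] != len(delays):
        raise ValueError("one delay per trace required")
    out = np.zeros(traces.shape[1])
    for trace, d in zip(traces, delays):
        out += _shift_advance(trace, d, dt)
    return out


def _receive_delays(rf: RFDataset, window: range) -> np.ndarray:
    pitch = float(rf.attrs["pitch"])
    n = int(rf.attrs["n_elements"])
    centers = (np.arange(n) - (n - 1) / 2.0) * pitch
    return focal_delays(
        centers[list(window)],
        focus_depth=float(rf.attrs.get("focus_depth", 0.010)),
        c_ref=float(rf.attrs.get("c_ref", 1570.0)),
    )


def compose_bscan(
    rf: RFDataset,
    order: str = "log_first",
    interp_factor: int = 4,
    dynamic_range: float = 50.0,
    c_ref: float | None = None,
) -> BScanImage:
    """Build a B-scan: one line per sweep position, laterally interpolated.

    ``order`` selects the processing chain applied to each 5-element
    subaperture before line composition:

    * ``"log_first"``: log-amplify each RF trace, envelope-detect, then
      delay-and-sum the envelopes;
    * ``"conventional"``: delay-and-sum the raw RF, then envelope-detect.

    Lines are then interpolated laterally (endpoint-preserving linear
    interpolation by ``interp_factor``), normalized to a 0 dB peak and
    clipped at ``-dynamic_range``.
    """
    if order not in ("log_first", "conventional"):
        raise ValueError("order must be 'log_first' or 'conventional'")
    aperture = int(rf.attrs.get("aperture_size", 5))
    step = int(rf.attrs.get("sweep_step", 1))
    n_positions = (rf.n_elements - aperture) // step + 1
    if rf.n_sweeps != n_positions:
        raise ValueError(
            f"dataset has {rf.n_sweeps} sweeps but the plan requires {n_positions}"
        )
    c_ref = c_ref if c_ref is not None else float(rf.attrs.get("c_ref", 1570.0))
    dt = rf.dt
    data = rf.values
    peak = np.abs(data).max()
    x_ref = peak / 1.0e3 if peak > 0 else None

    lines = np.empty((rf.n_sweeps, rf.n_samples))
    lateral = np.empty(rf.n_sweeps)
    pitch = float(rf.attrs["pitch"])
    n = int(rf.attrs["n_elements"])
    centers = (np.arange(n) - (n - 1) / 2.0) * pitch
    for s in range(rf.n_sweeps):
        window = range(s * step, s * step + aperture)
        delays = _receive_delays(rf, window)
        sub = data[s, list(window), :]
        if order == "log_first":
            processed = envelope(log_amplify(sub, x_ref), axis=-1)
            line = beamform_line(processed, delays, dt)
        else:
            line = np.abs(envelope(beamform_line(sub, delays, dt)))
        lines[s] = np.abs(line)
        lateral[s] = centers[list(window)].mean()

    # endpoint-preserving linear lateral interpolation
    if interp_factor < 1:
        raise ValueError("interpolation factor must be >= 1")
    n_lat = interp_factor * (rf.n_sweeps - 1) + 1
    lat_fine = np.linspace(lateral[0], lateral[-1], n_lat)
    img = np.empty((rf.n_samples, n_lat))
    for k in range(rf.n_samples):
        img[k] = np.interp(lat_fine, lateral, lines[:, k])

    peak_img = img.max()
    if peak_img > 0:
        floor = peak_img * 10.0 ** (-dynamic_range / 20.0)
        intensity = 20.0 * np.log10(np.maximum(img, floor) / peak_img)
    else:
        intensity = np.full_like(img, -dynamic_range)
    # time zero for range mapping: the moment the (last-fired, center)
    # element emits its envelope peak, i.e. pulse center + focal-law span
    t0 = float(rf.attrs.get("t0", 0.0))
    depth = c_ref * (rf.times - t0) / 2.0
    return BScanImage(
        intensity=intensity,
        depth_axis=depth,
        lateral_axis=lat_fine,
        dynamic_range=dynamic_range,
    )
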