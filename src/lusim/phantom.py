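"""Randomized inhomogeneous tissue phantoms for lung-ultrasound simulation.

The simulated scene is a chest-wall muscle slab imaged from below by a
linear array, with an ellipsoidal "lung disease zone" (LDZ) of
fluid-infiltrated lung tissue touching the muscle/lung interface.  Healthy
aerated lung above the interface reflects essentially all incident energy,
so it is not meshed at all: the interface itself becomes a pressure-release
boundary of the computational domain.

Material heterogeneity is synthesized from bounded random fields built as
sums of cosine modes with random wavevector, amplitude and phase.  A field
``f(x, y)`` normalized to the band [-1, 1] maps affinely onto sound speed
and mass density:

* LDZ:     v = 1070 + 430 f  (m/s),   rho = 715 + 285 f  (kg/m^3)
  i.e. spanning pure water (1500 m/s, 1000 kg/m^3) down to a 60 %-air
  mixture (640 m/s, 430 kg/m^3).
* Muscle:  v = 1570 + G g    (m/s),   rho = 1090 + G g   (kg/m^3)
  where the inhomogeneity level G (0, 5 or 10) sets the fluctuation
  amplitude around nominal muscle properties.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "Grid2D",
    "FieldSpectrumParams",
    "RandomField",
    "Variant",
    "ScenarioGeometry",
    "MaterialMap",
    "field_from_modes",
    "generate_random_field",
    "ldz_material",
    "muscle_material",
    "build_phantom",
    "make_grid",
]

# Nominal material constants (m/s and kg/m^3).
MUSCLE_VELOCITY = 1570.0
MUSCLE_DENSITY = 1090.0
LDZ_VELOCITY_MID = 1070.0
LDZ_VELOCITY_HALFRANGE = 430.0
LDZ_DENSITY_MID = 715.0
LDZ_DENSITY_HALFRANGE = 285.0
WATER_VELOCITY = 1500.0


@dataclass(frozen=True)
class Grid2D:
    """Uniform cell-centered 2D grid.

    ``x`` is the lateral coordinate (origin at the array face center) and
    ``y`` is depth into the tissue, increasing away from the array.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def x(self) -> np.ndarray:
        """Lateral cell-center coordinates (m)."""
        return self.x0 + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y(self) -> np.ndarray:
        """Depth cell-center coordinates (m)."""
        return self.y0 + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def width(self) -> float:
        return self.nx * self.dx

    @property
    def height(self) -> float:
        return self.ny * self.dy

    def points_per_wavelength(self, c_min: float, f_max: float) -> float:
        """Spatial samples across the shortest propagating wavelength."""
        return (c_min / f_max) / max(self.dx, self.dy)


@dataclass(frozen=True)
class FieldSpectrumParams:
    """Spectral content of a random cosine-mode field.

    ``k_min``/``k_max`` bound the radial spatial frequency of the modes in
    cycles/m.  ``anisotropy_ratio`` > 1 stretches the texture horizontally
    (x-wavenumbers divided by the ratio), emulating muscle-fiber structure.
    """

    n_modes: int = 400
    k_min: float = 0.0
    k_max: float = 2666.0
    seed: int = 0
    anisotropy_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if not (0 <= self.k_min < self.k_max):
            raise ValueError("need 0 <= k_min < k_max")
        if self.anisotropy_ratio <= 0:
            raise ValueError("anisotropy_ratio must be positive")

    @classmethod
    def for_frequency(
        cls,
        f0: float,
        seed: int = 0,
        anisotropy_ratio: float = 1.0,
        n_modes: int = 400,
    ) -> "FieldSpectrumParams":
        """Band such that the correlation length is about half a wavelength
        of the center frequency in water (k_max = 2 f0 / c_water)."""
        return cls(
            n_modes=n_modes,
            k_min=0.0,
            k_max=2.0 * f0 / WATER_VELOCITY,
            seed=seed,
            anisotropy_ratio=anisotropy_ratio,
        )


@dataclass(frozen=True)
class RandomField:
    """Bounded stochastic field with values in [-1, 1] and peak +1."""

    values: np.ndarray
    params: FieldSpectrumParams
    grid: Grid2D


class Variant(str, enum.Enum):
    """Scenario variants differing in LDZ lateral extent."""

    A = "A"          # 10 mm long LDZ
    B = "B"          # 4 mm long LDZ
    NARROW = "NARROW"  # 1 mm long, 4 MHz acquisition


_LDZ_LENGTH = {Variant.A: 0.010, Variant.B: 0.004, Variant.NARROW: 0.001}


@dataclass(frozen=True)
class ScenarioGeometry:
    """Physical layout: muscle rectangle, lateral absorbing strips, LDZ.

    The muscle rectangle spans ``[-width/2, width/2] x [0, height]``; the
    absorbing (PML) strips extend the lateral sides by ``pml_width`` each.
    The LDZ ellipse is centered laterally at ``ldz_center_x`` and touches
    the top (pleural) boundary: its vertical center is
    ``height - ldz_height / 2``.
    """

    width: float = 0.050
    height: float = 0.010
    pml_width: float = 0.005
    ldz_length: float = 0.010
    ldz_height: float = 0.005
    ldz_center_x: float = 0.0
    variant: Variant = Variant.A

    @classmethod
    def for_variant(cls, variant: Variant | str, **overrides) -> "ScenarioGeometry":
        variant = Variant(variant)
        geo = cls(variant=variant, ldz_length=_LDZ_LENGTH[variant])
        return replace(geo, **overrides) if overrides else geo

    @property
    def total_width(self) -> float:
        """Width including both absorbing strips."""
        return self.width + 2.0 * self.pml_width

    def validate(self) -> None:
        a = self.ldz_length / 2.0
        b = self.ldz_height / 2.0
        if self.ldz_length > 0:
            if self.ldz_center_x - a < -self.width / 2 or self.ldz_center_x + a > self.width / 2:
                raise ValueError("LDZ ellipse extends laterally outside the muscle rectangle")
            if self.ldz_height > self.height:
                raise ValueError("LDZ ellipse is taller than the muscle slab")
        if b < 0 or a < 0:
            raise ValueError("LDZ axes must be non-negative")


@dataclass
class MaterialMap:
    """Per-cell sound speed (m/s) and mass density (kg/m^3) on a grid.

    ``pml_width`` records how much of each lateral side is absorbing strip,
    which the wave solver turns into its damping profile.
    """

    grid: Grid2D
    velocity: np.ndarray
    density: np.ndarray
    ldz_mask: np.ndarray
    pml_width: float = 0.0

    @property
    def c_min(self) -> float:
        return float(self.velocity.min())

    @property
    def c_max(self) -> float:
        return float(self.velocity.max())

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("velocity", data=self.velocity)
            f.create_dataset("density", data=self.density)
            f.create_dataset("ldz_mask", data=self.ldz_mask)
            for k in ("nx", "ny", "dx", "dy", "x0", "y0"):
                f.attrs[k] = getattr(self.grid, k)
            f.attrs["pml_width"] = self.pml_width

    @classmethod
    def load(cls, path) -> "MaterialMap":
        with h5py.File(path, "r") as f:
            grid = Grid2D(
                nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]),
                dx=float(f.attrs["dx"]), dy=float(f.attrs["dy"]),
                x0=float(f.attrs["x0"]), y0=float(f.attrs["y0"]),
            )
            return cls(
                grid=grid,
                velocity=f["velocity"][...],
                density=f["density"][...],
                ldz_mask=f["ldz_mask"][...].astype(bool),
                pml_width=float(f.attrs["pml_width"]),
            )


def field_from_modes(
    grid: Grid2D,
    kx: np.ndarray,
    ky: np.ndarray,
    amplitudes: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    """Evaluate sum_m a_m cos(2 pi (kx_m x + ky_m y) + phi_m) on the grid.

    Wavenumbers are in cycles/m.  Returns the raw (unnormalized) field with
    shape ``grid.shape``.
    """
    X = grid.x[:, None]
    Y = grid.y[None, :]
    values = np.zeros(grid.shape)
    # chunk over modes to bound peak memory on large grids
    chunk = 64
    for s in range(0, len(kx), chunk):
        e = s + chunk
        arg = 2.0 * np.pi * (
            kx[s:e, None, None] * X[None, :, :] + ky[s:e, None, None] * Y[None, :, :]
        ) + phases[s:e, None, None]
        values += np.einsum("m,mxy->xy", amplitudes[s:e], np.cos(arg))
    return values


def generate_random_field(grid: Grid2D, params: FieldSpectrumParams) -> RandomField:
    """Draw a bounded random field from the given spectral band.

    Mode radial frequencies are uniform in [k_min, k_max], directions
    isotropic, amplitudes uniform in (0, 1], phases uniform in [0, 2 pi).
    The sum is rescaled so the largest-magnitude value is exactly 1, with
    the sign chosen to make the peak positive (the mode ensemble is
    sign-symmetric, so this costs no generality).
    """
    # Nyquist guard: the finest oscillation must be representable.
    kx_max = params.k_max / params.anisotropy_ratio
    if kx_max > 0.5 / grid.dx or params.k_max > 0.5 / grid.dy:
        raise ValueError(
            f"grid too coarse for spectral band: k_max={params.k_max:g} cycles/m "
            f"exceeds the grid Nyquist limit ({0.5 / grid.dx:g}, {0.5 / grid.dy:g})"
        )
    rng = np.random.default_rng(params.seed)
    k = rng.uniform(params.k_min, params.k_max, params.n_modes)
    theta = rng.uniform(0.0, 2.0 * np.pi, params.n_modes)
    # uniform on (0, 1]: 1 - U with U uniform on [0, 1)
    amplitudes = 1.0 - rng.random(params.n_modes)
    phases = rng.uniform(0.0, 2.0 * np.pi, params.n_modes)
    kx = k * np.cos(theta) / params.anisotropy_ratio
    ky = k * np.sin(theta)
    values = field_from_modes(grid, kx, ky, amplitudes, phases)
    peak = np.abs(values).max()
    if peak == 0.0:
        raise ValueError("degenerate field: all modes cancelled")
    values /= peak
    if values.max() < -values.min():
        values = -values
    return RandomField(values=values, params=params, grid=grid)


def _check_bounds(f: np.ndarray) -> None:
    if np.abs(f).max() > 1.0 + 1e-12:
        raise ValueError("field values must lie in [-1, 1]")


def ldz_material(f: np.ndarray | RandomField) -> tuple[np.ndarray, np.ndarray]:
    """Map a [-1, 1] field onto LDZ sound speed and density.

    f = -1 gives the 60 %-air mixture (640 m/s, 430 kg/m^3); f = +1 gives
    pure water (1500 m/s, 1000 kg/m^3).
    """
    if isinstance(f, RandomField):
        f = f.values
    f = np.asarray(f, dtype=float)
    _check_bounds(f)
    velocity = LDZ_VELOCITY_MID + LDZ_VELOCITY_HALFRANGE * f
    density = LDZ_DENSITY_MID + LDZ_DENSITY_HALFRANGE * f
    return velocity, density


def muscle_material(g: np.ndarray | RandomField, G: float) -> tuple[np.ndarray, np.ndarray]:
    """Map a [-1, 1] field onto muscle properties at inhomogeneity level G.

    The same numeric G perturbs sound speed (m/s) and density (kg/m^3)
    about the nominal 1570 / 1090.
    """
    if G < 0:
        raise ValueError("G must be non-negative")
    if isinstance(g, RandomField):
        g = g.values
    g = np.asarray(g, dtype=float)
    _check_bounds(g)
    velocity = MUSCLE_VELOCITY + G * g
    density = MUSCLE_DENSITY + G * g
    return velocity, density


def ldz_mask_for(geometry: ScenarioGeometry, grid: Grid2D) -> np.ndarray:
    """Rasterize the LDZ ellipse onto cell centers."""
    if geometry.ldz_length <= 0:
        return np.zeros(grid.shape, dtype=bool)
    a = geometry.ldz_length / 2.0
    b = geometry.ldz_height / 2.0
    yc = geometry.height - b
    X = grid.x[:, None]
    Y = grid.y[None, :]
    return ((X - geometry.ldz_center_x) / a) ** 2 + ((Y - yc) / b) ** 2 <= 1.0


def make_grid(
    geometry: ScenarioGeometry,
    f0: float,
    ppw: float = 10.0,
    c_min: float | None = None,
) -> Grid2D:
    """Build a square-celled grid resolving the slowest medium at ``ppw``
    points per wavelength of ``f0``.

    ``c_min`` defaults to the slowest material present: the LDZ minimum
    (640 m/s) when an LDZ exists, otherwise nominal muscle.
    """
    if c_min is None:
        c_min = (
            LDZ_VELOCITY_MID - LDZ_VELOCITY_HALFRANGE
            if geometry.ldz_length > 0
            else MUSCLE_VELOCITY
        )
    dx = c_min / (f0 * ppw)
    nx = int(np.ceil(geometry.total_width / dx))
    ny = int(np.ceil(geometry.height / dx))
    return Grid2D(nx=nx, ny=ny, dx=dx, dy=dx, x0=-geometry.total_width / 2.0, y0=0.0)


def build_phantom(
    geometry: ScenarioGeometry,
    grid: Grid2D,
    G: float,
    seed_ldz: int,
    seed_muscle: int,
    f0: float = 2.0e6,
    ldz_spectrum: FieldSpectrumParams | None = None,
    muscle_spectrum: FieldSpectrumParams | None = None,
    muscle_anisotropy: float = 4.0,
) -> MaterialMap:
    """Fill the full grid (muscle + absorbing strips) with muscle texture
    and overwrite the LDZ ellipse with fluid-infiltrated lung tissue.

    The muscle and LDZ fields are drawn from independent seeds so the two
    textures decorrelate.  The muscle spectrum is horizontally stretched
    (``muscle_anisotropy`` : 1) to mimic fiber structure.
    """
    geometry.validate()
    if grid.width < geometry.total_width - grid.dx or grid.height < geometry.height - grid.dy:
        raise ValueError("grid does not cover the scenario geometry")
    if muscle_spectrum is None:
        muscle_spectrum = FieldSpectrumParams.for_frequency(
            f0, seed=seed_muscle, anisotropy_ratio=muscle_anisotropy
        )
    g = generate_random_field(grid, muscle_spectrum)
    velocity, density = muscle_material(g, G)
    mask = ldz_mask_for(geometry, grid)
    if mask.any():
        if ldz_spectrum is None:
            ldz_spectrum = FieldSpectrumParams.for_frequency(f0, seed=seed_ldz)
        f = generate_random_field(grid, ldz_spectrum)
        v_ldz, d_ldz = ldz_material(f)
        velocity[mask] = v_ldz[mask]
        density[mask] = d_ldz[mask]
    return MaterialMap(
        grid=grid,
        velocity=velocity,
        density=density,
        ldz_mask=mask,
        pml_width=geometry.pml_width,
    )
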