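"""Synthetic off-axis digital-holographic-microscopy (DHM) scenes.

Off-axis DHM records the interference between an object wave that has passed a
semi-transparent specimen and a tilted plane reference wave.  Cells such as RBCs
are nearly pure phase objects: the camera sees carrier fringes that are locally
distorted by each cell's optical path delay.  This module generates such
holograms together with pixel-aligned ground-truth masks, and provides the
classical Fourier-sideband phase reconstruction as a round-trip oracle for the
forward model.  It stands in for real DHM recordings, which are not part of
this repository.

Geometry and units
------------------
All fields live on the camera pixel grid.  ``wavelength``, ``pixel_pitch`` and
``defocus_distance`` are in metres; carrier tilt angles in radians.  The
carrier spatial frequency in cycles/pixel is ``sin(theta) * pixel_pitch /
wavelength`` and must stay below Nyquist (0.5 cycles/pixel).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "SimOptics",
    "SimConfig",
    "CellSpec",
    "SceneError",
    "default_carrier_angle",
    "generate_scene",
    "phase_from_scene",
    "mask_from_scene",
    "generate_phase_map",
    "propagate_angular_spectrum",
    "synthesize_hologram",
    "synthesize_scene_hologram",
    "reconstruct_phase",
    "generate_sample",
    "generate_dataset",
    "read_hologram",
    "read_mask",
    "MASK_TAPER_CUTOFF",
    "MASK_RADIUS_FACTOR",
    "FULL_SCALE_INTENSITY",
]

#: fraction of the peak phase below which a pixel no longer counts as "cell"
MASK_TAPER_CUTOFF = 0.05
#: radius (in units of the taper radius R) at which the cos^2 taper crosses the cutoff
MASK_RADIUS_FACTOR = (2.0 / math.pi) * math.acos(math.sqrt(MASK_TAPER_CUTOFF))
#: intensity mapped to the top of the 16-bit range when holograms are written to disk
FULL_SCALE_INTENSITY = 6.0


class SceneError(RuntimeError):
    """Raised when a requested number of disjoint cells cannot be placed."""


def default_carrier_angle(
    wavelength: float = 682e-9,
    pixel_pitch: float = 5.7e-6,
    fringe_period_px: float = 4.0,
) -> tuple[float, float]:
    """Tilt angles giving ~``fringe_period_px``-pixel carrier fringes.

    The total carrier frequency ``1/fringe_period_px`` is split equally between
    the two axes so the fringes run diagonally, keeping both sidebands well
    inside the Nyquist square.
    """
    f_axis = (1.0 / fringe_period_px) / math.sqrt(2.0)
    theta = math.asin(f_axis * wavelength / pixel_pitch)
    return (theta, theta)


@dataclass(frozen=True)
class SimOptics:
    """Optical parameters of the simulated off-axis DHM.

    ``carrier_angle`` is the (theta_y, theta_x) tilt of the reference wave;
    ``defocus_distance`` propagates the whole object wave before interference
    (per-object defocus for bead scenes is handled by the scene synthesizer);
    ``noise_sigma`` is the standard deviation of additive Gaussian intensity
    noise, in the same units as the hologram (reference amplitude 1, so the
    noiseless fringes span [0, 4]).
    """

    wavelength: float = 682e-9
    pixel_pitch: float = 5.7e-6
    carrier_angle: tuple[float, float] | None = None
    defocus_distance: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_angle is None:
            object.__setattr__(
                self,
                "carrier_angle",
                default_carrier_angle(self.wavelength, self.pixel_pitch),
            )
        self.validate()

    def validate(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for f in self.carrier_frequency:
            if abs(f) >= 0.5:
                raise ValueError(
                    "carrier frequency %.3f cycles/px is at or above Nyquist "
                    "(|sin theta| * pitch / wavelength must be < 0.5): fringes "
                    "would alias" % f
                )

    @property
    def carrier_frequency(self) -> tuple[float, float]:
        """(f_y, f_x) carrier frequency in cycles per pixel."""
        ty, tx = self.carrier_angle
        return (
            math.sin(ty) * self.pixel_pitch / self.wavelength,
            math.sin(tx) * self.pixel_pitch / self.wavelength,
        )


@dataclass(frozen=True)
class SimConfig:
    """Morphological parameters of a synthetic cell scene.

    ``magnification_mode`` mimics the acquisition magnification: at ``"20x"``
    the field of view doubles over the same pixel grid, so cells shrink to half
    their 40x pixel radius.  ``"bead"`` keeps 40x sizing but gives every object
    an independent random defocus within ``defocus_range`` metres, producing a
    mix of focused and defocused objects; the ground-truth mask stays the
    in-focus support.
    """

    image_size: tuple[int, int] = (384, 384)
    n_cells_range: tuple[int, int] = (5, 15)
    cell_radius_range: tuple[float, float] = (10.0, 16.0)
    phase_amplitude_range: tuple[float, float] = (1.0, 2.5)
    magnification_mode: str = "40x"
    overlap_allowed: bool = False
    seed: int = 0
    defocus_range: float = 2e-3

    def __post_init__(self) -> None:
        if self.magnification_mode not in ("40x", "20x", "bead"):
            raise ValueError(f"unknown magnification_mode {self.magnification_mode!r}")
        if self.cell_radius_range[0] <= 0:
            raise ValueError("cell radii must be positive")
        if self.n_cells_range[0] < 0 or self.n_cells_range[1] < self.n_cells_range[0]:
            raise ValueError("n_cells_range must be a non-negative interval")
        if min(self.image_size) < 8:
            raise ValueError("image_size too small")

    @property
    def effective_radius_range(self) -> tuple[float, float]:
        lo, hi = self.cell_radius_range
        if self.magnification_mode == "20x":
            return (lo / 2.0, hi / 2.0)
        return (lo, hi)


@dataclass(frozen=True)
class CellSpec:
    """One disc-like phase object: centre (row, col), taper radius, peak phase
    (radians) and axial defocus (metres, 0 = in focus)."""

    row: float
    col: float
    radius: float
    amplitude: float
    defocus: float = 0.0

    @property
    def mask_radius(self) -> float:
        return self.radius * MASK_RADIUS_FACTOR


def _as_rng(rng: np.random.Generator | int | None, default_seed: int = 0) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        return np.random.default_rng(default_seed)
    return np.random.default_rng(rng)


def generate_scene(
    cfg: SimConfig, rng: np.random.Generator | int | None = None, max_tries: int = 200
) -> list[CellSpec]:
    """Sample cell positions, sizes, peak phases (and defocus in bead mode).

    With ``overlap_allowed=False`` rejection sampling enforces a >2-pixel gap
    between the *mask* supports so every cell stays its own connected
    component.  Raises :class:`SceneError` when a cell cannot be placed within
    ``max_tries`` attempts.
    """
    rng = _as_rng(rng, cfg.seed)
    h, w = cfg.image_size
    lo_n, hi_n = cfg.n_cells_range
    n_cells = int(rng.integers(lo_n, hi_n + 1))
    r_lo, r_hi = cfg.effective_radius_range
    a_lo, a_hi = cfg.phase_amplitude_range

    cells: list[CellSpec] = []
    for _ in range(n_cells):
        radius = float(rng.uniform(r_lo, r_hi))
        amplitude = float(rng.uniform(a_lo, a_hi))
        defocus = 0.0
        if cfg.magnification_mode == "bead":
            defocus = float(rng.uniform(-cfg.defocus_range, cfg.defocus_range))
        placed = False
        for _try in range(max_tries):
            row = float(rng.uniform(1.0, h - 1.0))
            col = float(rng.uniform(1.0, w - 1.0))
            cand = CellSpec(row, col, radius, amplitude, defocus)
            if cfg.overlap_allowed or all(
                math.hypot(c.row - row, c.col - col) > c.mask_radius + cand.mask_radius + 2.5
                for c in cells
            ):
                cells.append(cand)
                placed = True
                break
        if not placed:
            raise SceneError(
                f"could not place {n_cells} disjoint cells of radius "
                f"[{r_lo:.1f}, {r_hi:.1f}] px in a {h}x{w} field "
                f"(placed {len(cells)} before giving up)"
            )
    return cells


def _radial_distance(size: tuple[int, int], cell: CellSpec) -> np.ndarray:
    h, w = size
    yy = np.arange(h, dtype=np.float64)[:, None] - cell.row
    xx = np.arange(w, dtype=np.float64)[None, :] - cell.col
    return np.hypot(yy, xx)


def phase_from_scene(scene: list[CellSpec], size: tuple[int, int]) -> np.ndarray:
    """In-focus phase map: each cell adds A*cos^2(pi*r/(2R)) for r<=R.

    The cosine taper gives the smooth dome-like profile of an RBC phase image;
    background phase is exactly zero.
    """
    phase = np.zeros(size, dtype=np.float64)
    for cell in scene:
        r = _radial_distance(size, cell)
        inside = r <= cell.radius
        phase[inside] += cell.amplitude * np.cos(
            (math.pi / 2.0) * r[inside] / cell.radius
        ) ** 2
    return phase


def mask_from_scene(scene: list[CellSpec], size: tuple[int, int]) -> np.ndarray:
    """Ground-truth mask: pixels where a cell's taper is >= 5% of its peak."""
    mask = np.zeros(size, dtype=bool)
    for cell in scene:
        mask |= _radial_distance(size, cell) <= cell.mask_radius
    return mask


def generate_phase_map(
    cfg: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Generate a seeded random scene; return (phase map, mask, cell count)."""
    scene = generate_scene(cfg, rng)
    return (
        phase_from_scene(scene, cfg.image_size),
        mask_from_scene(scene, cfg.image_size),
        len(scene),
    )


def propagate_angular_spectrum(
    field: np.ndarray, distance: float, wavelength: float, pixel_pitch: float
) -> np.ndarray:
    """Propagate a complex field by ``distance`` with the angular-spectrum method.

    Evanescent components (spatial frequencies beyond 1/wavelength) are dropped.
    """
    if distance == 0.0:
        return np.asarray(field, dtype=np.complex128)
    h, w = field.shape
    fy = np.fft.fftfreq(h, d=pixel_pitch)[:, None]
    fx = np.fft.fftfreq(w, d=pixel_pitch)[None, :]
    arg = 1.0 - (wavelength * fy) ** 2 - (wavelength * fx) ** 2
    kernel = np.where(
        arg > 0.0,
        np.exp(2j * math.pi * distance / wavelength * np.sqrt(np.maximum(arg, 0.0))),
        0.0,
    )
    return np.fft.ifft2(np.fft.fft2(field) * kernel)


def _reference_wave(size: tuple[int, int], optics: SimOptics) -> np.ndarray:
    fy, fx = optics.carrier_frequency
    h, w = size
    yy = np.arange(h, dtype=np.float64)[:, None]
    xx = np.arange(w, dtype=np.float64)[None, :]
    return np.exp(2j * math.pi * (fy * yy + fx * xx))


def _interfere(
    object_wave: np.ndarray, optics: SimOptics, rng: np.random.Generator | int | None
) -> np.ndarray:
    ref = _reference_wave(object_wave.shape, optics)
    intensity = np.abs(object_wave + ref) ** 2
    if optics.noise_sigma > 0:
        rng = _as_rng(rng)
        intensity = intensity + rng.normal(0.0, optics.noise_sigma, intensity.shape)
    return np.maximum(intensity, 0.0)


def synthesize_hologram(
    phase: np.ndarray,
    optics: SimOptics,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Record the off-axis hologram of a phase object.

    The object wave is ``exp(i*phase)`` (optionally propagated by
    ``optics.defocus_distance``); the output is ``|O + R|**2`` plus clipped
    Gaussian noise, hence strictly non-negative.
    """
    optics.validate()
    obj = np.exp(1j * np.asarray(phase, dtype=np.float64))
    if optics.defocus_distance != 0.0:
        obj = propagate_angular_spectrum(
            obj, optics.defocus_distance, optics.wavelength, optics.pixel_pitch
        )
    return _interfere(obj, optics, rng)


def synthesize_scene_hologram(
    scene: list[CellSpec],
    size: tuple[int, int],
    optics: SimOptics,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Hologram of a scene whose objects may sit at different focal planes.

    Each object's scattered field ``exp(i*phase_k) - 1`` is propagated by its
    own defocus before superposition (first-order treatment, valid for the
    sparse scenes generated here): ``O = 1 + sum_k P_{z_k}[exp(i*phi_k) - 1]``.
    For an all-in-focus scene this reduces exactly to ``exp(i*phase)``.
    """
    obj = np.ones(size, dtype=np.complex128)
    for cell in scene:
        phi = phase_from_scene([cell], size)
        scattered = np.exp(1j * phi) - 1.0
        z = cell.defocus + optics.defocus_distance
        if z != 0.0:
            scattered = propagate_angular_spectrum(
                scattered, z, optics.wavelength, optics.pixel_pitch
            )
        obj += scattered
    return _interfere(obj, optics, rng)


def reconstruct_phase(
    hologram: np.ndarray,
    optics: SimOptics,
    bandpass_radius: float | None = None,
) -> np.ndarray:
    """Classical Fourier-sideband phase reconstruction (the round-trip oracle).

    The hologram is demodulated by the conjugate carrier (shifting the +1-order
    sideband to DC), low-pass filtered with a circular bandpass of
    ``bandpass_radius`` cycles/pixel (default: 45% of the carrier offset), and
    inverse transformed; the phase is the argument of the filtered field.  The
    result carries an arbitrary constant offset.
    """
    fy, fx = optics.carrier_frequency
    carrier_norm = math.hypot(fy, fx)
    if bandpass_radius is None:
        bandpass_radius = 0.45 * carrier_norm
    if carrier_norm < 2.0 * bandpass_radius:
        warnings.warn(
            "carrier frequency %.3f cycles/px is low relative to the bandpass "
            "radius %.3f: the +1-order sideband overlaps the DC term and the "
            "reconstruction may be corrupted" % (carrier_norm, bandpass_radius),
            RuntimeWarning,
            stacklevel=2,
        )
    h, w = hologram.shape
    yy = np.arange(h, dtype=np.float64)[:, None]
    xx = np.arange(w, dtype=np.float64)[None, :]
    # multiplying by the reference wave R = exp(+i*2*pi*f.x) shifts the
    # O*conj(R) sideband (which carries +phase) onto the DC bin
    demodulated = hologram * np.exp(2j * math.pi * (fy * yy + fx * xx))
    spectrum = np.fft.fft2(demodulated)
    gy = np.fft.fftfreq(h)[:, None]
    gx = np.fft.fftfreq(w)[None, :]
    spectrum[gy**2 + gx**2 > bandpass_radius**2] = 0.0
    return np.angle(np.fft.ifft2(spectrum))


def generate_sample(
    cfg: SimConfig,
    optics: SimOptics | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One (hologram, mask, cell count) triple under the configured conditions."""
    if optics is None:
        optics = SimOptics()
    rng = _as_rng(rng, cfg.seed)
    scene = generate_scene(cfg, rng)
    mask = mask_from_scene(scene, cfg.image_size)
    if cfg.magnification_mode == "bead":
        holo = synthesize_scene_hologram(scene, cfg.image_size, optics, rng)
    else:
        holo = synthesize_hologram(phase_from_scene(scene, cfg.image_size), optics, rng)
    return holo, mask, len(scene)


def _hologram_to_uint16(hologram: np.ndarray) -> np.ndarray:
    scaled = np.clip(hologram / FULL_SCALE_INTENSITY, 0.0, 1.0)
    return np.round(scaled * 65535.0).astype(np.uint16)


def read_hologram(path: str | Path) -> np.ndarray:
    """Read a 16-bit hologram TIFF back to intensity units."""
    raw = tifffile.imread(str(path)).astype(np.float64)
    return raw / 65535.0 * FULL_SCALE_INTENSITY


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path))) > 127


def generate_dataset(
    cfg: SimConfig,
    n_images: int,
    out_dir: str | Path,
    optics: SimOptics | None = None,
) -> pd.DataFrame:
    """Write ``n_images`` (hologram TIFF, mask PNG) pairs plus a CSV manifest.

    Per-image seeds are spawned deterministically from ``cfg.seed``, so the
    dataset is byte-reproducible from the config alone.  Returns the manifest
    (also written to ``out_dir/manifest.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_images)
    rows = []
    for i, child in enumerate(seeds):
        seed_i = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        holo, mask, n_cells = generate_sample(cfg, optics, np.random.default_rng(seed_i))
        holo_path = out_dir / f"holo_{i:04d}.tif"
        mask_path = out_dir / f"mask_{i:04d}.png"
        tifffile.imwrite(str(holo_path), _hologram_to_uint16(holo))
        Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(str(mask_path))
        rows.append(
            {
                "image_path": holo_path.name,
                "mask_path": mask_path.name,
                "n_cells": n_cells,
                "mode": cfg.magnification_mode,
                "seed": seed_i,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
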