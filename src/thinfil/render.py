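"""Synthetic single-molecule fluorescence movies of a thin filament.

Bound GFP-S1s appear as diffraction-limited spots on the pixel line
along the filament.  The optical model:

* a single excited GFP emits ``e`` fluorescence units per second
  (default 450), so one GFP bound for a whole frame has recorded peak
  intensity ``I_1 = e / f`` (45 at 10 Hz, ~118 at 3.8 Hz);
* its image is a Gaussian point-spread function of SD ``sigma_GFP``
  (160 nm = 2 pixels of 80 nm), *peak* amplitude in intensity units;
* a head bound for a fraction of the exposure is proportionally dimmer;
* each bound fluorophore's amplitude fluctuates frame to frame
  (Gaussian, SD ``sigma_F`` in scaled units — filament flexing etc.);
* uniform background noise per pixel (Gaussian, SD ``sigma_N`` in
  scaled units, condition dependent).

The dimensionless *scaled intensity* ``I_F = I * f / e`` removes the
frame-rate dependence: an ideal cluster of n GFPs has ``I_F = n``.
Negative noisy intensities are kept (no clipping); the downstream
baseline convention assumes unclipped noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Condition, FrameStack

__all__ = ["OpticsParams", "Movie", "Kymograph", "scaled_intensity",
           "render_movie", "make_kymograph"]


@dataclass(frozen=True)
class OpticsParams:
    """Camera / fluorophore parameters.

    e : emission rate of one excited GFP, fluorescence units / s.
    sigma_gfp_nm : PSF standard deviation, nm.
    pixel_nm : pixel size, nm.
    sigma_F : per-fluorophore, per-frame intensity noise SD (scaled units).
    margin_px : blank pixels added at each filament end so edge PSFs are
        not truncated.
    """

    e: float = 450.0
    sigma_gfp_nm: float = 160.0
    pixel_nm: float = 80.0
    sigma_F: float = 0.22
    margin_px: int = 5

    def __post_init__(self) -> None:
        if self.e <= 0 or self.sigma_gfp_nm <= 0 or self.pixel_nm <= 0:
            raise ValueError("e, sigma_gfp_nm and pixel_nm must be positive")
        if self.sigma_F < 0:
            raise ValueError("sigma_F must be non-negative")
        if self.margin_px < 0:
            raise ValueError("margin_px must be non-negative")

    @property
    def sigma_px(self) -> float:
        return self.sigma_gfp_nm / self.pixel_nm


@dataclass
class Movie:
    """Frames x pixels fluorescence intensities (raw units) along the filament."""

    intensity: np.ndarray  # (n_frames, n_pixels)
    frame_rate_hz: float
    pixel_nm: float

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class Kymograph:
    """Position x time image: row = pixel along the filament, column = frame."""

    image: np.ndarray  # (n_pixels, n_frames)
    frame_rate_hz: float
    scaled: bool = False  # True once intensities are in scaled (I*f/e) units


def scaled_intensity(I, f: float, e: float):
    """Dimensionless intensity ``I_F = I * f / e`` (n for a cluster of n GFPs)."""
    if f <= 0 or e <= 0:
        raise ValueError("frame rate and emission rate must be positive")
    return np.multiply(I, f / e) if isinstance(I, np.ndarray) else I * f / e


def fluorophore_positions_nm(n_sites: int, optics: OpticsParams,
                             spacing_nm: float = 5.5) -> np.ndarray:
    """Nanometre position of each binding site on the rendered pixel line."""
    offset = optics.margin_px * optics.pixel_nm
    return offset + (np.arange(n_sites) + 0.5) * spacing_nm


def n_pixels_for(n_sites: int, optics: OpticsParams, spacing_nm: float = 5.5) -> int:
    filament_nm = n_sites * spacing_nm
    return int(np.ceil(filament_nm / optics.pixel_nm)) + 2 * optics.margin_px


def render_movie(stacks: tuple[FrameStack, FrameStack], condition: Condition,
                 optics: OpticsParams, seed) -> Movie:
    """Render the two sides' frame stacks onto one noisy pixel line.

    Each bound fluorophore contributes a Gaussian of SD ``sigma_GFP``
    centred at its site's nanometre position, with peak amplitude
    ``(e/f) * (weight + eta_F)`` where ``eta_F ~ N(0, sigma_F)`` is drawn
    independently per fluorophore per frame; per-pixel background
    ``N(0, sigma_N * e/f)`` is then added.  The profile is evaluated at
    pixel centres (sub-pixel placement; no area integration — negligible
    at sigma_GFP = 2 px).
    """
    a, b = stacks
    if a.weights.shape != b.weights.shape:
        raise ValueError("the two frame stacks must have identical shapes")
    if abs(a.frame_rate_hz - condition.frame_rate_hz) > 1e-12:
        raise ValueError("frame stack and condition disagree on frame rate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames, n_sites = a.weights.shape
    f = condition.frame_rate_hz
    unit = optics.e / f  # raw intensity of one ideal GFP per frame
    n_px = n_pixels_for(n_sites, optics, condition.spacing_nm)
    x_px = (np.arange(n_px) + 0.5) * optics.pixel_nm
    pos_nm = fluorophore_positions_nm(n_sites, optics, condition.spacing_nm)
    sigma = optics.sigma_gfp_nm

    intensity = rng.normal(0.0, condition.sigma_N * unit, size=(n_frames, n_px))
    for stack in (a, b):
        w = stack.weights
        for k in range(n_frames):
            bound = np.flatnonzero(w[k] > 0)
            if bound.size == 0:
                continue
            eta = rng.normal(0.0, optics.sigma_F, size=bound.size)
            amps = unit * (w[k, bound] + eta)
            d = x_px[None, :] - pos_nm[bound][:, None]
            intensity[k] += (amps[:, None] * np.exp(-0.5 * (d / sigma) ** 2)).sum(axis=0)
    return Movie(intensity=intensity, frame_rate_hz=f, pixel_nm=optics.pixel_nm)


def make_kymograph(movie: Movie) -> Kymograph:
    """Stack the filament pixel line across frames into a 2D image.

    A pure reshaping (transpose) of the movie; no resampling.
    """
    if movie.intensity.size == 0:
        raise ValueError("movie is empty")
    return Kymograph(image=movie.intensity.T.copy(), frame_rate_hz=movie.frame_rate_hz)


def scale_kymograph(kymo: Kymograph, optics: OpticsParams) -> Kymograph:
    """Convert a raw-unit kymograph to scaled-intensity units (I*f/e)."""
    if kymo.scaled:
        return kymo
    img = scaled_intensity(kymo.image, kymo.frame_rate_hz, optics.e)
    return Kymograph(image=img, frame_rate_hz=kymo.frame_rate_hz, scaled=True)
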