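"""Ground-truth-annotated synthetic scenes and count populations.

Emulates the raw material of a digitized single-cell protein-counting
experiment so the whole pipeline is testable without real microscope data:

* a field of view holding non-overlapping round cells;
* per-cell discrete emitters (one emitter = one tagged protein complex) at
  ground-truth counts, each rendered as a separable 3D Gaussian PSF into a
  z-stack with the acquisition geometry of a high-NA QD experiment
  (~160 nm pixels, ~300 nm slice spacing, ~18 µm depth);
* a smooth per-cell diffuse autofluorescence field;
* Poisson shot noise on expected photons, Gaussian read noise, a constant
  camera baseline offset, and 16-bit quantization.

Population-level count samples (untreated vs treated, with an optional
drug-insensitive subpopulation) are drawn from negative-binomial models:
per-cell molecule counts are overdispersed, and the downstream scoring is
distribution-free, so the NB family is a representative choice rather than
a modelling commitment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneSpec",
    "PopulationSpec",
    "GroundTruth",
    "ScenePlacementError",
    "simulate_scene",
    "simulate_count_populations",
    "negative_binomial",
]


class ScenePlacementError(RuntimeError):
    """Raised when non-overlapping in-bounds cell placement cannot be satisfied."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    Geometry defaults follow a high-magnification QD acquisition: 160 nm
    pixels, 300 nm inter-slice spacing, 60 slices (18 µm depth), and cells of
    ~13–18 µm diameter (suspension leukemia cells). ``spot_peak_photons``,
    ``autofluor_amplitude`` and ``read_noise_sd`` default to a peak
    signal-to-noise ratio of ≈10 inside a cell
    (80 / sqrt(50 + 4²) ≈ 9.9).
    """

    field_shape: tuple[int, int] = (1024, 1024)  # (ny, nx) pixels
    n_slices: int = 60
    slice_spacing: float = 300.0  # nm
    pixel_size: float = 160.0  # nm
    n_cells: int = 20
    cell_radius_range: tuple[float, float] = (40.0, 55.0)  # pixels
    psf_sigma_xy: float = 1.1  # pixels
    psf_sigma_z: float = 1.0  # slices
    spot_peak_photons: float = 80.0
    autofluor_amplitude: float = 50.0  # photons / pixel / slice
    autofluor_smoothness: float = 12.0  # pixels (~2 µm organelle-scale haze)
    read_noise_sd: float = 4.0  # camera counts
    baseline_offset: float = 100.0  # camera counts
    bit_depth: int = 16
    mean_count: float = 100.0  # negative-binomial mean emitters per cell
    count_dispersion: float = 5.0  # negative-binomial size parameter
    true_counts: tuple[int, ...] | None = None  # explicit per-cell counts override
    min_separation: float = 0.0  # pixels; 0 = uniform placement
    poisson_noise: bool = True
    cell_margin: float = 6.0  # pixels kept clear between cells and to the border
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValueError("PSF sigmas must be positive")
        if self.pixel_size <= 0 or self.slice_spacing <= 0:
            raise ValueError("calibration values must be positive")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell_radius_range must satisfy 0 < min <= max")
        if self.true_counts is not None and len(self.true_counts) != self.n_cells:
            raise ValueError("true_counts must list one count per cell")
        if self.mean_count <= 0 or self.count_dispersion <= 0:
            raise ValueError("mean_count and count_dispersion must be positive")
        if not (1 <= self.bit_depth <= 16):
            raise ValueError("bit_depth must be in [1, 16]")


@dataclass(frozen=True)
class PopulationSpec:
    """Untreated/treated per-cell count population model.

    Untreated counts are NB(mu_untreated, dispersion). Treated counts are a
    mixture: with probability ``insensitive_fraction`` a cell keeps the
    untreated distribution, otherwise its mean is scaled down by
    ``(1 − inhibition)`` at the same dispersion. Defaults mirror a potent
    but incomplete kinase inhibition with a 20% insensitive subpopulation
    and ~200 cells sampled per condition.
    """

    mu_untreated: float = 100.0
    dispersion: float = 5.0
    inhibition: float = 0.8
    insensitive_fraction: float = 0.2
    n_cells: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_untreated <= 0:
            raise ValueError("mu_untreated must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.inhibition <= 1.0:
            raise ValueError("inhibition must lie in [0, 1]")
        if not 0.0 <= self.insensitive_fraction <= 1.0:
            raise ValueError("insensitive_fraction must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``cell_masks`` is a labeled 2D map (0 = background, cell ids from 1);
    ``cells`` has one row per cell (cell_id, cx, cy, radius, true_count,
    autofluor_integral); ``emitters`` one row per emitter
    (cell_id, x, y, z) in sub-pixel / sub-slice units.
    """

    cell_masks: np.ndarray
    cells: pd.DataFrame
    emitters: pd.DataFrame


def negative_binomial(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Gamma-Poisson draw of NB counts with mean ``mean`` and size ``dispersion``.

    Variance is mean + mean²/dispersion. ``mean`` may be an array
    (per-element means); mean 0 yields exact zeros.
    """
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping in-bounds disks; error when crowded."""
    ny, nx = spec.field_shape
    lo, hi = spec.cell_radius_range
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 1000
    for i in range(spec.n_cells):
        r = rng.uniform(lo, hi)
        for _ in range(max_attempts):
            margin = r + spec.cell_margin
            if 2 * margin >= min(nx, ny):
                break
            cx = rng.uniform(margin, nx - margin)
            cy = rng.uniform(margin, ny - margin)
            ok = all(
                np.hypot(cx - px, cy - py) > r + pr + spec.cell_margin
                for (px, py), pr in zip(centers, radii)
            )
            if ok:
                centers.append((cx, cy))
                radii.append(r)
                break
        else:
            raise ScenePlacementError(
                f"could not place cell {i} after {max_attempts} attempts: the "
                "non-overlap / fully-in-field constraint cannot be met (field too "
                "crowded for the requested n_cells and cell_radius_range)"
            )
        if len(centers) != i + 1:
            raise ScenePlacementError(
                f"cell radius {r:.1f} px plus margin does not fit inside the "
                f"{ny}x{nx} field"
            )
    return centers, radii


def _disk_mask(shape, cx, cy, r):
    ny, nx = shape
    y0, y1 = max(0, int(np.floor(cy - r)) - 1), min(ny, int(np.ceil(cy + r)) + 2)
    x0, x1 = max(0, int(np.floor(cx - r)) - 1), min(nx, int(np.ceil(cx + r)) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (slice(y0, y1), slice(x0, x1)), (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _sample_emitters(rng, cx, cy, r, count, labels, cell_id, n_slices, min_sep):
    """Uniform positions in the disk interior, guaranteed on in-mask pixels."""
    xs, ys, zs = [], [], []
    r_in = max(r - 1.5, 0.5)  # keep the rounded pixel inside the rasterized mask
    attempts = 0
    while len(xs) < count and attempts < 1000 * max(count, 1):
        attempts += 1
        u = rng.uniform()
        theta = rng.uniform(0, 2 * np.pi)
        rad = r_in * np.sqrt(u)
        x = cx + rad * np.cos(theta)
        y = cy + rad * np.sin(theta)
        px, py = int(round(x)), int(round(y))
        if labels[py, px] != cell_id:
            continue
        if min_sep > 0 and any(np.hypot(x - a, y - b) < min_sep for a, b in zip(xs, ys)):
            continue
        xs.append(x)
        ys.append(y)
        zs.append(rng.uniform(0, n_slices - 1) if n_slices > 1 else 0.0)
    if len(xs) < count:
        raise ScenePlacementError(
            f"could not place {count} emitters with min_separation={min_sep} "
            f"inside cell {cell_id}"
        )
    return np.array(xs), np.array(ys), np.array(zs)


def _render_emitter(photons, x, y, z, peak, sxy, sz):
    """Add one separable 3D Gaussian PSF onto the photon volume in place."""
    nz, ny, nx = photons.shape
    hx = int(np.ceil(4 * sxy)) + 1
    hz = int(np.ceil(4 * sz)) + 1
    x0, x1 = max(0, int(np.floor(x)) - hx), min(nx, int(np.ceil(x)) + hx + 1)
    y0, y1 = max(0, int(np.floor(y)) - hx), min(ny, int(np.ceil(y)) + hx + 1)
    z0, z1 = max(0, int(np.floor(z)) - hz), min(nz, int(np.ceil(z)) + hz + 1)
    gx = np.exp(-((np.arange(x0, x1) - x) ** 2) / (2 * sxy**2))
    gy = np.exp(-((np.arange(y0, y1) - y) ** 2) / (2 * sxy**2))
    gz = np.exp(-((np.arange(z0, z1) - z) ** 2) / (2 * sz**2))
    photons[z0:z1, y0:y1, x0:x1] += peak * (
        gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


def _autofluor_field(rng, box_shape, cx, cy, r, smoothness, amplitude, edge_blur):
    """Smooth positive diffuse field over one cell's bounding box.

    The per-pixel level is ``amplitude`` at the cell center, modulated by a
    gentle (20% SD) random texture at the ``smoothness`` scale, and tapered
    laterally by the projected chord of a sphere, sqrt(1 − (d/r)²) — the
    column density of fluorophores filling a round cell. A PSF-scale blur
    removes any residual hard edge, as real optics would.
    """
    if amplitude == 0:
        return np.zeros(box_shape, dtype=np.float32)
    pad = int(np.ceil(3 * smoothness))
    shape = (box_shape[0] + 2 * pad, box_shape[1] + 2 * pad)
    g = gaussian_filter(rng.standard_normal(shape), smoothness)
    g = g[pad:-pad or None, pad:-pad or None]
    sd = g.std()
    if sd > 0:
        g = g / sd
    yy, xx = np.mgrid[0 : box_shape[0], 0 : box_shape[1]]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    chord = np.sqrt(np.clip(1.0 - d2 / r**2, 0.0, None))
    # Gentle 20% relative spatial modulation: diffuse haze, not punctate texture.
    field = amplitude * np.clip(1.0 + 0.2 * g, 0.0, None) * chord
    return gaussian_filter(field, edge_blur).astype(np.float32)


def simulate_scene(spec: SceneSpec) -> tuple["ImageStack", GroundTruth]:
    """Render one synthetic field of view and its full ground truth.

    Deterministic: the same spec (including seed) gives a bit-identical
    stack and tables. Cell placement, per-cell emitters and autofluorescence
    use independent substreams spawned from the master seed, so earlier
    cells are unchanged when ``n_cells`` grows.
    """
    from .imgio import ImageStack  # local import avoids a module cycle

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_cells + 2)
    rng_place = np.random.default_rng(children[0])
    rng_noise = np.random.default_rng(children[1])

    ny, nx = spec.field_shape
    centers, radii = _place_cells(spec, rng_place)

    labels = np.zeros((ny, nx), dtype=np.int32)
    for i, ((cx, cy), r) in enumerate(zip(centers, radii), start=1):
        box, disk = _disk_mask((ny, nx), cx, cy, r)
        labels[box][disk] = i

    photons = np.zeros((spec.n_slices, ny, nx), dtype=np.float32)
    cell_rows = []
    emitter_rows = []
    for i, ((cx, cy), r) in enumerate(zip(centers, radii), start=1):
        rng_cell = np.random.default_rng(children[i + 1])
        if spec.true_counts is not None:
            count = int(spec.true_counts[i - 1])
        else:
            count = int(
                negative_binomial(rng_cell, spec.mean_count, spec.count_dispersion)
            )
        xs, ys, zs = _sample_emitters(
            rng_cell, cx, cy, r, count, labels, i, spec.n_slices, spec.min_separation
        )
        for x, y, z in zip(xs, ys, zs):
            _render_emitter(
                photons, x, y, z, spec.spot_peak_photons, spec.psf_sigma_xy, spec.psf_sigma_z
            )
            emitter_rows.append({"cell_id": i, "x": x, "y": y, "z": z})

        box, disk = _disk_mask((ny, nx), cx, cy, r)
        box_shape = disk.shape
        af = _autofluor_field(
            rng_cell, box_shape, cx - box[1].start, cy - box[0].start, r,
            spec.autofluor_smoothness, spec.autofluor_amplitude, spec.psf_sigma_xy,
        )
        af_integral = float(af.sum()) * spec.n_slices
        if spec.autofluor_amplitude > 0:
            photons[:, box[0], box[1]] += af[None, :, :]
        cell_rows.append(
            {
                "cell_id": i,
                "cx": cx,
                "cy": cy,
                "radius": r,
                "true_count": count,
                "autofluor_integral": af_integral,
            }
        )

    # Camera model, slice by slice to bound memory: Poisson(expected photons)
    # + Gaussian read noise + constant baseline, quantized to the ADC range.
    max_adu = 2**spec.bit_depth - 1
    voxels = np.empty((spec.n_slices, ny, nx), dtype=np.uint16)
    for z in range(spec.n_slices):
        sl = photons[z].astype(np.float64)
        out = rng_noise.poisson(sl).astype(np.float64) if spec.poisson_noise else sl
        if spec.read_noise_sd > 0:
            out = out + rng_noise.normal(0.0, spec.read_noise_sd, size=sl.shape)
        out = np.rint(out + spec.baseline_offset)
        voxels[z] = np.clip(out, 0, max_adu).astype(np.uint16)

    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "cx", "cy", "radius", "true_count", "autofluor_integral"],
    )
    emitters = pd.DataFrame(emitter_rows, columns=["cell_id", "x", "y", "z"])
    stack = ImageStack(
        voxels=voxels,
        pixel_size=spec.pixel_size,
        slice_spacing=spec.slice_spacing,
        channel_label="synthetic-QD",
    )
    return stack, GroundTruth(cell_masks=labels, cells=cells, emitters=emitters)


def simulate_count_populations(spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (untreated, treated) per-cell count samples from the mixture model.

    Untreated: n i.i.d. NB(mu, dispersion). Treated: each cell is
    insensitive with probability ``insensitive_fraction`` (keeps mean mu),
    otherwise its mean is mu × (1 − inhibition); dispersion is shared.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    untreated = negative_binomial(rng, spec.mu_untreated, spec.dispersion, size=spec.n_cells)

    insensitive = rng.uniform(size=spec.n_cells) < spec.insensitive_fraction
    means = np.where(
        insensitive, spec.mu_untreated, spec.mu_untreated * (1.0 - spec.inhibition)
    )
    treated = negative_binomial(rng, means, spec.dispersion)
    return untreated.astype(np.int64), treated.astype(np.int64)
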