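"""Seeded generators of synthetic microscopy images with recorded ground truth.

Each generator emulates one class of input the quantification pipelines
consume — an epithelial layer with basally enriched punctate RNA signal, a
membrane stain whose basal contour deviates from a straight segmentation
line, a cultured cell with a tunable cortical/interior intensity partition,
and a 3D stack of elongated fibers plus small spherical distractor blobs —
and returns a :class:`GroundTruth` record from which every metric's true
value is computable in closed form (or by quadrature of the generative
density), without running the analysis pipelines.

All generators are pure functions of ``(seed, params)``: identical calls
produce bit-identical images.  The noise model is Poisson shot noise plus
optional Gaussian read noise; the point-spread function is an isotropic
Gaussian (default sigma 1.2 px, roughly the diffraction limit at 0.065
um/px).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage, optimize

from .errors import InvalidParameterError
from .geometry import PolylineROI, area_fraction_region
from .image import DEFAULT_PIXEL_SIZE_UM, IntensityImage

logger = logging.getLogger(__name__)

DEFAULT_PSF_SIGMA_PX = 1.2


@dataclass
class GroundTruth:
    """Generative parameters and derived true values of one synthetic image."""

    seed: int
    params: dict[str, Any]
    true_basal_fraction: float | None = None
    target_basal_fraction: float | None = None
    true_displacement_px: np.ndarray | None = None
    true_mean_abs_displacement_px: float | None = None
    true_cortical_weight: float | None = None
    expected_cortical_ratio: float | None = None
    true_fiber_volumes_um3: list[float] | None = None
    true_blob_volumes_um3: list[float] | None = None
    labels: np.ndarray | None = None


def _apply_noise(
    expected: np.ndarray,
    rng: np.random.Generator,
    poisson_noise: bool,
    read_noise_sigma: float,
) -> np.ndarray:
    out = rng.poisson(expected).astype(float) if poisson_noise else expected.copy()
    if read_noise_sigma > 0:
        out = out + rng.normal(0.0, read_noise_sigma, size=out.shape)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# epithelial layer with basally enriched spots
# ---------------------------------------------------------------------------

def _truncated_exp_basal_mass(decay_length: float | None, thickness: float, extent: float) -> float:
    """Mass of the truncated exponential depth density within ``extent`` of the basal edge."""
    if decay_length is None or np.isinf(decay_length):
        return extent
    lam = decay_length
    return float((1 - np.exp(-extent * thickness / lam)) / (1 - np.exp(-thickness / lam)))


def decay_length_for_fraction(target: float, thickness: float, extent: float = 0.30) -> float | None:
    """Solve for the exponential decay length giving a target basal mass fraction.

    ``target == extent`` corresponds to a uniform depth density (infinite
    decay length, returned as ``None``).  Targets below the uniform floor or
    >= 1 are infeasible.
    """
    if abs(target - extent) < 1e-12:
        return None
    if not extent < target < 1:
        raise InvalidParameterError(
            f"target basal fraction {target} infeasible (must be in [{extent}, 1))"
        )
    f = lambda lam: _truncated_exp_basal_mass(lam, thickness, extent) - target
    return float(optimize.brentq(f, 1e-3 * thickness, 1e3 * thickness, xtol=1e-10))


def expected_basal_fraction(
    thickness: int,
    decay_length: float | None,
    psf_sigma: float,
    extent: float = 0.30,
    n_quad: int = 20001,
) -> float:
    """Expected measured basal intensity fraction under the generative model.

    Quadrature over the truncated-exponential depth density, propagated
    through the same sub-pixel splat and Gaussian blur the renderer applies,
    then integrated over the basal ``extent`` of the layer with unit-pixel
    bins.  Independent of the analysis pipeline.
    """
    T = thickness
    d = np.linspace(0.0, T, n_quad)
    if decay_length is None or np.isinf(decay_length):
        w = np.ones_like(d)
    else:
        w = np.exp(-d / decay_length)
    w /= w.sum()
    y0 = T - d - 0.5
    lo = np.floor(y0).astype(int)
    frac = y0 - lo
    profile = np.zeros(T)
    for shift, wt in ((0, 1.0 - frac), (1, frac)):
        rows = lo + shift
        ok = (rows >= 0) & (rows < T)
        np.add.at(profile, rows[ok], (w * wt)[ok])
    if psf_sigma > 0:
        profile = ndimage.gaussian_filter1d(profile, psf_sigma, mode="constant")
    # basal extent covers rows [ (1-extent)*T, T ) with pixel row y = [y, y+1)
    edge = (1.0 - extent) * T
    rows = np.arange(T)
    overlap = np.clip(rows + 1.0 - edge, 0.0, 1.0)
    return float((profile * overlap).sum() / profile.sum())


def make_layer_image(
    seed: int,
    width: int = 300,
    thickness: int = 100,
    n_spots: int = 2000,
    decay_length: float | None = None,
    target_basal_fraction: float | None = None,
    spot_amplitude: float = 100.0,
    psf_sigma: float = DEFAULT_PSF_SIGMA_PX,
    background: float = 0.0,
    poisson_noise: bool = False,
    read_noise_sigma: float = 0.0,
    basal_extent: float = 0.30,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[IntensityImage, GroundTruth]:
    """Epithelial layer band with punctate spots enriched toward the basal edge.

    The layer occupies the full image (``thickness`` rows x ``width``
    columns); the basal edge is the bottom.  Spot depth from the basal edge
    follows a truncated exponential density with scale ``decay_length``
    (``None`` = uniform); alternatively pass ``target_basal_fraction`` and
    the decay length is solved for.  Spots are Gaussian puncta of width
    ``psf_sigma``.
    """
    if width < 32 or thickness < 32:
        raise InvalidParameterError("layer dimensions must be >= 32 px")
    if n_spots < 1:
        raise InvalidParameterError("n_spots must be >= 1")
    if target_basal_fraction is not None:
        if decay_length is not None:
            raise InvalidParameterError("give decay_length or target_basal_fraction, not both")
        decay_length = decay_length_for_fraction(target_basal_fraction, thickness, basal_extent)

    rng = np.random.default_rng(seed)
    T = thickness
    # sample depths from the truncated exponential by inverse CDF
    u = rng.random(n_spots)
    if decay_length is None or np.isinf(decay_length):
        d = u * T
    else:
        lam = decay_length
        d = -lam * np.log1p(-u * (1 - np.exp(-T / lam)))
    x0 = rng.random(n_spots) * (width - 1)
    y0 = T - d - 0.5

    img = np.zeros((T, width))
    ylo, xlo = np.floor(y0).astype(int), np.floor(x0).astype(int)
    yf, xf = y0 - ylo, x0 - xlo
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        rows, cols = ylo + dy, xlo + dx
        wgt = (yf if dy else 1 - yf) * (xf if dx else 1 - xf)
        ok = (rows >= 0) & (rows < T) & (cols >= 0) & (cols < width)
        np.add.at(img, (rows[ok], cols[ok]), (spot_amplitude * wgt)[ok])
    if psf_sigma > 0:
        img = ndimage.gaussian_filter(img, psf_sigma, mode="constant")
    img = _apply_noise(img + background, rng, poisson_noise, read_noise_sigma)

    truth = GroundTruth(
        seed=seed,
        params=dict(
            width=width, thickness=thickness, n_spots=n_spots,
            decay_length=decay_length, spot_amplitude=spot_amplitude,
            psf_sigma=psf_sigma, background=background,
            poisson_noise=poisson_noise, read_noise_sigma=read_noise_sigma,
            basal_extent=basal_extent,
        ),
        true_basal_fraction=expected_basal_fraction(T, decay_length, psf_sigma, basal_extent),
        target_basal_fraction=_truncated_exp_basal_mass(decay_length, T, basal_extent),
    )
    return IntensityImage(img, pixel_size_um=pixel_size_um), truth


# ---------------------------------------------------------------------------
# membrane stain with displaced basal contour
# ---------------------------------------------------------------------------

def _displacement_field(
    rng: np.random.Generator, L: int, amplitude: float, waveform: str, period: float
) -> np.ndarray:
    x = np.arange(L)
    if waveform == "flat":
        return np.zeros(L)
    if waveform == "sine":
        return amplitude * np.sin(2 * np.pi * x / period)
    if waveform == "square":
        return amplitude * np.where(np.sin(2 * np.pi * x / period) >= 0, 1.0, -1.0)
    if waveform == "random_walk":
        w = np.cumsum(rng.normal(0.0, 1.0, L))
        w = ndimage.gaussian_filter1d(w, 5.0, mode="nearest")
        peak = np.abs(w).max()
        return amplitude * w / peak if peak > 0 else w
    raise InvalidParameterError(f"unknown waveform {waveform!r}")


def make_membrane_image(
    seed: int,
    L: int = 500,
    amplitude_px: float = 10.0,
    waveform: str = "sine",
    line_thickness_px: int = 3,
    intensity: float = 200.0,
    background: float = 10.0,
    period_px: float = 100.0,
    band_width_px: int = 121,
    poisson_noise: bool = False,
    read_noise_sigma: float = 0.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[IntensityImage, PolylineROI, GroundTruth]:
    """Membrane-stain image with a bright contour displaced from a straight line.

    The returned polyline is the straight horizontal segmentation line; the
    membrane is rendered as a connected curve of ``line_thickness_px`` at
    ``line_row + displacement(x)``.  The true displacement field is recorded.
    """
    half_band = (band_width_px - 1) / 2
    if amplitude_px >= half_band:
        raise InvalidParameterError(
            f"amplitude {amplitude_px} px must be below the band half-width {half_band}"
        )
    rng = np.random.default_rng(seed)
    disp = _displacement_field(rng, L, amplitude_px, waveform, period_px)
    H = band_width_px + 21
    y_line = H // 2
    y_curve = y_line + disp
    h = (line_thickness_px - 1) / 2
    img = np.full((H, L), float(background))
    nxt = np.concatenate([y_curve[1:], y_curve[-1:]])
    lo = np.floor(np.minimum(y_curve, nxt) - h).astype(int)
    hi = np.ceil(np.maximum(y_curve, nxt) + h).astype(int)
    for x in range(L):
        img[max(lo[x], 0): min(hi[x] + 1, H), x] = intensity
    img = _apply_noise(img, rng, poisson_noise, read_noise_sigma)

    line = PolylineROI(np.array([[0.0, y_line], [L - 1.0, y_line]]), closed=False)
    truth = GroundTruth(
        seed=seed,
        params=dict(
            L=L, amplitude_px=amplitude_px, waveform=waveform,
            line_thickness_px=line_thickness_px, intensity=intensity,
            background=background, period_px=period_px, band_width_px=band_width_px,
            poisson_noise=poisson_noise, read_noise_sigma=read_noise_sigma,
        ),
        true_displacement_px=disp,
        true_mean_abs_displacement_px=float(np.abs(disp).mean()),
    )
    return IntensityImage(img, pixel_size_um=pixel_size_um), line, truth


# ---------------------------------------------------------------------------
# cultured cell with cortical/interior intensity partition
# ---------------------------------------------------------------------------

def _cell_mask(rng: np.random.Generator, mask_shape: str, radius: float, grid: int) -> np.ndarray:
    yy, xx = np.mgrid[0:grid, 0:grid]
    cy = cx = (grid - 1) / 2
    if mask_shape == "disk":
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    if mask_shape == "ellipse":
        return ((xx - cx) / radius) ** 2 + ((yy - cy) / (0.6 * radius)) ** 2 <= 1.0
    if mask_shape == "blob":
        theta = np.arctan2(yy - cy, xx - cx)
        r_pix = np.hypot(xx - cx, yy - cy)
        amp = 0.15 * rng.random(3)
        phase = 2 * np.pi * rng.random(3)
        rb = radius * (1 + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase))))
        return r_pix <= rb
    raise InvalidParameterError(f"unknown mask shape {mask_shape!r}")


def make_cell_image(
    seed: int,
    mask_shape: str = "disk",
    radius: float = 40.0,
    cortical_weight: float = 0.5,
    photons: float = 1e5,
    peripheral_frac: float = 0.15,
    central_frac: float = 0.65,
    poisson_noise: bool = False,
    read_noise_sigma: float = 0.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[IntensityImage, np.ndarray, GroundTruth]:
    """Cell with fraction ``cortical_weight`` of intensity in its peripheral band.

    A fraction ``w`` of the total expected photon count is spread uniformly
    over the peripheral ``peripheral_frac`` area band of the mask, and
    ``1 - w`` uniformly over the remaining interior.  The expected cortical
    ratio follows in closed form from the recorded region areas:
    ``(w / A_peripheral) / ((1 - w) / A_interior)`` (the central region is a
    subset of the interior, where density is uniform).
    """
    w = cortical_weight
    if not 0 <= w <= 1:
        raise InvalidParameterError(f"cortical_weight must be in [0, 1], got {w}")
    rng = np.random.default_rng(seed)
    grid = int(np.ceil(2 * radius)) + 21
    mask = _cell_mask(rng, mask_shape, radius, grid)
    band = area_fraction_region(mask, peripheral_frac, "peripheral")
    interior = mask & ~band
    a_band, a_int = int(band.sum()), int(interior.sum())
    expected = np.zeros(mask.shape)
    expected[band] = w * photons / a_band
    expected[interior] = (1 - w) * photons / a_int
    img = _apply_noise(expected, rng, poisson_noise, read_noise_sigma)

    dens_band = w / a_band
    dens_int = (1 - w) / a_int
    ratio = dens_band / dens_int if dens_int > 0 else np.nan
    truth = GroundTruth(
        seed=seed,
        params=dict(
            mask_shape=mask_shape, radius=radius, cortical_weight=w,
            photons=photons, peripheral_frac=peripheral_frac,
            central_frac=central_frac, poisson_noise=poisson_noise,
            read_noise_sigma=read_noise_sigma, peripheral_area=a_band,
            interior_area=a_int,
        ),
        true_cortical_weight=w,
        expected_cortical_ratio=float(ratio) if np.isfinite(ratio) else None,
    )
    return IntensityImage(img, pixel_size_um=pixel_size_um), mask, truth


# ---------------------------------------------------------------------------
# 3D fiber stack with spherical distractors
# ---------------------------------------------------------------------------

FIBER_LABEL = 1
BLOB_LABEL = 2


def make_fiber_stack(
    seed: int,
    shape: tuple[int, int, int] = (64, 128, 128),
    n_fibers: int = 5,
    fiber_radius_vox: float = 3.0,
    fiber_length_vox: float = 70.0,
    n_blobs: int = 10,
    blob_radius_vox: float = 4.0,
    fiber_intensity: float = 200.0,
    blob_intensity: float = 200.0,
    background: float = 10.0,
    poisson_noise: bool = False,
    read_noise_sigma: float = 0.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_step_um: float = DEFAULT_PIXEL_SIZE_UM,
    avoid_overlap: bool = True,
    max_tries: int = 200,
) -> tuple[IntensityImage, GroundTruth]:
    """3D stack of randomly oriented solid cylinders plus spherical distractor blobs.

    Geometry is in voxel units with isotropic voxels by default (the axial
    step matching the in-plane pixel size), so blobs are genuinely spherical
    in physical space.  With ``avoid_overlap`` (default) object positions are
    rejection-sampled so fiber and blob labels stay unambiguous; otherwise
    later objects overwrite earlier ones and overlaps are logged.
    """
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    labels = np.zeros(shape, dtype=np.uint8)
    # occupancy dilated by one voxel: placed objects must not touch (26-conn)
    occupied_dil = np.zeros(shape, dtype=bool)
    voxel_vol = pixel_size_um**2 * z_step_um
    fiber_vols: list[float] = []
    blob_vols: list[float] = []

    def _place(render) -> np.ndarray | None:
        for _ in range(max_tries):
            obj = render()
            if obj is None:
                continue
            if avoid_overlap and np.any(occupied_dil & obj):
                continue
            if not avoid_overlap and np.any(labels[obj]):
                logger.info("object overlaps existing foreground; overwriting")
            occupied_dil[ndimage.binary_dilation(obj, np.ones((3, 3, 3), bool))] = True
            return obj
        return None

    margin_f = fiber_radius_vox + 1
    for _ in range(n_fibers):
        def render_fiber():
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            c = np.array([
                rng.uniform(margin_f, nz - margin_f),
                rng.uniform(margin_f, ny - margin_f),
                rng.uniform(margin_f, nx - margin_f),
            ])
            ends = np.stack([c - u * fiber_length_vox / 2, c + u * fiber_length_vox / 2])
            if (ends.min(axis=0) < margin_f).any() or (
                ends[:, 0].max() > nz - margin_f
                or ends[:, 1].max() > ny - margin_f
                or ends[:, 2].max() > nx - margin_f
            ):
                return None
            p = np.stack([zz - c[0], yy - c[1], xx - c[2]])
            along = u[0] * p[0] + u[1] * p[1] + u[2] * p[2]
            perp2 = p[0] ** 2 + p[1] ** 2 + p[2] ** 2 - along**2
            return (np.abs(along) <= fiber_length_vox / 2) & (perp2 <= fiber_radius_vox**2)

        obj = _place(render_fiber)
        if obj is None:
            raise InvalidParameterError("could not place all fibers; reduce density or sizes")
        labels[obj] = FIBER_LABEL
        fiber_vols.append(float(obj.sum()) * voxel_vol)

    margin_b = blob_radius_vox + 1
    for _ in range(n_blobs):
        def render_blob():
            c = np.array([
                rng.uniform(margin_b, nz - margin_b),
                rng.uniform(margin_b, ny - margin_b),
                rng.uniform(margin_b, nx - margin_b),
            ])
            return (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= blob_radius_vox**2

        obj = _place(render_blob)
        if obj is None:
            raise InvalidParameterError("could not place all blobs; reduce density or sizes")
        labels[obj] = BLOB_LABEL
        blob_vols.append(float(obj.sum()) * voxel_vol)

    expected = np.full(shape, float(background))
    expected[labels == FIBER_LABEL] = fiber_intensity
    expected[labels == BLOB_LABEL] = blob_intensity
    img = _apply_noise(expected, rng, poisson_noise, read_noise_sigma)

    truth = GroundTruth(
        seed=seed,
        params=dict(
            shape=shape, n_fibers=n_fibers, fiber_radius_vox=fiber_radius_vox,
            fiber_length_vox=fiber_length_vox, n_blobs=n_blobs,
            blob_radius_vox=blob_radius_vox, fiber_intensity=fiber_intensity,
            blob_intensity=blob_intensity, background=background,
            poisson_noise=poisson_noise, read_noise_sigma=read_noise_sigma,
            avoid_overlap=avoid_overlap,
        ),
        true_fiber_volumes_um3=fiber_vols,
        true_blob_volumes_um3=blob_vols,
        labels=labels,
    )
    return IntensityImage(img, pixel_size_um=pixel_size_um, z_step_um=z_step_um), truth
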