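"""Synthetic inputs: defect patterns, AFM-like images, a blob detector, noisy spectra.

Everything the pipeline consumes can be generated here without any external
data: ground-truth defect point patterns with controlled clustering
(homogeneous Poisson or Thomas/Neyman-Scott cluster processes), AFM-lookalike
topography images rendered from a defect set, a classical multi-scale
Laplacian-of-Gaussian blob detector that stands in for a trained CNN
detector, and noise-perturbed reference spectra for fitting experiments.

The rendered images are synthetic lookalikes -- flat background plus
correlated roughness, per-scanline offsets and Gaussian pits at defect
positions; they do not simulate AFM tip convolution.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from skimage.feature import blob_log

from .defect_sets import DEFAULT_R_BOX_NM, PIXEL_SIZE_NM, DefectSet
from .eis_model import EISSpectrum, FrequencyGrid, MembraneParams, MeshParams, model_spectrum
from .exceptions import ParameterError, ValidationError


# ---------------------------------------------------------------------------
# point processes
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PointProcessParams:
    """Ground-truth pattern parameters.

    ``kind`` is ``"poisson"`` (homogeneous) or ``"thomas"`` (Neyman-Scott
    clusters: Poisson parents, Gaussian-scattered offspring).  ``density`` is
    the target defect density in um^-2.  For the Thomas process the density is
    split as ``parent_density * mean_offspring``; ``cluster_spread`` is the
    offspring Gaussian SD in nm.
    """

    kind: str = "poisson"
    density: float = 10.0
    parent_density: float = 1.0
    mean_offspring: float = 10.0
    cluster_spread: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "thomas"):
            raise ParameterError(f"unknown point process kind {self.kind!r}")
        if self.density <= 0 or self.parent_density <= 0 or self.cluster_spread <= 0:
            raise ParameterError("densities and cluster spread must be positive")


def sample_point_process(
    params: PointProcessParams,
    field_width: float = 4000.0,
    field_height: float = 4000.0,
    r_box: float = DEFAULT_R_BOX_NM,
) -> DefectSet:
    """Draw one defect pattern on the field; reproducible from ``params.seed``.

    Thomas parents are drawn on a field padded by three cluster spreads so the
    offspring density is unbiased near the edges; offspring falling outside
    the field are discarded.
    """
    rng = np.random.default_rng(params.seed)
    area_um2 = field_width * field_height / 1.0e6
    if params.kind == "poisson":
        n = rng.poisson(params.density * area_um2)
        xy = rng.uniform((0.0, 0.0), (field_width, field_height), size=(n, 2))
    else:
        pad = 3.0 * params.cluster_spread
        pw, ph = field_width + 2 * pad, field_height + 2 * pad
        n_parents = rng.poisson(params.parent_density * pw * ph / 1.0e6)
        parents = rng.uniform((-pad, -pad), (field_width + pad, field_height + pad), size=(n_parents, 2))
        mean_offspring = params.density / params.parent_density
        pts = []
        for p in parents:
            k = rng.poisson(mean_offspring)
            pts.append(p + rng.normal(0.0, params.cluster_spread, size=(k, 2)))
        xy = np.vstack(pts) if pts else np.empty((0, 2))
        inside = (
            (xy[:, 0] >= 0.0) & (xy[:, 0] <= field_width)
            & (xy[:, 1] >= 0.0) & (xy[:, 1] <= field_height)
        )
        xy = xy[inside]
    if len(xy) < 3:
        import warnings

        warnings.warn(
            f"only {len(xy)} defects sampled: clustering sigma is not computable",
            stacklevel=2,
        )
    return DefectSet.from_coordinates(xy, field_width, field_height, r_box=r_box,
                                      label=f"{params.kind}(seed={params.seed})")


#: Pattern presets emulating the three imaged surfaces: densities in the
#: 6-11 um^-2 range with clustering sigma from ~0.9 (weak) to ~1.2 (strong).
SURFACE_PRESETS: dict[str, PointProcessParams] = {
    "surface1": PointProcessParams(
        kind="thomas", density=10.75, parent_density=1.7, cluster_spread=180.0
    ),
    "surface2": PointProcessParams(
        kind="thomas", density=6.06, parent_density=1.3, cluster_spread=200.0
    ),
    "surface3": PointProcessParams(
        kind="thomas", density=9.88, parent_density=2.8, cluster_spread=260.0
    ),
}


# ---------------------------------------------------------------------------
# AFM image rendering
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ImageRenderParams:
    """Rendering knobs for AFM-lookalike topographs (all lengths in nm)."""

    pixel_size: float = PIXEL_SIZE_NM
    defect_depth: float = 2.0
    defect_apparent_radius: float = 15.0
    roughness_amplitude: float = 0.3
    roughness_correlation: float = 40.0
    scanline_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel size must be positive")


def render_afm_image(defect_set: DefectSet, params: ImageRenderParams) -> np.ndarray:
    """Render a height map (nm) of the defect set.

    Flat background + correlated Gaussian roughness + per-scanline offsets,
    with a Gaussian pit of the given depth and apparent radius at every defect
    center.  The field must be an integer number of pixels.
    """
    px = params.pixel_size
    nx = defect_set.field_width / px
    ny = defect_set.field_height / px
    if abs(nx - round(nx)) > 1e-6 or abs(ny - round(ny)) > 1e-6:
        raise ValidationError(
            f"field {defect_set.field_width} x {defect_set.field_height} nm is not "
            f"an integer number of {px} nm pixels"
        )
    nx, ny = int(round(nx)), int(round(ny))
    rng = np.random.default_rng(params.seed)
    height = np.zeros((ny, nx))
    if params.roughness_amplitude > 0:
        rough = gaussian_filter(
            rng.standard_normal((ny, nx)), params.roughness_correlation / px, mode="wrap"
        )
        sd = rough.std()
        if sd > 0:
            height += rough * (params.roughness_amplitude / sd)
    if params.scanline_noise > 0:
        height += rng.normal(0.0, params.scanline_noise, size=(ny, 1))
    # pixel centers in nm
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    for d in defect_set.defects:
        r = params.defect_apparent_radius
        j0, j1 = np.searchsorted(xs, [d.x - 4 * r, d.x + 4 * r])
        i0, i1 = np.searchsorted(ys, [d.y - 4 * r, d.y + 4 * r])
        dx = xs[j0:j1] - d.x
        dy = ys[i0:i1] - d.y
        height[i0:i1, j0:j1] -= params.defect_depth * np.exp(
            -(dx[None, :] ** 2 + dy[:, None] ** 2) / (2.0 * (r / 2.0) ** 2)
        )
    return height


def write_afm_tiff(height: np.ndarray, path: str | Path, pixel_size: float = PIXEL_SIZE_NM) -> None:
    """Export a height map as 16-bit grayscale TIFF with a YAML calibration sidecar."""
    import tifffile

    path = Path(path)
    lo, hi = float(height.min()), float(height.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((height - lo) / span * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, scaled)
    sidecar = {
        "pixel_size_nm": float(pixel_size),
        "height_offset_nm": lo,
        "height_scale_nm_per_count": span / 65535.0,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_afm_tiff(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a height map written by :func:`write_afm_tiff`; returns (nm map, pixel size)."""
    import tifffile

    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    raw = tifffile.imread(path).astype(float)
    height = raw * sidecar["height_scale_nm_per_count"] + sidecar["height_offset_nm"]
    return height, float(sidecar["pixel_size_nm"])


# ---------------------------------------------------------------------------
# blob detection (CNN stand-in)
# ---------------------------------------------------------------------------

def detect_blobs(
    image: np.ndarray,
    pixel_size: float = PIXEL_SIZE_NM,
    min_radius: float = 8.0,
    max_radius: float = 30.0,
    threshold: float = 0.2,
    r_box: float = DEFAULT_R_BOX_NM,
) -> DefectSet:
    """Detect pit-like defects by multi-scale Laplacian-of-Gaussian filtering.

    The height map is inverted (pits become bright), background-subtracted and
    normalised by the pit depth scale before LoG detection, so ``threshold``
    is a fraction of the deepest pit response.  Returns detected centers in nm
    with the standard 25 nm half-width detection boxes.  A constant image
    yields an empty set with a warning.
    """
    image = np.asarray(image, dtype=float)
    depth = np.median(image) - image  # pits positive
    scale = np.percentile(depth, 99.9)
    if scale <= 0:
        import warnings

        warnings.warn("image has no pits (constant or saturated)", stacklevel=2)
        return DefectSet((), image.shape[1] * pixel_size, image.shape[0] * pixel_size)
    norm = np.clip(depth / scale, 0.0, None)
    blobs = blob_log(
        norm,
        min_sigma=min_radius / pixel_size / np.sqrt(2.0),
        max_sigma=max_radius / pixel_size / np.sqrt(2.0),
        num_sigma=6,
        threshold=threshold,
    )
    h, w = image.shape
    xy = np.column_stack([(blobs[:, 1] + 0.5) * pixel_size, (blobs[:, 0] + 0.5) * pixel_size])
    xy[:, 0] = np.clip(xy[:, 0], 0.0, w * pixel_size)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, h * pixel_size)
    return DefectSet.from_coordinates(
        xy, w * pixel_size, h * pixel_size, r_box=r_box, label="blob_log"
    )


# ---------------------------------------------------------------------------
# noisy reference spectra
# ---------------------------------------------------------------------------

def synth_reference_spectrum(
    defect_set: DefectSet,
    mp: MembraneParams,
    fg: FrequencyGrid,
    noise_sd_phase_deg: float = 0.0,
    seed: int = 0,
    mesh: MeshParams = MeshParams(),
) -> EISSpectrum:
    """Forward-model spectrum with independent Gaussian phase noise per frequency.

    The magnitude is kept consistent with the perturbed phase (the complex
    admittance is rotated), emulating a measured spectrum of known provenance.
    """
    spectrum = model_spectrum(defect_set, mp, fg, mesh)
    if noise_sd_phase_deg <= 0:
        return spectrum
    rng = np.random.default_rng(seed)
    delta = np.radians(rng.normal(0.0, noise_sd_phase_deg, size=len(spectrum.frequencies)))
    return EISSpectrum(spectrum.frequencies, spectrum.admittance * np.exp(1j * delta))
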