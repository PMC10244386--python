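"""Hessian-eigenvalue tubeness and naive-calibrated PVS segmentation.

Perivascular spaces filled with a T1-shortening tracer appear as bright,
slender tubes of near-voxel width.  For a bright tube the smoothed
intensity field has one near-zero principal curvature along the axis and
two strongly negative curvatures across it, so with the Hessian
eigenvalues sorted ``lam1 >= lam2 >= lam3`` a tube satisfies
``0 > lam1 > lam2 > lam3`` with ``lam1 ~ 0`` and ``lam2 ~ lam3 << 0``.
The per-voxel tubeness score is the geometric mean of the two most
negative eigenvalues,

    tubeness = sqrt(lam2 * lam3)   if lam2 < 0 and lam3 < 0, else 0,

a single-scale variant of Frangi vesselness.  The segmentation threshold
is not a fixed number: it is calibrated on control volumes acquired
without tracer ("naive" brains) as the intensity-peak-aligned tubeness
quantile (default 0.95) within each region, averaged over the controls.
The brain surface gets its own, higher threshold because the
brain/background interface produces strong curvature even without tracer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .core import GeometryError, ImageVolume

__all__ = [
    "TubenessConfig",
    "remap_intensity",
    "histogram_mode",
    "compute_tubeness",
    "brain_regions",
    "calibrate_threshold",
    "segment_pvs",
    "percent_volume",
    "PVSSegmenter",
]

_CUBE = np.ones((3, 3, 3), dtype=bool)  # 26-connected structuring element


@dataclass
class TubenessConfig:
    """Knobs of the tubeness/segmentation stage.

    gaussian_sigma : physical smoothing scale in mm (default 0.04, one
        voxel at the native resolution, tuned to single-voxel tubes).
    interior_quantile : cumulative level of the naive tubeness
        distribution used as threshold (default 0.95).
    surface_shell_voxels : thickness in voxels of the brain-surface shell
        that gets the separate (higher) threshold.
    reference_peak : target intensity for histogram-peak alignment; None
        disables remapping.
    hessian : "central" = Gaussian smooth then spacing-aware central
        second differences; "gaussian" = Gaussian-derivative convolution.
    """

    gaussian_sigma: float = 0.04
    interior_quantile: float = 0.95
    surface_shell_voxels: int = 3
    reference_peak: float | None = None
    hessian: str = "central"

    def __post_init__(self) -> None:
        if not self.gaussian_sigma > 0:
            raise ValueError("gaussian_sigma must be positive")
        if not 0 < self.interior_quantile < 1:
            raise ValueError("interior_quantile must be in (0, 1)")
        if self.surface_shell_voxels < 1:
            raise ValueError("surface_shell_voxels must be >= 1")
        if self.hessian not in ("central", "gaussian"):
            raise ValueError("hessian must be 'central' or 'gaussian'")


def histogram_mode(values: np.ndarray, bins: int = 256) -> float:
    """Mode of a sample as the center of the tallest histogram bin.

    Bins span the 0.5-99.5 percentile range so stray extreme values do
    not stretch the binning.
    """
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = np.percentile(values, [0.5, 99.5])
    if not hi > lo:
        raise ValueError("degenerate (near-constant) intensity distribution; cannot locate peak")
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def remap_intensity(volume: ImageVolume, brain_mask: ImageVolume,
                    reference_peak: float) -> ImageVolume:
    """Linearly rescale so the within-brain intensity mode hits ``reference_peak``.

    Tracer uptake shifts the whole intensity range between animals; before
    the tubeness thresholds from the controls can be applied, each
    volume's parenchymal histogram peak is aligned to a common reference.
    The scale factor is recorded in ``meta['remap_scale']``.
    """
    volume.check_geometry(brain_mask, "brain mask")
    if not brain_mask.data.any():
        raise ValueError("brain mask is empty")
    mode = histogram_mode(volume.data[brain_mask.data.astype(bool)])
    if mode == 0:
        raise ValueError("intensity mode is zero; cannot rescale")
    scale = reference_peak / mode
    out = ImageVolume(volume.data * scale, volume.spacing, dict(volume.meta))
    out.meta["remap_scale"] = scale
    out.meta["remap_mode"] = mode
    return out


def _hessian_fields(data: np.ndarray, spacing, sigma_mm: float, method: str) -> np.ndarray:
    """Six unique Hessian components, shape (..., 3, 3), physical units (1/mm^2)."""
    sigma_vox = [sigma_mm / s for s in spacing]
    H = np.empty(data.shape + (3, 3), dtype=np.float32)
    if method == "central":
        sm = ndimage.gaussian_filter(data.astype(np.float64), sigma_vox, mode="nearest")
        # compact stencils: [1,-2,1]/h^2 on the diagonal, successive
        # central first differences [-1,0,1]/2h for the mixed terms
        for i in range(3):
            H[..., i, i] = ndimage.correlate1d(
                sm, np.array([1.0, -2.0, 1.0]) / spacing[i] ** 2, axis=i, mode="nearest"
            )
        for i in range(3):
            for j in range(i + 1, 3):
                gi = ndimage.correlate1d(
                    sm, np.array([0.5, 0.0, -0.5]) / spacing[i], axis=i, mode="nearest"
                )
                gij = ndimage.correlate1d(
                    gi, np.array([0.5, 0.0, -0.5]) / spacing[j], axis=j, mode="nearest"
                )
                H[..., i, j] = gij
                H[..., j, i] = gij
    else:  # Gaussian-derivative convolution
        d64 = data.astype(np.float64)
        for i in range(3):
            for j in range(i, 3):
                order = [0, 0, 0]
                order[i] += 1
                order[j] += 1
                h = ndimage.gaussian_filter(d64, sigma_vox, order=order, mode="nearest")
                h /= spacing[i] * spacing[j]
                H[..., i, j] = h
                H[..., j, i] = h
    return H


def compute_tubeness(volume: ImageVolume, config: TubenessConfig | None = None) -> ImageVolume:
    """Per-voxel tubeness of the Gaussian-smoothed intensity field.

    The Hessian is computed at physical scale ``gaussian_sigma`` with
    spacing-aware derivatives (anisotropic voxels are handled by
    expressing sigma and the difference stencils in mm), its eigenvalues
    sorted descending, and ``sqrt(lam2*lam3)`` taken wherever both are
    negative.  Replicate-edge padding is used at the volume boundary.
    """
    config = config or TubenessConfig()
    H = _hessian_fields(volume.data, volume.spacing, config.gaussian_sigma, config.hessian)
    flat = H.reshape(-1, 3, 3)
    tub = np.zeros(flat.shape[0], dtype=np.float32)
    chunk = 1 << 21  # bound eigvalsh workspace on large volumes
    for s in range(0, flat.shape[0], chunk):
        w = np.linalg.eigvalsh(flat[s : s + chunk])  # ascending: lam3, lam2, lam1
        lam3, lam2 = w[:, 0], w[:, 1]
        ok = (lam2 < 0) & (lam3 < 0)
        tub[s : s + chunk][ok] = np.sqrt(lam2[ok] * lam3[ok])
    out = ImageVolume(tub.reshape(volume.shape), volume.spacing, dict(volume.meta))
    out.meta["tubeness_config"] = config
    return out


def brain_regions(brain_mask: ImageVolume, shell_voxels: int = 3) -> dict[str, ImageVolume]:
    """Partition the brain into a surface shell and the interior.

    The shell is the set of brain voxels removed by ``shell_voxels``
    iterations of 26-connected erosion; interior is the rest.
    """
    b = brain_mask.data.astype(bool)
    interior = ndimage.binary_erosion(b, structure=_CUBE, iterations=shell_voxels)
    return {
        "interior": ImageVolume(interior, brain_mask.spacing),
        "surface": ImageVolume(b & ~interior, brain_mask.spacing),
    }


def calibrate_threshold(naive_tubeness: Sequence[ImageVolume],
                        region_masks: Mapping[str, ImageVolume],
                        quantile: float = 0.95) -> dict[str, float]:
    """Per-region tubeness thresholds from naive (no-tracer) volumes.

    For each region the threshold is the mean over control volumes of
    that volume's ``quantile``-level tubeness within the region, i.e. a
    value exceeding the tubeness of (on average) a ``quantile`` fraction
    of control voxels.
    """
    if len(naive_tubeness) == 0:
        raise ValueError("need at least one naive tubeness volume")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    thresholds: dict[str, float] = {}
    for name, region in region_masks.items():
        rmask = region.data.astype(bool)
        if not rmask.any():
            raise ValueError(f"region {name!r} mask is empty")
        qs = []
        for tub in naive_tubeness:
            tub.check_geometry(region, f"region {name!r}")
            qs.append(float(np.quantile(tub.data[rmask], quantile)))
        thresholds[name] = float(np.mean(qs))
    return thresholds


def segment_pvs(tubeness: ImageVolume, thresholds: Mapping[str, float],
                region_masks: Mapping[str, ImageVolume], brain_mask: ImageVolume,
                ventricle_mask: ImageVolume | None = None,
                exclusion_masks: Iterable[ImageVolume] = ()) -> ImageVolume:
    """Threshold the tubeness map region by region.

    A voxel is PVS iff its tubeness strictly exceeds the threshold of the
    region containing it, it lies inside the brain, and it lies outside
    the ventricles and every exclusion mask (e.g. the cerebellum, whose
    internal boundaries confound tubeness).
    """
    tubeness.check_geometry(brain_mask, "brain mask")
    out = np.zeros(tubeness.shape, dtype=bool)
    for name, thr in thresholds.items():
        if name not in region_masks:
            raise KeyError(f"no region mask supplied for threshold {name!r}")
        region = region_masks[name]
        tubeness.check_geometry(region, f"region {name!r}")
        out |= (tubeness.data > thr) & region.data.astype(bool)
    out &= brain_mask.data.astype(bool)
    if ventricle_mask is not None:
        tubeness.check_geometry(ventricle_mask, "ventricle mask")
        out &= ~ventricle_mask.data.astype(bool)
    for excl in exclusion_masks:
        tubeness.check_geometry(excl, "exclusion mask")
        out &= ~excl.data.astype(bool)
    return ImageVolume(out, tubeness.spacing, {"thresholds": dict(thresholds)})


def percent_volume(pvs_mask: ImageVolume, voi_mask: ImageVolume) -> float:
    """Percent of VOI voxels segmented as PVS: 100 * |pvs & voi| / |voi|."""
    pvs_mask.check_geometry(voi_mask, "VOI mask")
    voi = voi_mask.data.astype(bool)
    n_voi = int(voi.sum())
    if n_voi == 0:
        raise ValueError("VOI mask is empty")
    return 100.0 * int((pvs_mask.data.astype(bool) & voi).sum()) / n_voi


class PVSSegmenter(BaseEstimator):
    """Naive-calibrated tubeness segmenter with a fit/predict interface.

    ``fit`` consumes control volumes (no tracer) with their brain masks
    and learns per-region tubeness thresholds; ``predict`` segments a
    contrast-enhanced volume with those thresholds.  Peak alignment, when
    ``reference_peak`` is set, is applied consistently to controls and
    targets so the thresholds transfer across intensity scales.

    Parameters mirror :class:`TubenessConfig`.  Fitted attributes:

    thresholds_ : dict region name -> tubeness threshold
    n_naive_ : number of control volumes used
    scale_factors_ : remap scale applied to each control (empty if no
        remapping)
    """

    def __init__(self, gaussian_sigma: float = 0.04, interior_quantile: float = 0.95,
                 surface_shell_voxels: int = 3, reference_peak: float | None = None,
                 hessian: str = "central"):
        self.gaussian_sigma = gaussian_sigma
        self.interior_quantile = interior_quantile
        self.surface_shell_voxels = surface_shell_voxels
        self.reference_peak = reference_peak
        self.hessian = hessian

    def _config(self) -> TubenessConfig:
        return TubenessConfig(
            gaussian_sigma=self.gaussian_sigma,
            interior_quantile=self.interior_quantile,
            surface_shell_voxels=self.surface_shell_voxels,
            reference_peak=self.reference_peak,
            hessian=self.hessian,
        )

    def _prepare(self, volume: ImageVolume, brain_mask: ImageVolume) -> tuple[ImageVolume, float]:
        if self.reference_peak is not None:
            remapped = remap_intensity(volume, brain_mask, self.reference_peak)
            return remapped, float(remapped.meta["remap_scale"])
        return volume, 1.0

    def fit(self, naive_volumes: Sequence[ImageVolume],
            brain_masks: Sequence[ImageVolume]) -> "PVSSegmenter":
        if len(naive_volumes) == 0:
            raise ValueError("need at least one naive control volume to calibrate thresholds")
        if len(naive_volumes) != len(brain_masks):
            raise ValueError("one brain mask per naive volume is required")
        cfg = self._config()
        self.scale_factors_ = []
        per_region: dict[str, list[float]] = {}
        for vol, brain in zip(naive_volumes, brain_masks):
            prepared, scale = self._prepare(vol, brain)
            self.scale_factors_.append(scale)
            tub = compute_tubeness(prepared, cfg)
            regions = brain_regions(brain, cfg.surface_shell_voxels)
            thr = calibrate_threshold([tub], regions, cfg.interior_quantile)
            for name, val in thr.items():
                per_region.setdefault(name, []).append(val)
        self.thresholds_ = {name: float(np.mean(vals)) for name, vals in per_region.items()}
        self.n_naive_ = len(naive_volumes)
        return self

    def predict(self, volume: ImageVolume, brain_mask: ImageVolume,
                ventricle_mask: ImageVolume | None = None,
                exclusion_masks: Iterable[ImageVolume] = ()) -> ImageVolume:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("PVSSegmenter must be fitted on naive volumes before predict")
        cfg = self._config()
        prepared, _ = self._prepare(volume, brain_mask)
        tub = compute_tubeness(prepared, cfg)
        regions = brain_regions(brain_mask, cfg.surface_shell_voxels)
        return segment_pvs(tub, self.thresholds_, regions, brain_mask,
                           ventricle_mask, exclusion_masks)
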