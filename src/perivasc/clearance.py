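"""Minimum clearance distance (MCD) maps and parenchymal transport time scales.

How far is brain tissue from the nearest cerebrospinal-fluid (CSF) space?
Every parenchyma voxel gets the Euclidean distance L to the nearest CSF
voxel, where CSF is the ventricles plus everything outside the brain (a
subarachnoid-space proxy), optionally also the segmented perivascular
spaces.  Treating the PVS as CSF shrinks L dramatically, and with it the
clearance time scales

    tau_d = L^2 / D*      (purely diffusive, effective diffusivity D*)
    tau_a = L / u         (purely advective, interstitial speed u)

which scale quadratically and linearly in L respectively.  Two geometric
corrections quantify known biases of voxelized ex vivo data: the
voxel-vertex underestimate of in-plane clearance around a sub-voxel
vessel, and isotropic rescaling for fixation shrinkage.

Unit convention: distances are mm inside maps, um in the correction
arithmetic; diffusivities um^2/s; times returned in seconds with
formatting helpers for min/h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume

__all__ = [
    "ClearanceParams",
    "distance_to_csf",
    "mcd_stats",
    "diffusive_time",
    "advective_time",
    "peclet_velocity",
    "mcd_voxel_correction",
    "shrinkage_correction",
    "seconds_to",
    "format_time",
]

MM_TO_UM = 1000.0


@dataclass
class ClearanceParams:
    """Solute transport constants.

    D_star : effective diffusivity in parenchyma (um^2/s); hindered, so
        no greater than the free diffusivity D.
    u : interstitial velocity magnitude (um/s), used for the advective
        time scale.
    """

    D_star: float = 62.3  # amyloid-beta in parenchyma, um^2/s
    D: float | None = None  # free diffusivity, um^2/s
    u: float | None = None  # um/s

    def __post_init__(self) -> None:
        if not self.D_star > 0:
            raise ValueError("D_star must be positive")
        if self.D is not None and self.D < self.D_star:
            raise ValueError("effective diffusivity D_star cannot exceed free diffusivity D")


def distance_to_csf(brain_mask: ImageVolume, ventricle_mask: ImageVolume,
                    pvs_mask: ImageVolume | None = None) -> ImageVolume:
    """Euclidean distance transform from parenchyma to the nearest CSF voxel.

    CSF = ventricles | exterior of the brain | (PVS if given).  Distances
    are between voxel centers in physical mm (anisotropy-aware), so a
    voxel face-adjacent to CSF is one spacing away.  Voxels inside the
    CSF set itself get distance 0; the map is meaningful on
    brain & ~CSF (parenchyma).
    """
    brain_mask.check_geometry(ventricle_mask, "ventricle mask")
    csf = ~brain_mask.data.astype(bool) | ventricle_mask.data.astype(bool)
    with_pvs = pvs_mask is not None
    if with_pvs:
        brain_mask.check_geometry(pvs_mask, "PVS mask")
        csf = csf | pvs_mask.data.astype(bool)
    if not csf.any():
        raise ValueError("CSF compartment is empty; distance transform undefined")
    dist = ndimage.distance_transform_edt(~csf, sampling=brain_mask.spacing)
    return ImageVolume(dist, brain_mask.spacing, {"csf_includes_pvs": with_pvs})


def mcd_stats(dmap: ImageVolume, region_mask: ImageVolume,
              bins: int = 50, hist_range: tuple[float, float] | None = None) -> dict:
    """Mean/SD/max and a histogram of clearance distances over a region."""
    dmap.check_geometry(region_mask, "region mask")
    region = region_mask.data.astype(bool)
    if not region.any():
        raise ValueError("region mask is empty")
    vals = dmap.data[region]
    if hist_range is None:
        hist_range = (0.0, float(vals.max()) or 1.0)
    counts, edges = np.histogram(vals, bins=bins, range=hist_range)
    return {
        "mean_mm": float(vals.mean()),
        "sd_mm": float(vals.std()),
        "max_mm": float(vals.max()),
        "n_voxels": int(vals.size),
        "hist_counts": counts,
        "hist_edges_mm": edges,
    }


def diffusive_time(L_mm: float, D_star_um2_s: float) -> float:
    """tau_d = L^2 / D*, in seconds (L in mm, D* in um^2/s)."""
    if not D_star_um2_s > 0:
        raise ValueError("D_star must be positive")
    L = np.asarray(L_mm, dtype=float)
    if np.any(L < 0):
        raise ValueError("clearance distance must be >= 0")
    out = (L * MM_TO_UM) ** 2 / D_star_um2_s
    return float(out) if out.ndim == 0 else out


def advective_time(L_mm: float, u_um_s: float) -> float:
    """tau_a = L / u, in seconds (L in mm, u in um/s)."""
    if not u_um_s > 0:
        raise ValueError("interstitial velocity u must be positive")
    L = np.asarray(L_mm, dtype=float)
    if np.any(L < 0):
        raise ValueError("clearance distance must be >= 0")
    out = L * MM_TO_UM / u_um_s
    return float(out) if out.ndim == 0 else out


def peclet_velocity(L_mm: float, D_star_um2_s: float) -> float:
    """Interstitial speed (um/s) giving Pe = uL/D* = 1, i.e. equal
    advective and diffusive time scales over distance L."""
    if not L_mm > 0:
        raise ValueError("L must be positive")
    return D_star_um2_s / (L_mm * MM_TO_UM)


def mcd_voxel_correction(vessel_diameter_um: float, spacing_um: float = 40.0) -> float:
    """Worst-case in-plane MCD underestimate for a sub-voxel vessel, in um.

    A vessel thinner than the voxel can sit at the shared vertex of four
    in-plane voxels and enhance all four; the segmentation then puts the
    CSF boundary at those voxel centers.  The distance actually missing
    is center-to-vertex minus the vessel radius:

        sqrt(2) * spacing/2 - diameter/2

    clamped at zero once the vessel is wide enough to reach the centers.
    """
    if not spacing_um > 0:
        raise ValueError("spacing must be positive")
    if vessel_diameter_um < 0:
        raise ValueError("vessel diameter must be >= 0")
    if vessel_diameter_um >= 2 * spacing_um:
        raise ValueError("correction applies only to vessels thinner than two voxels")
    corr = np.sqrt(2.0) * spacing_um / 2.0 - vessel_diameter_um / 2.0
    if corr < 0:
        warnings.warn("vessel reaches beyond the voxel centers; correction clamped to 0")
        return 0.0
    return float(corr)


def shrinkage_correction(volume_shrinkage_fraction: float) -> dict[str, float]:
    """Undo isotropic fixation shrinkage on volumes, lengths and time scales.

    Fixation shrinks the tissue by a volume fraction f; restoring in vivo
    size multiplies volume by 1/(1-f).  Lengths grow by the cube root of
    that, and diffusive time scales (quadratic in length) by its square.
    Returns fractional increases (0.0381 = +3.81%).
    """
    f = float(volume_shrinkage_fraction)
    if not 0 <= f < 1:
        raise ValueError("shrinkage fraction must satisfy 0 <= f < 1")
    vol = 1.0 / (1.0 - f) - 1.0
    lin = (1.0 + vol) ** (1.0 / 3.0) - 1.0
    ts = (1.0 + lin) ** 2 - 1.0
    return {"volume_increase": vol, "linear_increase": lin, "timescale_increase": ts}


def seconds_to(t_s: float, unit: str) -> float:
    factors = {"s": 1.0, "min": 60.0, "h": 3600.0}
    return t_s / factors[unit]


def format_time(t_s: float) -> str:
    """Human-readable time with magnitude-appropriate unit."""
    if t_s < 120:
        return f"{t_s:.3g} s"
    if t_s < 7200:
        return f"{t_s / 60:.3g} min"
    return f"{t_s / 3600:.3g} h"
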