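"""From a two-channel confocal z-stack to axisymmetric drop profiles.

The protocol: locate the substrate plane as the z slice of maximum
xy-averaged reflected-light intensity; discard slices below it; smooth the
fluorescence channel with a small Gaussian; binarize by Otsu's threshold
computed once on the cropped volume; label 26-connected components; keep
those that touch the base plane and no other volume boundary.  Each kept
mask is reduced to an (r, z) profile by measuring, per z slice, the
equivalent-area disk radius of the hole-filled cross section, augmented by
the distance between that slice's center and the droplet's symmetry axis,
with the apex point (0, z_max) appended.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian as _gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as _label

from .shapes import Profile
from .synth_data import Stack3D

__all__ = ["CondensateMask", "find_base", "segment", "extract_profile",
           "export_masks_tiff"]

log = logging.getLogger(__name__)

#: Gaussian smoothing "radius" in voxels; sigma = radius / 2, kernel
#: truncated at 4 sigma.
SMOOTH_RADIUS = 2.0


@dataclass
class CondensateMask:
    """Boolean mask of one sessile condensate, cropped to z >= base.

    Local slice 0 is the base slice (the substrate plane z = 0 is its
    bottom face).
    """

    voxels: np.ndarray  # (nz, ny, nx) bool, cropped
    spacing: tuple[float, float, float]
    id: int

    @property
    def bounding_box(self):
        idx = np.nonzero(self.voxels)
        return tuple((int(a.min()), int(a.max())) for a in idx)

    @property
    def volume_um3(self) -> float:
        dx, dy, dz = self.spacing
        return float(self.voxels.sum()) * dx * dy * dz


def find_base(stack: Stack3D, channel: str = "reflection") -> int:
    """Substrate z index: argmax over z of the xy-mean intensity.

    Ties break toward the lowest z.  A flat profile (no distinct plane)
    logs a warning and returns index 0.
    """
    vol = stack.channel(channel)
    zprofile = vol.mean(axis=(1, 2))
    if np.ptp(zprofile) < 1e-12 * max(1.0, abs(float(zprofile[0]))):
        log.warning("reflection channel has no distinct plane; using z = 0")
        return 0
    return int(np.argmax(zprofile))


def segment(
    stack: Stack3D,
    base: int | None = None,
    channel: str = "fluorescence",
) -> list[CondensateMask]:
    """Segment sessile condensates from the fluorescence channel.

    Slices below ``base`` are discarded (the base slice itself is kept);
    the cropped volume is Gaussian smoothed and thresholded by Otsu once
    for the whole volume; 26-connected components that touch the base
    plane but no lateral or top boundary are returned, sorted by volume
    descending.
    """
    if base is None:
        base = find_base(stack)
    vol = stack.channel(channel)
    if not 0 <= base < vol.shape[0]:
        raise ValueError(f"base index {base} outside stack of {vol.shape[0]} slices")
    cropped = vol[base:]
    smoothed = _gaussian_filter(
        cropped, sigma=SMOOTH_RADIUS / 2.0, truncate=4.0, preserve_range=True
    )
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:  # constant image
        log.info("constant fluorescence volume; nothing to segment")
        return []
    binary = smoothed > thr
    if not binary.any():
        log.info("nothing above the Otsu threshold")
        return []

    labels = _label(binary, connectivity=3)
    masks: list[CondensateMask] = []
    nz, ny, nx = labels.shape
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        zs, ys, xs = np.nonzero(comp)
        touches_base = zs.min() == 0
        touches_other = (
            zs.max() == nz - 1
            or ys.min() == 0
            or ys.max() == ny - 1
            or xs.min() == 0
            or xs.max() == nx - 1
        )
        if touches_base and not touches_other:
            masks.append(CondensateMask(voxels=comp, spacing=stack.spacing, id=lab))
    masks.sort(key=lambda m: m.voxels.sum(), reverse=True)
    return masks


def extract_profile(mask: CondensateMask, spacing=None) -> Profile:
    """Reduce a condensate mask to an axisymmetric (r, z) profile.

    Per z slice: interior holes are filled; the radius is that of the
    equal-area disk, sqrt(A / pi), augmented by the planar distance
    between the slice's centroid and the droplet's symmetry axis (the
    whole-mask xy centroid) so it measures the mean distance from the
    optimal axis.  z is assigned at slice centers above the base; the
    apex point (0, z_max) is appended with z_max at the top face of the
    highest occupied slice.
    """
    if spacing is None:
        spacing = mask.spacing
    dx, dy, dz = spacing
    if abs(dx - dy) > 1e-9 * dx:
        raise ValueError("profile extraction requires isotropic xy spacing")

    vox = mask.voxels
    zs, ys, xs = np.nonzero(vox)
    axis_y = ys.mean()
    axis_x = xs.mean()

    rows: list[tuple[float, float]] = []
    top_slice = int(zs.max())
    for k in range(top_slice + 1):
        sl = vox[k]
        if not sl.any():
            log.info("empty slice %d inside the occupied z range; skipped", k)
            continue
        filled = ndimage.binary_fill_holes(sl)
        area = float(filled.sum())
        r_eq = math.sqrt(area / math.pi) * dx
        cy, cx = ndimage.center_of_mass(filled)
        offset = math.hypot((cy - axis_y) * dy, (cx - axis_x) * dx)
        rows.append((r_eq + offset, (k + 0.5) * dz))

    z_max = (top_slice + 1) * dz
    rows.append((0.0, z_max))
    prof = Profile(np.array(rows), source="extracted")
    prof.validate(min_points=2)
    return prof


def export_masks_tiff(masks: list[CondensateMask], path) -> None:
    """Write masks as one label image (uint16, 0 = background)."""
    import tifffile

    if not masks:
        raise ValueError("no masks to export")
    labels = np.zeros(masks[0].voxels.shape, dtype=np.uint16)
    for mask in masks:
        labels[mask.voxels] = mask.id
    dz = masks[0].spacing[2]
    tifffile.imwrite(path, labels, metadata={"axes": "ZYX", "spacing": dz})
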