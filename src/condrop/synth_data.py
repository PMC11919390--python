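"""Synthetic confocal stacks and cloud-point data.

Emulates the two kinds of raw data the analysis consumes:

* two-channel 3D z-stacks of sessile drops — a fluorescence channel with
  uniform interior intensity over background plus Poisson/Gaussian noise,
  and a reflected-light channel marking the substrate plane with a bright
  slice — with known voxel spacing and an optional axial stretch standing
  in for the refraction aberration of oil-immersion imaging of aqueous
  samples;
* cloud-point tables (phi, Tp) drawn from a Flory-Huggins binodal with
  Gaussian temperature noise.

Every generator is a pure function of its parameters and seed.

Conventions: stack axes are (z, y, x) with z index 0 at the bottom of the
recorded volume; voxel centers sit at (i + 0.5) * spacing in stack-local
coordinates, and physical height z = 0 (the substrate) is the bottom face of the slice at
``base_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .phase_diagram import CloudPoint, FHParams, chi_at_binodal
from .shapes import Profile

__all__ = [
    "Stack3D",
    "NoiseModel",
    "voxelize",
    "apply_axial_stretch",
    "add_noise",
    "gen_cloud_points",
    "save_stack",
    "load_stack",
]

DEFAULT_SPACING = (0.24, 0.24, 0.42)  # (dx, dy, dz) um, typical 63x/1.4 stack
DEFAULT_INTENSITIES = (100.0, 5.0, 1000.0)  # interior, background, reflection


@dataclass
class Stack3D:
    """A multi-channel 3D voxel image.

    ``voxels`` maps channel name -> (nz, ny, nx) float array;
    ``spacing`` is (dx, dy, dz) in um/voxel; ``base_index`` is the z index
    of the substrate plane (z = 0 at that slice's bottom face; voxel
    centers sit at (i + 0.5) * spacing).
    """

    voxels: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    base_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        shapes = {v.shape for v in self.voxels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def channels(self) -> list[str]:
        return list(self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.voxels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.voxels:
            raise KeyError(
                f"channel {name!r} not in stack; available: {self.channels}"
            )
        return self.voxels[name]


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise model: optional Poisson shot noise on intensities
    followed by additive Gaussian noise of scale gaussian_sigma, clipped
    at zero."""

    gaussian_sigma: float = 5.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


def voxelize(
    profile: Profile,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    intensities: tuple[float, float, float] = DEFAULT_INTENSITIES,
    pad: float = 3.0,
    center_xy: tuple[float, float] | None = None,
    base_pad_slices: int = 3,
) -> Stack3D:
    """Render a drop profile as a two-channel confocal stack.

    The fluorescence channel takes the ``inside`` intensity at every voxel
    whose center lies within the solid of revolution of the profile about
    the drop axis (at heights 0 <= z <= z_max) and ``background``
    elsewhere; the reflection channel is ``reflection_peak`` on the single
    base slice.  ``pad`` (um) of background is added laterally and above
    the apex; ``base_pad_slices`` below-substrate slices make the base
    detectable.  Membership is by voxel center, no antialiasing.
    """
    profile.validate(min_points=2)
    inside, background, reflection_peak = intensities
    dx, dy, dz = spacing
    if abs(dx - dy) > 1e-9:
        raise ValueError("lateral spacing must be isotropic (dx == dy)")

    r_max = float(np.max(profile.r))
    z_max = profile.z_max
    half_w = r_max + pad
    nx = int(np.ceil(2 * half_w / dx))
    ny = int(np.ceil(2 * half_w / dy))
    nz = base_pad_slices + int(np.ceil((z_max + pad) / dz)) + 1
    if nx < 4 or ny < 4 or nz < 4:
        raise ValueError("drop and padding give a degenerate grid")
    base_index = base_pad_slices

    cx = nx * dx / 2.0 if center_xy is None else center_xy[0]
    cy = ny * dy / 2.0 if center_xy is None else center_xy[1]

    # physical coordinates of voxel centers; the substrate plane is the
    # bottom face of the base slice, so its center sits at z = dz/2
    zs = (np.arange(nz) - base_index + 0.5) * dz
    xs = (np.arange(nx) + 0.5) * dx - cx
    ys = (np.arange(ny) + 0.5) * dy - cy
    rho = np.hypot(ys[:, None], xs[None, :])
    if xs.min() > -r_max or xs.max() < r_max or ys.min() > -r_max or ys.max() < r_max:
        raise ValueError("drop larger than the padded grid")

    # drop-surface radius at height z (single-valued for axisymmetric drops)
    r_of_z = np.interp(zs, profile.z, profile.r, left=0.0, right=0.0)
    r_of_z[(zs < 0) | (zs > z_max)] = 0.0

    fluo = np.full((nz, ny, nx), background, dtype=float)
    for k in range(nz):
        if r_of_z[k] > 0:
            fluo[k][rho <= r_of_z[k]] = inside

    refl = np.full((nz, ny, nx), background, dtype=float)
    refl[base_index] = reflection_peak

    return Stack3D(
        voxels={"fluorescence": fluo, "reflection": refl},
        spacing=spacing,
        base_index=base_index,
        meta={"z_max_um": z_max, "r_max_um": r_max},
    )


def apply_axial_stretch(obj: Profile | Stack3D, factor: float):
    """Stretch the axial (z) coordinate by ``factor``.

    For a Profile, z values are scaled directly.  For a Stack3D, each
    channel is resampled along z above the base plane by linear
    interpolation, so that a feature at height z moves to factor * z;
    slices at and below the base are untouched.  Lateral coordinates are
    never changed.  factor 1.2 emulates the apparent axial elongation of
    oil-immersion confocal images of aqueous samples; its inverse 1/1.2
    is the correction.
    """
    if factor <= 0:
        raise ValueError("stretch factor must be positive")
    if isinstance(obj, Profile):
        return obj.with_z_scaled(factor)
    if not isinstance(obj, Stack3D):
        raise TypeError("expected Profile or Stack3D")

    nz = obj.shape[0]
    b = obj.base_index
    k = np.arange(nz)
    # sample the stretched image at slice k from original height z/factor,
    # with heights measured from the base slice's bottom face
    src = np.where(k > b, b - 0.5 + (k - b + 0.5) / factor, k).astype(float)
    voxels = {}
    for name, vol in obj.voxels.items():
        lo = np.clip(np.floor(src).astype(int), 0, nz - 1)
        hi = np.clip(lo + 1, 0, nz - 1)
        w = src - lo
        voxels[name] = (1 - w)[:, None, None] * vol[lo] + w[:, None, None] * vol[hi]
    meta = dict(obj.meta)
    meta["axial_stretch"] = meta.get("axial_stretch", 1.0) * factor
    return Stack3D(voxels=voxels, spacing=obj.spacing, base_index=b, meta=meta)


def add_noise(stack: Stack3D, model: NoiseModel) -> Stack3D:
    """Apply the detection-noise model, reproducibly by its seed."""
    rng = np.random.default_rng(model.seed)
    voxels = {}
    for name, vol in stack.voxels.items():
        out = rng.poisson(np.clip(vol, 0, None)).astype(float) if model.poisson else vol.astype(float)
        if model.gaussian_sigma > 0:
            out = out + rng.normal(0.0, model.gaussian_sigma, vol.shape)
        voxels[name] = np.clip(out, 0.0, None)
    return Stack3D(voxels=voxels, spacing=stack.spacing,
                   base_index=stack.base_index, meta=dict(stack.meta))


def gen_cloud_points(
    fh: FHParams,
    phis,
    sigma_T: float = 0.5,
    seed: int = 0,
) -> list[CloudPoint]:
    """Cloud points drawn from the model binodal with Gaussian T noise.

    For each requested phi the transition temperature is the temperature
    at which phi sits on the coexistence curve, Tp = B / (chi*(phi) - A).
    Compositions with no positive transition temperature are returned
    flagged (Tp = nan placeholder is not used; the model Tc bound applies)
    rather than silently dropped.
    """
    rng = np.random.default_rng(seed)
    out: list[CloudPoint] = []
    for phi in phis:
        eps = rng.normal()  # one draw per point keeps the stream aligned
        try:
            chi_star = chi_at_binodal(float(phi), fh.n_chain)
        except ValueError:
            chi_star = None
        if chi_star is None or chi_star <= fh.A or fh.B <= 0:
            # never on the binodal at any positive temperature
            out.append(CloudPoint(phi=float(phi), Tp=1e-6, flagged=True))
            continue
        Tp = fh.B / (chi_star - fh.A) + sigma_T * eps
        out.append(CloudPoint(phi=float(phi), Tp=float(Tp)))
    return out


# ---------------------------------------------------------------------------
# TIFF + JSON-sidecar persistence

def save_stack(stack: Stack3D, path: str | Path) -> Path:
    """Write a multi-channel TIFF (axes CZYX) plus a JSON sidecar holding
    channels, spacing, base index and any ground-truth metadata."""
    path = Path(path)
    data = np.stack([stack.voxels[c] for c in stack.channels]).astype(np.float32)
    dx, dy, dz = stack.spacing
    tifffile.imwrite(
        path,
        data,
        metadata={"axes": "CZYX", "spacing": dz},
        resolution=(1.0 / dx, 1.0 / dy),
    )
    sidecar = {
        "channels": stack.channels,
        "spacing_um": list(stack.spacing),
        "base_index": stack.base_index,
        "meta": stack.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_stack(path: str | Path) -> Stack3D:
    """Read a stack written by :func:`save_stack`."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if data.ndim == 3:
        data = data[None]
    voxels = {c: data[i] for i, c in enumerate(sidecar["channels"])}
    return Stack3D(
        voxels=voxels,
        spacing=tuple(sidecar["spacing_um"]),
        base_index=int(sidecar["base_index"]),
        meta=sidecar.get("meta", {}),
    )
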