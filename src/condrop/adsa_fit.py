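"""Young-Laplace fitting of drop profiles (axisymmetric drop-shape analysis).

An extracted profile (R_i, Z_i) is matched to the family of theoretical
sessile-drop surfaces parameterized by apex curvature radius R0, capillary
length lc and vertical translation z0.  For trial parameters the surface is
integrated to a fixed arc length smax, sampled at 1000 points evenly spaced
in arc length, and scored by the mean squared distance from each measured
point to its nearest trial point,

    lambda(R0, lc, z0, smax) = (1/N) sum_i [(R_i - r_i)^2 + (Z_i - z_i)^2].

smax is held at 1.2x the smoothed contour length of the measured profile
while lambda is minimized over (R0, lc, z0) by Nelder-Mead.  After
convergence the theoretical profile is re-integrated until it crosses the
substrate plane z = 0, smax is redefined at the crossing, and the contact
angle is the surface inclination there, theta = |psi(smax)|.  Fits with
lambda * N / smax > 0.5 um are poor and flagged for discard, as are drops
with contact radius below 10 um, whose apparent shape is dominated by the
point-spread function.

Before fitting, profiles from oil-immersion confocal stacks of aqueous
samples are corrected for the refraction focal shift by scaling z by 1/1.2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .shapes import IntegrationFailure, Profile, YLParams, integrate_arc, _N_STEPS

__all__ = [
    "FitConfig",
    "FitResult",
    "GeometryError",
    "rescale_profile",
    "estimate_smax",
    "objective",
    "fit_profile",
    "quality_filter",
]

log = logging.getLogger(__name__)

AXIAL_RESCALE = 1.0 / 1.2  # refraction correction for oil-into-water imaging
QUALITY_THRESHOLD_UM = 0.5
MIN_CONTACT_RADIUS_UM = 10.0
N_TRIAL_POINTS = 1000


class GeometryError(RuntimeError):
    """The theoretical profile never reaches the substrate plane."""


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the fitting procedure."""

    n_trial_points: int = N_TRIAL_POINTS
    lc_init: float = 100.0  # um
    quality_threshold: float = QUALITY_THRESHOLD_UM  # um
    min_contact_radius: float = MIN_CONTACT_RADIUS_UM  # um
    max_iter: int = 2000


@dataclass
class FitResult:
    """Outcome of one profile fit."""

    theta_deg: float
    params: YLParams | None
    lambda_um2: float
    contact_radius_um: float
    quality_um: float
    accepted: bool
    n_points: int
    reason: str = ""
    nfev: int = 0

    def as_row(self) -> dict:
        p = self.params
        return {
            "theta_deg": self.theta_deg,
            "R0_um": p.R0 if p else math.nan,
            "lc_um": p.lc if p else math.nan,
            "z0_um": p.z0 if p else math.nan,
            "smax_um": p.smax if p else math.nan,
            "lambda_um2": self.lambda_um2,
            "contact_radius_um": self.contact_radius_um,
            "quality_um": self.quality_um,
            "accepted": self.accepted,
            "reason": self.reason,
        }


def rescale_profile(profile: Profile, factor: float = AXIAL_RESCALE) -> Profile:
    """Scale the z coordinates by ``factor`` (radii untouched).

    With the default 1/1.2 this undoes the apparent axial elongation of
    aqueous samples imaged through an oil-immersion objective.
    """
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    return profile.with_z_scaled(factor)


def _smoothed_radii(r: np.ndarray, half: int = 3) -> np.ndarray:
    """Centered moving average of width 2*half+1, clipped at the ends."""
    n = len(r)
    csum = np.concatenate([[0.0], np.cumsum(r)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def estimate_smax(profile: Profile) -> float:
    """Arc-length budget: 1.2x the smoothed contour length.

    Radii are smoothed with a centered 7-point moving average and the
    polyline length is accumulated over segments i = 4 .. N-1 (1-based),
    then multiplied by 1.2 so the trial arc comfortably overshoots the
    measured contour.
    """
    if profile.n < 8:
        raise ValueError(f"need >= 8 profile points for smax, got {profile.n}")
    rbar = _smoothed_radii(profile.r)
    z = profile.z
    i = np.arange(3, profile.n - 1)  # 1-based 4 .. N-1
    seg = np.hypot(rbar[i + 1] - rbar[i], z[i + 1] - z[i])
    return 1.2 * float(seg.sum())


def _trial_points(params: YLParams, z_ref: float, n: int) -> np.ndarray:
    """Theoretical (r, z) trial points; apex placed at z_ref + z0."""
    s = np.linspace(0.0, params.smax, n)
    _, r, u = integrate_arc(params, s)
    z = u + z_ref + params.z0
    return np.column_stack([r, z])


def objective(
    params: YLParams,
    profile: Profile,
    config: FitConfig = FitConfig(),
    _z_ref: float | None = None,
) -> float:
    """Mean squared nearest-point distance lambda (um^2).

    The theoretical profile is sampled at ``config.n_trial_points`` points
    evenly spaced in arc length on [0, smax]; each measured point is
    scored against its nearest trial point (exact nearest-neighbour via a
    k-d tree).
    """
    z_ref = profile.z_max if _z_ref is None else _z_ref
    trial = _trial_points(params, z_ref, config.n_trial_points)
    d, _ = cKDTree(trial).query(profile.points, k=1)
    return float(np.mean(d**2))


def _circle_fit_R0(profile: Profile) -> float:
    """Apex curvature initializer: axis-centered circle fit to the upper
    half of the profile (points mirrored across the axis keep the center
    on it).  r^2 + (z - b)^2 = R^2 is linear in (b, R^2 - b^2)."""
    z = profile.z
    r = profile.r
    sel = z >= 0.5 * (z.min() + z.max())
    if sel.sum() < 3:
        sel = np.ones_like(z, dtype=bool)
    rs, zs = r[sel], z[sel]
    A = np.column_stack([2 * zs, np.ones_like(zs)])
    y = zs**2 + rs**2
    try:
        (b, c), *_ = np.linalg.lstsq(A, y, rcond=None)
        R0 = math.sqrt(max(c + b * b, 1e-12))
    except np.linalg.LinAlgError:
        R0 = float(z.max())
    if not np.isfinite(R0) or R0 <= 0:
        R0 = max(float(z.max()), 1e-3)
    return R0


def _terminal_state(params: YLParams, z_ref: float):
    """Integrate until the theoretical profile crosses z = 0, i.e. depth
    below the apex equals z_ref + z0.  Returns (s*, psi*, r*)."""
    target = z_ref + params.z0
    if target <= 0:
        raise GeometryError("apex at or below the substrate; no crossing")
    span = 3.0 * params.smax
    s = np.linspace(0.0, span, 3 * _N_STEPS + 1)
    psi, r, u = integrate_arc(params, s, _partial=True)
    depth = -u
    crossed = np.nonzero(depth >= target)[0]
    if len(crossed) == 0:
        raise GeometryError(
            f"profile never reaches z = 0 within 3 x smax = {span:.3g} um"
        )
    idx = int(crossed[0])
    if idx == 0:
        raise GeometryError("profile starts below the substrate")
    w = (target - depth[idx - 1]) / (depth[idx] - depth[idx - 1])
    s_star = s[idx - 1] + w * (s[idx] - s[idx - 1])
    psi_star = psi[idx - 1] + w * (psi[idx] - psi[idx - 1])
    r_star = r[idx - 1] + w * (r[idx] - r[idx - 1])
    return float(s_star), float(psi_star), float(r_star)


def _run_once(
    profile: Profile,
    R0_init: float,
    smax: float,
    config: FitConfig,
) -> tuple[np.ndarray, float, int]:
    """One Nelder-Mead descent over (R0, ln lc, z0); returns (x, lambda, nfev)."""
    z_ref = profile.z_max

    def cost(x):
        R0, log_lc, z0 = x
        if R0 <= 0 or abs(log_lc) > 50:
            return 1e12
        try:
            p = YLParams(R0=R0, lc=math.exp(log_lc), z0=z0, smax=smax)
            return objective(p, profile, config, _z_ref=z_ref)
        except IntegrationFailure:
            return 1e12

    x0 = np.array([R0_init, math.log(config.lc_init), 0.0])
    res = minimize(
        cost,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1e-8,
            "fatol": 1e-12,
            "maxiter": config.max_iter,
            "maxfev": 4 * config.max_iter,
        },
    )
    return res.x, float(res.fun), int(res.nfev)


def fit_profile(profile: Profile, config: FitConfig = FitConfig()) -> FitResult:
    """Fit the Young-Laplace family to a (rescaled) profile.

    Initializes R0 from an axis-centered circle fit to the upper half of
    the profile, lc at 100 um and z0 at 0; minimizes lambda by
    Nelder-Mead with smax fixed at the contour-length estimate; then
    redefines smax where the optimal profile crosses z = 0 and reads off
    theta = |psi(smax)|, the contact radius r(smax) and the quality
    metric lambda * N / smax.  If the quality gate fails the descent is
    restarted from 0.5x and 2x the initial R0 and the best result kept.
    """
    profile.validate(min_points=8)
    smax = estimate_smax(profile)
    R0_init = _circle_fit_R0(profile)

    best: tuple[np.ndarray, float, int] | None = None
    tried = []
    for scale in (1.0, 0.5, 2.0):
        x, lam, nfev = _run_once(profile, scale * R0_init, smax, config)
        tried.append((x, lam, nfev))
        if best is None or lam < best[1]:
            best = (x, lam, nfev)
        # provisional quality with the optimization-time smax
        if best[1] * profile.n / smax <= config.quality_threshold:
            break
    x, lam_opt, nfev = best
    nfev_total = sum(t[2] for t in tried)

    R0, log_lc, z0 = x
    if R0 <= 0 or not np.isfinite(lam_opt) or lam_opt >= 1e12:
        return FitResult(
            theta_deg=math.nan, params=None, lambda_um2=math.inf,
            contact_radius_um=math.nan, quality_um=math.inf, accepted=False,
            n_points=profile.n, reason="optimizer failed to converge",
            nfev=nfev_total,
        )
    params = YLParams(R0=float(R0), lc=float(math.exp(log_lc)), z0=float(z0), smax=smax)

    # redefine smax where the theoretical profile meets the substrate
    s_star, psi_star, r_star = _terminal_state(params, profile.z_max)
    final = YLParams(R0=params.R0, lc=params.lc, z0=params.z0, smax=s_star)
    lam = objective(final, profile, config, _z_ref=profile.z_max)
    theta = abs(math.degrees(psi_star))
    quality = lam * profile.n / s_star

    reasons = []
    if quality > config.quality_threshold:
        reasons.append(
            f"poor fit: lambda*N/smax = {quality:.3g} um > {config.quality_threshold} um"
        )
    if r_star < config.min_contact_radius:
        reasons.append(
            f"contact radius {r_star:.3g} um < {config.min_contact_radius} um"
        )
    return FitResult(
        theta_deg=theta,
        params=final,
        lambda_um2=lam,
        contact_radius_um=r_star,
        quality_um=quality,
        accepted=not reasons,
        n_points=profile.n,
        reason="; ".join(reasons),
        nfev=nfev_total,
    )


def quality_filter(results: list[FitResult], config: FitConfig = FitConfig()):
    """Partition fits into (kept, discarded) by the two acceptance rules:
    quality <= 0.5 um and contact radius >= 10 um.  Discard reasons are
    recorded on each result."""
    kept, discarded = [], []
    for res in results:
        reasons = []
        if not np.isfinite(res.quality_um) or res.quality_um > config.quality_threshold:
            reasons.append("quality")
        if not (res.contact_radius_um >= config.min_contact_radius):
            reasons.append("contact_radius")
        if reasons:
            res.accepted = False
            extra = f"discarded: {', '.join(reasons)}"
            res.reason = f"{res.reason}; {extra}" if res.reason else extra
            discarded.append(res)
        else:
            res.accepted = True
            kept.append(res)
    return kept, discarded
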