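"""Geometry of axisymmetric sessile drops.

The surface of a sessile drop with full rotational symmetry is governed by
the Young-Laplace balance between Laplace and hydrostatic pressure.  In the
Bashforth-Adams arc-length parameterization the surface inclination psi
evolves along the arc length s (measured from the apex) as

    dpsi/ds = 2/R0 + h/lc**2 - sin(psi)/r,

where h is the depth below the apex, r the radial coordinate, R0 the apex
radius of curvature, and lc the capillary length sqrt(gamma / (drho * g)).
With dr/ds = cos(psi) and dh/ds = sin(psi) this closes into a first-order
system that is integrated numerically from the apex, where the
sin(psi)/r term has the regular limit 1/R0.

Angles are degrees at all public boundaries and radians internally.
Lengths are micrometres throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ArcState",
    "YLParams",
    "Profile",
    "SphericalCap",
    "IntegrationFailure",
    "integrate_arc",
    "integrate_profile",
    "cap_profile",
]

#: arc fraction near the apex handled by the series expansion
_APEX_SERIES_FRACTION = 1e-3


class IntegrationFailure(RuntimeError):
    """Raised when the Young-Laplace integration leaves its physical domain."""


@dataclass(frozen=True)
class ArcState:
    """State of the drop surface at one arc position.

    Attributes
    ----------
    s : float
        Arc length from the apex (um), >= 0.
    psi_deg : float
        Surface inclination from the horizontal (degrees); 0 at the apex.
    r : float
        Radial coordinate (um), >= 0.
    u : float
        Signed vertical coordinate relative to the apex (um); 0 at the
        apex and negative below it, so -u is the depth below the apex.
    """

    s: float
    psi_deg: float
    r: float
    u: float

    def __post_init__(self) -> None:
        if self.s < 0 or self.r < 0:
            raise ValueError("arc state requires s >= 0 and r >= 0")


@dataclass(frozen=True)
class YLParams:
    """Parameters of a theoretical Young-Laplace profile.

    R0 is the apex radius of curvature (um), lc the capillary length (um),
    z0 a vertical translation applied when placing the theoretical profile
    in the lab frame, and smax the arc length to integrate to (um).
    """

    R0: float
    lc: float
    z0: float
    smax: float

    def __post_init__(self) -> None:
        if not (self.R0 > 0 and self.lc > 0 and self.smax > 0):
            raise ValueError("YLParams requires R0 > 0, lc > 0, smax > 0")


@dataclass
class Profile:
    """Ordered (r, z) coordinates of an axisymmetric drop surface.

    Points are in um, ordered by ascending z, with the apex point
    (0, z_max) last.  ``source`` tags where the profile came from
    (``synthetic`` or ``extracted``).
    """

    points: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("Profile.points must be an (N, 2) array")

    @property
    def r(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def z_max(self) -> float:
        return float(self.points[-1, 1])

    def validate(self, min_points: int = 8) -> None:
        """Check the ordering/positivity invariants, raising ValueError."""
        if self.n < min_points:
            raise ValueError(f"profile has {self.n} points, needs >= {min_points}")
        if np.any(self.r < 0):
            raise ValueError("profile radii must be non-negative")
        if np.any(np.diff(self.z) < 0):
            raise ValueError("profile must be ordered by ascending z")
        if abs(self.points[-1, 0]) > 1e-9:
            raise ValueError("profile must end with the apex point (0, z_max)")

    def with_z_scaled(self, factor: float) -> "Profile":
        pts = self.points.copy()
        pts[:, 1] *= factor
        return Profile(pts, source=self.source)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            self.points,
            delimiter=",",
            header="r_um,z_um",
            comments="",
            fmt="%.9g",
        )

    @classmethod
    def from_csv(cls, path, source: str = "extracted") -> "Profile":
        pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(pts, source=source)


@dataclass(frozen=True)
class SphericalCap:
    """A spherical cap: zero-gravity sessile drop of given contact angle.

    theta_deg is the contact angle in degrees (0 < theta < 180),
    r_contact the contact-line radius (um).  The sphere radius is
    R = r_contact / sin(theta) and the cap height R * (1 - cos(theta)).
    """

    theta_deg: float
    r_contact: float
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_deg < 180.0:
            raise ValueError("contact angle must lie strictly in (0, 180) degrees")
        if self.r_contact <= 0:
            raise ValueError("contact radius must be positive")

    @property
    def sphere_radius(self) -> float:
        return self.r_contact / math.sin(math.radians(self.theta_deg))

    @property
    def center_z(self) -> float:
        # sphere-center height above the substrate; negative for theta < 90
        return -self.sphere_radius * math.cos(math.radians(self.theta_deg))

    @property
    def height(self) -> float:
        return self.sphere_radius + self.center_z

    @property
    def max_radius(self) -> float:
        """Largest radius of the cap (equals sphere radius when theta > 90)."""
        if self.theta_deg <= 90.0:
            return self.r_contact
        return self.sphere_radius


def _apex_series(s: float, R0: float) -> tuple[float, float, float]:
    # circular-arc expansion about the apex; gravity enters only at O(s^3)
    x = s / R0
    return (x, R0 * math.sin(x), -R0 * (1.0 - math.cos(x)))


@numba.njit(cache=True)
def _rk4_core(R0, lc, s_eval, h_max, psi_out, r_out, u_out):  # pragma: no cover
    """Fixed-step classical RK4 over the Young-Laplace system, sampled at
    the nodes of s_eval.  Returns the number of nodes filled before the
    state left its physical domain (psi > pi or r < 0)."""
    inv_lc2 = 1.0 / (lc * lc)
    two_over_R0 = 2.0 / R0
    tiny_r = 1e-12 * R0
    s0 = 1e-3 * R0
    pi_guard = math.pi + 1e-9

    n = s_eval.shape[0]
    i = 0
    # series region
    while i < n and s_eval[i] <= s0:
        x = s_eval[i] / R0
        psi_out[i] = x
        r_out[i] = R0 * math.sin(x)
        u_out[i] = -R0 * (1.0 - math.cos(x))
        i += 1
    # state at the series boundary
    s = s0
    psi = s0 / R0
    r = R0 * math.sin(psi)
    u = -R0 * (1.0 - math.cos(psi))
    for j in range(i, n):
        target = s_eval[j]
        span = target - s
        if span > 0.0:
            m = int(math.ceil(span / h_max))
            h = span / m
            for _ in range(m):
                # k1
                sinp = math.sin(psi)
                c1 = sinp / r if r > tiny_r else 1.0 / R0
                k1p = two_over_R0 - u * inv_lc2 - c1
                k1r = math.cos(psi)
                k1u = -sinp
                # k2
                p2 = psi + 0.5 * h * k1p
                r2 = r + 0.5 * h * k1r
                u2 = u + 0.5 * h * k1u
                sinp = math.sin(p2)
                c2 = sinp / r2 if r2 > tiny_r else 1.0 / R0
                k2p = two_over_R0 - u2 * inv_lc2 - c2
                k2r = math.cos(p2)
                k2u = -sinp
                # k3
                p3 = psi + 0.5 * h * k2p
                r3 = r + 0.5 * h * k2r
                u3 = u + 0.5 * h * k2u
                sinp = math.sin(p3)
                c3 = sinp / r3 if r3 > tiny_r else 1.0 / R0
                k3p = two_over_R0 - u3 * inv_lc2 - c3
                k3r = math.cos(p3)
                k3u = -sinp
                # k4
                p4 = psi + h * k3p
                r4 = r + h * k3r
                u4 = u + h * k3u
                sinp = math.sin(p4)
                c4 = sinp / r4 if r4 > tiny_r else 1.0 / R0
                k4p = two_over_R0 - u4 * inv_lc2 - c4
                k4r = math.cos(p4)
                k4u = -sinp

                psi += h * (k1p + 2.0 * k2p + 2.0 * k3p + k4p) / 6.0
                r += h * (k1r + 2.0 * k2r + 2.0 * k3r + k4r) / 6.0
                u += h * (k1u + 2.0 * k2u + 2.0 * k3u + k4u) / 6.0
                s += h
                if psi > pi_guard or r < -1e-9:
                    return j
        psi_out[j] = psi
        r_out[j] = r
        u_out[j] = u
    return n


#: steps per arc length used by the fixed-step integrator
_N_STEPS = 2000


def integrate_arc(
    params: YLParams,
    s_eval: np.ndarray,
    *,
    max_step: float | None = None,
    _partial: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the Young-Laplace system, returning (psi, r, u) at s_eval.

    Apex-origin convention: psi(0) = 0, r(0) = 0, u(0) = 0 and u decreases
    along the arc (the profile descends from the apex).  A short series
    expansion covers s < 1e-3 * R0 (where sin(psi)/r is 0/0); the rest is
    integrated with classical fixed-step RK4 at step <= smax/2000 (or
    ``max_step`` if smaller).

    With ``_partial`` the arrays are returned truncated at the point where
    the state leaves its physical domain instead of raising.
    """
    s_eval = np.ascontiguousarray(s_eval, dtype=float)
    smax = float(s_eval[-1])
    h = smax / _N_STEPS
    if max_step is not None:
        h = min(h, float(max_step))
    psi = np.empty_like(s_eval)
    r = np.empty_like(s_eval)
    u = np.empty_like(s_eval)
    filled = _rk4_core(params.R0, params.lc, s_eval, h, psi, r, u)
    if filled < len(s_eval):
        if _partial:
            return psi[:filled], r[:filled], u[:filled]
        raise IntegrationFailure(
            f"unphysical state (psi > 180 deg or r < 0) near s = "
            f"{s_eval[filled]:.6g} um"
        )
    return psi, r, u


def integrate_profile(
    params: YLParams,
    n_points: int = 1000,
    **integrate_kwargs,
) -> tuple[Profile, float]:
    """Generate a theoretical sessile-drop profile.

    Returns ``n_points`` surface points evenly spaced in arc length on
    [0, smax], expressed in the lab frame with the arc endpoint at z = 0
    plus the translation ``params.z0`` (so the apex sits at
    -u(smax) + z0).  The second return value is the magnitude of the
    endpoint inclination psi(smax) in degrees: the contact angle when the
    endpoint lies on the substrate.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    s_eval = np.linspace(0.0, params.smax, n_points)
    psi, r, u = integrate_arc(params, s_eval, **integrate_kwargs)
    z = u - u[-1] + params.z0
    # reverse so z ascends and the apex point (r = 0) comes last
    pts = np.column_stack([r[::-1], z[::-1]])
    pts[-1, 0] = 0.0
    return Profile(pts, source="synthetic"), abs(math.degrees(psi[-1]))


def _contact_state(R0: float, lc: float, theta_deg: float, s_hi_factor: float = 12.0):
    """Integrate until psi reaches theta; return (s, r, depth) there."""
    theta = math.radians(theta_deg)
    params = YLParams(R0=R0, lc=lc, z0=0.0, smax=s_hi_factor * R0)
    s = np.linspace(0.0, params.smax, 4 * _N_STEPS + 1)
    psi, r, u = integrate_arc(params, s, _partial=True)
    crossed = np.nonzero(psi >= theta)[0]  # first crossing (psi need not be monotone)
    idx = int(crossed[0]) if len(crossed) else 0
    if idx == 0:
        raise IntegrationFailure(
            f"inclination never reaches {theta_deg} deg for R0={R0:.4g}, lc={lc:.4g}"
        )
    w = (theta - psi[idx - 1]) / (psi[idx] - psi[idx - 1])
    s_star = s[idx - 1] + w * (s[idx] - s[idx - 1])
    r_star = r[idx - 1] + w * (r[idx] - r[idx - 1])
    u_star = u[idx - 1] + w * (u[idx] - u[idx - 1])
    return float(s_star), float(r_star), float(-u_star)


def profile_for_contact(
    theta_deg: float,
    r_contact: float,
    lc: float,
    n_points: int = 150,
) -> tuple[Profile, YLParams]:
    """Ground-truth Young-Laplace profile with prescribed contact angle
    and contact radius.

    Finds the apex curvature radius R0 whose profile reaches inclination
    theta at radial coordinate r_contact (bisection on R0, which scales
    the whole drop), then samples it.  Returns the profile (apex point
    last, contact line at z = 0) and the generating parameters.
    """
    if not 0.0 < theta_deg < 180.0:
        raise ValueError("contact angle must lie in (0, 180) degrees")
    from scipy.optimize import brentq

    def gap(R0: float) -> float:
        return _contact_state(R0, lc, theta_deg)[1] - r_contact

    # zero-gravity solution brackets the root: R0 ~ r_contact / sin(theta)
    guess = r_contact / math.sin(math.radians(theta_deg))
    lo, hi = 0.2 * guess, 5.0 * guess
    R0 = brentq(gap, lo, hi, xtol=1e-10 * guess)
    smax, r_end, _depth = _contact_state(R0, lc, theta_deg)
    params = YLParams(R0=R0, lc=lc, z0=0.0, smax=smax)
    profile, _ = integrate_profile(params, n_points)
    return profile, params


def cap_profile(cap: SphericalCap, n_points: int = 200) -> Profile:
    """Exact analytic profile of a spherical cap, apex point last.

    Points are sampled uniformly in polar angle from the contact line
    (angle theta from the upward vertical through the sphere center) to
    the apex (angle 0).
    """
    theta = math.radians(cap.theta_deg)
    R = cap.sphere_radius
    zc = cap.center_z
    phi = np.linspace(theta, 0.0, n_points)
    pts = np.column_stack([R * np.sin(phi), zc + R * np.cos(phi)])
    pts[0, 1] = max(pts[0, 1], 0.0)  # clamp contact point to the substrate
    pts[-1, 0] = 0.0
    return Profile(pts, source="synthetic")
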