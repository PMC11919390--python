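"""Flory-Huggins phase diagrams for protein cloud-point data.

A solution of a polymer of effective chain length n (lattice sites) at
volume fraction phi has the Flory-Huggins free energy per site

    f(phi) = (phi/n) ln(phi) + (1 - phi) ln(1 - phi) + chi * phi * (1 - phi)

in units of kT.  For an upper-critical-solution-temperature (UCST) system
the interaction parameter decreases with temperature; the minimal form used
here is chi(T) = A + B/T with B > 0 in kelvin.  Coexisting compositions at
a given chi satisfy the common-tangent conditions: equal exchange chemical
potential f'(phi_1) = f'(phi_2) and equal osmotic pressure
f(phi_1) - phi_1 f'(phi_1) = f(phi_2) - phi_2 f'(phi_2).

The critical point is at phi_c = 1/(1 + sqrt(n)),
chi_c = (1 + 1/sqrt(n))^2 / 2; for chi <= chi_c the mixture is one-phase.

Cloud points (phi, Tp) are treated as binodal crossings: Tp is the
temperature at which composition phi sits on the coexistence curve.  The
degree of phase separation Delta-phi = phi_dense - phi_dilute at a
reference temperature measures how strongly the protein partitions;
1 - Delta-phi approximates the condensate water content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "CloudPoint",
    "FHParams",
    "Binodal",
    "DeltaPhi",
    "OnePhaseError",
    "binodal_at_chi",
    "binodal_at_T",
    "chi_at_binodal",
    "fit_cloud_points",
    "compute_binodal",
    "delta_phi",
]

_EPS = 1e-12


class OnePhaseError(ValueError):
    """Raised when coexistence is requested in the one-phase region."""


@dataclass(frozen=True)
class CloudPoint:
    """One cloud-point observation: volume fraction phi at transition
    temperature Tp (kelvin)."""

    phi: float
    Tp: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if self.Tp <= 0:
            raise ValueError("Tp must be positive (kelvin)")


@dataclass(frozen=True)
class FHParams:
    """Flory-Huggins model parameters: chain length n_chain (sites),
    entropic chi coefficient A (dimensionless) and enthalpic coefficient
    B (kelvin); chi(T) = A + B/T."""

    n_chain: float
    A: float
    B: float

    def __post_init__(self) -> None:
        if self.n_chain < 1:
            raise ValueError("n_chain must be >= 1")

    def chi(self, T: float) -> float:
        return self.A + self.B / T

    @property
    def chi_c(self) -> float:
        return 0.5 * (1.0 + 1.0 / math.sqrt(self.n_chain)) ** 2

    @property
    def phi_c(self) -> float:
        return 1.0 / (1.0 + math.sqrt(self.n_chain))

    @property
    def T_c(self) -> float:
        """Critical temperature (K); inf if chi never reaches chi_c."""
        if self.B <= 0 or self.chi_c <= self.A:
            return math.inf
        return self.B / (self.chi_c - self.A)


@dataclass
class Binodal:
    """Coexistence curve sampled on a temperature grid (K)."""

    T: np.ndarray
    phi_dilute: np.ndarray
    phi_dense: np.ndarray


@dataclass(frozen=True)
class DeltaPhi:
    """Degree of phase separation at a reference temperature."""

    value: float
    T_ref: float
    one_phase: bool = False


def _f(phi: np.ndarray, n: float, chi: float) -> np.ndarray:
    return (phi / n) * np.log(phi) + (1 - phi) * np.log(1 - phi) + chi * phi * (1 - phi)


def _fp(phi, n: float, chi: float):
    """df/dphi (exchange chemical potential)."""
    return (np.log(phi) + 1.0) / n - np.log(1 - phi) - 1.0 + chi * (1.0 - 2.0 * phi)


def _grand(phi, n: float, chi: float):
    """f - phi f' (negative osmotic pressure of the solvent)."""
    return _f(phi, n, chi) - phi * _fp(phi, n, chi)


def _spinodal(n: float, chi: float) -> tuple[float, float]:
    """Roots of f''(phi) = 0, i.e. 1/(n phi) + 1/(1-phi) = 2 chi."""
    a = 2.0 * chi * n
    b = n - 1.0 - 2.0 * chi * n
    c = 1.0
    disc = b * b - 4.0 * a * c
    if disc <= 0:
        raise OnePhaseError(f"no spinodal at chi = {chi:.6g} (n = {n:g})")
    root = math.sqrt(disc)
    lo = (-b - root) / (2.0 * a)
    hi = (-b + root) / (2.0 * a)
    return min(lo, hi), max(lo, hi)


def binodal_at_chi(n: float, chi: float, tol: float = 1e-12) -> tuple[float, float]:
    """Coexisting volume fractions (phi_dilute, phi_dense) at given chi.

    Solves the two common-tangent conditions by nested bracketing: for a
    trial dilute composition phi1 below the spinodal, the dense partner
    phi2 with equal exchange chemical potential is found on the dense side
    of the spinodal, and phi1 is adjusted until the osmotic condition also
    holds.  Raises OnePhaseError for chi <= chi_c.
    """
    chi_c = 0.5 * (1.0 + 1.0 / math.sqrt(n)) ** 2
    if chi <= chi_c * (1 + 1e-12):
        raise OnePhaseError(f"chi = {chi:.6g} <= chi_c = {chi_c:.6g}: one phase")
    sp_lo, sp_hi = _spinodal(n, chi)

    def partner(phi1: float) -> float:
        mu = _fp(phi1, n, chi)
        lo, hi = sp_hi, 1.0 - _EPS
        flo = _fp(lo, n, chi) - mu
        fhi = _fp(hi, n, chi) - mu
        if flo > 0:  # mu below the local minimum: no partner on this branch
            return math.nan
        if fhi < 0:
            return math.nan
        return brentq(lambda p: _fp(p, n, chi) - mu, lo, hi, xtol=tol)

    def resid(phi1: float) -> float:
        phi2 = partner(phi1)
        if math.isnan(phi2):
            return math.nan
        return _grand(phi1, n, chi) - _grand(phi2, n, chi)

    # The partner exists only for f'(phi1) >= f'(sp_hi) (the local minimum
    # of f' on the dense side); f' is increasing on (0, sp_lo), so the
    # valid dilute interval is [phi_min, sp_lo) with f'(phi_min) = f'(sp_hi).
    # The dilute root can be exponentially small for deep quenches, so the
    # search runs in log(phi1).
    mu_min = _fp(sp_hi, n, chi)
    t_min = brentq(
        lambda t: _fp(math.exp(t), n, chi) - mu_min,
        math.log(1e-300), math.log(sp_lo), xtol=1e-13,
    )
    t_hi = math.log(sp_lo)
    dt = 1e-7 * (t_hi - t_min) + 1e-12
    lo_t, hi_t = t_min + dt, t_hi - dt
    r_lo, r_hi = resid(math.exp(lo_t)), resid(math.exp(hi_t))
    if math.isnan(r_lo) or math.isnan(r_hi) or r_lo * r_hi > 0:
        raise RuntimeError(
            f"coexistence bracketing failed at chi = {chi:.6g}, n = {n:g} "
            f"(resid {r_lo:.3g} .. {r_hi:.3g})"
        )
    t1 = brentq(lambda t: resid(math.exp(t)), lo_t, hi_t, xtol=1e-14)
    phi1 = math.exp(t1)
    phi2 = partner(phi1)
    return phi1, phi2


def binodal_at_T(fh: FHParams, T: float) -> tuple[float, float]:
    """Coexisting (phi_dilute, phi_dense) at temperature T (K).

    Raises OnePhaseError above the critical temperature.
    """
    chi = fh.chi(T)
    try:
        return binodal_at_chi(fh.n_chain, chi)
    except OnePhaseError as exc:
        raise OnePhaseError(f"one-phase at T = {T:.6g} K (chi = {chi:.6g})") from exc


def chi_at_binodal(phi: float, n: float, chi_max: float = 50.0) -> float:
    """The chi at which composition phi lies on the coexistence curve.

    Depends only on n, not on the temperature mapping; used to predict
    cloud-point temperatures via chi(Tp) = chi_at_binodal(phi).
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    chi_c = 0.5 * (1.0 + 1.0 / math.sqrt(n)) ** 2
    phi_c = 1.0 / (1.0 + math.sqrt(n))
    dilute_side = phi < phi_c

    def branch_gap(chi: float) -> float:
        try:
            lo, hi = binodal_at_chi(n, chi)
        except RuntimeError:
            # numerically degenerate (essentially critical): treat the
            # binodal as collapsed onto phi_c, preserving the sign
            lo = hi = phi_c
        return (lo - phi) if dilute_side else (hi - phi)

    lo_chi = chi_c * (1.0 + 1e-9)
    g_lo = branch_gap(lo_chi)
    hi_chi = chi_c + 0.1
    g_hi = branch_gap(hi_chi)
    while g_lo * g_hi > 0 and hi_chi < chi_max:
        hi_chi = chi_c + 2 * (hi_chi - chi_c)
        g_hi = branch_gap(hi_chi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"phi = {phi:.4g} not on the binodal for chi up to {chi_max:g}"
        )
    return brentq(branch_gap, lo_chi, hi_chi, xtol=1e-12)


def predicted_Tp(phi: float, fh: FHParams) -> float:
    """Cloud-point temperature for composition phi: inverts
    chi(T) = A + B/T at the coexistence chi of phi."""
    chi_star = chi_at_binodal(phi, fh.n_chain)
    if chi_star <= fh.A:
        raise ValueError(
            f"chi_at_binodal(phi={phi:.4g}) = {chi_star:.4g} <= A = {fh.A:.4g}; "
            "no positive transition temperature"
        )
    return fh.B / (chi_star - fh.A)


def fit_cloud_points(
    points: list[CloudPoint] | np.ndarray,
    n_chain: float,
) -> tuple[FHParams, dict]:
    """Fit chi(T) = A + B/T to cloud points by least squares on the
    predicted binodal temperature.

    Since the coexistence chi of each phi depends only on n_chain, the
    model is Tp(phi) = B / (chi*(phi) - A); a linear regression of
    chi*(phi) on 1/Tp initializes a nonlinear least-squares polish on
    temperature residuals.  Returns (FHParams, info) where info carries
    residual statistics and a ``degenerate`` flag when B <= 0.
    """
    if isinstance(points, np.ndarray):
        pts = [CloudPoint(float(p), float(t)) for p, t in points]
    else:
        pts = list(points)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 cloud points, got {len(pts)}")
    phi = np.array([p.phi for p in pts])
    Tp = np.array([p.Tp for p in pts])
    chi_star = np.array([chi_at_binodal(p, n_chain) for p in phi])

    # chi* = A + B * (1/Tp): linear init
    X = np.column_stack([np.ones_like(Tp), 1.0 / Tp])
    (A0, B0), *_ = np.linalg.lstsq(X, chi_star, rcond=None)

    def resid(ab):
        A, B = ab
        denom = chi_star - A
        if np.any(denom <= 0) or B <= 0:
            return 1e6 * np.ones_like(Tp)
        return B / denom - Tp

    sol = least_squares(resid, x0=[A0, max(B0, 1e-3)], method="lm")
    A, B = sol.x
    fh = FHParams(n_chain=n_chain, A=float(A), B=float(B))
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return fh, {"rmse_K": rmse, "degenerate": bool(B <= 0), "n_points": len(pts)}


def compute_binodal(fh: FHParams, T: np.ndarray) -> Binodal:
    """Sample the coexistence curve on a temperature grid; NaN above Tc."""
    T = np.asarray(T, dtype=float)
    lo = np.full_like(T, np.nan)
    hi = np.full_like(T, np.nan)
    for i, t in enumerate(T):
        try:
            lo[i], hi[i] = binodal_at_T(fh, float(t))
        except OnePhaseError:
            pass
    return Binodal(T=T, phi_dilute=lo, phi_dense=hi)


def delta_phi(fh: FHParams, T_ref: float = 295.15) -> DeltaPhi:
    """Degree of phase separation phi_dense - phi_dilute at T_ref (K).

    Returns value 0 with the one_phase flag set when T_ref is above the
    critical temperature.
    """
    try:
        lo, hi = binodal_at_T(fh, T_ref)
    except OnePhaseError:
        return DeltaPhi(value=0.0, T_ref=T_ref, one_phase=True)
    return DeltaPhi(value=hi - lo, T_ref=T_ref)
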