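"""Worm-like-chain elasticity and supercoiling bookkeeping.

The entropic elasticity of a torsionally relaxed DNA tether is described by
the Marko–Siggia interpolation of the worm-like chain (WLC),

    F = (kT / L_p) * (-1/4 + 1/(4 (1 - x)^2) + x),    x = L_e / (N_b * L_0),

where ``L_p`` is the persistence length, ``L_0`` the rise per base pair,
``N_b`` the number of base pairs and ``x`` the fractional extension.  The
same functional form is applied to each helical phase (B or L) with its own
``(L_p, L_0)`` pair.  This module provides the forward force law, its
numerical inverse, least-squares fitting of ``(L_C, L_p)`` to
force–extension data, and the turns <-> supercoiling-density conversions
``sigma = n_t / (N_b / bp_per_turn)``.

Units are fixed package-wide: nm, pN, pN·nm, turns; sigma is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "PhaseParams",
    "TetherSpec",
    "Thermal",
    "ForceExtensionCurve",
    "WlcFitResult",
    "WlcDomainError",
    "WlcFitError",
    "wlc_force",
    "wlc_relative_extension",
    "wlc_extension",
    "fit_wlc",
    "sigma_from_turns",
    "turns_from_sigma",
    "DEFAULT_KT",
]

#: Thermal energy at 310 K in pN·nm.
DEFAULT_KT = 4.28

# Upper limit of the bracketed search for the fractional extension; the WLC
# force diverges as x -> 1 so the inverse never needs to reach it.
_X_MAX = 1.0 - 1e-9


class WlcDomainError(ValueError):
    """Input outside the domain of the WLC force law or its inverse."""


class WlcFitError(RuntimeError):
    """WLC least-squares fit failed to converge; carries best-so-far state."""

    def __init__(self, message: str, best: "WlcFitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class PhaseParams:
    """Mechanical parameters of one helical phase.

    Parameters
    ----------
    persistence_length : float
        Bending persistence length L_p in nm.
    rise_per_bp : float
        Axial rise per base pair L_0 in nm.
    """

    persistence_length: float
    rise_per_bp: float

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ValueError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )
        if not self.rise_per_bp > 0:
            raise ValueError(f"rise_per_bp must be > 0, got {self.rise_per_bp}")

    def contour_length(self, n_bp: int) -> float:
        """Contour length N_b * L_0 in nm."""
        return n_bp * self.rise_per_bp


@dataclass(frozen=True)
class TetherSpec:
    """Size and helical repeat of the tethered DNA construct."""

    n_bp: int
    bp_per_turn: float = 10.4

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError(f"n_bp must be >= 1, got {self.n_bp}")
        if not self.bp_per_turn > 0:
            raise ValueError(f"bp_per_turn must be > 0, got {self.bp_per_turn}")

    @property
    def natural_turns(self) -> float:
        """Helical turns of the relaxed tether, N_b / bp_per_turn."""
        return self.n_bp / self.bp_per_turn


@dataclass(frozen=True)
class Thermal:
    """Thermal energy kT in pN·nm."""

    kT: float = DEFAULT_KT

    def __post_init__(self) -> None:
        if not self.kT > 0:
            raise ValueError(f"kT must be > 0, got {self.kT}")


@dataclass
class ForceExtensionCurve:
    """A force–extension record: paired forces (pN) and extensions (nm)."""

    force: np.ndarray
    extension: np.ndarray
    tether: TetherSpec | None = None

    # generous bound: no known duplex phase exceeds ~0.6 nm/bp of rise
    MAX_RISE_NM = 0.7

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.force.shape != self.extension.shape:
            raise ValueError("force and extension must have equal lengths")
        if np.any(self.force <= 0):
            raise ValueError("all forces must be > 0")
        if np.any(self.extension < 0):
            raise ValueError("extensions must be >= 0")
        if self.tether is not None:
            cap = self.tether.n_bp * self.MAX_RISE_NM
            if np.any(self.extension >= cap):
                raise ValueError(
                    f"extension exceeds {cap:.0f} nm, implausible for "
                    f"{self.tether.n_bp} bp"
                )

    def __len__(self) -> int:
        return self.force.size


@dataclass(frozen=True)
class WlcFitResult:
    """Estimates of contour length L_C and persistence length L_p (nm)."""

    contour_length: float
    persistence_length: float
    contour_length_stderr: float
    persistence_length_stderr: float
    residual_norm: float

    def __post_init__(self) -> None:
        if not (self.contour_length > 0 and self.persistence_length > 0):
            raise ValueError("fitted lengths must be positive")


def _wlc_reduced(x: np.ndarray | float) -> np.ndarray | float:
    """Dimensionless Marko–Siggia response g(x) = -1/4 + 1/(4(1-x)^2) + x."""
    return -0.25 + 0.25 / (1.0 - x) ** 2 + x


def wlc_force(
    relative_extension: float | np.ndarray,
    phase: PhaseParams,
    thermal: Thermal = Thermal(),
) -> float | np.ndarray:
    """WLC force (pN) at fractional extension ``x = L_e / (N_b L_0)``.

    Strictly increasing on [0, 1); diverges as x -> 1.  Raises
    :class:`WlcDomainError` for x outside [0, 1).
    """
    x = np.asarray(relative_extension, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        bad = x[(x < 0) | (x >= 1)]
        raise WlcDomainError(
            f"relative_extension must lie in [0, 1); got {np.atleast_1d(bad)[0]!r}"
        )
    out = (thermal.kT / phase.persistence_length) * _wlc_reduced(x)
    return float(out) if np.isscalar(relative_extension) else out


def wlc_relative_extension(
    force: float,
    phase: PhaseParams,
    thermal: Thermal = Thermal(),
) -> float:
    """Invert the WLC force law for the fractional extension x in [0, 1).

    Brent bracketed root finding on [0, 1 - 1e-9]; the force law is strictly
    monotone there so convergence is guaranteed.
    """
    if not force > 0:
        raise WlcDomainError(
            f"force must be > 0 pN for the WLC inverse, got {force}"
        )
    g_target = force * phase.persistence_length / thermal.kT

    def h(x: float) -> float:
        return _wlc_reduced(x) - g_target

    if h(_X_MAX) < 0:  # unreachable for physical forces; guard anyway
        return _X_MAX
    return brentq(h, 0.0, _X_MAX, xtol=1e-12, rtol=8.9e-16)


def wlc_extension(
    force: float,
    phase: PhaseParams,
    tether: TetherSpec,
    thermal: Thermal = Thermal(),
) -> float:
    """Equilibrium extension (nm) of a tether at the given force (pN)."""
    x = wlc_relative_extension(force, phase, thermal)
    return tether.n_bp * phase.rise_per_bp * x


def _wlc_extension_model(
    forces: np.ndarray, contour_length: float, persistence_length: float, kT: float
) -> np.ndarray:
    """Predicted extensions for an array of forces (used by the fitter)."""
    g = forces * persistence_length / kT
    out = np.empty_like(forces)
    for i, gi in enumerate(g):
        out[i] = brentq(
            lambda x: _wlc_reduced(x) - gi, 0.0, _X_MAX, xtol=1e-12, rtol=8.9e-16
        )
    return contour_length * out


def fit_wlc(
    curve: ForceExtensionCurve,
    thermal: Thermal = Thermal(),
    initial_guess: tuple[float, float] | None = None,
) -> WlcFitResult:
    """Fit (L_C, L_p) to a force–extension curve by least squares.

    Residuals are in extension space (extension predicted from force), which
    matches how magnetic-tweezers data are acquired: force is set, extension
    is measured.  Standard errors come from the Jacobian at the optimum.

    Requires at least 4 distinct force values spanning a factor >= 3.
    """
    f = curve.force
    z = curve.extension
    distinct = np.unique(f)
    if distinct.size < 4:
        raise ValueError(
            f"need >= 4 distinct force points, got {distinct.size}"
        )
    if distinct.max() / distinct.min() < 3.0:
        raise ValueError(
            "forces must span at least a factor of 3 "
            f"(span {distinct.max() / distinct.min():.2f})"
        )
    if initial_guess is None:
        initial_guess = (float(z.max()) / 0.95, 50.0)

    def resid(p: np.ndarray) -> np.ndarray:
        return _wlc_extension_model(f, p[0], p[1], thermal.kT) - z

    sol = least_squares(
        resid,
        x0=np.asarray(initial_guess, dtype=float),
        bounds=([1e-6, 1e-6], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=200,
    )
    lc, lp = sol.x
    dof = max(len(curve) - 2, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    result = WlcFitResult(
        contour_length=float(lc),
        persistence_length=float(lp),
        contour_length_stderr=float(se[0]),
        persistence_length_stderr=float(se[1]),
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
    )
    if not sol.success:
        raise WlcFitError(f"WLC fit did not converge: {sol.message}", best=result)
    return result


def sigma_from_turns(n_t: float, tether: TetherSpec) -> float:
    """Supercoiling density sigma = n_t / (N_b / bp_per_turn)."""
    return n_t * tether.bp_per_turn / tether.n_bp


def turns_from_sigma(sigma: float, tether: TetherSpec) -> float:
    """Imposed turns corresponding to supercoiling density sigma."""
    return sigma * tether.n_bp / tether.bp_per_turn
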