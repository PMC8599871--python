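"""Two-phase (B/L) coexistence model of negatively supercoiled DNA.

Under tension above ~1 pN, unwinding a torsionally constrained DNA tether
converts a turn-proportional fraction ``chi`` of the molecule from the
right-handed B helix to the underwound, left-handed L form instead of
forming plectonemes.  The mixed-phase extension is the chi-weighted convex
combination of the two pure-phase WLC extensions,

    L_eBL(F, n_t) = L_eB(F) (1 - chi) + L_eL(F) chi,
    chi = (n_t - n_b_max) / (n_t_max - n_b_max),

so the extension is linear in imposed turns with slope
``(L_eL - L_eB) / (n_t_max - n_b_max)``.  Because the L form is both longer
per base pair (larger rise) and far floppier (smaller persistence length),
the two pure-phase extension curves cross at a unique tension: the
*inversion force* F*, where the mixed-phase slope vanishes.  Measuring F*
therefore pins a one-parameter family of (rise ratio, L persistence length)
pairs; fixing the rise ratio from helix geometry yields the L-form
persistence length.

This module implements the forward model (mixed extension, slope, F*), the
inverse inference of the L-form persistence length from a measured F*, the
compatibility region over (rise ratio, L_pL) grids, and the geometric
reconstruction of the rise ratio from the B->L completion threshold
``sigma_max`` by conservation of backbone arc length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .core_model import (
    PhaseParams,
    TetherSpec,
    Thermal,
    _wlc_reduced,
    turns_from_sigma,
    wlc_extension,
    wlc_relative_extension,
)

__all__ = [
    "ModelConfig",
    "InversionResult",
    "CompatibilityRegion",
    "HelixGeometry",
    "RegimeRangeError",
    "NoCrossingError",
    "DegeneratePhasesError",
    "InfeasibleGeometryError",
    "l_fraction",
    "mixed_extension",
    "bl_slope",
    "inversion_force",
    "lpl_from_inversion",
    "compatibility_region",
    "contour_ratio_from_sigma",
    "default_config",
]

# Force bracket (pN) for the inversion-force search; spans all tensions at
# which the B->L coexistence is observed in magnetic-tweezers experiments.
F_BRACKET = (0.01, 50.0)


class RegimeRangeError(ValueError):
    """Imposed turns outside the mixed-phase (BL) validity range."""

    def __init__(self, message: str, regime: str):
        super().__init__(message)
        self.regime = regime  # "B-plectonemic" or "L-plectonemic"


class NoCrossingError(RuntimeError):
    """The two pure-phase extension curves do not cross in the bracket."""


class DegeneratePhasesError(ValueError):
    """B and L phases are identical; extension curves coincide everywhere."""


class InfeasibleGeometryError(ValueError):
    """Requested helix geometry cannot conserve the backbone arc length."""


@dataclass(frozen=True)
class ModelConfig:
    """Full two-phase model configuration.

    ``sigma_max`` is the supercoiling density at which conversion to the L
    form completes (default -1.8); ``n_b_max`` the turns absorbed by elastic
    twisting before buckling, negligible against the total imposed twist in
    the BL regime (default 0, magnitude at most ~30 for tethers of this
    size).
    """

    phase_B: PhaseParams
    phase_L: PhaseParams
    tether: TetherSpec
    thermal: Thermal = Thermal()
    sigma_max: float = -1.8
    n_b_max: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_max < 0:
            raise ValueError(f"sigma_max must be < 0, got {self.sigma_max}")
        if abs(self.n_b_max) > 30:
            raise ValueError(
                f"|n_b_max| must be <= 30 turns, got {self.n_b_max}"
            )
        if self.phase_L.rise_per_bp < self.phase_B.rise_per_bp:
            raise ValueError(
                "L-form rise per bp must be >= B-form rise per bp"
            )

    @property
    def n_t_max(self) -> float:
        """Turns at complete conversion to the L form (negative)."""
        return turns_from_sigma(self.sigma_max, self.tether)


def default_config(
    n_bp: int = 4642,
    lpl: float = 3.0,
    ratio_l0: float | None = None,
    lpb: float = 50.0,
    l0b: float = 0.34,
    l0l: float = 0.48,
    kT: float | None = None,
    sigma_max: float = -1.8,
    n_b_max: float = 0.0,
) -> ModelConfig:
    """Canonical B/L model: L_pB = 50 nm, L_0B = 0.34 nm, L_0L = 0.48 nm.

    ``ratio_l0``, if given, overrides ``l0l`` as ``l0b * ratio_l0``.
    """
    if ratio_l0 is not None:
        l0l = l0b * ratio_l0
    thermal = Thermal() if kT is None else Thermal(kT)
    return ModelConfig(
        phase_B=PhaseParams(lpb, l0b),
        phase_L=PhaseParams(lpl, l0l),
        tether=TetherSpec(n_bp),
        thermal=thermal,
        sigma_max=sigma_max,
        n_b_max=n_b_max,
    )


@dataclass(frozen=True)
class InversionResult:
    """Inversion force F* (pN) with the search bracket used."""

    f_star: float
    bracket: tuple[float, float]
    converged: bool

    def __post_init__(self) -> None:
        if not self.f_star > 0:
            raise ValueError("f_star must be > 0")
        lo, hi = self.bracket
        if not (lo <= self.f_star <= hi):
            raise ValueError("bracket must contain f_star")


@dataclass
class CompatibilityRegion:
    """Grid of predicted F* over (rise ratio, L_pL) with acceptance mask.

    ``flagged`` marks grid points where the inversion force is undefined
    (no crossing, or degenerate/invalid phase parameters); those points are
    masked incompatible rather than raising.
    """

    ratio_axis: np.ndarray
    lpl_axis: np.ndarray
    f_star_grid: np.ndarray  # shape (len(ratio_axis), len(lpl_axis)), NaN where flagged
    mask: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        expect = (self.ratio_axis.size, self.lpl_axis.size)
        for name in ("f_star_grid", "mask", "flagged"):
            if getattr(self, name).shape != expect:
                raise ValueError(f"{name} has shape inconsistent with axes")


@dataclass(frozen=True)
class HelixGeometry:
    """Backbone helix geometry of the B form used in the rise-ratio
    reconstruction: helix radius (nm), base pairs per turn and rise per bp."""

    radius: float = 0.92
    bp_per_turn_B: float = 10.4
    rise_B: float = 0.34

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


def l_fraction(n_t: float, config: ModelConfig) -> float:
    """Fraction chi of the tether in the L form at ``n_t`` imposed turns.

    Linear in turns: 0 at the buckling bound ``n_b_max``, 1 at complete
    conversion ``n_t_max``.  Outside that range the molecule is plectonemic
    and :class:`RegimeRangeError` identifies which branch.
    """
    n_t_max = config.n_t_max
    n_b_max = config.n_b_max
    if n_t > n_b_max:
        raise RegimeRangeError(
            f"n_t = {n_t} is above n_b_max = {n_b_max}: "
            "B-plectonemic regime, outside the mixed BL range",
            regime="B-plectonemic",
        )
    if n_t < n_t_max:
        raise RegimeRangeError(
            f"n_t = {n_t} is below n_t_max = {n_t_max:.1f}: "
            "L-plectonemic regime, outside the mixed BL range",
            regime="L-plectonemic",
        )
    return (n_t - n_b_max) / (n_t_max - n_b_max)


def mixed_extension(force: float, n_t: float, config: ModelConfig) -> float:
    """Extension (nm) of the mixed BL phase at given force and turns."""
    chi = l_fraction(n_t, config)
    le_b = wlc_extension(force, config.phase_B, config.tether, config.thermal)
    le_l = wlc_extension(force, config.phase_L, config.tether, config.thermal)
    return le_b * (1.0 - chi) + le_l * chi


def bl_slope(force: float, config: ModelConfig) -> float:
    """Mixed-phase slope dL_eBL/dn_t (nm/turn) at the given force.

    The mixed extension is linear in turns, so the slope is constant in
    ``n_t``: ``(L_eL(F) - L_eB(F)) / (n_t_max - n_b_max)``.  Positive below
    the inversion force, zero at it, negative above.
    """
    le_b = wlc_extension(force, config.phase_B, config.tether, config.thermal)
    le_l = wlc_extension(force, config.phase_L, config.tether, config.thermal)
    return (le_l - le_b) / (config.n_t_max - config.n_b_max)


def inversion_force(
    config: ModelConfig, bracket: tuple[float, float] = F_BRACKET
) -> InversionResult:
    """Force F* (pN) at which pure-B and pure-L extensions are equal.

    Requires the L form to be longer per bp *and* floppier than the B form,
    in which case the extension curves cross exactly once: the L form wins
    at high tension (longer contour) and loses at low tension (stronger
    entropic contraction).
    """
    b, l = config.phase_B, config.phase_L
    if b == l:
        raise DegeneratePhasesError(
            "phase_L equals phase_B: extension curves coincide everywhere"
        )
    if not (
        l.rise_per_bp > b.rise_per_bp
        and l.persistence_length < b.persistence_length
    ):
        raise ValueError(
            "inversion force requires rise_L > rise_B and L_pL < L_pB "
            "(otherwise the extension curves need not cross)"
        )

    def diff(f: float) -> float:
        return wlc_extension(f, b, config.tether, config.thermal) - wlc_extension(
            f, l, config.tether, config.thermal
        )

    lo, hi = bracket
    d_lo, d_hi = diff(lo), diff(hi)
    if d_lo * d_hi > 0:
        raise NoCrossingError(
            "no sign change of L_eB - L_eL in bracket "
            f"[{lo}, {hi}] pN: diff({lo}) = {d_lo:.3f} nm, "
            f"diff({hi}) = {d_hi:.3f} nm"
        )
    f_star = brentq(diff, lo, hi, xtol=1e-10, rtol=8.9e-16)
    return InversionResult(f_star=float(f_star), bracket=bracket, converged=True)


def lpl_from_inversion(
    f_star: float, ratio_l0: float, config: ModelConfig
) -> float:
    """L-form persistence length (nm) implied by a measured inversion force.

    At F* the two pure-phase extensions are equal, so the fractional
    extensions satisfy ``x_L = x_B / ratio_l0``; substituting x_L into the
    L-phase WLC force law and solving for the persistence length gives the
    closed form ``L_pL = (kT / F*) g(x_L)`` with g the Marko–Siggia
    response.  The B-phase parameters and kT are taken from ``config``;
    its ``phase_L`` persistence length is ignored.
    """
    if not f_star > 0:
        raise ValueError(f"f_star must be > 0, got {f_star}")
    if not ratio_l0 > 1:
        raise ValueError(f"ratio_l0 must be > 1, got {ratio_l0}")
    x_b = wlc_relative_extension(f_star, config.phase_B, config.thermal)
    x_l = x_b / ratio_l0
    if x_l >= 1:
        raise InfeasibleGeometryError(
            f"x_B / ratio = {x_l:.3f} >= 1: no WLC state matches"
        )
    return config.thermal.kT / f_star * float(_wlc_reduced(x_l))


def compatibility_region(
    f_star: float,
    delta_f: float,
    ratio_grid: np.ndarray,
    lpl_grid: np.ndarray,
    config: ModelConfig,
) -> CompatibilityRegion:
    """Map the (rise ratio, L_pL) pairs compatible with a measured F*.

    Evaluates the predicted inversion force on the Cartesian grid; a point
    is compatible when ``|F*_pred - f_star| <= delta_f``.  Points where the
    inversion force is undefined are flagged and masked incompatible, never
    raised, so the full map always renders.
    """
    if delta_f < 0:
        raise ValueError(f"delta_f must be >= 0, got {delta_f}")
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    lpl_grid = np.asarray(lpl_grid, dtype=float)
    if ratio_grid.size == 0 or lpl_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(ratio_grid) < 0) or np.any(np.diff(lpl_grid) < 0):
        raise ValueError("grids must be sorted ascending")

    shape = (ratio_grid.size, lpl_grid.size)
    fgrid = np.full(shape, np.nan)
    flagged = np.zeros(shape, dtype=bool)
    for i, ratio in enumerate(ratio_grid):
        l0l = config.phase_B.rise_per_bp * ratio
        for j, lpl in enumerate(lpl_grid):
            try:
                trial = replace(
                    config, phase_L=PhaseParams(lpl, l0l)
                )
                fgrid[i, j] = inversion_force(trial).f_star
            except (ValueError, NoCrossingError):
                flagged[i, j] = True
    mask = np.abs(fgrid - f_star) <= delta_f
    mask &= ~flagged
    return CompatibilityRegion(
        ratio_axis=ratio_grid,
        lpl_axis=lpl_grid,
        f_star_grid=fgrid,
        mask=mask,
        flagged=flagged,
    )


def contour_ratio_from_sigma(
    sigma_max: float, geometry: HelixGeometry = HelixGeometry()
) -> float:
    """Rise ratio L_0L/L_0B implied by backbone-length conservation.

    All duplex phases share the same backbone arc length per base pair,
    ``s = sqrt(rise_B^2 + (2 pi r / n_B)^2)`` with ``n_B`` bp per B turn and
    ``r`` the backbone helix radius.  At the completion threshold
    ``sigma_max`` the residual twist per bp is ``(1 + sigma_max) / n_B``
    turns (left-handed for sigma < -1); solving the same arc-length relation
    for the L-form rise and dividing by the B rise gives the ratio.

    This reconstructs the threshold-geometry argument from first
    principles; the radius default of 0.92 nm sits inside the accepted
    0.9–1.0 nm range for the B-DNA backbone helix.
    """
    if not (-2.0 < sigma_max <= 0.0):
        raise ValueError(
            f"sigma_max must lie in (-2, 0], got {sigma_max}"
        )
    circ_B = 2.0 * math.pi * geometry.radius / geometry.bp_per_turn_B
    a = abs(1.0 + sigma_max)  # L twist per bp in units of the B twist
    # rise_L^2 = s^2 - (a circ_B)^2 with s^2 = rise_B^2 + circ_B^2, grouped
    # to cancel exactly when a = 1 (sigma_max = 0: identical helix)
    under = geometry.rise_B**2 + circ_B**2 * (1.0 - a * a)
    if under < 0:
        raise InfeasibleGeometryError(
            "backbone cannot conserve arc length: circumferential path "
            f"{a * circ_B:.3f} nm/bp exceeds the per-bp arc length"
        )
    rise_L = math.sqrt(under)
    return rise_L / geometry.rise_B
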