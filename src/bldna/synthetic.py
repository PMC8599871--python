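"""Synthetic magnetic-tweezers data with the structure the analysis assumes.

Generates extension-versus-turns traces at fixed force with the
three-regime shape seen in twist experiments on torsionally constrained
DNA — B plectonemic shortening at positive turns, the linear mixed-BL
regime at intermediate negative turns, and L plectonemic shortening beyond
complete conversion — plus WLC force–extension curves for the pure phases.
The generator calls the same model operations the analysis pipeline fits,
so at zero noise the generated points equal the model exactly; axial
tracking noise is i.i.d. Gaussian on extension (default sd 10 nm, the
tracking precision of bead imaging along the optical axis), and points
clipped at zero extension are flagged.

At forces below ~0.5 pN unwinding is relaxed by writhing rather than by
the B->L transition, so low-force traces are generated as symmetric
plectonemic shortening on both sides of the buckling point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import TetherSpec, wlc_extension
from .phase_transition import ModelConfig
from .plectoneme import PlectonemeParams, plectoneme_slope

__all__ = [
    "TwistTrace",
    "NoiseModel",
    "RegimeConfigError",
    "gen_twist_trace",
    "gen_force_extension",
    "LOW_FORCE_THRESHOLD",
]

#: Below this force (pN) unwinding writhes instead of driving the B->L
#: transition; traces are generated as symmetric plectonemic shortening.
LOW_FORCE_THRESHOLD = 0.5


class RegimeConfigError(ValueError):
    """Inconsistent regime request, e.g. a BL branch at low force."""


@dataclass(frozen=True)
class NoiseModel:
    """Axial tracking noise: i.i.d. Gaussian sd (nm) and RNG seed."""

    axial_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axial_sd < 0:
            raise ValueError(f"axial_sd must be >= 0, got {self.axial_sd}")


@dataclass
class TwistTrace:
    """One extension-versus-turns record at fixed force."""

    trace_id: str
    force: float
    n_t: np.ndarray
    extension: np.ndarray
    dna_label: str = "WT"
    tether: TetherSpec | None = None
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.n_t = np.asarray(self.n_t)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.n_t.shape != self.extension.shape:
            raise ValueError("n_t and extension must have equal lengths")
        d = np.diff(self.n_t)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("n_t must be strictly monotone")
        if not np.all(np.isfinite(self.extension)):
            raise ValueError("extension must be finite")
        if np.any(self.extension < 0):
            raise ValueError("extension must be >= 0 after clipping")
        if self.clipped is None:
            self.clipped = np.zeros(self.n_t.shape, dtype=bool)

    def __len__(self) -> int:
        return self.n_t.size


def _noiseless_extension(
    n_t: np.ndarray,
    force: float,
    config: ModelConfig,
    plect: PlectonemeParams,
    style: str,
) -> np.ndarray:
    """Piecewise model extension; continuous at the regime junctions."""
    le_b = wlc_extension(force, config.phase_B, config.tether, config.thermal)
    slope_b = plectoneme_slope(force, config.phase_B, config.thermal, plect)
    n_b_max = config.n_b_max
    out = np.empty(n_t.shape, dtype=float)

    if style == "plectoneme":
        # symmetric writhing on both sides of the buckling point
        out[:] = le_b - slope_b * np.abs(n_t - n_b_max)
        return out

    n_t_max = config.n_t_max
    le_l = wlc_extension(force, config.phase_L, config.tether, config.thermal)
    slope_l = plectoneme_slope(force, config.phase_L, config.thermal, plect)
    bl_rate = (le_l - le_b) / (n_t_max - n_b_max)

    b_side = n_t > n_b_max
    l_side = n_t < n_t_max
    mid = ~(b_side | l_side)
    out[b_side] = le_b - slope_b * (n_t[b_side] - n_b_max)
    out[mid] = le_b + bl_rate * (n_t[mid] - n_b_max)  # == Eq.(3) linear form
    out[l_side] = le_l + slope_l * (n_t[l_side] - n_t_max)
    return out


def gen_twist_trace(
    force: float,
    n_t_range: tuple[int, int],
    config: ModelConfig,
    plect: PlectonemeParams = PlectonemeParams(),
    noise: NoiseModel = NoiseModel(),
    *,
    step: int = 5,
    trace_id: str = "trace-0",
    dna_label: str = "WT",
    style: str = "auto",
) -> TwistTrace:
    """Generate one extension-vs-turns trace at fixed force.

    ``style`` selects the regime structure: ``"bl"`` forces the
    three-regime B / mixed-BL / L shape, ``"plectoneme"`` the symmetric
    low-force writhing shape, ``"auto"`` picks by comparing ``force``
    against :data:`LOW_FORCE_THRESHOLD`.  Requesting ``"bl"`` below the
    threshold raises :class:`RegimeConfigError`: at such forces writhing
    outcompetes the B->L transition and the mixed-phase model does not
    apply.

    Turns are sampled every ``step`` turns over ``n_t_range`` (inclusive
    endpoints), mimicking a twist scan.  Noise is added after the model
    evaluation and the trace is clipped at zero extension with clipped
    points flagged.
    """
    if not force > 0:
        raise ValueError(f"force must be > 0, got {force}")
    if style not in ("auto", "bl", "plectoneme"):
        raise ValueError(f"unknown style {style!r}")
    if style == "bl" and force < LOW_FORCE_THRESHOLD:
        raise RegimeConfigError(
            f"BL regime requested at F = {force} pN < "
            f"{LOW_FORCE_THRESHOLD} pN: writhing dominates below threshold"
        )
    if style == "auto":
        style = "plectoneme" if force < LOW_FORCE_THRESHOLD else "bl"

    lo, hi = n_t_range
    if lo > hi:
        lo, hi = hi, lo
    n_t = np.arange(lo, hi + 1, step)
    clean = _noiseless_extension(n_t, force, config, plect, style)

    if noise.axial_sd > 0:
        rng = np.random.default_rng(noise.seed)
        ext = clean + rng.normal(0.0, noise.axial_sd, size=clean.shape)
    else:
        ext = clean.copy()
    clipped = ext < 0
    ext[clipped] = 0.0
    return TwistTrace(
        trace_id=trace_id,
        force=force,
        n_t=n_t,
        extension=ext,
        dna_label=dna_label,
        tether=config.tether,
        clipped=clipped,
    )


def gen_force_extension(
    forces,
    phase,
    tether: TetherSpec,
    thermal,
    noise: NoiseModel = NoiseModel(),
):
    """WLC force–extension curve with seeded Gaussian noise.

    Returns a :class:`bldna.core_model.ForceExtensionCurve`; at
    ``axial_sd = 0`` the curve is the exact WLC prediction.
    """
    from .core_model import ForceExtensionCurve

    forces = np.asarray(forces, dtype=float)
    if np.any(forces <= 0):
        raise ValueError("all forces must be > 0")
    ext = np.array(
        [wlc_extension(f, phase, tether, thermal) for f in forces]
    )
    if noise.axial_sd > 0:
        rng = np.random.default_rng(noise.seed)
        ext = ext + rng.normal(0.0, noise.axial_sd, size=ext.shape)
    ext = np.clip(ext, 0.0, None)
    return ForceExtensionCurve(force=forces, extension=ext, tether=tether)
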