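"""Qualitative plectoneme-slope surrogate.

In the plectonemic regimes (B form at positive turns or low force; L form
beyond complete conversion) each added turn sequesters roughly one
superhelical gyre of contour length, shortening the tether.  Quantitative
models of this slope minimise bending plus electrostatic energy of the
superhelix; reproducing such a model is out of scope here.  Instead this
module provides a loop-balance surrogate: the gyre circumference scales as
the bending/tension length ``sqrt(kT L_p / (2F))``, giving a slope
magnitude

    |dL_e/dn_t| = c * 2 pi * sqrt(kT L_p / (2 F)),

with a single calibration factor ``c`` (default 0.4, placing low-force
B-form slopes in the tens-of-nm/turn range typical of magnetic-tweezers
data).  The surrogate reproduces only the two qualitative facts the
analysis relies on — the slope magnitude decreases with force and grows
with persistence length — and must not be read as a quantitative
prediction.  For the L form in particular, measured slopes in the
literature fall well below loop-balance estimates, so no surrogate of this
family can be quantitative there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import PhaseParams, Thermal

__all__ = ["PlectonemeParams", "plectoneme_slope"]


@dataclass(frozen=True)
class PlectonemeParams:
    """Surrogate parameters.

    ``ionic_strength`` (mM) is accepted for interface parity with
    electrostatic slope models but does not enter the surrogate;
    ``efficiency`` is the calibration factor c in (0, 1].
    """

    ionic_strength: float = 150.0
    efficiency: float = 0.4

    def __post_init__(self) -> None:
        if not self.ionic_strength > 0:
            raise ValueError(
                f"ionic_strength must be > 0, got {self.ionic_strength}"
            )
        if not 0 < self.efficiency <= 1:
            raise ValueError(
                f"efficiency must be in (0, 1], got {self.efficiency}"
            )


def plectoneme_slope(
    force: float,
    phase: PhaseParams,
    thermal: Thermal = Thermal(),
    params: PlectonemeParams = PlectonemeParams(),
) -> float:
    """Slope magnitude |dL_e/dn_t| (nm/turn) of a plectonemic regime.

    Strictly decreasing in force and increasing in persistence length.
    """
    if not force > 0:
        raise ValueError(f"force must be > 0, got {force}")
    return (
        params.efficiency
        * 2.0
        * math.pi
        * math.sqrt(thermal.kT * phase.persistence_length / (2.0 * force))
    )
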