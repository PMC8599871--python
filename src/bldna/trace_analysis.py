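"""Inference pipeline for extension-versus-turns traces.

Mirrors how the mechanical parameters are read off magnetic-tweezers twist
scans: each trace is segmented into its three linear regimes (L
plectonemic, mixed BL, B plectonemic, in order of increasing turns) by an
exhaustive two-breakpoint changepoint search; per-regime slopes are
assembled as a function of force; the inversion force F* is the zero
crossing of the BL slope versus force; and the L-form persistence length
follows from F* through the two-phase WLC balance
(:func:`bldna.phase_transition.lpl_from_inversion`).

The changepoint search is exhaustive over observed turn values (prefix-sum
algebra makes each candidate O(1), so traces of ~10^3 points are
desk-scale) rather than heuristic, for determinism: the same trace always
yields the same segmentation.  Ties in the total squared error are broken
by the candidate with the longest middle (BL) segment, then by the smaller
first breakpoint.  Slope fits exclude the inner 10% of each segment's
points adjacent to a breakpoint to reduce junction-curvature bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SlopeEstimate",
    "Segmentation",
    "FStarEstimate",
    "SegmentationError",
    "NoSlopeCrossingError",
    "segment_trace",
    "slope_vs_force",
    "estimate_f_star",
]

logger = logging.getLogger(__name__)

REGIMES = ("L", "BL", "B")  # in order of increasing turns


class SegmentationError(RuntimeError):
    """No valid three-segment candidate for this trace."""


class NoSlopeCrossingError(RuntimeError):
    """BL slopes do not change sign across the sampled forces."""


@dataclass(frozen=True)
class SlopeEstimate:
    """Fitted linear slope of a trace segment."""

    regime: str
    slope: float
    stderr: float
    force: float
    n_points: int
    turn_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n_points < 3:
            raise ValueError(f"n_points must be >= 3, got {self.n_points}")


@dataclass(frozen=True)
class Segmentation:
    """Three-regime piecewise-linear decomposition of one trace.

    ``breakpoints`` are the two turn values (BL/L and B/BL boundaries, in
    ascending turn order) at which the optimal candidate splits the trace.
    """

    breakpoints: tuple[float, float]
    sse: float
    slopes: Mapping[str, SlopeEstimate]
    single_regime_suspected: bool = False

    def __post_init__(self) -> None:
        if not self.breakpoints[0] <= self.breakpoints[1]:
            raise ValueError("breakpoints must be ordered")


@dataclass(frozen=True)
class FStarEstimate:
    """Inversion force with a bootstrap confidence interval."""

    f_star: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.f_star <= self.ci_high):
            raise ValueError("require ci_low <= f_star <= ci_high")


def _prefix_sums(x: np.ndarray, y: np.ndarray):
    z = np.zeros(1)
    return (
        np.concatenate([z, np.cumsum(x)]),
        np.concatenate([z, np.cumsum(y)]),
        np.concatenate([z, np.cumsum(x * x)]),
        np.concatenate([z, np.cumsum(x * y)]),
        np.concatenate([z, np.cumsum(y * y)]),
    )


def _segment_sse(px, py, pxx, pxy, pyy, i, j):
    """SSE of the least-squares line over points [i, j); i, j broadcastable."""
    with np.errstate(divide="ignore", invalid="ignore"):
        n = (j - i).astype(float)
        sx = px[j] - px[i]
        sy = py[j] - py[i]
        sxx = pxx[j] - pxx[i]
        sxy = pxy[j] - pxy[i]
        syy = pyy[j] - pyy[i]
        cxx = sxx - sx * sx / n
        cxy = sxy - sx * sy / n
        cyy = syy - sy * sy / n
        sse = cyy - np.where(cxx > 0, cxy * cxy / np.where(cxx > 0, cxx, 1.0), 0.0)
    return np.maximum(np.nan_to_num(sse, nan=np.inf), 0.0)  # clamp float cancellation


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and its standard error."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ y) / sxx
    resid = y - y.mean() - slope * xc
    dof = max(n - 2, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / sxx))
    return slope, stderr


def _trimmed_slope(
    x: np.ndarray,
    y: np.ndarray,
    trim_left: bool,
    trim_right: bool,
    trim_frac: float,
) -> tuple[float, float, int, tuple[float, float]]:
    """Fit a line after dropping ``trim_frac`` of points at junction ends."""
    k = int(np.floor(trim_frac * x.size))
    lo = k if trim_left else 0
    hi = x.size - k if trim_right else x.size
    if hi - lo < 3:  # keep at least 3 points
        lo, hi = 0, x.size
    xs, ys = x[lo:hi], y[lo:hi]
    slope, stderr = _fit_line(xs, ys)
    return slope, stderr, xs.size, (float(xs.min()), float(xs.max()))


def segment_trace(
    trace,
    window: tuple[float, float] | None = None,
    *,
    min_seg: int = 4,
    trim_frac: float = 0.1,
) -> Segmentation:
    """Segment one trace into its three linear regimes.

    Exhaustive search over ordered breakpoint pairs on the observed turn
    values; each candidate scores the summed SSE of three independent
    least-squares lines.  Requires at least 12 points in the fit window
    (three segments of at least ``min_seg = 4`` points each).

    A trace that is globally linear cannot distinguish candidates by SSE;
    it is segmented by the tie-break rule and flagged
    ``single_regime_suspected``.
    """
    x = np.asarray(trace.n_t, dtype=float)
    y = np.asarray(trace.extension, dtype=float)
    if x.size and x[0] > x[-1]:  # analyse in ascending turn order
        x, y = x[::-1], y[::-1]
    if window is not None:
        lo, hi = min(window), max(window)
        keep = (x >= lo) & (x <= hi)
        x, y = x[keep], y[keep]
    n = x.size
    if n < 3 * min_seg:
        raise SegmentationError(
            f"need >= {3 * min_seg} points spanning the window, got {n}"
        )

    px, py, pxx, pxy, pyy = _prefix_sums(x, y)
    # candidate breakpoint index pairs: segments [0,b1), [b1,b2), [b2,n)
    b1 = np.arange(min_seg, n - 2 * min_seg + 1)
    b2 = np.arange(2 * min_seg, n - min_seg + 1)
    B1, B2 = np.meshgrid(b1, b2, indexing="ij")
    valid = B2 - B1 >= min_seg
    left = _segment_sse(px, py, pxx, pxy, pyy, np.zeros_like(b1), b1)
    right = _segment_sse(px, py, pxx, pxy, pyy, b2, np.full_like(b2, n))
    mid = _segment_sse(px, py, pxx, pxy, pyy, B1, B2)
    total = left[:, None] + mid + right[None, :]
    total[~valid] = np.inf
    if not np.isfinite(total).any():
        raise SegmentationError("no valid three-segment candidate")

    tmin = float(total.min())
    # ties (exact or within float dust): longest middle, then smaller b1
    tol = 1e-12 * max(1.0, tmin)
    ti, tj = np.nonzero(total <= tmin + tol)
    lengths = B2[ti, tj] - B1[ti, tj]
    order = np.lexsort((B1[ti, tj], -lengths))
    i1 = int(B1[ti[order[0]], tj[order[0]]])
    i2 = int(B2[ti[order[0]], tj[order[0]]])

    sse_1seg = float(
        _segment_sse(px, py, pxx, pxy, pyy, np.array([0]), np.array([n]))[0]
    )
    single = sse_1seg <= tmin * (1.0 + 1e-6) + 1e-9
    if single:
        logger.warning(
            "trace %s: single-regime suspected (whole-trace line fits as "
            "well as three segments)",
            getattr(trace, "trace_id", "?"),
        )

    segs = ((0, i1, "L"), (i1, i2, "BL"), (i2, n, "B"))
    slopes = {}
    for lo_i, hi_i, regime in segs:
        slope, stderr, npts, win = _trimmed_slope(
            x[lo_i:hi_i],
            y[lo_i:hi_i],
            trim_left=lo_i > 0,
            trim_right=hi_i < n,
            trim_frac=trim_frac,
        )
        slopes[regime] = SlopeEstimate(
            regime=regime,
            slope=slope,
            stderr=stderr,
            force=float(trace.force),
            n_points=npts,
            turn_window=win,
        )
    return Segmentation(
        breakpoints=(float(x[i1]), float(x[i2])),
        sse=tmin,
        slopes=slopes,
        single_regime_suspected=bool(single),
    )


def _window_slope(trace, window: tuple[float, float], regime: str) -> SlopeEstimate | None:
    """Single-line slope over a fixed turn window (no segmentation)."""
    x = np.asarray(trace.n_t, dtype=float)
    y = np.asarray(trace.extension, dtype=float)
    lo, hi = min(window), max(window)
    keep = (x >= lo) & (x <= hi)
    if keep.sum() < 3:
        return None
    xs, ys = x[keep], y[keep]
    slope, stderr = _fit_line(xs, ys)
    return SlopeEstimate(
        regime=regime,
        slope=slope,
        stderr=stderr,
        force=float(trace.force),
        n_points=int(keep.sum()),
        turn_window=(float(xs.min()), float(xs.max())),
    )


def slope_vs_force(
    traces: Iterable,
    regime: str,
    window: tuple[float, float] | None = None,
    *,
    return_per_trace: bool = False,
):
    """Per-force regime slope across a family of traces.

    With ``window`` given, the slope is a single least-squares line over
    that fixed turn window (published-figure style); otherwise each trace
    is segmented and the matching regime's slope taken.  Traces in which
    the regime is absent are skipped with a logged warning.  B-regime
    slopes are reported as absolute values, matching the convention for
    plectonemic shortening rates.

    Returns a list of :class:`SlopeEstimate`, one per force (ascending).
    With ``return_per_trace=True`` also returns a dict mapping force to
    the individual per-trace slopes (for trace-level bootstrap).
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    by_force: dict[float, list[SlopeEstimate]] = {}
    for trace in traces:
        f = round(float(trace.force), 9)
        if window is not None:
            est = _window_slope(trace, window, regime)
        else:
            try:
                est = segment_trace(trace).slopes[regime]
            except SegmentationError as exc:
                logger.warning(
                    "trace %s skipped: %s", getattr(trace, "trace_id", "?"), exc
                )
                est = None
        if est is None:
            logger.warning(
                "trace %s: regime %s absent, skipped",
                getattr(trace, "trace_id", "?"),
                regime,
            )
            continue
        by_force.setdefault(f, []).append(est)

    out: list[SlopeEstimate] = []
    per_trace: dict[float, list[float]] = {}
    for f in sorted(by_force):
        ests = by_force[f]
        raw = np.array([e.slope for e in ests])
        if regime == "B":
            raw = np.abs(raw)
        per_trace[f] = [float(s) for s in raw]
        if len(ests) > 1:
            stderr = float(raw.std(ddof=1) / np.sqrt(len(ests)))
        else:
            stderr = ests[0].stderr
        out.append(
            SlopeEstimate(
                regime=regime,
                slope=float(raw.mean()),
                stderr=stderr,
                force=f,
                n_points=int(sum(e.n_points for e in ests)),
                turn_window=(
                    min(e.turn_window[0] for e in ests),
                    max(e.turn_window[1] for e in ests),
                ),
            )
        )
    if return_per_trace:
        return out, per_trace
    return out


def _interp_zero(forces: np.ndarray, slopes: np.ndarray) -> float:
    """Linear interpolation of the slope-vs-force zero crossing.

    Slopes decrease through zero as force increases; the first adjacent
    sign change is used.
    """
    for i in range(forces.size - 1):
        s0, s1 = slopes[i], slopes[i + 1]
        if s0 == 0.0:
            return float(forces[i])
        if s0 > 0 > s1 or s0 < 0 < s1:
            return float(
                forces[i] + s0 * (forces[i + 1] - forces[i]) / (s0 - s1)
            )
    if slopes[-1] == 0.0:
        return float(forces[-1])
    raise NoSlopeCrossingError(
        "no sign change of the BL slope across forces "
        f"[{forces.min():g}, {forces.max():g}] pN; slope range "
        f"[{slopes.min():.4g}, {slopes.max():.4g}] nm/turn"
    )


def estimate_f_star(
    slopes: Sequence[SlopeEstimate],
    *,
    per_trace: Mapping[float, Sequence[float]] | None = None,
    n_boot: int = 1999,
    seed: int = 0,
) -> FStarEstimate:
    """Inversion force from the zero crossing of BL slope versus force.

    The point estimate interpolates linearly across the sign change of the
    per-force mean slope.  When ``per_trace`` slopes are supplied the
    confidence interval comes from resampling whole traces with
    replacement within each force level (``n_boot`` replicates, seeded)
    and taking the 2.5/97.5 percentiles of the recomputed crossing;
    replicates without a sign change are dropped.  Without ``per_trace``
    (or with ``n_boot = 0``) the interval degenerates to the point
    estimate.
    """
    if not slopes:
        raise ValueError("no slope estimates supplied")
    order = np.argsort([e.force for e in slopes])
    forces = np.array([slopes[i].force for i in order])
    vals = np.array([slopes[i].slope for i in order])
    f_star = _interp_zero(forces, vals)

    if per_trace and n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = [np.asarray(per_trace[f], dtype=float) for f in forces]
        draws = []
        for _ in range(n_boot):
            means = np.array(
                [g[rng.integers(0, g.size, g.size)].mean() for g in groups]
            )
            try:
                draws.append(_interp_zero(forces, means))
            except NoSlopeCrossingError:
                continue
        if draws:
            lo, hi = np.percentile(draws, [2.5, 97.5])
            return FStarEstimate(
                f_star=f_star,
                ci_low=float(min(lo, f_star)),
                ci_high=float(max(hi, f_star)),
                method=f"trace-bootstrap({len(draws)}/{n_boot})",
            )
    return FStarEstimate(
        f_star=f_star, ci_low=f_star, ci_high=f_star, method="interpolation"
    )
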