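"""Configuration, CSV I/O and the staged analysis pipeline.

Traces and derived tables travel as plain CSV with explicit headers —
magnetic-tweezers data have no community standard format and CSV keeps
every artifact auditable.  Every file written here carries a comment
header with the run seed and a hash of the configuration, so any artifact
is reproducible from (config, seed) alone.

Trace schema: ``trace_id, dna_label, force_pN, n_turns, extension_nm,
clipped`` (one file may hold many traces).  Force–extension schema:
``force_pN, extension_nm``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import ForceExtensionCurve, TetherSpec
from .phase_transition import default_config, lpl_from_inversion
from .plectoneme import PlectonemeParams
from .synthetic import NoiseModel, TwistTrace, gen_twist_trace
from .trace_analysis import estimate_f_star, segment_trace, slope_vs_force

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_traces",
    "write_traces",
    "read_force_extension",
    "write_force_extension",
    "load_config",
    "run_pipeline",
    "PIPELINE_STAGES",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = [
    "trace_id",
    "dna_label",
    "force_pN",
    "n_turns",
    "extension_nm",
    "clipped",
]

PIPELINE_STAGES = ("simulate", "segment", "slopes", "fstar", "infer-lpl")


class SchemaError(ValueError):
    """CSV header does not match the expected schema."""


@dataclass
class RunConfig:
    """Flat run configuration for the staged pipeline.

    Mechanical defaults are the canonical two-phase values (B: 50 nm /
    0.34 nm; L: 3.8 nm persistence with rise ratio 1.4); the simulation
    defaults mirror typical twist-scan campaigns: forces spanning 1–4 pN,
    a few traces per force, turn scans from +100 down past complete
    conversion.
    """

    # model
    n_bp: int = 4642
    lpb: float = 50.0
    l0b: float = 0.34
    lpl: float = 3.8
    ratio_l0: float = 1.4
    kT: float = 4.28
    sigma_max: float = -1.8
    n_b_max: float = 0.0
    # plectoneme surrogate
    ionic_strength: float = 150.0
    efficiency: float = 0.4
    # noise / simulation campaign
    noise_sd: float = 10.0
    seed: int = 0
    forces: tuple = tuple(np.round(np.linspace(1.0, 4.0, 9), 6))
    traces_per_force: int = 3
    n_t_min: int = -900
    n_t_max_scan: int = 100
    step: int = 5
    # analysis
    bl_window_lo: float = -700.0
    bl_window_hi: float = -100.0
    dna_label: str = "WT"
    output_dir: str = "results"

    def model(self):
        return default_config(
            n_bp=self.n_bp,
            lpl=self.lpl,
            ratio_l0=self.ratio_l0,
            lpb=self.lpb,
            l0b=self.l0b,
            kT=self.kT,
            sigma_max=self.sigma_max,
            n_b_max=self.n_b_max,
        )

    def plectoneme(self) -> PlectonemeParams:
        return PlectonemeParams(
            ionic_strength=self.ionic_strength, efficiency=self.efficiency
        )

    def noise(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(
            axial_sd=self.noise_sd, seed=self.seed if seed is None else seed
        )

    def hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a flat key = value config file (YAML or JSON dialect).

    Unknown keys raise; ``overrides`` win over file values.  The resolved
    config is echoed to the log.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"config {path} must be a flat mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    if "forces" in data:
        data["forces"] = tuple(float(f) for f in data["forces"])
    cfg = RunConfig(**data)
    logger.info("config (hash %s): %s", cfg.hash(), dataclasses.asdict(cfg))
    return cfg


def _header_comment(cfg: RunConfig | None) -> str:
    if cfg is None:
        return ""
    return f"# bldna seed={cfg.seed} config_hash={cfg.hash()}\n"


def write_traces(
    traces, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write traces to CSV (long format, one row per point)."""
    rows = []
    for t in traces:
        rows.append(
            pd.DataFrame(
                {
                    "trace_id": t.trace_id,
                    "dna_label": t.dna_label,
                    "force_pN": t.force,
                    "n_turns": t.n_t,
                    "extension_nm": t.extension,
                    "clipped": t.clipped.astype(int),
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        df.to_csv(fh, index=False)


def read_traces(path: str | Path) -> list[TwistTrace]:
    """Read traces from CSV, grouped by trace_id with row order preserved.

    Missing columns raise :class:`SchemaError` naming them; non-numeric
    cells raise with the offending line number; unknown extra columns are
    ignored with a warning; an empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty and df.columns.size == 0:
        logger.warning("%s: empty trace file", path)
        return []
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in TRACE_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    for col in ("force_pN", "n_turns", "extension_nm", "clipped"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering (comment header adds one
            # more, reported approximately)
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column {col} near line {line}"
            )
        df[col] = coerced
    if df.empty:
        logger.warning("%s: trace file has headers but no rows", path)
        return []
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        traces.append(
            TwistTrace(
                trace_id=str(tid),
                dna_label=str(g["dna_label"].iloc[0]),
                force=float(g["force_pN"].iloc[0]),
                n_t=g["n_turns"].to_numpy(),
                extension=g["extension_nm"].to_numpy(dtype=float),
                clipped=g["clipped"].to_numpy(dtype=bool),
            )
        )
    return traces


def write_force_extension(
    curve: ForceExtensionCurve, path: str | Path, config: RunConfig | None = None
) -> None:
    df = pd.DataFrame(
        {"force_pN": curve.force, "extension_nm": curve.extension}
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        df.to_csv(fh, index=False)


def read_force_extension(
    path: str | Path, tether: TetherSpec | None = None
) -> ForceExtensionCurve:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("force_pN", "extension_nm") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return ForceExtensionCurve(
        force=df["force_pN"].to_numpy(dtype=float),
        extension=df["extension_nm"].to_numpy(dtype=float),
        tether=tether,
    )


def simulate_family(cfg: RunConfig) -> list[TwistTrace]:
    """Simulate the configured trace campaign (seeded, deterministic)."""
    model = cfg.model()
    plect = cfg.plectoneme()
    traces = []
    k = 0
    for force in cfg.forces:
        for rep in range(cfg.traces_per_force):
            traces.append(
                gen_twist_trace(
                    force=float(force),
                    n_t_range=(cfg.n_t_min, cfg.n_t_max_scan),
                    config=model,
                    plect=plect,
                    noise=cfg.noise(seed=cfg.seed * 100003 + k),
                    step=cfg.step,
                    trace_id=f"{cfg.dna_label}-F{force:g}-r{rep}",
                    dna_label=cfg.dna_label,
                )
            )
            k += 1
    return traces


def segments_table(traces, config: RunConfig | None = None) -> pd.DataFrame:
    rows = []
    for t in traces:
        seg = segment_trace(t)
        row = {
            "trace_id": t.trace_id,
            "force_pN": t.force,
            "bp_LBL_turns": seg.breakpoints[0],
            "bp_BLB_turns": seg.breakpoints[1],
            "sse_nm2": seg.sse,
            "single_regime_suspected": int(seg.single_regime_suspected),
        }
        for regime, est in seg.slopes.items():
            row[f"slope_{regime}_nm_per_turn"] = est.slope
            row[f"stderr_{regime}_nm_per_turn"] = est.stderr
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: RunConfig, stages: tuple[str, ...] = PIPELINE_STAGES
) -> dict:
    """Run a prefix of simulate -> segment -> slopes -> fstar -> infer-lpl.

    Each stage writes its CSV artifact under ``cfg.output_dir`` and
    contributes to ``summary.json``.  Re-running with the same (config,
    seed) reproduces every artifact.  Returns the summary dict.
    """
    stages = tuple(stages)
    if stages != PIPELINE_STAGES[: len(stages)]:
        raise ValueError(
            f"stages must be a prefix of {PIPELINE_STAGES}, got {stages}"
        )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.hash()}
    logger.info("pipeline start: stages=%s hash=%s", stages, cfg.hash())

    traces = None
    slopes = per_trace = None
    for stage in stages:
        if stage == "simulate":
            traces = simulate_family(cfg)
            write_traces(traces, out / "traces.csv", cfg)
            summary["n_traces"] = len(traces)
        elif stage == "segment":
            df = segments_table(traces, cfg)
            with open(out / "segments.csv", "w") as fh:
                fh.write(_header_comment(cfg))
                df.to_csv(fh, index=False)
        elif stage == "slopes":
            slopes, per_trace = slope_vs_force(
                traces,
                "BL",
                window=(cfg.bl_window_lo, cfg.bl_window_hi),
                return_per_trace=True,
            )
            df = pd.DataFrame(
                {
                    "force_pN": [e.force for e in slopes],
                    "slope_nm_per_turn": [e.slope for e in slopes],
                    "stderr_nm_per_turn": [e.stderr for e in slopes],
                    "n_points": [e.n_points for e in slopes],
                }
            )
            with open(out / "slopes.csv", "w") as fh:
                fh.write(_header_comment(cfg))
                df.to_csv(fh, index=False)
        elif stage == "fstar":
            est = estimate_f_star(
                slopes, per_trace=per_trace, seed=cfg.seed
            )
            summary["f_star_pN"] = est.f_star
            summary["f_star_ci_pN"] = [est.ci_low, est.ci_high]
            summary["f_star_method"] = est.method
        elif stage == "infer-lpl":
            summary["lpl_estimate_nm"] = lpl_from_inversion(
                summary["f_star_pN"], cfg.ratio_l0, cfg.model()
            )
            summary["lpl_ci_nm"] = [
                lpl_from_inversion(f, cfg.ratio_l0, cfg.model())
                for f in sorted(summary["f_star_ci_pN"], reverse=True)
            ]
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline done: %s", summary)
    return summary
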