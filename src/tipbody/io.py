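"""Table readers/writers and the end-to-end pipeline driver.

Canonical on-disk format is TSV with a header (CSV accepted by extension);
frames are 0-based, times in seconds, lengths in micrometres, intensities
in arbitrary units. Empty cells are missing values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tipbody import __version__
from tipbody.annotation import AnnotationConfig, annotate
from tipbody.intensity import LossSummary, loss_frequency
from tipbody.phase_diagram import PhaseGrid
from tipbody.rates import MixedModelFit, extract_partials, fit_lme
from tipbody.droplets import FusionEvent
from tipbody.trajectory import Trajectory

TRACK_COLUMNS = ["cell_id", "punctum_id", "strain", "frame", "time_s", "length_um", "intensity_au"]
SEGMENT_COLUMNS = ["cell_id", "punctum_id", "strain", "start_frame", "end_frame", "kind",
                   "slope", "intercept", "slope_p"]


class SchemaError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings."""

    dt: float = 3.5
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    loss_window_s: float = 175.0
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_tracks(path) -> list[Trajectory]:
    """Read a tracks table into trajectories, validating the schema.

    Mandatory columns: cell_id, punctum_id, strain, frame, time_s,
    length_um, intensity_au. An optional ``lost`` column (0/1) flags
    punctum loss. Duplicate frames within a trajectory are integrity
    errors reported with their row numbers.
    """
    df = _read_table(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
    out = []
    for (cell, punc, strain), g in df.groupby(["cell_id", "punctum_id", "strain"], sort=True):
        g = g.sort_values("frame")
        dup = g["frame"].duplicated()
        if dup.any():
            rows = (g.index[dup] + 2).tolist()  # header + 1-based
            raise IntegrityError(
                f"{path}: duplicate frame for trajectory {cell}/{punc} at file row(s) {rows}"
            )
        lost = bool(g["lost"].any()) if "lost" in g.columns else False
        out.append(
            Trajectory(
                cell_id=str(cell),
                punctum_id=str(punc),
                strain=str(strain),
                frame=g["frame"].to_numpy(dtype=int),
                time=g["time_s"].to_numpy(dtype=float),
                length=g["length_um"].to_numpy(dtype=float),
                intensity=g["intensity_au"].to_numpy(dtype=float),
                lost=lost,
            )
        )
    return out


def write_tracks(trajectories: list[Trajectory], path) -> None:
    rows = []
    for tr in trajectories:
        for i in range(tr.n_frames):
            rows.append(
                (tr.cell_id, tr.punctum_id, tr.strain, tr.frame[i], tr.time[i],
                 tr.length[i], tr.intensity[i], int(tr.lost))
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS + ["lost"])
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def segments_frame(trajectories, annotations) -> pd.DataFrame:
    rows = []
    for tr, ann in zip(trajectories, annotations):
        for seg in ann.segments:
            rows.append(
                (tr.cell_id, tr.punctum_id, tr.strain, seg.start_frame, seg.end_frame,
                 seg.kind, seg.slope, seg.intercept, seg.slope_p)
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def lme_results_frame(fits: list[MixedModelFit]) -> pd.DataFrame:
    rows = []
    for fit in fits:
        for strain in fit.strains:
            for which, eff in (("intercept", fit.intercepts[strain]),
                               ("slope", fit.slopes[strain])):
                rows.append(
                    (strain, fit.phase_kind, fit.response_kind, which, eff.estimate,
                     eff.se, eff.t, eff.p, eff.ci_lo, eff.ci_hi)
                )
    return pd.DataFrame(
        rows,
        columns=["strain", "phase", "response", "effect", "estimate", "se", "t", "p",
                 "ci_lo", "ci_hi"],
    )


def read_fusion_events(path) -> list[FusionEvent]:
    """Read a droplet table (event_id, frame, time_s, L_um, W_um)."""
    df = _read_table(path)
    required = {"event_id", "time_s", "L_um", "W_um"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for eid, g in df.groupby("event_id", sort=True):
        g = g.sort_values("time_s")
        events.append(
            FusionEvent(
                event_id=str(eid),
                t=g["time_s"].to_numpy(dtype=float),
                L=g["L_um"].to_numpy(dtype=float),
                W=g["W_um"].to_numpy(dtype=float),
            )
        )
    return events


def read_phase_grid(path) -> PhaseGrid:
    df = _read_table(path)
    required = {"protein_uM", "nacl_mM", "separated"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return PhaseGrid(df[["protein_uM", "nacl_mM", "separated"]])


@dataclass
class PipelineResult:
    segments: pd.DataFrame
    lme_results: pd.DataFrame
    loss: LossSummary | None
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(trajectories: list[Trajectory], config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Annotate all trajectories, fit joint rate models, summarise loss.

    Deterministic given inputs and config; the manifest records the config
    hash, seed and package version so reruns can be verified identical.
    """
    config = config or PipelineConfig()
    annotations = [annotate(tr, config.annotation) for tr in trajectories]
    seg_df = segments_frame(trajectories, annotations)

    fits: list[MixedModelFit] = []
    for response in ("length", "intensity"):
        for phase in ("growth", "shrinkage"):
            partials = []
            for tr, ann in zip(trajectories, annotations):
                partials.extend(
                    p for p in extract_partials(tr, ann, response) if p.phase_kind == phase
                )
            if len(partials) >= 2:
                try:
                    fits.append(fit_lme(partials, response, phase))
                except Exception as exc:  # propagate with stage context
                    raise RuntimeError(f"fit_lme failed for {response}/{phase}: {exc}") from exc
    lme_df = lme_results_frame(fits)

    loss = loss_frequency(trajectories, config.loss_window_s) if trajectories else None
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "n_trajectories": len(trajectories),
        "n_segments": int(len(seg_df)),
    }
    return PipelineResult(seg_df, lme_df, loss, manifest)
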