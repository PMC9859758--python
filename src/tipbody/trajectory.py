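"""Frame-indexed fluorescent-punctum trajectories.

A :class:`Trajectory` holds the per-frame time series measured for one
punctum in one cell: the distance between the punctum and its spindle pole
body (interpreted as microtubule length, in micrometres) and the punctum's
background-subtracted fluorescence intensity (arbitrary units). Missing
measurements are NaN. Simulated trajectories additionally carry the
ground-truth dynamic-instability phase per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROWTH = "growth"
SHRINKAGE = "shrinkage"
INDETERMINATE = "indeterminate"


@dataclass
class Trajectory:
    """Per-frame series for one punctum in one cell of one strain.

    Parameters
    ----------
    cell_id, punctum_id, strain
        Labels identifying the trajectory.
    frame
        0-based, strictly increasing integer frame indices.
    time
        Acquisition time of each frame, seconds.
    length
        Punctum-to-SPB distance per frame, micrometres (NaN = missing).
    intensity
        Punctum intensity per frame, a.u. (NaN = missing, e.g. after loss).
    lost
        True if the punctum was lost during the movie.
    loss_time
        Time (s) of the loss event, if known; None otherwise.
    true_phase
        Simulator ground truth per frame ("growth"/"shrinkage"); None for
        measured data.
    """

    cell_id: str
    punctum_id: str
    strain: str
    frame: np.ndarray
    time: np.ndarray
    length: np.ndarray
    intensity: np.ndarray
    lost: bool = False
    loss_time: float | None = None
    true_phase: np.ndarray | None = field(default=None, repr=False)
    #: simulator-only continuous-time phase log: list of (t_start, t_end, phase)
    true_phase_log: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.frame)
        if not (len(self.time) == len(self.length) == len(self.intensity) == n):
            raise ValueError("frame/time/length/intensity must have equal length")
        if n and np.any(np.diff(self.frame) <= 0):
            raise ValueError("frames must be strictly increasing")

    @property
    def key(self) -> str:
        return f"{self.cell_id}/{self.punctum_id}"

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def dt(self) -> float:
        """Median frame interval in seconds."""
        if self.n_frames < 2:
            return float("nan")
        return float(np.median(np.diff(self.time)))
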