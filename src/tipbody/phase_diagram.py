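"""Approximate binodal construction from phase-separation screens.

A screen tests a grid of protein concentration x salt conditions and scores
each well as phase-separated or soluble. The approximate binodal boundary
is drawn through the midpoints between the highest-salt separated condition
and the next tested salt at each protein concentration; concentrations
whose wells are all separated (or all soluble) are censored above (below)
the tested salt range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

CENSORED_NONE = "none"
CENSORED_ABOVE = "above_max"
CENSORED_BELOW = "below_min"


@dataclass
class PhaseGrid:
    """Boolean phase-separation calls on a (concentration, salt) grid.

    Wraps a DataFrame with columns ``protein_uM`` (concentration of each
    component in the equimolar mixture), ``nacl_mM`` and ``separated``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein_uM", "nacl_mM", "separated"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phase grid missing columns: {sorted(missing)}")
        if self.data.duplicated(["protein_uM", "nacl_mM"]).any():
            raise ValueError("duplicate (concentration, salt) entries")
        self.data = self.data.copy()
        self.data["separated"] = self.data["separated"].astype(bool)

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["protein_uM"].unique())

    @property
    def salts(self) -> np.ndarray:
        return np.sort(self.data["nacl_mM"].unique())


@dataclass
class BinodalPoint:
    protein_uM: float
    boundary_salt_mM: float  # nan when censored
    censored: str = CENSORED_NONE


@dataclass
class Binodal:
    """Midpoint boundary polyline of one phase diagram."""

    points: list[BinodalPoint]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.protein_uM, p.boundary_salt_mM, p.censored) for p in self.points],
            columns=["protein_uM", "boundary_salt_mM", "censored"],
        )

    def boundary_at(self, conc: float) -> BinodalPoint | None:
        for p in self.points:
            if np.isclose(p.protein_uM, conc):
                return p
        return None


def binodal_from_grid(grid: PhaseGrid) -> Binodal:
    """Construct the approximate binodal of a phase grid.

    Per concentration: take the contiguous separated block starting at the
    lowest tested salt; the boundary is the arithmetic midpoint between the
    block's highest salt and the next tested salt. All wells separated ->
    censored above the tested range; none separated (at the lowest salt) ->
    censored below. Separation reappearing at higher salt (non-monotonic,
    possible with scoring noise) triggers a warning and is ignored in
    favour of the lowest-salt block.
    """
    points = []
    for conc in grid.concentrations:
        col = grid.data[grid.data["protein_uM"] == conc].sort_values("nacl_mM")
        salts = col["nacl_mM"].to_numpy()
        sep = col["separated"].to_numpy()
        if len(salts) < 2:
            warnings.warn(
                f"concentration {conc} tested at fewer than 2 salts; skipped", stacklevel=2
            )
            continue
        first_sep = np.nonzero(sep)[0]
        if len(first_sep) == 0:
            points.append(BinodalPoint(float(conc), float("nan"), CENSORED_BELOW))
            continue
        if not sep[0]:
            # separated somewhere but not at the lowest salt: treat as below-range
            # boundary is between lowest salt and 0? Paper's direction is
            # separation at low salt; warn and report censored below.
            warnings.warn(
                f"concentration {conc}: no separation at lowest salt but separation "
                "at higher salt (non-monotonic column)",
                stacklevel=2,
            )
            points.append(BinodalPoint(float(conc), float("nan"), CENSORED_BELOW))
            continue
        # contiguous block from the lowest salt
        block_end = 0
        while block_end + 1 < len(sep) and sep[block_end + 1]:
            block_end += 1
        if block_end + 1 < len(sep) and sep[block_end + 1 :].any():
            warnings.warn(
                f"concentration {conc}: separation reappears at higher salt; using the "
                "lowest-salt contiguous block",
                stacklevel=2,
            )
        if block_end == len(sep) - 1:
            points.append(BinodalPoint(float(conc), float("nan"), CENSORED_ABOVE))
            continue
        mid = (salts[block_end] + salts[block_end + 1]) / 2.0
        points.append(BinodalPoint(float(conc), float(mid), CENSORED_NONE))
    return Binodal(points)


def critical_concentration(grid: PhaseGrid, salt: float) -> tuple[float | None, float | None]:
    """Bracketing concentrations of the phase-separation onset at one salt.

    Scanning upward in concentration at the given salt, returns (highest
    soluble concentration, lowest separated concentration). A missing side
    of the bracket is None (censored: all separated or all soluble).
    """
    col = grid.data[np.isclose(grid.data["nacl_mM"], salt)].sort_values("protein_uM")
    if len(col) < 2:
        raise ValueError(f"need >= 2 concentrations tested at salt {salt}")
    concs = col["protein_uM"].to_numpy()
    sep = col["separated"].to_numpy()
    if sep.all():
        return None, float(concs[0])
    if not sep.any():
        return float(concs[-1]), None
    first_sep = int(np.nonzero(sep)[0][0])
    if first_sep == 0:
        return None, float(concs[0])
    if not np.all(sep[first_sep:]):
        warnings.warn(
            f"non-monotonic separation in concentration at salt {salt}; "
            "reporting the first transition",
            stacklevel=2,
        )
    return float(concs[first_sep - 1]), float(concs[first_sep])


def compare_binodals(a: Binodal, b: Binodal) -> pd.DataFrame:
    """Per-concentration boundary differences a - b (mM), with censoring
    propagated (a censored side yields a NaN difference)."""
    fa, fb = a.as_frame(), b.as_frame()
    merged = fa.merge(fb, on="protein_uM", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("binodals share no concentrations")
    diff = merged["boundary_salt_mM_a"] - merged["boundary_salt_mM_b"]
    censored = (merged["censored_a"] != CENSORED_NONE) | (merged["censored_b"] != CENSORED_NONE)
    return pd.DataFrame(
        {
            "protein_uM": merged["protein_uM"],
            "difference_mM": np.where(censored, np.nan, diff),
            "censored": censored,
        }
    )
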