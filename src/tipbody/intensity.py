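"""Punctum-intensity statistics and the study's significance tests.

Covers the asymmetry index of a fluorescent protein's distribution across
the two spindle sides, cumulative intensity, punctum-loss frequency with
Wilson binomial confidence intervals, fluorescence stoichiometry
calibration against a reference complex of known copy number, exposure-time
intensity scaling, Welch's t-test and the two-proportion z-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from tipbody.trajectory import Trajectory


@dataclass
class SpindleIntensityPair:
    """Background-subtracted integrated densities on the two spindle sides."""

    I_bud: float
    I_mother: float

    def __post_init__(self) -> None:
        if self.I_bud < 0 or self.I_mother < 0:
            raise ValueError("intensities must be non-negative")


@dataclass
class StoichiometryCalibration:
    """Single-molecule brilliance from a reference punctum of known copy number.

    ``ref_punctum_intensity`` is the aggregate intensity of a reference
    structure containing ``n_sites * copies_per_site`` fluorophore-tagged
    molecules (e.g. a kinetochore cluster); ``brilliance`` is intensity per
    molecule.
    """

    ref_punctum_intensity: float
    n_sites: int
    copies_per_site: int

    def __post_init__(self) -> None:
        if min(self.ref_punctum_intensity, self.n_sites, self.copies_per_site) <= 0:
            raise ValueError("all calibration inputs must be positive")

    @property
    def brilliance(self) -> float:
        return self.ref_punctum_intensity / (self.n_sites * self.copies_per_site)


@dataclass
class LossSummary:
    """Punctum-loss frequency over an observation window, with Wilson CI."""

    n_lost: int
    n_total: int
    window: float
    fraction: float
    ci_lo: float
    ci_hi: float


def asymmetry_index(pair: SpindleIntensityPair) -> float:
    """|I_bud - I_mother| / (I_bud + I_mother), in [0, 1].

    0 means a perfectly symmetric distribution, 1 fully one-sided; the
    index is symmetric in its arguments and invariant under joint scaling.
    """
    total = pair.I_bud + pair.I_mother
    if total <= 0:
        raise ValueError("asymmetry index undefined for zero total intensity")
    return abs(pair.I_bud - pair.I_mother) / total


def cumulative_intensity(pair: SpindleIntensityPair) -> float:
    """Sum of intensities on both spindle sides."""
    return pair.I_bud + pair.I_mother


def brilliance_per_molecule(
    ref_punctum_intensity: float, n_sites: int, copies_per_site: int
) -> float:
    """Intensity of a single fluorophore-tagged molecule (a.u./molecule)."""
    return StoichiometryCalibration(ref_punctum_intensity, n_sites, copies_per_site).brilliance


def molecule_count(punctum_intensity: float, brilliance: float) -> float:
    """Number of molecules in a punctum given per-molecule brilliance."""
    if brilliance <= 0:
        raise ValueError("brilliance must be positive")
    return punctum_intensity / brilliance


def exposure_scale_factor(reference_ms: float, measured_ms: float) -> float:
    """Multiplicative factor bringing an intensity measured at
    ``measured_ms`` exposure onto the ``reference_ms`` exposure scale."""
    if reference_ms <= 0 or measured_ms <= 0:
        raise ValueError("exposure times must be positive")
    return reference_ms / measured_ms


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1 or not (0 <= successes <= n):
        raise ValueError("need 0 <= successes <= n and n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    lo = 0.0 if successes == 0 else max(float(lo), 0.0)
    hi = 1.0 if successes == n else min(float(hi), 1.0)
    return lo, hi


def loss_frequency(trajectories: Iterable[Trajectory], window_s: float) -> LossSummary:
    """Fraction of trajectories losing their punctum within the window.

    A trajectory counts as lost if its lost flag is set and the loss time
    (when known) falls inside ``window_s``. The 95% CI is the Wilson score
    interval.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories given")
    n_lost = sum(
        1
        for t in trajs
        if t.lost and (t.loss_time is None or t.loss_time <= window_s)
    )
    n = len(trajs)
    lo, hi = wilson_ci(n_lost, n)
    return LossSummary(n_lost, n, window_s, n_lost / n, lo, hi)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-tailed two-proportion z-test with pooled standard error.

    Degenerate pooled proportions of exactly 0 or 1 (no variability) return
    z = 0, p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed Welch's t-test; returns (t, Welch-Satterthwaite df, p).

    Both samples of zero variance are handled degenerately: equal means
    give t = 0, p = 1; unequal means give infinite t, p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
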