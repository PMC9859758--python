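"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure of the measured data the
analysis assumes: microtubule dynamic instability with catastrophes and
rescues sampled as exponential waiting times, phase-dependent punctum
intensity drift with stochastic punctum loss, area-conserving droplet
coalescence with exponential aspect-parameter relaxation (tau proportional
to the final radius), phase-separation screens on a concentration x salt
grid, and bud/mother spindle intensity pairs with a prescribed asymmetry
index.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from tipbody.droplets import FusionEvent, axes_from_aspect
from tipbody.phase_diagram import PhaseGrid
from tipbody.trajectory import GROWTH, SHRINKAGE, Trajectory


@dataclass
class MtSimParams:
    """Dynamic-instability simulation parameters.

    Growth and shrinkage speeds are in um/s; catastrophe (growth->shrinkage)
    and rescue (shrinkage->growth) frequencies in 1/s. ``len_noise_sd`` is
    additive Gaussian measurement noise on the recorded length (um). The
    default frame interval of 3.5 s and 50 frames match a typical plus-end
    tracking movie. When ``reflect_at_zero`` is set (default), a microtubule
    shrinking to zero length immediately restarts a growth phase, emulating
    punctum re-assembly next to the spindle pole body.
    """

    v_growth: float = 0.02
    v_shrink: float = 0.02
    f_cat: float = 0.01
    f_res: float = 0.01
    len_noise_sd: float = 0.0
    n_frames: int = 50
    dt: float = 3.5
    init_length: float = 0.5
    seed: int = 0
    reflect_at_zero: bool = True

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("v_growth", "v_shrink", "f_cat", "f_res", "len_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.init_length < 0:
            raise ValueError("init_length must be non-negative")


@dataclass
class IntensitySimParams:
    """Punctum-intensity simulation parameters.

    Intensity drifts linearly at ``drift_growth`` (a.u./s) during growth and
    ``drift_shrink`` during shrinkage, with additive Gaussian noise per
    frame. During shrinkage the punctum is lost with hazard
    ``loss_hazard_shrink`` (1/s); after a loss event the intensity record is
    missing (NaN) and the trajectory carries a lost flag.
    """

    base_intensity: float = 200.0
    drift_growth: float = 0.2
    drift_shrink: float = -0.4
    noise_sd: float = 10.0
    loss_hazard_shrink: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.loss_hazard_shrink < 0:
            raise ValueError("loss_hazard_shrink must be non-negative")


@dataclass
class FusionSimParams:
    """Droplet-coalescence simulation parameters.

    Two equal parent droplets of radius ``parent_radius`` (um) coalesce; the
    final radius conserves cross-sectional area, R = sqrt(2) * parent_radius.
    The aspect parameter A = (L - W)/(L + W) relaxes as A0 * exp(-t/tau)
    with tau = capillary_slope * R (inverse capillary velocity in s/um).
    Gaussian noise of sd ``shape_noise_sd`` (um) is added independently to
    the major and minor axes.
    """

    parent_radius: float = 1.0
    capillary_slope: float = 11.34
    A0: float = 0.5
    shape_noise_sd: float = 0.0
    n_frames: int = 60
    dt: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.A0 < 1):
            raise ValueError("A0 must lie in (0, 1)")
        if self.capillary_slope <= 0:
            raise ValueError("capillary_slope must be positive")
        if self.parent_radius <= 0:
            raise ValueError("parent_radius must be positive")
        if self.n_frames < 2 or self.dt <= 0:
            raise ValueError("need n_frames >= 2 and dt > 0")


def _exp_wait(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


def simulate_trajectory(
    mt: MtSimParams,
    inten: IntensitySimParams,
    cell_id: str = "cell0",
    punctum_id: str = "p0",
    strain: str = "wt",
) -> Trajectory:
    """Simulate one punctum trajectory under dynamic instability.

    The microtubule alternates between growth (speed ``v_growth``) and
    shrinkage (speed ``v_shrink``); switches follow exponential waiting
    times with rates ``f_cat`` and ``f_res``. Length is recorded at frame
    times with additive noise; intensity follows the phase-dependent drift
    of ``inten`` until an optional loss event truncates it.
    """
    mt.validate()
    inten.validate()
    rng = np.random.default_rng(mt.seed)
    rng_i = np.random.default_rng((inten.seed, mt.seed))

    times = np.arange(mt.n_frames) * mt.dt
    t_end = times[-1]
    speeds = {GROWTH: mt.v_growth, SHRINKAGE: -mt.v_shrink}
    rates = {GROWTH: mt.f_cat, SHRINKAGE: mt.f_res}

    # Event-driven pass: build the piecewise-linear true length and the
    # phase at every instant, then sample at frame times.
    seg_t = [0.0]
    seg_len = [mt.init_length]
    seg_phase: list[str] = []
    t, length, phase = 0.0, mt.init_length, GROWTH
    shrink_intervals: list[tuple[float, float]] = []
    while t < t_end:
        wait = _exp_wait(rng, rates[phase])
        t_next = min(t + wait, t_end)
        v = speeds[phase]
        if phase == SHRINKAGE and v < 0 and length + v * (t_next - t) < 0:
            # hits zero before the next switch
            t_hit = t + length / mt.v_shrink
            shrink_intervals.append((t, t_hit))
            seg_t.append(t_hit)
            seg_len.append(0.0)
            seg_phase.append(phase)
            t, length = t_hit, 0.0
            phase = GROWTH if mt.reflect_at_zero else SHRINKAGE
            if not mt.reflect_at_zero:
                # stay at zero until the rescue fires
                t_resc = min(t + _exp_wait(rng, mt.f_res), t_end)
                seg_t.append(t_resc)
                seg_len.append(0.0)
                seg_phase.append(SHRINKAGE)
                t, phase = t_resc, GROWTH
            continue
        if phase == SHRINKAGE:
            shrink_intervals.append((t, t_next))
        length = length + v * (t_next - t)
        seg_t.append(t_next)
        seg_len.append(length)
        seg_phase.append(phase)
        t = t_next
        phase = SHRINKAGE if phase == GROWTH else GROWTH

    seg_t_arr = np.array(seg_t)
    true_len = np.interp(times, seg_t_arr, np.array(seg_len))
    # phase at a frame time = phase of the segment covering it
    idx = np.clip(np.searchsorted(seg_t_arr, times, side="right") - 1, 0, len(seg_phase) - 1)
    true_phase = np.array([seg_phase[i] for i in idx])

    noise = rng.normal(0.0, mt.len_noise_sd, size=mt.n_frames) if mt.len_noise_sd > 0 else 0.0
    obs_len = np.maximum(true_len + noise, 0.0)

    # intensity: integrate phase-dependent drift along the phase path
    drift = {GROWTH: inten.drift_growth, SHRINKAGE: inten.drift_shrink}
    inten_breaks = [0.0]
    inten_vals = [inten.base_intensity]
    for a, b, ph in zip(seg_t[:-1], seg_t[1:], seg_phase):
        inten_breaks.append(b)
        inten_vals.append(max(inten_vals[-1] + drift[ph] * (b - a), 0.0))
    true_inten = np.interp(times, np.array(inten_breaks), np.array(inten_vals))
    obs_inten = true_inten + (
        rng_i.normal(0.0, inten.noise_sd, size=mt.n_frames) if inten.noise_sd > 0 else 0.0
    )
    obs_inten = np.maximum(obs_inten, 0.0)

    lost = False
    loss_time: float | None = None
    if inten.loss_hazard_shrink > 0:
        for a, b in shrink_intervals:
            w = rng_i.exponential(1.0 / inten.loss_hazard_shrink)
            if a + w < b:
                lost, loss_time = True, a + w
                break
    if lost and loss_time is not None:
        obs_inten[times > loss_time] = np.nan

    return Trajectory(
        cell_id=cell_id,
        punctum_id=punctum_id,
        strain=strain,
        frame=np.arange(mt.n_frames),
        time=times,
        length=obs_len,
        intensity=obs_inten,
        lost=lost,
        loss_time=loss_time,
        true_phase=true_phase,
        true_phase_log=[(a, b, ph) for a, b, ph in zip(seg_t[:-1], seg_t[1:], seg_phase)],
    )


def simulate_fusion_event(p: FusionSimParams, event_id: str = "event0") -> FusionEvent:
    """Simulate one droplet-coalescence event.

    Per frame the aspect parameter A(t) = A0 * exp(-t/tau) is inverted,
    together with the area constraint L * W = 4 R^2, into major/minor axes
    (L, W); independent Gaussian noise is then added to both axes.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    R = math.sqrt(2.0) * p.parent_radius
    tau = p.capillary_slope * R
    t = np.arange(p.n_frames) * p.dt
    A = p.A0 * np.exp(-t / tau)
    L, W = axes_from_aspect(A, R)
    if p.shape_noise_sd > 0:
        L = L + rng.normal(0.0, p.shape_noise_sd, size=p.n_frames)
        W = W + rng.normal(0.0, p.shape_noise_sd, size=p.n_frames)
        eps = 1e-9
        L = np.maximum(L, eps)
        W = np.minimum(np.maximum(W, eps), L)
    return FusionEvent(event_id=event_id, t=t, L=L, W=W, true_tau=tau, true_R=R, true_A0=p.A0)


def tabulated_binodal(conc: Sequence[float], salt: Sequence[float]) -> Callable[[float], float]:
    """Monotone tabulated boundary salt(conc), linearly interpolated and
    clamped at the table's ends."""
    c = np.asarray(conc, dtype=float)
    s = np.asarray(salt, dtype=float)
    order = np.argsort(c)
    c, s = c[order], s[order]
    return lambda x: float(np.interp(x, c, s))


def simulate_phase_grid(
    binodal_salt_of_conc: Callable[[float], float],
    conc_list: Iterable[float],
    salt_list: Iterable[float],
    flip_prob: float = 0.0,
    seed: int = 0,
) -> PhaseGrid:
    """Simulate a phase-separation screen on a concentration x salt grid.

    A well phase-separates iff its salt lies below the boundary at its
    protein concentration; each call is then flipped independently with
    probability ``flip_prob`` to emulate scoring noise.
    """
    if not (0.0 <= flip_prob <= 1.0):
        raise ValueError("flip_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc_list:
        boundary = binodal_salt_of_conc(c)
        for s in salt_list:
            separated = s < boundary
            if rng.random() < flip_prob:
                separated = not separated
            rows.append((float(c), float(s), bool(separated)))
    df = pd.DataFrame(rows, columns=["protein_uM", "nacl_mM", "separated"])
    return PhaseGrid(df)


def simulate_spindle_intensities(
    n_cells: int,
    asym_level: float,
    total_intensity_mean: float = 400.0,
    total_intensity_sd: float = 50.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate bud/mother spindle-side intensity pairs.

    The background-subtracted, noiseless asymmetry index
    |I_bud - I_mother| / (I_bud + I_mother) of every pair equals
    ``asym_level``; which side carries the larger share is random. Returned
    intensities include the background; the ``background`` column records
    the amount to subtract.
    """
    if not (0.0 <= asym_level <= 1.0):
        raise ValueError("asym_level must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    total = np.maximum(rng.normal(total_intensity_mean, total_intensity_sd, n_cells), 1e-6)
    hi = total * (1.0 + asym_level) / 2.0
    lo = total * (1.0 - asym_level) / 2.0
    bud_is_hi = rng.random(n_cells) < 0.5
    bud = np.where(bud_is_hi, hi, lo)
    mother = np.where(bud_is_hi, lo, hi)
    if noise_sd > 0:
        bud = bud + rng.normal(0.0, noise_sd, n_cells)
        mother = mother + rng.normal(0.0, noise_sd, n_cells)
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(n_cells)],
            "I_bud": np.maximum(bud, 0.0) + background,
            "I_mother": np.maximum(mother, 0.0) + background,
            "background": background,
        }
    )
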