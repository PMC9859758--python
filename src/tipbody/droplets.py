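"""Condensate fluidity quantification from droplet-coalescence movies.

When two liquid droplets coalesce, the fused droplet relaxes from an
elongated to a spherical shape. The aspect parameter A = (L - W)/(L + W)
of the deformed droplet (L, W: major and minor ellipse axes) decays
exponentially with characteristic fusion time tau; across droplets of
different sizes tau grows linearly with the final radius R, and the slope
tau/R — the inverse capillary velocity — is proportional to the ratio of
condensed-phase viscosity to surface tension, tau/R = (19/20) eta_int/gamma
in the high-internal-viscosity limit of the two-fluid Navier-Stokes
relaxation time. The module also provides FRAP bleaching/defocus
normalisation against reference droplets, partition coefficients, and
ellipse-axis extraction from binary masks.

Internal unit convention: micrometres, seconds, Pa*s and N/m; inverse
capillary velocities are reported in s/um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage import measure


@dataclass
class FusionEvent:
    """Major/minor ellipse axes of one coalescing droplet over time."""

    event_id: str
    t: np.ndarray  # s, strictly increasing
    L: np.ndarray  # um, major axis
    W: np.ndarray  # um, minor axis
    true_tau: float | None = None
    true_R: float | None = None
    true_A0: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if not (len(self.t) == len(self.L) == len(self.W)):
            raise ValueError("t, L, W must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def aspect_series(self) -> np.ndarray:
        return aspect_parameter(self.L, self.W)


@dataclass
class FusionFit:
    """Exponential relaxation fit of one fusion event."""

    event_id: str
    A0: float
    tau: float  # s
    R: float  # um, final spherical radius
    residual: float
    n_frames: int
    ok: bool = True
    message: str = ""


@dataclass
class HydrodynamicParams:
    """Viscosities and surface tension entering the relaxation-time formulas."""

    eta_int: float  # Pa*s, condensed phase
    eta_ext: float  # Pa*s, dilute phase
    gamma: float  # N/m, surface tension

    def __post_init__(self) -> None:
        if min(self.eta_int, self.eta_ext, self.gamma) <= 0:
            raise ValueError("viscosities and surface tension must be positive")

    @property
    def lam(self) -> float:
        """Viscosity ratio eta_int / eta_ext."""
        return self.eta_int / self.eta_ext


@dataclass
class CapillaryFit:
    """Origin-constrained linear fit of fusion time vs final radius."""

    slope: float  # s/um, inverse capillary velocity
    stderr: float  # nan when undefined (single droplet)
    n_droplets: int


def aspect_parameter(L, W):
    """Aspect parameter (L - W)/(L + W) of a deformed droplet, in [0, 1)."""
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0) or np.any(L < W):
        raise ValueError("require L >= W > 0")
    out = (L - W) / (L + W)
    return float(out) if out.ndim == 0 else out


def axes_from_aspect(A, R):
    """Invert the aspect parameter at fixed cross-sectional area.

    Solves (L - W)/(L + W) = A together with L * W = 4 R^2 (the area of the
    relaxed droplet of radius R): L = 2R sqrt((1+A)/(1-A)), W = 4R^2/L.
    Exact inverse of :func:`aspect_parameter`.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or np.any(A >= 1):
        raise ValueError("A must lie in [0, 1)")
    s = np.sqrt((1.0 + A) / (1.0 - A))
    L = 2.0 * R * s
    W = 2.0 * R / s
    return L, W


def fit_fusion_time(event: FusionEvent, relaxed_threshold: float = 0.05) -> FusionFit:
    """Fit A(t) = A0 * exp(-t / tau) to one fusion event.

    The final radius R is the mean of (L + W)/4 over the last 10% of frames
    where A < ``relaxed_threshold``; if relaxation is incomplete, R falls
    back to the mean of sqrt(L * W)/2 over the last 10% of frames (the
    area-equivalent radius). Non-decaying events are returned with
    ``ok=False`` and are excluded from downstream slope fits.
    """
    n = len(event.t)
    if n < 5:
        return FusionFit(event.event_id, np.nan, np.nan, np.nan, np.nan, n, False,
                         "need >= 5 frames")
    A = event.aspect_series()
    t = event.t - event.t[0]
    if np.ptp(A) <= 0 or A[0] <= 0:
        return FusionFit(event.event_id, np.nan, np.nan, np.nan, np.nan, n, False,
                         "aspect series does not decay")
    # log-linear start values on the positive part of the series
    pos = A > 0
    slope0 = np.polyfit(t[pos], np.log(A[pos]), 1)[0]
    tau0 = -1.0 / slope0 if slope0 < 0 else t[-1] / 2
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda tt, a0, tau: a0 * np.exp(-tt / tau),
                t, A, p0=[max(A[0], 1e-3), max(tau0, 1e-6)], maxfev=10000,
            )
    except RuntimeError as exc:
        return FusionFit(event.event_id, np.nan, np.nan, np.nan, np.nan, n, False, str(exc))
    A0_hat, tau_hat = float(popt[0]), float(popt[1])
    if tau_hat <= 0 or not np.isfinite(tau_hat):
        return FusionFit(event.event_id, A0_hat, tau_hat, np.nan, np.nan, n, False,
                         "fitted tau not positive")
    resid = float(np.sum((A - A0_hat * np.exp(-t / tau_hat)) ** 2))

    n_tail = max(int(np.ceil(0.1 * n)), 1)
    relaxed = np.nonzero(A < relaxed_threshold)[0]
    if len(relaxed) >= n_tail:
        idx = relaxed[-n_tail:]
        R = float(np.mean((event.L[idx] + event.W[idx]) / 4.0))
    else:
        idx = np.arange(n - n_tail, n)
        R = float(np.mean(np.sqrt(event.L[idx] * event.W[idx]) / 2.0))
    return FusionFit(event.event_id, A0_hat, tau_hat, R, resid, n, True)


def fit_capillary_slope(fits: list[FusionFit]) -> CapillaryFit:
    """Inverse capillary velocity: least squares of tau on R through the origin.

    Physically tau(0) = 0, so the regression is origin-constrained:
    slope = sum(tau * R) / sum(R^2), equivalently the R^2-weighted mean of
    tau/R. The standard error is the usual one-parameter regression SE
    (undefined for a single droplet).
    """
    good = [f for f in fits if f.ok and np.isfinite(f.tau) and np.isfinite(f.R)]
    if not good:
        raise ValueError("no successful fusion fits")
    R = np.array([f.R for f in good])
    tau = np.array([f.tau for f in good])
    slope = float(np.sum(tau * R) / np.sum(R * R))
    n = len(good)
    if n < 2:
        return CapillaryFit(slope, float("nan"), n)
    resid = tau - slope * R
    se = float(np.sqrt(np.sum(resid**2) / (n - 1) / np.sum(R * R)))
    return CapillaryFit(slope, se, n)


def eq1_fusion_time(h: HydrodynamicParams, R_um: float, const: float = 16.0) -> float:
    """Two-fluid droplet relaxation time, full viscosity-ratio form.

    tau = [(2 lam + 3)(19 lam + c) / (40 (lam + 1))] * eta_ext * R / gamma
    with lam = eta_int/eta_ext and c = 16 by default, the value for which
    the lam -> infinity limit reproduces the simplified (19/20) eta_int R /
    gamma form. R in um, result in seconds.
    """
    lam = h.lam
    pref = (2 * lam + 3) * (19 * lam + const) / (40 * (lam + 1))
    return pref * h.eta_ext * (R_um * 1e-6) / h.gamma


def eq2_fusion_time(eta_int: float, R_um: float, gamma: float) -> float:
    """Simplified relaxation time tau = (19/20) eta_int R / gamma, valid when
    the condensed phase is far more viscous than the dilute phase."""
    if eta_int <= 0 or gamma <= 0 or R_um <= 0:
        raise ValueError("inputs must be positive")
    return 0.95 * eta_int * (R_um * 1e-6) / gamma


def inverse_capillary_velocity(eta_int: float, gamma: float) -> float:
    """Predicted tau/R slope (19/20) eta_int / gamma, in s/um."""
    if eta_int <= 0 or gamma <= 0:
        raise ValueError("inputs must be positive")
    return 0.95 * eta_int / gamma * 1e-6


def ellipse_axes_from_mask(mask: np.ndarray) -> tuple[float, float]:
    """Major/minor axes (pixels) of the moment-equivalent ellipse of a mask.

    The mask must contain exactly one connected foreground region; axes come
    from the second central moments of the region.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    if len(props) != 1:
        raise ValueError(f"expected one connected region, found {len(props)}")
    p = props[0]
    return float(p.axis_major_length), float(p.axis_minor_length)


def frap_normalize(
    target: np.ndarray,
    references: list[np.ndarray] | np.ndarray,
    bleach_frame: int,
    background: float = 0.0,
) -> np.ndarray:
    """Reference-droplet bleaching/defocus correction of a FRAP trace.

    All traces are background-subtracted; each unbleached reference is
    normalised to its own pre-bleach mean; the target is divided by the
    per-frame average of the normalised references and finally normalised
    to its own (corrected) pre-bleach mean, so a full recovery plateaus
    at 1.
    """
    tgt = np.asarray(target, dtype=float) - background
    refs = np.atleast_2d(np.asarray(references, dtype=float)) - background
    if refs.shape[1] != len(tgt):
        raise ValueError("target and references must share the time base")
    if bleach_frame < 1 or bleach_frame > len(tgt):
        raise ValueError("no pre-bleach frames")
    pre = slice(0, bleach_frame)
    ref_pre = refs[:, pre].mean(axis=1)
    if np.any(ref_pre <= 0):
        raise ValueError("zero or negative reference pre-bleach intensity")
    ref_norm = refs / ref_pre[:, None]
    ref_avg = ref_norm.mean(axis=0)
    if np.any(ref_avg <= 0):
        raise ValueError("zero reference intensity at some frame")
    corrected = tgt / ref_avg
    pre_mean = corrected[pre].mean()
    if pre_mean <= 0:
        raise ValueError("non-positive target pre-bleach intensity")
    return corrected / pre_mean


def partition_coefficient(
    inside_density: float, outside_density: float, background_density: float = 0.0
) -> float:
    """Background-subtracted inside/outside density ratio of a droplet.

    The background is the signal of the unlabelled protein mixture; the
    convention is that it is subtracted from both densities before taking
    the ratio.
    """
    denom = outside_density - background_density
    if denom <= 0:
        raise ValueError("outside density must exceed background (enrichment unquantifiable)")
    return (inside_density - background_density) / denom
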