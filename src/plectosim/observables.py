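"""Measurements and reference curves.

Covers: degree-of-freedom counting, kinetic-energy equipartition and
Boltzmann (Gamma-law) statistics, autocorrelation and relaxation times,
tangent-tangent correlation and persistence-length fits, twist/writhe and
overtwist bookkeeping, FJC/WLC reference force-extension curves, hat-curve
slopes and supercoil geometry, buckling two-state statistics, critical
torque and the plectonemic affine torque law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import optimize, stats
from statsmodels.tsa.stattools import acf as _sm_acf

from .constraint_dynamics import JointSet, _ROWS
from .dna_elasticity import langevin
from .model_state import ChainState, InvalidParameterError

__all__ = [
    "ObservableSeries", "SupercoilGeometry", "count_dof",
    "kinetic_energy_stats", "autocorrelation", "fit_relaxation_time",
    "mean_with_autocorr_se", "tangent_correlation", "fit_persistence_length",
    "twist_writhe", "writhe_polyline", "overtwist", "fjc_extension",
    "wlc_interpolation_force", "wlc_extension", "hat_curve_slope",
    "supercoil_relation", "estimate_plectoneme_geometry", "buckling_analysis",
    "estimate_critical_torque", "fit_affine_torque_law",
]

# Bouchiat et al. seven-coefficient WLC interpolation formula
WLC_COEFFS = (-0.5164228, -2.737418, 16.07497, -38.87607, 39.49944,
              -14.17718)


@dataclass(frozen=True)
class ObservableSeries:
    """Named time series sampled at a fixed stride."""

    name: str
    times: np.ndarray
    values: np.ndarray
    stride: int = 1

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.shape[0] != v.shape[0]:
            raise InvalidParameterError("times and values length mismatch")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass
class SupercoilGeometry:
    """Plectoneme geometry estimate: superhelix radius R, angle alpha."""

    R: float
    alpha: float
    n_pairs: int = 0


# ---------------------------------------------------------------------------
# degrees of freedom, kinetic energy
# ---------------------------------------------------------------------------


def count_dof(joints: JointSet, n_bodies: int) -> int:
    """n_dof = 6 N - m with m the non-redundant permanent constraint rows
    (3 per ball joint, 6 per weld, 3/2 per bead clamp mode)."""
    m = int(sum(_ROWS[int(k)] for k in joints.kind))
    return 6 * n_bodies - m


@dataclass(frozen=True)
class KineticStats:
    mean_ratio: float      # <E> / (n_dof kBT / 2)
    ks_statistic: float
    p_value: float         # GOF vs Gamma(n_dof/2, scale=kBT)
    n_samples: int


def kinetic_energy_stats(ekin, n_dof: int, kBT: float = 1.0) -> KineticStats:
    """Equipartition ratio and goodness of fit against the Boltzmann
    (Gamma) law  p(E) ~ E^(n_dof/2 - 1) exp(-E/kBT)."""
    e = np.asarray(ekin, float)
    if e.size < 10:
        raise InvalidParameterError("series too short for a distribution test")
    ratio = float(np.mean(e) / (0.5 * n_dof * kBT))
    ks = stats.kstest(e, stats.gamma(a=0.5 * n_dof, scale=kBT).cdf)
    return KineticStats(mean_ratio=ratio, ks_statistic=float(ks.statistic),
                        p_value=float(ks.pvalue), n_samples=e.size)


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------


def autocorrelation(series, max_lag: int) -> np.ndarray:
    """Normalized autocovariance c(k), c(0) = 1, for lags 0..max_lag."""
    x = np.asarray(series, float)
    if x.size < 2:
        raise InvalidParameterError("series too short")
    if np.std(x) == 0:
        return np.ones(min(max_lag, x.size - 1) + 1)
    nlag = min(max_lag, x.size - 1)
    half = x.size // 2
    d = abs(np.mean(x[half:]) - np.mean(x[:half]))
    if d > 2.0 * np.std(x):
        warnings.warn("series appears non-stationary", stacklevel=2)
    return _sm_acf(x, nlags=nlag, fft=True)


@dataclass(frozen=True)
class RelaxationFit:
    tau: float
    tau_stderr: float
    n_lags_used: int


def fit_relaxation_time(c: np.ndarray, dt_lag: float = 1.0,
                        c_floor: float = 0.2) -> RelaxationFit:
    """Exponential fit of the initial decay of c(k); tau in units of
    dt_lag (the time between successive lags)."""
    c = np.asarray(c, float)
    k_end = 1
    while k_end < c.size and c[k_end] > c_floor:
        k_end += 1
    k_end = min(max(k_end + 1, 3), c.size)
    lags = np.arange(k_end)
    y = np.log(np.clip(c[:k_end], 1e-12, None))
    A = np.column_stack([lags, np.ones_like(lags)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    if slope >= 0:
        return RelaxationFit(tau=np.inf, tau_stderr=np.inf, n_lags_used=k_end)
    dof = max(k_end - 2, 1)
    resid = y - A @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    tau = -dt_lag / slope
    return RelaxationFit(tau=float(tau),
                         tau_stderr=float(dt_lag * np.sqrt(cov[0, 0])
                                          / slope ** 2),
                         n_lags_used=k_end)


def integrated_autocorr_time(x) -> float:
    """Sokal-style integrated autocorrelation time (in sample strides)."""
    x = np.asarray(x, float)
    if x.size < 8 or np.std(x) == 0:
        return 1.0
    nlag = min(x.size // 4, 2000)
    c = _sm_acf(x, nlags=nlag, fft=True)
    tau = 0.5
    for k in range(1, c.size):
        if c[k] < 0.05:
            break
        tau += c[k]
    return max(float(tau), 0.5)


def mean_with_autocorr_se(x):
    """(mean, autocorrelation-corrected standard error, n_effective)."""
    x = np.asarray(x, float)
    tau = integrated_autocorr_time(x)
    neff = max(x.size / (2.0 * tau), 1.0)
    se = float(np.std(x, ddof=1) / np.sqrt(neff)) if x.size > 1 else np.inf
    return float(np.mean(x)), se, neff


# ---------------------------------------------------------------------------
# tangent correlation / persistence length
# ---------------------------------------------------------------------------


def tangent_correlation(tangents: np.ndarray) -> np.ndarray:
    """<t_i . t_{i+s}> averaged over i and frames.

    ``tangents``: (n_frames, n_cyl, 3) unit tangents.  Returns corr(s),
    s = 0..n_cyl-1; corr(0) = 1 exactly.
    """
    t = np.asarray(tangents, float)
    if t.ndim == 2:
        t = t[None]
    nf, n, _ = t.shape
    out = np.zeros(n)
    counts = np.zeros(n)
    for s in range(n):
        d = np.einsum("fik,fik->fi", t[:, :n - s], t[:, s:])
        out[s] = d.mean()
        counts[s] = d.size
    out[0] = 1.0
    return out


def fit_persistence_length(corr: np.ndarray, b: float = 1.0,
                           corr_floor: float = 0.2) -> float:
    """Persistence length from exp(-s b / l_p) fit of the initial decay."""
    c = np.asarray(corr, float)
    s_end = 1
    while s_end < c.size and c[s_end] > corr_floor:
        s_end += 1
    s_end = min(max(s_end, 3), c.size)
    s = np.arange(s_end)
    y = np.log(np.clip(c[:s_end], 1e-12, None))
    slope = np.polyfit(s, y, 1)[0]
    if slope >= 0:
        return np.inf
    return float(-b / slope)


# ---------------------------------------------------------------------------
# twist / writhe / overtwist
# ---------------------------------------------------------------------------


@njit(cache=True)
def _writhe_pairs(v):
    """Sum of Gauss-integral contributions over all segment pairs of the
    polyline v (exact per-pair solid-angle formula)."""
    n = v.shape[0] - 1
    wr = 0.0
    for i in range(n - 1):
        for j in range(i + 2, n):
            p1 = v[i]
            p2 = v[i + 1]
            p3 = v[j]
            p4 = v[j + 1]
            r13 = p3 - p1
            r14 = p4 - p1
            r23 = p3 - p2
            r24 = p4 - p2
            r12 = p2 - p1
            r34 = p4 - p3
            n1 = np.cross(r13, r14)
            n2 = np.cross(r14, r24)
            n3 = np.cross(r24, r23)
            n4 = np.cross(r23, r13)
            a1 = np.sqrt(n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2)
            a2 = np.sqrt(n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2)
            a3 = np.sqrt(n3[0] ** 2 + n3[1] ** 2 + n3[2] ** 2)
            a4 = np.sqrt(n4[0] ** 2 + n4[1] ** 2 + n4[2] ** 2)
            if a1 < 1e-14 or a2 < 1e-14 or a3 < 1e-14 or a4 < 1e-14:
                continue
            d12 = (n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]) / (a1 * a2)
            d23 = (n2[0] * n3[0] + n2[1] * n3[1] + n2[2] * n3[2]) / (a2 * a3)
            d34 = (n3[0] * n4[0] + n3[1] * n4[1] + n3[2] * n4[2]) / (a3 * a4)
            d41 = (n4[0] * n1[0] + n4[1] * n1[1] + n4[2] * n1[2]) / (a4 * a1)
            if d12 > 1.0:
                d12 = 1.0
            elif d12 < -1.0:
                d12 = -1.0
            if d23 > 1.0:
                d23 = 1.0
            elif d23 < -1.0:
                d23 = -1.0
            if d34 > 1.0:
                d34 = 1.0
            elif d34 < -1.0:
                d34 = -1.0
            if d41 > 1.0:
                d41 = 1.0
            elif d41 < -1.0:
                d41 = -1.0
            omega = (np.arcsin(d12) + np.arcsin(d23) + np.arcsin(d34)
                     + np.arcsin(d41))
            cr = np.cross(r34, r12)
            sgn = cr[0] * r13[0] + cr[1] * r13[1] + cr[2] * r13[2]
            if sgn > 0.0:
                wr += omega
            elif sgn < 0.0:
                wr -= omega
    return wr / (2.0 * np.pi)


def writhe_polyline(vertices: np.ndarray, closure: str = "two-ray",
                    ray_length: float = 1e6) -> float:
    """Writhe of the chain centreline.

    ``closure='two-ray'`` extends the curve by straight rays along -z below
    the first vertex and +z above the last one (the virtual circuit through
    anchor surface and magnets that defines the linking number in a tweezers
    setup); ``closure='none'`` requires an already closed polyline and
    raises otherwise.
    """
    v = np.asarray(vertices, float)
    if closure == "two-ray":
        lo = v[0] + np.array([0.0, 0.0, -ray_length])
        hi = v[-1] + np.array([0.0, 0.0, ray_length])
        v = np.vstack([lo, v, hi])
    elif closure == "none":
        if np.linalg.norm(v[0] - v[-1]) > 1e-9:
            raise InvalidParameterError(
                "open curve: writhe requires the two-ray closure")
    else:
        raise InvalidParameterError(f"unknown closure {closure}")
    return float(_writhe_pairs(np.ascontiguousarray(v)))


def twist_writhe(state: ChainState, tw_cum: np.ndarray):
    """(Tw, Wr): Tw from the unwrapped per-joint twists, Wr from the
    discrete Gauss integral with the two-ray closure."""
    tw = float(np.sum(tw_cum[:state.n_cyl - 1])) / (2.0 * np.pi)
    wr = writhe_polyline(state.vertices())
    return tw, wr


def overtwist(turns: float, Lk0: float) -> float:
    """Relative overtwist sigma = n / Lk0."""
    if Lk0 <= 0:
        raise InvalidParameterError("Lk0 must be positive")
    return turns / Lk0


# ---------------------------------------------------------------------------
# reference force-extension curves
# ---------------------------------------------------------------------------


def fjc_extension(f, b: float = 1.0, kBT: float = 1.0):
    """Freely-jointed chain: z/L0 = L(f b / kBT)."""
    return langevin(np.asarray(f, float) * b / kBT)


def wlc_interpolation_force(z_rel, l_p: float, kBT: float = 1.0):
    """Worm-like chain interpolation formula (seven-coefficient form):

    f l_p / kBT = z - 1/4 + 1/(4 (1-z)^2) + sum_{i=2}^{7} a_i z^i.
    """
    z = np.asarray(z_rel, float)
    if np.any(z >= 1.0) or np.any(z < 0.0):
        raise InvalidParameterError("relative extension must be in [0, 1)")
    poly = np.zeros_like(z)
    for i, a in enumerate(WLC_COEFFS, start=2):
        poly = poly + a * z ** i
    out = (kBT / l_p) * (z - 0.25 + 0.25 / (1.0 - z) ** 2 + poly)
    return out if out.ndim else float(out)


def wlc_extension(f: float, l_p: float, kBT: float = 1.0) -> float:
    """Numerical inverse of the WLC interpolation formula."""
    if f <= 0:
        return 0.0
    return float(optimize.brentq(
        lambda z: wlc_interpolation_force(z, l_p, kBT) - f, 0.0, 1.0 - 1e-9,
        xtol=1e-12))


# ---------------------------------------------------------------------------
# hat curve / supercoil geometry
# ---------------------------------------------------------------------------


def hat_curve_slope(turns, z, min_points: int = 3):
    """Slope q of the linear (post-buckling) branch of a hat curve.

    Uses the longest tail of strictly decreasing z(|n|) points, trimmed to
    the best linear fit; raises if no linear region is present.
    """
    n = np.asarray(turns, float)
    z = np.asarray(z, float)
    order = np.argsort(np.abs(n))
    na, za = np.abs(n)[order], z[order]
    # find start of the monotone decreasing tail
    start = len(na) - 2
    while start > 0 and za[start - 1] > za[start]:
        start -= 1
    if len(na) - start < min_points:
        raise InvalidParameterError("no linear region detected in hat curve")
    sl, ic, *_ = stats.linregress(na[start:], za[start:])
    return float(sl)


def supercoil_relation(R: float, alpha: float, ratio: float = 1.9,
                       rel_ext: float = 1.0) -> float:
    """Hat-curve slope predicted from the supercoil geometry.

    One turn absorbed into a plectoneme of superhelical radius R and angle
    alpha converts 4 pi R / sin(2 alpha) of contour (writhe density
    sin(2 alpha) / (4 pi R)), each unit of which contributed ``rel_ext`` of
    extension, so q = - rel_ext * 4 pi R / sin(2 alpha).  ``ratio``
    (l_t/l_p) influences the equilibrium (R, alpha) but not this geometric
    map; it is accepted for interface symmetry with the inverse estimators.
    """
    if not (0.0 < alpha < 0.5 * np.pi):
        raise InvalidParameterError("alpha must be in (0, pi/2)")
    if R <= 0:
        raise InvalidParameterError("R must be positive")
    return -rel_ext * 4.0 * np.pi * R / np.sin(2.0 * alpha)


def invert_supercoil_relation(q: float, alpha: Optional[float] = None,
                              R: Optional[float] = None,
                              rel_ext: float = 1.0) -> tuple[float, float]:
    """Invert the slope relation for the remaining free parameter.

    The scalar slope q determines only one of (R, alpha); the other must
    be supplied.  Returns (R, alpha).
    """
    if (alpha is None) == (R is None):
        raise InvalidParameterError("supply exactly one of alpha or R")
    if alpha is not None:
        Rv = -q * np.sin(2.0 * alpha) / (4.0 * np.pi * rel_ext)
        return float(Rv), float(alpha)
    s = -4.0 * np.pi * R * rel_ext / q
    if not (0.0 < s <= 1.0):
        raise InvalidParameterError("slope inconsistent with given R")
    return float(R), float(0.5 * np.arcsin(s))


def estimate_plectoneme_geometry(state: ChainState,
                                 contact_scale: float = 2.5
                                 ) -> SupercoilGeometry:
    """(R, alpha) from the geometry of close non-adjacent segment pairs.

    R is half the mean inter-axis distance of plectonemic (nearly
    antiparallel, close) cylinder pairs; alpha is half the mean deviation
    of their crossing angle from pi.  This is a constructed estimator for
    simulated configurations, not a transcription of a published recipe.
    """
    from . import _kernels

    n = state.n_cyl
    R = state.frames()
    t = R[:n, :, 2]
    dists = []
    angles = []
    cut = contact_scale * 2.0 * float(np.mean(state.radius[:n]))
    for i in range(n):
        for j in range(i + 4, n):
            s, u = _kernels.segment_closest_params(
                state.pos[i], np.ascontiguousarray(t[i]),
                state.half_length[i], state.pos[j],
                np.ascontiguousarray(t[j]), state.half_length[j])
            c1 = state.pos[i] + s * t[i]
            c2 = state.pos[j] + u * t[j]
            d = float(np.linalg.norm(c1 - c2))
            if d < cut:
                ct = float(np.clip(np.dot(t[i], t[j]), -1.0, 1.0))
                ang = np.arccos(ct)
                if ang > 0.5 * np.pi:  # antiparallel: plectonemic crossing
                    dists.append(d)
                    angles.append(ang)
    if not dists:
        raise InvalidParameterError("no plectonemic segment pairs found")
    Rm = 0.5 * float(np.mean(dists))
    alpha = 0.5 * float(np.mean(np.pi - np.array(angles)))
    return SupercoilGeometry(R=Rm, alpha=alpha, n_pairs=len(dists))


# ---------------------------------------------------------------------------
# buckling / torque analysis
# ---------------------------------------------------------------------------


@dataclass
class TwoStateStats:
    bimodal: bool
    means: tuple[float, float]
    stds: tuple[float, float]
    dwell_fractions: tuple[float, float]
    correlation_z_sigma: float


def _two_means(x, max_iter=200):
    """Deterministic 1-d two-means clustering (split at moving midpoint)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    m1, m2 = lo, hi
    for _ in range(max_iter):
        cut = 0.5 * (m1 + m2)
        g1 = x[x <= cut]
        g2 = x[x > cut]
        if g1.size == 0 or g2.size == 0:
            break
        n1, n2 = float(np.mean(g1)), float(np.mean(g2))
        if abs(n1 - m1) < 1e-12 and abs(n2 - m2) < 1e-12:
            break
        m1, m2 = n1, n2
    cut = 0.5 * (m1 + m2)
    mask = x > cut
    return m1, m2, mask


def buckling_analysis(z, sigma) -> TwoStateStats:
    """Two-state decomposition of extension/overtwist series near buckling.

    The extension series is split by deterministic two-means clustering;
    bimodality requires the two cluster means to be separated by more than
    the sum of the cluster standard deviations.
    """
    z = np.asarray(z, float)
    s = np.asarray(sigma, float)
    if z.size != s.size or z.size < 10:
        raise InvalidParameterError("series too short or mismatched")
    m1, m2, hi_mask = _two_means(z)
    g1, g2 = z[~hi_mask], z[hi_mask]
    s1 = float(np.std(g1)) if g1.size > 1 else 0.0
    s2 = float(np.std(g2)) if g2.size > 1 else 0.0
    f2 = float(np.mean(hi_mask))
    bimodal = (g1.size > 2 and g2.size > 2
               and (m2 - m1) > (s1 + s2) and min(f2, 1 - f2) > 0.02)
    corr = float(np.corrcoef(z, s)[0, 1]) if np.std(z) > 0 and np.std(s) > 0 \
        else 0.0
    return TwoStateStats(bimodal=bool(bimodal), means=(m1, m2),
                         stds=(s1, s2), dwell_fractions=(1 - f2, f2),
                         correlation_z_sigma=corr)


def estimate_critical_torque(torques, sigma_vars):
    """Critical torque as the variance-maximizing torque of a sweep
    (bistability criterion), with a parabolic refinement and a half-grid
    spacing as the uncertainty."""
    g = np.asarray(torques, float)
    v = np.asarray(sigma_vars, float)
    if g.size < 3:
        raise InvalidParameterError("need at least 3 torques")
    k = int(np.argmax(v))
    if k == 0 or k == g.size - 1:
        warnings.warn("variance maximum at sweep edge: critical torque "
                      "poorly determined", stacklevel=2)
        return float(g[k]), float(np.max(np.abs(np.diff(g))))
    # parabola through the three points around the max
    x = g[k - 1:k + 2]
    y = v[k - 1:k + 2]
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) \
        / denom
    bq = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
          + x[0] ** 2 * (y[1] - y[2])) / denom
    gc = -bq / (2 * a) if a < 0 else g[k]
    return float(gc), float(0.5 * max(abs(x[1] - x[0]), abs(x[2] - x[1])))


def fit_affine_torque_law(sigma, torque, pitch: float = 1.0,
                          kBT: float = 1.0):
    """Fit the plectonemic-regime affine law Gamma = 2 pi kBT (xi_p/p)
    (sigma - sigma*); returns (xi_p, sigma_star)."""
    s = np.asarray(sigma, float)
    g = np.asarray(torque, float)
    if s.size < 2:
        raise InvalidParameterError("need at least 2 points")
    slope, intercept = np.polyfit(s, g, 1)
    xi_p = slope * pitch / (2.0 * np.pi * kBT)
    sigma_star = -intercept / slope
    return float(xi_p), float(sigma_star)
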