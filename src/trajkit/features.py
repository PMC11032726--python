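"""Trajectory descriptors.

Seventeen scalar features quantify a single trajectory: kinematic
quantities built on the time-averaged mean squared displacement (MSD)
and the velocity autocorrelation function (VACF), shape descriptors
derived from the gyration tensor, path-geometry ratios, and a spectral
summary.  Together they embed a trajectory in a feature space where
diffusion modes (sub-, normal, super- and anomalous diffusion) separate.

Conventions used throughout
---------------------------
* ``N`` is the number of sample points, ``d`` the spatial dimension and
  ``dt`` the (uniform) time step.
* The largest MSD/VACF lag is ``n_max = floor(N/4)``; longer lags are
  averaged over too few displacement pairs to be reliable.
* The anomalous exponent ``alpha`` is the log–log slope of the MSD over
  lags ``1..n_max``.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .core import (
    DegenerateTrajectoryError,
    GyrationSpectrum,
    MsdCurve,
    Trajectory,
    TrajkitError,
    Vacf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "msd_time_averaged",
    "msd_ensemble",
    "anomalous_exponent",
    "msd_ratio",
    "gyration_tensor",
    "gyration_radius",
    "asymmetry",
    "anisotropy",
    "kurtosis",
    "fractal_dimension_katz",
    "straightness",
    "efficiency",
    "trappedness",
    "gaussianity",
    "velocity_series",
    "vacf",
    "green_kubo_diffusivity",
    "fourier_dominant_frequency",
    "extract_all_features",
]

#: The public feature vocabulary, alphabetical for stable CSV columns.
FEATURE_NAMES: Tuple[str, ...] = (
    "alpha",
    "anisotropy",
    "asymmetry",
    "d_greenkubo",
    "dominant_frequency",
    "efficiency",
    "fractal_dim",
    "gaussianity",
    "gyration_radius",
    "kurtosis",
    "mean_speed",
    "msd_at_quarter_lag",
    "msd_ratio",
    "msd_slope_diffusivity",
    "straightness",
    "trappedness",
    "vacf_first_lag",
)

# Trappedness constants from the published single-particle-tracking
# feature family; see docs/methods.md.
TRAPPEDNESS_C1 = 0.2048
TRAPPEDNESS_C2 = 0.25117


def _max_lag(n_points: int) -> int:
    """Largest usable lag index: floor(N/4), at least 1."""
    return max(1, n_points // 4)


# ---------------------------------------------------------------------------
# Mean squared displacement


def msd_time_averaged(traj: Trajectory, n_max: Optional[int] = None) -> MsdCurve:
    """Time-averaged MSD over all time origins.

    ``MSD(n dt) = (1/(N-n)) sum_i |x_{i+n} - x_i|^2`` for lags
    ``n = 1..n_max`` (default ``floor(N/4)``).  Requires a uniform time
    step and ``N >= 3``.
    """
    if traj.n_points < 3:
        raise DegenerateTrajectoryError("time-averaged MSD needs at least 3 points")
    dt = traj.uniform_dt()
    x = traj.positions
    N = traj.n_points
    if n_max is None:
        n_max = _max_lag(N)
    n_max = min(n_max, N - 1)
    vals = np.empty(n_max)
    for n in range(1, n_max + 1):
        disp = x[n:] - x[:-n]
        vals[n - 1] = np.mean(np.einsum("ij,ij->i", disp, disp))
    lags = dt * np.arange(1, n_max + 1)
    return MsdCurve(lags=lags, values=vals)


def msd_ensemble(trajs: list[Trajectory]) -> MsdCurve:
    """Ensemble MSD: mean over trajectories of ``|x_n - x_0|^2``.

    All trajectories must share the same time step; each is referenced
    to its own starting point.  The curve extends to the shortest
    trajectory's last frame.
    """
    if not trajs:
        raise DegenerateTrajectoryError("empty trajectory list")
    dts = [t.uniform_dt() for t in trajs]
    dt = dts[0]
    if any(abs(d - dt) > 1e-9 * abs(dt) for d in dts):
        from .core import SpacingError

        raise SpacingError(
            f"trajectories have mismatched time steps: {sorted(set(np.round(dts, 12)))}"
        )
    n_min = min(t.n_points for t in trajs)
    sq = np.zeros(n_min - 1)
    for t in trajs:
        disp = t.positions[1:n_min] - t.positions[0]
        sq += np.einsum("ij,ij->i", disp, disp)
    sq /= len(trajs)
    lags = dt * np.arange(1, n_min)
    return MsdCurve(lags=lags, values=sq)


def anomalous_exponent(msd: MsdCurve) -> float:
    """Anomalous diffusion exponent: slope of log MSD vs log lag.

    ``alpha = 1`` for normal diffusion, ``< 1`` sub-diffusive, ``> 1``
    super-diffusive, ``= 2`` ballistic.  Requires at least 3 strictly
    positive MSD points.
    """
    if len(msd) < 3:
        raise DegenerateTrajectoryError("exponent fit needs at least 3 lag points")
    if np.any(msd.values <= 0):
        raise DegenerateTrajectoryError(
            "MSD vanishes at some lag (constant or periodic trajectory); "
            "log-log exponent fit is undefined"
        )
    slope, _ = np.polyfit(np.log(msd.lags), np.log(msd.values), 1)
    return float(slope)


def msd_ratio(msd: MsdCurve, n1: int = 1, n2: Optional[int] = None) -> float:
    """MSD ratio ``MSD(n1)/MSD(n2) - n1/n2`` for lag indices n1 < n2.

    Zero for linear (normal-diffusive) MSD, positive for a confined
    plateau, negative for super-diffusive curvature.  Defaults:
    ``n1 = 1``, ``n2 = max(2, len(msd)//2)``.
    """
    if n2 is None:
        n2 = max(2, len(msd) // 2)
    if not (1 <= n1 < n2 <= len(msd)):
        raise DegenerateTrajectoryError(
            f"need 1 <= n1 < n2 <= {len(msd)}, got n1={n1}, n2={n2}"
        )
    m2 = msd.values[n2 - 1]
    if m2 == 0:
        raise DegenerateTrajectoryError("MSD(n2) = 0; ratio undefined")
    return float(msd.values[n1 - 1] / m2 - n1 / n2)


# ---------------------------------------------------------------------------
# Gyration-tensor shape descriptors


def gyration_tensor(traj: Trajectory) -> GyrationSpectrum:
    """Gyration tensor: covariance (1/N normalization) of the positions.

    ``T_ab = (1/N) sum_i (x_ia - mean_a)(x_ib - mean_b)``.  Its
    eigenvalues describe the spatial extent of the trajectory's
    footprint along its principal axes.
    """
    x = traj.positions
    centered = x - x.mean(axis=0)
    T = centered.T @ centered / x.shape[0]
    return GyrationSpectrum(tensor=T)


def gyration_radius(spec: GyrationSpectrum) -> float:
    """Radius of gyration ``R_g = sqrt(sum of eigenvalues)``."""
    return float(np.sqrt(np.sum(spec.eigenvalues)))


def asymmetry(spec: GyrationSpectrum) -> float:
    """Elongation of the position cloud from the top two eigenvalues.

    ``a = -ln(1 - (l1 - l2)^2 / (2 (l1 + l2)^2))``; 0 for an isotropic
    cloud, ``ln 2`` for perfectly collinear points.  In 3-D the planar
    form on the two leading eigenvalues is used.
    """
    lam = spec.eigenvalues
    l1 = float(lam[0])
    l2 = float(lam[1]) if lam.size > 1 else 0.0
    s = l1 + l2
    if s <= 0:
        raise DegenerateTrajectoryError("all gyration eigenvalues are zero")
    return float(-math.log(1.0 - (l1 - l2) ** 2 / (2.0 * s * s)))


def anisotropy(spec: GyrationSpectrum) -> float:
    """Shape anisotropy in [0, 1]: 0 isotropic, 1 collinear.

    2-D: ``(l1 - l2)^2 / (l1 + l2)^2``.
    3-D: ``1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2``.
    1-D trajectories are collinear by construction (returns 1).
    """
    lam = np.asarray(spec.eigenvalues, dtype=float)
    tr = lam.sum()
    if tr <= 0:
        raise DegenerateTrajectoryError("zero-trace gyration tensor")
    if lam.size == 1:
        return 1.0
    if lam.size == 2:
        return float((lam[0] - lam[1]) ** 2 / tr**2)
    pairsum = lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
    return float(1.0 - 3.0 * pairsum / tr**2)


def kurtosis(traj: Trajectory, spec: Optional[GyrationSpectrum] = None) -> float:
    """Fourth standardized moment of positions projected on the
    dominant principal axis (``m4 / m2^2``; 3 for a Gaussian cloud,
    1 for points alternating between two values)."""
    if spec is None:
        spec = gyration_tensor(traj)
    proj = traj.positions @ spec.eigenvectors[:, 0]
    proj = proj - proj.mean()
    m2 = np.mean(proj**2)
    if m2 <= 0:
        raise DegenerateTrajectoryError("zero variance along the dominant axis")
    return float(np.mean(proj**4) / m2**2)


# ---------------------------------------------------------------------------
# Path geometry


def _path_length(x: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(x, axis=0), axis=1)))


def _max_extent(x: np.ndarray) -> float:
    """Maximum pairwise distance between visited points.

    Exact via pdist for modest N; for large N the convex hull reduces
    the candidate set.  If the hull is degenerate (collinear points),
    the extent along the principal axis is used, which is exact in that
    case.
    """
    n, d = x.shape
    if d == 1:
        return float(x.max() - x.min())
    if n <= 1500:
        return float(pdist(x).max())
    try:
        hull = ConvexHull(x)
        pts = x[hull.vertices]
        return float(pdist(pts).max())
    except QhullError:
        centered = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        return float(proj.max() - proj.min())


def fractal_dimension_katz(traj: Trajectory) -> float:
    """Katz fractal dimension of the path.

    ``D = ln(n) / (ln(n) + ln(e/L))`` with ``n = N - 1`` steps, total
    path length ``L`` and maximal extent ``e``.  1 for a straight line,
    larger for space-filling paths.  When ``e/L = 1/n`` the denominator
    vanishes; ``+inf`` is returned as a sentinel (downstream consumers
    impute it).
    """
    x = traj.positions
    L = _path_length(x)
    if L <= 0:
        raise DegenerateTrajectoryError("zero path length")
    e = _max_extent(x)
    if e <= 0:
        raise DegenerateTrajectoryError("zero spatial extent")
    n = traj.n_points - 1
    denom = math.log(n) + math.log(e / L)
    if denom == 0 or abs(denom) < 1e-15 * math.log(max(n, 2)):
        logger.warning("Katz fractal dimension degenerate (e/L = 1/n); returning inf")
        return math.inf
    return float(math.log(n) / denom)


def straightness(traj: Trajectory) -> float:
    """Net displacement over total path length, in [0, 1]."""
    x = traj.positions
    L = _path_length(x)
    if L <= 0:
        raise DegenerateTrajectoryError("zero path length")
    return float(np.linalg.norm(x[-1] - x[0]) / L)


def efficiency(traj: Trajectory) -> float:
    """Squared net displacement over ``(N-1)`` times the sum of squared
    step lengths, in [0, 1]; 1 for a uniform straight walk."""
    x = traj.positions
    steps = np.diff(x, axis=0)
    denom = (x.shape[0] - 1) * float(np.sum(steps**2))
    if denom <= 0:
        raise DegenerateTrajectoryError("zero path length")
    net = x[-1] - x[0]
    return float(net @ net / denom)


def trappedness(traj: Trajectory, msd: Optional[MsdCurve] = None) -> float:
    """Probability-like confinement score in [0, 1].

    ``P = 1 - exp(c1 - c2 * D0 * T / r0^2)`` clamped to [0, 1], with the
    short-time diffusivity ``D0`` from a through-origin fit to the first
    two MSD points, total duration ``T = (N-1) dt`` and ``r0`` half the
    maximal pairwise extent.  Large for trajectories that explore much
    less space than free diffusion at their short-time rate would.
    """
    if msd is None:
        msd = msd_time_averaged(traj)
    r0 = 0.5 * _max_extent(traj.positions)
    if r0 <= 0:
        raise DegenerateTrajectoryError("zero spatial extent")
    # through-origin least squares MSD = 2 d D0 tau on the first two lags
    k = min(2, len(msd))
    taus = msd.lags[:k]
    vals = msd.values[:k]
    slope = float(taus @ vals / (taus @ taus))
    d0 = slope / (2.0 * traj.ndim)
    arg = TRAPPEDNESS_C1 - TRAPPEDNESS_C2 * d0 * traj.duration / r0**2
    return float(np.clip(1.0 - math.exp(arg), 0.0, 1.0))


def gaussianity(traj: Trajectory, msd: Optional[MsdCurve] = None, lag: int = 1) -> float:
    """Excess of the fourth displacement moment over the Gaussian value.

    At the reference lag (default 1, the best-sampled lag):
    ``g = <r^4> / ((1 + 2/d) <r^2>^2) - 1``, with time-averaged moments.
    0 for Gaussian displacements (normal diffusion).
    """
    traj.uniform_dt()
    x = traj.positions
    if lag >= traj.n_points:
        raise DegenerateTrajectoryError(f"lag {lag} out of range for N={traj.n_points}")
    disp = x[lag:] - x[:-lag]
    r2 = np.einsum("ij,ij->i", disp, disp)
    m2 = float(r2.mean())
    if m2 <= 0:
        raise DegenerateTrajectoryError("zero mean squared displacement at reference lag")
    m4 = float(np.mean(r2**2))
    return float(m4 / ((1.0 + 2.0 / traj.ndim) * m2**2) - 1.0)


# ---------------------------------------------------------------------------
# Velocity, VACF, Green-Kubo


def velocity_series(traj: Trajectory) -> Tuple[np.ndarray, float]:
    """Finite-difference velocities ``v_i = (x_{i+1} - x_i)/dt`` and the
    mean speed ``mean |v_i|``.  Requires a uniform time step."""
    dt = traj.uniform_dt()
    v = np.diff(traj.positions, axis=0) / dt
    mean_speed = float(np.mean(np.linalg.norm(v, axis=1)))
    return v, mean_speed


def _vacf_raw(traj: Trajectory, n_max: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Unnormalized VACF ``C(n dt) = (1/(M-n)) sum_i v_i . v_{i+n}``
    for lags 0..n_max over the M = N-1 velocities."""
    dt = traj.uniform_dt()
    if traj.n_points < 3:
        raise DegenerateTrajectoryError("VACF needs at least 3 points")
    v, _ = velocity_series(traj)
    M = v.shape[0]
    if n_max is None:
        n_max = _max_lag(traj.n_points)
    n_max = min(n_max, M - 1)
    vals = np.empty(n_max + 1)
    for n in range(n_max + 1):
        prod = np.einsum("ij,ij->i", v[: M - n], v[n:])
        vals[n] = prod.mean()
    return dt * np.arange(n_max + 1), vals


def vacf(traj: Trajectory, n_max: Optional[int] = None) -> Vacf:
    """Velocity autocorrelation normalized by its zero-lag value.

    1 at lag 0; ~0 at positive lags for uncorrelated (Brownian) steps;
    alternating sign for oscillatory motion; ~1 for persistent drift.
    """
    lags, vals = _vacf_raw(traj, n_max)
    c0 = vals[0]
    if c0 <= 0:
        raise DegenerateTrajectoryError("zero velocity variance; VACF undefined")
    return Vacf(lags=lags, values=vals / c0)


def green_kubo_diffusivity(traj: Trajectory, n_max: Optional[int] = None) -> float:
    """Diffusion coefficient from the Green-Kubo relation.

    ``D = (1/d) * integral of the unnormalized VACF`` by trapezoidal
    quadrature, truncated at the first zero crossing of the VACF (the
    crossing point is located by linear interpolation) or at
    ``n_max * dt`` if the VACF never crosses zero.  Truncation removes
    the noise-dominated tail of the correlation integral.
    """
    lags, vals = _vacf_raw(traj, n_max)
    if vals[0] == 0.0:
        return 0.0
    neg = np.flatnonzero(vals[1:] <= 0.0)
    if neg.size:
        k = int(neg[0]) + 1  # first non-positive lag index
        integral = float(np.trapezoid(vals[:k], lags[:k]))
        c_prev, c_next = vals[k - 1], vals[k]
        if c_next < 0.0:  # interpolate the exact crossing
            t_cross = lags[k - 1] + (lags[k] - lags[k - 1]) * c_prev / (c_prev - c_next)
            integral += 0.5 * c_prev * (t_cross - lags[k - 1])
    else:
        integral = float(np.trapezoid(vals, lags))
    return integral / traj.ndim


# ---------------------------------------------------------------------------
# Spectral


def fourier_dominant_frequency(traj: Trajectory, rel_tol: float = 1e-12) -> float:
    """Frequency of the strongest spectral peak.

    Each coordinate is mean-subtracted, its discrete power spectrum
    computed (rectangular window), spectra are summed over dimensions,
    and the frequency of the maximum over nonzero-frequency bins is
    returned.  Returns 0 when the nonzero-bin power is negligible
    (constant trajectory).
    """
    dt = traj.uniform_dt()
    N = traj.n_points
    if N < 4:
        raise DegenerateTrajectoryError("Fourier analysis needs at least 4 points")
    x = traj.positions - traj.positions.mean(axis=0)
    spectra = np.abs(np.fft.rfft(x, axis=0)) ** 2
    power = spectra.sum(axis=1)
    freqs = np.fft.rfftfreq(N, d=dt)
    nonzero = power[1:]
    scale = N * float(np.sum(traj.positions**2))
    if nonzero.sum() <= rel_tol * max(scale, 1.0):
        return 0.0
    return float(freqs[1 + int(np.argmax(nonzero))])


# ---------------------------------------------------------------------------
# Full feature vector


def extract_all_features(
    traj: Trajectory, msd_ratio_lags: Optional[Tuple[int, int]] = None
) -> Dict[str, float]:
    """Compute all 17 descriptors for one trajectory.

    Returns a dict with exactly the keys of :data:`FEATURE_NAMES`, in
    that (alphabetical) order.  Any failure in a constituent feature is
    re-raised with the feature name attached.  Requires a uniform time
    step and enough points for a 3-lag MSD fit (``N >= 12``).
    """
    results: Dict[str, float] = {}

    def compute(name: str, fn):
        try:
            results[name] = float(fn())
        except TrajkitError as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    msd = msd_time_averaged(traj)
    spec = gyration_tensor(traj)
    n_max = len(msd)

    compute("alpha", lambda: anomalous_exponent(msd))
    compute("anisotropy", lambda: anisotropy(spec))
    compute("asymmetry", lambda: asymmetry(spec))
    compute("d_greenkubo", lambda: green_kubo_diffusivity(traj))
    compute("dominant_frequency", lambda: fourier_dominant_frequency(traj))
    compute("efficiency", lambda: efficiency(traj))
    compute("fractal_dim", lambda: fractal_dimension_katz(traj))
    compute("gaussianity", lambda: gaussianity(traj, msd))
    compute("gyration_radius", lambda: gyration_radius(spec))
    compute("kurtosis", lambda: kurtosis(traj, spec))
    compute("mean_speed", lambda: velocity_series(traj)[1])
    compute(
        "msd_at_quarter_lag",
        lambda: msd.values[max(1, n_max // 2) - 1],
    )
    if msd_ratio_lags is None:
        compute("msd_ratio", lambda: msd_ratio(msd))
    else:
        compute("msd_ratio", lambda: msd_ratio(msd, *msd_ratio_lags))
    compute(
        "msd_slope_diffusivity",
        lambda: msd.values[0] / (2.0 * traj.ndim * msd.lags[0]),
    )
    compute("straightness", lambda: straightness(traj))
    compute("trappedness", lambda: trappedness(traj, msd))
    def _vacf_first_lag():
        c = vacf(traj)
        return c.values[1] if c.values.size > 1 else 1.0

    compute("vacf_first_lag", _vacf_first_lag)

    return {name: results[name] for name in FEATURE_NAMES}
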