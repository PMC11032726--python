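"""Core data model for trajectory analysis.

A trajectory is an ordered sequence of positions sampled at strictly
increasing times.  Everything else in the package — the feature
descriptors, the diffusion-mode simulators, the classification
pipeline — consumes or produces :class:`Trajectory` objects and the
small intermediate containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TrajkitError",
    "FormatError",
    "SpacingError",
    "DegenerateTrajectoryError",
    "SchemaError",
    "ValidationError",
    "DIFFUSION_LABELS",
    "Trajectory",
    "MsdCurve",
    "Vacf",
    "GyrationSpectrum",
]


class TrajkitError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TrajkitError):
    """A file or table does not match the expected layout."""


class SpacingError(TrajkitError):
    """An operation requiring a uniform time step got irregular times."""


class DegenerateTrajectoryError(TrajkitError):
    """The trajectory carries no signal for the requested quantity
    (e.g. a constant path has zero mean squared displacement)."""


class SchemaError(TrajkitError):
    """Feature names or labels do not match the expected vocabulary."""


class ValidationError(TrajkitError):
    """A simulation spec or configuration value is out of range."""


#: Canonical class vocabulary for diffusion-mode classification.
DIFFUSION_LABELS = ("subdiffusion", "normal", "superdiffusion", "anomalous")


@dataclass(frozen=True)
class Trajectory:
    """An ordered time/position sequence.

    Parameters
    ----------
    times
        Strictly increasing sample times, shape ``(N,)``, ``N >= 2``.
    positions
        Positions, shape ``(N, d)`` with ``d`` in {1, 2, 3}.  A 1-D
        array is promoted to a single spatial column.
    id
        Optional text label carried through feature tables.
    """

    times: np.ndarray
    positions: np.ndarray
    id: Optional[str] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        x = np.asarray(self.positions, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.ndim != 2:
            raise FormatError(f"positions must be 1-D or 2-D, got ndim={x.ndim}")
        if t.shape[0] != x.shape[0]:
            raise FormatError(
                f"times ({t.shape[0]}) and positions ({x.shape[0]}) length mismatch"
            )
        if t.shape[0] < 2:
            raise DegenerateTrajectoryError(
                f"a trajectory needs at least 2 points, got {t.shape[0]}"
            )
        if x.shape[1] not in (1, 2, 3):
            raise FormatError(f"spatial dimension must be 1, 2 or 3, got {x.shape[1]}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise FormatError("times/positions contain NaN or infinite values")
        if np.any(np.diff(t) <= 0):
            raise FormatError("times must be strictly increasing")
        t.setflags(write=False)
        x.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)

    @property
    def n_points(self) -> int:
        return self.times.shape[0]

    @property
    def ndim(self) -> int:
        """Spatial dimension d."""
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def uniform_dt(self, rtol: float = 1e-9) -> float:
        """Return the uniform time step, or raise :class:`SpacingError`.

        Lag-based averages (MSD by lag, velocity autocorrelation,
        discrete Fourier transform) are only well defined on a regular
        time grid; geometric descriptors do not call this.
        """
        steps = np.diff(self.times)
        dt = float(steps.mean())
        if np.any(np.abs(steps - dt) > rtol * max(abs(dt), 1e-300)):
            raise SpacingError(
                "trajectory times are not uniformly spaced "
                f"(max deviation {np.abs(steps - dt).max():.3g} from dt={dt:.6g})"
            )
        return dt


@dataclass(frozen=True)
class MsdCurve:
    """Mean squared displacement as a function of lag time.

    ``lags`` are strictly increasing positive lag times; ``values`` are
    the corresponding nonnegative MSD values (length squared).  By
    convention MSD(0) = 0 and is not stored.
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float).ravel()
        vals = np.asarray(self.values, dtype=float).ravel()
        if lags.shape != vals.shape:
            raise FormatError("lags and values must have the same length")
        if lags.size == 0:
            raise DegenerateTrajectoryError("empty MSD curve")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise FormatError("MSD lags must be positive and strictly increasing")
        if np.any(vals < 0):
            raise FormatError("MSD values must be nonnegative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.lags.size


@dataclass(frozen=True)
class Vacf:
    """Velocity autocorrelation function, normalized so C(0) = 1.

    ``lags`` start at 0; ``values[0]`` is 1 whenever the trajectory has
    nonzero speed.
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float).ravel()
        vals = np.asarray(self.values, dtype=float).ravel()
        if lags.shape != vals.shape:
            raise FormatError("lags and values must have the same length")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class GyrationSpectrum:
    """Gyration tensor of the visited positions with its eigensystem.

    The tensor is the covariance matrix of the positions (population
    normalization, 1/N).  Eigenvalues are sorted descending; the
    eigenvector sign convention makes the first nonzero component of
    each eigenvector positive so the decomposition is reproducible.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]
    eigenvectors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T = np.asarray(self.tensor, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise FormatError("gyration tensor must be square")
        if not np.allclose(T, T.T, atol=1e-12 * max(1.0, np.abs(T).max())):
            raise FormatError("gyration tensor must be symmetric")
        if self.eigenvalues is None or self.eigenvectors is None:
            lam, vec = np.linalg.eigh(T)
            order = np.argsort(lam)[::-1]
            lam = lam[order]
            vec = vec[:, order]
            # numerical PSD clip
            lam = np.where(np.abs(lam) < 1e-14 * max(1.0, lam.max(initial=0.0)), 0.0, lam)
            for j in range(vec.shape[1]):
                col = vec[:, j]
                nz = np.flatnonzero(np.abs(col) > 1e-12)
                if nz.size and col[nz[0]] < 0:
                    vec[:, j] = -col
            object.__setattr__(self, "eigenvalues", lam)
            object.__setattr__(self, "eigenvectors", vec)
        if np.any(np.asarray(self.eigenvalues) < -1e-10):
            raise FormatError("gyration tensor must be positive semi-definite")

    @property
    def ndim(self) -> int:
        return self.tensor.shape[0]
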