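"""Synthetic trajectory generators for the four diffusion modes.

Four engines produce the canonical motion regimes used to train and
test diffusion-mode classifiers:

``normal``
    Brownian motion: i.i.d. Gaussian increments with per-dimension
    variance ``2 D dt``.  Ensemble MSD = ``2 d D t``.
``anomalous``
    Fractional Brownian motion (fBm) with Hurst exponent
    ``H = alpha/2``, sampled exactly from the fBm covariance
    ``Cov(B_s, B_t) = D (s^a + t^a - |t-s|^a)`` per coordinate via a
    Cholesky factorization.  Ensemble MSD = ``2 d D t^alpha``.
``confined``
    Brownian proposal steps inside a reflecting sphere of radius ``R``
    centered at the origin; steps that leave the sphere are reflected
    back across the boundary, so the MSD plateaus near the confinement
    scale (sub-diffusive signature).
``directed``
    Brownian motion plus a constant drift ``v``; ballistic at long
    times (super-diffusive signature).

All engines start at the origin and are fully determined by their
:class:`SimulationSpec` (one master seed per spec, one deterministic
sub-stream per coordinate), so identical specs give byte-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import DIFFUSION_LABELS, Trajectory, ValidationError

__all__ = [
    "SimulationSpec",
    "MODE_LABELS",
    "DIFFUSION_MODES",
    "simulate",
    "simulate_normal",
    "simulate_anomalous",
    "simulate_confined",
    "simulate_directed",
    "generate_labeled_set",
    "make_training_specs",
]

#: Mode -> classification label. Confinement produces the sub-diffusive
#: signature, drift the super-diffusive one; the "anomalous" label is
#: reserved for fBm with alpha != 1.
MODE_LABELS: Dict[str, str] = {
    "confined": "subdiffusion",
    "normal": "normal",
    "directed": "superdiffusion",
    "anomalous": "anomalous",
}

DIFFUSION_MODES: Tuple[str, ...] = tuple(MODE_LABELS)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters fully determining one synthetic trajectory.

    Mode-specific fields must be present exactly when required:
    ``alpha`` (anomalous only, in (0, 2]), ``radius`` (confined only,
    > 0), ``velocity`` (directed only, nonzero drift vector of length
    ``dim``).
    """

    mode: str
    n_points: int
    dt: float = 1.0
    dim: int = 2
    diffusivity: float = 1.0
    alpha: Optional[float] = None
    radius: Optional[float] = None
    velocity: Optional[Tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODE_LABELS:
            raise ValidationError(f"unknown mode '{self.mode}'; expected one of {DIFFUSION_MODES}")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.dim not in (1, 2, 3):
            raise ValidationError("dim must be 1, 2 or 3")
        if self.diffusivity <= 0:
            raise ValidationError("diffusivity must be positive")
        if self.mode == "anomalous":
            if self.alpha is None or not 0 < self.alpha <= 2:
                raise ValidationError("anomalous mode requires alpha in (0, 2]")
        elif self.alpha is not None:
            raise ValidationError("alpha is only valid for anomalous mode")
        if self.mode == "confined":
            if self.radius is None or self.radius <= 0:
                raise ValidationError("confined mode requires radius > 0")
        elif self.radius is not None:
            raise ValidationError("radius is only valid for confined mode")
        if self.mode == "directed":
            if self.velocity is None:
                raise ValidationError("directed mode requires a drift velocity")
            v = tuple(float(c) for c in self.velocity)
            if len(v) != self.dim:
                raise ValidationError(f"velocity must have {self.dim} components")
            if not any(c != 0 for c in v):
                raise ValidationError("directed mode requires nonzero drift (use normal mode)")
            object.__setattr__(self, "velocity", v)
        elif self.velocity is not None:
            raise ValidationError("velocity is only valid for directed mode")

    @property
    def label(self) -> str:
        return MODE_LABELS[self.mode]


def _coordinate_rngs(spec: SimulationSpec) -> List[np.random.Generator]:
    """One deterministic random sub-stream per spatial coordinate."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.dim)
    return [np.random.default_rng(c) for c in children]


def _brownian_steps(spec: SimulationSpec) -> np.ndarray:
    """(N-1) x d Gaussian increments with variance 2 D dt per dimension."""
    sigma = np.sqrt(2.0 * spec.diffusivity * spec.dt)
    rngs = _coordinate_rngs(spec)
    return np.column_stack(
        [rng.normal(0.0, sigma, spec.n_points - 1) for rng in rngs]
    )


def _times(spec: SimulationSpec) -> np.ndarray:
    return spec.dt * np.arange(spec.n_points)


def simulate_normal(spec: SimulationSpec) -> Trajectory:
    """Free Brownian motion started at the origin."""
    if spec.mode != "normal":
        raise ValidationError(f"spec.mode is '{spec.mode}', expected 'normal'")
    steps = _brownian_steps(spec)
    pos = np.vstack([np.zeros(spec.dim), np.cumsum(steps, axis=0)])
    return Trajectory(times=_times(spec), positions=pos, id=f"normal-{spec.seed}")


def simulate_anomalous(spec: SimulationSpec) -> Trajectory:
    """Fractional Brownian motion with Hurst ``H = alpha/2``.

    Each coordinate is drawn exactly from the fBm law by factorizing
    the covariance matrix of the sample times (suitable for
    desk-scale ``N`` up to a few thousand).  If the numerical Cholesky
    fails, a tiny diagonal jitter is added once before giving up.
    """
    if spec.mode != "anomalous":
        raise ValidationError(f"spec.mode is '{spec.mode}', expected 'anomalous'")
    a = float(spec.alpha)
    t = spec.dt * np.arange(1, spec.n_points)
    ta = t**a
    cov = spec.diffusivity * (ta[:, None] + ta[None, :] - np.abs(t[:, None] - t[None, :]) ** a)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(cov) / cov.shape[0]
        L = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
    rngs = _coordinate_rngs(spec)
    coords = [L @ rng.standard_normal(spec.n_points - 1) for rng in rngs]
    pos = np.vstack([np.zeros(spec.dim), np.column_stack(coords)])
    return Trajectory(times=_times(spec), positions=pos, id=f"anomalous-{spec.seed}")


def _reflect_into_sphere(x: np.ndarray, radius: float) -> np.ndarray:
    """Specular (radial) reflection of a point back inside |x| <= R."""
    r = float(np.linalg.norm(x))
    while r > radius:
        if r == 0.0:  # pragma: no cover - unreachable, r > radius >= 0
            break
        x = x * ((2.0 * radius - r) / r)
        r = abs(2.0 * radius - r)
    return x


def simulate_confined(spec: SimulationSpec) -> Trajectory:
    """Brownian motion inside a reflecting sphere of radius R.

    Reflection (rather than rejection) preserves the step-length
    statistics; every output point satisfies ``|x| <= R``.
    """
    if spec.mode != "confined":
        raise ValidationError(f"spec.mode is '{spec.mode}', expected 'confined'")
    R = float(spec.radius)
    steps = _brownian_steps(spec)
    pos = np.zeros((spec.n_points, spec.dim))
    for i in range(1, spec.n_points):
        pos[i] = _reflect_into_sphere(pos[i - 1] + steps[i - 1], R)
    return Trajectory(times=_times(spec), positions=pos, id=f"confined-{spec.seed}")


def simulate_directed(spec: SimulationSpec) -> Trajectory:
    """Brownian motion with a constant drift velocity."""
    if spec.mode != "directed":
        raise ValidationError(f"spec.mode is '{spec.mode}', expected 'directed'")
    v = np.asarray(spec.velocity, dtype=float)
    steps = _brownian_steps(spec) + v * spec.dt
    pos = np.vstack([np.zeros(spec.dim), np.cumsum(steps, axis=0)])
    return Trajectory(times=_times(spec), positions=pos, id=f"directed-{spec.seed}")


_ENGINES = {
    "normal": simulate_normal,
    "anomalous": simulate_anomalous,
    "confined": simulate_confined,
    "directed": simulate_directed,
}


def simulate(spec: SimulationSpec) -> Trajectory:
    """Dispatch a spec to its diffusion-mode engine."""
    return _ENGINES[spec.mode](spec)


def generate_labeled_set(
    specs: Sequence[SimulationSpec],
    labels: Optional[Sequence[str]] = None,
) -> List[Tuple[Trajectory, str]]:
    """Simulate each spec and pair it with its diffusion-mode label.

    Labels default to the canonical mode -> label mapping; explicit
    labels must come from the four-label vocabulary.
    """
    if labels is None:
        labels = [s.label for s in specs]
    if len(labels) != len(specs):
        raise ValidationError("labels and specs must have equal length")
    bad = set(labels) - set(DIFFUSION_LABELS)
    if bad:
        raise ValidationError(f"unknown labels {sorted(bad)}; expected {DIFFUSION_LABELS}")
    return [(simulate(s), lab) for s, lab in zip(specs, labels)]


def make_training_specs(
    n_per_class: int = 100,
    n_points: int = 250,
    dt: float = 1.0,
    dim: int = 2,
    seed: int = 0,
) -> List[SimulationSpec]:
    """Balanced specs spanning the parameter space of each regime.

    Per-trajectory parameters are drawn deterministically from ``seed``:
    diffusivity log-uniform in [0.1, 10]; fBm exponent uniform in
    [0.3, 0.7] or [1.3, 1.7] (away from the normal-diffusion point
    alpha = 1); confinement radius such that ``R^2`` is a few percent
    of the free-diffusion range ``2 d D T`` (strong confinement); drift
    speed uniform in [0.5, 2] per unit diffusivity with a random
    direction.  Each spec carries its own sub-seed below 2^31.
    """
    master = np.random.default_rng(np.random.SeedSequence(seed))
    specs: List[SimulationSpec] = []
    for mode in DIFFUSION_MODES:
        for _ in range(n_per_class):
            sub_seed = int(master.integers(0, 2**31 - 1))
            D = float(10.0 ** master.uniform(-1, 1))
            common = dict(n_points=n_points, dt=dt, dim=dim, diffusivity=D, seed=sub_seed)
            if mode == "normal":
                specs.append(SimulationSpec(mode="normal", **common))
            elif mode == "anomalous":
                lo, hi = (0.3, 0.7) if master.uniform() < 0.5 else (1.3, 1.7)
                specs.append(
                    SimulationSpec(mode="anomalous", alpha=float(master.uniform(lo, hi)), **common)
                )
            elif mode == "confined":
                free_range = 2.0 * dim * D * n_points * dt
                R = float(np.sqrt(free_range * master.uniform(0.01, 0.05)))
                specs.append(SimulationSpec(mode="confined", radius=R, **common))
            else:  # directed
                speed = float(master.uniform(0.5, 2.0)) * np.sqrt(D)
                direction = master.standard_normal(dim)
                direction /= np.linalg.norm(direction)
                specs.append(
                    SimulationSpec(
                        mode="directed", velocity=tuple(speed * direction), **common
                    )
                )
    return specs
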