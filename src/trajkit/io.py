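"""Reading and writing the formats the toolkit touches.

Three formats are supported:

* trajectory CSV — a header row with one time column (default ``t``)
  and 1–3 coordinate columns (default ``x``, ``y``, ``z``);
* LAMMPS-style YAML dump — a stream of per-timestep documents, each
  with a ``timestep`` number and per-particle rows keyed by an integer
  ``id`` plus coordinate columns;
* feature-table CSV — one row per trajectory, the 17 feature columns
  (alphabetical) and an optional diffusion-mode label column.

Missing values are rejected, never imputed.  Coordinates are taken as
Cartesian as written; no periodic-boundary unwrapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    DIFFUSION_LABELS,
    DegenerateTrajectoryError,
    FormatError,
    SchemaError,
    Trajectory,
)
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "read_trajectory_csv",
    "read_lammps_yaml",
    "FeatureTable",
    "write_feature_table",
    "read_feature_table",
    "write_trajectory_csv",
]

_DEFAULT_TIME_COL = "t"
_DEFAULT_COORD_COLS = ("x", "y", "z")


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.index[vals.isna()]
    if len(bad):
        raise FormatError(
            f"{path}: non-numeric or missing value in column '{col}' "
            f"at data row {int(bad[0])}"
        )
    return vals.to_numpy(dtype=float)


def read_trajectory_csv(
    path: Union[str, Path],
    time_col: str = _DEFAULT_TIME_COL,
    coord_cols: Optional[Sequence[str]] = None,
    id: Optional[str] = None,
) -> Trajectory:
    """Read one trajectory from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row.
    time_col
        Name of the time column (default ``"t"``).
    coord_cols
        Coordinate column names in axis order.  By default the columns
        ``x``, ``y``, ``z`` present in the header (in that order) are
        used.
    id
        Trajectory label; defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    cols = list(df.columns)
    if cols.count(time_col) != 1:
        raise FormatError(
            f"{path}: expected exactly one time column '{time_col}', "
            f"found {cols.count(time_col)} (columns: {cols})"
        )
    if coord_cols is None:
        coord_cols = [c for c in _DEFAULT_COORD_COLS if c in cols]
        if not coord_cols:
            raise FormatError(
                f"{path}: no coordinate columns among {_DEFAULT_COORD_COLS} "
                f"(columns: {cols}); pass coord_cols explicitly"
            )
    missing = [c for c in coord_cols if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing coordinate columns {missing}")
    if not 1 <= len(coord_cols) <= 3:
        raise FormatError(f"{path}: need 1-3 coordinate columns, got {len(coord_cols)}")

    times = _numeric_column(df, time_col, path)
    if times.size < 2:
        raise DegenerateTrajectoryError(f"{path}: fewer than 2 rows")
    positions = np.column_stack([_numeric_column(df, c, path) for c in coord_cols])
    return Trajectory(times=times, positions=positions, id=id or path.stem)


def write_trajectory_csv(
    traj: Trajectory,
    path: Union[str, Path],
    time_col: str = _DEFAULT_TIME_COL,
    coord_cols: Optional[Sequence[str]] = None,
) -> None:
    """Write a trajectory as CSV with default column names t, x, y, z."""
    if coord_cols is None:
        coord_cols = list(_DEFAULT_COORD_COLS[: traj.ndim])
    data = {time_col: traj.times}
    for j, c in enumerate(coord_cols):
        data[c] = traj.positions[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_lammps_yaml(path: Union[str, Path]) -> List[Trajectory]:
    """Parse a LAMMPS-style YAML dump into per-particle trajectories.

    Expects a YAML stream of per-frame documents, each carrying a
    ``timestep`` number, a ``keywords`` list naming the per-particle
    columns (must include ``id`` and coordinate columns ``x``/``y``/``z``)
    and a ``data`` list of rows.  One :class:`Trajectory` is returned
    per particle id present in *every* frame; ids missing from any
    frame are dropped with a warning.  Wrapped coordinates are taken
    as-is.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            docs = [d for d in yaml.safe_load_all(fh) if d is not None]
        except yaml.YAMLError as exc:
            raise FormatError(f"{path}: malformed YAML: {exc}") from exc
    if not docs:
        raise FormatError(f"{path}: no YAML documents")

    frames = []  # (timestep, {id: coords})
    ndim = None
    for i, doc in enumerate(docs):
        if not isinstance(doc, dict) or "timestep" not in doc:
            raise FormatError(f"{path}: document {i} lacks a 'timestep' key")
        keywords = doc.get("keywords")
        data = doc.get("data")
        if not keywords or data is None:
            raise FormatError(f"{path}: document {i} lacks 'keywords'/'data'")
        if "id" not in keywords:
            raise FormatError(f"{path}: document {i} has no 'id' column")
        coord_names = [c for c in _DEFAULT_COORD_COLS if c in keywords]
        if not coord_names:
            raise FormatError(f"{path}: document {i} has no coordinate columns")
        if ndim is None:
            ndim = len(coord_names)
        elif len(coord_names) != ndim:
            raise FormatError(
                f"{path}: inconsistent coordinate count across frames "
                f"({ndim} vs {len(coord_names)} in document {i})"
            )
        id_idx = keywords.index("id")
        coord_idx = [keywords.index(c) for c in coord_names]
        particles = {}
        for row in data:
            pid = int(row[id_idx])
            particles[pid] = [float(row[k]) for k in coord_idx]
        frames.append((float(doc["timestep"]), particles))

    frames.sort(key=lambda f: f[0])
    all_ids = [set(p) for _, p in frames]
    common = set.intersection(*all_ids)
    dropped = set.union(*all_ids) - common
    if dropped:
        logger.warning(
            "%s: %d particle id(s) missing from some frames, dropped: %s",
            path, len(dropped), sorted(dropped),
        )
    times = np.array([ts for ts, _ in frames])
    trajs = []
    for pid in sorted(common):
        pos = np.array([p[pid] for _, p in frames])
        trajs.append(Trajectory(times=times, positions=pos, id=str(pid)))
    return trajs


# ---------------------------------------------------------------------------
# Feature tables


@dataclass
class FeatureTable:
    """Rows = trajectories, columns = the 17 features, optional label.

    ``data`` holds an ``id`` column, the feature columns in the
    canonical (alphabetical) order and, when labeled, a ``label``
    column whose values come from the four-mode vocabulary.  Labels are
    all-present or all-absent; mixing raises :class:`SchemaError`.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if len(df) == 0:
            raise DegenerateTrajectoryError("empty feature table")
        missing = [f for f in FEATURE_NAMES if f not in df.columns]
        if missing:
            raise SchemaError(f"feature table missing columns: {missing}")
        extra = [
            c for c in df.columns if c not in FEATURE_NAMES and c not in ("id", "label")
        ]
        if extra:
            raise SchemaError(f"unexpected feature-table columns: {extra}")
        if "id" not in df.columns:
            df = df.assign(id=[str(i) for i in range(len(df))])
        ordered = ["id", *FEATURE_NAMES] + (["label"] if "label" in df.columns else [])
        df = df[ordered].reset_index(drop=True)
        if "label" in df.columns:
            if df["label"].isna().any():
                if df["label"].isna().all():
                    df = df.drop(columns="label")
                else:
                    raise SchemaError("labels must be all-present or all-absent")
            else:
                bad = set(df["label"]) - set(DIFFUSION_LABELS)
                if bad:
                    raise SchemaError(
                        f"unknown labels {sorted(bad)}; expected {DIFFUSION_LABELS}"
                    )
        self.data = df

    # -- accessors --------------------------------------------------------
    @property
    def feature_names(self) -> tuple:
        return FEATURE_NAMES

    @property
    def is_labeled(self) -> bool:
        return "label" in self.data.columns

    @property
    def ids(self) -> List[str]:
        return [str(v) for v in self.data["id"]]

    @property
    def labels(self) -> Optional[List[str]]:
        return list(self.data["label"]) if self.is_labeled else None

    def feature_matrix(self) -> np.ndarray:
        """Feature values as a float matrix, rows in table order."""
        return self.data[list(FEATURE_NAMES)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def write_feature_table(table: FeatureTable, path: Union[str, Path]) -> None:
    """Write a feature table as CSV (full float precision, round-trips
    through :func:`read_feature_table`)."""
    table.data.to_csv(path, index=False)


def read_feature_table(path: Union[str, Path]) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" in df.columns:
        df["id"] = df["id"].astype(str)
    return FeatureTable(data=df)
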