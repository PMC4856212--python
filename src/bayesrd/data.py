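"""Core data structures for regression discontinuity analyses.

The single input object of every estimator in this package is the
:class:`RDDataset`: patient-level records of a continuous assignment
score ``x`` (e.g. a 10-year cardiovascular risk score), a binary
treatment indicator ``t`` (e.g. statin prescription) and a continuous
outcome ``y`` (e.g. LDL cholesterol in mmol/l), together with the
guideline threshold ``x0`` on the assignment scale.

The threshold indicator ``z`` is derived, never stored: z = 1 wherever
x >= x0 (boundary inclusive above), z = 0 below.  Records exactly at
the threshold therefore belong to the "above" group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RDDataset",
    "EmptySideError",
    "assign_threshold_indicator",
    "center_scores",
    "filter_bandwidth",
    "read_dataset",
]


class EmptySideError(ValueError):
    """Raised when an operation requires records on both sides of the threshold."""

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"no records on the '{side}' side of the threshold")


def _as_float_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{name} contains a non-finite value at index {idx}")
    return arr


def assign_threshold_indicator(x, x0: float) -> np.ndarray:
    """Threshold indicator z: 1 where ``x >= x0``, else 0.

    The boundary is inclusive above: a subject whose score equals the
    threshold is assigned to the treated-by-guideline group.

    Parameters
    ----------
    x : array-like of float
        Assignment scores; must be finite.
    x0 : float
        Threshold on the same scale as ``x``.

    Returns
    -------
    numpy.ndarray of int
        Vector of 0/1 indicators, same length as ``x``.
    """
    arr = _as_float_vector(x, "x")
    return (arr >= float(x0)).astype(int)


def center_scores(x, x0: float) -> np.ndarray:
    """Centred distance from the threshold, ``x - x0``.

    A subject exactly at the threshold maps to 0, so the two segment
    intercepts of the local linear model are the expected outcomes at
    the threshold itself.
    """
    arr = _as_float_vector(x, "x")
    return arr - float(x0)


@dataclass(frozen=True)
class RDDataset:
    """Patient-level records for a regression discontinuity analysis.

    Attributes
    ----------
    x : ndarray
        Continuous assignment score (risk-score units, typically in [0, 1]).
    t : ndarray
        Binary treatment indicator, 1 = treated.
    y : ndarray
        Continuous outcome (mmol/l in the statin application).
    x0 : float
        Guideline threshold on the scale of ``x``.
    ids : ndarray or None
        Optional subject identifiers.
    covariates : dict[str, ndarray]
        Optional named covariate columns, carried for diagnostics only;
        the outcome model itself has no covariates.
    """

    x: np.ndarray
    t: np.ndarray
    y: np.ndarray
    x0: float
    ids: np.ndarray | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        x = _as_float_vector(self.x, "x")
        y = _as_float_vector(self.y, "y")
        t = np.asarray(self.t)
        if t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        tf = t.astype(float)
        if not np.isin(tf, (0.0, 1.0)).all():
            raise ValueError("t must contain only 0/1 values")
        n = len(x)
        if n < 1:
            raise ValueError("dataset must contain at least one record")
        if not (len(t) == n and len(y) == n):
            raise ValueError("x, t and y must have equal length")
        ids = self.ids
        if ids is not None:
            ids = np.asarray(ids)
            if len(ids) != n:
                raise ValueError("ids must have the same length as x")
        for name, col in self.covariates.items():
            if len(np.asarray(col)) != n:
                raise ValueError(f"covariate column '{name}' has wrong length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", tf.astype(int))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x0", float(self.x0))
        object.__setattr__(self, "ids", ids)
        object.__setattr__(
            self,
            "covariates",
            {k: np.asarray(v) for k, v in self.covariates.items()},
        )

    # -- derived columns ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def z(self) -> np.ndarray:
        """Threshold indicator, 1 where x >= x0."""
        return assign_threshold_indicator(self.x, self.x0)

    @property
    def xc(self) -> np.ndarray:
        """Centred assignment score x - x0."""
        return center_scores(self.x, self.x0)

    @property
    def n_above(self) -> int:
        return int(self.z.sum())

    @property
    def n_below(self) -> int:
        return self.n - self.n_above

    def require_both_sides(self) -> None:
        if self.n_below == 0:
            raise EmptySideError("below")
        if self.n_above == 0:
            raise EmptySideError("above")

    def _take(self, mask: np.ndarray) -> "RDDataset":
        return RDDataset(
            x=self.x[mask],
            t=self.t[mask],
            y=self.y[mask],
            x0=self.x0,
            ids=None if self.ids is None else self.ids[mask],
            covariates={k: v[mask] for k, v in self.covariates.items()},
        )

    def filter_bandwidth(self, h: float) -> "RDDataset":
        """Restrict to the closed window ``|x - x0| <= h`` (see :func:`filter_bandwidth`)."""
        return filter_bandwidth(self, h)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x0: float,
        x_col: str = "x",
        t_col: str = "t",
        y_col: str = "y",
        id_col: str | None = None,
        covariate_cols: list[str] | None = None,
    ) -> "RDDataset":
        """Build a dataset from a dataframe, dropping incomplete records.

        Rows with missing x, t or y are dropped with a logged count.
        """
        for col in (x_col, t_col, y_col):
            if col not in df.columns:
                raise ValueError(f"required column '{col}' not found in input")
        sub = df[[x_col, t_col, y_col]]
        complete = sub.notna().all(axis=1).to_numpy()
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.warning("dropped %d record(s) with missing x, t or y", n_dropped)
        df = df.loc[complete]
        if len(df) == 0:
            raise ValueError("no complete records remain after dropping missing values")
        covs = {}
        for col in covariate_cols or []:
            if col not in df.columns:
                raise ValueError(f"covariate column '{col}' not found in input")
            covs[col] = df[col].to_numpy()
        return cls(
            x=df[x_col].to_numpy(dtype=float),
            t=df[t_col].to_numpy(),
            y=df[y_col].to_numpy(dtype=float),
            x0=x0,
            ids=df[id_col].to_numpy() if id_col else None,
            covariates=covs,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        if self.ids is not None:
            data["id"] = self.ids
        data.update({"x": self.x, "t": self.t, "y": self.y})
        data.update(self.covariates)
        return pd.DataFrame(data)


def filter_bandwidth(data: RDDataset, h: float) -> RDDataset:
    """Retain records within the closed bandwidth window ``|x - x0| <= h``.

    Local linear RD estimators use only data within a fixed bandwidth h on
    either side of the threshold; both boundaries are included.

    Raises
    ------
    ValueError
        If ``h <= 0``.
    EmptySideError
        If no record remains on one side of the threshold, naming the side.
    """
    h = float(h)
    if not h > 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    # closed boundary, robust to the rounding of x - x0 (|0.15 - 0.2| is one
    # ulp above 0.05 in binary floating point)
    tol = 8 * np.finfo(float).eps * np.maximum(np.abs(data.x), max(abs(data.x0), h))
    mask = np.abs(data.x - data.x0) <= h + tol
    if not mask.any():
        raise EmptySideError("below", "bandwidth window retains no records at all")
    out = data._take(mask)
    out.require_both_sides()
    logger.debug(
        "bandwidth %.4g retained %d below / %d above", h, out.n_below, out.n_above
    )
    return out


def read_dataset(
    path,
    x0: float,
    x_col: str = "x",
    t_col: str = "t",
    y_col: str = "y",
    id_col: str | None = None,
    covariate_cols: list[str] | None = None,
) -> RDDataset:
    """Read an :class:`RDDataset` from a delimited text file with a header.

    The threshold is supplied by the analyst, never inferred from data.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surface the offending line
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if id_col is None and "id" in df.columns:
        id_col = "id"
    return RDDataset.from_dataframe(
        df, x0=x0, x_col=x_col, t_col=t_col, y_col=y_col,
        id_col=id_col, covariate_cols=covariate_cols,
    )
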