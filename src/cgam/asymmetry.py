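"""Per-step symmetry indices and the step-by-parameter asymmetry matrix.

The symmetry index (SI) of a paired observation is the signed percent
difference normalized by the bilateral mean,

    SI = (x_left - x_right) / (0.5 * (x_left + x_right)) * 100,

zero for perfect symmetry with algebraic range (-200, 200).  Signed values
are kept (not absolute) because the downstream covariance uses co-variation
between parameters, which absolute values would distort.  The side carried in
the numerator is configurable; left-minus-right is the default and is
recorded on the matrix so scores are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .parameters import PairedStepTable

__all__ = ["symmetry_index", "AsymmetryMatrix", "build_asymmetry_matrix"]

log = logging.getLogger(__name__)

#: relative tolerance below which the bilateral mean counts as zero (SI undefined)
SI_EPS = 1e-9


def symmetry_index(x_left, x_right, eps: float = SI_EPS):
    """Signed symmetry index in percent; NaN where the bilateral mean vanishes.

    Accepts scalars or arrays (broadcast).  An SI is undefined when
    ``|x_left + x_right| < eps * max(|x_left|, |x_right|)`` — i.e. the sides
    cancel — and is returned as NaN for the caller to handle.
    """
    xl = np.asarray(x_left, dtype=float)
    xr = np.asarray(x_right, dtype=float)
    denom = 0.5 * (xl + xr)
    scale = np.maximum(np.abs(xl), np.abs(xr))
    undefined = np.abs(xl + xr) < eps * scale
    both_zero = scale == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        si = (xl - xr) / denom * 100.0
    si = np.where(undefined | both_zero, np.nan, si)
    si = np.where(both_zero & ~np.isnan(xl) & ~np.isnan(xr), np.nan, si)
    if si.ndim == 0:
        return float(si)
    return si


@dataclass
class AsymmetryMatrix:
    """The m-step x n-parameter symmetry-index matrix ("Data").

    Rows are complete stride pairs, columns the active gait parameters,
    entries dimensionless percent.  ``side_convention`` documents which side
    sits positive in the SI numerator.
    """

    values: np.ndarray
    params: tuple
    step_index: np.ndarray
    side_convention: str = "left-minus-right"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.params = tuple(self.params)
        if self.values.ndim != 2:
            raise ParameterError("asymmetry matrix must be 2-D (steps x parameters)")
        if self.values.shape[1] != len(self.params):
            raise ParameterError("column count must equal number of parameter names")
        self.step_index = np.asarray(self.step_index)
        if self.step_index.shape[0] != self.values.shape[0]:
            raise ParameterError("step_index length must equal row count")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ParameterError("asymmetry matrix entries must be finite")
        if self.values.size and np.any(np.abs(self.values) >= 200.0):
            raise ParameterError(
                "symmetry indices outside the algebraic range (-200, 200); "
                "check input pairing"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.params))
        df.insert(0, "stride_index", self.step_index)
        return df

    def to_csv(self, path) -> None:
        from .io import _write_csv_with_comment
        from . import __version__

        _write_csv_with_comment(
            path, self.to_frame(),
            f"# cgam v{__version__} asymmetry matrix (percent SI, "
            f"{self.side_convention})\n",
        )


def build_asymmetry_matrix(
    table: PairedStepTable,
    side_convention: str = "left-minus-right",
    eps: float = SI_EPS,
) -> AsymmetryMatrix:
    """Convert a paired step table into the SI matrix of complete rows.

    Rows flagged incomplete in the table, and rows where any SI is undefined,
    are dropped (counts logged).  Raises if nothing survives.
    """
    if side_convention not in ("left-minus-right", "right-minus-left"):
        raise ParameterError(f"unknown side convention {side_convention!r}")
    df = table.complete()
    if len(df) == 0:
        raise InsufficientDataError("no complete stride pairs in parameter table")
    cols = []
    for p in table.params:
        left = df[f"{p}_L"].to_numpy()
        right = df[f"{p}_R"].to_numpy()
        if side_convention == "left-minus-right":
            cols.append(symmetry_index(left, right, eps))
        else:
            cols.append(symmetry_index(right, left, eps))
    values = np.column_stack(cols) if cols else np.empty((len(df), 0))
    keep = np.isfinite(values).all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropping %d step(s) with undefined symmetry index", n_drop)
    if not keep.any():
        raise InsufficientDataError("all rows dropped: every step had an undefined SI")
    return AsymmetryMatrix(
        values=values[keep],
        params=table.params,
        step_index=df["stride_index"].to_numpy()[keep],
        side_convention=side_convention,
    )
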