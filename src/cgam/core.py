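"""The combined gait asymmetry metric (CGAM).

The metric treats each step's vector of symmetry indices x_i (one entry per
gait parameter) as a point in parameter space and measures its Mahalanobis
distance from the origin — the origin being ideal symmetry — under the sample
covariance Sigma of the step-by-parameter matrix:

    q_i = x_i' inv(Sigma) x_i            (squared form, distance from zero)
    d_i = sqrt(q_i / S),   S = sum of all entries of inv(Sigma)
    score = mean_i d_i

Dividing by S turns the quadratic form into a weighted mean over parameters:
parameters whose asymmetry varies more from step to step receive less weight,
so a noisy parameter cannot dominate the score.  The per-parameter effective
weight is the normalized column sum of inv(Sigma).

Note the covariance is taken about the column means (ordinary sample
covariance) while the distance is measured from zero, not from the mean —
a consistently asymmetric gait scores high even if it is consistent.

The model/results split follows the statsmodels idiom: build a :class:`CGAM`
model from the asymmetry matrix (optionally with an externally supplied
covariance), call :meth:`CGAM.fit`, and read estimates, weights, diagnostics
and bootstrap intervals off the :class:`CGAMResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .asymmetry import AsymmetryMatrix
from .errors import InsufficientDataError, IntegrityError, ParameterError

__all__ = [
    "CovarianceModel",
    "CGAM",
    "CGAMResults",
    "estimate_covariance",
    "cgam_score",
    "effective_weights",
    "compare_conditions",
]

log = logging.getLogger(__name__)

#: condition number above which the sample covariance is ridge-regularized
COND_MAX = 1e10
#: relative ridge seed: eps = RIDGE_SEED * trace(Sigma) / n
RIDGE_SEED = 1e-8
#: absolute ridge floor used when trace(Sigma) == 0 (e.g. a zero matrix)
RIDGE_FLOOR = 1e-12


@dataclass
class CovarianceModel:
    """Covariance of the asymmetry matrix columns and its inverse.

    ``ridge`` is the diagonal loading actually added (0 if none); ``S`` is the
    grand sum of the inverse's entries — the normalizer of the metric.
    """

    Sigma: np.ndarray
    Sigma_inv: np.ndarray
    S: float
    ridge: float
    m_used: int
    params: tuple = ()

    def __post_init__(self):
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.Sigma_inv = np.asarray(self.Sigma_inv, dtype=float)
        n = self.Sigma.shape[0]
        if self.Sigma.shape != (n, n) or self.Sigma_inv.shape != (n, n):
            raise ParameterError("Sigma and Sigma_inv must be square and congruent")
        if self.S == 0:
            raise IntegrityError("sum of inverse covariance entries is zero")

    @property
    def n(self) -> int:
        return self.Sigma.shape[0]

    def marginal_variances(self) -> np.ndarray:
        return np.diag(self.Sigma).copy()


def _invert_spd(a: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    c, low = sla.cho_factor(a, lower=True)
    return sla.cho_solve((c, low), np.eye(a.shape[0]))


def make_covariance_model(Sigma: np.ndarray, m_used: int = 0,
                          params: Sequence[str] = (), ridge: float = 0.0
                          ) -> CovarianceModel:
    """Build a CovarianceModel from an externally supplied covariance."""
    Sigma = np.asarray(Sigma, dtype=float)
    if not np.allclose(Sigma, Sigma.T, atol=1e-12):
        raise ParameterError("supplied covariance must be symmetric")
    reg = Sigma + ridge * np.eye(Sigma.shape[0])
    try:
        inv = _invert_spd(reg)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("supplied covariance is not positive definite") from exc
    return CovarianceModel(Sigma=Sigma, Sigma_inv=inv, S=float(inv.sum()),
                           ridge=ridge, m_used=m_used, params=tuple(params))


def estimate_covariance(
    matrix: AsymmetryMatrix | np.ndarray,
    ridge_policy: str | float = "auto",
    params: Sequence[str] = (),
) -> CovarianceModel:
    """Sample covariance of the matrix columns, ridge-regularized when needed.

    The sample covariance (about column means, denominator m-1) is inverted
    directly when well conditioned.  If its condition number exceeds 1e10 or
    m < n + 2, a deterministic diagonal ridge eps = 1e-8 * trace(Sigma)/n is
    added, escalating tenfold until the Cholesky factorization succeeds; the
    ridge actually used is recorded so results are reproducible bit for bit.
    ``ridge_policy`` may also be a fixed non-negative float, or ``"none"``.
    """
    if isinstance(matrix, AsymmetryMatrix):
        X = matrix.values
        params = params or matrix.params
    else:
        X = np.asarray(matrix, dtype=float)
    m, n = X.shape
    if m < 2:
        raise InsufficientDataError(f"need at least 2 steps to estimate covariance, got {m}")
    Sigma = np.cov(X, rowvar=False, ddof=1)
    Sigma = np.atleast_2d(Sigma)

    tr = float(np.trace(Sigma))
    seed = RIDGE_SEED * tr / n if tr > 0 else RIDGE_FLOOR
    if isinstance(ridge_policy, str):
        if ridge_policy == "none":
            ridge, escalate = 0.0, False
        elif ridge_policy == "auto":
            needs = m < n + 2 or _cond(Sigma) > COND_MAX
            ridge, escalate = (seed if needs else 0.0), True
        else:
            raise ParameterError(f"unknown ridge policy {ridge_policy!r}")
    else:
        ridge = float(ridge_policy)
        if ridge < 0:
            raise ParameterError("ridge must be non-negative")
        escalate = False

    while True:
        try:
            inv = _invert_spd(Sigma + ridge * np.eye(n))
            break
        except np.linalg.LinAlgError:
            if not escalate:
                raise ParameterError(
                    "covariance not positive definite under the requested "
                    "ridge policy"
                ) from None
            ridge = seed if ridge == 0 else ridge * 10.0
    if ridge > 0:
        log.warning("covariance ridge-regularized with eps=%.3g", ridge)
    S = float(inv.sum())
    return CovarianceModel(Sigma=Sigma, Sigma_inv=inv, S=S, ridge=ridge,
                           m_used=m, params=tuple(params))


def _cond(a: np.ndarray) -> float:
    try:
        w = np.linalg.eigvalsh(a)
    except np.linalg.LinAlgError:
        return np.inf
    lo, hi = w.min(), w.max()
    if lo <= 0:
        return np.inf
    return float(hi / lo)


def effective_weights(cov: CovarianceModel) -> pd.Series:
    """Per-parameter effective weight: normalized column sums of inv(Sigma).

    Weights sum to one; a parameter with larger step-to-step variability
    (larger marginal variance, for diagonal covariance) gets a smaller weight.
    """
    w = cov.Sigma_inv.sum(axis=0) / cov.S
    names = list(cov.params) if cov.params else list(range(cov.n))
    return pd.Series(w, index=names, name="effective_weight")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CGAM:
    """Combined gait asymmetry model for one trial's asymmetry matrix.

    Parameters
    ----------
    data : AsymmetryMatrix, DataFrame or (m, n) array
        Per-step symmetry indices in percent.  DataFrame columns become
        parameter names.
    cov : CovarianceModel or (n, n) array, optional
        Externally supplied covariance (e.g. pooled across conditions).
        When omitted the covariance is estimated from ``data``.
    ridge_policy : 'auto' | 'none' | float
        Regularization policy for the estimated covariance.
    """

    def __init__(self, data, cov=None, ridge_policy: str | float = "auto"):
        if isinstance(data, AsymmetryMatrix):
            self.matrix = data
        elif isinstance(data, pd.DataFrame):
            vals = data.to_numpy(dtype=float)
            self.matrix = AsymmetryMatrix(
                values=vals, params=tuple(map(str, data.columns)),
                step_index=np.asarray(data.index),
            )
        else:
            vals = np.asarray(data, dtype=float)
            self.matrix = AsymmetryMatrix(
                values=vals, params=tuple(f"p{i}" for i in range(vals.shape[1])),
                step_index=np.arange(vals.shape[0]),
            )
        if self.matrix.m == 0:
            raise InsufficientDataError("empty asymmetry matrix")
        self.ridge_policy = ridge_policy
        if cov is None:
            self.cov: Optional[CovarianceModel] = None
        elif isinstance(cov, CovarianceModel):
            if cov.n != self.matrix.n:
                raise ParameterError(
                    f"covariance dimension {cov.n} != parameter count {self.matrix.n}"
                )
            self.cov = cov
        else:
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.matrix.n, self.matrix.n):
                raise ParameterError(
                    f"covariance shape {cov.shape} != ({self.matrix.n}, {self.matrix.n})"
                )
            self.cov = make_covariance_model(cov, m_used=0, params=self.matrix.params)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CGAM":
        return cls(df, **kwargs)

    @classmethod
    def from_paired_table(cls, table, side_convention: str = "left-minus-right",
                          **kwargs) -> "CGAM":
        from .asymmetry import build_asymmetry_matrix

        return cls(build_asymmetry_matrix(table, side_convention), **kwargs)

    def fit(self) -> "CGAMResults":
        cov = self.cov or estimate_covariance(self.matrix, self.ridge_policy)
        X = self.matrix.values
        q = np.einsum("ij,jk,ik->i", X, cov.Sigma_inv, X)
        if np.any(q < -1e-9):
            raise IntegrityError(
                f"negative quadratic form ({q.min():.3e}); covariance is not PSD"
            )
        q = np.clip(q, 0.0, None)
        d = np.sqrt(q / cov.S)
        return CGAMResults(model=self, cov=cov, per_step_sq=q, per_step_distance=d)


@dataclass
class CGAMResults:
    """Fitted CGAM: per-step distances, trial score, weights, diagnostics."""

    model: CGAM
    cov: CovarianceModel
    per_step_sq: np.ndarray
    per_step_distance: np.ndarray

    @property
    def score(self) -> float:
        """Trial score: mean per-step normalized Mahalanobis distance."""
        return float(self.per_step_distance.mean())

    @property
    def n_steps(self) -> int:
        return int(self.per_step_distance.size)

    @property
    def params(self) -> tuple:
        return self.model.matrix.params

    @property
    def weights(self) -> pd.Series:
        return effective_weights(self.cov)

    def conf_int(self, alpha: float = 0.05, n_boot: int = 1000,
                 seed: int | None = None) -> tuple:
        """Percentile bootstrap CI for the score, resampling steps."""
        rng = np.random.default_rng(seed)
        d = self.per_step_distance
        idx = rng.integers(0, d.size, size=(n_boot, d.size))
        means = d[idx].mean(axis=1)
        lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)

    def aggregate(self, how: str = "mean") -> float:
        """Alternative aggregations over steps: mean (default), median, rms,
        or pooled (sqrt of mean squared form / S)."""
        d = self.per_step_distance
        if how == "mean":
            return float(d.mean())
        if how == "median":
            return float(np.median(d))
        if how == "rms":
            return float(np.sqrt(np.mean(d ** 2)))
        if how == "pooled":
            return float(np.sqrt(self.per_step_sq.mean() / self.cov.S))
        raise ParameterError(f"unknown aggregation {how!r}")

    def summary(self) -> str:
        lines = [
            "Combined Gait Asymmetry Metric",
            "=" * 46,
            f"steps (rows)          {self.n_steps:>10d}",
            f"parameters            {len(self.params):>10d}",
            f"score                 {self.score:>10.4f}",
            f"median step distance  {np.median(self.per_step_distance):>10.4f}",
            f"covariance ridge      {self.cov.ridge:>10.3g}",
            "",
            f"{'parameter':<10}{'weight':>10}{'marg. var':>12}",
            "-" * 32,
        ]
        mv = self.cov.marginal_variances()
        for name, w, v in zip(self.params, self.weights.to_numpy(), mv):
            lines.append(f"{name:<10}{w:>10.4f}{v:>12.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "n_steps": self.n_steps,
            "params": list(self.params),
            "weights": {k: float(v) for k, v in self.weights.items()},
            "per_step_distance": [float(v) for v in self.per_step_distance],
            "ridge": float(self.cov.ridge),
            "S": float(self.cov.S),
            "side_convention": self.model.matrix.side_convention,
        }

    def plot_weights(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(list(map(str, self.params)), self.weights.to_numpy())
        ax.set_ylabel("effective weight")
        ax.set_title("CGAM parameter weights")
        return ax

    def plot_distances(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.per_step_distance, marker="o")
        ax.axhline(self.score, ls="--", color="k", label=f"score = {self.score:.3f}")
        ax.set_xlabel("step")
        ax.set_ylabel("normalized Mahalanobis distance")
        ax.legend()
        return ax


def cgam_score(matrix, cov=None, ridge_policy: str | float = "auto") -> CGAMResults:
    """One-call form: fit the metric to an asymmetry matrix.

    ``cov`` may be a CovarianceModel or raw (n, n) covariance; omitted, the
    covariance is estimated from the same matrix.
    """
    return CGAM(matrix, cov=cov, ridge_policy=ridge_policy).fit()


def compare_conditions(
    results: List[CGAMResults],
    labels: Sequence[str],
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Rank fitted conditions by score with bootstrap CIs over steps.

    Conditions with fewer than 2 steps are excluded with a warning.  Ties keep
    input order (stable sort).  Parameter sets must match across conditions.
    """
    if len(results) < 2:
        raise ParameterError("need at least 2 conditions to compare")
    if len(labels) != len(results):
        raise ParameterError("labels must match results one-to-one")
    ref = results[0].params
    for r, lab in zip(results, labels):
        if r.params != ref:
            raise ParameterError(
                f"condition {lab!r} uses parameters {r.params}, expected {ref}"
            )
    rows = []
    rng = np.random.default_rng(seed)
    for r, lab in zip(results, labels):
        if r.n_steps < 2:
            log.warning("condition %r has <2 steps; excluded from comparison", lab)
            continue
        lo, hi = r.conf_int(alpha=alpha, n_boot=n_boot,
                            seed=int(rng.integers(0, 2 ** 31 - 1)))
        rows.append({"label": lab, "score": r.score, "ci_low": lo, "ci_high": hi,
                     "n_steps": r.n_steps})
    df = pd.DataFrame(rows)
    return df.sort_values("score", ascending=False, kind="stable",
                          ignore_index=True)
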