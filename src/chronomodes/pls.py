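"""Single-response partial least squares (PLS1) on concatenated brain features.

The model extracts components sequentially by NIPALS with X-deflation:
each weight vector maximizes covariance between the deflated feature
matrix and the centered binary target, scores are mutually orthogonal,
and new data are mapped into the latent space through the rotation
``R = W (P^T W)^{-1}`` so that ``X_c R`` reproduces the training scores
exactly.  Fitting is fully deterministic: the first NIPALS iterate is the
cross-covariance direction and, with a single response, the inner loop
converges immediately.

Conventions
-----------
* features are centered and (by default) scaled to unit variance; the
  centering/scaling vectors are stored in the model so transformation
  and cross-cohort projection are self-contained;
* per component, the largest-magnitude weight entry is made positive
  (the latent sign is otherwise arbitrary); the morning/evening
  orientation of a component is then read off a group t-test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_TOL = 1e-10
_MAX_ITER = 500


class GroupTTest(NamedTuple):
    t: float
    df: int
    p: float


@dataclass
class PLSModel:
    """Fitted PLS1 model: weights W, x-loadings P, x-scores T (p x k / n x k)."""

    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    y_loadings: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    k: int
    feature_names: list[str]
    blocks: list[str] | None = None
    n_iter: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.T.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[0]

    def rotation(self) -> np.ndarray:
        """R = W (P^T W)^{-1}, computed by linear solve (no explicit inverse)."""
        M = self.P.T @ self.W
        return self.W @ np.linalg.solve(M, np.eye(self.k))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "feature_names": list(self.feature_names),
            "blocks": list(self.blocks) if self.blocks is not None else None,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "T": self.T.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center,
            "y_scale": self.y_scale,
            "n_iter": list(self.n_iter),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            P=np.asarray(d["P"], dtype=float),
            T=np.asarray(d["T"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_center=np.asarray(d["x_center"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            y_center=float(d["y_center"]),
            y_scale=float(d["y_scale"]),
            k=int(d["k"]),
            feature_names=list(d["feature_names"]),
            blocks=list(d["blocks"]) if d.get("blocks") is not None else None,
            n_iter=list(d.get("n_iter", [])),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    return np.ascontiguousarray(X, dtype=float), None


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, k: int,
                 tol: float = _TOL, max_iter: int = _MAX_ITER
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """NIPALS on pre-centered data; mutates neither argument.

    Returns (W, P, T, q, n_iter).  Deterministic: initialized from the
    cross-covariance direction.
    """
    X = Xc.copy()
    y = yc.copy()
    n, p = X.shape
    W = np.empty((p, k))
    P = np.empty((p, k))
    T = np.empty((n, k))
    q = np.empty(k)
    iters: list[int] = []
    ref_nw = 0.0
    for j in range(k):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if j == 0:
            ref_nw = nw
        # relative threshold: exhaustion leaves only rounding noise behind
        if nw <= max(ref_nw * 1e-12, np.finfo(float).tiny * max(n, p)):
            raise ValueError(
                f"component {j + 1}: residual cross-covariance is zero "
                "(k exceeds the rank of the informative subspace)")
        w /= nw
        it = 1
        while it < max_iter:
            t = X @ w
            tt = float(t @ t)
            if tt <= 0:
                raise ValueError(f"component {j + 1}: degenerate score (zero variance)")
            qj = float(y @ t) / tt
            u = y * qj
            w_new = X.T @ u
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
            it += 1
        t = X @ w
        tt = float(t @ t)
        if tt <= 0 or not np.isfinite(tt):
            raise ValueError(f"component {j + 1}: degenerate score column")
        pj = X.T @ t / tt
        qj = float(y @ t) / tt
        X -= np.outer(t, pj)
        y = y - qj * t
        W[:, j], P[:, j], T[:, j], q[j] = w, pj, t, qj
        iters.append(it)
    return W, P, T, q, iters


def fit_pls(X, y, k: int, *, scale: bool = True,
            feature_names: Sequence[str] | None = None,
            blocks: Sequence[str] | None = None,
            tol: float = _TOL, max_iter: int = _MAX_ITER) -> PLSModel:
    """Fit PLS1 of the -1/+1 target on the feature matrix.

    ``X`` may be an ndarray or a DataFrame (column names become feature
    names).  Requires both target classes present and ``1 <= k < rank(X)``
    (rank exhaustion is detected during extraction).
    """
    Xm, inferred = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if y.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k={k} must satisfy 1 <= k <= min(n-1, p) = {min(n - 1, p)}")
    classes = np.unique(y)
    if set(classes) - {-1.0, 1.0}:
        raise ValueError(f"target must be coded -1/+1, got values {classes}")
    if classes.size < 2:
        raise ValueError("single-class target: both -1 and +1 must be present")
    if np.isnan(Xm).any():
        raise ValueError("X contains missing values; residualize/impute upstream")

    x_center = Xm.mean(axis=0)
    x_scale = Xm.std(axis=0, ddof=0) if scale else np.ones(p)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    Xc = (Xm - x_center) / x_scale
    y_center = float(y.mean())
    yc = y - y_center

    W, P, T, q, iters = _nipals_pls1(Xc, yc, k, tol=tol, max_iter=max_iter)

    # sign convention: largest-|weight| entry positive, per component
    for j in range(k):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] *= -1
            P[:, j] *= -1
            T[:, j] *= -1
            q[j] *= -1

    names = (list(feature_names) if feature_names is not None
             else inferred if inferred is not None
             else [f"x{i}" for i in range(p)])
    return PLSModel(
        W=W, P=P, T=T, y_loadings=q,
        x_center=x_center, x_scale=x_scale,
        y_center=y_center, y_scale=1.0,
        k=k, feature_names=names,
        blocks=list(blocks) if blocks is not None else None,
        n_iter=iters,
    )


def transform(model: PLSModel, X_new) -> np.ndarray:
    """Map new rows over the model's features into the latent space.

    Applies the stored centering/scaling, then the rotation
    ``R = W (P^T W)^{-1}``; on the training matrix this reproduces the
    training scores.  DataFrame columns must match the model's features
    in name and order.
    """
    Xm, names = _as_matrix(X_new)
    if names is not None:
        for i, (got, want) in enumerate(zip(names, model.feature_names)):
            if got != want:
                raise ValueError(
                    f"feature mismatch at column {i}: got {got!r}, expected {want!r}")
        if len(names) != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {len(names)}")
    elif Xm.shape[1] != model.p:
        raise ValueError(f"expected {model.p} features, got {Xm.shape[1]}")
    Xc = (Xm - model.x_center) / model.x_scale
    return Xc @ model.rotation()


def latent_correlation(model: PLSModel, y) -> np.ndarray:
    """Pearson correlation between each score column and the target."""
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != model.n:
        raise ValueError("y is not row-aligned with the model scores")
    return score_target_correlation(model.T, y)


def score_target_correlation(T: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of a score matrix with a target."""
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Tc = T - T.mean(axis=0)
    yc = y - y.mean()
    tn = np.linalg.norm(Tc, axis=0)
    yn = np.linalg.norm(yc)
    if yn == 0:
        raise ValueError("target has zero variance")
    if np.any(tn == 0):
        raise ValueError("score column has zero variance")
    return (Tc.T @ yc) / (tn * yn)


def group_ttest(scores, group) -> GroupTTest:
    """Pooled-variance two-sample t-test of scores between target groups.

    ``t`` compares the -1 (early bird) group mean against the +1 (night
    owl) group; df = n1 + n2 - 2; two-sided p.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    group = np.asarray(group, dtype=float).ravel()
    a = scores[group == -1.0]
    b = scores[group == 1.0]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 members")
    res = stats.ttest_ind(a, b, equal_var=True)
    return GroupTTest(t=float(res.statistic), df=a.size + b.size - 2,
                      p=float(res.pvalue))
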