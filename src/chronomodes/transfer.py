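"""Cross-cohort projection onto a trained latent space, and age stratification.

An external cohort measured on a subset of the trained features (for
example only the grey-matter block) is mapped into the trained latent
space by restricting the weight and x-loading matrices to that subset
and applying the rotation ``R_sub = W_sub (P_sub^T W_sub)^{-1}``.  The
rotation is computed by linear solve, never an explicit inverse, and a
numerically singular ``P_sub^T W_sub`` is a hard failure: the projection
formula presumes invertibility.

External features are residualized against the external cohort's own
covariates upstream and are, by default, centered/scaled with the
external cohort's own statistics — acquisition scales differ between
cohorts and each is preprocessed independently.  Pass
``standardize="training"`` to reuse the training statistics instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pls import PLSModel

#: adult cohort brackets (years); shared endpoints resolved left-closed
ADULT_BRACKETS_YEARS: tuple[tuple[float, float], ...] = (
    (40, 50), (50, 55), (55, 60), (60, 65), (65, 70))
#: child cohort brackets (months)
CHILD_BRACKETS_MONTHS: tuple[tuple[float, float], ...] = (
    (100, 110), (110, 120), (120, 130), (130, 140))

_COND_LIMIT = 1e12


@dataclass
class ProjectionModel:
    feature_subset: list[str]
    W_sub: np.ndarray
    P_sub: np.ndarray
    R_sub: np.ndarray
    train_center: np.ndarray
    train_scale: np.ndarray
    condition_number: float
    k: int

    def to_dict(self) -> dict:
        return {
            "feature_subset": list(self.feature_subset),
            "W_sub": self.W_sub.tolist(),
            "P_sub": self.P_sub.tolist(),
            "R_sub": self.R_sub.tolist(),
            "train_center": self.train_center.tolist(),
            "train_scale": self.train_scale.tolist(),
            "condition_number": self.condition_number,
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionModel":
        return cls(
            feature_subset=list(d["feature_subset"]),
            W_sub=np.asarray(d["W_sub"], dtype=float),
            P_sub=np.asarray(d["P_sub"], dtype=float),
            R_sub=np.asarray(d["R_sub"], dtype=float),
            train_center=np.asarray(d["train_center"], dtype=float),
            train_scale=np.asarray(d["train_scale"], dtype=float),
            condition_number=float(d["condition_number"]),
            k=int(d["k"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_projection(model: PLSModel, subset: str | Sequence[str]
                     ) -> ProjectionModel:
    """Restrict a trained model to a feature subset and build its rotation.

    ``subset`` is either a block tag (e.g. ``"GMV"``) or an explicit list
    of feature names; the trained feature order is preserved either way.
    """
    if isinstance(subset, str):
        if model.blocks is None:
            raise ValueError("model carries no block tags; pass explicit names")
        wanted = {subset}
        idx = [i for i, b in enumerate(model.blocks) if b in wanted]
        if not idx:
            raise ValueError(f"no features tagged {subset!r} in the model")
    else:
        subset = list(subset)
        if not subset:
            raise ValueError("empty feature subset")
        pos = {name: i for i, name in enumerate(model.feature_names)}
        missing = [s for s in subset if s not in pos]
        if missing:
            raise ValueError(f"features not in the model: {missing[:5]}")
        idx = sorted(pos[s] for s in subset)
    idx = np.asarray(idx)

    W_sub = model.W[idx]
    P_sub = model.P[idx]
    M = P_sub.T @ W_sub
    cond = float(np.linalg.cond(M))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ValueError(
            f"P_sub^T W_sub is numerically singular (condition number {cond:.3g}); "
            "the projection formula presumes invertibility — choose a larger or "
            "better-conditioned feature subset")
    R_sub = W_sub @ np.linalg.solve(M, np.eye(model.k))
    return ProjectionModel(
        feature_subset=[model.feature_names[i] for i in idx],
        W_sub=W_sub, P_sub=P_sub, R_sub=R_sub,
        train_center=model.x_center[idx], train_scale=model.x_scale[idx],
        condition_number=cond, k=model.k,
    )


def project_cohort(proj: ProjectionModel, X_ext, *,
                   standardize: str = "external") -> np.ndarray:
    """Project external rows into the trained latent space.

    ``X_ext`` must cover exactly ``proj.feature_subset`` (checked by name
    for DataFrames).  ``standardize`` selects the centering/scaling
    statistics: ``"external"`` (default) uses the external cohort's own
    mean/SD, ``"training"`` reuses the stored training statistics.
    """
    if isinstance(X_ext, pd.DataFrame):
        got = [str(c) for c in X_ext.columns]
        for i, (g, w) in enumerate(zip(got, proj.feature_subset)):
            if g != w:
                raise ValueError(
                    f"feature mismatch at column {i}: got {g!r}, expected {w!r}")
        if len(got) != len(proj.feature_subset):
            raise ValueError(
                f"expected {len(proj.feature_subset)} features, got {len(got)}")
        Xm = X_ext.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_ext, dtype=float)
        if Xm.ndim != 2 or Xm.shape[1] != len(proj.feature_subset):
            raise ValueError(
                f"expected {len(proj.feature_subset)} feature columns")
    if standardize == "external":
        center = Xm.mean(axis=0)
        scale = Xm.std(axis=0, ddof=0)
        scale = np.where(scale == 0, 1.0, scale)
    elif standardize == "training":
        center, scale = proj.train_center, proj.train_scale
    else:
        raise ValueError("standardize must be 'external' or 'training'")
    return (Xm - center) / scale @ proj.R_sub


def age_bracket_summary(scores, ages, brackets=ADULT_BRACKETS_YEARS, *,
                        unit: str = "years") -> pd.DataFrame:
    """Mean/SD/n of each score column within each age bracket.

    Brackets are left-closed, right-open ``[lo, hi)`` except the final
    bracket, which is right-closed — the printed bracket lists share
    endpoints, so a deterministic convention is required.  Empty brackets
    are emitted with n=0 and undefined mean/SD; SD is the sample SD
    (ddof=1) and is undefined for n < 2.  Participants outside every
    bracket are counted in the table attribute ``n_outside``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and scores.shape[1] > 1:
        scores = scores.T
    ages = np.asarray(ages, dtype=float).ravel()
    if ages.shape[0] != scores.shape[0]:
        raise ValueError("scores and ages are not row-aligned")
    brackets = [tuple(map(float, b)) for b in brackets]
    for (lo, hi) in brackets:
        if hi <= lo:
            raise ValueError(f"bracket ({lo}, {hi}) is empty or inverted")
    order = sorted(range(len(brackets)), key=lambda i: brackets[i])
    for a, b in zip(order, order[1:]):
        if brackets[b][0] < brackets[a][1]:
            raise ValueError(
                f"brackets {brackets[a]} and {brackets[b]} overlap under the "
                "left-closed convention")

    last = max(range(len(brackets)), key=lambda i: brackets[i][1])
    covered = np.zeros(ages.shape[0], dtype=bool)
    rows = []
    for i, (lo, hi) in enumerate(brackets):
        mask = (ages >= lo) & ((ages <= hi) if i == last else (ages < hi))
        covered |= mask
        for j in range(scores.shape[1]):
            vals = scores[mask, j]
            rows.append({
                "bracket": f"{lo:g}-{hi:g}",
                "bracket_low": lo, "bracket_high": hi, "unit": unit,
                "component": j + 1,
                "n": int(mask.sum()),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            })
    out = pd.DataFrame(rows)
    out.attrs["n_outside"] = int((~covered).sum())
    return out
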