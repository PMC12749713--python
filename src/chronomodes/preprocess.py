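"""Target encoding, participant exclusions, and nuisance residualization.

The data-preparation contract: the six-level diurnal-preference
questionnaire response is collapsed to a binary -1 (early bird) / +1
(night owl) target, shift workers and participants whose coded
chronotype changed between the two assessment visits are excluded, and
brain features are residualized (ordinary least squares, intercept
included) on nuisance covariates.  Age and sex are deliberately *not*
residualized; they are study variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CHRONOTYPE_LEVELS, EVENING_LEVELS, MORNING_LEVELS

#: questionnaire level -> encoded value (None = participant dropped)
ENCODING: dict[str, float | None] = {
    **{level: -1.0 for level in MORNING_LEVELS},
    **{level: +1.0 for level in EVENING_LEVELS},
    **{level: None for level in CHRONOTYPE_LEVELS[4:]},
}

#: nuisance covariate columns the pipeline residualizes on, when present
DEFAULT_NUISANCE = ("site", "motion", "icv", "sleep_duration", "daytime_napping",
                    "insomnia", "snoring", "daytime_dozing")


@dataclass
class EncodedTarget:
    values: np.ndarray  # entries in {-1, +1}
    kept_ids: pd.Index

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isin(self.values, (-1.0, 1.0))):
            raise ValueError("encoded target must contain only -1 and +1")
        if len(self.kept_ids) != len(self.values):
            raise ValueError("kept_ids and values length mismatch")


@dataclass
class ResidualizedFeatures:
    matrix: pd.DataFrame
    coefficients: pd.DataFrame  # design column x feature
    blocks: pd.Series | None = None
    dropped_ids: pd.Index = field(default_factory=lambda: pd.Index([]))


def encode_chronotype(raw: pd.Series) -> EncodedTarget:
    """Collapse six-level responses to -1 / +1; drop non-codable answers.

    Raises ``ValueError`` naming the first unrecognized level.
    """
    raw = pd.Series(raw)
    unknown = set(raw.dropna().unique()) - set(ENCODING)
    if unknown:
        raise ValueError(f"unrecognized chronotype level: {sorted(unknown)[0]!r}")
    mapped = raw.map(lambda v: ENCODING.get(v) if pd.notna(v) else None)
    keep = mapped.notna()
    return EncodedTarget(mapped[keep].to_numpy(dtype=float), raw.index[keep])


def apply_exclusions(table: pd.DataFrame, *,
                     id_col: str = "participant_id",
                     shift_col: str = "shift_work_flag",
                     initial_col: str | None = "chronotype_raw_initial",
                     imaging_col: str = "chronotype_raw") -> pd.Index:
    """Ids surviving the shift-work and visit-consistency exclusions.

    A participant is dropped when the shift-work flag is set, or when the
    initial-visit and imaging-visit responses both encode to a binary
    chronotype and the two codes disagree.  Order is preserved and ids
    are never duplicated.
    """
    for col in filter(None, (id_col, shift_col, imaging_col)):
        if col not in table.columns:
            raise ValueError(f"participant table lacks required column {col!r}")
    keep = ~table[shift_col].astype(bool)
    if initial_col is not None and initial_col in table.columns:
        enc_init = table[initial_col].map(ENCODING)
        enc_imag = table[imaging_col].map(ENCODING)
        both = enc_init.notna() & enc_imag.notna()
        keep &= ~(both & (enc_init != enc_imag))
    return pd.Index(table.loc[keep, id_col])


def build_design(C: pd.DataFrame) -> pd.DataFrame:
    """Intercept + one-hot categoricals (reference level dropped) + numerics."""
    parts = [pd.Series(1.0, index=C.index, name="intercept")]
    for name in C.columns:
        col = C[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def _collinear_columns(D: np.ndarray, names: list[str]) -> list[str]:
    """Name design columns made redundant by earlier ones (pivoted QR)."""
    from scipy.linalg import qr
    _, r, piv = qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def residualize(X: pd.DataFrame, C: pd.DataFrame | None) -> ResidualizedFeatures:
    """Per-feature OLS residuals of X on the covariates in C.

    ``C`` may be empty or ``None`` (intercept-only: output is the
    column-centered X).  Rows with missing covariate values are dropped
    from both the fit and the output, and reported in ``dropped_ids``.
    Rank-deficient designs are rejected, naming the collinear columns.
    """
    X = pd.DataFrame(X)
    if C is None or C.shape[1] == 0:
        C = pd.DataFrame(index=X.index)
    else:
        C = pd.DataFrame(C)
    if not X.index.equals(C.index):
        raise ValueError("feature and covariate tables are not row-aligned")

    complete = ~C.isna().any(axis=1)
    dropped = X.index[~complete]
    Xc, Cc = X.loc[complete], C.loc[complete]

    D = build_design(Cc)
    Dm = D.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Dm)
    if rank < Dm.shape[1]:
        bad = _collinear_columns(Dm, list(D.columns))
        raise ValueError(f"covariate design is rank-deficient; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(Dm, Xc.to_numpy(dtype=float), rcond=None)
    resid = Xc.to_numpy(dtype=float) - Dm @ beta
    return ResidualizedFeatures(
        matrix=pd.DataFrame(resid, index=Xc.index, columns=X.columns),
        coefficients=pd.DataFrame(beta, index=D.columns, columns=X.columns),
        dropped_ids=dropped,
    )


def zscore(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization (mean 0, SD 1; constant columns -> 0)."""
    X = pd.DataFrame(X)
    sd = X.std(ddof=0).replace(0.0, 1.0)
    return (X - X.mean()) / sd


def prepare_cohort(bundle) -> tuple[pd.DataFrame, np.ndarray, pd.Series, pd.DataFrame]:
    """Full preparation chain for one cohort bundle.

    Encodes the imaging-visit chronotype, applies the exclusion rules,
    residualizes the brain features on whichever default nuisance
    covariates the participant table carries, and z-scores the result.
    Returns ``(X, y, block_tags, kept_participant_rows)`` with X and y
    row-aligned on the surviving participants.
    """
    table = bundle.participants.set_index("participant_id")
    target = encode_chronotype(table["chronotype_raw"])
    kept = apply_exclusions(bundle.participants).intersection(target.kept_ids)
    y = pd.Series(target.values, index=target.kept_ids).loc[kept].to_numpy()
    nuisance = [c for c in DEFAULT_NUISANCE if c in table.columns]
    res = residualize(bundle.brain.loc[kept], table.loc[kept, nuisance])
    X = zscore(res.matrix)
    return X, y, bundle.brain_blocks, table.loc[kept]


def preprocessing_report(n_input: int, n_codable: int, n_kept: int) -> str:
    """Plain-text exclusion accounting for the run log."""
    lines = [
        f"participants in: {n_input}",
        f"dropped (non-codable chronotype): {n_input - n_codable}",
        f"dropped (shift work / visit disparity): {n_codable - n_kept}",
        f"participants analysed: {n_kept}",
    ]
    return "\n".join(lines)
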