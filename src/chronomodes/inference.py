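"""Permutation significance and bootstrap loading inference for PLS modes.

Two resampling procedures assess the fitted model:

* :func:`permutation_test` — the target vector is shuffled across
  participants while the brain features are held fixed, and the
  per-component latent correlation is recomputed, yielding an empirical
  null for each component.  Two null schemes are provided (see below).
* :func:`bootstrap_loadings` — participants are resampled with
  replacement, the model is refit, the refit components are re-matched to
  the reference components with the Hungarian algorithm on a correlation
  similarity matrix (sign-aligned after assignment), and 5-95% percentile
  intervals of the x-loadings flag features robustly different from zero.

Null schemes
------------
``"projection"`` (default, the protocol scheme): the trained model's
score columns are held fixed and correlated with each shuffled target.
This matches the common applied practice of testing associations "in the
derived embedding space" of an already-trained model.  Because the
observed in-sample correlation is inflated by the fit itself while the
null draws are not, this scheme is anti-conservative as a test of model
significance; it answers the narrower question "is this fixed latent
projection associated with the target?".

``"refit"`` — the model is refit from scratch on each shuffled target
and the null correlation is taken from the refit model's own scores.
This is the exchangeable, exactly calibrated test of model-level
significance: under the null its p-values are uniform.  Its power is
limited at small n/p because a refit null component is free to chase
noise in the full feature space (in-sample null correlations concentrate
near sqrt(p/(n+p))).

Both schemes use magnitude comparison (|rho|): under the sign
convention the component orientation is arbitrary, so a signed one-sided
comparison would be ill-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .pls import PLSModel, _nipals_pls1, fit_pls, score_target_correlation

NULL_SCHEMES = ("projection", "refit")


@dataclass
class PermutationResult:
    observed_rho: np.ndarray  # k, signed
    null_rho: np.ndarray      # B x k, signed
    p_values: np.ndarray      # k; (1 + exceedances of |rho|) / (1 + B)
    B: int
    seed: int
    null_scheme: str

    def significant(self, alpha: float = 0.001) -> np.ndarray:
        return self.p_values < alpha


@dataclass
class BootstrapResult:
    loading_draws: np.ndarray  # B x p x k, matched and sign-aligned
    ci_low: np.ndarray         # p x k (5th percentile by default)
    ci_high: np.ndarray        # p x k (95th percentile by default)
    significant: np.ndarray    # p x k boolean: CI excludes zero
    B: int
    seed: int
    n_redraws: int
    reference: PLSModel


def _empirical_p(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """(1 + #{|null| >= |obs|}) / (1 + B), per component."""
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + null.shape[0])


def permutation_test(X, y, k: int, B: int = 1000, seed: int = 0, *,
                     null_scheme: str = "projection", scale: bool = True,
                     refit_budget: int = 500_000) -> PermutationResult:
    """Empirical null for per-component latent correlations under target shuffling.

    Per iteration the target is permuted uniformly and the per-component
    correlation magnitude is recorded positionally (null component j is
    compared with observed component j; no max-statistic pooling).
    p-values use the add-one estimator, so the smallest attainable value
    is 1/(1+B) and observations that beat every null draw reproduce the
    "stronger than all null models" decision rule.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if null_scheme not in NULL_SCHEMES:
        raise ValueError(f"null_scheme must be one of {NULL_SCHEMES}")
    model = fit_pls(X, y, k, scale=scale)
    y = np.asarray(y, dtype=float).ravel()
    observed = score_target_correlation(model.T, y)

    rng = np.random.default_rng(seed)
    n = y.shape[0]
    null = np.empty((B, k))
    if null_scheme == "projection":
        # fixed trained embedding; only the correlation is recomputed
        Tc = model.T - model.T.mean(axis=0)
        Tn = Tc / np.linalg.norm(Tc, axis=0)
        yc = y - y.mean()
        yn = yc / np.linalg.norm(yc)
        for b in range(B):
            null[b] = Tn.T @ yn[rng.permutation(n)]
    else:
        if B * k > refit_budget:
            warnings.warn(
                f"permutation refit budget exceeded ({B} x {k} component fits); "
                "proceeding anyway", RuntimeWarning, stacklevel=2)
        Xc = (np.asarray(X, dtype=float) - model.x_center) / model.x_scale
        for b in range(B):
            yp = y[rng.permutation(n)]
            _, _, T_null, _, _ = _nipals_pls1(Xc, yp - yp.mean(), k)
            null[b] = score_target_correlation(T_null, yp)

    return PermutationResult(
        observed_rho=observed, null_rho=null,
        p_values=_empirical_p(observed, null),
        B=B, seed=seed, null_scheme=null_scheme,
    )


def match_components(L_boot: np.ndarray, L_ref: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of resampled components to reference components.

    A correlation similarity matrix is computed between the two loading
    matrices (columns = components); the assignment maximizes the total
    |correlation|, and the sign of each matched correlation is returned
    so the caller can align orientations.  Returns ``(perm, signs)`` such
    that ``L_boot[:, perm] * signs`` is the matched, sign-aligned matrix.
    """
    L_boot = np.asarray(L_boot, dtype=float)
    L_ref = np.asarray(L_ref, dtype=float)
    if L_boot.shape != L_ref.shape:
        raise ValueError("loading matrices must share a shape")
    p, k = L_ref.shape
    if k > p:
        raise ValueError("more components than features")
    Ab = L_boot - L_boot.mean(axis=0)
    Ar = L_ref - L_ref.mean(axis=0)
    nb = np.linalg.norm(Ab, axis=0)
    nr = np.linalg.norm(Ar, axis=0)
    if np.any(nb == 0) or np.any(nr == 0):
        raise ValueError("constant loading column: correlation undefined")
    corr = (Ab / nb).T @ (Ar / nr)  # k_boot x k_ref
    boot_idx, ref_idx = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(k, dtype=int)
    perm[ref_idx] = boot_idx
    signs = np.sign(corr[perm, np.arange(k)])
    signs[signs == 0] = 1.0
    return perm, signs


def bootstrap_loadings(X, y, k: int, B: int = 1000, seed: int = 0, *,
                       scale: bool = True, ci: tuple[float, float] = (5.0, 95.0),
                       max_redraws: int = 10_000) -> BootstrapResult:
    """Percentile-CI inference on x-loadings under participant resampling.

    Each iteration resamples rows with replacement (same sample size),
    refits, matches the refit components to the reference model's
    loadings (Hungarian, sign-aligned), and records the aligned loading
    matrix.  A loading is flagged significant when its two-sided
    percentile interval excludes zero.  Resamples that lose one target
    class are redrawn (the count is reported).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    reference = fit_pls(X, y, k, scale=scale)
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape

    rng = np.random.default_rng(seed)
    draws = np.empty((B, p, k))
    n_redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == 2:
                break
            n_redraws += 1
        else:
            raise ValueError("could not draw a two-class bootstrap resample")
        boot = fit_pls(Xm[idx], y[idx], k, scale=scale)
        perm, signs = match_components(boot.P, reference.P)
        draws[b] = boot.P[:, perm] * signs

    lo, hi = np.percentile(draws, list(ci), axis=0)
    significant = (lo > 0) | (hi < 0)
    return BootstrapResult(
        loading_draws=draws, ci_low=lo, ci_high=hi, significant=significant,
        B=B, seed=seed, n_redraws=n_redraws, reference=reference,
    )
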