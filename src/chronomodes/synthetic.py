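"""Synthetic cohorts with planted brain-chronotype covariance modes.

Real population cohorts with multimodal imaging-derived phenotypes (IDPs)
are access-restricted, so every downstream stage of the pipeline is
exercised against cohorts generated here.  The generator plants a small
number of low-rank covariance modes between a brain feature matrix and a
binary morningness/eveningness target, leaks nuisance covariates into the
features, and attaches a phenome (behavior / diagnosis / medication
families) with known associations to the planted latent scores.  A
:class:`GroundTruth` object is returned alongside each cohort so recovery
can be measured exactly.

Model
-----
Latent scores ``Z`` are i.i.d. standard normal (n x k).  The brain matrix
is ``X = Z diag(c) V^T + C G + noise_sd * E`` with unit-norm sparse
loading columns ``V`` (random +/- entries, block-restricted support),
``C`` the numeric covariate matrix scaled by a leakage coefficient, and
``E`` i.i.d. standard normal.  The binary target is produced by a
liability threshold: ``L = sum_j rho_j Z_j + sqrt(1 - sum rho_j^2) eps``
is cut at the normal quantile of ``1 - target_balance``; ``rho_j`` is
chosen in closed form so that the point-biserial correlation between
``Z_j`` and the +/-1 target equals the configured ``mode_strengths[j]``.
Age enters through a rank-remap of a latent-weighted Gaussian onto the
configured uniform age range, which preserves the Gaussianity of ``Z``
while planting sign-controlled age-score associations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

GMV, FA, FC = "GMV", "FA", "FC"
BLOCKS = (GMV, FA, FC)

FAMILIES = ("behavior", "diagnosis", "medication")

#: The six questionnaire responses, in their canonical order.
CHRONOTYPE_LEVELS = (
    "definitely a morning person",
    "more a morning than an evening person",
    "more an evening than a morning person",
    "definitely an evening person",
    "do not know",
    "prefer not to answer",
)
MORNING_LEVELS = CHRONOTYPE_LEVELS[:2]
EVENING_LEVELS = CHRONOTYPE_LEVELS[2:4]
NONCODABLE_LEVELS = CHRONOTYPE_LEVELS[4:]

SLEEP_VARIABLES = (
    "sleep_duration",
    "daytime_napping",
    "insomnia",
    "snoring",
    "daytime_dozing",
)


@dataclass(frozen=True)
class CovariateSpec:
    """Nuisance structure leaked into the brain features.

    ``leakage`` is the standard deviation of the random per-feature
    coefficients on the (standardized) numeric covariate columns; 0 turns
    covariate contamination off entirely.
    """

    n_sites: int = 3
    sleep_variables: tuple[str, ...] = SLEEP_VARIABLES
    motion: bool = True
    leakage: float = 0.2


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic cohort draw.

    Defaults emulate the adult study design: 139 regional grey matter
    volumes, 48 white-matter tract FA values, functional coupling links
    between 21 network components (21*20/2 = 210 features), a -1/+1
    morningness/eveningness target with roughly one third night owls,
    five planted modes, and a phenome of 977 behavioral, 1,396 diagnosis
    and 133 medication phenotypes.
    """

    n_participants: int = 2000
    gmv: int = 139
    fa: int = 48
    fc_components: int = 21
    n_modes: int = 5
    mode_strengths: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10)
    mode_amplitude: float = 3.0
    loading_sparsity: float = 0.10
    #: optional per-mode restriction of loading support to a subset of blocks
    mode_block_support: tuple[tuple[str, ...], ...] | None = None
    noise_sd: float = 1.0
    target_balance: float = 0.334
    n_phenotypes_per_family: Mapping[str, int] = field(
        default_factory=lambda: {"behavior": 977, "diagnosis": 1396, "medication": 133}
    )
    n_planted_per_mode: int = 3
    phenotype_effects: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10)
    binary_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"diagnosis": 0.05, "medication": 0.10}
    )
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    age_range: tuple[float, float] = (40.0, 70.0)
    age_unit: str = "years"
    age_effects: tuple[float, ...] = (-0.30, 0.20, 0.20, 0.15, 0.15)
    sex_ratio: float = 0.5444
    noncodable_rate: float = 0.02
    shift_work_rate: float = 0.02
    inconsistent_rate: float = 0.01
    seed: int = 42

    @property
    def fc(self) -> int:
        """Number of FC features: one per unordered component pair."""
        return self.fc_components * (self.fc_components - 1) // 2

    @property
    def block_sizes(self) -> dict[str, int]:
        return {GMV: self.gmv, FA: self.fa, FC: self.fc}

    @property
    def n_features(self) -> int:
        return self.gmv + self.fa + self.fc

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("gmv", "fa", "fc_components"):
            if getattr(self, name) <= 0:
                raise ValueError(f"block size {name!r} must be positive")
        if self.n_modes <= 0:
            raise ValueError("n_modes must be positive")
        strengths = np.asarray(self.mode_strengths, dtype=float)
        if strengths.shape != (self.n_modes,):
            raise ValueError("mode_strengths must have one entry per mode")
        if np.any(strengths < 0) or np.any(strengths >= 1):
            raise ValueError("mode_strengths must lie in [0, 1)")
        if np.any(np.diff(strengths) > 0):
            raise ValueError("mode_strengths must be sorted non-increasing")
        if not 0 < self.loading_sparsity <= 1:
            raise ValueError("loading_sparsity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.target_balance < 1:
            raise ValueError("target_balance must lie in (0, 1)")
        if len(self.age_effects) != self.n_modes:
            raise ValueError("age_effects must have one entry per mode")
        if len(self.phenotype_effects) != self.n_modes:
            raise ValueError("phenotype_effects must have one entry per mode")
        rho = _liability_weights(strengths, self.target_balance)
        if float(rho @ rho) >= 1.0:
            raise ValueError(
                "mode_strengths infeasible: the implied liability weights have "
                f"squared norm {float(rho @ rho):.3f} >= 1"
            )
        a = np.asarray(self.age_effects, dtype=float)
        if float(a @ a) >= 1.0:
            raise ValueError("age_effects infeasible: squared norm >= 1")
        if self.mode_block_support is not None:
            if len(self.mode_block_support) != self.n_modes:
                raise ValueError("mode_block_support must have one entry per mode")
            for support in self.mode_block_support:
                unknown = set(support) - set(BLOCKS)
                if unknown:
                    raise ValueError(f"unknown blocks in mode_block_support: {sorted(unknown)}")
                if not support:
                    raise ValueError("each mode needs at least one supporting block")
        for block, size in self.block_sizes.items():
            if max(1, round(self.loading_sparsity * size)) > size:
                raise ValueError(f"loading_sparsity infeasible for block {block}")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_phenotypes_per_family"] = dict(self.n_phenotypes_per_family)
        d["binary_prevalence"] = dict(self.binary_prevalence)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "covariates" in d and isinstance(d["covariates"], Mapping):
            cov = dict(d["covariates"])
            if "sleep_variables" in cov:
                cov["sleep_variables"] = tuple(cov["sleep_variables"])
            d["covariates"] = CovariateSpec(**cov)
        for key in ("mode_strengths", "age_effects", "phenotype_effects"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("mode_block_support") is not None:
            d["mode_block_support"] = tuple(tuple(s) for s in d["mode_block_support"])
        for key in ("age_range",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CohortBundle:
    """One cohort: participants, block-tagged brain features, phenome."""

    participants: pd.DataFrame
    brain: pd.DataFrame
    brain_blocks: pd.Series
    phenome: dict[str, pd.DataFrame]
    phenome_meta: dict[str, pd.DataFrame]

    @property
    def n(self) -> int:
        return len(self.participants)

    def block_features(self, block: str) -> list[str]:
        return list(self.brain_blocks.index[self.brain_blocks == block])

    def validate(self) -> None:
        ids = self.participants["participant_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate participant ids")
        if not self.brain.index.equals(pd.Index(ids)):
            raise ValueError("brain matrix not row-aligned to participant table")
        if not self.brain_blocks.index.equals(self.brain.columns):
            raise ValueError("block tags not aligned to brain feature columns")
        unknown = set(self.brain_blocks.unique()) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown block tags: {sorted(unknown)}")
        for family, table in self.phenome.items():
            if not table.index.equals(self.brain.index):
                raise ValueError(f"phenome family {family!r} not row-aligned")


@dataclass
class GroundTruth:
    """What was planted: the recovery oracle for every downstream stage."""

    latent_scores: np.ndarray  # n x k
    true_loadings: np.ndarray  # p x k, unit-norm columns
    feature_names: list[str]
    true_target_correlations: np.ndarray  # k
    target: np.ndarray  # planted -1/+1 vector, pre-exclusion
    age_effects: np.ndarray  # k, signed age-latent associations
    phenotype_effect_map: dict[str, tuple[int, float]]  # name -> (mode, effect)

    def loading_block(self, blocks: pd.Series, block: str) -> np.ndarray:
        mask = np.asarray(blocks.reindex(self.feature_names) == block)
        return self.true_loadings[mask]


def _liability_weights(strengths: np.ndarray, balance: float) -> np.ndarray:
    """Liability weights giving point-biserial corr(Z_j, y) = strengths[j].

    With standard-normal liability L cut at tau = Phi^-1(1 - balance) and
    y in {-1, +1}: corr(Z_j, y) = rho_j * phi(tau) / sqrt(balance * (1 - balance)).
    """
    tau = norm.ppf(1.0 - balance)
    return strengths * math.sqrt(balance * (1.0 - balance)) / norm.pdf(tau)


def _feature_names(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    names: list[str] = []
    blocks: list[str] = []
    names += [f"GMV_{i + 1:03d}" for i in range(config.gmv)]
    blocks += [GMV] * config.gmv
    names += [f"FA_{i + 1:03d}" for i in range(config.fa)]
    blocks += [FA] * config.fa
    for i in range(config.fc_components):
        for j in range(i + 1, config.fc_components):
            names.append(f"FC_c{i + 1:02d}_c{j + 1:02d}")
            blocks.append(FC)
    return names, blocks


def _planted_loadings(config: GeneratorConfig, rng: np.random.Generator,
                      blocks: np.ndarray) -> np.ndarray:
    """Unit-norm sparse +/- loading columns with block-restricted support."""
    p = config.n_features
    V = np.zeros((p, config.n_modes))
    support_spec = config.mode_block_support or tuple(
        BLOCKS for _ in range(config.n_modes)
    )
    for j, allowed in enumerate(support_spec):
        rows: list[int] = []
        for block in allowed:
            block_idx = np.flatnonzero(blocks == block)
            m = max(1, round(config.loading_sparsity * block_idx.size))
            rows.extend(rng.choice(block_idx, size=m, replace=False))
        rows = np.asarray(sorted(rows))
        V[rows, j] = rng.choice([-1.0, 1.0], size=rows.size)
        V[:, j] /= np.linalg.norm(V[:, j])
    return V


def _draw_ages(config: GeneratorConfig, rng: np.random.Generator,
               Z: np.ndarray, reverse: bool = False) -> np.ndarray:
    """Ages uniform on age_range, rank-coupled to the latent scores.

    A Gaussian age propensity sum_j a_j Z_j + noise is mapped through its
    empirical ranks onto the uniform age range; the monotone remap keeps
    the sign (and most of the magnitude) of each planted age-latent
    association while leaving Z exactly standard normal.
    """
    a = np.asarray(config.age_effects, dtype=float)
    if reverse:
        a = -a
    resid = math.sqrt(max(1.0 - float(a @ a), 0.0))
    propensity = Z @ a + resid * rng.standard_normal(Z.shape[0])
    u = (rankdata(propensity, method="ordinal") - 0.5) / Z.shape[0]
    lo, hi = config.age_range
    return lo + (hi - lo) * u


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator,
                     n: int, extra_continuous: tuple[str, ...] = ()) -> pd.DataFrame:
    spec = config.covariates
    cols: dict[str, np.ndarray] = {}
    cols["site"] = rng.integers(1, spec.n_sites + 1, size=n)
    if spec.motion:
        cols["motion"] = rng.standard_normal(n)
    for name in extra_continuous:
        cols[name] = rng.standard_normal(n)
    for name in spec.sleep_variables:
        cols[name] = rng.standard_normal(n)
    df = pd.DataFrame(cols)
    df["site"] = df["site"].map(lambda s: f"site_{s}").astype("category")
    return df


def _numeric_covariates(cov: pd.DataFrame) -> np.ndarray:
    """One-hot sites (reference level dropped) + standardized continuous."""
    parts = []
    for name in cov.columns:
        col = cov[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(parts) if parts else np.empty((len(cov), 0))


def _raw_chronotype(rng: np.random.Generator, y: np.ndarray,
                    noncodable_rate: float) -> np.ndarray:
    """Map the planted +/-1 target to six-level questionnaire responses."""
    n = y.shape[0]
    definite = rng.random(n) < 0.5
    raw = np.where(
        y < 0,
        np.where(definite, MORNING_LEVELS[0], MORNING_LEVELS[1]),
        np.where(definite, EVENING_LEVELS[1], EVENING_LEVELS[0]),
    ).astype(object)
    noncodable = rng.random(n) < noncodable_rate
    raw[noncodable] = rng.choice(NONCODABLE_LEVELS, size=int(noncodable.sum()))
    return raw


def _generate_phenome(config: GeneratorConfig, rng: np.random.Generator,
                      Z: np.ndarray
                      ) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame],
                                 dict[str, tuple[int, float]]]:
    """Phenome families with per-mode planted associations.

    Continuous (behavior) planted columns are ``eff * Z_j + sqrt(1-eff^2) *
    noise``; binary (diagnosis / medication) columns come from a liability
    threshold at the configured prevalence.  All remaining columns are pure
    noise of the matching type.
    """
    n, k = Z.shape
    categories = {
        "behavior": ("cognition", "lifestyle", "physical", "mood"),
        "diagnosis": ("circulatory", "endocrine", "mental", "genitourinary"),
        "medication": ("cardiovascular", "nervous_system", "alimentary"),
    }
    tables: dict[str, pd.DataFrame] = {}
    metas: dict[str, pd.DataFrame] = {}
    effect_map: dict[str, tuple[int, float]] = {}
    for family in FAMILIES:
        q = int(config.n_phenotypes_per_family[family])
        binary = family in config.binary_prevalence
        planted_total = min(config.n_planted_per_mode * k, q)
        data = np.empty((n, q))
        names = [f"{family[:3]}_{i + 1:04d}" for i in range(q)]
        col = 0
        for j in range(k):
            eff = float(config.phenotype_effects[j])
            for _ in range(config.n_planted_per_mode):
                if col >= planted_total:
                    break
                signal = eff * Z[:, j] + math.sqrt(1 - eff**2) * rng.standard_normal(n)
                if binary:
                    prev = float(config.binary_prevalence[family])
                    data[:, col] = (signal > norm.ppf(1 - prev)).astype(float)
                else:
                    data[:, col] = signal
                effect_map[names[col]] = (j, eff)
                col += 1
        while col < q:
            noise = rng.standard_normal(n)
            if binary:
                prev = float(config.binary_prevalence[family])
                data[:, col] = (noise > norm.ppf(1 - prev)).astype(float)
            else:
                data[:, col] = noise
            col += 1
        tables[family] = pd.DataFrame(data, columns=names)
        metas[family] = pd.DataFrame({
            "phenotype": names,
            "category": [categories[family][i % len(categories[family])]
                         for i in range(q)],
            "type": "binary" if binary else "continuous",
            "family": family,
        })
    return tables, metas, effect_map


def generate_cohort(config: GeneratorConfig | None = None
                    ) -> tuple[CohortBundle, GroundTruth]:
    """Generate one cohort plus its ground truth.

    Deterministic given ``config`` (byte-identical tables for the same
    seed and settings).
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k, p = config.n_participants, config.n_modes, config.n_features

    names, block_list = _feature_names(config)
    blocks = np.asarray(block_list)

    Z = rng.standard_normal((n, k))
    strengths = np.asarray(config.mode_strengths, dtype=float)
    rho = _liability_weights(strengths, config.target_balance)
    resid = math.sqrt(1.0 - float(rho @ rho))
    liability = Z @ rho + resid * rng.standard_normal(n)
    tau = norm.ppf(1.0 - config.target_balance)
    y = np.where(liability > tau, 1.0, -1.0)

    V = _planted_loadings(config, rng, blocks)
    ages = _draw_ages(config, rng, Z)
    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    cov = _draw_covariates(config, rng, n)
    C = _numeric_covariates(cov)
    G = rng.standard_normal((C.shape[1], p)) * config.covariates.leakage

    X = (Z * config.mode_amplitude) @ V.T + C @ G \
        + config.noise_sd * rng.standard_normal((n, p))

    raw_imaging = _raw_chronotype(rng, y, config.noncodable_rate)
    raw_initial = raw_imaging.copy()
    flip = rng.random(n) < config.inconsistent_rate
    codable = ~np.isin(raw_initial, NONCODABLE_LEVELS)
    for i in np.flatnonzero(flip & codable):
        if raw_initial[i] in MORNING_LEVELS:
            raw_initial[i] = rng.choice(EVENING_LEVELS)
        else:
            raw_initial[i] = rng.choice(MORNING_LEVELS)
    shift_work = rng.random(n) < config.shift_work_rate

    ids = [f"P{i + 1:06d}" for i in range(n)]
    participants = pd.DataFrame({
        "participant_id": ids,
        "age": ages,
        "age_unit": config.age_unit,
        "sex": sex,
        "chronotype_raw_initial": raw_initial,
        "chronotype_raw": raw_imaging,
        "shift_work_flag": shift_work,
    })
    participants = pd.concat([participants, cov], axis=1)

    brain = pd.DataFrame(X, columns=names, index=pd.Index(ids, name="participant_id"))
    brain_blocks = pd.Series(blocks, index=brain.columns, name="block")

    phenome, metas, effect_map = _generate_phenome(config, rng, Z)
    for family in phenome:
        phenome[family].index = brain.index

    bundle = CohortBundle(participants, brain, brain_blocks, phenome, metas)
    bundle.validate()
    truth = GroundTruth(
        latent_scores=Z,
        true_loadings=V,
        feature_names=names,
        true_target_correlations=strengths,
        target=y,
        age_effects=np.asarray(config.age_effects, dtype=float),
        phenotype_effect_map=effect_map,
    )
    return bundle, truth


def default_external_config(source: GeneratorConfig, *,
                            n_participants: int = 1500,
                            seed: int | None = None) -> GeneratorConfig:
    """Companion config for the external (child) cohort: months, 107-133."""
    return source.replace(
        n_participants=n_participants,
        age_range=(107.0, 133.0),
        age_unit="months",
        seed=source.seed + 1 if seed is None else seed,
    )


def generate_external_cohort(config: GeneratorConfig, truth: GroundTruth
                             ) -> tuple[CohortBundle, GroundTruth]:
    """GMV-only external cohort sharing the source GMV loading structure.

    The external cohort measures only the grey-matter block; its GMV
    loading rows are copied verbatim from ``truth`` so that cross-cohort
    projection is exact by construction.  Each planted age-latent
    association has its sign reversed relative to the source design,
    emulating reversed age distributions between an adult and a child
    cohort.
    """
    config.validate()
    src_blocks = pd.Series(
        [n.split("_")[0] for n in truth.feature_names], index=truth.feature_names
    )
    gmv_names = [n for n in truth.feature_names if n.startswith("GMV_")]
    if not gmv_names:
        raise ValueError("ground truth lacks GMV loadings; cannot build external cohort")
    V_gmv = truth.loading_block(src_blocks, GMV)
    if not np.any(V_gmv):
        raise ValueError("ground truth GMV loadings are all zero")

    rng = np.random.default_rng(config.seed)
    n, k = config.n_participants, truth.latent_scores.shape[1]
    p = len(gmv_names)

    Z = rng.standard_normal((n, k))
    strengths = truth.true_target_correlations
    rho = _liability_weights(strengths, config.target_balance)
    resid = math.sqrt(1.0 - float(rho @ rho))
    liability = Z @ rho + resid * rng.standard_normal(n)
    tau = norm.ppf(1.0 - config.target_balance)
    y = np.where(liability > tau, 1.0, -1.0)

    ages = _draw_ages(config, rng, Z, reverse=True)
    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    cov = _draw_covariates(config, rng, n, extra_continuous=("icv",))
    C = _numeric_covariates(cov)
    G = rng.standard_normal((C.shape[1], p)) * config.covariates.leakage

    X = (Z * config.mode_amplitude) @ V_gmv.T + C @ G \
        + config.noise_sd * rng.standard_normal((n, p))

    raw = _raw_chronotype(rng, y, config.noncodable_rate)
    ids = [f"E{i + 1:06d}" for i in range(n)]
    participants = pd.DataFrame({
        "participant_id": ids,
        "age": ages,
        "age_unit": config.age_unit,
        "sex": sex,
        "chronotype_raw_initial": raw,
        "chronotype_raw": raw,
        "shift_work_flag": np.zeros(n, dtype=bool),
    })
    participants = pd.concat([participants, cov], axis=1)

    brain = pd.DataFrame(X, columns=gmv_names,
                         index=pd.Index(ids, name="participant_id"))
    brain_blocks = pd.Series(GMV, index=brain.columns, name="block")

    bundle = CohortBundle(participants, brain, brain_blocks, {}, {})
    bundle.validate()
    ext_truth = GroundTruth(
        latent_scores=Z,
        true_loadings=V_gmv,
        feature_names=gmv_names,
        true_target_correlations=strengths.copy(),
        target=y,
        age_effects=-truth.age_effects,
        phenotype_effect_map={},
    )
    return bundle, ext_truth
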