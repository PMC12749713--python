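"""Mass-univariate association scans of brain scores against a phenome.

Each scan (behavioral PheWAS, diagnosis DiaWAS, medication MedWAS)
correlates every phenotype column with every latent score column using
Pearson correlation on pairwise-complete observations (binary phenotypes
enter as 0/1 numerics, i.e. point-biserial), converts r to a two-sided
p-value through the t transform with ``n_used - 2`` degrees of freedom,
and applies Bonferroni control *within* the family: a row is significant
when ``p < alpha / m_family`` with ``m_family`` the number of phenotypes
actually tested in that family.  Results are reported as -log10(p) in
the Manhattan-plot convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: statuses a phenotype row can carry
TESTED, UNTESTED, ZERO_VARIANCE = "tested", "untested", "zero_variance"

_P_FLOOR = np.nextafter(0, 1)  # smallest positive double; keeps -log10 finite


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    df = x.size - 2
    if abs(r) == 1.0:
        return r, _P_FLOOR
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, max(float(p), _P_FLOOR)


def filter_missingness(phenome: pd.DataFrame, min_coverage: float = 0.8
                       ) -> pd.DataFrame:
    """Drop phenotypes observed in fewer than ``min_coverage`` of participants."""
    coverage = phenome.notna().mean(axis=0)
    return phenome.loc[:, coverage >= min_coverage]


def run_association_scan(scores, phenome: pd.DataFrame, family: str, *,
                         alpha: float = 0.05, min_n: int = 50,
                         meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scan one phenome family against every score column.

    Returns a long-format table keyed by (component, family, phenotype,
    category) with r, n_used, p, neglog10p, the family Bonferroni
    threshold, the significance flag, and a status column; zero-variance
    or under-observed phenotypes are emitted flagged rather than dropped.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and scores.shape[1] > 1 and len(phenome) > 1:
        scores = scores.T
    phenome = pd.DataFrame(phenome)
    if scores.shape[0] != len(phenome):
        raise ValueError("scores and phenome are not row-aligned")
    n, k = scores.shape

    categories = {}
    types = {}
    if meta is not None:
        categories = dict(zip(meta["phenotype"], meta.get("category", "")))
        types = dict(zip(meta["phenotype"], meta.get("type", "")))

    values = phenome.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    rows = []
    for c_idx, name in enumerate(phenome.columns):
        mask = observed[:, c_idx]
        n_used = int(mask.sum())
        col = values[mask, c_idx]
        for j in range(k):
            row = {
                "component": j + 1,
                "family": family,
                "phenotype": str(name),
                "category": categories.get(name, ""),
                "type": types.get(name, ""),
                "n_used": n_used,
                "r": np.nan, "p": np.nan, "neglog10p": np.nan,
                "status": TESTED,
            }
            if n_used < max(min_n, 3):
                row["status"] = UNTESTED
            elif np.ptp(col) == 0 or np.ptp(scores[mask, j]) == 0:
                row["status"] = ZERO_VARIANCE
            else:
                r, p = _pearson_with_p(scores[mask, j], col)
                row.update(r=r, p=p, neglog10p=-np.log10(p))
            rows.append(row)

    table = pd.DataFrame(rows)
    tested = table["status"] == TESTED
    m_family = int(table.loc[tested, "phenotype"].nunique())
    threshold = alpha / m_family if m_family else np.nan
    table["m_family"] = m_family
    table["threshold"] = threshold
    table["significant"] = tested & (table["p"] < threshold)
    return table


def summarize_hits(table: pd.DataFrame) -> pd.DataFrame:
    """Significant rows ranked within (component, family, category).

    Ordered by -log10(p) descending; ties broken by |r| descending, then
    by phenotype name for stability.
    """
    if table.empty:
        return table.iloc[0:0].copy()
    hits = table[table["significant"]].copy()
    if hits.empty:
        return hits
    hits["_absr"] = hits["r"].abs()
    hits = hits.sort_values(
        by=["component", "family", "category", "neglog10p", "_absr", "phenotype"],
        ascending=[True, True, True, False, False, True],
        kind="mergesort",
    ).drop(columns="_absr")
    hits["rank_in_category"] = hits.groupby(
        ["component", "family", "category"]).cumcount() + 1
    return hits.reset_index(drop=True)
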