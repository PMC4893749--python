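"""Nonparametric univariate tests and FDR-controlled differential OTUs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import OtuTable

EXACT_MWU_MAX_N = 12  # combined sample size below which the exact null is used


@dataclasses.dataclass
class TestResult:
    feature: str
    statistic: float
    raw_p: float
    adjusted_p: float
    direction: str  # enriched / depleted / unchanged, first cell vs reference
    significant: bool


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).

    The exact null distribution is enumerated when the combined sample
    size is at most 12 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used. Samples
    that are entirely one constant shared by both groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p on g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_otus(
    table,
    metadata: pd.DataFrame | None,
    cell_a: tuple[str, int],
    cell_b: tuple[str, int],
    alpha_fdr: float = 0.05,
) -> list[TestResult]:
    """Per-OTU Mann-Whitney between two (group, day) cells, BH-adjusted.

    ``table`` is an OtuTable (relative abundances are computed) or an
    already-normalised samples x OTUs DataFrame with ``metadata``
    supplied separately. Direction is the sign of the median difference
    of ``cell_a`` minus ``cell_b`` (the reference).
    """
    if isinstance(table, OtuTable):
        rel = table.relative_abundances()
        metadata = table.metadata
    else:
        rel = table
        if metadata is None:
            raise ValueError("metadata required with a plain DataFrame")
    meta = metadata.loc[rel.index]

    def cell_ids(cell):
        g, d = cell
        return rel.index[(meta["group"] == g) & (meta["day"] == int(d))]

    a_ids, b_ids = cell_ids(cell_a), cell_ids(cell_b)
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError("empty contrast cell")
    stats_, raw = [], []
    for otu in rel.columns:
        u, p = mann_whitney_u(rel.loc[a_ids, otu], rel.loc[b_ids, otu])
        stats_.append(u)
        raw.append(p)
    adjusted = benjamini_hochberg(raw)
    results = []
    for otu, u, p, q in zip(rel.columns, stats_, raw, adjusted):
        diff = float(
            rel.loc[a_ids, otu].median() - rel.loc[b_ids, otu].median()
        )
        direction = "enriched" if diff > 0 else "depleted" if diff < 0 else "unchanged"
        results.append(
            TestResult(
                feature=otu,
                statistic=float(u),
                raw_p=float(p),
                adjusted_p=float(q),
                direction=direction,
                significant=bool(q < alpha_fdr),
            )
        )
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results]).set_index(
        "feature"
    )
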