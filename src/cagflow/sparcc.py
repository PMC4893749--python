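"""SparCC: basis correlations from compositional counts, plus networks.

Relative abundances carry no information about absolute scale, so naive
Pearson correlations of fractions are biased (closure). SparCC instead
works from log-ratio variances t_ij = Var log(x_i/x_j), which are
invariant to per-sample scaling. Under a sparsity assumption (most taxa
uncorrelated) the basis variances omega solve a linear system in the
row sums of t, and basis correlations follow as

    rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)).

Strongly correlated pairs violate sparsity, so the most extreme pair is
iteratively excluded from the system; fractions are resampled from the
Dirichlet posterior of the counts (add-one smoothing) and the median
over resampling iterations is reported. Significance is assessed
against a null built by independently permuting each taxon's counts
across samples, which destroys all inter-taxon association while
preserving marginals.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd

from .containers import OtuTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SparccResult:
    rho: pd.DataFrame
    omega: pd.Series
    p_values: pd.DataFrame | None = None
    n_null: int = 0
    excluded_pairs: set = dataclasses.field(default_factory=set)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.rho.index)


def _counts_frame(counts) -> pd.DataFrame:
    if isinstance(counts, OtuTable):
        return counts.counts
    return counts


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = unbiased sample variance over samples of log(f_i / f_j).

    ``fractions`` is samples x OTUs with strictly positive entries.
    Computed from the covariance of the log fractions:
    Var(a - b) = Var a + Var b - 2 Cov(a, b).
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape[1] < 4:
        raise ValueError("SparCC requires at least 4 OTUs")
    if f.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if (f <= 0).any():
        raise ValueError("fractions must be strictly positive (apply pseudocounts)")
    logf = np.log(f)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum(t, 0.0)
    np.fill_diagonal(t, 0.0)
    return t


def basis_correlations_once(
    T: np.ndarray, excluded: set[tuple[int, int]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the sparsity approximation for one log-ratio variance matrix.

    The linear system M omega = rowsums(T) has diagonal (number of
    retained partners) and off-diagonal 1 for retained pairs, 0 for
    excluded ones. Non-positive omega estimates are flagged and the
    affected OTU's correlations zeroed.
    """
    T = np.asarray(T, dtype=float)
    p = T.shape[0]
    if p < 4:
        raise ValueError("need at least 4 OTUs")
    t = T.copy()
    M = np.ones((p, p)) + np.diag([p - 2.0] * p)
    for i, j in excluded or ():
        t[i, j] = t[j, i] = 0.0
        M[i, j] = M[j, i] = 0.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
    omega = np.linalg.solve(M, t.sum(axis=1))
    bad = omega <= 0
    if bad.any():
        logger.warning(
            "non-positive basis variance for %d OTU(s); their correlations set to 0",
            int(bad.sum()),
        )
    om = np.where(bad, 1.0, omega)  # placeholder to keep sqrt defined
    denom = 2.0 * np.sqrt(np.outer(om, om))
    rho = (om[:, None] + om[None, :] - T) / denom
    rho = np.clip(rho, -1.0, 1.0)
    rho[bad, :] = 0.0
    rho[:, bad] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho, omega


def _estimate_once(
    fractions: np.ndarray,
    exclusion_threshold: float,
    max_exclusions: int,
) -> tuple[np.ndarray, np.ndarray, set[tuple[int, int]]]:
    T = log_ratio_variances(fractions)
    excluded: set[tuple[int, int]] = set()
    rho, omega = basis_correlations_once(T, excluded)
    for _ in range(max_exclusions):
        a = np.abs(rho.copy())
        np.fill_diagonal(a, 0.0)
        for i, j in excluded:
            a[i, j] = a[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(a), a.shape)
        if a[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        rho, omega = basis_correlations_once(T, excluded)
    return rho, omega, excluded


def sparcc_estimate(
    counts,
    n_est_iter: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int = 0,
) -> SparccResult:
    """Full SparCC estimate on a count table.

    Per iteration, fractions are drawn from the Dirichlet posterior of
    each sample's counts (add-one smoothing), the sparsity system is
    solved with iterative strongest-pair exclusion, and the final rho
    and omega are the element-wise medians over iterations.
    """
    df = _counts_frame(counts)
    ids = list(df.columns)
    c = df.to_numpy(dtype=float)
    if c.shape[1] < 4:
        raise ValueError("SparCC requires at least 4 OTUs")
    rng = np.random.default_rng(seed)
    rhos, omegas = [], []
    excluded_all: set[tuple[int, int]] = set()
    for _ in range(n_est_iter):
        g = rng.standard_gamma(c + 1.0)
        fractions = g / g.sum(axis=1, keepdims=True)
        rho, omega, excl = _estimate_once(
            fractions, exclusion_threshold, max_exclusions
        )
        rhos.append(rho)
        omegas.append(omega)
        excluded_all |= excl
    rho_med = np.median(np.stack(rhos), axis=0)
    rho_med = np.clip((rho_med + rho_med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    omega_med = np.median(np.stack(omegas), axis=0)
    return SparccResult(
        rho=pd.DataFrame(rho_med, index=ids, columns=ids),
        omega=pd.Series(omega_med, index=ids, name="omega"),
        excluded_pairs={(ids[i], ids[j]) for i, j in excluded_all},
    )


def sparcc_null_pvalues(
    counts,
    rho_obs: pd.DataFrame,
    n_null: int = 100,
    seed: int = 0,
    n_est_iter: int = 5,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> pd.DataFrame:
    """Two-sided permutation pseudo-p for every correlation.

    Each null replicate permutes every OTU's counts independently
    across samples and re-estimates rho; p_ij = (1 + #{|rho_null| >=
    |rho_obs|}) / (n_null + 1), with floor 1/(n_null + 1).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    df = _counts_frame(counts)
    ids = list(df.columns)
    obs = np.abs(rho_obs.loc[ids, ids].to_numpy())
    rng = np.random.default_rng(seed)
    c = df.to_numpy()
    exceed = np.zeros_like(obs)
    for _ in range(n_null):
        null = np.column_stack(
            [rng.permutation(c[:, j]) for j in range(c.shape[1])]
        )
        null_df = pd.DataFrame(null, index=df.index, columns=ids)
        res = sparcc_estimate(
            null_df,
            n_est_iter=n_est_iter,
            exclusion_threshold=exclusion_threshold,
            max_exclusions=max_exclusions,
            seed=int(rng.integers(2**31 - 1)),
        )
        exceed += np.abs(res.rho.to_numpy()) >= obs - 1e-12
    p = (1.0 + exceed) / (n_null + 1.0)
    return pd.DataFrame(p, index=ids, columns=ids)


def build_network(
    result: SparccResult,
    edge_threshold: float = 0.5,
    mean_abundance: pd.Series | None = None,
) -> nx.Graph:
    """Correlation network with edges where |rho| exceeds the threshold.

    Edge sign mirrors the correlation's sign; node attribute
    ``mean_abundance`` is attached when provided (used for node sizing
    in exports).
    """
    g = nx.Graph()
    ids = result.otu_ids
    for otu in ids:
        attrs = {}
        if mean_abundance is not None and otu in mean_abundance.index:
            attrs["mean_abundance"] = float(mean_abundance[otu])
        g.add_node(otu, **attrs)
    rho = result.rho
    pvals = result.p_values
    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            r = float(rho.at[a, b])
            if abs(r) > edge_threshold:
                attrs = {"rho": r, "sign": "positive" if r > 0 else "negative"}
                if pvals is not None:
                    attrs["p"] = float(pvals.at[a, b])
                g.add_edge(a, b, **attrs)
    return g


def network_edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"source": a, "target": b, **attrs} for a, b, attrs in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "p"])
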