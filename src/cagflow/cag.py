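"""Co-abundance groups: Ward clustering of SparCC correlations with
PERMANOVA-validated splits, CAG trajectories and invader correlates.

OTUs are the observations here: their dissimilarity is d = 1 - rho
(anticorrelated OTUs end up in opposing groups), a Ward dendrogram is
built, and each split is kept only if a PERMANOVA of the two child OTU
sets against the correlation-derived distances is significant at a
strict alpha. Recursion stops at non-significant nodes, which become
co-abundance groups; the number of CAGs is therefore data-determined.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .permanova import permanova_test
from .sparcc import SparccResult
from .stats import benjamini_hochberg, kruskal_wallis


def correlation_distance(rho: pd.DataFrame) -> DistanceMatrix:
    """d_ij = 1 - rho_ij; 0 for perfect correlation, 2 for perfect anti."""
    mat = 1.0 - rho.to_numpy(dtype=float)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    mat = np.clip(mat, 0.0, 2.0)
    return DistanceMatrix(mat, ids=list(rho.index))


def ward_dendrogram(D: DistanceMatrix) -> np.ndarray:
    """Ward linkage (Lance-Williams update) on a dissimilarity matrix."""
    condensed = squareform(D.data, checks=False)
    return linkage(condensed, method="ward")


@dataclasses.dataclass
class CagAssignment:
    assignment: pd.Series  # OTU -> CAG id
    linkage: np.ndarray
    ids: list[str]
    split_pvalues: dict[int, float]  # dendrogram node id -> PERMANOVA p

    @property
    def n_cags(self) -> int:
        return self.assignment.nunique()

    def members(self, cag_id: str) -> list[str]:
        return list(self.assignment.index[self.assignment == cag_id])

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.ids)
        return str(tree).strip()


def _split_f(d2: np.ndarray, left_mask: np.ndarray) -> float:
    """PERMANOVA pseudo-F of a 2-way split given squared distances."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for mask in (left_mask, ~left_mask):
        k = int(mask.sum())
        if k > 1:
            ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * k)
    denom = ss_within / (n - 2)
    if denom <= 0:
        return np.inf
    return float((ss_total - ss_within) / denom)


def _shuffle_split_pvalue(
    sub: np.ndarray, left_mask: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Selection-aware significance of a dendrogram split.

    The null randomly rearranges the observed dissimilarity values over
    the OTU pairs (keeping their distribution), re-clusters each
    shuffled matrix with Ward, and takes the pseudo-F of *its* root
    split — i.e. the best split the dendrogram would find in
    structureless data with the same dissimilarity spectrum. This
    accounts for the split under test having been chosen by the same
    dendrogram, which a plain label permutation does not.
    """
    m = sub.shape[0]
    f_obs = _split_f(sub**2, left_mask)
    vals = squareform(sub, checks=False)
    iu = np.triu_indices(m, 1)
    exceed = 0
    for _ in range(n_perm):
        shuffled = np.zeros((m, m))
        perm_vals = rng.permutation(vals)
        shuffled[iu] = perm_vals
        shuffled += shuffled.T
        z = linkage(perm_vals, method="ward")
        root = to_tree(z)
        left = root.left.pre_order(lambda x: x.id)
        mask = np.zeros(m, dtype=bool)
        mask[left] = True
        if _split_f(shuffled**2, mask) >= f_obs - 1e-12:
            exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)


def permanova_cut(
    Z: np.ndarray,
    D: DistanceMatrix,
    alpha: float = 0.005,
    n_perm: int = 9999,
    seed: int = 0,
    split_test: str = "shuffle",
) -> CagAssignment:
    """Cut a Ward dendrogram into CAGs by recursive PERMANOVA testing.

    Top-down from the root: at each node the two child OTU sets are
    scored by the PERMANOVA pseudo-F on the node's distance submatrix.
    A split is accepted when p < alpha; recursion continues into
    children with at least 2 members, and a singleton child of an
    accepted split becomes its own CAG. A node whose split is not
    significant (or is too small to test) becomes a single CAG.

    ``split_test`` selects the null: ``"shuffle"`` (default) rearranges
    the dissimilarity values and re-clusters, which is calibrated under
    structureless correlations; ``"label_permutation"`` permutes OTU
    labels against the fixed split, the textbook PERMANOVA null —
    anti-conservative here because Ward chose the split from the same
    distances, so it is kept only as the literal variant.

    Shuffle draws per node are scaled down as max(299, n_perm // 10)
    (each draw re-runs a Ward clustering) with the p floor this implies.
    """
    if split_test not in ("shuffle", "label_permutation"):
        raise ValueError("split_test must be 'shuffle' or 'label_permutation'")
    ids = list(D.ids)
    root = to_tree(Z)
    clusters: list[list[str]] = []
    split_pvalues: dict[int, float] = {}

    def leaves(node) -> list[str]:
        return [ids[i] for i in node.pre_order(lambda x: x.id)]

    def node_rng(node_id: int) -> np.random.Generator:
        # node-keyed streams: p-values do not depend on traversal order
        return np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(node_id,))
        )

    def recurse(node) -> None:
        if node.is_leaf():
            clusters.append([ids[node.id]])
            return
        left, right = leaves(node.left), leaves(node.right)
        members = left + right
        # need n - g >= 1 residual df to form a pseudo-F at all
        if len(members) < 3:
            clusters.append(members)
            return
        if split_test == "shuffle":
            sub = D.filter(members).data
            mask = np.array([o in set(left) for o in members])
            p = _shuffle_split_pvalue(
                sub, mask, max(299, n_perm // 10), node_rng(node.id)
            )
        else:
            labels = {o: ("L" if o in set(left) else "R") for o in members}
            res = permanova_test(
                D.filter(members),
                labels,
                n_perm=n_perm,
                seed=int(node_rng(node.id).integers(2**31 - 1)),
                min_group_size=1,
            )
            p = res.p_value
        split_pvalues[node.id] = p
        if p < alpha:
            for child in (node.left, node.right):
                recurse(child)
        else:
            clusters.append(members)

    recurse(root)
    mapping = {}
    for k, members in enumerate(clusters):
        for otu in members:
            mapping[otu] = f"CAG{k + 1:02d}"
    assignment = pd.Series({o: mapping[o] for o in ids}, name="cag")
    return CagAssignment(
        assignment=assignment, linkage=Z, ids=ids, split_pvalues=split_pvalues
    )


def cluster_cags(
    result: SparccResult,
    alpha: float = 0.005,
    n_perm: int = 9999,
    seed: int = 0,
) -> CagAssignment:
    """Convenience wrapper: rho -> 1 - rho distance -> Ward -> cut."""
    ids = list(result.rho.index)
    if len(ids) == 1:  # nothing to cluster: the lone OTU is its own CAG
        return CagAssignment(
            assignment=pd.Series({ids[0]: "CAG01"}, name="cag"),
            linkage=np.empty((0, 4)),
            ids=ids,
            split_pvalues={},
        )
    D = correlation_distance(result.rho)
    Z = ward_dendrogram(D)
    return permanova_cut(Z, D, alpha=alpha, n_perm=n_perm, seed=seed)


def cag_abundance_profiles(
    relative_abundances: pd.DataFrame, assignment: CagAssignment | pd.Series
) -> pd.DataFrame:
    """Per-sample total relative abundance of each CAG's member OTUs."""
    mapping = (
        assignment.assignment if isinstance(assignment, CagAssignment) else assignment
    )
    missing = [o for o in mapping.index if o not in relative_abundances.columns]
    if missing:
        raise ValueError(f"assignment OTUs not in the table: {missing[:5]}")
    profile = {}
    for cag_id in sorted(mapping.unique()):
        otus = list(mapping.index[mapping == cag_id])
        profile[cag_id] = relative_abundances[otus].sum(axis=1)
    return pd.DataFrame(profile)


def cag_group_dynamics(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_group: str = "DSS",
    fdr_thresholds: tuple[float, ...] = (0.05, 0.01, 0.005),
) -> pd.DataFrame:
    """Kruskal-Wallis of each CAG's abundance, group vs reference per day.

    Every (CAG, day, group != reference) cell is tested against the
    reference group at the same day; Benjamini-Hochberg adjustment runs
    across the whole CAG x day x group family and significance stars
    mark the FDR thresholds (one per threshold passed).
    """
    meta = metadata.loc[profile.index]
    groups = sorted(meta["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} absent")
    rows = []
    for day in sorted(meta["day"].unique()):
        day_mask = meta["day"] == day
        if meta.loc[day_mask, "group"].nunique() < 2:
            raise ValueError(f"day {day} has fewer than 2 groups")
        ref_ids = meta.index[day_mask & (meta["group"] == reference_group)]
        for group in groups:
            if group == reference_group:
                continue
            g_ids = meta.index[day_mask & (meta["group"] == group)]
            for cag_id in profile.columns:
                H, p = kruskal_wallis(
                    [
                        profile.loc[g_ids, cag_id].to_numpy(),
                        profile.loc[ref_ids, cag_id].to_numpy(),
                    ]
                )
                rows.append(
                    {
                        "cag": cag_id,
                        "day": int(day),
                        "group": group,
                        "reference": reference_group,
                        "H": H,
                        "raw_p": p,
                    }
                )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = benjamini_hochberg(out["raw_p"].to_numpy())
    stars = sorted(fdr_thresholds, reverse=True)

    def star(p: float) -> str:
        return "*" * sum(p < t for t in stars)

    out["stars"] = out["adjusted_p"].map(star)
    return out


def invader_correlates(
    result: SparccResult, invader_otu: str, threshold: float = 0.5
) -> tuple[set[str], set[str]]:
    """OTUs whose basis correlation with the invader exceeds the cutoff.

    Returns (positive set: rho > threshold, negative set: rho <
    -threshold), excluding the invader itself.
    """
    if invader_otu not in result.rho.index:
        raise ValueError(f"{invader_otu!r} not present in the correlation matrix")
    row = result.rho.loc[invader_otu].drop(invader_otu)
    positive = set(row.index[row > threshold])
    negative = set(row.index[row < -threshold])
    return positive, negative
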