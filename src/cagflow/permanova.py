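"""Permutational multivariate analysis of variance on distance matrices.

The pseudo-F statistic partitions the sum of squared dissimilarities
into between- and within-group components:

    SS_total  = (1/n) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = (SS_between / (g - 1)) / (SS_within / (n - g))

Significance comes from uniform permutations of the sample labels; the
observed statistic is included in both numerator and denominator of the
pseudo-p, so p >= 1/(n_perm + 1). An exact mode enumerates every
distinct label assignment for small n.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: dict


def _as_matrix_labels(D, labels):
    if isinstance(D, DistanceMatrix):
        ids = list(D.ids)
        mat = D.data
    else:
        mat = np.asarray(D, dtype=float)
        ids = list(range(mat.shape[0]))
    if isinstance(labels, dict):
        lab = np.array([labels[i] for i in ids])
    elif isinstance(labels, pd.Series):
        lab = labels.loc[ids].to_numpy()
    else:
        lab = np.asarray(labels)
        if lab.shape[0] != mat.shape[0]:
            raise ValueError("labels do not match the distance matrix")
    return mat, lab


def _f_from_codes(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    """Pseudo-F for a batch of label-code rows (codes: perms x n)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    g = sizes.shape[0]
    ss_within = np.zeros(codes.shape[0])
    for gi in range(g):
        Z = (codes == gi).astype(float)
        zDz = ((Z @ d2) * Z).sum(axis=1)
        ss_within += zDz / (2.0 * sizes[gi])
    ss_between = ss_total - ss_within
    denom = ss_within / (n - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(
            denom > 0, (ss_between / (g - 1)) / denom, np.inf
        )
    return F


def permanova_test(
    D,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
    exact: bool = False,
    min_group_size: int = 2,
) -> PermanovaResult:
    """One-way PERMANOVA of ``labels`` on distance matrix ``D``.

    With ``exact=True`` every distinct assignment of the label multiset
    is enumerated and p is the exact fraction with F >= F_observed
    (the identity assignment included); otherwise ``n_perm`` uniform
    permutations are drawn and p = (1 + #{F_perm >= F_obs})/(n_perm + 1).
    """
    mat, lab = _as_matrix_labels(D, labels)
    groups, codes = np.unique(lab, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < min_group_size:
        raise ValueError(
            f"every group needs >= {min_group_size} samples (got {sizes.min()})"
        )
    n = mat.shape[0]
    if n - len(groups) < 1:
        raise ValueError("not enough samples for the residual degrees of freedom")
    d2 = mat.astype(float) ** 2
    f_obs = float(_f_from_codes(d2, codes[None, :], sizes)[0])

    if exact:
        perms = np.array(list(multiset_permutations(codes.tolist())))
        f_all = _f_from_codes(d2, perms, sizes)
        p = float(np.mean(f_all >= f_obs - 1e-12))
        n_eff = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(
            np.tile(codes, (n_perm, 1)), axis=1
        )
        f_perm = _f_from_codes(d2, perms, sizes)
        p = (1.0 + float(np.sum(f_perm >= f_obs - 1e-12))) / (n_perm + 1.0)
        n_eff = n_perm
    group_sizes = {g: int(s) for g, s in zip(groups, sizes)}
    return PermanovaResult(
        pseudo_F=f_obs, p_value=p, n_permutations=n_eff, group_sizes=group_sizes
    )


def pairwise_screen(
    D: DistanceMatrix,
    metadata: pd.DataFrame,
    contrasts,
    alpha: float = 0.05,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA per (group, day) vs (group, day) contrast.

    Each contrast is a pair of cells ((group_a, day_a), (group_b,
    day_b)); the test runs on the corresponding row/column subset of
    ``D``. Contrasts with fewer than 2 samples on a side are skipped
    with a warning. Significance is flagged at the unadjusted ``alpha``
    (this screen gates the random-forest models downstream).
    """
    ids = list(D.ids)
    meta = metadata.loc[ids]
    records = []
    rng = np.random.default_rng(seed)
    for cell_a, cell_b in contrasts:
        sub_seed = int(rng.integers(2**31 - 1))
        sel = {}
        for cell in (cell_a, cell_b):
            g, d = cell
            sel[cell] = [
                s
                for s in ids
                if meta.at[s, "group"] == g and int(meta.at[s, "day"]) == int(d)
            ]
        name = f"{cell_a[0]}@d{cell_a[1]}_vs_{cell_b[0]}@d{cell_b[1]}"
        if min(len(sel[cell_a]), len(sel[cell_b])) < 2:
            logger.warning("contrast %s skipped: fewer than 2 samples on a side", name)
            continue
        chosen = sel[cell_a] + sel[cell_b]
        labels = {s: "a" for s in sel[cell_a]}
        labels.update({s: "b" for s in sel[cell_b]})
        res = permanova_test(
            D.filter(chosen), labels, n_perm=n_perm, seed=sub_seed
        )
        records.append(
            {
                "contrast": name,
                "group_a": cell_a[0],
                "day_a": int(cell_a[1]),
                "group_b": cell_b[0],
                "day_b": int(cell_b[1]),
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
                "n_perm": res.n_permutations,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(records)
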