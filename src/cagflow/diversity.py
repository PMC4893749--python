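"""Rarefaction, alpha diversity, Bray-Curtis distances and PCoA."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .containers import OtuTable


@dataclasses.dataclass
class RarefiedTable:
    """One seeded rarefaction instance plus the repetition bookkeeping.

    ``table`` holds repetition 0 (used for beta diversity); alpha
    diversity is averaged over ``n_repetitions`` fresh subsamples via
    :func:`mean_alpha_diversity` with the same seed.
    """

    table: OtuTable
    depth: int
    n_repetitions: int
    excluded_samples: list[str]
    seed: int


def rarefy(
    table: OtuTable, depth: int = 9000, n_rep: int = 1000, seed: int = 0
) -> RarefiedTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are excluded and recorded.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    depths = table.depths()
    keep = depths.index[depths >= depth]
    excluded = [s for s in table.sample_ids if s not in set(keep)]
    if len(keep) == 0:
        raise ValueError("all samples fall below the rarefaction depth")
    rng = np.random.default_rng(seed)
    rows = []
    for sid in keep:
        counts = table.counts.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    counts_df = pd.DataFrame(rows, index=list(keep), columns=table.otu_ids)
    sub = OtuTable(
        counts=counts_df,
        metadata=table.metadata.loc[list(keep)].copy(),
        taxonomy=table.taxonomy,
    )
    return RarefiedTable(
        table=sub,
        depth=depth,
        n_repetitions=n_rep,
        excluded_samples=excluded,
        seed=seed,
    )


def observed_otus(sample_counts) -> int:
    """Number of OTUs with a non-zero count."""
    return int((np.asarray(sample_counts) > 0).sum())


def shannon(sample_counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log(p_i), log base 2 by default."""
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def mean_alpha_diversity(
    table: OtuTable,
    depth: int = 9000,
    n_rep: int = 1000,
    seed: int = 0,
    base: float = 2.0,
) -> pd.DataFrame:
    """Mean observed OTUs and Shannon index over ``n_rep`` rarefactions.

    Samples below ``depth`` are dropped, mirroring :func:`rarefy`.
    """
    depths = table.depths()
    keep = depths.index[depths >= depth]
    rng = np.random.default_rng(seed)
    records = {}
    log_base = np.log(base)
    for sid in keep:
        counts = table.counts.loc[sid].to_numpy()
        reps = rng.multivariate_hypergeometric(counts, depth, size=n_rep)
        obs = (reps > 0).sum(axis=1).mean()
        p = reps / depth
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * (np.log(p) / log_base), 0.0)
        sh = (-terms.sum(axis=1)).mean()
        records[sid] = {"observed_otus": obs, "shannon": sh}
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    Accepts an OtuTable or a samples x OTUs DataFrame; rows should be
    equal-depth (rarefied) counts or relative abundances.
    """
    df = table.counts if isinstance(table, OtuTable) else table
    d = pdist(df.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(df.index))


@dataclasses.dataclass
class OrdinationResult:
    """PCoA output: sample coordinates on the positive-eigenvalue axes."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


def pcoa(D, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by Gower centering.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by the square root of their (positive) eigenvalues. Negative
    eigenvalues are dropped and their number reported; proportions
    explained are taken over the positive eigenvalues.
    """
    if isinstance(D, DistanceMatrix):
        ids = list(D.ids)
        mat = D.data
    else:
        mat = np.asarray(D, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
        if not np.allclose(mat, mat.T):
            raise ValueError("distance matrix must be symmetric")
    n = mat.shape[0]
    d2 = mat**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    n_neg = int((evals < -tol).sum())
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    axis_names = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axis_names),
        eigenvalues=evals,
        proportion_explained=prop,
        n_negative_eigenvalues=n_neg,
    )


def pca_scores(relative_abundances: pd.DataFrame) -> OrdinationResult:
    """PCA scores via PCoA of Euclidean distances (mathematically equal)."""
    d = pdist(relative_abundances.to_numpy(dtype=float), metric="euclidean")
    D = DistanceMatrix(squareform(d), ids=list(relative_abundances.index))
    return pcoa(D)


def distance_from_baseline(
    D: DistanceMatrix, metadata: pd.DataFrame, baseline_day: int | None = None
) -> pd.DataFrame:
    """Mean distance of each sample to its own group's baseline samples.

    For baseline-day samples the mean excludes the sample itself. The
    per-group-per-day mean of this statistic tracks how far a community
    has moved from its pre-treatment state.
    """
    if baseline_day is None:
        baseline_day = int(metadata["day"].min())
    ids = list(D.ids)
    meta = metadata.loc[ids]
    rows = []
    for sid in ids:
        group = meta.at[sid, "group"]
        base_ids = [
            b
            for b in ids
            if meta.at[b, "group"] == group
            and int(meta.at[b, "day"]) == baseline_day
            and b != sid
        ]
        if not base_ids:
            continue
        dist = float(np.mean([D[sid, b] for b in base_ids]))
        rows.append(
            {
                "sample_id": sid,
                "group": group,
                "day": int(meta.at[sid, "day"]),
                "distance_to_baseline": dist,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
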