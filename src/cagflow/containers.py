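"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("group", "day", "subject")


@dataclasses.dataclass
class OtuTable:
    """A samples x OTUs integer count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per OTU id;
        non-negative integer cells.
    metadata
        DataFrame indexed by sample id with columns ``group`` (str),
        ``day`` (int) and ``subject`` (str), aligned to ``counts``.
    taxonomy
        Optional OTU id -> taxonomy string series; carried as metadata
        only, never interpreted.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("OTU ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> pd.DataFrame:
        """Row-normalised fractions; rows sum to 1."""
        depths = self.counts.sum(axis=1)
        if (depths == 0).any():
            raise ValueError("cannot normalise all-zero samples")
        return self.counts.div(depths, axis=0)

    def select_samples(self, sample_ids) -> "OtuTable":
        tax = self.taxonomy
        return OtuTable(
            counts=self.counts.loc[list(sample_ids)].copy(),
            metadata=self.metadata.loc[list(sample_ids)].copy(),
            taxonomy=None if tax is None else tax.copy(),
        )

    def select_otus(self, otu_ids) -> "OtuTable":
        otu_ids = list(otu_ids)
        tax = None if self.taxonomy is None else self.taxonomy.reindex(otu_ids)
        return OtuTable(
            counts=self.counts[otu_ids].copy(),
            metadata=self.metadata.copy(),
            taxonomy=tax,
        )

    def samples_for(self, group: str, day: int) -> list[str]:
        m = self.metadata
        return list(m.index[(m["group"] == group) & (m["day"] == day)])

    # ---- on-disk round trip (plain TSV; OTUs as rows per field convention)

    def to_tsv(self, counts_path, metadata_path) -> None:
        self.counts.T.to_csv(counts_path, sep="\t", index_label="otu_id")
        meta = self.metadata.copy()
        meta.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path, taxonomy_path=None) -> "OtuTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="otu_id").T
        counts.index.name = "sample_id"
        metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        metadata["day"] = metadata["day"].astype(int)
        taxonomy = None
        if taxonomy_path is not None and Path(taxonomy_path).exists():
            taxonomy = pd.read_csv(
                taxonomy_path, sep="\t", index_col="otu_id"
            )["taxonomy"]
        counts = counts.astype(np.int64)
        return cls(counts=counts, metadata=metadata, taxonomy=taxonomy)
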