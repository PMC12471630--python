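"""OTU count tables with sample metadata.

The central input of the pipeline: an integer count matrix (samples x taxa)
plus per-sample treatment metadata for the 2x2x2 water (W) x nitrogen (N) x
phosphorus (P) factorial design (binary factor levels and a block identifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OtuTable", "FACTORS", "TREATMENTS", "treatment_label"]

FACTORS = ("W", "N", "P")

#: canonical treatment ordering: control, singles, two-way, three-way
TREATMENTS = ("C", "W", "N", "P", "WN", "WP", "NP", "WNP")


def treatment_label(w: int, n: int, p: int) -> str:
    """Compact treatment code from binary factor levels (C for the control)."""
    label = "".join(f for f, lev in zip(FACTORS, (w, n, p)) if lev)
    return label or "C"


@dataclass
class OtuTable:
    """Integer OTU counts (samples x taxa) plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one integer column per taxon.
    metadata
        DataFrame indexed by sample id with columns ``W``, ``N``, ``P``
        (binary), ``block`` (1-based) and ``treatment`` (label). May be None
        for tables without design information.
    taxon_domains
        Optional mapping taxon id -> domain label (e.g. "bacteria"/"fungi");
        carried as metadata only.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    taxon_domains: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.counts
        arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("OTU counts must be integers")
        self.counts = counts.astype(np.int64)
        if self.metadata is not None:
            missing = self.counts.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing samples: {list(missing)[:5]}")
            self.metadata = self.metadata.loc[self.counts.index]

    # -- basic accessors ---------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def taxon_totals(self) -> pd.Series:
        """Total count of each taxon summed over all samples."""
        return self.counts.sum(axis=0)

    def select_taxa(self, taxa) -> "OtuTable":
        taxa = list(taxa)
        domains = {t: d for t, d in self.taxon_domains.items() if t in set(taxa)}
        return OtuTable(self.counts[taxa].copy(), self.metadata, domains)

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write counts as TSV, taxa as rows and one column per sample."""
        self.counts.T.rename_axis(index="taxon", columns=None).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata_csv=None, orientation: str = "auto") -> "OtuTable":
        """Read a count TSV (taxon rows by default; ``orientation='samples'``
        for sample rows) and optionally a metadata CSV indexed by sample id."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation not in ("auto", "taxa", "samples"):
            raise ValueError(f"unknown orientation {orientation!r}")
        if orientation in ("auto", "taxa"):
            df = df.T
        df.index.name = "sample_id"
        df.columns.name = None
        meta = None
        if metadata_csv is not None:
            meta = pd.read_csv(metadata_csv, index_col=0)
        return cls(df, meta)

    def metadata_to_csv(self, path) -> None:
        if self.metadata is None:
            raise ValueError("table has no metadata")
        out = self.metadata.copy()
        out.index.name = "sample_id"
        out.to_csv(path)
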