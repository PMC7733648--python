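"""Diploid biallelic genotype matrix with missingness.

Genotypes are stored as counts of the scored allele per locus (0, 1 or 2),
with ``NaN`` marking missing calls — the dialect written by DArT-style SNP
pipelines after conversion to a samples × loci count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Samples × loci diploid allele-count matrix.

    Parameters
    ----------
    ids : sequence of str
        Sample (larva) identifiers, one per row.
    loci : sequence of str
        Locus identifiers, one per column.
    calls : ndarray of float, shape (n_samples, n_loci)
        Allele counts in {0, 1, 2}; ``NaN`` marks a missing call.
    """

    ids: np.ndarray
    loci: np.ndarray
    calls: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.loci = np.asarray(self.loci, dtype=object)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples × loci array")
        if self.calls.shape != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} ids × {len(self.loci)} loci"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sample ids")
        finite = self.calls[~np.isnan(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing (NaN)")
        self._index = {s: i for i, s in enumerate(self.ids)}

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    def row(self, sample_id: str) -> np.ndarray:
        """Genotype vector for one sample."""
        return self.calls[self._index[sample_id]]

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        """Row-subset preserving the requested order."""
        rows = [self._index[s] for s in sample_ids]
        return GenotypeMatrix(
            ids=np.asarray(list(sample_ids), dtype=object),
            loci=self.loci.copy(),
            calls=self.calls[rows].copy(),
        )

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeMatrix":
        """Read a genotype CSV: first column sample id, remaining columns loci."""
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"genotype file {path} contains no calls")
        return cls(
            ids=df.index.astype(str).to_numpy(dtype=object),
            loci=df.columns.astype(str).to_numpy(dtype=object),
            calls=df.to_numpy(dtype=float),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.calls, index=pd.Index(self.ids, name="larva_id"),
                          columns=self.loci)
        # integers where present, empty cell for missing
        df.to_csv(path, float_format="%.0f")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=pd.Index(self.ids, name="larva_id"),
                            columns=self.loci)
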