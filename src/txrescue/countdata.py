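"""Gene-by-sample count matrix with a sample-to-group design, and TSV I/O.

The container mirrors the shape of RSEM-style expected-count tables rounded
to integers: rows are genes, columns are samples, and a two-column design
table assigns every sample to a biological group (control, disease, or a
treatment arm).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample -> group design.

    Parameters
    ----------
    counts
        DataFrame indexed by unique gene ids; columns are unique sample ids;
        values are non-negative integers.
    design
        Series indexed by sample id with group labels as values. Every count
        column must appear in the design.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.size == 0:
            raise DataError("empty count matrix")
        if c.index.duplicated().any():
            raise DataError("duplicate gene ids in count matrix")
        if c.columns.duplicated().any():
            raise DataError("duplicate sample ids in count matrix")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise DataError("counts must be numeric")
        if np.any(vals < 0):
            raise DataError("counts must be non-negative")
        if not np.all(np.mod(vals, 1) == 0):
            raise DataError("counts must be integers")
        if self.design.index.duplicated().any():
            raise DataError("duplicate sample ids in design")
        missing = set(c.columns) - set(self.design.index)
        if missing:
            raise DataError(f"samples without a group assignment: {sorted(missing)}")
        # keep only and exactly the samples present in the matrix, in order
        self.design = self.design.loc[list(c.columns)]
        self.design.index.name = "sample"
        self.design.name = "group"

    # ---------------------------------------------------------------- groups
    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.design))

    def samples_in(self, group: str) -> list[str]:
        samples = list(self.design.index[self.design == group])
        if not samples:
            raise DataError(f"group {group!r} has no samples in the design")
        return samples

    def subset_groups(self, groups: list[str]) -> "CountMatrix":
        samples = [s for g in groups for s in self.samples_in(g)]
        return CountMatrix(self.counts[samples].copy(), self.design.loc[samples].copy())

    # ------------------------------------------------------------------- I/O
    def write(self, counts_tsv: str | Path, design_tsv: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene"
        out.to_csv(counts_tsv, sep="\t")
        self.design.rename_axis("sample").to_frame("group").to_csv(design_tsv, sep="\t")

    @classmethod
    def read(cls, counts_tsv: str | Path, design_tsv: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        design = pd.read_csv(design_tsv, sep="\t", index_col=0)["group"]
        return cls(counts, design)
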