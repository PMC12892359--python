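"""Gene-family presence/absence (and copy-number) matrices."""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["PresenceMatrix"]


class PresenceMatrix:
    """Families x genomes occurrence table.

    Internally copy counts are kept when available; the profiling and
    inference stages consume the binarised view (>=1 copy -> present).
    Rows are gene-family ids, columns genome (tip) ids.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate family ids: {dups}")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate genome ids")
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number) or (arr < 0).any()):
            raise ValueError("matrix entries must be nonnegative numbers")
        self.counts = counts.astype(int) if arr.size else counts

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts >= 1).astype(int)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def profile(self, family: str) -> dict[str, int]:
        """Binary presence of one family over all genomes."""
        row = self.counts.loc[family]
        return {g: int(v >= 1) for g, v in row.items()}

    def member_counts(self) -> pd.Series:
        """Total members per family (copy counts summed over genomes)."""
        return self.counts.sum(axis=1)

    def select_families(self, families: Iterable[str]) -> "PresenceMatrix":
        return PresenceMatrix(self.counts.loc[list(families)])

    def content_of(self, genome: str) -> set[str]:
        """Set of families present in one genome."""
        col = self.counts[genome]
        return set(col.index[col >= 1])

    def check_against_tree(self, tree) -> None:
        """Validate that columns are exactly the tree's tips."""
        tips = set(tree.tips)
        cols = set(self.genomes)
        if tips != cols:
            missing = sorted(tips - cols)
            extra = sorted(cols - tips)
            raise ValueError(
                f"matrix columns do not match tree tips "
                f"(missing={missing}, extra={extra})"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PresenceMatrix({self.shape[0]} families x {self.shape[1]} genomes)"
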