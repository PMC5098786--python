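"""Feature x sample abundance tables and their TSV dialect.

All tables share one on-disk dialect: tab-separated, header row, first
column the feature ID, remaining columns the samples.  In memory they
wrap a pandas DataFrame (rows = features, columns = samples).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OtuTable", "GenomeTable", "KoAbundanceTable"]


class _AbundanceTable:
    """Base wrapper around a features x samples DataFrame."""

    index_name = "feature_id"

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ValueError(f"duplicate {self.index_name} entries in table")
        values = df.to_numpy(dtype=float, copy=False)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("abundance table contains negative entries")
        self.df = df
        self.df.index.name = self.index_name

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @classmethod
    def read_tsv(cls, path: Path | str):
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path: Path | str) -> None:
        self.df.to_csv(path, sep="\t")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, _AbundanceTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        n, m = self.df.shape
        return f"<{type(self).__name__} {n} features x {m} samples>"


class OtuTable(_AbundanceTable):
    """OTU x sample count table (the A_t values, one column per sample)."""

    index_name = "otu_id"


class GenomeTable(_AbundanceTable):
    """Genome x sample abundance table; fractional values arise from tie splitting."""

    index_name = "genome_id"


class KoAbundanceTable(_AbundanceTable):
    """Ortholog x sample inferred abundance table (the A_K values)."""

    index_name = "ko_id"
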