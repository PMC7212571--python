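"""Expression matrix container and TSV input/output.

The canonical in-memory object is a samples x genes :class:`pandas.DataFrame`
of non-negative values with string gene identifiers (Entrez IDs serialized as
strings) plus an optional per-sample metadata table. A thin dataclass keeps
the two aligned and validates the contracts every downstream stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "read_metadata_tsv"]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with per-sample metadata.

    Parameters
    ----------
    data
        Samples x genes frame; index = sample IDs, columns = gene IDs (str).
    metadata
        Per-sample table aligned on the same index (tissue / cancer type,
        sex, binary traits). May be empty.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (samples x genes)")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.data.columns.duplicated().any():
            raise ValueError("gene IDs must be unique")
        if self.data.index.duplicated().any():
            raise ValueError("sample IDs must be unique")
        self.data.columns = self.data.columns.astype(str)
        if len(self.metadata) and not self.metadata.index.equals(self.data.index):
            self.metadata = self.metadata.loc[self.data.index]

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        meta = self.metadata.loc[sample_ids] if len(self.metadata) else self.metadata
        return ExpressionMatrix(self.data.loc[sample_ids].copy(), meta.copy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(gene_ids)].copy(), self.metadata.copy())

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path, metadata_path=None) -> None:
        """Write the matrix (and optionally metadata) as TSV.

        Rows are samples, the first column is the sample ID, the header
        carries the gene IDs.
        """
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")
        if metadata_path is not None:
            self.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_expression_tsv(path, metadata_path=None) -> ExpressionMatrix:
    """Read an expression TSV (first column sample IDs, header gene IDs)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.columns = data.columns.astype(str)
    meta = pd.DataFrame()
    if metadata_path is not None and Path(metadata_path).exists():
        meta = read_metadata_tsv(metadata_path)
    return ExpressionMatrix(data, meta)


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
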