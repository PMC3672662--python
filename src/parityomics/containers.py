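"""In-memory containers shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SiteCountMatrix"]


@dataclass
class ExpressionMatrix:
    """Gene x sample log2-expression matrix with condition labels.

    values_frame : frame indexed by gene id, one column per sample.
    conditions : Series mapping sample id -> condition label
        (``"virgin"`` / ``"parous"`` in this study).
    """

    values_frame: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.values_frame.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if list(self.conditions.index) != list(self.values_frame.columns):
            self.conditions = self.conditions.reindex(self.values_frame.columns)
        if self.conditions.isna().any():
            raise ValueError("every sample needs a condition label")
        if not np.isfinite(self.values_frame.to_numpy(float)).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values_frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values_frame.columns)

    def condition_frame(self, condition: str) -> pd.DataFrame:
        """Sub-matrix of the samples carrying one condition label."""
        cols = self.conditions.index[self.conditions == condition]
        if len(cols) == 0:
            raise ValueError(f"no samples with condition {condition!r}")
        return self.values_frame.loc[:, cols]

    def to_tsv(self, expr_path, sample_sheet_path=None) -> None:
        self.values_frame.to_csv(expr_path, sep="\t", index_label="gene")
        if sample_sheet_path is not None:
            pd.DataFrame(
                {"sample": self.conditions.index, "condition": self.conditions.values}
            ).to_csv(sample_sheet_path, index=False)

    @classmethod
    def from_tsv(cls, expr_path, sample_sheet_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_sheet_path)
        cond = pd.Series(
            sheet["condition"].to_numpy(), index=sheet["sample"].astype(str)
        )
        return cls(values, cond)


@dataclass
class SiteCountMatrix:
    """Gene x motif matrix of predicted binding-site counts in proximal
    promoters; nonnegative integers, typically sparse."""

    values_frame: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values_frame.to_numpy(float)
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise ValueError("site counts must be finite and nonnegative")
        if self.values_frame.index.has_duplicates:
            raise ValueError("duplicate gene ids")

    @property
    def zero_motifs(self) -> list[str]:
        """Motifs with no sites anywhere (unidentifiable activities)."""
        col_sums = self.values_frame.sum(axis=0)
        return list(col_sums.index[col_sums == 0])

    def to_tsv(self, path) -> None:
        self.values_frame.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "SiteCountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))
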