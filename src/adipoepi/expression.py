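"""Expression matrix container shared by the stage- and lineage-level analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

FEATURE_CLASSES = ("coding", "lncRNA", "miRNA")


@dataclass
class ExpressionMatrix:
    """Feature x ordered-stage abundance table for one lineage.

    ``data`` rows are features, columns are stages in differentiation order
    (the order is meaningful and fixed per lineage). Values are FPKM for
    RNA-seq classes and raw array signal for miRNAs.
    """

    data: pd.DataFrame
    feature_class: str = "coding"
    unit: str = "FPKM"  # FPKM | array_signal
    lineage: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )
        if self.unit not in ("FPKM", "array_signal"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 stages")
        if (self.data.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def stages(self) -> list[str]:
        return list(self.data.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, feature_class: str = "coding", unit: str = "FPKM",
                 lineage: str = "") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, feature_class=feature_class, unit=unit, lineage=lineage)
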