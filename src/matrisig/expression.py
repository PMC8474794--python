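"""Expression-matrix container and TSV input/output.

The matrix is features x samples. Values are either linear-scale
intensities (all > 0) or their log2; the ``scale`` flag records which.
For the two-condition fibroblast arrays a ``condition`` map labels each
sample ``case`` or ``control``; tumour cohorts carry no condition map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
_SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """Features x samples intensity table.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    scale
        ``"linear"`` (intensities > 0) or ``"log2"``.
    condition
        Optional mapping ``sample_id -> {"case", "control"}``; when
        present every sample must be labelled.
    gene_symbols
        Optional mapping ``feature_id -> gene symbol`` (probe annotation).
    """

    values: pd.DataFrame
    scale: str = "linear"
    condition: dict[str, str] | None = None
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale intensities must be non-negative")
        if self.condition is not None:
            missing = [s for s in self.values.columns if s not in self.condition]
            if missing:
                raise ValueError(f"samples without a condition label: {missing}")
            bad = {v for v in self.condition.values()} - {CASE, CONTROL}
            if bad:
                raise ValueError(f"condition labels must be case/control, got {bad}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        if self.condition is None:
            raise ValueError("matrix has no condition labels")
        return [s for s in self.values.columns if self.condition[s] == condition]

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("cannot log2-transform non-positive intensities")
        return ExpressionMatrix(
            np.log2(self.values), "log2", self.condition, dict(self.gene_symbols)
        )

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(
            np.exp2(self.values).astype(float),
            "linear",
            self.condition,
            dict(self.gene_symbols),
        )


def read_expression(
    path,
    scale: str = "linear",
    conditions_path=None,
    annotation_path=None,
) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column = feature id).

    ``conditions_path`` is a two-column TSV ``sample_id<TAB>condition``;
    ``annotation_path`` a two-column TSV ``probe_id<TAB>gene_symbol``.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    condition = None
    if conditions_path is not None:
        cond = pd.read_csv(conditions_path, sep="\t", index_col=0).iloc[:, 0]
        condition = {str(k): str(v) for k, v in cond.items()}
    symbols: dict[str, str] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0).iloc[:, 0]
        symbols = {str(k): str(v) for k, v in ann.items()}
    return ExpressionMatrix(values, scale=scale, condition=condition, gene_symbols=symbols)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id")


def write_conditions(expr: ExpressionMatrix, path) -> None:
    if expr.condition is None:
        raise ValueError("matrix has no condition labels")
    pd.Series(expr.condition, name="condition").rename_axis("sample_id").to_csv(
        path, sep="\t"
    )
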