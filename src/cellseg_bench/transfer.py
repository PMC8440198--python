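"""Cross-cell-type generalization scoring.

A model trained on cell type A and evaluated on cell type B gets the
log2-transformed transfer ratio r_{A,B} = log2(AP_B / AP_A), where AP_A is the
model's AP on its own training type.  The transferability index is the negated
mean of all n(n-1) ordered off-diagonal ratios: 0 means transfer matches
self-performance on average, positive values mean transfer degrades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedRatioError(ValueError):
    """A transfer ratio involves a zero or missing AP."""


@dataclass
class TransferMatrix:
    """Train-type x eval-type AP grid (fractional AP values)."""

    table: pd.DataFrame  # index: train type, columns: eval type

    def __post_init__(self) -> None:
        if list(self.table.index) != list(self.table.columns):
            missing = set(self.table.index) ^ set(self.table.columns)
            if missing:
                raise ValueError(f"train/eval cell types differ: {sorted(missing)}")
            self.table = self.table[list(self.table.index)]

    @property
    def cell_types(self) -> list[str]:
        return list(self.table.index)

    def ap(self, train: str, eval_: str) -> float:
        return float(self.table.loc[train, eval_])

    @classmethod
    def from_csv(cls, path) -> "TransferMatrix":
        return cls(pd.read_csv(path, index_col=0))


def transfer_ratio(
    matrix: TransferMatrix, train_type: str, eval_type: str, floor: float | None = None
) -> float:
    """r_{A,B} = log2(AP on eval type / AP on own training type).

    Zero APs make the ratio undefined; pass ``floor`` (e.g. 1e-4) to clamp them
    explicitly instead of erroring.
    """
    if train_type == eval_type:
        raise ValueError("transfer ratio requires distinct train and eval types")
    ap_a = matrix.ap(train_type, train_type)
    ap_b = matrix.ap(train_type, eval_type)
    if floor is not None:
        ap_a, ap_b = max(ap_a, floor), max(ap_b, floor)
    if not (ap_a > 0 and ap_b > 0) or np.isnan(ap_a) or np.isnan(ap_b):
        raise UndefinedRatioError(
            f"undefined ratio for ({train_type!r}, {eval_type!r}): "
            f"AP_self={ap_a}, AP_eval={ap_b}"
        )
    return float(np.log2(ap_b / ap_a))


def transferability_index(matrix: TransferMatrix, floor: float | None = None) -> float:
    """Negated mean log2 transfer ratio over all ordered off-diagonal pairs."""
    types = matrix.cell_types
    n = len(types)
    if n < 2:
        raise ValueError("transferability index requires at least 2 cell types")
    bad: list[tuple[str, str]] = []
    total = 0.0
    for c1 in types:
        for c2 in types:
            if c1 == c2:
                continue
            try:
                total += transfer_ratio(matrix, c1, c2, floor=floor)
            except UndefinedRatioError:
                bad.append((c1, c2))
    if bad:
        raise UndefinedRatioError(f"undefined ratios for pairs: {bad}")
    return -total / (n * (n - 1)) + 0.0  # avoid IEEE -0.0 for symmetric grids
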