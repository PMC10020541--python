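"""Time-course expression container and TSV I/O.

Expression is a genes x samples matrix; each sample carries a time label and
a group label (``reference`` or ``case``).  Values are assumed to be
pre-normalised (e.g. log-scale abundances); no library-size correction or
imputation is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REFERENCE = "reference"
CASE = "case"

MIN_REFERENCE_SAMPLES = 3  # Pearson correlation needs >= 3 points


class DatasetError(ValueError):
    pass


@dataclass
class ExpressionDataset:
    """Genes x samples expression with per-sample time and group labels.

    ``values`` is a DataFrame indexed by gene, columns = sample ids;
    ``meta`` is a DataFrame indexed by sample id with columns ``time`` and
    ``group``.  Time labels keep their input order of first appearance.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.meta.index):
            # allow same set, different order
            if set(self.values.columns) != set(self.meta.index):
                raise DatasetError("expression columns and metadata sample ids differ")
            self.meta = self.meta.loc[self.values.columns]
        if self.values.index.has_duplicates:
            raise DatasetError("duplicate gene identifiers")
        if self.meta.index.has_duplicates:
            raise DatasetError("duplicate sample identifiers")
        bad_groups = set(self.meta["group"]) - {REFERENCE, CASE}
        if bad_groups:
            raise DatasetError(f"unknown group labels: {sorted(bad_groups)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise DatasetError("expression matrix contains missing or non-finite values")
        for t in self.time_labels:
            if not ((self.meta["time"] == t) & (self.meta["group"] == CASE)).any():
                continue
        n_ref_per_time = (
            self.meta[self.meta["group"] == REFERENCE].groupby("time", sort=False).size()
        )
        if (self.meta["group"] == REFERENCE).sum() < MIN_REFERENCE_SAMPLES:
            raise DatasetError(
                f"need >= {MIN_REFERENCE_SAMPLES} reference samples in total, "
                f"got {(self.meta['group'] == REFERENCE).sum()}"
            )
        del n_ref_per_time

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def time_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.meta["time"]:
            seen.setdefault(str(t), None)
        return list(seen)

    def samples(self, time: str | None = None, group: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        if time is not None:
            mask &= self.meta["time"].astype(str) == str(time)
        if group is not None:
            mask &= self.meta["group"] == group
        return list(self.meta.index[mask])

    def matrix(self, sample_ids: list[str], genes: list[str] | None = None) -> np.ndarray:
        sub = self.values[sample_ids]
        if genes is not None:
            sub = sub.loc[genes]
        return sub.to_numpy(dtype=float)

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[genes].copy(), self.meta.copy())


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Read expression TSV (first column gene id) + metadata TSV.

    Metadata columns: ``sample_id``, ``time``, ``group``.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    values.index = values.index.astype(str)
    values.index.name = None
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "time", "group"}
    if not required.issubset(meta.columns):
        raise DatasetError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")[["time", "group"]]
    return ExpressionDataset(values, meta)


def write_expression(data: ExpressionDataset, expr_path: str | Path, meta_path: str | Path) -> None:
    data.values.to_csv(expr_path, sep="\t", index_label="gene")
    out = data.meta.copy()
    out.index.name = "sample_id"
    out.to_csv(meta_path, sep="\t")
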