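"""Peptide intensity tables: the LiP-MS observation unit.

A table holds one row per peptide with replicate intensity columns named
``intensity_<condition>_<rep>`` (1-based replicate index). The scale flag
distinguishes raw linear intensities from log2-transformed ones; missing
measurements are NaN in memory and ``NA`` on disk, never zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("vehicle", "compound")


def intensity_columns(df: pd.DataFrame, condition: str) -> list[str]:
    prefix = f"intensity_{condition}_"
    cols = [c for c in df.columns if c.startswith(prefix)]
    return sorted(cols, key=lambda c: int(c.rsplit("_", 1)[1]))


@dataclass
class PeptideIntensityTable:
    """Peptide sequences with replicate intensities per condition.

    Parameters
    ----------
    df
        Columns ``peptide_id``, ``sequence`` and the intensity columns.
    scale
        ``"linear"`` or ``"log2"``.
    conditions
        Condition labels, vehicle first.
    """

    df: pd.DataFrame
    scale: str = "linear"
    conditions: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.df["peptide_id"].duplicated().any():
            dupes = self.df.loc[self.df["peptide_id"].duplicated(), "peptide_id"]
            raise ValueError(f"duplicate peptide ids: {sorted(set(dupes))[:5]}")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        for cond in self.conditions:
            if not intensity_columns(self.df, cond):
                raise ValueError(f"no intensity columns for condition {cond!r}")
        if self.scale == "linear":
            vals = self.intensity_matrix()
            with np.errstate(invalid="ignore"):
                bad_rows = (vals <= 0).any(axis=1)  # NaN compares False: missing is fine
            if bad_rows.any():
                bad = self.df.loc[bad_rows, "peptide_id"].tolist()
                raise ValueError(f"non-positive linear intensities in rows {bad[:5]}")

    def columns(self, condition: str) -> list[str]:
        return intensity_columns(self.df, condition)

    def all_intensity_columns(self) -> list[str]:
        return [c for cond in self.conditions for c in self.columns(cond)]

    def intensity_matrix(self) -> np.ndarray:
        return self.df[self.all_intensity_columns()].to_numpy(float)

    def __len__(self) -> int:
        return len(self.df)

    # -- TSV io --------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        scale: str = "linear",
        conditions: tuple[str, ...] = CONDITIONS,
    ) -> "PeptideIntensityTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(df, scale=scale, conditions=conditions)
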