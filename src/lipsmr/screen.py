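"""The directional-conflict protection screen.

Ligand binding locally shields a protein from proteinase K, so in a LiP-MS
experiment a binding site shows up as significant peptides shifting in
OPPOSITE directions at the same or nearly adjacent residue positions. The
screen therefore (1) keeps proteins with at least one significant
up-regulated AND one significant down-regulated peptide, then (2) keeps
those where some up/down pair of peptide locations overlaps or lies within
``gap_max`` residues, and ranks candidates by the joint evidence of their
best pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_GAP = 10

_P_FLOOR = 1e-300  # keeps the score finite for p reported as exactly 0


def interval_gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Residues strictly between two intervals; 0 when they overlap or abut."""
    return max(0, max(start1, start2) - min(end1, end2) - 1)


@dataclass(frozen=True)
class ConflictPair:
    """An up/down pair of significant peptide locations on one protein."""

    up_peptide_id: str
    up_interval: tuple[int, int]
    up_p: float
    down_peptide_id: str
    down_interval: tuple[int, int]
    down_p: float
    gap: int

    @property
    def score(self) -> float:
        return -math.log10(max(self.up_p, _P_FLOOR)) - math.log10(
            max(self.down_p, _P_FLOOR)
        )


@dataclass
class CandidateProtein:
    """A protein passing the screen, with its conflict pairs and rank score."""

    protein_id: str
    conflict_pairs: list[ConflictPair]
    best_pair: ConflictPair
    score: float
    n_up: int
    n_down: int
    shared: bool


def both_direction_filter(annotated: pd.DataFrame) -> set[str]:
    """Protein ids with at least one significant up AND one significant
    down peptide mapped to them."""
    sig = annotated[annotated["direction"].isin(["up", "down"])]
    per = sig.groupby("protein_id")["direction"].agg(set)
    return set(per[per.apply(lambda s: {"up", "down"} <= s)].index)


def find_conflicts(
    annotated: pd.DataFrame,
    protein_ids: set[str] | None = None,
    gap_max: int = DEFAULT_GAP,
) -> list[CandidateProtein]:
    """Enumerate up/down location pairs within ``gap_max`` residues.

    Every (up, down) pair of significant peptide locations on a protein
    whose interval gap is <= ``gap_max`` is a conflict pair; proteins with
    at least one become candidates, ordered by descending score of the best
    pair, ties by smaller best gap, then protein_id. Each occurrence of a
    peptide is a separate location and may form pairs independently.
    """
    if gap_max < 0:
        raise ValueError("gap_max must be >= 0")
    if protein_ids is None:
        protein_ids = both_direction_filter(annotated)

    sig = annotated[
        annotated["direction"].isin(["up", "down"])
        & annotated["protein_id"].isin(protein_ids)
    ]
    candidates: list[CandidateProtein] = []
    for protein_id, grp in sig.groupby("protein_id"):
        ups = grp[grp["direction"] == "up"]
        downs = grp[grp["direction"] == "down"]
        if ups.empty or downs.empty:
            continue
        us, ue = ups["start"].to_numpy(int), ups["end"].to_numpy(int)
        ds, de = downs["start"].to_numpy(int), downs["end"].to_numpy(int)
        gaps = np.maximum(
            0, np.maximum(us[:, None], ds[None, :]) - np.minimum(ue[:, None], de[None, :]) - 1
        )
        iu, idn = np.nonzero(gaps <= gap_max)
        if iu.size == 0:
            continue
        pairs = [
            ConflictPair(
                up_peptide_id=ups.iloc[i]["peptide_id"],
                up_interval=(int(us[i]), int(ue[i])),
                up_p=float(ups.iloc[i]["p"]),
                down_peptide_id=downs.iloc[j]["peptide_id"],
                down_interval=(int(ds[j]), int(de[j])),
                down_p=float(downs.iloc[j]["p"]),
                gap=int(gaps[i, j]),
            )
            for i, j in zip(iu, idn)
        ]
        best = min(
            pairs,
            key=lambda pr: (-pr.score, pr.gap, pr.up_peptide_id, pr.down_peptide_id),
        )
        shared_ids = set(grp.loc[grp["shared"], "peptide_id"])
        pair_ids = {p.up_peptide_id for p in pairs} | {p.down_peptide_id for p in pairs}
        candidates.append(
            CandidateProtein(
                protein_id=str(protein_id),
                conflict_pairs=pairs,
                best_pair=best,
                score=best.score,
                n_up=int(ups["peptide_id"].nunique()),
                n_down=int(downs["peptide_id"].nunique()),
                shared=bool(pair_ids & shared_ids),
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.best_pair.gap, c.protein_id))
    return candidates


def candidates_frame(candidates: list[CandidateProtein]) -> pd.DataFrame:
    """Tabular view of a ranked candidate list (intervals as 'start-end',
    1-based inclusive)."""
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "score": c.score,
                "n_up": c.n_up,
                "n_down": c.n_down,
                "best_gap": c.best_pair.gap,
                "best_up_interval": f"{c.best_pair.up_interval[0]}-{c.best_pair.up_interval[1]}",
                "best_down_interval": f"{c.best_pair.down_interval[0]}-{c.best_pair.down_interval[1]}",
                "shared_flag": c.shared,
            }
            for c in candidates
        ],
        columns=[
            "protein_id",
            "score",
            "n_up",
            "n_down",
            "best_gap",
            "best_up_interval",
            "best_down_interval",
            "shared_flag",
        ],
    )


def export_candidates(
    candidates: list[CandidateProtein], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``candidates.tsv`` and ``gene_list.txt`` (one id per line) to
    ``out_dir``; returns the two paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        tsv = out / "candidates.tsv"
        genes = out / "gene_list.txt"
        candidates_frame(candidates).to_csv(tsv, sep="\t", index=False)
        genes.write_text("".join(c.protein_id + "\n" for c in candidates))
    except OSError as exc:
        raise OSError(f"failed writing candidate files under {out}: {exc}") from exc
    return tsv, genes
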