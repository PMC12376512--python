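"""End-to-end LiP-MS screen: simulate/load -> normalize -> test -> map -> screen."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intensities import PeptideIntensityTable
from .mapping import annotate_results
from .proteins import ProteinDB
from .screen import CandidateProtein, both_direction_filter, find_conflicts
from .simulate import LipSimConfig, LipTruthTable, generate_lipms_dataset
from .stats import DEFAULT_ALPHA, DEFAULT_LFC_MIN, normalize_intensities, test_peptides


@dataclass
class LipScreenRun:
    """All intermediate products of one screen run."""

    db: ProteinDB
    table: PeptideIntensityTable
    results: pd.DataFrame
    annotated: pd.DataFrame
    both_direction: set[str]
    candidates: list[CandidateProtein]
    truth: LipTruthTable | None = None


def run_lip_screen(
    db: ProteinDB,
    table: PeptideIntensityTable,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    gap_max: int = 10,
    truth: LipTruthTable | None = None,
) -> LipScreenRun:
    """Run the full screen on a linear-scale intensity table."""
    if table.scale == "linear":
        table = normalize_intensities(table)
    results = test_peptides(table, alpha=alpha, lfc_min=lfc_min)
    annotated = annotate_results(results, db)
    both = both_direction_filter(annotated)
    candidates = find_conflicts(annotated, both, gap_max=gap_max)
    return LipScreenRun(
        db=db,
        table=table,
        results=results,
        annotated=annotated,
        both_direction=both,
        candidates=candidates,
        truth=truth,
    )


def run_simulated_screen(
    config: LipSimConfig,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    gap_max: int | None = None,
) -> LipScreenRun:
    """Simulate a dataset under ``config`` and screen it; the run keeps the
    truth table so recovery can be scored against the planted classes."""
    db, table, truth = generate_lipms_dataset(config)
    return run_lip_screen(
        db,
        table,
        alpha=alpha,
        lfc_min=lfc_min,
        gap_max=config.adjacency_gap if gap_max is None else gap_max,
        truth=truth,
    )


def score_recovery(run: LipScreenRun) -> dict:
    """Sensitivity/specificity of a simulated run against its truth."""
    if run.truth is None:
        raise ValueError("run has no truth table")
    cls = dict(zip(run.truth.proteins["protein_id"], run.truth.proteins["cls"]))
    found = {c.protein_id for c in run.candidates}
    targets = {p for p, c in cls.items() if c == "target"}
    far = {p for p, c in cls.items() if c == "far_decoy"}
    same = {p for p, c in cls.items() if c == "same_direction_decoy"}
    nulls = {p for p, c in cls.items() if c == "null"}
    return {
        "n_candidates": len(found),
        "sensitivity": len(found & targets) / len(targets) if targets else float("nan"),
        "n_far_decoy_hits": len(found & far),
        "n_same_direction_hits": len(found & same),
        "n_null_hits": len(found & nulls),
    }
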