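import logging

import numpy as np
import pandas as pd
import pytest

from lipsmr import LipSimConfig, generate_lipms_dataset


@pytest.fixture(autouse=True)
def _quiet_logging():
    logging.getLogger("lipsmr").setLevel(logging.ERROR)
    yield
    logging.getLogger("lipsmr").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def small_lip_dataset():
    """A small simulated LiP-MS dataset shared across tests."""
    cfg = LipSimConfig(
        n_proteins=30, n_targets=3, n_far_decoys=3, n_same_direction_decoys=2, seed=42
    )
    return generate_lipms_dataset(cfg)


def random_annotated_table(rng: np.random.Generator, n_proteins=None, n_peptides=None):
    """A random annotated-peptide table (directions, positions, p-values)
    for exercising the screen independently of the upstream stages."""
    n_prot = int(rng.integers(2, 51)) if n_proteins is None else n_proteins
    n_pep = int(rng.integers(5, 201)) if n_peptides is None else n_peptides
    protein = rng.integers(0, n_prot, n_pep)
    start = rng.integers(1, 400, n_pep)
    length = rng.integers(6, 30, n_pep)
    direction = rng.choice(["up", "down", "ns"], n_pep, p=[0.3, 0.3, 0.4])
    return pd.DataFrame(
        {
            "peptide_id": [f"pep{i:04d}" for i in range(n_pep)],
            "protein_id": [f"prot{p:03d}" for p in protein],
            "start": start,
            "end": start + length - 1,
            "direction": direction,
            "p": rng.uniform(1e-8, 1.0, n_pep),
            "shared": rng.random(n_pep) < 0.05,
        }
    )


def brute_force_candidates(annotated: pd.DataFrame, gap_max: int) -> dict[str, list]:
    """O(n^2) enumeration over all peptide-location pairs: candidate
    proteins mapped to their conflict pairs (the screen's independent
    oracle)."""
    rows = annotated.to_dict("records")
    out: dict[str, list] = {}
    for a in rows:
        for b in rows:
            if a["protein_id"] != b["protein_id"]:
                continue
            if a["direction"] != "up" or b["direction"] != "down":
                continue
            gap = max(0, max(a["start"], b["start"]) - min(a["end"], b["end"]) - 1)
            if gap <= gap_max:
                out.setdefault(a["protein_id"], []).append(
                    (a["peptide_id"], b["peptide_id"], gap)
                )
    return out
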