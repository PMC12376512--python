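"""Map peptides onto the protein database.

Gives every differential result its 1-based [start, end] residue
coordinates. Matching is exact (no isoleucine/leucine equivalence); a
peptide matching more than one protein is flagged ``shared`` and
participates in screening for every protein it maps to.
"""

from __future__ import annotations

import logging

import pandas as pd

from .proteins import ProteinDB

logger = logging.getLogger(__name__)


def locate_peptide(peptide: str, db: ProteinDB) -> list[tuple[str, int, int]]:
    """All exact occurrences of ``peptide`` across the database as
    (protein_id, start, end), 1-based inclusive, ordered by protein_id then
    start. Overlapping occurrences within one protein are all reported.
    Returns an empty list when the peptide is absent."""
    if not peptide or peptide != peptide.upper():
        raise ValueError("peptide must be non-empty and uppercase")
    return db.locate(peptide)


def annotate_results(results: pd.DataFrame, db: ProteinDB) -> pd.DataFrame:
    """Join differential results to their locations in the database.

    Parameters
    ----------
    results
        Output of :func:`lipsmr.stats.test_peptides` (needs at least
        ``peptide_id, sequence, log2fc, p, q, direction``).
    db
        The protein database the peptides derive from.

    Returns
    -------
    DataFrame with one row per (peptide, location): the result columns plus
    ``protein_id, start, end, shared``. Unmapped peptides are excluded and
    logged. ``shared`` is True when the peptide maps to more than one protein.
    """
    if len(results) == 0 or len(db) == 0:
        raise ValueError("results and protein database must be non-empty")
    if results["peptide_id"].duplicated().any():
        raise ValueError("duplicate peptide_id in results")

    rows = []
    n_unmapped = 0
    n_shared = 0
    for rec in results.itertuples(index=False):
        hits = db.locate(rec.sequence)
        if not hits:
            n_unmapped += 1
            continue
        shared = len({h[0] for h in hits}) > 1
        n_shared += int(shared)
        for protein_id, start, end in hits:
            rows.append((rec.peptide_id, protein_id, start, end, shared))

    if n_unmapped:
        logger.warning("%d peptide(s) did not map to any protein", n_unmapped)
    if n_shared:
        logger.info("%d peptide(s) map to more than one protein", n_shared)

    loc = pd.DataFrame(
        rows, columns=["peptide_id", "protein_id", "start", "end", "shared"]
    )
    out = results.merge(loc, on="peptide_id", how="inner")
    return out.sort_values(
        ["protein_id", "start", "peptide_id"], kind="mergesort"
    ).reset_index(drop=True)
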