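"""In-silico tryptic digestion.

Trypsin cleaves C-terminal of lysine (K) or arginine (R) except when the
next residue is proline (P). Coordinates are 1-based with inclusive ends
throughout the package.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


def cleavage_sites(sequence: str) -> list[int]:
    """Return 0-based indices i such that trypsin cuts between sequence[i]
    and sequence[i+1] (K/R at i, no P at i+1)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_tryptic(
    sequence: str,
    missed_cleavages: int = 0,
    min_len: int | None = None,
    max_len: int | None = None,
) -> list[tuple[str, int, int]]:
    """Digest a protein sequence with trypsin.

    Parameters
    ----------
    sequence
        Uppercase amino-acid sequence (20 standard letters).
    missed_cleavages
        Maximum number of internal missed cleavage sites per peptide.
    min_len, max_len
        Optional peptide length window; peptides outside it are dropped.

    Returns
    -------
    list of (peptide_sequence, start, end)
        1-based inclusive coordinates. With ``missed_cleavages=0`` and no
        length filter the peptides tile the sequence. Fully cleaved
        peptides come first (in order), then longer missed-cleavage forms.

    Raises
    ------
    ValueError
        On empty sequence or a letter outside the standard alphabet.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    for ch in sequence:
        if ch not in _AA_SET:
            raise ValueError(f"invalid amino-acid letter {ch!r} in sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")

    # fragment boundaries: [b_k, b_{k+1}) in 0-based half-open coordinates
    cuts = cleavage_sites(sequence)
    bounds = [0] + [i + 1 for i in cuts] + [len(sequence)]
    n_frag = len(bounds) - 1

    out: list[tuple[str, int, int]] = []
    for mc in range(missed_cleavages + 1):
        for k in range(n_frag - mc):
            lo, hi = bounds[k], bounds[k + mc + 1]
            length = hi - lo
            if min_len is not None and length < min_len:
                continue
            if max_len is not None and length > max_len:
                continue
            out.append((sequence[lo:hi], lo + 1, hi))
    return out
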