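"""Protein sequence database: the positional reference frame for peptides."""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import _AA_SET


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier and its amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: invalid letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinDB:
    """Ordered collection of unique ProteinRecords with exact peptide lookup.

    Lookup uses a lazily built concatenated-text index so that locating
    thousands of peptides against hundreds of proteins stays fast.
    """

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.protein_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids: {dupes}")
        self._index: dict[str, int] = {r.protein_id: k for k, r in enumerate(self.records)}
        self._text: str | None = None
        self._offsets: list[int] = []

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self.records[self._index[protein_id]]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def _build_text(self) -> None:
        # '#' separators prevent matches spanning two proteins
        parts, offsets, pos = [], [], 0
        for r in self.records:
            offsets.append(pos)
            parts.append(r.sequence)
            pos += len(r.sequence) + 1
        self._text = "#".join(parts)
        self._offsets = offsets

    def locate(self, peptide: str) -> list[tuple[str, int, int]]:
        """All exact occurrences of ``peptide`` as (protein_id, start, end),
        1-based inclusive, ordered by protein_id then start (overlapping
        occurrences included). Empty list when absent."""
        if not peptide:
            raise ValueError("peptide must be non-empty")
        if self._text is None:
            self._build_text()
        assert self._text is not None
        hits: list[tuple[str, int, int]] = []
        pos = self._text.find(peptide)
        while pos != -1:
            k = bisect.bisect_right(self._offsets, pos) - 1
            rec = self.records[k]
            start = pos - self._offsets[k] + 1
            hits.append((rec.protein_id, start, start + len(peptide) - 1))
            pos = self._text.find(peptide, pos + 1)
        hits.sort(key=lambda h: (h[0], h[1]))
        return hits

    # -- FASTA io ------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinDB":
        records = [
            ProteinRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            (SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in self.records),
            str(path),
            "fasta",
        )
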