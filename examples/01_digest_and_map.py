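"""Tryptic digestion and peptide-to-protein mapping.

Digest a toy protein, then locate a peptide back in a small database.
Coordinates are 1-based with inclusive ends.
"""

from lipsmr import ProteinDB, ProteinRecord, digest_tryptic, locate_peptide

seq = "AAKAARPAAKMSTRGGK"
print(f"protein: {seq}")
for pep, start, end in digest_tryptic(seq):
    print(f"  peptide {pep:>10s}  residues {start:2d}-{end:2d}")
# the R before P is not cleaved (trypsin skips K/R-P bonds)

db = ProteinDB([ProteinRecord("demo", seq), ProteinRecord("other", "MAARPAAKW")])
hits = locate_peptide("AARPAAK", db)
print("\nlocations of AARPAAK:")
for protein_id, start, end in hits:
    print(f"  {protein_id}: {start}-{end}")
# the peptide is shared between the two proteins; the screen would flag it
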