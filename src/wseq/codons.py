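"""Standard genetic code lookup tables (built from Biopython's table 1)."""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, with stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], tuple())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

NUCLEOTIDES = ("A", "C", "G", "T")


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def split_codons(cds: str) -> list[str]:
    """Split a CDS into codons; length must be divisible by 3."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def translate_cds(cds: str) -> str:
    """Translate a frame-0 CDS, stops rendered as '*'."""
    return "".join(CODON_TO_AA[c] for c in split_codons(cds))
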