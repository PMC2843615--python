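"""Shared domain types for the WSP microevolution toolkit.

The unit of analysis is a *wsp* allele: a unique nucleotide sequence of the
typed gene fragment, translated in frame 0 (the fragment is internal, so no
start codon is required and any stop codon is an error).  A protein haplotype
is summarised by a :class:`WspProfile` — the 4-tuple of hypervariable-region
(HVR) peptide identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from Bio.Data import CodonTable

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: Standard genetic code, forward table only (no stops).
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)

VALID_NT = frozenset("ACGT")
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class SequenceError(ValueError):
    """A nucleotide or protein sequence violates a precondition."""


def translate_cds(nt_seq: str) -> str:
    """Translate an in-frame coding fragment with the standard genetic code.

    Raises :class:`SequenceError` for empty input, a length not divisible by
    3, non-ACGT characters (ambiguity codes are a dataset requirement, not a
    recoverable condition) or any stop codon.
    """
    seq = nt_seq.upper()
    if not seq or len(seq) % 3:
        raise SequenceError(
            f"sequence length {len(seq)} is not a positive multiple of 3"
        )
    bad = set(seq) - VALID_NT
    if bad:
        raise SequenceError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    residues = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise SequenceError(f"stop codon {codon} at nucleotide position {i}")
        residues.append(CODON_TO_AA[codon])
    return "".join(residues)


@dataclass(frozen=True)
class Allele:
    """A numbered, deduplicated nucleotide sequence plus its translation."""

    allele_id: int
    nt_seq: str
    aa_seq: str

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)

    @classmethod
    def from_nt(cls, allele_id: int, nt_seq: str) -> "Allele":
        if allele_id < 1:
            raise ValueError(f"allele_id must be positive, got {allele_id}")
        nt = nt_seq.upper()
        return cls(allele_id=allele_id, nt_seq=nt, aa_seq=translate_cds(nt))

    def __post_init__(self) -> None:
        if self.aa_seq and len(self.nt_seq) != 3 * len(self.aa_seq):
            raise SequenceError("aa_seq length inconsistent with nt_seq length")


class WspProfile(NamedTuple):
    """Protein haplotype: one peptide identifier per HVR, in gene order."""

    h1: int
    h2: int
    h3: int
    h4: int

    def __str__(self) -> str:  # used in TSV artifacts
        return f"{self.h1}-{self.h2}-{self.h3}-{self.h4}"

    @classmethod
    def parse(cls, text: str) -> "WspProfile":
        parts = text.split("-")
        if len(parts) != 4:
            raise ValueError(f"cannot parse profile {text!r}")
        return cls(*(int(p) for p in parts))


@dataclass(frozen=True)
class IsolateRecord:
    """One host record: which allele was found in which host, where."""

    isolate_id: str
    allele_id: int
    host_order: str = ""
    host_family: str = ""
    host_genus: str = ""
    host_species: str = ""
    country: str = ""
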