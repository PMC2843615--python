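"""Readers/writers for all pipeline inputs and outputs.

All tabular artifacts are tab-separated, UTF-8, header row required, no
quoting, so that outputs are bit-exact diffable.  Allele numbering is
first-seen when a registry is built fresh; a registry loaded from TSV is
authoritative and new sequences extend from ``max_id + 1`` (pubMLST-style
compatibility with externally curated numbering).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Allele, IsolateRecord, IUPAC_NT, SequenceError, WspProfile

PROFILE_COLUMNS = ["allele_id", "hvr1", "hvr2", "hvr3", "hvr4"]
ISOLATE_COLUMNS = [
    "isolate_id",
    "allele_id",
    "host_order",
    "host_family",
    "host_genus",
    "host_species",
    "country",
]


class TableError(ValueError):
    """A tabular input violates its contract."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record_id, uppercased_sequence), ...]``.

    File order is preserved.  Errors: empty file, duplicate record ids, and
    characters outside the IUPAC nucleotide alphabet (named per record).
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise TableError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise TableError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records:
        raise TableError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Allele registry
# ---------------------------------------------------------------------------

class AlleleRegistry:
    """Stable nucleotide-sequence -> allele-id mapping.

    Ids are dense from 1 when built fresh; duplicates collapse onto the
    existing id.  Round-trips losslessly through its TSV serialization.
    """

    def __init__(self) -> None:
        self._ids: dict[str, int] = {}
        self._alleles: dict[int, Allele] = {}

    # -- construction -----------------------------------------------------

    @property
    def next_id(self) -> int:
        return max(self._alleles, default=0) + 1

    def register(self, nt_seq: str) -> int:
        """Register one sequence, returning its (possibly pre-existing) id."""
        seq = nt_seq.upper()
        existing = self._ids.get(seq)
        if existing is not None:
            return existing
        allele = Allele.from_nt(self.next_id, seq)  # validates the sequence
        self._ids[seq] = allele.allele_id
        self._alleles[allele.allele_id] = allele
        return allele.allele_id

    def register_many(self, seqs: Iterable[str]) -> list[int]:
        return [self.register(s) for s in seqs]

    def _load(self, allele_id: int, nt_seq: str) -> None:
        seq = nt_seq.upper()
        if seq in self._ids and self._ids[seq] != allele_id:
            raise TableError(
                f"sequence registered twice with ids {self._ids[seq]} and {allele_id}"
            )
        if allele_id in self._alleles and self._alleles[allele_id].nt_seq != seq:
            raise TableError(f"allele_id {allele_id} maps to two sequences")
        allele = Allele.from_nt(allele_id, seq)
        self._ids[seq] = allele_id
        self._alleles[allele_id] = allele

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._alleles)

    def __contains__(self, nt_seq: str) -> bool:
        return nt_seq.upper() in self._ids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleRegistry):
            return NotImplemented
        return self._ids == other._ids

    def id_of(self, nt_seq: str) -> int:
        return self._ids[nt_seq.upper()]

    def __getitem__(self, allele_id: int) -> Allele:
        return self._alleles[allele_id]

    def alleles(self) -> list[Allele]:
        """All alleles in ascending id order."""
        return [self._alleles[i] for i in sorted(self._alleles)]

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "allele_id": [a.allele_id for a in self.alleles()],
                "nt_seq": [a.nt_seq for a in self.alleles()],
            }
        )
        _write_tsv(df, path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleRegistry":
        df = _read_tsv(path, ["allele_id", "nt_seq"])
        reg = cls()
        for allele_id, nt_seq in zip(df["allele_id"].astype(int), df["nt_seq"]):
            reg._load(int(allele_id), str(nt_seq))
        return reg


def register_alleles(seqs: Sequence[str]) -> AlleleRegistry:
    """Assign allele numbers to unique sequences in first-seen order."""
    reg = AlleleRegistry()
    reg.register_many(seqs)
    return reg


# ---------------------------------------------------------------------------
# Profile / isolate tables
# ---------------------------------------------------------------------------

def read_profile_table(path: str | Path) -> dict[int, WspProfile]:
    """Read an allele -> WSP-profile table (columns allele_id, hvr1..hvr4)."""
    df = _read_tsv(path, PROFILE_COLUMNS)
    ids = df["allele_id"].astype(int)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise TableError(f"duplicate allele_id rows in profile table: {dupes}")
    return {
        int(row.allele_id): WspProfile(
            int(row.hvr1), int(row.hvr2), int(row.hvr3), int(row.hvr4)
        )
        for row in df.itertuples()
    }


def write_profile_table(path: str | Path, profiles: dict[int, WspProfile]) -> None:
    rows = [
        {"allele_id": aid, "hvr1": p.h1, "hvr2": p.h2, "hvr3": p.h3, "hvr4": p.h4}
        for aid, p in sorted(profiles.items())
    ]
    _write_tsv(pd.DataFrame(rows, columns=PROFILE_COLUMNS), path)


def read_isolate_table(path: str | Path) -> list[IsolateRecord]:
    """Read the isolate metadata table; blank taxonomy fields are allowed."""
    df = _read_tsv(path, ISOLATE_COLUMNS).fillna("")
    records = [
        IsolateRecord(
            isolate_id=str(row.isolate_id),
            allele_id=int(row.allele_id),
            host_order=str(row.host_order),
            host_family=str(row.host_family),
            host_genus=str(row.host_genus),
            host_species=str(row.host_species),
            country=str(row.country),
        )
        for row in df.itertuples()
    ]
    triples = [(r.host_species, r.allele_id, r.country) for r in records]
    if len(triples) != len(set(triples)):
        raise TableError(
            "duplicate (host_species, allele_id, country) triples in isolate table"
        )
    return records


def write_isolate_table(path: str | Path, records: Sequence[IsolateRecord]) -> None:
    rows = [
        {
            "isolate_id": r.isolate_id,
            "allele_id": r.allele_id,
            "host_order": r.host_order,
            "host_family": r.host_family,
            "host_genus": r.host_genus,
            "host_species": r.host_species,
            "country": r.country,
        }
        for r in records
    ]
    _write_tsv(pd.DataFrame(rows, columns=ISOLATE_COLUMNS), path)


# ---------------------------------------------------------------------------
# TSV dialect helpers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def _read_tsv(path: str | Path, required_columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"empty table: {path}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    return df
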