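"""Segment WSP proteins into HVR/CR sections and assign haplotype profiles.

The typing system partitions a WSP protein into four consecutive peptides,
each spanning one hypervariable region (HVR) plus short flanks of the two
adjacent conserved regions (CRs).  Each distinct peptide per HVR class is
numbered, and a protein haplotype is the 4-tuple of peptide numbers (a "WSP
profile").  CRs show no indels, so short exact anchor motifs inside CRs
locate section boundaries without a multiple alignment; a coordinate-based
schema is available as a fallback for divergent sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .core import Allele, WspProfile
from .io_tables import _read_tsv, _write_tsv

_HVR_NAME = re.compile(r"(?i)^hvr[1-4]$")

#: Locator kinds: section starts at the anchor motif, right after it, or at
#: fixed amino-acid coordinates "start-end" (end ignored; sections tile).
LOCATORS = ("anchor_start", "anchor_after", "coords")


class SchemaError(ValueError):
    """Segmentation schema cannot be applied to a sequence."""


@dataclass(frozen=True)
class Section:
    name: str
    locator: str  # one of LOCATORS
    value: str    # anchor motif or "start-end"

    def __post_init__(self) -> None:
        if self.locator not in LOCATORS:
            raise SchemaError(f"unknown locator {self.locator!r}")


@dataclass(frozen=True)
class SectionSchema:
    """Ordered, non-overlapping sections jointly covering the typed region."""

    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        hvrs = [s for s in self.sections if _HVR_NAME.match(s.name)]
        if len(hvrs) != 4:
            raise SchemaError(
                f"schema must contain exactly four HVR sections, found {len(hvrs)}"
            )
        names = [s.name for s in self.sections]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate section names in schema")

    @property
    def hvr_names(self) -> list[str]:
        return [s.name for s in self.sections if _HVR_NAME.match(s.name)]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [{"section": s.name, "locator": s.locator, "value": s.value}
             for s in self.sections]
        )
        _write_tsv(df, path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SectionSchema":
        df = _read_tsv(path, ["section", "locator", "value"])
        return cls(
            tuple(
                Section(str(r.section), str(r.locator), str(r.value))
                for r in df.itertuples()
            )
        )


class SectionSpan(NamedTuple):
    name: str
    start: int  # aa coordinate, inclusive
    end: int    # aa coordinate, exclusive
    peptide: str


def _find_anchor(aa_seq: str, motif: str, tolerance: int, context: str) -> int:
    """Locate a unique anchor motif, optionally within a Hamming tolerance."""
    if tolerance == 0:
        hits = [m.start() for m in re.finditer(f"(?={re.escape(motif)})", aa_seq)]
    else:
        k = len(motif)
        scored = [
            (sum(a != b for a, b in zip(aa_seq[i : i + k], motif)), i)
            for i in range(len(aa_seq) - k + 1)
        ]
        best = min((d for d, _ in scored), default=tolerance + 1)
        hits = [i for d, i in scored if d == best] if best <= tolerance else []
    if not hits:
        raise SchemaError(f"anchor {motif!r} for section {context} not found")
    if len(hits) > 1:
        raise SchemaError(
            f"anchor {motif!r} for section {context} matches at {len(hits)} positions"
        )
    return hits[0]


def segment(
    aa_seq: str, schema: SectionSchema, tolerance: int = 0
) -> dict[str, SectionSpan]:
    """Partition ``aa_seq`` into the schema's sections.

    Returns an ordered mapping section name -> :class:`SectionSpan`.  The
    concatenation of section peptides reconstructs the typed region (first
    section start to sequence end).  Anchor motifs must match exactly once;
    with ``tolerance > 0``, two candidate matches at equal Hamming distance
    are an error, never a silent choice.
    """
    starts: list[int] = []
    for sec in schema.sections:
        if sec.locator == "coords":
            start = int(sec.value.split("-")[0])
            if start > len(aa_seq):
                raise SchemaError(
                    f"sequence of length {len(aa_seq)} shorter than schema "
                    f"coordinate {start} for section {sec.name}"
                )
        else:
            pos = _find_anchor(aa_seq, sec.value, tolerance, sec.name)
            start = pos + (len(sec.value) if sec.locator == "anchor_after" else 0)
        starts.append(start)
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise SchemaError(f"section starts are not strictly increasing: {starts}")
    spans: dict[str, SectionSpan] = {}
    bounds = starts + [len(aa_seq)]
    for sec, start, end in zip(schema.sections, bounds, bounds[1:]):
        spans[sec.name] = SectionSpan(sec.name, start, end, aa_seq[start:end])
    return spans


def segment_peptides(aa_seq: str, schema: SectionSchema, tolerance: int = 0) -> dict[str, str]:
    """Convenience wrapper returning section name -> peptide string."""
    return {name: span.peptide for name, span in segment(aa_seq, schema, tolerance).items()}


# ---------------------------------------------------------------------------
# Peptide registry and profile assignment
# ---------------------------------------------------------------------------

class PeptideRegistry:
    """Per-HVR-class mapping peptide string -> peptide id, dense from 1."""

    def __init__(self) -> None:
        self._ids: dict[str, dict[str, int]] = {}
        self._strings: dict[str, dict[int, str]] = {}

    def assign(self, hvr_class: str, peptide: str) -> int:
        forward = self._ids.setdefault(hvr_class, {})
        pid = forward.get(peptide)
        if pid is None:
            pid = len(forward) + 1
            forward[peptide] = pid
            self._strings.setdefault(hvr_class, {})[pid] = peptide
        return pid

    def peptide(self, hvr_class: str, pid: int) -> str:
        return self._strings[hvr_class][pid]

    def classes(self) -> list[str]:
        return list(self._ids)

    def n_peptides(self, hvr_class: str) -> int:
        return len(self._ids.get(hvr_class, {}))

    def peptides(self, hvr_class: str) -> list[str]:
        strings = self._strings.get(hvr_class, {})
        return [strings[i] for i in sorted(strings)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeptideRegistry):
            return NotImplemented
        return self._ids == other._ids

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"hvr_class": cls, "peptide_id": pid, "peptide_seq": pep}
            for cls in self._strings
            for pid, pep in sorted(self._strings[cls].items())
        ]
        _write_tsv(pd.DataFrame(rows, columns=["hvr_class", "peptide_id", "peptide_seq"]), path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeptideRegistry":
        df = _read_tsv(path, ["hvr_class", "peptide_id", "peptide_seq"])
        reg = cls()
        for r in df.itertuples():
            hvr, pid, pep = str(r.hvr_class), int(r.peptide_id), str(r.peptide_seq)
            reg._ids.setdefault(hvr, {})[pep] = pid
            reg._strings.setdefault(hvr, {})[pid] = pep
        return reg


def assign_profiles(
    alleles: Sequence[Allele],
    schema: SectionSchema,
    registry: PeptideRegistry | None = None,
    tolerance: int = 0,
) -> tuple[PeptideRegistry, dict[int, WspProfile]]:
    """Type every allele: segment, number peptides first-seen, build profiles.

    Synonymous alleles (equal ``aa_seq``) necessarily receive equal profiles.
    A supplied pre-existing registry is authoritative for known peptides.
    """
    registry = registry if registry is not None else PeptideRegistry()
    profiles: dict[int, WspProfile] = {}
    for allele in alleles:
        try:
            spans = segment(allele.aa_seq, schema, tolerance)
        except SchemaError as exc:
            raise SchemaError(f"allele {allele.allele_id}: {exc}") from exc
        ids = [registry.assign(name, spans[name].peptide) for name in schema.hvr_names]
        profiles[allele.allele_id] = WspProfile(*ids)
    return registry, profiles


def peptide_length_stats(registry: PeptideRegistry) -> pd.DataFrame:
    """Per-HVR (min, max) peptide length and distinct-peptide count."""
    if not registry.classes():
        raise ValueError("empty peptide registry")
    rows = []
    for cls in registry.classes():
        lengths = [len(p) for p in registry.peptides(cls)]
        rows.append(
            {
                "hvr_class": cls,
                "min_length": min(lengths),
                "max_length": max(lengths),
                "n_peptides": len(lengths),
            }
        )
    return pd.DataFrame(rows).set_index("hvr_class")
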