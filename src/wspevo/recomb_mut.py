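"""Discriminate mutant from recombinant single-HVR variants.

Within a complex, every founder->variant divergence at one HVR is classified:

(i)   >= ``major_threshold`` amino-acid polymorphic sites (substitutions plus
      indel columns, default 4) -> recombinant ("major");
(ii)  otherwise, if the variant's SHV peptide also occurs in other complexes,
      the nucleotide substitution patterns underlying the peptide are
      compared, each polarized against its own complex's ancestral-allele
      section:  differing patterns -> mutant;  one matching shared
      substitution -> mutant by convergence;  multiple matching shared
      substitutions -> recombination, assigned to the profile with the
      greater amino-acid change count versus its own founder (both on a tie);
(iii) a peptide unique in the dataset -> mutant.

Contribution accounting follows two axes: haplotype diversity (event counts
by class) and amino-acid diversity (summed changes by class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._align import count_changes, global_align
from .core import Allele, WspProfile
from .hvr_typing import PeptideRegistry, SectionSchema, segment
from .profile_clustering import (
    ClusterResult,
    Complex,
    profile_distance,
    representative_allele,
)

MAJOR_THRESHOLD_DEFAULT = 4


def count_aa_changes(pep_a: str, pep_b: str) -> tuple[int, int]:
    """(substitution columns, indel columns) between two peptides.

    Computed from a fixed-scoring global alignment; identical equal-length
    peptides give (0, 0).
    """
    if not pep_a or not pep_b:
        raise ValueError("peptides must be non-empty")
    return count_changes(pep_a, pep_b)


def substitution_pattern(section_nt: str, ancestral_nt: str) -> frozenset[tuple[int, str]]:
    """Set of (position-in-section, derived state) differences vs the ancestor.

    Positions are indexed on a per-section pairwise alignment; gap columns
    contribute the derived state ``'-'``.
    """
    a, b = global_align(ancestral_nt, section_nt)
    return frozenset(
        (i, y) for i, (x, y) in enumerate(zip(a, b)) if x != y
    )


@dataclass(frozen=True)
class ShvEvent:
    """One founder->variant (or predecessor->variant) divergence event."""

    complex_id: int
    profile: WspProfile
    parent_profile: WspProfile
    hvr_index: int  # 1-based
    n_subs: int
    n_indel_cols: int
    classification: str  # "mutant" | "recombinant"
    evidence: str  # "major" | "shared-pattern" | "unique-peptide" | "convergent-single-sub"

    @property
    def n_changes(self) -> int:
        return self.n_subs + self.n_indel_cols


@dataclass
class ContributionSummary:
    """Mutation vs recombination, on the haplotype and amino-acid axes."""

    table: pd.DataFrame  # rows HVR1..HVR4 + overall

    @property
    def pct_mutant_events(self) -> float:
        return float(self.table.loc["overall", "pct_events_mutant"])

    @property
    def pct_recombinant_events(self) -> float:
        return float(self.table.loc["overall", "pct_events_recombinant"])

    @property
    def pct_aa_mutation(self) -> float:
        return float(self.table.loc["overall", "pct_changes_mutant"])

    @property
    def pct_aa_recombination(self) -> float:
        return float(self.table.loc["overall", "pct_changes_recombinant"])


class _EventContext:
    """Shared lookups for event classification across complexes."""

    def __init__(
        self,
        clusters: ClusterResult,
        alleles_by_id: Mapping[int, Allele],
        profiles: Mapping[int, WspProfile],
        registry: PeptideRegistry,
        schema: SectionSchema,
        isolates_by_allele: Mapping[int, int] | None = None,
        tolerance: int = 0,
    ) -> None:
        self.clusters = clusters
        self.alleles = alleles_by_id
        self.registry = registry
        self.schema = schema
        self.hvr_names = schema.hvr_names
        self.iso = isolates_by_allele or {}
        self.tolerance = tolerance
        self.alleles_by_profile: dict[WspProfile, list[int]] = {}
        for aid in sorted(profiles):
            self.alleles_by_profile.setdefault(profiles[aid], []).append(aid)
        # (hvr index, peptide id) -> [(complex, profile)] over all complex members
        self.peptide_sites: dict[tuple[int, int], list[tuple[Complex, WspProfile]]] = {}
        for cx in clusters.complexes:
            for p in cx.members:
                for i, pid in enumerate(p):
                    self.peptide_sites.setdefault((i, pid), []).append((cx, p))
        self._spans_cache: dict[int, dict] = {}
        self._rep_cache: dict[WspProfile, int] = {}

    def rep_allele(self, profile: WspProfile) -> int:
        if profile not in self._rep_cache:
            self._rep_cache[profile] = representative_allele(
                profile, self.alleles_by_profile, self.iso
            )
        return self._rep_cache[profile]

    def section_nt(self, profile: WspProfile, hvr_index: int) -> str:
        """Nucleotides coding the typing section of ``profile`` at one HVR."""
        aid = self.rep_allele(profile)
        if aid not in self.alleles:
            raise KeyError(f"missing nucleotide sequence for allele {aid}")
        allele = self.alleles[aid]
        if aid not in self._spans_cache:
            self._spans_cache[aid] = segment(allele.aa_seq, self.schema, self.tolerance)
        span = self._spans_cache[aid][self.hvr_names[hvr_index]]
        return allele.nt_seq[3 * span.start : 3 * span.end]

    def peptide(self, hvr_index: int, pid: int) -> str:
        return self.registry.peptide(self.hvr_names[hvr_index], pid)

    def variant_pattern(self, cx: Complex, profile: WspProfile, hvr_index: int):
        """Nucleotide pattern of a member's section vs its own predecessor."""
        base = cx.parent[profile] if cx.parent.get(profile) is not None else None
        if base is None:  # the founder itself: nothing derived
            return frozenset()
        if profile[hvr_index] == base[hvr_index]:
            return frozenset()
        return substitution_pattern(
            self.section_nt(profile, hvr_index), self.section_nt(base, hvr_index)
        )

    def classify_pair(
        self, cx: Complex, parent: WspProfile, variant: WspProfile, major_threshold: int
    ) -> ShvEvent:
        diffs = [i for i in range(4) if parent[i] != variant[i]]
        if len(diffs) != 1:
            raise ValueError(
                f"profiles {parent} and {variant} differ at {len(diffs)} HVRs, expected 1"
            )
        hvr = diffs[0]
        pep_parent = self.peptide(hvr, parent[hvr])
        pep_variant = self.peptide(hvr, variant[hvr])
        n_subs, n_ind = count_aa_changes(pep_parent, pep_variant)
        total = n_subs + n_ind
        if total >= major_threshold:
            cls, ev = "recombinant", "major"
        else:
            pattern = substitution_pattern(
                self.section_nt(variant, hvr), self.section_nt(parent, hvr)
            )
            sharers = [
                (ocx, oprof)
                for ocx, oprof in self.peptide_sites.get((hvr, variant[hvr]), [])
                if ocx.complex_id != cx.complex_id
            ]
            if not sharers:
                cls, ev = "mutant", "unique-peptide"
            else:
                # shared substitutions = intersection of the two patterns,
                # each polarized against its own complex's ancestor
                single_shared = False
                rival_totals = []
                for ocx, oprof in sharers:
                    opattern = self.variant_pattern(ocx, oprof, hvr)
                    shared = len(opattern & pattern)
                    if shared == 0:
                        continue
                    if shared == 1:
                        single_shared = True
                        continue
                    obase = ocx.parent[oprof]
                    rival_totals.append(
                        sum(
                            count_aa_changes(
                                self.peptide(hvr, obase[hvr]),
                                self.peptide(hvr, oprof[hvr]),
                            )
                        )
                    )
                if rival_totals:
                    if total >= max(rival_totals):
                        cls, ev = "recombinant", "shared-pattern"
                    else:
                        cls, ev = "mutant", "shared-pattern"
                elif single_shared:
                    cls, ev = "mutant", "convergent-single-sub"
                else:
                    cls, ev = "mutant", "shared-pattern"
        return ShvEvent(
            complex_id=cx.complex_id,
            profile=variant,
            parent_profile=parent,
            hvr_index=hvr + 1,
            n_subs=n_subs,
            n_indel_cols=n_ind,
            classification=cls,
            evidence=ev,
        )


def classify_events(
    clusters: ClusterResult,
    alleles_by_id: Mapping[int, Allele],
    profiles: Mapping[int, WspProfile],
    registry: PeptideRegistry,
    schema: SectionSchema,
    isolates_by_allele: Mapping[int, int] | None = None,
    major_threshold: int = MAJOR_THRESHOLD_DEFAULT,
    tolerance: int = 0,
) -> list[ShvEvent]:
    """Classify every founder->SHV divergence in every complex.

    Complexes of exactly two profiles reduce to a direct pairwise comparison
    under the same rules.  Raises ``KeyError`` listing the allele id when a
    needed nucleotide sequence is missing.
    """
    ctx = _EventContext(
        clusters, alleles_by_id, profiles, registry, schema, isolates_by_allele, tolerance
    )
    events = []
    for cx in clusters.complexes:
        for p in cx.members:
            if cx.depth[p] == 1:
                events.append(ctx.classify_pair(cx, cx.founder, p, major_threshold))
    return events


def classify_subgroup_events(
    clusters: ClusterResult,
    alleles_by_id: Mapping[int, Allele],
    profiles: Mapping[int, WspProfile],
    registry: PeptideRegistry,
    schema: SectionSchema,
    isolates_by_allele: Mapping[int, int] | None = None,
    major_threshold: int = MAJOR_THRESHOLD_DEFAULT,
    tolerance: int = 0,
) -> list[ShvEvent]:
    """Classify DHVs (and deeper members) against their immediate predecessor."""
    ctx = _EventContext(
        clusters, alleles_by_id, profiles, registry, schema, isolates_by_allele, tolerance
    )
    events = []
    for cx in clusters.complexes:
        for p in cx.members:
            if cx.depth[p] >= 2:
                events.append(ctx.classify_pair(cx, cx.parent[p], p, major_threshold))
    return events


def summarize_contributions(events: Sequence[ShvEvent]) -> ContributionSummary:
    """Per-HVR and overall mutation/recombination contributions.

    Haplotype axis: event counts by class.  Amino-acid axis: summed
    substitution + indel columns by class.  Percentages on each axis sum to
    100 up to rounding.
    """
    if not events:
        raise ValueError("no events to summarize")
    rows = {}
    labels = [f"HVR{i}" for i in range(1, 5)] + ["overall"]
    for label in labels:
        sel = [
            e for e in events if label == "overall" or e.hvr_index == int(label[-1])
        ]
        mut = [e for e in sel if e.classification == "mutant"]
        rec = [e for e in sel if e.classification == "recombinant"]
        n_events = len(sel)
        n_changes = sum(e.n_changes for e in sel)
        rows[label] = {
            "mutant_events": len(mut),
            "recombinant_events": len(rec),
            "mutant_changes": sum(e.n_changes for e in mut),
            "recombinant_changes": sum(e.n_changes for e in rec),
            "pct_events_mutant": 100.0 * len(mut) / n_events if n_events else float("nan"),
            "pct_events_recombinant": 100.0 * len(rec) / n_events if n_events else float("nan"),
            "pct_changes_mutant": 100.0 * sum(e.n_changes for e in mut) / n_changes
            if n_changes
            else float("nan"),
            "pct_changes_recombinant": 100.0 * sum(e.n_changes for e in rec) / n_changes
            if n_changes
            else float("nan"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "section"
    return ContributionSummary(table=table)


def events_to_frame(events: Sequence[ShvEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "complex_id": e.complex_id,
                "profile": str(e.profile),
                "parent_profile": str(e.parent_profile),
                "hvr": e.hvr_index,
                "n_subs": e.n_subs,
                "n_indels": e.n_indel_cols,
                "class": e.classification,
                "evidence": e.evidence,
            }
            for e in events
        ],
        columns=[
            "complex_id",
            "profile",
            "parent_profile",
            "hvr",
            "n_subs",
            "n_indels",
            "class",
            "evidence",
        ],
    )
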