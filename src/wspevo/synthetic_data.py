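"""Forward generator for WSP-like gene populations with planted ground truth.

The generative model mirrors the inferred microevolution of the gene: a
single-copy fragment of an outer-membrane-protein gene with four
hypervariable regions (HVRs) interleaved with short conserved regions (CRs),
AT-biased third codon positions, founder haplotypes radiating into complexes
through point mutations confined to one HVR (1-3 amino-acid changes),
recombination events that replace a whole HVR peptide with a divergent donor
(>= 4 changes, indels permitted), and synonymous-only variants.  Isolates are
assigned to a balanced host taxonomy with a configurable within-genus
strain affinity.  Every emitted allele carries a machine-readable truth
record (parent, event type, affected HVR, section boundaries), so each
pipeline stage can be tested against planted ground truth without any
external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import count_changes
from .core import (
    AA_ALPHABET,
    Allele,
    CODON_TO_AA,
    IsolateRecord,
    STOP_CODONS,
    WspProfile,
    translate_cds,
)
from .hvr_typing import PeptideRegistry, Section, SectionSchema
from .io_tables import (
    write_fasta,
    write_isolate_table,
    write_profile_table,
    _write_tsv,
)

_ANCHOR_LEN = 5
_COUNTRIES = (
    "USA", "Brazil", "France", "Japan", "Australia",
    "Kenya", "India", "Mexico", "Spain", "Panama",
)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated population.

    HVR section length ranges are the typing-section lengths (HVR core plus
    the two 6-aa CR flanks, except HVR4 which has only the left flank);
    defaults follow the observed per-HVR length ranges of the real protein.
    The GC3 target reflects the strong AT bias at synonymous third positions
    (about 83% AT).  The mutation:recombination event ratio defaults to 8:1.
    """

    seed: int
    n_founders: int = 55
    mean_events_per_founder: float = 4.5
    recombination_weight: float = 1.0 / 9.0  # P(recombination | nonsynonymous event)
    synonymous_rate: float = 0.15            # P(event is synonymous-only)
    syn_cr_weight: float = 0.7  # P(a synonymous change lands in SP/CR scaffold)
    mutant_subs_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # 1..3 aa changes
    recomb_min_changes: int = 4
    recomb_changes_range: tuple[int, int] = (4, 18)  # per-event target, uniform
    recomb_indel_prob: float = 0.35
    donor_reuse_prob: float = 0.15
    hvr_section_ranges: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (30, 38), 2: (44, 50), 3: (50, 52), 4: (26, 45)}
    )
    cr_length: int = 12
    sp_length: int = 20
    gc3_target: float = 0.17
    founder_parent_weight: float = 0.85
    min_shvs_for_subgroup: int = 3  # chains only once a complex has radiated
    syn_founder_weight: float = 0.65
    n_isolates: int = 480
    n_orders: int = 8
    n_families_per_order: int = 3
    n_genera_per_family: int = 4
    n_species_per_genus: int = 3
    genus_affinity: float = 0.8
    founder_isolate_boost: float = 0.6

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_founders < 1 or self.mean_events_per_founder < 0:
            raise ValueError("founder/event counts must be positive")
        if not (0 <= self.recombination_weight < 1):
            raise ValueError("recombination_weight must be in [0, 1)")
        if not (0 <= self.synonymous_rate < 1):
            raise ValueError("synonymous_rate must be in [0, 1)")
        if not (0 < self.gc3_target < 1):
            raise ValueError("gc3_target must be in (0, 1)")
        if abs(sum(self.mutant_subs_probs) - 1) > 1e-9:
            raise ValueError("mutant_subs_probs must sum to 1")
        flank = self.cr_length // 2
        for k, (lo, hi) in self.hvr_section_ranges.items():
            core_lo = lo - (2 * flank if k < 4 else flank)
            if core_lo < 4 or hi < lo:
                raise ValueError(
                    f"HVR{k} section range {lo}-{hi} leaves no room for a core"
                )
        if not (0 <= self.genus_affinity <= 1):
            raise ValueError("genus_affinity must be in [0, 1]")

    def core_range(self, k: int) -> tuple[int, int]:
        flank = self.cr_length // 2
        off = 2 * flank if k < 4 else flank
        lo, hi = self.hvr_section_ranges[k]
        return lo - off, hi - off


def alignable_params(seed: int, **overrides) -> SimParams:
    """Conditions with fixed HVR1-3 lengths so the typed region (minus HVR4)
    concatenates into a gap-free alignment — used for distance-based analyses."""
    ranges = {1: (34, 34), 2: (47, 47), 3: (51, 51), 4: (26, 45)}
    return SimParams(seed=seed, hvr_section_ranges=ranges, **overrides)


# ---------------------------------------------------------------------------
# Truth log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthEvent:
    allele_id: int
    parent_allele: int  # 0 for founders
    event_type: str     # founder | point-mutation | recombination | synonymous
    hvr: int            # 1-4, or 0 when not applicable
    n_changes: int
    complex_id: int     # planted complex (founder lineage), 1-based
    donor_index: int    # donor-pool index for recombination, else -1


@dataclass
class TruthLog:
    events: list[TruthEvent]
    boundaries: dict[int, dict[str, tuple[int, int]]]  # typing sections per allele
    founder_allele: dict[int, int]  # complex -> founder allele id
    params: SimParams

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.events])

    def boundaries_frame(self) -> pd.DataFrame:
        rows = [
            {"allele_id": aid, "section": name, "start": s, "end": e}
            for aid, spans in sorted(self.boundaries.items())
            for name, (s, e) in spans.items()
        ]
        return pd.DataFrame(rows, columns=["allele_id", "section", "start", "end"])

    def event_type_of(self) -> dict[int, str]:
        return {e.allele_id: e.event_type for e in self.events}

    def parent_of(self) -> dict[int, int]:
        return {e.allele_id: e.parent_allele for e in self.events}


# ---------------------------------------------------------------------------
# Codon machinery
# ---------------------------------------------------------------------------

def _codon_weights(gc3_target: float) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-amino-acid codon distribution hitting the GC3 target exactly
    whenever the synonymous codon set offers both AT- and GC-ending codons."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(CODON_TO_AA.items()):
        by_aa.setdefault(aa, []).append(codon)
    weights = {}
    for aa, codons in by_aa.items():
        gc = [c for c in codons if c[2] in "GC"]
        at = [c for c in codons if c[2] in "AT"]
        if gc and at:
            probs = [
                gc3_target / len(gc) if c in gc else (1 - gc3_target) / len(at)
                for c in codons
            ]
        else:
            probs = [1 / len(codons)] * len(codons)
        weights[aa] = (codons, np.array(probs))
    return weights


class _CodonMachine:
    def __init__(self, gc3_target: float, rng: np.random.Generator) -> None:
        self.weights = _codon_weights(gc3_target)
        self.rng = rng

    def backtranslate(self, aa_seq: str) -> str:
        out = []
        for aa in aa_seq:
            codons, probs = self.weights[aa]
            out.append(codons[self.rng.choice(len(codons), p=probs)])
        return "".join(out)

    def backtranslate_balanced(self, aa_seq: str, gc3_target: float) -> str:
        """Backtranslate, then flip synonymous third positions until the
        realized GC3 over eligible codons matches the target count.

        Used for sequence shared verbatim across the whole population (the
        conserved scaffold), where one high-variance draw would otherwise
        dominate the population-wide composition.
        """
        codons = [self.backtranslate(aa) for aa in aa_seq]
        def eligible(c: str) -> bool:
            aa = CODON_TO_AA[c]
            return any(
                CODON_TO_AA.get(c[:2] + b) == aa for b in "ACGT" if b != c[2]
            )
        idx = [i for i, c in enumerate(codons) if eligible(c)]
        target = round(gc3_target * len(idx))
        while True:
            gc_now = sum(codons[i][2] in "GC" for i in idx)
            if gc_now == target:
                break
            want_gc = gc_now < target
            flippable = [
                i for i in idx
                if (codons[i][2] in "AT") == want_gc and any(
                    CODON_TO_AA.get(codons[i][:2] + b) == CODON_TO_AA[codons[i]]
                    and (b in "GC") == want_gc
                    for b in "ACGT"
                )
            ]
            i = flippable[int(self.rng.integers(len(flippable)))]
            alts = [
                codons[i][:2] + b
                for b in "ACGT"
                if CODON_TO_AA.get(codons[i][:2] + b) == CODON_TO_AA[codons[i]]
                and (b in "GC") == want_gc
            ]
            codons[i] = alts[int(self.rng.integers(len(alts)))]
        return "".join(codons)

    def synonymous_third(self, codon: str) -> str | None:
        """A synonymous replacement differing only at the third position."""
        aa = CODON_TO_AA[codon]
        alts = [
            c for c in self.weights[aa][0] if c[:2] == codon[:2] and c != codon
        ]
        if not alts:
            return None
        codons, probs = self.weights[aa]
        idx = [codons.index(c) for c in alts]
        p = probs[idx] / probs[idx].sum()
        return alts[self.rng.choice(len(alts), p=p)]

    def nonsynonymous_change(self, codon: str) -> str:
        """A single-base change producing a different, non-stop amino acid."""
        candidates = []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in STOP_CODONS and CODON_TO_AA[alt] != CODON_TO_AA[codon]:
                    candidates.append(alt)
        return candidates[self.rng.choice(len(candidates))]


# ---------------------------------------------------------------------------
# Population container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPopulation:
    alleles: list[Allele]
    profiles: dict[int, WspProfile]
    peptides: PeptideRegistry
    isolates: list[IsolateRecord]
    typing_schema: SectionSchema
    selection_schema: SectionSchema
    truth: TruthLog

    def alleles_by_id(self) -> dict[int, Allele]:
        return {a.allele_id: a for a in self.alleles}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "alleles.fasta",
            "profiles": outdir / "profiles.tsv",
            "isolates": outdir / "isolates.tsv",
            "typing_schema": outdir / "typing_schema.tsv",
            "selection_schema": outdir / "selection_schema.tsv",
            "peptides": outdir / "peptides.tsv",
            "truth_events": outdir / "truth_events.tsv",
            "truth_boundaries": outdir / "truth_boundaries.tsv",
            "params": outdir / "params.json",
        }
        write_fasta(paths["fasta"], [(f"wsp-{a.allele_id}", a.nt_seq) for a in self.alleles])
        write_profile_table(paths["profiles"], self.profiles)
        write_isolate_table(paths["isolates"], self.isolates)
        self.typing_schema.to_tsv(paths["typing_schema"])
        self.selection_schema.to_tsv(paths["selection_schema"])
        self.peptides.to_tsv(paths["peptides"])
        _write_tsv(self.truth.events_frame(), paths["truth_events"])
        _write_tsv(self.truth.boundaries_frame(), paths["truth_boundaries"])
        params = asdict(self.truth.params)
        params["hvr_section_ranges"] = {
            str(k): list(v) for k, v in params["hvr_section_ranges"].items()
        }
        paths["params"].write_text(json.dumps(params, indent=2, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

# Parts layout: [SP, CR1, core1, CR2, core2, CR3, core3, CR4, core4] (nt)
_CR_PART = {1: 1, 2: 3, 3: 5, 4: 7}
_CORE_PART = {1: 2, 2: 4, 3: 6, 4: 8}


class _Builder:
    def __init__(self, params: SimParams) -> None:
        params.validate()
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.codons = _CodonMachine(params.gc3_target, self.rng)
        self._make_scaffold()
        self._make_donor_pools()
        self.parts_by_allele: dict[int, list[str]] = {}
        self.truth_events: list[TruthEvent] = []
        self.founder_allele: dict[int, int] = {}
        self.complex_alleles: dict[int, list[int]] = {}
        self.seen_nt: set[str] = set()
        self.seen_cores: dict[int, set[str]] = {k: set() for k in range(1, 5)}
        self.next_id = 1

    # -- scaffold ---------------------------------------------------------

    def _random_aa(self, length: int) -> str:
        idx = self.rng.choice(len(AA_ALPHABET), size=length)
        return "".join(AA_ALPHABET[i] for i in idx)

    def _make_scaffold(self) -> None:
        for _ in range(200):
            sp = self._random_aa(self.p.sp_length)
            crs = [self._random_aa(self.p.cr_length) for _ in range(4)]
            motifs = self._anchor_motifs(crs)
            template = "|".join([sp] + crs)
            if len(set(motifs)) == len(motifs) and all(
                template.count(m) == 1 for m in motifs
            ):
                self.sp_aa, self.cr_aa = sp, crs
                scaffold_nt = self.codons.backtranslate_balanced(
                    sp + "".join(crs), self.p.gc3_target
                )
                self.sp_nt = scaffold_nt[: 3 * len(sp)]
                self.cr_nt = []
                off = 3 * len(sp)
                for c in crs:
                    self.cr_nt.append(scaffold_nt[off : off + 3 * len(c)])
                    off += 3 * len(c)
                self.motifs = motifs
                return
        raise RuntimeError("could not build an anchor-safe conserved scaffold")

    @staticmethod
    def _anchor_motifs(crs: Sequence[str]) -> list[str]:
        out = []
        for cr in crs:
            out.append(cr[6 : 6 + _ANCHOR_LEN])       # typing anchor (mid-CR)
            out.append(cr[:_ANCHOR_LEN])              # selection: CR start
            out.append(cr[-_ANCHOR_LEN:])             # selection: CR end
        return out

    def typing_schema(self) -> SectionSchema:
        return SectionSchema(
            tuple(
                Section(f"HVR{k}", "anchor_start", self.cr_aa[k - 1][6 : 6 + _ANCHOR_LEN])
                for k in range(1, 5)
            )
        )

    def selection_schema(self) -> SectionSchema:
        sections = []
        for k in range(1, 5):
            sections.append(
                Section(f"hvr{k}", "anchor_after", self.cr_aa[k - 1][-_ANCHOR_LEN:])
            )
            if k < 4:
                sections.append(
                    Section(f"CR{k + 1}", "anchor_start", self.cr_aa[k][:_ANCHOR_LEN])
                )
        return SectionSchema(tuple(sections))

    # -- donor pools ------------------------------------------------------

    def _make_donor_pools(self) -> None:
        # Pools grow as recombination events mint donors; reuse of a pool
        # entry plants the cross-complex HVR sharing seen in real data.
        self.donor_pools: dict[int, list[tuple[str, str]]] = {k: [] for k in range(1, 5)}

    def _mint_donor(self, parent_core: str, k: int) -> tuple[str, int]:
        """A donor peptide at a drawn distance (subs + optional indel) from
        the acceptor's current core, kept within the HVR length range."""
        lo, hi = self.p.core_range(k)
        m_lo, m_hi = self.p.recomb_changes_range
        m = int(self.rng.integers(m_lo, m_hi + 1))
        core = parent_core
        d = 0
        if self.rng.random() < self.p.recomb_indel_prob:
            deltas = [
                x for x in range(-3, 4)
                if x != 0 and lo <= len(core) + x <= hi and abs(x) < m
            ]
            if deltas:
                delta = deltas[int(self.rng.integers(len(deltas)))]
                d = abs(delta)
                if delta > 0:
                    for _ in range(delta):
                        pos = int(self.rng.integers(len(core) + 1))
                        core = core[:pos] + self._random_aa(1) + core[pos:]
                else:
                    pos = int(self.rng.integers(len(core) + delta + 1))
                    core = core[:pos] + core[pos - delta :]
        n_subs = max(1, m - d)
        positions = self.rng.choice(len(core), size=min(n_subs, len(core)), replace=False)
        out = list(core)
        for pos in positions:
            choices = [a for a in AA_ALPHABET if a != out[pos]]
            out[pos] = choices[int(self.rng.integers(len(choices)))]
        return "".join(out), m

    # -- allele assembly --------------------------------------------------

    def _aa_of(self, parts: Sequence[str]) -> str:
        return translate_cds("".join(parts))

    def _anchor_safe(self, aa_seq: str) -> bool:
        return all(aa_seq.count(m) == 1 for m in self.motifs)

    def _core_aa(self, parts: Sequence[str], k: int) -> str:
        return translate_cds(parts[_CORE_PART[k]]) if parts[_CORE_PART[k]] else ""

    def _profile_key(self, parts: Sequence[str]) -> tuple[str, str, str, str]:
        return tuple(self._core_aa(parts, k) for k in range(1, 5))

    def _admit(self, parts: list[str], event: TruthEvent) -> int:
        nt = "".join(parts)
        if nt in self.seen_nt:
            raise RuntimeError("duplicate nucleotide sequence generated")
        self.seen_nt.add(nt)
        aid = self.next_id
        self.next_id += 1
        self.parts_by_allele[aid] = parts
        for k in range(1, 5):
            self.seen_cores[k].add(self._core_aa(parts, k))
        self.truth_events.append(
            TruthEvent(
                allele_id=aid,
                parent_allele=event.parent_allele,
                event_type=event.event_type,
                hvr=event.hvr,
                n_changes=event.n_changes,
                complex_id=event.complex_id,
                donor_index=event.donor_index,
            )
        )
        self.complex_alleles.setdefault(event.complex_id, []).append(aid)
        return aid

    # -- founders ---------------------------------------------------------

    def _new_founder(self, complex_id: int) -> int:
        for _ in range(100):
            parts = [self.sp_nt]
            for k in range(1, 5):
                lo, hi = self.p.core_range(k)
                core_aa = self._random_aa(int(self.rng.integers(lo, hi + 1)))
                parts.extend([self.cr_nt[k - 1], self.codons.backtranslate(core_aa)])
            aa = self._aa_of(parts)
            key = self._profile_key(parts)
            if self._anchor_safe(aa) and all(
                key[k - 1] not in self.seen_cores[k] for k in range(1, 5)
            ):
                aid = self._admit(
                    parts,
                    TruthEvent(0, 0, "founder", 0, 0, complex_id, -1),
                )
                self.founder_allele[complex_id] = aid
                return aid
        raise RuntimeError("could not place an anchor-safe founder")

    # -- events -----------------------------------------------------------

    def _mutate(self, parent_parts: list[str], complex_id: int, parent_id: int,
                member_keys: set[tuple], k: int | None = None) -> int | None:
        if k is None:
            k = int(self.rng.integers(1, 5))
        n_subs = 1 + int(
            self.rng.choice(len(self.p.mutant_subs_probs), p=self.p.mutant_subs_probs)
        )
        core_nt = parent_parts[_CORE_PART[k]]
        n_codons = len(core_nt) // 3
        n_subs = min(n_subs, n_codons)
        for _ in range(60):
            idx = self.rng.choice(n_codons, size=n_subs, replace=False)
            new = list(core_nt[i : i + 3] for i in range(0, len(core_nt), 3))
            for i in idx:
                new[i] = self.codons.nonsynonymous_change(new[i])
            child = list(parent_parts)
            child[_CORE_PART[k]] = "".join(new)
            key = self._profile_key(child)
            if key in member_keys or key[k - 1] in self.seen_cores[k]:
                continue
            if not self._anchor_safe(self._aa_of(child)):
                continue
            return self._admit(
                child,
                TruthEvent(0, parent_id, "point-mutation", k, n_subs, complex_id, -1),
            )
        return None

    def _recombine(self, parent_parts: list[str], complex_id: int, parent_id: int,
                   member_keys: set[tuple], k: int | None = None) -> int | None:
        if k is None:
            k = int(self.rng.integers(1, 5))
        parent_core = self._core_aa(parent_parts, k)
        pool = self.donor_pools[k]
        for _ in range(60):
            if pool and self.rng.random() < self.p.donor_reuse_prob:
                di = int(self.rng.integers(len(pool)))
                donor_aa, donor_nt = pool[di]
                minted = False
            else:
                donor_aa, _ = self._mint_donor(parent_core, k)
                donor_nt = self.codons.backtranslate(donor_aa)
                di = len(pool)
                minted = True
            n_changes = sum(count_changes(parent_core, donor_aa))
            if n_changes < self.p.recomb_min_changes:
                continue
            child = list(parent_parts)
            child[_CORE_PART[k]] = donor_nt
            key = self._profile_key(child)
            if key in member_keys:
                continue
            if not self._anchor_safe(self._aa_of(child)):
                continue
            if minted:
                pool.append((donor_aa, donor_nt))
            return self._admit(
                child,
                TruthEvent(0, parent_id, "recombination", k, n_changes, complex_id, di),
            )
        return None

    def _synonymize(self, parent_parts: list[str], complex_id: int, parent_id: int) -> int | None:
        nt = "".join(parent_parts)
        # synonymous drift is biased toward the conserved scaffold: shared
        # hypervariable motifs are recent and carry little synonymous
        # divergence relative to the CRs
        offsets = np.cumsum([0] + [len(p) for p in parent_parts])
        scaffold_parts = {0, 1, 3, 5, 7}
        pools: dict[str, list[int]] = {"scaffold": [], "core": []}
        for pi, part in enumerate(parent_parts):
            region = "scaffold" if pi in scaffold_parts else "core"
            for i in range(int(offsets[pi]), int(offsets[pi + 1]), 3):
                if self.codons.synonymous_third(nt[i : i + 3]) is not None:
                    pools[region].append(i)
        n = int(self.rng.integers(1, 3))
        for _ in range(60):
            seq = list(nt)
            picked: set[int] = set()
            for _ in range(n):
                use_scaffold = self.rng.random() < self.p.syn_cr_weight
                pool = pools["scaffold"] if use_scaffold else pools["core"]
                pool = [i for i in pool if i not in picked] or [
                    i for i in pools["scaffold"] + pools["core"] if i not in picked
                ]
                if not pool:
                    break
                i = pool[int(self.rng.integers(len(pool)))]
                picked.add(i)
                new_codon = self.codons.synonymous_third(nt[i : i + 3])
                seq[i : i + 3] = list(new_codon)
            new_nt = "".join(seq)
            if new_nt in self.seen_nt:
                continue
            # re-split into parts along the original boundaries
            child, off = [], 0
            for part in parent_parts:
                child.append(new_nt[off : off + len(part)])
                off += len(part)
            return self._admit(
                child,
                TruthEvent(0, parent_id, "synonymous", 0, n, complex_id, -1),
            )
        return None

    def run_complex(self, complex_id: int, n_events: int) -> None:
        founder_id = self._new_founder(complex_id)
        shv_ids: list[int] = []
        for _ in range(n_events):
            u = self.rng.random()
            if u < self.p.synonymous_rate:
                pool = self.complex_alleles[complex_id]
                if self.rng.random() < self.p.syn_founder_weight:
                    parent_id = founder_id
                else:
                    parent_id = pool[int(self.rng.integers(len(pool)))]
                self._synonymize(self.parts_by_allele[parent_id], complex_id, parent_id)
                continue
            if (
                len(shv_ids) >= self.p.min_shvs_for_subgroup
                and self.rng.random() >= self.p.founder_parent_weight
            ):
                parent_id = shv_ids[int(self.rng.integers(len(shv_ids)))]
            else:
                parent_id = founder_id
            member_keys = {
                self._profile_key(self.parts_by_allele[a])
                for a in self.complex_alleles[complex_id]
            }
            parent_parts = self.parts_by_allele[parent_id]
            recomb = self.rng.random() < self.p.recombination_weight
            if recomb:
                child = self._recombine(parent_parts, complex_id, parent_id, member_keys)
            else:
                child = self._mutate(parent_parts, complex_id, parent_id, member_keys)
            if child is not None and parent_id == founder_id:
                shv_ids.append(child)

    # -- final assembly ---------------------------------------------------

    def boundaries(self, parts: Sequence[str]) -> dict[str, tuple[int, int]]:
        lengths = [len(p) // 3 for p in parts]
        pos = np.cumsum([0] + lengths)
        flank = self.p.cr_length // 2
        starts = {k: int(pos[_CR_PART[k]]) + flank for k in range(1, 5)}
        total = int(pos[-1])
        out = {}
        for k in range(1, 5):
            end = starts[k + 1] if k < 4 else total
            out[f"HVR{k}"] = (starts[k], end)
        return out

    def finalize(self) -> tuple[list[Allele], dict[int, WspProfile], PeptideRegistry, TruthLog]:
        alleles, profiles = [], {}
        registry = PeptideRegistry()
        boundaries = {}
        flank = self.p.cr_length // 2
        for aid in sorted(self.parts_by_allele):
            parts = self.parts_by_allele[aid]
            allele = Allele.from_nt(aid, "".join(parts))
            alleles.append(allele)
            ids = []
            for k in range(1, 5):
                left = self.cr_aa[k - 1][flank:]
                right = self.cr_aa[k][:flank] if k < 4 else ""
                peptide = left + self._core_aa(parts, k) + right
                ids.append(registry.assign(f"HVR{k}", peptide))
            profiles[aid] = WspProfile(*ids)
            boundaries[aid] = self.boundaries(parts)
        truth = TruthLog(
            events=self.truth_events,
            boundaries=boundaries,
            founder_allele=dict(self.founder_allele),
            params=self.p,
        )
        return alleles, profiles, registry, truth

    # -- hosts ------------------------------------------------------------

    def make_isolates(self, profiles: Mapping[int, WspProfile]) -> list[IsolateRecord]:
        p = self.p
        species = []
        for o in range(p.n_orders):
            for f in range(p.n_families_per_order):
                for g in range(p.n_genera_per_family):
                    genus = f"genus{o + 1:02d}{f + 1}{g + 1}"
                    for s in range(p.n_species_per_genus):
                        species.append(
                            (
                                f"order{o + 1:02d}",
                                f"family{o + 1:02d}{f + 1}",
                                genus,
                                f"{genus} sp{s + 1}",
                            )
                        )
        complex_ids = sorted(self.complex_alleles)
        genera = sorted({sp[2] for sp in species})
        # every lineage gets at least one primary host genus (round-robin over
        # a shuffled genus list), mirroring the observed founder/host pattern
        shuffled = [genera[i] for i in self.rng.permutation(len(genera))]
        home = {
            g: complex_ids[i % len(complex_ids)] for i, g in enumerate(shuffled)
        }
        all_alleles = sorted(self.parts_by_allele)
        records, seen = [], set()
        for i in range(p.n_isolates):
            for _ in range(80):
                order, family, genus, sp = species[int(self.rng.integers(len(species)))]
                if self.rng.random() < p.genus_affinity:
                    cid = home[genus]
                    members = self.complex_alleles[cid]
                    if self.rng.random() < p.founder_isolate_boost:
                        aid = self.founder_allele[cid]
                    else:
                        aid = members[int(self.rng.integers(len(members)))]
                else:
                    aid = all_alleles[int(self.rng.integers(len(all_alleles)))]
                country = _COUNTRIES[int(self.rng.integers(len(_COUNTRIES)))]
                key = (sp, aid, country)
                if key not in seen:
                    seen.add(key)
                    records.append(
                        IsolateRecord(
                            isolate_id=f"iso{i + 1:04d}",
                            allele_id=aid,
                            host_order=order,
                            host_family=family,
                            host_genus=genus,
                            host_species=sp,
                            country=country,
                        )
                    )
                    break
        return records


def generate_population(params: SimParams) -> SyntheticPopulation:
    """Generate a full population: alleles, profiles, isolates, truth log.

    Reproducible given the seed: identical params produce byte-identical
    output bundles.
    """
    builder = _Builder(params)
    for f in range(params.n_founders):
        n_events = int(builder.rng.poisson(params.mean_events_per_founder))
        builder.run_complex(f + 1, n_events)
    alleles, profiles, registry, truth = builder.finalize()
    isolates = builder.make_isolates(profiles)
    return SyntheticPopulation(
        alleles=alleles,
        profiles=profiles,
        peptides=registry,
        isolates=isolates,
        typing_schema=builder.typing_schema(),
        selection_schema=builder.selection_schema(),
        truth=truth,
    )


def generate_fixture_tables(seed: int = 7) -> SyntheticPopulation:
    """A <= 20-allele worked-example bundle with hand-checkable structure.

    Contains one star complex (founder + three 1-2-substitution mutant SHVs
    + one major recombinant SHV + one synonymous variant of the founder),
    one chain complex (founder -> SHV -> DHV, so one subgroup founder), and
    two singletons.
    """
    params = SimParams(
        seed=seed,
        n_founders=4,
        mean_events_per_founder=0.0,
        n_isolates=40,
        n_orders=2,
        n_families_per_order=2,
        n_genera_per_family=2,
        n_species_per_genus=3,
    )
    builder = _Builder(params)
    # complex 1: star with three mutants and one major recombinant
    builder._new_founder(1)
    f1 = builder.founder_allele[1]

    def keys(cid: int) -> set[tuple]:
        return {
            builder._profile_key(builder.parts_by_allele[a])
            for a in builder.complex_alleles[cid]
        }

    for _ in range(3):
        builder._mutate(builder.parts_by_allele[f1], 1, f1, keys(1))
    builder._recombine(builder.parts_by_allele[f1], 1, f1, keys(1))
    builder._synonymize(builder.parts_by_allele[f1], 1, f1)
    # complex 2: chain founder -> SHV (at HVR4) -> DHV (at HVR2)
    builder._new_founder(2)
    f2 = builder.founder_allele[2]
    shv = builder._mutate(builder.parts_by_allele[f2], 2, f2, keys(2), k=4)
    builder._mutate(builder.parts_by_allele[shv], 2, shv, keys(2), k=2)
    # singletons
    builder._new_founder(3)
    builder._new_founder(4)
    alleles, profiles, registry, truth = builder.finalize()
    isolates = builder.make_isolates(profiles)
    return SyntheticPopulation(
        alleles=alleles,
        profiles=profiles,
        peptides=registry,
        isolates=isolates,
        typing_schema=builder.typing_schema(),
        selection_schema=builder.selection_schema(),
        truth=truth,
    )
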