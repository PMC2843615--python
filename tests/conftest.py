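"""Shared fixtures: generated populations and a hand-built mini dataset."""

from __future__ import annotations

import pytest

from wspevo.core import CODON_TO_AA, Allele
from wspevo.hvr_typing import Section, SectionSchema, assign_profiles
from wspevo.synthetic_data import (
    SimParams,
    alignable_params,
    generate_fixture_tables,
    generate_population,
)

# One deterministic codon per amino acid (alphabetically first), so tests can
# build nucleotide sequences from peptides and then override single codons.
CODON_OF = {}
for codon in sorted(CODON_TO_AA):
    CODON_OF.setdefault(CODON_TO_AA[codon], codon)


def nt_of(aa_seq: str, overrides: dict[int, str] | None = None) -> str:
    codons = [CODON_OF[a] for a in aa_seq]
    for pos, codon in (overrides or {}).items():
        codons[pos] = codon
    return "".join(codons)


# Conserved regions for hand-built proteins; anchors are the middle 5-mers.
CRS = ["MDNHEIKWTRFY", "MQDGHVSELWPA", "MNRAFTEKDYVH", "MWTPSQHRGEIL"]


def typing_schema() -> SectionSchema:
    return SectionSchema(
        tuple(
            Section(f"HVR{k}", "anchor_start", CRS[k - 1][6:11]) for k in range(1, 5)
        )
    )


def build_protein(cores: tuple[str, str, str, str]) -> str:
    parts = []
    for k in range(4):
        parts.append(CRS[k])
        parts.append(cores[k])
    return "".join(parts)


def build_alleles(
    cores_by_id: dict[int, tuple[str, str, str, str]],
    codon_overrides: dict[int, dict[int, str]] | None = None,
) -> list[Allele]:
    """Alleles from per-id HVR cores, with optional per-residue codon overrides."""
    out = []
    for aid in sorted(cores_by_id):
        aa = build_protein(cores_by_id[aid])
        nt = nt_of(aa, (codon_overrides or {}).get(aid))
        out.append(Allele.from_nt(aid, nt))
    return out


@pytest.fixture(scope="session")
def default_pop():
    """The default study conditions (about 300 alleles, seed 1)."""
    return generate_population(SimParams(seed=1))


@pytest.fixture(scope="session")
def alignable_pop():
    """Fixed HVR1-3 lengths: the typed region (minus HVR4) aligns trivially."""
    return generate_population(alignable_params(seed=2, n_founders=20, n_isolates=180))


@pytest.fixture(scope="session")
def fixture_pop():
    """The <= 20-allele hand-checkable bundle."""
    return generate_fixture_tables(seed=7)


@pytest.fixture(scope="session")
def default_typed(default_pop):
    registry, profiles = assign_profiles(default_pop.alleles, default_pop.typing_schema)
    return registry, profiles
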