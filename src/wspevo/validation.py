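"""Validation harness for externally curated reference datasets.

The headline numbers of the real-data analysis derive from a fixed
515-allele dataset whose sequences live in the pubMLST *wsp* database and
whose profile/isolate tables are distributed as supplementary material, not
reproduced here.  When those tables (and optionally the allele FASTA) are
available locally, the functions below recompute the reference quantities
with the same pipeline used everywhere else in the package.

Expected file layout (all TSV/FASTA, see io_tables for column contracts)::

    data/wsp_profiles.tsv    # allele_id, hvr1..hvr4   (515 rows)
    data/wsp_isolates.tsv    # isolate metadata        (831 rows)
    data/wsp_alleles.fasta   # nucleotide alleles      (optional)
"""

from __future__ import annotations

from pathlib import Path

from .io_tables import read_isolate_table, read_profile_table
from .population_structure import dedupe_species_allele, host_range_summary
from .profile_clustering import find_complexes, profile_support


def profile_table_stats(path: str | Path) -> dict[str, int]:
    """Clustering summary of an allele -> profile table.

    Reports the counts a profile table fully determines: distinct proteins,
    complexes/singletons under SLV linkage, the two largest complex sizes,
    distinct HVR1 peptide ids, and proteins coded by >= 2 alleles.
    """
    profiles = read_profile_table(path)
    support = profile_support(profiles)
    distinct = set(profiles.values())
    result = find_complexes(
        distinct,
        support.allele_counts,
        support.isolate_counts,
        support.min_allele_id,
    )
    sizes = sorted((c.size for c in result.complexes), reverse=True)
    return {
        "n_alleles": len(profiles),
        "n_distinct_profiles": len(distinct),
        "n_complexes": len(result.complexes),
        "n_grouped_profiles": sum(sizes),
        "n_singletons": len(result.singletons),
        "largest_complex_sizes": sizes[:2],
        "n_hvr1_peptides": len({p.h1 for p in distinct}),
        "n_profiles_multiallele": sum(
            1 for c in support.allele_counts.values() if c >= 2
        ),
    }


def sequence_validation_stats(
    fasta_path: str | Path,
    profiles_path: str | Path,
    isolates_path: str | Path,
    schema_path: str | Path,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Sequence-dependent reference checks (needs the pubMLST alleles).

    Runs typing, clustering, event classification and the global
    host-association test on a locally supplied allele FASTA + tables +
    section schema, and reports the fraction of mutational SHVs, the
    amino-acid contribution split, and the observed within-genus mean
    distance.
    """
    from .hvr_typing import SectionSchema, assign_profiles
    from .io_tables import read_fasta, register_alleles
    from .population_structure import (
        aa_distance_matrix,
        genus_association_test,
        typed_alignment,
    )
    from .recomb_mut import classify_events, summarize_contributions

    registry = register_alleles([seq for _, seq in read_fasta(fasta_path)])
    schema = SectionSchema.from_tsv(schema_path)
    peptides, profiles = assign_profiles(registry.alleles(), schema)
    records = dedupe_species_allele(read_isolate_table(isolates_path))
    support = profile_support(profiles, records)
    clusters = find_complexes(
        set(profiles.values()),
        support.allele_counts,
        support.isolate_counts,
        support.min_allele_id,
    )
    events = classify_events(
        clusters,
        {a.allele_id: a for a in registry.alleles()},
        profiles,
        peptides,
        schema,
        support.isolates_by_allele,
    )
    summary = summarize_contributions(events)
    used = sorted({r.allele_id for r in records})
    ids, rows = typed_alignment([registry[i] for i in used], schema)
    dm = aa_distance_matrix(ids, rows)
    assoc = genus_association_test(dm, records, "global", n_perm=n_perm, seed=seed)
    return {
        "pct_shv_mutational": summary.pct_mutant_events,
        "pct_aa_mutation": summary.pct_aa_mutation,
        "pct_aa_recombination": summary.pct_aa_recombination,
        "within_genus_mean_distance": assoc.observed_mean,
        "p_global_mean": assoc.p_mean,
    }


def isolate_table_stats(path: str | Path, widespread_allele: int = 10) -> dict[str, object]:
    """Host-metadata summary: genus count, dedup size, host range of one allele."""
    records = read_isolate_table(path)
    deduped = dedupe_species_allele(records)
    return {
        "n_records": len(records),
        "n_host_genera": len({r.host_genus for r in records if r.host_genus}),
        "n_dedup_records": len(deduped),
        "host_range": host_range_summary(records, widespread_allele),
    }
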