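"""Mutant/recombinant event classification and contribution accounting."""

import pytest

from conftest import CRS, build_alleles, typing_schema
from wspevo.hvr_typing import assign_profiles
from wspevo.profile_clustering import find_complexes, profile_support
from wspevo.recomb_mut import (
    ShvEvent,
    classify_events,
    classify_subgroup_events,
    count_aa_changes,
    substitution_pattern,
    summarize_contributions,
)
from wspevo.core import WspProfile


class TestCountAaChanges:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AKT", "AKT", (0, 0)),
            ("AKT", "AQT", (1, 0)),
            # Needleman-Wunsch (match 1 / mismatch -1 / gap -1): three matches
            # plus two terminal gaps beats any substitution-heavy alignment
            ("AKTLL", "AKT", (0, 2)),
        ],
    )
    def test_examples(self, a, b, expected):
        assert count_aa_changes(a, b) == expected

    def test_symmetric(self):
        assert count_aa_changes("AKTLL", "AKT") == count_aa_changes("AKT", "AKTLL")

    def test_empty_peptide_is_error(self):
        with pytest.raises(ValueError):
            count_aa_changes("", "AKT")


class TestSubstitutionPattern:
    def test_identical_sections_empty_pattern(self):
        assert substitution_pattern("AAATTT", "AAATTT") == frozenset()

    def test_derived_states_polarized_on_ancestor(self):
        assert substitution_pattern("AAGTTT", "AAATTT") == frozenset({(2, "G")})


def _classify(alleles, isolates=None, major_threshold=4, schema=None):
    schema = schema or typing_schema()
    registry, profiles = assign_profiles(alleles, schema)
    support = profile_support(profiles, isolates or [])
    clusters = find_complexes(
        set(profiles.values()),
        support.allele_counts,
        support.isolate_counts,
        support.min_allele_id,
    )
    by_id = {a.allele_id: a for a in alleles}
    events = classify_events(
        clusters, by_id, profiles, registry, schema,
        support.isolates_by_allele, major_threshold,
    )
    sub = classify_subgroup_events(
        clusters, by_id, profiles, registry, schema,
        support.isolates_by_allele, major_threshold,
    )
    return clusters, profiles, events, sub


class TestClassifyEvents:
    def test_major_recombinant_at_threshold(self):
        # 5 substitutions at HVR2 vs the founder
        alleles = build_alleles(
            {1: ("AAAA", "CCCCDD", "EEFF", "GGHH"), 2: ("AAAA", "KKKKKD", "EEFF", "GGHH")}
        )
        _, _, events, _ = _classify(alleles)
        (event,) = events
        assert (event.classification, event.evidence) == ("recombinant", "major")
        assert event.n_subs == 5 and event.hvr_index == 2

    def test_unique_peptide_single_sub_is_mutant(self):
        alleles = build_alleles(
            {1: ("AAAA", "CCDD", "EEFF", "GGHH"), 2: ("AAAA", "CCDE", "EEFF", "GGHH")}
        )
        _, _, events, _ = _classify(alleles)
        (event,) = events
        assert (event.classification, event.evidence) == ("mutant", "unique-peptide")

    def test_every_shv_yields_exactly_one_event(self, default_pop, default_typed):
        registry, profiles = default_typed
        support = profile_support(profiles, default_pop.isolates)
        clusters = find_complexes(
            set(profiles.values()),
            support.allele_counts,
            support.isolate_counts,
            support.min_allele_id,
        )
        events = classify_events(
            clusters, default_pop.alleles_by_id(), profiles, registry,
            default_pop.typing_schema, support.isolates_by_allele,
        )
        n_shvs = sum(len(cx.shvs) for cx in clusters.complexes)
        assert len(events) == n_shvs
        sub = classify_subgroup_events(
            clusters, default_pop.alleles_by_id(), profiles, registry,
            default_pop.typing_schema, support.isolates_by_allele,
        )
        assert len(events) + len(sub) == sum(cx.size - 1 for cx in clusters.complexes)

    def test_raising_threshold_never_adds_major_recombinants(self, fixture_pop):
        pop = fixture_pop
        counts = []
        for threshold in (2, 4, 6, 20):
            _, _, events, _ = _classify(pop.alleles, pop.isolates, threshold, pop.typing_schema)
            counts.append(sum(e.evidence == "major" for e in events))
        assert counts == sorted(counts, reverse=True)

    def test_no_recombination_planted_means_no_major_calls(self):
        from wspevo.synthetic_data import SimParams, generate_population

        pop = generate_population(
            SimParams(seed=9, n_founders=25, recombination_weight=0.0)
        )
        _, _, events, sub = _classify(pop.alleles, pop.isolates, schema=pop.typing_schema)
        assert all(e.evidence != "major" for e in events + sub)


class TestSharedPatternRules:
    """Hand-enumerated application of the cross-complex pattern rules.

    Complex X: founder core2 GAZZ.., variant core2 CPZZ.. (2 aa changes,
    3 nt substitutions).  Complex Y: founder core2 GPZZ.., variant core2
    CPZZ.. with identical codons (1 aa change, 2 nt substitutions).  The two
    variants share the peptide and 2 derived substitutions, so the one with
    more amino-acid changes (X's) is the recombinant, the other the mutant.
    """

    def _population(self, y_codon_override=None):
        pad = "KLMN"
        cores = {
            1: ("AAAA", "G" + "A" + pad, "EEFF", "GGHH"),   # founder X
            2: ("AAAA", "C" + "P" + pad, "EEFF", "GGHH"),   # variant X = shared peptide
            3: ("WWWW", "G" + "P" + pad, "FFEE", "HHGG"),   # founder Y
            4: ("WWWW", "C" + "P" + pad, "FFEE", "HHGG"),   # variant Y = shared peptide
        }
        # CR1..CR4 are 12 aa; core2 starts at aa 12+4+12 = 28 in the protein.
        # Founders:  G = GGG (pos 28), A = GCA, P = CCA
        # Variants:  C = TGC (shared derived states T.. ..C), P = CCA
        overrides = {
            1: {28: "GGG", 29: "GCA"},
            2: {28: "TGC", 29: "CCA"},
            3: {28: "GGG", 29: "CCA"},
            4: {28: y_codon_override or "TGC", 29: "CCA"},
        }
        return build_alleles(cores, overrides)

    def test_rule_b_recombinant_goes_to_higher_change_count(self):
        alleles = self._population()
        _, profiles, events, _ = _classify(alleles, isolates=None)
        by_profile = {e.profile: e for e in events}
        ex = by_profile[profiles[2]]
        ey = by_profile[profiles[4]]
        assert ex.n_subs == 2 and ey.n_subs == 1
        assert (ex.classification, ex.evidence) == ("recombinant", "shared-pattern")
        assert (ey.classification, ey.evidence) == ("mutant", "shared-pattern")

    def test_single_shared_substitution_is_convergence(self):
        # same shared peptide but via a different codon path: TGT vs TGC both
        # code Cys; only the (pos, T) substitution is shared -> both mutants
        alleles = self._population(y_codon_override="TGT")
        _, profiles, events, _ = _classify(alleles)
        assert profiles[2].h2 == profiles[4].h2  # identical peptide either way
        classes = {(e.classification, e.evidence) for e in events}
        assert classes == {("mutant", "convergent-single-sub")}


class TestSubgroupEvents:
    def test_fixture_chain_dhv_is_mutant(self, fixture_pop):
        pop = fixture_pop
        _, profiles, events, sub = _classify(pop.alleles, pop.isolates, schema=pop.typing_schema)
        truth = {e.allele_id: e.event_type for e in pop.truth.events}
        planted_recombinant = {
            profiles[aid] for aid, t in truth.items() if t == "recombination"
        }
        planted_mutant = {
            profiles[aid] for aid, t in truth.items() if t == "point-mutation"
        }
        for e in events + sub:
            if e.profile in planted_recombinant:
                assert e.classification == "recombinant"
            elif e.profile in planted_mutant:
                assert e.classification == "mutant"


class TestSummarizeContributions:
    def test_all_mutant_events(self):
        events = [
            ShvEvent(1, WspProfile(1, 1, 1, i), WspProfile(1, 1, 1, 9), 4, 1, 0,
                     "mutant", "unique-peptide")
            for i in range(3)
        ]
        s = summarize_contributions(events)
        assert s.pct_mutant_events == 100.0
        assert s.pct_aa_mutation == 100.0
        assert s.pct_recombinant_events == 0.0

    def test_mixed_events_split_both_axes(self):
        rec = ShvEvent(1, WspProfile(1, 1, 1, 2), WspProfile(1, 1, 1, 9), 4, 8, 2,
                       "recombinant", "major")
        mut = ShvEvent(1, WspProfile(1, 1, 2, 9), WspProfile(1, 1, 1, 9), 3, 1, 0,
                       "mutant", "unique-peptide")
        s = summarize_contributions([rec, mut])
        assert s.pct_mutant_events == pytest.approx(50.0)
        assert s.pct_aa_recombination == pytest.approx(100 * 10 / 11)
        assert s.pct_aa_mutation == pytest.approx(100 / 11)

    def test_percentages_sum_to_100(self, default_pop, default_typed):
        registry, profiles = default_typed
        support = profile_support(profiles, default_pop.isolates)
        clusters = find_complexes(
            set(profiles.values()), support.allele_counts,
            support.isolate_counts, support.min_allele_id,
        )
        events = classify_events(
            clusters, default_pop.alleles_by_id(), profiles, registry,
            default_pop.typing_schema,
        )
        s = summarize_contributions(events)
        assert s.pct_mutant_events + s.pct_recombinant_events == pytest.approx(100)
        assert s.pct_aa_mutation + s.pct_aa_recombination == pytest.approx(100)
        overall = s.table.loc["overall"]
        per_hvr = s.table.drop("overall")
        assert per_hvr["mutant_events"].sum() == overall["mutant_events"]
        assert per_hvr["recombinant_changes"].sum() == overall["recombinant_changes"]

    def test_empty_event_list_is_error(self):
        with pytest.raises(ValueError):
            summarize_contributions([])
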