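"""Diversity, Nei-Gojobori dN/dS, Tajima's D, GC3, Wilcoxon tests, and the
section selection profile — each checked against an independent oracle."""

import itertools
import math

import numpy as np
import pytest

from wspevo.core import CODON_TO_AA, STOP_CODONS
from wspevo.popgen_stats import (
    dn_ds_pair,
    gc3,
    identity_clusters,
    nucleotide_diversity,
    section_selection_profile,
    synonymous_diversity,
    synonymous_variant_profile,
    tajimas_d,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# Independent Nei-Gojobori oracle: naive full enumeration, written without
# reference to the implementation.
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def oracle_diffs(c1, c2):
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(pos):
        cur, sd, nd, blocked = c1, 0, 0, False
        for i in order:
            step = cur[:i] + c2[i] + cur[i + 1:]
            if step in STOP_CODONS or cur in STOP_CODONS:
                blocked = True
                nd += 1
            elif CODON_TO_AA[step] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = step
        results.append((sd, nd, blocked))
    open_paths = [r for r in results if not r[2]] or results
    return (
        sum(r[0] for r in open_paths) / len(open_paths),
        sum(r[1] for r in open_paths) / len(open_paths),
    )


def oracle_dn_ds(a, b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = oracle_diffs(ca, cb)
        Sd += ds
        Nd += dn
    pS, pN = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(pN), jc(pS), pN, pS


def random_codon_seq(rng, n_codons):
    codons = [c for c in CODON_TO_AA if c not in STOP_CODONS]
    return "".join(rng.choice(codons) for _ in range(n_codons))


def mutate_seq(rng, seq, n_subs):
    seq = list(seq)
    for _ in range(n_subs):
        while True:
            i = int(rng.integers(len(seq)))
            b = "ACGT"[int(rng.integers(4))]
            codon_start = 3 * (i // 3)
            trial = seq.copy()
            trial[i] = b
            if "".join(trial[codon_start:codon_start + 3]) not in STOP_CODONS:
                seq = trial
                break
    return "".join(seq)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        assert nucleotide_diversity(["A" * 100, "A" * 100]).pi == 0.0

    def test_single_difference(self):
        a = "A" * 100
        b = "C" + "A" * 99
        assert nucleotide_diversity([a, b]).pi == pytest.approx(0.01)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(6)]
        expected = np.mean(
            [
                sum(x != y for x, y in zip(a, b)) / 60
                for a, b in itertools.combinations(seqs, 2)
            ]
        )
        assert nucleotide_diversity(seqs).pi == pytest.approx(expected)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["AAA", "AAAA"])


class TestDnDs:
    def test_identical_sequences(self):
        est = dn_ds_pair("GATGAT", "GATGAT")
        assert est.dN == 0 and est.dS == 0

    def test_asp_to_glu_is_nonsynonymous(self):
        # GAT (Asp) -> GAA (Glu): third-position change, still nonsynonymous
        est = dn_ds_pair("GAT", "GAA")
        assert est.pS == 0 and est.pN > 0

    def test_phe_codon_swap_is_synonymous(self):
        est = dn_ds_pair("TTT", "TTC")
        assert est.pN == 0 and est.pS > 0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = random_codon_seq(rng, 20)
        b = mutate_seq(rng, a, 6)
        x, y = dn_ds_pair(a, b), dn_ds_pair(b, a)
        assert x.pN == pytest.approx(y.pN) and x.pS == pytest.approx(y.pS)

    def test_matches_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            a = random_codon_seq(rng, 12)
            b = mutate_seq(rng, a, int(rng.integers(1, 8)))
            est = dn_ds_pair(a, b)
            dn, ds, pn, ps = oracle_dn_ds(a, b)
            assert est.pN == pytest.approx(pn, abs=1e-9)
            assert est.pS == pytest.approx(ps, abs=1e-9)
            if not est.undefined:
                assert est.dN == pytest.approx(dn, abs=1e-9)
                assert est.dS == pytest.approx(ds, abs=1e-9)

    def test_exclusively_synonymous_divergence_has_zero_dn(self):
        # Leu: CTT vs CTC vs CTA are all synonymous
        est = dn_ds_pair("CTTCTTCTT", "CTCCTACTT")
        assert est.pN == 0 and est.pS > 0


class TestSynonymousDiversity:
    def test_identical(self):
        assert synonymous_diversity(["TTTAAA", "TTTAAA"]) == 0.0

    def test_single_synonymous_codon_difference(self):
        # Phe TTT vs TTC: one synonymous difference over 1/3 synonymous site,
        # and no nonsynonymous divergence at all (Phe -> Phe)
        assert synonymous_diversity(["TTT", "TTC"]) == pytest.approx(3.0)
        assert dn_ds_pair("TTT", "TTC").pN == 0

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        seqs = [random_codon_seq(rng, 30)]
        for _ in range(4):
            seqs.append(mutate_seq(rng, seqs[0], 3))
        expected = np.mean(
            [oracle_dn_ds(a, b)[3] for a, b in itertools.combinations(seqs, 2)]
        )
        assert synonymous_diversity(seqs) == pytest.approx(expected, abs=1e-9)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        with pytest.raises(ValueError, match="segregating"):
            tajimas_d(["AAAA"] * 4)

    def test_requires_four_sequences(self):
        with pytest.raises(ValueError, match="4"):
            tajimas_d(["AAAA"] * 3)

    def test_singleton_only_polymorphism_is_negative(self):
        base = "A" * 50
        seqs = [base]
        for i in range(4):
            seqs.append(base[:i] + "C" + base[i + 1:])
        assert tajimas_d(seqs).D < 0

    def test_frequency_spectrum_null_has_mean_near_zero(self):
        # sites drawn from the neutral frequency spectrum P(i) ~ 1/i make
        # pi-hat and S/a1 estimate the same theta, so E[D] ~ 0
        rng = np.random.default_rng(4)
        n, S = 20, 30
        a1 = sum(1 / i for i in range(1, n))
        probs = np.array([1 / i for i in range(1, n)]) / a1
        values = []
        for _ in range(400):
            arr = np.full((n, S), "A")
            for s in range(S):
                count = 1 + int(rng.choice(n - 1, p=probs))
                carriers = rng.choice(n, size=count, replace=False)
                arr[carriers, s] = "C"
            values.append(tajimas_d(["".join(row) for row in arr]).D)
        assert abs(np.mean(values)) < 0.1


class TestGc3:
    def test_all_gly_codons(self):
        assert gc3(["GGGGGG"]) == 1.0

    def test_met_only_sequence_is_error(self):
        with pytest.raises(ValueError):
            gc3(["ATGATG"])

    def test_generator_hits_planted_target(self, default_pop):
        value = gc3([a.nt_seq for a in default_pop.alleles])
        assert value == pytest.approx(0.17, abs=0.02)


class TestWilcoxonSignedRank:
    def test_rank_sum_identity(self):
        rng = np.random.default_rng(5)
        pairs = [(float(x), float(y)) for x, y in rng.normal(size=(8, 2))]
        w_plus, w_minus, _ = wilcoxon_signed_rank(pairs)
        assert w_plus + w_minus == 36  # n(n+1)/2 for n=8

    def test_single_pair_p_is_one(self):
        assert wilcoxon_signed_rank([(1.0, 0.0)])[2] == 1.0

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([(1.0, 1.0)] * 5)

    def test_exact_p_matches_sign_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            diffs = rng.normal(size=8)
            pairs = [(float(d), 0.0) for d in diffs]
            w_plus, w_minus, p = wilcoxon_signed_rank(pairs)
            # brute force over all 2^8 sign assignments
            from scipy.stats import rankdata

            ranks = rankdata(np.abs(diffs))
            total = ranks.sum()
            observed_dev = abs(w_plus - total / 2)
            count = 0
            for signs in itertools.product([0, 1], repeat=8):
                w = sum(r for s, r in zip(signs, ranks) if s)
                if abs(w - total / 2) >= observed_dev - 1e-12:
                    count += 1
            assert p == pytest.approx(count / 256)

    def test_strongly_one_sided_example(self):
        # eight pairs, seven negative differences and one tiny positive one:
        # W+ = 1, W- = 35, exact two-sided p = 4/256
        pairs = [(0.1, 0.0)] + [(0.0, float(i)) for i in range(1, 8)]
        w_plus, w_minus, p = wilcoxon_signed_rank(pairs)
        assert (w_plus, w_minus) == (1.0, 35.0)
        assert p == pytest.approx(4 / 256)


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        u, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_complete_separation_minimal_u(self):
        u, p = wilcoxon_rank_sum([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert min(u, 25 - u) == 0

    def test_exact_p_matches_labeling_enumeration(self):
        rng = np.random.default_rng(7)
        a = list(rng.normal(size=6))
        b = list(rng.normal(loc=0.8, size=6))
        u, p = wilcoxon_rank_sum(a, b)
        from scipy.stats import rankdata

        pooled = np.array(a + b)
        ranks = rankdata(pooled)
        obs = sum(ranks[:6])
        count = total = 0
        for combo in itertools.combinations(range(12), 6):
            w = sum(ranks[i] for i in combo)
            mean = sum(ranks) / 2
            if abs(w - mean) >= abs(obs - mean) - 1e-12:
                count += 1
            total += 1
        assert p == pytest.approx(count / total)


class TestSectionSelectionProfile:
    def test_deduplicated_singleton_section_is_missing(self):
        profile = section_selection_profile({"CR2": ["AAATTT"] * 5})
        assert profile.section_means["CR2"] is None

    def test_nonsynonymous_only_cluster_contributes_one(self):
        # three equal-length variants differing only nonsynonymously
        seqs = ["GATGATGATGATGATGATGATGAT"]
        seqs.append("CAT" + seqs[0][3:])   # Asp -> His
        seqs.append("AAT" + seqs[0][3:])   # Asp -> Asn
        profile = section_selection_profile({"hvr1": seqs}, identity_threshold=0.9)
        assert profile.cluster_values["hvr1"] == [1.0]

    def test_cluster_membership_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(8)
        base = random_codon_seq(rng, 12)
        seqs = [mutate_seq(rng, base, int(rng.integers(0, 4))) for _ in range(30)]
        clusters = identity_clusters(seqs, 0.95)
        # brute force
        unique = sorted(set(seqs))
        adj = {s: set() for s in unique}
        for a, b in itertools.combinations(unique, 2):
            if len(a) == len(b) and sum(x == y for x, y in zip(a, b)) / len(a) >= 0.95:
                adj[a].add(b)
                adj[b].add(a)
        seen, expected = set(), []
        for s in unique:
            if s in seen:
                continue
            comp, stack = set(), [s]
            while stack:
                cur = stack.pop()
                if cur in comp:
                    continue
                comp.add(cur)
                stack.extend(adj[cur] - comp)
            seen |= comp
            expected.append(frozenset(comp))
        assert {frozenset(c) for c in clusters} == set(expected)

    def test_constructed_sections_force_cr_hvr_ordering(self):
        # CR variants drift only synonymously; hvr variants accumulate five
        # nonsynonymous changes per synonymous one, so per-site rates must
        # order the section means as CR < 1 < hvr
        rng = np.random.default_rng(9)

        def syn_mutate(seq, n):
            out = list(seq)
            done = 0
            while done < n:
                i = 3 * int(rng.integers(len(seq) // 3))
                codon = "".join(out[i:i + 3])
                alts = [
                    codon[:2] + b for b in "ACGT"
                    if b != codon[2]
                    and CODON_TO_AA.get(codon[:2] + b) == CODON_TO_AA.get(codon)
                ]
                if alts:
                    out[i:i + 3] = alts[int(rng.integers(len(alts)))]
                    done += 1
            return "".join(out)

        def nonsyn_mutate(seq, n):
            out = list(seq)
            done = 0
            while done < n:
                i = 3 * int(rng.integers(len(seq) // 3))
                codon = "".join(out[i:i + 3])
                alts = [
                    codon[:j] + b + codon[j + 1:]
                    for j in range(3)
                    for b in "ACGT"
                    if b != codon[j]
                    and codon[:j] + b + codon[j + 1:] not in STOP_CODONS
                    and CODON_TO_AA[codon[:j] + b + codon[j + 1:]] != CODON_TO_AA[codon]
                ]
                out[i:i + 3] = alts[int(rng.integers(len(alts)))]
                done += 1
            return "".join(out)

        cr_base = random_codon_seq(rng, 15)
        crs = [cr_base] + [syn_mutate(cr_base, 2) for _ in range(3)]
        hvr_base = random_codon_seq(rng, 15)
        hvrs = [hvr_base] + [
            syn_mutate(nonsyn_mutate(hvr_base, 5), 1) for _ in range(3)
        ]
        profile = section_selection_profile(
            {"CR2": crs, "hvr1": hvrs}, identity_threshold=0.8
        )
        assert profile.section_means["CR2"] < 1 < profile.section_means["hvr1"]

    def test_generator_cr_clusters_below_hvr_clusters(self, default_pop):
        from wspevo.hvr_typing import segment

        sections = {}
        for a in default_pop.alleles:
            spans = segment(a.aa_seq, default_pop.selection_schema)
            for name, span in spans.items():
                sections.setdefault(name, []).append(
                    a.nt_seq[3 * span.start: 3 * span.end]
                )
        profile = section_selection_profile(sections)
        cr_means = [
            v for k, v in profile.section_means.items()
            if k.startswith("CR") and v is not None
        ]
        hvr_means = [
            v for k, v in profile.section_means.items()
            if k.startswith("hvr") and v is not None
        ]
        assert cr_means and hvr_means
        # CRs drift only synonymously, hvrs are nonsynonymous-enriched
        assert max(cr_means) < min(hvr_means)
        # nonsynonymous-only hvr clusters take the conservative value 1
        assert any(
            1.0 in profile.cluster_values[k]
            for k in profile.cluster_values
            if k.startswith("hvr")
        )


class TestSynonymousVariantProfile:
    def test_single_allele_protein_undefined(self, fixture_pop):
        pop = fixture_pop
        table = synonymous_variant_profile(pop.alleles, pop.profiles)
        singles = table[table["n_allele_variants"] == 1]
        assert singles["pi_syn"].isna().all()

    def test_two_synonymous_alleles(self):
        from wspevo.core import Allele

        a = Allele.from_nt(1, "TTTAAAGGG")
        b = Allele.from_nt(2, "TTCAAAGGG")
        from wspevo.core import WspProfile

        profiles = {1: WspProfile(1, 1, 1, 1), 2: WspProfile(1, 1, 1, 1)}
        table = synonymous_variant_profile([a, b], profiles)
        row = table.iloc[0]
        assert row["n_allele_variants"] == 2
        assert row["pi_syn"] > 0
        assert row["all_polymorphisms_unique"]

    def test_star_radiation_unique_vs_reticulate(self):
        from wspevo.core import Allele, WspProfile

        base = "TTTAAAGGGCCC"
        star = [
            Allele.from_nt(1, base),
            Allele.from_nt(2, "TTC" + base[3:]),
            Allele.from_nt(3, base[:3] + "AAG" + base[6:]),
        ]
        profiles = {i: WspProfile(1, 1, 1, 1) for i in (1, 2, 3)}
        table = synonymous_variant_profile(star, profiles)
        assert table.iloc[0]["all_polymorphisms_unique"]
        # reticulate: the same derived state appears in two of four alleles
        ret = [
            Allele.from_nt(1, base),
            Allele.from_nt(2, "TTC" + base[3:]),
            Allele.from_nt(3, "TTC" + base[3:6] + "GGA" + base[9:]),
            Allele.from_nt(4, base[:9] + "CCG"),
        ]
        profiles = {i: WspProfile(1, 1, 1, 1) for i in (1, 2, 3, 4)}
        table = synonymous_variant_profile(ret, profiles)
        assert not table.iloc[0]["all_polymorphisms_unique"]
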