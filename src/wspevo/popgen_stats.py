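"""Population-genetic and selection statistics.

Implements average pairwise nucleotide diversity (pi), Nei–Gojobori (1986)
synonymous/nonsynonymous counting with Jukes–Cantor correction, Tajima's D,
GC content at synonymously variable third codon positions, exact Wilcoxon
tests, a per-section selection profile built from 95%-identity single-linkage
clusters, and the synonymous-variant profile of protein haplotypes.

Nei–Gojobori conventions: each codon's synonymous sites are the summed
fraction of synonymous single-base changes (S), with N = 3 - S; pairwise
differences are averaged over all minimal mutational pathways with equal
weight, excluding pathways through stop codons (falling back to all pathways
when every pathway is blocked).  pS and pN use site counts averaged over the
two sequences; dX = -(3/4) ln(1 - 4 pX / 3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, log, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Allele, CODON_TO_AA, STOP_CODONS, VALID_NT, WspProfile

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityEstimate:
    pi: float
    pi_syn: float | None
    n_seqs: int
    n_sites: int


def _pairwise_p_distance(a: str, b: str, valid: frozenset[str] = VALID_NT) -> float:
    """Differences per compared site, with pairwise deletion of gap columns."""
    diffs = compared = 0
    for x, y in zip(a, b):
        if x in valid and y in valid:
            compared += 1
            diffs += x != y
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    return diffs / compared


def nucleotide_diversity(seqs: Sequence[str]) -> DiversityEstimate:
    """Average pairwise differences per site over all sequence pairs.

    Sequences must be aligned to equal length; columns where either member
    of a pair carries a gap or ambiguity are excluded for that pair.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    pairs = list(itertools.combinations(seqs, 2))
    pi = float(np.mean([_pairwise_p_distance(a, b) for a, b in pairs]))
    return DiversityEstimate(pi=pi, pi_syn=None, n_seqs=len(seqs), n_sites=lengths.pop())


# ---------------------------------------------------------------------------
# Nei–Gojobori machinery
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> float:
    """Synonymous sites of one codon (summed synonymous fraction per position)."""
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1 / 3
    return syn


def _step_is_synonymous(c1: str, c2: str) -> bool:
    return CODON_TO_AA[c1] == CODON_TO_AA[c2]


def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged with equal weight over all minimal mutational pathways; pathways
    through stop codons are excluded unless all are blocked.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        current = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                blocked = True
                nd += 1
            elif _step_is_synonymous(current, nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((sd, nd, blocked))
    usable = [p for p in paths if not p[2]] or paths
    sd = float(np.mean([p[0] for p in usable]))
    nd = float(np.mean([p[1] for p in usable]))
    return sd, nd


@dataclass(frozen=True)
class DnDsEstimate:
    dN: float | None
    dS: float | None
    ratio: float | None
    pN: float
    pS: float
    undefined: bool  # JC correction or the ratio itself is undefined


def _codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _jc(p: float) -> float | None:
    arg = 1 - 4 * p / 3
    return None if arg <= 0 else -0.75 * log(arg)


def _pair_counts(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """(S_avg, N_avg, Sd, Nd) over comparable codons of a pair."""
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in zip(_codons(seq_a), _codons(seq_b)):
        if set(ca) - VALID_NT or set(cb) - VALID_NT:
            continue  # pairwise deletion of gapped/ambiguous codons
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in frame-0 comparison: {ca}/{cb}")
        sa, sb = _codon_sites(ca), _codon_sites(cb)
        s_sites += (sa + sb) / 2
        n_sites += 3 - (sa + sb) / 2
        d_s, d_n = _codon_diffs(ca, cb)
        sd += d_s
        nd += d_n
    return s_sites, n_sites, sd, nd


def dn_ds_pair(seq_a: str, seq_b: str) -> DnDsEstimate:
    """Nei–Gojobori dN/dS for one codon-aligned sequence pair."""
    s_sites, n_sites, sd, nd = _pair_counts(seq_a, seq_b)
    if s_sites == 0 or n_sites == 0:
        raise ValueError("degenerate site counts (no synonymous or no nonsynonymous sites)")
    pS = sd / s_sites
    pN = nd / n_sites
    dS = _jc(pS)
    dN = _jc(pN)
    undefined = dS is None or dN is None or dS == 0
    ratio = None if undefined else dN / dS
    return DnDsEstimate(dN=dN, dS=dS, ratio=ratio, pN=pN, pS=pS, undefined=undefined)


def synonymous_diversity(seqs: Sequence[str], jukes_cantor: bool = False) -> float:
    """Average pairwise synonymous differences per synonymous site (pi-syn).

    Per-pair pS (optionally Jukes–Cantor corrected) averaged over all pairs.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    values = []
    for a, b in itertools.combinations(seqs, 2):
        s_sites, _, sd, _ = _pair_counts(a, b)
        if s_sites == 0:
            raise ValueError("pair with zero synonymous sites")
        p = sd / s_sites
        if jukes_cantor:
            corrected = _jc(p)
            if corrected is None:
                raise ValueError(f"pS = {p} out of range for Jukes-Cantor correction")
            p = corrected
        values.append(p)
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaResult:
    D: float
    S: int
    pi: float  # per-site
    n: int


def tajimas_d(seqs: Sequence[str]) -> TajimaResult:
    """Tajima (1989) D over complete (gap-free, unambiguous) columns.

    Requires n >= 4 sequences; undefined (error) when there are no
    segregating sites.
    """
    n = len(seqs)
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(s) for s in seqs])
    complete = np.all(np.isin(arr, list(VALID_NT)), axis=0)
    arr = arr[:, complete]
    if arr.shape[1] == 0:
        raise ValueError("no complete columns")
    segregating = np.array([len(set(col)) > 1 for col in arr.T])
    S = int(segregating.sum())
    if S == 0:
        raise ValueError("no segregating sites: Tajima's D undefined")
    k_hat = float(
        np.mean([
            np.sum(arr[i] != arr[j])
            for i, j in itertools.combinations(range(n), 2)
        ])
    )
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (k_hat - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaResult(D=D, S=S, pi=k_hat / arr.shape[1], n=n)


# ---------------------------------------------------------------------------
# GC3
# ---------------------------------------------------------------------------

def gc3(seqs: Sequence[str]) -> float:
    """G+C fraction at synonymously variable third codon positions.

    Codons whose third position admits no synonymous change (Met, Trp) are
    excluded; an input with no eligible positions is an error.
    """
    gc = total = 0
    for seq in seqs:
        for codon in _codons(seq):
            if set(codon) - VALID_NT or codon in STOP_CODONS:
                continue
            aa = CODON_TO_AA[codon]
            synonymous_third = any(
                CODON_TO_AA.get(codon[:2] + b) == aa for b in _BASES if b != codon[2]
            )
            if synonymous_third:
                total += 1
                gc += codon[2] in "GC"
    if total == 0:
        raise ValueError("no synonymously variable third positions")
    return gc / total


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Exact two-sided Wilcoxon signed-rank test: (W+, W-, p).

    Zero differences are removed; |differences| are midranked.  For n <= 25
    the p-value enumerates the 2^n equally likely sign assignments (via a
    convolution over doubled midranks, which are integers); larger n uses the
    normal approximation with tie correction.
    """
    diffs = [x - y for x, y in pairs if x != y]
    n = len(diffs)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata([abs(d) for d in diffs])
    w_plus = float(sum(r for d, r in zip(diffs, ranks) if d > 0))
    w_minus = float(sum(r for d, r in zip(diffs, ranks) if d < 0))
    if n <= 25:
        doubled = [int(round(2 * r)) for r in ranks]
        counts: dict[int, int] = {0: 1}
        for r in doubled:
            nxt: dict[int, int] = {}
            for s, c in counts.items():
                nxt[s] = nxt.get(s, 0) + c
                nxt[s + r] = nxt.get(s + r, 0) + c
            counts = nxt
        total = 2**n
        center = sum(doubled) / 2
        observed_dev = abs(2 * w_plus - center)
        extreme = sum(
            c for s, c in counts.items() if abs(s - center) >= observed_dev - 1e-9
        )
        p = min(1.0, extreme / total)
    else:
        mean = n * (n + 1) / 4
        tie_term = sum(
            t**3 - t for t in np.unique(ranks, return_counts=True)[1]
        )
        var = n * (n + 1) * (2 * n + 1) / 24 - tie_term / 48
        z = (w_plus - mean) / sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
    return w_plus, w_minus, p


def wilcoxon_rank_sum(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test: (U, p).

    Exact for small tie-free samples, normal approximation with midrank tie
    correction otherwise (scipy's implementation).
    """
    if not len(sample_a) or not len(sample_b):
        raise ValueError("both samples must be nonempty")
    ties = len(set(sample_a) | set(sample_b)) < len(sample_a) + len(sample_b)
    method = "asymptotic" if ties or max(len(sample_a), len(sample_b)) > 12 else "exact"
    res = sps.mannwhitneyu(sample_a, sample_b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Section selection profile (95% identity single-linkage clusters)
# ---------------------------------------------------------------------------

@dataclass
class SectionSelectionProfile:
    """Per-section cluster dN/dS values and their mean (None when missing)."""

    cluster_values: dict[str, list[float]]
    section_means: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "section": name,
                "n_clusters": len(self.cluster_values.get(name, [])),
                "mean_dn_ds": self.section_means[name],
            }
            for name in self.section_means
        ]
        return pd.DataFrame(rows, columns=["section", "n_clusters", "mean_dn_ds"])


def identity_clusters(
    seqs: Sequence[str], identity_threshold: float = 0.95
) -> list[list[str]]:
    """Single-linkage clusters among equal-length sequences at >= threshold identity.

    Identity is matches / length on ungapped equal-length sequences; unequal
    lengths never cluster (the 100%-matching-length rule).
    """
    unique = sorted(set(seqs))
    parent = list(range(len(unique)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(unique)), 2):
        a, b = unique[i], unique[j]
        if len(a) != len(b):
            continue
        matches = sum(x == y for x, y in zip(a, b))
        if matches / len(a) >= identity_threshold:
            parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, seq in enumerate(unique):
        groups.setdefault(find(i), []).append(seq)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def _cluster_dn_ds(cluster: Sequence[str]) -> float:
    """Mean pairwise dN/dS; exclusively nonsynonymous divergence -> 1.0."""
    ratios = []
    for a, b in itertools.combinations(cluster, 2):
        est = dn_ds_pair(a, b)
        if not est.undefined:
            ratios.append(est.ratio)
    if not ratios:
        # sequences diverged only nonsynonymously: conservative estimate
        return 1.0
    return float(np.mean(ratios))


def section_selection_profile(
    sections: Mapping[str, Sequence[str]],
    identity_threshold: float = 0.95,
    min_cluster_size: int = 3,
) -> SectionSelectionProfile:
    """Selection profile over gene sections (hvr1, CR2, ..., hvr4).

    Within each section, nucleotide redundancy is discarded, sequences are
    clustered by single linkage at the identity threshold with exact length
    matching, and the mean dN/dS over clusters of >= min_cluster_size is
    reported.  A section with no qualifying cluster is reported as missing
    (None), never as zero.
    """
    cluster_values: dict[str, list[float]] = {}
    means: dict[str, float | None] = {}
    for name, seqs in sections.items():
        values = [
            _cluster_dn_ds(cluster)
            for cluster in identity_clusters(seqs, identity_threshold)
            if len(cluster) >= min_cluster_size
        ]
        cluster_values[name] = values
        means[name] = float(np.mean(values)) if values else None
    return SectionSelectionProfile(cluster_values=cluster_values, section_means=means)


# ---------------------------------------------------------------------------
# Synonymous allele variants per protein
# ---------------------------------------------------------------------------

def _all_polymorphisms_unique(seqs: Sequence[str]) -> bool:
    """True when every polymorphic column has its minor state in one sequence.

    This is the star-radiation (no-homoplasy) signature of recent
    independent divergence from a common ancestral allele.
    """
    arr = np.array([list(s) for s in seqs])
    for col in arr.T:
        states, counts = np.unique(col, return_counts=True)
        if len(states) == 1:
            continue
        if len(states) > 2 or counts.min() != 1:
            return False
    return True


def synonymous_variant_profile(
    alleles: Sequence[Allele], profiles: Mapping[int, WspProfile]
) -> pd.DataFrame:
    """Per-protein allele-variant counts, pi-syn, and uniqueness flags.

    Proteins with a single allele get an undefined (NaN) pi-syn; the
    uniqueness flag is only meaningful for proteins with >= 2 variants.
    """
    by_profile: dict[WspProfile, list[Allele]] = {}
    for a in sorted(alleles, key=lambda x: x.allele_id):
        by_profile.setdefault(profiles[a.allele_id], []).append(a)
    rows = []
    for profile in sorted(by_profile):
        group = by_profile[profile]
        n = len(group)
        if n >= 2:
            pi_syn = synonymous_diversity([a.nt_seq for a in group])
            unique = _all_polymorphisms_unique([a.nt_seq for a in group])
        else:
            pi_syn, unique = float("nan"), None
        rows.append(
            {
                "profile": str(profile),
                "n_allele_variants": n,
                "pi_syn": pi_syn,
                "all_polymorphisms_unique": unique,
            }
        )
    return pd.DataFrame(
        rows, columns=["profile", "n_allele_variants", "pi_syn", "all_polymorphisms_unique"]
    )
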