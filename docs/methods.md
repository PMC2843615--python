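# Methods

This note documents the models, conventions and numerical choices behind
`wspevo`, in the order the pipeline applies them, and states what the
synthetic study conditions do and do not demonstrate about real data.

## The typing system

A *wsp* allele is a unique in-frame nucleotide sequence of the typed
fragment; translation uses the standard genetic code in frame 0 with no
start-codon requirement (the fragment is internal), and any stop codon is a
hard error rather than masked.  Ambiguity codes are rejected at registration:
the analysis is defined on unambiguous alleles.  Allele numbers are assigned
first-seen; a registry loaded from TSV is authoritative and new sequences
extend from `max_id + 1`, so externally curated numbering survives.

Proteins are segmented by a `SectionSchema`: an ordered list of sections,
each located either by a short anchor motif (default, exact match) or by
fixed coordinates.  Anchors exploit the CRs' conservation (>90% identity, no
indels): a 5-residue motif inside a CR pins each section start without any
multiple alignment.  An anchor that is absent or matches more than once is an
error naming the anchor; with a Hamming tolerance > 0, two candidate matches
at equal distance are likewise an error, never a silent choice.  Two schema
variants exist because the typing sections and the selection sections differ:
typing HVR sections include ~6-residue flanks of both adjacent CRs, while the
selection analysis uses bare hvr cores plus whole CR sections.

Peptides are numbered first-seen per HVR class; a profile is the 4-tuple of
peptide ids.  Profile identity is protein-haplotype identity over the typed
region: synonymous alleles necessarily share a profile.

## Clustering and founders

A WSP complex is a connected component (size ≥ 2) of the graph joining
profiles at Hamming distance exactly 1 on the 4-tuple — eBURST's
single-locus-variant rule applied to a single 4-locus profile.  Neighbour
search hashes each profile under its four 3-of-4 locus keys, which yields
exactly the distance-1 pairs; tests verify equivalence with brute-force
union-find.  Components are sorted by decreasing size then founder profile
before numbering, so output is invariant under input permutation.

The founder is the member with the most SLVs.  Ties fall through
allele-variant count, isolate count, lowest representative allele id, and
finally lexicographic profile order, making prediction total and
deterministic.  This tie-break order encodes the auxiliary evidence that
founders are typically also the proteins with the most synonymous variants
and the widest isolate frequency.  Roles are assigned by BFS from the
founder (deterministic neighbour ordering): distance 1 = SHV, distance ≥ 2 =
DHV, and an SHV with DHV children is a subgroup founder.  Founder prediction
by SLV count is known to fail on chain-shaped complexes (the middle of a
3-chain has the most SLVs); nucleotide-level parsimony correction is out of
scope, and `representative_ancestral_allele` approximates it with isolate
frequency plus lowest-id tie-breaking among founder-profile alleles.

## Mutation versus recombination

For every founder→SHV step (and every predecessor→DHV step in the subgroup
expansion) the two peptides at the differing HVR are globally aligned with
fixed scoring — match +1, mismatch −1, gap −1, no end-gap bonus, ties in the
traceback preferring substitutions over gaps — and the change count is
substitution columns plus gap columns.  The aligner is written in-package
because the tie-break must be pinned for reproducibility; the peptides
involved are short and near-identical, so scoring choices barely matter but
determinism requires one.

Classification rules, applied per event:

1. **Major**: total changes ≥ 4 (configurable) → recombinant.  Within
   complexes indels essentially only enter through this route, since point
   mutations never change length.
2. **Shared peptide**: otherwise, if the variant's peptide occurs in another
   complex, nucleotide substitution patterns are compared.  A pattern is the
   set of (aligned position, derived state) differences of a member's
   section-coding nucleotides relative to its own complex's ancestral-allele
   section.  The *shared* substitutions of two members are the intersection
   of their patterns.  No shared substitutions → mutant.  Exactly one shared
   substitution → convergence, mutant.  Two or more shared substitutions →
   recombination, assigned to the profile with the greater amino-acid change
   count versus its own founder; both are recombinant on a tie.  The
   intersection (rather than set-equality) reading is required for the
   asymmetric case where one variant carries extra private changes.
3. **Unique peptide**: a peptide found nowhere else → mutant.

Peptide sharing is taken as identity of the peptide string (equal peptide id
in the same HVR class); "similar" peptides do not trigger rule 2.  Patterns
are polarized against each member's own predecessor, so a founder's own
peptide contributes an empty pattern and can never match.

Contributions are summarised on two axes: haplotype diversity (events by
class) and amino-acid diversity (summed changes by class), per HVR and
overall; percentages on each axis sum to 100.  Synonymous-only divergence is
deliberately ignored — the target is protein diversity.

## Population-genetic statistics

* **π** — mean pairwise differences per compared site, with pairwise
  deletion of gap/ambiguous columns (the DNAsp convention).
* **Nei–Gojobori (1986)** — synonymous sites per codon are the summed
  fraction of synonymous single-base changes, with nonsynonymous sites
  N = 3 − S; pairwise codon differences are averaged with equal weight over
  all minimal mutational pathways, excluding pathways through stop codons
  and falling back to all pathways when every one is blocked; pS = Sd/S̄ and
  pN = Nd/N̄ use site counts averaged over the pair;
  dX = −(3/4)·ln(1 − 4pX/3), flagged undefined when pX ≥ 3/4.  π-syn is the
  per-pair pS averaged over pairs, reported uncorrected by default with a
  Jukes–Cantor option (`jukes_cantor=True`), since reference
  implementations differ on this point.
* **Tajima's D** — the 1989 constants, computed over gap-free unambiguous
  columns, requiring n ≥ 4 and erroring (not returning 0) when no site
  segregates.  The null calibration in tests draws each site's derived-allele
  count from the neutral frequency spectrum P(i) ∝ 1/i, which makes π̂ and
  S/a₁ estimate the same θ by construction, so the mean of D is near 0
  without coalescent machinery.
* **GC3** — G+C fraction at third positions of codons whose third position
  admits a synonymous change (Met and Trp excluded).
* **Wilcoxon signed-rank** — exact two-sided p for n ≤ 25 by convolution
  over doubled midranks (integers, so the distribution of 2·W⁺ over the 2ⁿ
  sign assignments is computed exactly); W⁺ + W⁻ = n(n+1)/2 after
  zero-difference removal.  The rank-sum test delegates to
  `scipy.stats.mannwhitneyu` (exact for small tie-free samples).
* **Section selection profile** — per section, nucleotide redundancy is
  dropped, equal-length sequences are clustered by single linkage at ≥ 95%
  identity (unequal lengths never cluster: the 100%-matching-length rule),
  and each cluster of ≥ 3 sequences contributes its mean pairwise dN/dS;
  clusters whose members differ only nonsynonymously return no ratio and are
  conservatively assigned 1.  A section with no qualifying cluster is
  reported missing, never zero.

## Host association, rarefaction, saturation fit

The association dataset keeps one record per (host species, allele) pair —
records without a species are excluded with a log entry — and distances are
amino-acid p-distances on an alignment with HVR4 removed (too recombinant
and too length-variable to align).  For a single genus the statistic is the
mean (and median) within-genus pairwise distance; the global statistic
averages the within-genus means, unweighted, over genera with ≥ 2 records,
with the between-genus mean reported symmetrically and a pooled-pairs
variant available by flag (the averaging convention is genuinely ambiguous;
both are exposed).  The null shuffles host labels across all sequences
without replacement; the one-tailed p is the plain proportion of
pseudoreplicates with statistic ≤ observed (ties count, conservatively),
with the add-one-corrected value (count+1)/(n+1) reported alongside for
statistical hygiene.

Rarefaction uses the exact hypergeometric expectation of distinct classes at
each grid size (step, 2·step, …, always ending at N, where the expectation
equals the observed count), with a seeded Monte-Carlo mode for
cross-checking.  The saturation fit runs `scipy.optimize.curve_fit` on
y = a·x + b·x/(x+c) from several starting points, keeps the best-RSS
convergent fit, and reports the marginal new-variant rate a + b·c/(x+c)² at
the largest sampled x.

## The synthetic study conditions

The generator emulates the inferred evolutionary model of the gene, and its
defaults are the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| founders | 55 | with ~4.5 events each, ≈ 300 alleles per population |
| events per founder | Poisson(4.5) | complex-size spread with large and small complexes |
| mutation : recombination | 8 : 1 | observed haplotype-axis split (~88.5% / 11.5%) |
| mutant changes | 1–3 aa (P = .6/.3/.1) | sub-threshold by definition; 1 nt per aa change |
| recombinant changes | uniform 4–18, indels P = .35 | threshold rule; half of real events exceeded 10 changes; indels enter only via recombination |
| donor reuse | P = .15 | plants cross-complex HVR sharing (lateral shuffling) |
| chain (subgroup) events | P = .15, only once a complex has ≥ 3 SHVs | subgroup founders are observed in the major, radiated complexes; small complexes are stars |
| HVR section lengths | 30–38 / 44–50 / 50–52 / 26–45 aa | observed per-HVR ranges |
| GC3 target | 0.17 | observed AT bias at synonymous third positions (~83% AT) |
| synonymous events | P = .15, 70% landing in SP/CR scaffold | yields ~15% synonymous variants; conserved regions carry most synonymous diversity while shared HVR motifs carry little, matching the observed contrast |
| isolates | 480 over an 8×3×4×3 host taxonomy | ~1.6 records per allele as in the reference dataset |
| genus affinity | 0.8, founder boost 0.6, every complex home to ≥ 1 genus | founders are the most frequent and most widespread profiles |

Codon choice is i.i.d. per amino acid from a distribution that hits the GC3
target exactly whenever the synonymous codon set offers both AT- and
GC-ending codons; the conserved scaffold, which is shared verbatim by every
allele and would otherwise contribute a single high-variance draw, is
backtranslated with a quota balancer that flips synonymous third positions
until the scaffold's realized GC3 matches the target.  Anchors are checked
to occur exactly once in every emitted protein; offending draws are
resampled.  Everything is driven by one `numpy` Generator, so identical
parameters and seed give byte-identical output bundles.

Recombination is modelled as whole-HVR peptide replacement from an external
donor pool, not intra-genome conversion — consistent with the single-copy
status of the gene.  Host taxonomy is a balanced tree; affinity mixes
"reuse the genus's home complex" with a uniform allele draw.

**What passing tests show, and what they do not.**  On these conditions the
pipeline recovers planted event labels and founders at ≥ 90% (typically
≥ 96%), and the statistics match independent oracles to 1e−9.  Real data
differ in ways the generator does not emulate: real complexes include chains
whose founders SLV-counting genuinely mispredicts (the reference analysis
corrected three founders with nucleotide-level parsimony, which this package
approximates only by isolate frequency); real HVRs are too divergent for any
fixed anchor set, so real runs need a curated schema or coordinates on a
reference alignment; and the association analysis on real data requires a
curated MSA as input, whereas synthetic populations with fixed HVR1–3
lengths (`alignable_params`) make the typed-region concatenation a trivial
alignment.  Sequence-dependent reference numbers therefore live in an
optional validation harness (`wspevo.validation`) that runs only when the
curated tables are supplied locally.

## Degenerate inputs and tie-breaks, collected

Empty FASTA, duplicate headers, non-IUPAC characters, length not divisible
by 3, internal stops, duplicate profile rows, missing columns, duplicate
(species, allele, country) triples, absent/multiple anchors, < 2 sequences
for a distance matrix, zero segregating sites for D, all-zero differences
for the signed-rank test, step > N for rarefaction, and < 4 points for the
saturation fit are all hard errors with specific messages.  Every ordering
the pipeline relies on (complex numbering, BFS parents, founder prediction,
registry ids) has a stated deterministic tie-break.
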