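"""Host-association permutation tests, host-range summaries and rarefaction.

The association test asks whether WSP protein sequences found in hosts of
the same genus are more similar than expected by chance.  Amino-acid
p-distances are computed on an alignment with HVR4 excluded (it is hard to
align and highly recombinant); the null distribution is built by resampling
host-taxon labels without replacement across all sequences, and the observed
mean/median within-group distance is compared one-tailed against the
pseudoreplicate distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import gammaln

from .core import Allele, IsolateRecord
from .hvr_typing import SectionSchema, segment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

def dedupe_species_allele(records: Sequence[IsolateRecord]) -> list[IsolateRecord]:
    """Keep one record per (host_species, allele_id) pair, first occurrence.

    This avoids over-representing a single sequence found in the same host
    species from different localities.  Records without a species are
    excluded (logged), since they cannot participate in the pairing.
    """
    seen: set[tuple[str, int]] = set()
    kept: list[IsolateRecord] = []
    dropped = 0
    for rec in records:
        if not rec.host_species:
            dropped += 1
            continue
        key = (rec.host_species, rec.allele_id)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    if dropped:
        logger.info("dedupe_species_allele: excluded %d records without species", dropped)
    return kept


def typed_alignment(
    alleles: Sequence[Allele],
    schema: SectionSchema,
    exclude_sections: frozenset[str] | set[str] = frozenset({"HVR4"}),
    tolerance: int = 0,
) -> tuple[list[int], list[str]]:
    """Concatenate typing sections (minus excluded ones) into an alignment.

    Valid when the retained sections have equal length across alleles —
    true by construction for synthetic populations generated with fixed
    HVR1-3 lengths; for real data a curated MSA is an input instead.
    """
    ids, rows = [], []
    for a in alleles:
        spans = segment(a.aa_seq, schema, tolerance)
        rows.append("".join(s.peptide for n, s in spans.items() if n not in exclude_sections))
        ids.append(a.allele_id)
    if len({len(r) for r in rows}) != 1:
        raise ValueError(
            "retained sections have unequal lengths across alleles; "
            "supply a pre-computed alignment instead"
        )
    return ids, rows


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[int]
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def index_of(self, allele_id: int) -> int:
        return self.ids.index(allele_id)


def aa_distance_matrix(
    ids: Sequence[int],
    aligned_aa_seqs: Sequence[str],
    exclude_columns: Sequence[int] | None = None,
) -> DistanceMatrix:
    """Amino-acid p-distance matrix with pairwise gap deletion."""
    if len(aligned_aa_seqs) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in aligned_aa_seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(s) for s in aligned_aa_seqs])
    if exclude_columns is not None:
        keep = np.setdiff1d(np.arange(arr.shape[1]), np.asarray(exclude_columns))
        arr = arr[:, keep]
    valid = (arr != "-") & (arr != "X")
    n = arr.shape[0]
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            raise ValueError(f"no comparable columns between sequences {i} and {j}")
        m[i, j] = m[j, i] = float(np.sum(arr[i][both] != arr[j][both])) / compared
    return DistanceMatrix(ids=list(ids), matrix=m)


# ---------------------------------------------------------------------------
# Association test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    group: str  # genus name or "global"
    observed_mean: float
    observed_median: float
    p_mean: float
    p_median: float
    p_mean_corrected: float  # add-one corrected: (count + 1) / (n_perm + 1)
    p_median_corrected: float
    n_isolates: int
    n_species: int
    n_alleles: int
    n_perm: int
    observed_between_mean: float | None = None


def _within_group_stats(
    dists: np.ndarray, labels: np.ndarray, group: str
) -> tuple[float, float]:
    idx = np.flatnonzero(labels == group)
    sub = dists[np.ix_(idx, idx)]
    vals = sub[np.triu_indices(len(idx), k=1)]
    return float(np.mean(vals)), float(np.median(vals))


def _global_stats(
    dists: np.ndarray, labels: np.ndarray, pooled: bool
) -> tuple[float, float, float]:
    """(within mean, within median, between mean) averaged over genera.

    Unweighted average across genera with >= 2 members by default; the
    pooled variant averages over all within-genus pairs directly.
    """
    groups = [g for g, c in zip(*np.unique(labels, return_counts=True)) if c >= 2]
    within_pairs_mask = np.zeros_like(dists, dtype=bool)
    means, medians = [], []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = dists[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        means.append(np.mean(vals))
        medians.append(np.median(vals))
        within_pairs_mask[np.ix_(idx, idx)] = True
    triu = np.triu_indices(len(labels), k=1)
    within_sel = within_pairs_mask[triu]
    between_vals = dists[triu][~within_sel]
    between_mean = float(np.mean(between_vals)) if between_vals.size else float("nan")
    if pooled:
        within_vals = dists[triu][within_sel]
        return float(np.mean(within_vals)), float(np.median(within_vals)), between_mean
    return float(np.mean(means)), float(np.mean(medians)), between_mean


def genus_association_test(
    dm: DistanceMatrix,
    records: Sequence[IsolateRecord],
    group: str = "global",
    n_perm: int = 1000,
    seed: int | None = None,
    pooled: bool = False,
) -> AssociationResult:
    """Permutation test for association of WSP sequences with a host genus.

    ``group="global"`` averages the within-genus statistic over all genera
    with >= 2 records (between-genus distances are summarised symmetrically
    and reported alongside).  One-tailed p: the proportion of label-shuffled
    pseudoreplicates whose statistic is <= the observed one (ties count).
    """
    rng = np.random.default_rng(seed)
    rows = [dm.index_of(rec.allele_id) for rec in records]
    labels = np.array([rec.host_genus for rec in records])
    dists = dm.matrix[np.ix_(rows, rows)]

    if group == "global":
        def stat(lab: np.ndarray) -> tuple[float, float]:
            w_mean, w_median, _ = _global_stats(dists, lab, pooled)
            return w_mean, w_median

        obs_mean, obs_median, between_mean = _global_stats(dists, labels, pooled)
        sel = labels != ""
        n_iso = int(sel.sum())
        n_species = len({r.host_species for r in records if r.host_genus})
        n_alleles = len({r.allele_id for r in records if r.host_genus})
    else:
        members = np.flatnonzero(labels == group)
        if len(members) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 records")

        def stat(lab: np.ndarray) -> tuple[float, float]:
            return _within_group_stats(dists, lab, group)

        obs_mean, obs_median = _within_group_stats(dists, labels, group)
        between_mean = None
        n_iso = len(members)
        n_species = len({r.host_species for r in records if r.host_genus == group})
        n_alleles = len({r.allele_id for r in records if r.host_genus == group})

    count_mean = count_median = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        pm, pmed = stat(perm)
        count_mean += pm <= obs_mean
        count_median += pmed <= obs_median
    return AssociationResult(
        group=group,
        observed_mean=obs_mean,
        observed_median=obs_median,
        p_mean=count_mean / n_perm,
        p_median=count_median / n_perm,
        p_mean_corrected=(count_mean + 1) / (n_perm + 1),
        p_median_corrected=(count_median + 1) / (n_perm + 1),
        n_isolates=n_iso,
        n_species=n_species,
        n_alleles=n_alleles,
        n_perm=n_perm,
        observed_between_mean=between_mean,
    )


# ---------------------------------------------------------------------------
# Host range
# ---------------------------------------------------------------------------

def host_range_summary(records: Sequence[IsolateRecord], allele_id: int) -> dict[str, int]:
    """Distinct host species/genera/families/orders in which an allele occurs."""
    hits = [r for r in records if r.allele_id == allele_id]
    if not hits:
        raise ValueError(f"allele {allele_id} absent from records")
    return {
        "species": len({r.host_species for r in hits if r.host_species}),
        "genera": len({r.host_genus for r in hits if r.host_genus}),
        "families": len({r.host_family for r in hits if r.host_family}),
        "orders": len({r.host_order for r in hits if r.host_order}),
    }


# ---------------------------------------------------------------------------
# Rarefaction and saturation fit
# ---------------------------------------------------------------------------

@dataclass
class RarefactionCurve:
    sample_sizes: np.ndarray
    expected_alleles: np.ndarray
    expected_proteins: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.sample_sizes,
                "expected_alleles": self.expected_alleles,
                "expected_proteins": self.expected_proteins,
            }
        )


def _expected_distinct_analytic(class_counts: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Hypergeometric expectation of distinct classes at each sample size."""
    total = int(class_counts.sum())

    def log_comb(a: np.ndarray, b: int) -> np.ndarray:
        out = np.full(a.shape, -np.inf, dtype=float)
        ok = a >= b
        out[ok] = gammaln(a[ok] + 1) - gammaln(b + 1) - gammaln(a[ok] - b + 1)
        return out

    expectations = []
    for n in grid:
        n = int(n)
        log_miss = log_comb(total - class_counts, n) - (
            gammaln(total + 1) - gammaln(n + 1) - gammaln(total - n + 1)
        )
        expectations.append(float(np.sum(1.0 - np.exp(log_miss))))
    return np.array(expectations)


def _expected_distinct_montecarlo(
    labels: np.ndarray, grid: np.ndarray, rng: np.random.Generator, reps: int
) -> np.ndarray:
    out = np.zeros(len(grid))
    total = len(labels)
    for _ in range(reps):
        perm = labels[rng.permutation(total)]
        for gi, n in enumerate(grid):
            out[gi] += len(set(perm[: int(n)]))
    return out / reps


def rarefaction(
    records: Sequence[IsolateRecord],
    profiles_by_allele: Mapping[int, object],
    step: int = 20,
    mode: str = "analytic",
    seed: int | None = None,
    reps: int = 1000,
) -> RarefactionCurve:
    """Expected distinct-allele and distinct-protein counts vs sample size.

    The grid runs step, 2*step, ... and always includes the full sample size
    (where the expectation equals the exact distinct count).  Analytic mode
    uses the hypergeometric expectation; montecarlo averages ``reps``
    subsamples without replacement.
    """
    if not records:
        raise ValueError("no records")
    total = len(records)
    if step > total:
        raise ValueError(f"step {step} exceeds number of records {total}")
    grid = np.arange(step, total + 1, step)
    if grid[-1] != total:
        grid = np.append(grid, total)
    allele_labels = np.array([r.allele_id for r in records])
    protein_labels = np.array([str(profiles_by_allele[r.allele_id]) for r in records])
    if mode == "analytic":
        a_counts = np.unique(allele_labels, return_counts=True)[1].astype(float)
        p_counts = np.unique(protein_labels, return_counts=True)[1].astype(float)
        ea = _expected_distinct_analytic(a_counts, grid)
        ep = _expected_distinct_analytic(p_counts, grid)
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        ea = _expected_distinct_montecarlo(allele_labels, grid, rng, reps)
        rng = np.random.default_rng(seed)
        ep = _expected_distinct_montecarlo(protein_labels, grid, rng, reps)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RarefactionCurve(sample_sizes=grid, expected_alleles=ea, expected_proteins=ep)


@dataclass(frozen=True)
class SaturationFit:
    a: float
    b: float
    c: float
    rss: float
    marginal_rate: float  # dy/dx at the largest sampled x


def _saturation(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * x + b * x / (x + c)


def fit_saturation(points: Sequence[tuple[float, float]]) -> SaturationFit:
    """Nonlinear least squares for y = a*x + b*x/(x+c).

    Several starting points are tried; the best-RSS convergent fit wins.
    The marginal new-variant rate is the derivative a + b*c/(x+c)^2 at the
    largest sampled x.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    slope_all = float(np.polyfit(x, y, 1)[0])
    xmax, ymax = float(x.max()), float(y.max())
    starts = [
        (slope_all / 2, ymax / 2, float(np.median(x))),
        (0.0, ymax, float(np.median(x))),
        (slope_all, 0.1 * max(ymax, 1.0), xmax / 4 + 1.0),
    ]
    best: tuple[float, np.ndarray] | None = None
    errors = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(_saturation, x, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            errors.append(str(exc))
            continue
        rss = float(np.sum((y - _saturation(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError(f"saturation fit failed to converge: {errors}")
    rss, (a, b, c) = best[0], best[1]
    marginal = a + b * c / (xmax + c) ** 2
    return SaturationFit(a=float(a), b=float(b), c=float(c), rss=rss, marginal_rate=float(marginal))
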