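"""eBURST-style clustering of WSP profiles into complexes.

A WSP complex is a connected component of the graph whose vertices are the
distinct profiles and whose edges join profiles differing at exactly one HVR
(single-HVR variants, SHVs) — the single-locus-variant semantics of eBURST
applied to one four-locus profile.  Components of size one are singletons.
The founder of a complex is the member with the most SLVs; ties are broken
by allele-variant count, then isolate count, then lowest representative
allele id, so prediction is deterministic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .core import IsolateRecord, WspProfile


def profile_distance(p: WspProfile, q: WspProfile) -> int:
    """Number of HVR positions with unequal peptide ids (0..4)."""
    return sum(a != b for a, b in zip(p, q))


def slv_graph(profiles: Iterable[WspProfile]) -> nx.Graph:
    """Graph with an edge for every profile pair at distance exactly 1.

    Edges are found by hashing each profile under its four 3-of-4 locus
    keys: two distinct profiles share such a key iff they differ only at
    the wildcarded position, i.e. are SLVs of each other.
    """
    g = nx.Graph()
    g.add_nodes_from(profiles)
    buckets: dict[tuple, list[WspProfile]] = defaultdict(list)
    for p in g.nodes:
        for i in range(4):
            buckets[(i, p[:i] + p[i + 1 :])].append(p)
    for members in buckets.values():
        for i, p in enumerate(members):
            for q in members[i + 1 :]:
                g.add_edge(p, q)
    return g


@dataclass
class Complex:
    """One eBURST group: founder, SHVs, subgroup founders and DHVs."""

    complex_id: int
    members: tuple[WspProfile, ...]
    founder: WspProfile
    slv_count: dict[WspProfile, int]
    depth: dict[WspProfile, int]          # BFS distance from the founder
    parent: dict[WspProfile, WspProfile | None]
    roles: dict[WspProfile, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.roles:
            self.roles = {}
            for p in self.members:
                if p == self.founder:
                    self.roles[p] = "founder"
                elif self.depth[p] == 1:
                    self.roles[p] = "SHV"
                else:
                    self.roles[p] = "DHV"
            for p in self.members:
                if self.roles[p] == "SHV" and any(
                    self.parent[q] == p for q in self.members if self.depth[q] == 2
                ):
                    self.roles[p] = "subgroup_founder"

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def shvs(self) -> list[WspProfile]:
        return [p for p in self.members if self.depth[p] == 1]

    def __iter__(self):
        return iter(self.members)


@dataclass
class ClusterResult:
    """Complexes plus singletons; together a partition of the profile set."""

    complexes: list[Complex]
    singletons: list[WspProfile]

    @property
    def n_profiles(self) -> int:
        return sum(c.size for c in self.complexes) + len(self.singletons)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cx in self.complexes:
            for p in cx.members:
                rows.append(
                    {
                        "complex_id": cx.complex_id,
                        "profile": str(p),
                        "role": cx.roles[p],
                        "slv_count": cx.slv_count[p],
                    }
                )
        for p in self.singletons:
            rows.append(
                {"complex_id": 0, "profile": str(p), "role": "singleton", "slv_count": 0}
            )
        return pd.DataFrame(rows, columns=["complex_id", "profile", "role", "slv_count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterResult":
        singletons = [
            WspProfile.parse(r.profile) for r in df.itertuples() if r.role == "singleton"
        ]
        complexes = []
        grouped = df[df["role"] != "singleton"]
        for cid, sub in grouped.groupby("complex_id"):
            members = [WspProfile.parse(r.profile) for r in sub.itertuples()]
            founder = next(
                WspProfile.parse(r.profile) for r in sub.itertuples() if r.role == "founder"
            )
            complexes.append(_build_complex(int(cid), members, founder))
        complexes.sort(key=lambda c: c.complex_id)
        return cls(complexes, singletons)


def predict_founder(
    members: Sequence[WspProfile],
    slv_count: Mapping[WspProfile, int],
    allele_counts: Mapping[WspProfile, int],
    isolate_counts: Mapping[WspProfile, int],
    min_allele_id: Mapping[WspProfile, int],
) -> WspProfile:
    """Member maximizing SLV count, with deterministic tie-breaking.

    Ties go to the profile coded by the most allele variants, then found in
    the most isolates, then with the lowest representative allele id, then
    (as a final total order) the lexicographically smallest profile.
    """
    big = 10 ** 9
    return max(
        members,
        key=lambda p: (
            slv_count.get(p, 0),
            allele_counts.get(p, 0),
            isolate_counts.get(p, 0),
            -min_allele_id.get(p, big),
            tuple(-x for x in p),
        ),
    )


def _bfs(
    founder: WspProfile, members: Sequence[WspProfile], adj: Mapping[WspProfile, list],
    slv_count: Mapping[WspProfile, int],
) -> tuple[dict, dict]:
    order_key = lambda p: (-slv_count.get(p, 0), tuple(p))
    depth = {founder: 0}
    parent: dict[WspProfile, WspProfile | None] = {founder: None}
    frontier = [founder]
    while frontier:
        nxt = []
        for node in sorted(frontier, key=order_key):
            for nb in sorted(adj[node], key=order_key):
                if nb not in depth:
                    depth[nb] = depth[node] + 1
                    parent[nb] = node
                    nxt.append(nb)
        frontier = nxt
    return depth, parent


def _build_complex(
    complex_id: int,
    members: Sequence[WspProfile],
    founder: WspProfile | None = None,
    allele_counts: Mapping[WspProfile, int] | None = None,
    isolate_counts: Mapping[WspProfile, int] | None = None,
    min_allele_id: Mapping[WspProfile, int] | None = None,
) -> Complex:
    sub = slv_graph(members)
    slv_count = {p: sub.degree(p) for p in members}
    adj = {p: list(sub.neighbors(p)) for p in members}
    if founder is None:
        founder = predict_founder(
            sorted(members), slv_count, allele_counts or {}, isolate_counts or {},
            min_allele_id or {},
        )
    depth, parent = _bfs(founder, members, adj, slv_count)
    return Complex(
        complex_id=complex_id,
        members=tuple(sorted(members)),
        founder=founder,
        slv_count=slv_count,
        depth=depth,
        parent=parent,
    )


def build_complex(
    members: Sequence[WspProfile],
    founder: WspProfile | None = None,
    allele_counts: Mapping[WspProfile, int] | None = None,
    isolate_counts: Mapping[WspProfile, int] | None = None,
    min_allele_id: Mapping[WspProfile, int] | None = None,
    complex_id: int = 1,
) -> Complex:
    """A single complex from known members, optionally with a fixed founder.

    Passing ``founder`` overrides prediction — useful when the ancestral
    profile is known from external evidence (nucleotide-level parsimony, or
    a simulation truth log).
    """
    return _build_complex(
        complex_id, members, founder, allele_counts, isolate_counts, min_allele_id
    )


def find_complexes(
    profiles: Iterable[WspProfile],
    allele_counts: Mapping[WspProfile, int] | None = None,
    isolate_counts: Mapping[WspProfile, int] | None = None,
    min_allele_id: Mapping[WspProfile, int] | None = None,
) -> ClusterResult:
    """Cluster distinct profiles into complexes (components >= 2) and singletons.

    The result is invariant under input permutation: components are sorted
    by decreasing size then lexicographic founder profile before numbering.
    """
    distinct = sorted(set(profiles))
    g = slv_graph(distinct)
    complexes: list[Complex] = []
    singletons: list[WspProfile] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            singletons.append(members[0])
        else:
            complexes.append(
                _build_complex(0, members, None, allele_counts, isolate_counts, min_allele_id)
            )
    complexes.sort(key=lambda c: (-c.size, c.founder))
    for i, cx in enumerate(complexes, start=1):
        cx.complex_id = i
    return ClusterResult(complexes, sorted(singletons))


def find_subgroups(cx: Complex) -> list[tuple[WspProfile, tuple[WspProfile, ...]]]:
    """Subgroup founders (SHVs with their own SLVs at distance 2) and their DHVs."""
    out = []
    for p in cx.members:
        if cx.depth[p] != 1:
            continue
        dhvs = tuple(
            sorted(q for q in cx.members if cx.depth[q] == 2 and cx.parent[q] == p)
        )
        if dhvs:
            out.append((p, dhvs))
    return out


# ---------------------------------------------------------------------------
# Support statistics from allele/isolate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSupport:
    """Per-profile evidence used in founder prediction and reporting."""

    allele_counts: dict[WspProfile, int]
    isolate_counts: dict[WspProfile, int]
    min_allele_id: dict[WspProfile, int]
    alleles_by_profile: dict[WspProfile, tuple[int, ...]]
    isolates_by_allele: dict[int, int]


def profile_support(
    profiles: Mapping[int, WspProfile],
    isolates: Sequence[IsolateRecord] | None = None,
) -> ProfileSupport:
    by_profile: dict[WspProfile, list[int]] = defaultdict(list)
    for aid in sorted(profiles):
        by_profile[profiles[aid]].append(aid)
    iso_by_allele: dict[int, int] = defaultdict(int)
    for rec in isolates or []:
        iso_by_allele[rec.allele_id] += 1
    return ProfileSupport(
        allele_counts={p: len(a) for p, a in by_profile.items()},
        isolate_counts={
            p: sum(iso_by_allele.get(a, 0) for a in aids)
            for p, aids in by_profile.items()
        },
        min_allele_id={p: min(a) for p, a in by_profile.items()},
        alleles_by_profile={p: tuple(a) for p, a in by_profile.items()},
        isolates_by_allele=dict(iso_by_allele),
    )


def representative_ancestral_allele(
    cx: Complex,
    alleles_by_profile: Mapping[WspProfile, Sequence[int]],
    isolates_by_allele: Mapping[int, int] | None = None,
) -> int:
    """Among founder-profile alleles, the one with most isolates (tie: lowest id).

    This approximates nucleotide-level ancestral-allele inference with the
    same frequency evidence eBURST uses for founders.
    """
    candidates = alleles_by_profile[cx.founder]
    if not candidates:
        raise ValueError("founder profile has no alleles")
    iso = isolates_by_allele or {}
    return min(candidates, key=lambda a: (-iso.get(a, 0), a))


def representative_allele(
    profile: WspProfile,
    alleles_by_profile: Mapping[WspProfile, Sequence[int]],
    isolates_by_allele: Mapping[int, int] | None = None,
) -> int:
    """Most-isolates (tie: lowest id) allele coding an arbitrary profile."""
    iso = isolates_by_allele or {}
    return min(alleles_by_profile[profile], key=lambda a: (-iso.get(a, 0), a))
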