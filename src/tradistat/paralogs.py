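"""Paralog-group construction from all-vs-all self-proteome BLAST hits.

Two proteins are *similarity neighbours* when (1) the shorter is at least 60%
the length of the longer, and (2) the bit score of their cross comparison
(the larger of the two directed hits) reaches a fraction of ``Max_bit_score``
— the larger of their two self-comparison bit scores — of 0.1 when they share
a COG functional label and 0.2 otherwise.

Grouping walks second-order neighbourhoods: the second-order neighbours of p
are the non-redundant union of the neighbours of p's neighbours, p itself
excluded.  Iteratively, the unassigned protein with the most second-order
neighbours (ties broken lexicographically) anchors a group; each of its
second-order neighbours joins when its own second-order count is at least 20%
of the anchor's.  Assigned proteins leave the graph, so later rounds count
neighbourhoods on the remaining subgraph, and the loop runs until every
protein is assigned.  Reported groups have at least two members; singletons
exist internally but are filtered from output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import BlastHit, self_scores

__all__ = [
    "SimilarityGraph",
    "ParalogGroup",
    "length_compatible",
    "bitscore_compatible",
    "build_similarity_graph",
    "first_order_neighbors",
    "second_order_neighbors",
    "cluster_paralogs",
    "summarize_groups",
]

DEFAULT_MIN_LEN_FRAC = 0.6
DEFAULT_SAME_COG_FRAC = 0.1
DEFAULT_DIFF_COG_FRAC = 0.2
DEFAULT_MEMBER_FRAC = 0.2


@dataclass(frozen=True)
class SimilarityGraph:
    proteins: frozenset[str]
    self_score: dict = field(hash=False, default_factory=dict)
    adjacency: dict = field(hash=False, default_factory=dict)  # protein -> set of neighbours


@dataclass(frozen=True)
class ParalogGroup:
    reference_protein: str
    members: frozenset[str]  # includes the reference

    @property
    def size(self) -> int:
        return len(self.members)


def length_compatible(len_a: int, len_b: int, min_frac: float = DEFAULT_MIN_LEN_FRAC) -> bool:
    """Shorter protein at least ``min_frac`` of the longer (boundary inclusive)."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("protein lengths must be positive")
    return min(len_a, len_b) >= min_frac * max(len_a, len_b)


def bitscore_compatible(
    a: str,
    b: str,
    cross_scores: dict[tuple[str, str], float],
    self_score: dict[str, float],
    cog_map: dict[str, set[str]],
    same_cog_frac: float = DEFAULT_SAME_COG_FRAC,
    diff_cog_frac: float = DEFAULT_DIFF_COG_FRAC,
) -> bool:
    """Cross bit score >= (0.1 or 0.2) x Max_bit_score, COG-dependent.

    ``cross_scores`` maps directed (query, subject) pairs to bit scores; the
    cross score of (a, b) is the larger of the two directions, 0 when no hit
    exists.  Sharing any COG label selects the lenient fraction.
    """
    for p in (a, b):
        if p not in self_score:
            raise KeyError(f"protein {p!r} has no self-comparison hit")
    max_bit = max(self_score[a], self_score[b])
    cross = max(cross_scores.get((a, b), 0.0), cross_scores.get((b, a), 0.0))
    shared_cog = bool(cog_map.get(a, set()) & cog_map.get(b, set()))
    frac = same_cog_frac if shared_cog else diff_cog_frac
    return cross >= frac * max_bit


def build_similarity_graph(
    hits: list[BlastHit],
    lengths: dict[str, int],
    cog_map: dict[str, set[str]] | None = None,
    min_len_frac: float = DEFAULT_MIN_LEN_FRAC,
    same_cog_frac: float = DEFAULT_SAME_COG_FRAC,
    diff_cog_frac: float = DEFAULT_DIFF_COG_FRAC,
) -> SimilarityGraph:
    """Edges between all protein pairs passing both similarity criteria.

    Only pairs with at least one directed hit are candidates, so the build is
    linear in the hit table rather than quadratic in the proteome.
    """
    cog_map = cog_map or {}
    selfs = self_scores(hits)
    missing = sorted(set(lengths) - set(selfs))
    if missing:
        raise KeyError(f"proteins without self-hits: {missing[:10]}")
    cross: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.is_self:
            continue
        key = (h.query_id, h.subject_id)
        cross[key] = max(cross.get(key, 0.0), h.bit_score)
    adjacency: dict[str, set[str]] = {p: set() for p in lengths}
    for q, s in {tuple(sorted(k)) for k in cross}:
        if q not in lengths or s not in lengths:
            raise KeyError(f"hit references protein absent from the length table: {q!r}/{s!r}")
        if not length_compatible(lengths[q], lengths[s], min_frac=min_len_frac):
            continue
        if bitscore_compatible(q, s, cross, selfs, cog_map,
                               same_cog_frac=same_cog_frac, diff_cog_frac=diff_cog_frac):
            adjacency[q].add(s)
            adjacency[s].add(q)
    return SimilarityGraph(frozenset(lengths), {p: selfs[p] for p in lengths}, adjacency)


def first_order_neighbors(p: str, graph: SimilarityGraph, subset: frozenset | set | None = None) -> set[str]:
    """Direct similarity neighbours, optionally on an induced subgraph."""
    nbrs = graph.adjacency.get(p, set())
    return set(nbrs) if subset is None else nbrs & subset


def second_order_neighbors(p: str, graph: SimilarityGraph, subset: frozenset | set | None = None) -> set[str]:
    """Non-redundant union of neighbours-of-neighbours, excluding p itself."""
    out: set[str] = set()
    for q in first_order_neighbors(p, graph, subset):
        out |= first_order_neighbors(q, graph, subset)
    out.discard(p)
    return out


def cluster_paralogs(
    graph: SimilarityGraph,
    member_frac: float = DEFAULT_MEMBER_FRAC,
    include_singletons: bool = False,
) -> list[ParalogGroup]:
    """Assign every protein to exactly one group via second-order neighbourhoods.

    Each round recomputes second-order counts on the subgraph of unassigned
    proteins, anchors on the protein with the largest count (ties ->
    lexicographically smallest id) and admits its second-order neighbours
    whose own count is >= ``member_frac`` times the anchor's.  Deterministic
    and independent of input order.
    """
    remaining = set(graph.proteins)
    groups: list[ParalogGroup] = []
    while remaining:
        so = {p: second_order_neighbors(p, graph, remaining) for p in remaining}
        ref = min(remaining, key=lambda p: (-len(so[p]), p))
        threshold = member_frac * len(so[ref])
        members = {ref} | {q for q in so[ref] if len(so[q]) >= threshold}
        groups.append(ParalogGroup(ref, frozenset(members)))
        remaining -= members
    groups.sort(key=lambda g: g.reference_protein)
    if include_singletons:
        return groups
    return [g for g in groups if g.size >= 2]


def summarize_groups(groups: list[ParalogGroup], calls: dict[str, str]) -> dict:
    """Per-group label composition; domain-essential members count as essential."""
    compositions = []
    pure_essential = pure_non_essential = pure_unclear = mixed = with_unclear = 0
    n_proteins = 0
    sizes = []
    for g in groups:
        counts = {"essential": 0, "non_essential": 0, "unclear": 0}
        for member in sorted(g.members):
            if member not in calls:
                raise KeyError(f"group member {member!r} has no essentiality call")
            label = calls[member]
            if label == "domain_essential":
                label = "essential"
            if label not in counts:
                raise ValueError(f"{member}: unknown label {calls[member]!r}")
            counts[label] += 1
        compositions.append({"reference": g.reference_protein, "size": g.size, **counts})
        n_proteins += g.size
        sizes.append(g.size)
        present = {lab for lab, n in counts.items() if n}
        if present == {"essential"}:
            pure_essential += 1
        elif present == {"non_essential"}:
            pure_non_essential += 1
        elif present == {"unclear"}:
            pure_unclear += 1
        else:
            mixed += 1
        if counts["unclear"]:
            with_unclear += 1
    return {
        "n_groups": len(groups),
        "n_proteins": n_proteins,
        "pure_essential": pure_essential,
        "pure_non_essential": pure_non_essential,
        "pure_unclear": pure_unclear,
        "mixed": mixed,
        "with_unclear": with_unclear,
        "max_size": max(sizes) if sizes else 0,
        "compositions": compositions,
    }
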