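"""BLAST-hit filtering, bidirectional best hits and conservation profiling.

Orthologs between two proteomes are approximated by bidirectional best hits
(BBH) on reciprocal BLAST tables that were pre-filtered on E-value and on
query *and* subject alignment coverage (boundary values kept).  Proteins with
paralogies that are hard to resolve are discarded: when either partner has a
runner-up hit scoring at least ``paralogy_margin`` (default 0.9) times its
best bit score, the pair is dropped.

Conservation profiles collapse hits to species (to iron out strain-level
redundancy) and flag, per query gene, whether every species with a surviving
hit sits inside a nested taxonomic level (here Planctomycetes ⊆ PVC ⊆
Prokaryotes by default).  A gene with no surviving external hit is specific to
the query's own taxon by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io import BlastHit

__all__ = [
    "OrthologPair",
    "ConservationRecord",
    "DEFAULT_LEVELS",
    "filter_hits",
    "bidirectional_best_hits",
    "compare_essentiality",
    "conservation_profile",
]

#: Nested taxonomic levels, innermost first.
DEFAULT_LEVELS = ("Planctomycetes", "PVC", "Prokaryotes")


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    bit_score_ab: float
    bit_score_ba: float


@dataclass(frozen=True)
class ConservationRecord:
    feature_id: str
    taxa_present: frozenset[str]          # species with >= 1 surviving hit
    level_flags: dict = field(hash=False, default_factory=dict)  # level -> all species within
    no_external_homologs: bool = False


def filter_hits(
    hits: list[BlastHit],
    max_evalue: float = 1e-5,
    min_qcov: float = 70.0,
    min_scov: float = 70.0,
) -> list[BlastHit]:
    """Keep hits with evalue <= max_evalue and both coverages >= threshold."""
    kept = []
    for h in hits:
        if math.isnan(h.query_cov) or math.isnan(h.subject_cov):
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} carries no coverage; "
                "read the table with with_lengths=True"
            )
        if h.evalue <= max_evalue and h.query_cov >= min_qcov and h.subject_cov >= min_scov:
            kept.append(h)
    return kept


def _hit_rank(h: BlastHit) -> tuple:
    # higher bit score, then higher identity, then lexicographically smaller subject
    return (-h.bit_score, -h.percent_identity, h.subject_id)


def _best_and_runner(hits: list[BlastHit]) -> tuple[dict[str, BlastHit], dict[str, float]]:
    """Best hit per query (multi-HSP rows collapsed per subject) and the
    runner-up bit score to a *different* subject."""
    per_query: dict[str, dict[str, BlastHit]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        best = per_query.setdefault(h.query_id, {})
        old = best.get(h.subject_id)
        if old is None or _hit_rank(h) < _hit_rank(old):
            best[h.subject_id] = h
    best_hit: dict[str, BlastHit] = {}
    runner_bit: dict[str, float] = {}
    for q, by_subject in per_query.items():
        ranked = sorted(by_subject.values(), key=_hit_rank)
        best_hit[q] = ranked[0]
        runner_bit[q] = ranked[1].bit_score if len(ranked) > 1 else -math.inf
    return best_hit, runner_bit


def bidirectional_best_hits(
    hits_ab: list[BlastHit],
    hits_ba: list[BlastHit],
    paralogy_margin: float = 0.9,
) -> list[OrthologPair]:
    """Mutual best hits, dropping pairs with a close runner-up on either side.

    Ties for best hit break on bit score, then percent identity, then subject
    id, so the pairing is deterministic across input row order.
    """
    if not 0 < paralogy_margin <= 1:
        raise ValueError("paralogy_margin must lie in (0, 1]")
    best_ab, runner_ab = _best_and_runner(hits_ab)
    best_ba, runner_ba = _best_and_runner(hits_ba)
    pairs = []
    for a, hit_ab in sorted(best_ab.items()):
        b = hit_ab.subject_id
        hit_ba = best_ba.get(b)
        if hit_ba is None or hit_ba.subject_id != a:
            continue
        if runner_ab[a] >= paralogy_margin * hit_ab.bit_score:
            continue
        if runner_ba[b] >= paralogy_margin * hit_ba.bit_score:
            continue
        pairs.append(OrthologPair(a, b, hit_ab.bit_score, hit_ba.bit_score))
    return pairs


_COMPARE_LABELS = ("essential", "non_essential", "unclear")


def compare_essentiality(
    pairs: list[OrthologPair],
    calls_a: dict[str, str],
    calls_b: dict[str, str],
) -> dict:
    """Cross-tabulate essentiality labels over ortholog pairs.

    ``calls_a``/``calls_b`` map feature id -> label in
    {essential, non_essential, unclear}.  Returns the 3x3 contingency table,
    agreement percentages and the derived gene lists.
    """
    contingency = pd.DataFrame(
        0, index=list(_COMPARE_LABELS), columns=list(_COMPARE_LABELS), dtype=int
    )
    agree_essential, agree_non_essential = [], []
    essential_a_only, essential_b_only = [], []
    for p in pairs:
        for calls, fid in ((calls_a, p.id_a), (calls_b, p.id_b)):
            if fid not in calls:
                raise KeyError(f"pair references {fid!r} with no essentiality call")
            if calls[fid] not in _COMPARE_LABELS:
                raise ValueError(f"{fid}: label {calls[fid]!r} not in {_COMPARE_LABELS}")
        la, lb = calls_a[p.id_a], calls_b[p.id_b]
        contingency.loc[la, lb] += 1
        if la == lb == "essential":
            agree_essential.append(p)
        elif la == lb == "non_essential":
            agree_non_essential.append(p)
        if la == "essential" and lb != "essential":
            essential_a_only.append(p)
        if lb == "essential" and la != "essential":
            essential_b_only.append(p)
    n = len(pairs)
    n_agree = int(sum(contingency.loc[l, l] for l in _COMPARE_LABELS))
    return {
        "n_pairs": n,
        "contingency": contingency,
        "n_agree": n_agree,
        "pct_agree": 100.0 * n_agree / n if n else 0.0,
        "agree_essential": agree_essential,
        "agree_non_essential": agree_non_essential,
        "pct_agree_essential": 100.0 * len(agree_essential) / n_agree if n_agree else 0.0,
        "pct_agree_non_essential": 100.0 * len(agree_non_essential) / n_agree if n_agree else 0.0,
        "essential_a_only": essential_a_only,
        "essential_b_only": essential_b_only,
    }


def _organism_of(subject_id: str) -> str:
    """KEGG-style subject ids carry the organism code before the first colon."""
    return subject_id.split(":", 1)[0]


def conservation_profile(
    query_hits: list[BlastHit],
    organism_to_species: dict[str, str],
    species_to_taxon: dict[str, str],
    query_calls: dict[str, str],
    levels: tuple[str, ...] = DEFAULT_LEVELS,
) -> tuple[list[ConservationRecord], pd.DataFrame]:
    """Species-collapsed conservation per query gene plus a per-level summary.

    ``levels`` are nested, innermost first; a species mapped to level i counts
    as inside every level j >= i.  The summary counts, per level and
    essentiality label, the genes *specific to* that level (all species with a
    surviving hit inside it); genes with no surviving hit are specific to the
    innermost level and flagged ``no_external_homologs``.
    """
    level_rank = {name: i for i, name in enumerate(levels)}
    species_by_gene: dict[str, set[str]] = {fid: set() for fid in query_calls}
    for h in query_hits:
        if h.query_id not in species_by_gene:
            continue  # hit for a gene outside the call set
        org = _organism_of(h.subject_id)
        if org not in organism_to_species:
            offenders = sorted(
                {_organism_of(x.subject_id) for x in query_hits
                 if _organism_of(x.subject_id) not in organism_to_species}
            )
            raise KeyError(f"organisms missing from the species map: {offenders}")
        species_by_gene[h.query_id].add(organism_to_species[org])

    records = []
    for fid in sorted(query_calls):
        species = species_by_gene[fid]
        for sp in species:
            if sp not in species_to_taxon:
                raise KeyError(f"species {sp!r} missing from the taxon map")
            if species_to_taxon[sp] not in level_rank:
                raise ValueError(f"species {sp!r} maps to unknown level {species_to_taxon[sp]!r}")
        if species:
            outermost = max(level_rank[species_to_taxon[sp]] for sp in species)
            flags = {name: level_rank[name] >= outermost for name in levels}
            no_ext = False
        else:
            flags = {name: True for name in levels}
            no_ext = True
        records.append(ConservationRecord(fid, frozenset(species), flags, no_ext))

    labels = ("essential", "non_essential", "unclear")
    rows = []
    calls_of = {r.feature_id: query_calls[r.feature_id] for r in records}
    for name in reversed(levels):  # outermost (total) first, Table-style
        counts = {lab: 0 for lab in labels}
        for r in records:
            if r.level_flags[name]:
                lab = calls_of[r.feature_id]
                if lab == "domain_essential":
                    lab = "essential"
                counts[lab] += 1
        rows.append({"level": name, **counts, "total": sum(counts.values())})
    summary = pd.DataFrame(rows).set_index("level")
    return records, summary
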