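"""Presence/absence phyletic profiles of ortholog groups across taxonomic classes.

Each query gene maps to an ortholog group (OG); each OG's frequency in a
taxonomic class is the fraction of the class's organisms carrying at least one
member of the group (duplicate occurrences within an organism collapse to
one).  Classes with fewer than ``min_class_size`` organisms are dropped.  Rows
are ordered for heatmap display by agglomerative complete-linkage clustering
on Euclidean distances, and rows can be partitioned into interpretable
patterns (universal, lineage-restricted, ...) by threshold predicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PhyleticMatrix",
    "build_matrix",
    "cluster_matrix",
    "extract_pattern_groups",
]

DEFAULT_MIN_CLASS_SIZE = 5
DEFAULT_TAU_HIGH = 0.5
DEFAULT_TAU_LOW = 0.1


@dataclass(frozen=True)
class PhyleticMatrix:
    """OG x class frequency matrix plus the genes that lack an OG."""

    frequencies: pd.DataFrame = field(hash=False)
    genes_without_group: tuple[str, ...] = ()

    @property
    def row_ids(self) -> list[str]:
        return list(self.frequencies.index)


def build_matrix(
    gene_to_og: dict[str, str],
    organism_og_presence: Iterable[tuple[str, str]],
    organism_to_class: dict[str, str],
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> PhyleticMatrix:
    """Frequency of each query OG per taxonomic class.

    ``organism_og_presence`` lists (organism, og) pairs; duplicates are
    collapsed.  Class size counts every organism in ``organism_to_class``,
    with or without presences.  An organism appearing in the presence table
    but missing from the class map is an error.
    """
    class_orgs: dict[str, set[str]] = {}
    for org, cls in organism_to_class.items():
        class_orgs.setdefault(cls, set()).add(org)
    classes = sorted(c for c, orgs in class_orgs.items() if len(orgs) >= min_class_size)

    presence: set[tuple[str, str]] = set()
    for org, og in organism_og_presence:
        if org not in organism_to_class:
            raise KeyError(f"organism {org!r} has no taxonomic class")
        presence.add((org, og))

    ogs = sorted(set(gene_to_og.values()))
    genes_without = tuple(sorted(g for g, og in gene_to_og.items() if not og))
    ogs = [og for og in ogs if og]

    orgs_with_og: dict[str, set[str]] = {}
    for org, og in presence:
        orgs_with_og.setdefault(og, set()).add(org)

    data = np.zeros((len(ogs), len(classes)))
    for i, og in enumerate(ogs):
        carriers = orgs_with_og.get(og, set())
        for j, cls in enumerate(classes):
            members = class_orgs[cls]
            data[i, j] = len(carriers & members) / len(members)
    freq = pd.DataFrame(data, index=ogs, columns=classes)
    return PhyleticMatrix(freq, genes_without)


def _to_newick(node: hierarchy.ClusterNode, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    return f"({left},{right}):{node.dist:.6g}"


def cluster_matrix(matrix: PhyleticMatrix) -> tuple[list[str], np.ndarray | None, str | None]:
    """Complete-linkage / Euclidean row ordering for heatmap display.

    Returns ``(leaf_order, linkage, newick)``.  Rows are sorted by id before
    clustering so tie distances resolve deterministically; a single row gets
    the identity ordering with no tree.
    """
    freq = matrix.frequencies.sort_index()
    ids = list(freq.index)
    if len(ids) < 1:
        return [], None, None
    if len(ids) == 1:
        return ids, None, None
    z = hierarchy.linkage(pdist(freq.to_numpy(), metric="euclidean"), method="complete")
    order = [ids[i] for i in hierarchy.leaves_list(z)]
    newick = _to_newick(hierarchy.to_tree(z), ids) + ";"
    return order, z, newick


def _default_patterns(
    columns: Sequence[str],
    class_subsets: dict[str, Sequence[str]],
    tau_high: float,
    tau_low: float,
) -> list[tuple[str, Callable[[pd.Series], bool]]]:
    patterns: list[tuple[str, Callable[[pd.Series], bool]]] = [
        ("universal", lambda row: bool((row >= tau_high).all())),
    ]
    for name, subset in class_subsets.items():
        subset = list(subset)
        rest = [c for c in columns if c not in subset]

        def pred(row: pd.Series, s=subset, r=rest) -> bool:
            return bool((row[s] >= tau_high).all()) and bool((row[r] <= tau_low).all() if r else True)

        patterns.append((f"restricted_{name}", pred))
    patterns.append(("other", lambda row: True))
    return patterns


def extract_pattern_groups(
    matrix: PhyleticMatrix,
    class_subsets: dict[str, Sequence[str]] | None = None,
    tau_high: float = DEFAULT_TAU_HIGH,
    tau_low: float = DEFAULT_TAU_LOW,
    patterns: Sequence[tuple[str, Callable[[pd.Series], bool]]] | None = None,
) -> dict[str, list[str]]:
    """Partition rows by the first matching presence pattern.

    Default patterns: ``universal`` (>= tau_high everywhere), one
    ``restricted_<name>`` per class subset (>= tau_high inside, <= tau_low
    outside) and a terminal ``other``.  Custom ``(name, predicate)`` pairs
    override the defaults; evaluation order resolves overlaps.
    """
    freq = matrix.frequencies
    unknown = [c for subset in (class_subsets or {}).values() for c in subset
               if c not in freq.columns]
    if unknown:
        raise KeyError(f"unknown classes in subsets: {sorted(set(unknown))}")
    if patterns is None:
        patterns = _default_patterns(list(freq.columns), class_subsets or {}, tau_high, tau_low)
    out: dict[str, list[str]] = {name: [] for name, _ in patterns}
    for og, row in freq.iterrows():
        for name, pred in patterns:
            if pred(row):
                out[name].append(og)
                break
        else:
            raise ValueError(f"row {og!r} matched no pattern; add a catch-all")
    return out
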