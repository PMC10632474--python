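"""Synthetic transposon libraries and toy BLAST universes with known truth.

The generator reproduces the statistical structure the essentiality analysis
assumes: a saturated library inserts roughly once every 11 bp into dispensable
sequence (genes and intergenic alike), essential genes are (near) free of
insertions, and a small fraction of genes carry a single insertion-free block
— an essential protein domain — inside an otherwise freely hit gene.  The
insertion process is per-base Bernoulli (binomial per region): coverage in
real saturated libraries is even, with no hotspot structure worth modelling.

Defaults: 2000 genes, gamma-distributed lengths with mean 900 bp, ~15% of the
genome intergenic, 15% essential genes with zero leak insertions, 2%
domain-essential genes carrying a 450-bp insertion-free block (long enough
that a 300-bp window sliding every 150 bp is guaranteed to land inside it),
and one insertion per 11 bp elsewhere.  Read counts per site are geometric —
they are carried for format realism only; the analysis uses unique sites.

All randomness flows through ``numpy.random.default_rng`` seeded from
``SimConfig.seed``; identical configs give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BlastHit, GeneFeature, InsertionSite

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_insertions",
    "simulate_blast_universe",
]

logger = logging.getLogger(__name__)

TRUTH_LABELS = ("essential", "non_essential", "domain_essential")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic library."""

    seed: int = 0
    n_genes: int = 2000
    mean_gene_length: int = 900
    intergenic_fraction: float = 0.15
    essential_fraction: float = 0.15
    domain_essential_fraction: float = 0.02
    nonessential_density: float = 1.0 / 11.0
    essential_leak_density: float = 0.0
    domain_free_block: int = 450
    min_gene_length: int = 60
    length_shape: float = 4.0  # gamma shape of the gene-length distribution

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("intergenic_fraction", "essential_fraction", "domain_essential_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.essential_fraction + self.domain_essential_fraction > 1:
            raise ValueError("essential + domain_essential fractions exceed 1")
        if self.nonessential_density < 0 or self.essential_leak_density < 0:
            raise ValueError("densities must be >= 0")
        if self.intergenic_fraction >= 1:
            raise ValueError("intergenic_fraction must be < 1")
        if self.domain_free_block < 300:
            raise ValueError("domain_free_block must be >= 300")


def simulate_genome(config: SimConfig, replicon_id: str = "chr1") -> tuple[list[GeneFeature], int]:
    """Lay out ``n_genes`` non-overlapping genes separated by intergenic gaps.

    Gene lengths are gamma distributed with mean ``mean_gene_length``; gap
    lengths are exponential with mean chosen so the expected intergenic share
    of the genome equals ``intergenic_fraction``.
    """
    rng = np.random.default_rng(config.seed)
    lengths = rng.gamma(config.length_shape, config.mean_gene_length / config.length_shape,
                        config.n_genes)
    lengths = np.maximum(np.rint(lengths).astype(int), config.min_gene_length)
    f = config.intergenic_fraction
    gap_mean = config.mean_gene_length * f / (1 - f)
    gaps = np.rint(rng.exponential(gap_mean, config.n_genes + 1)).astype(int) if gap_mean > 0 \
        else np.zeros(config.n_genes + 1, dtype=int)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    features: list[GeneFeature] = []
    pos = 1 + int(gaps[0])
    width = max(5, len(str(config.n_genes)))
    for i in range(config.n_genes):
        start = pos
        end = start + int(lengths[i]) - 1
        features.append(
            GeneFeature(replicon_id, start, end, f"g{i:0{width}d}", str(strands[i]), "CDS")
        )
        pos = end + 1 + int(gaps[i + 1])
    genome_length = features[-1].end + int(gaps[-1])
    return features, genome_length


def _bernoulli_positions(rng: np.random.Generator, start: int, end: int, density: float) -> np.ndarray:
    """Unique 1-based positions of a per-base Bernoulli(density) process on [start, end]."""
    span = end - start + 1
    if span <= 0 or density <= 0:
        return np.empty(0, dtype=np.int64)
    count = rng.binomial(span, min(density, 1.0))
    if count == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.choice(span, size=count, replace=False).astype(np.int64)) + start


def simulate_insertions(
    annotation: list[GeneFeature],
    config: SimConfig,
    genome_length: int | None = None,
) -> tuple[list[InsertionSite], dict[str, str]]:
    """Draw an insertion library over the annotation; returns (sites, truth).

    Truth labels each gene ``essential`` (leak density only),
    ``domain_essential`` (non-essential density outside one uniformly placed
    insertion-free block of ``domain_free_block`` bp) or ``non_essential``.
    A gene drawn as domain-essential but shorter than the free block is
    relabelled essential and the relabelling logged.  Intergenic sequence is
    hit at the non-essential density.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(annotation)
    order = rng.permutation(n)
    n_ess = int(round(n * config.essential_fraction))
    n_dom = int(round(n * config.domain_essential_fraction))
    truth: dict[str, str] = {}
    for rank, idx in enumerate(order):
        gene = annotation[idx]
        if rank < n_ess:
            truth[gene.feature_id] = "essential"
        elif rank < n_ess + n_dom:
            if gene.length < config.domain_free_block:
                logger.info(
                    "gene %s (%d bp) shorter than the %d bp free block; relabelled essential",
                    gene.feature_id, gene.length, config.domain_free_block,
                )
                truth[gene.feature_id] = "essential"
            else:
                truth[gene.feature_id] = "domain_essential"
        else:
            truth[gene.feature_id] = "non_essential"

    positions: dict[str, list[np.ndarray]] = {}

    def add(replicon: str, arr: np.ndarray) -> None:
        if arr.size:
            positions.setdefault(replicon, []).append(arr)

    by_rep: dict[str, list[GeneFeature]] = {}
    for gene in annotation:
        by_rep.setdefault(gene.replicon_id, []).append(gene)

    for replicon, genes in by_rep.items():
        genes = sorted(genes, key=lambda g: g.start)
        prev_end = 0
        for gene in genes:
            # intergenic span before this gene
            add(replicon, _bernoulli_positions(rng, prev_end + 1, gene.start - 1,
                                               config.nonessential_density))
            label = truth[gene.feature_id]
            if label == "essential":
                add(replicon, _bernoulli_positions(rng, gene.start, gene.end,
                                                   config.essential_leak_density))
            elif label == "non_essential":
                add(replicon, _bernoulli_positions(rng, gene.start, gene.end,
                                                   config.nonessential_density))
            else:  # domain_essential: free block placed uniformly inside the gene
                block_offset = int(rng.integers(0, gene.length - config.domain_free_block + 1))
                block_start = gene.start + block_offset
                block_end = block_start + config.domain_free_block - 1
                add(replicon, _bernoulli_positions(rng, gene.start, block_start - 1,
                                                   config.nonessential_density))
                add(replicon, _bernoulli_positions(rng, block_end + 1, gene.end,
                                                   config.nonessential_density))
            prev_end = max(prev_end, gene.end)
        if genome_length is not None and genome_length > prev_end:
            add(replicon, _bernoulli_positions(rng, prev_end + 1, genome_length,
                                               config.nonessential_density))

    sites: list[InsertionSite] = []
    for replicon in sorted(positions):
        pos = np.unique(np.concatenate(positions[replicon]))
        counts = rng.geometric(0.5, size=pos.size)
        sites.extend(
            InsertionSite(replicon, int(p), int(c)) for p, c in zip(pos, counts)
        )
    return sites, truth


def simulate_blast_universe(
    n_families: int,
    family_sizes: Sequence[int],
    config: SimConfig,
) -> tuple[dict[str, int], list[BlastHit], dict[str, set[str]], list[frozenset[str]]]:
    """Toy all-vs-all proteome with planted paralog families.

    Returns ``(protein_lengths, hits, cog_map, truth_groups)``.  Within-family
    pairs get mutual hits comfortably above the paralog similarity thresholds
    (60% length rule, 0.1x Max_bit_score with a shared COG); between-family
    hits, when present, score below 0.1x the largest self score.  Every
    protein has a self-hit, and each family carries its own COG label.  Truth
    groups are the families of size >= 2.
    """
    if len(family_sizes) != n_families:
        raise ValueError("family_sizes must list one size per family")
    if any(s < 1 for s in family_sizes):
        raise ValueError("family sizes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lengths: dict[str, int] = {}
    cog_map: dict[str, set[str]] = {}
    families: list[list[str]] = []
    for fam, size in enumerate(family_sizes):
        base = int(rng.integers(200, 601))
        members = []
        for i in range(size):
            pid = f"F{fam:03d}_{i:02d}"
            lengths[pid] = max(50, int(round(base * rng.uniform(0.85, 1.0))))
            cog_map[pid] = {f"COG{fam:03d}"}
            members.append(pid)
        families.append(members)

    def hit(q: str, s: str, bit: float) -> BlastHit:
        aln = min(lengths[q], lengths[s])
        return BlastHit(
            query_id=q, subject_id=s, percent_identity=80.0, alignment_length=aln,
            evalue=1e-50, bit_score=float(bit),
            query_length=lengths[q], subject_length=lengths[s],
            query_cov=100.0 * aln / lengths[q], subject_cov=100.0 * aln / lengths[s],
        )

    hits: list[BlastHit] = []
    self_score = {pid: 2.0 * lengths[pid] for pid in lengths}
    for pid, score in self_score.items():
        hits.append(hit(pid, pid, score))
    for members in families:
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                strong = 0.6 * min(self_score[a], self_score[b])
                hits.append(hit(a, b, strong))
                hits.append(hit(b, a, strong * rng.uniform(0.95, 1.0)))
    # sparse weak background between families, below every similarity cutoff
    max_self = max(self_score.values())
    all_ids = sorted(lengths)
    n_noise = min(len(all_ids), 3 * n_families)
    for _ in range(n_noise):
        a, b = rng.choice(all_ids, size=2, replace=False)
        if cog_map[a] == cog_map[b]:
            continue
        hits.append(hit(str(a), str(b), 0.05 * max_self * rng.uniform(0.2, 1.0)))

    truth = [frozenset(m) for m in families if len(m) >= 2]
    return lengths, hits, cog_map, truth
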