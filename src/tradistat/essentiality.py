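"""Insertion-index computation and the two-component essentiality model.

The statistic is the *insertion index*: the number of unique transposon
insertion sites inside a feature divided by its length in bp.  In a saturated
library its distribution over genes is bimodal — a spike at (near) zero for
essential genes and a broad mode around the genome-wide insertion density for
dispensable genes.

Because the two modes overlap, the index range is split into three sections at
manually chosen cutoffs (defaults 0.013, 0.022, 0.25):

* indices in ``[0, cutoff_low)`` fit an exponential distribution (the
  essential mode; closed-form MLE ``rate = n / sum(x)``, zeros included);
* indices in ``[cutoff_mid, cutoff_high]`` fit a gamma distribution (the
  dispensable mode; numerical MLE with location fixed at 0);
* the transition band ``[cutoff_low, cutoff_mid)`` and outliers above
  ``cutoff_high`` are excluded from fitting but still scored.

Each gene is then scored with ``log2(f_exp(x) / f_gamma(x))`` and called
essential when the score exceeds ``log2(k)`` (default k = 12, i.e. at least
12 times more likely under the essential mode), non-essential below
``-log2(k)`` and unclear in between.  An index of exactly zero scores the
``+inf`` sentinel: the gamma density vanishes at 0 for shape > 1, so a
zero-index gene is always at least as essential-looking as any gene with
insertions.

Degenerate edge: when every index in the first section is zero the
exponential MLE is ``rate = +inf`` (a point mass at zero).  Scores remain
well defined: ``+inf`` at index 0 and ``-inf`` elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneFeature, InsertionSite

__all__ = [
    "InsertionIndexRecord",
    "MixtureFit",
    "EssentialityCall",
    "DEFAULT_CUTOFFS",
    "DEFAULT_K_THRESHOLD",
    "sites_by_replicon",
    "insertion_index_table",
    "library_summary",
    "fit_mixture",
    "log_likelihood_score",
    "classify",
]

DEFAULT_CUTOFFS = (0.013, 0.022, 0.25)
DEFAULT_K_THRESHOLD = 12.0


@dataclass(frozen=True)
class InsertionIndexRecord:
    """Per-feature unique-insertion count normalized by feature length."""

    feature_id: str
    replicon_id: str
    length_bp: int
    unique_insertions: int
    insertion_index: float


@dataclass(frozen=True)
class MixtureFit:
    """Fitted exponential (essential) and gamma (dispensable) components."""

    exp_rate: float
    gamma_shape: float
    gamma_scale: float
    cutoff_low: float = DEFAULT_CUTOFFS[0]
    cutoff_mid: float = DEFAULT_CUTOFFS[1]
    cutoff_high: float = DEFAULT_CUTOFFS[2]
    n_exp_fit: int = 0
    n_gamma_fit: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cutoff_low < self.cutoff_mid < self.cutoff_high):
            raise ValueError("cutoffs must satisfy 0 < low < mid < high")
        if self.exp_rate <= 0 or self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("fitted parameters must be strictly positive")

    @property
    def gamma_mean(self) -> float:
        """Mean insertion index of the dispensable component (shape * scale)."""
        return self.gamma_shape * self.gamma_scale


@dataclass(frozen=True)
class EssentialityCall:
    feature_id: str
    replicon_id: str
    length_bp: int
    unique_insertions: int
    insertion_index: float
    log_likelihood_score: float
    label: str


def sites_by_replicon(insertions: list[InsertionSite]) -> dict[str, np.ndarray]:
    """Sorted arrays of unique site positions keyed by replicon."""
    grouped: dict[str, list[int]] = {}
    for site in insertions:
        grouped.setdefault(site.replicon_id, []).append(site.position)
    return {rep: np.unique(np.asarray(pos, dtype=np.int64)) for rep, pos in grouped.items()}


def count_in_interval(positions: np.ndarray, start: int, end: int) -> int:
    """Number of sorted positions p with start <= p <= end (1-based inclusive)."""
    return int(np.searchsorted(positions, end, side="right") - np.searchsorted(positions, start, side="left"))


def insertion_index_table(
    annotation: list[GeneFeature], insertions: list[InsertionSite]
) -> list[InsertionIndexRecord]:
    """One record per annotated feature; overlapping features each count shared sites."""
    by_rep = sites_by_replicon(insertions)
    records = []
    for gene in annotation:
        if gene.length <= 0:
            raise ValueError(f"{gene.feature_id}: zero-length feature")
        positions = by_rep.get(gene.replicon_id, np.empty(0, dtype=np.int64))
        n = count_in_interval(positions, gene.start, gene.end)
        records.append(
            InsertionIndexRecord(
                feature_id=gene.feature_id,
                replicon_id=gene.replicon_id,
                length_bp=gene.length,
                unique_insertions=n,
                insertion_index=n / gene.length,
            )
        )
    return records


def library_summary(
    annotation: list[GeneFeature],
    insertions: list[InsertionSite],
    replicon_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-replicon saturation summary.

    Columns: unique insertion sites, genic/intergenic split (a site is genic
    when it falls inside at least one feature) and the headline
    bp-per-insertion figure ``round(replicon_length / unique_sites)``.
    """
    by_rep = sites_by_replicon(insertions)
    rows = []
    for rep, length in replicon_lengths.items():
        positions = by_rep.get(rep, np.empty(0, dtype=np.int64))
        genic_mask = np.zeros(positions.shape, dtype=bool)
        for gene in annotation:
            if gene.replicon_id != rep:
                continue
            lo = np.searchsorted(positions, gene.start, side="left")
            hi = np.searchsorted(positions, gene.end, side="right")
            genic_mask[lo:hi] = True
        total = int(positions.size)
        genic = int(genic_mask.sum())
        rows.append(
            {
                "replicon_id": rep,
                "length_bp": int(length),
                "unique_sites": total,
                "genic_sites": genic,
                "intergenic_sites": total - genic,
                "bp_per_insertion": round(length / total) if total else math.inf,
            }
        )
    return pd.DataFrame(rows).set_index("replicon_id")


def fit_mixture(
    indices,
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
    min_section: int = 5,
) -> MixtureFit:
    """Fit the sectioned exponential + gamma model to insertion indices.

    ``indices`` is any sequence of per-gene insertion indices (records from
    :func:`insertion_index_table` are accepted too).  Raises ``ValueError``
    when a fitting section holds fewer than ``min_section`` observations —
    the cutoffs then need manual adjustment — and ``RuntimeError`` when the
    gamma MLE fails to converge to finite positive parameters.
    """
    x = np.asarray(
        [r.insertion_index if isinstance(r, InsertionIndexRecord) else float(r) for r in indices],
        dtype=float,
    )
    low, mid, high = cutoffs
    if not 0 < low < mid < high:
        raise ValueError("cutoffs must satisfy 0 < low < mid < high")
    sec1 = x[x < low]
    sec2 = x[(x >= mid) & (x <= high)]
    if sec1.size < min_section:
        raise ValueError(
            f"exponential section [0, {low}) holds {sec1.size} < {min_section} observations; "
            "adjust the cutoffs"
        )
    if sec2.size < min_section:
        raise ValueError(
            f"gamma section [{mid}, {high}] holds {sec2.size} < {min_section} observations; "
            "adjust the cutoffs"
        )
    total = float(sec1.sum())
    exp_rate = sec1.size / total if total > 0 else math.inf  # point mass at 0 limit
    shape, _, scale = stats.gamma.fit(sec2, floc=0)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise RuntimeError(
            f"gamma MLE did not converge (shape={shape}, scale={scale}, n={sec2.size}, "
            f"section mean={sec2.mean():.5g})"
        )
    return MixtureFit(
        exp_rate=exp_rate,
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        cutoff_low=low,
        cutoff_mid=mid,
        cutoff_high=high,
        n_exp_fit=int(sec1.size),
        n_gamma_fit=int(sec2.size),
    )


_LN2 = math.log(2.0)


def log_likelihood_score(index: float, fit: MixtureFit) -> float:
    """``log2(f_exp(index) / f_gamma(index))``; +inf sentinel at index 0."""
    if index < 0:
        raise ValueError(f"insertion index must be >= 0, got {index}")
    if index == 0:
        return math.inf
    if math.isinf(fit.exp_rate):
        return -math.inf  # degenerate point-mass component has no density off 0
    log2_exp = math.log2(fit.exp_rate) - fit.exp_rate * index / _LN2
    log2_gamma = float(stats.gamma.logpdf(index, fit.gamma_shape, scale=fit.gamma_scale)) / _LN2
    return log2_exp - log2_gamma


def classify(
    index_table: list[InsertionIndexRecord],
    fit: MixtureFit,
    k_threshold: float = DEFAULT_K_THRESHOLD,
) -> list[EssentialityCall]:
    """Label every feature essential / non_essential / unclear by its score.

    Strict inequalities: a score of exactly ``log2(k_threshold)`` (or its
    negative) stays unclear.
    """
    if k_threshold <= 1:
        raise ValueError("k_threshold must exceed 1")
    t = math.log2(k_threshold)
    calls = []
    for rec in index_table:
        s = log_likelihood_score(rec.insertion_index, fit)
        if s > t:
            label = "essential"
        elif s < -t:
            label = "non_essential"
        else:
            label = "unclear"
        calls.append(
            EssentialityCall(
                feature_id=rec.feature_id,
                replicon_id=rec.replicon_id,
                length_bp=rec.length_bp,
                unique_insertions=rec.unique_insertions,
                insertion_index=rec.insertion_index,
                log_likelihood_score=s,
                label=label,
            )
        )
    return calls
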