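"""Readers and writers for the standard formats the pipeline touches.

Everything is normalized into a small internal data model:

* :class:`GeneFeature` — one annotated feature, 1-based inclusive coordinates
  (the GFF3 convention; BED input is converted on read).
* :class:`InsertionSite` — one unique transposon junction position with its
  read support.  Orientation is collapsed: a position is one site regardless
  of the strand the junction reads mapped to.
* :class:`BlastHit` — one row of BLAST tabular output (outfmt 6), optionally
  extended with query/subject lengths from which alignment coverage is
  computed.

Supported annotation dialects: GFF3 and a flat ``feature_tsv`` with columns
``feature_id, replicon_id, start, end, strand, kind``.  Supported insertion
dialects: ``plot`` (one line per genome position, two whitespace-separated
read-count columns that are summed), ``bed`` (0-based half-open single-base
intervals, score column = read count) and ``tsv``
(``replicon_id, position, read_count``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneFeature",
    "InsertionSite",
    "BlastHit",
    "ParseError",
    "FEATURE_KINDS",
    "CALL_LABELS",
    "read_annotation",
    "write_annotation",
    "read_insertions",
    "write_insertions",
    "read_blast_tabular",
    "self_scores",
    "write_calls",
    "read_calls",
]

#: Feature kinds retained from annotation input.  Pseudogenes, tRNA and rRNA
#: are analyzed exactly like CDS downstream.
FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "ncRNA", "pseudogene", "other")

#: The four-value call vocabulary used throughout the pipeline.
CALL_LABELS = ("essential", "non_essential", "unclear", "domain_essential")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True, order=True)
class GeneFeature:
    """One annotated genomic feature on a replicon (1-based, inclusive)."""

    replicon_id: str
    start: int
    end: int
    feature_id: str
    strand: str = "+"
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.feature_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.feature_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be + or -, got {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"{self.feature_id}: unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, order=True)
class InsertionSite:
    """A unique transposon junction position with its read support."""

    replicon_id: str
    position: int
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"insertion position must be >= 1, got {self.position}")
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")


@dataclass(frozen=True)
class BlastHit:
    """One BLAST tabular row with derived alignment coverage.

    ``query_cov``/``subject_cov`` are ``100 * alignment_length / length`` and
    are NaN when the input table carried no qlen/slen columns.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_length: int | None = None
    subject_length: int | None = None
    query_cov: float = math.nan
    subject_cov: float = math.nan

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_GFF3_KINDS = {"CDS", "tRNA", "rRNA", "ncRNA", "pseudogene"}


def _gff3_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_annotation(path: str | Path, format: str = "gff3") -> list[GeneFeature]:
    """Read an annotation file into a sorted list of :class:`GeneFeature`.

    Only CDS/tRNA/rRNA/ncRNA/pseudogene records are emitted (GFF3 ``gene``
    and ``exon`` wrappers are skipped); output is sorted by
    ``(replicon_id, start)``.  Duplicate feature ids are a hard error.
    """
    path = Path(path)
    features: list[GeneFeature] = []
    if format == "gff3":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ParseError(
                        f"{path}:{lineno}: expected 9 tab-separated GFF3 columns, got {len(cols)}"
                    )
                seqid, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
                if ftype not in _GFF3_KINDS:
                    continue
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
                attrs = _gff3_attributes(attrs_s)
                fid = attrs.get("ID") or attrs.get("locus_tag")
                if not fid:
                    raise ParseError(f"{path}:{lineno}: feature has no ID or locus_tag attribute")
                try:
                    features.append(
                        GeneFeature(seqid, start, end, fid, strand if strand in "+-" else "+", ftype)
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
    elif format == "feature_tsv":
        table = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "replicon_id": str})
        required = {"feature_id", "replicon_id", "start", "end", "strand", "kind"}
        missing = required - set(table.columns)
        if missing:
            raise ParseError(f"{path}: feature_tsv is missing columns {sorted(missing)}")
        for row in table.itertuples(index=False):
            features.append(
                GeneFeature(
                    str(row.replicon_id), int(row.start), int(row.end),
                    str(row.feature_id), str(row.strand), str(row.kind),
                )
            )
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    seen: set[str] = set()
    for feat in features:
        if feat.feature_id in seen:
            raise ParseError(f"{path}: duplicate feature_id {feat.feature_id!r}")
        seen.add(feat.feature_id)
    features.sort(key=lambda f: (f.replicon_id, f.start, f.feature_id))
    return features


def write_annotation(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as minimal GFF3 (source ``tradistat``, ID attribute)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.replicon_id}\ttradistat\t{f.kind}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# insertion sites
# ---------------------------------------------------------------------------

def _merge_sites(raw: Iterable[tuple[str, int, int]], source: str) -> list[InsertionSite]:
    counts: dict[tuple[str, int], int] = {}
    for replicon, position, count in raw:
        if position < 0 or count < 0:
            raise ParseError(f"{source}: negative position or count ({position}, {count})")
        if count == 0:
            continue
        if position < 1:
            raise ParseError(f"{source}: position {position} is not 1-based")
        counts[(replicon, position)] = counts.get((replicon, position), 0) + count
    return [
        InsertionSite(rep, pos, n)
        for (rep, pos), n in sorted(counts.items())
    ]


def read_insertions(
    path: str | Path, format: str = "tsv", replicon_id: str | None = None
) -> list[InsertionSite]:
    """Read mapped insertion sites, merging duplicates and dropping zeros.

    ``plot`` files carry no replicon name, so ``replicon_id`` is required for
    that dialect; line number = genome position, the two count columns
    (forward/reverse junction reads) are summed.  BED input must be 0-based
    half-open single-base intervals; its score column is the read count.
    """
    path = Path(path)
    raw: list[tuple[str, int, int]] = []
    if format == "plot":
        if replicon_id is None:
            raise ValueError("plot format carries no replicon name; pass replicon_id=")
        with path.open() as fh:
            for position, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                try:
                    count = sum(int(p) for p in parts)
                except ValueError as exc:
                    raise ParseError(f"{path}:{position}: non-integer count") from exc
                raw.append((replicon_id, position, count))
    elif format == "bed":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 5:
                    raise ParseError(f"{path}:{lineno}: BED needs >=5 columns (score = read count)")
                chrom, start_s, end_s, _, score_s = cols[:5]
                try:
                    start, end, count = int(start_s), int(end_s), int(float(score_s))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric BED fields") from exc
                if end - start != 1:
                    raise ParseError(
                        f"{path}:{lineno}: insertion BED intervals must be single-base "
                        f"(got [{start},{end}))"
                    )
                raw.append((chrom, start + 1, count))  # 0-based half-open -> 1-based
    elif format == "tsv":
        table = pd.read_csv(path, sep="\t", dtype={"replicon_id": str})
        required = {"replicon_id", "position", "read_count"}
        missing = required - set(table.columns)
        if missing:
            raise ParseError(f"{path}: insertion TSV is missing columns {sorted(missing)}")
        for row in table.itertuples(index=False):
            raw.append((str(row.replicon_id), int(row.position), int(row.read_count)))
    else:
        raise ValueError(f"unknown insertion format {format!r}")
    return _merge_sites(raw, str(path))


def write_insertions(sites: Iterable[InsertionSite], path: str | Path) -> None:
    """Write sites as the TSV dialect (round-trips through read_insertions)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("replicon_id\tposition\tread_count\n")
        for s in sorted(sites):
            fh.write(f"{s.replicon_id}\t{s.position}\t{s.read_count}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path, with_lengths: bool = False) -> list[BlastHit]:
    """Read BLAST outfmt-6 rows, optionally with appended qlen/slen columns.

    When lengths are present, alignment coverage is derived as
    ``100 * alignment_length / qlen`` (and ``/ slen``).
    """
    path = Path(path)
    names = _BLAST6_COLUMNS + (["qlen", "slen"] if with_lengths else [])
    try:
        table = pd.read_csv(
            path, sep="\t", header=None, names=names, comment="#",
            dtype={0: str, 1: str},
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if table.shape[1] != len(names):
        raise ParseError(f"{path}: expected {len(names)} columns, found {table.shape[1]}")
    if table[names].isna().any().any():
        bad = int(table[table[names].isna().any(axis=1)].index[0]) + 1
        raise ParseError(f"{path}:{bad}: row has fewer columns than declared")
    hits: list[BlastHit] = []
    for row in table.itertuples(index=False):
        qlen = int(row.qlen) if with_lengths else None
        slen = int(row.slen) if with_lengths else None
        aln = int(row.length)
        hits.append(
            BlastHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                percent_identity=float(row.pident),
                alignment_length=aln,
                evalue=float(row.evalue),
                bit_score=float(row.bitscore),
                query_length=qlen,
                subject_length=slen,
                query_cov=100.0 * aln / qlen if qlen else math.nan,
                subject_cov=100.0 * aln / slen if slen else math.nan,
            )
        )
    return hits


def self_scores(hits: Iterable[BlastHit]) -> dict[str, float]:
    """Best self-comparison bit score per protein (query == subject rows)."""
    out: dict[str, float] = {}
    for h in hits:
        if h.is_self:
            out[h.query_id] = max(out.get(h.query_id, -math.inf), h.bit_score)
    return out


# ---------------------------------------------------------------------------
# essentiality calls
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "feature_id", "replicon", "length_bp", "unique_insertions",
    "insertion_index", "log_likelihood_score", "label",
]


def write_calls(calls: Sequence, path: str | Path) -> None:
    """Write essentiality calls as TSV; floats use repr so reads round-trip."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            if c.label not in CALL_LABELS:
                raise ValueError(f"{c.feature_id}: unknown label {c.label!r}")
            fh.write(
                f"{c.feature_id}\t{c.replicon_id}\t{c.length_bp}\t{c.unique_insertions}\t"
                f"{c.insertion_index!r}\t{c.log_likelihood_score!r}\t{c.label}\n"
            )


def read_calls(path: str | Path) -> list:
    """Read a calls TSV back into :class:`~tradistat.essentiality.EssentialityCall`."""
    from .essentiality import EssentialityCall  # local import avoids a cycle

    path = Path(path)
    calls: list[EssentialityCall] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CALL_COLUMNS:
            raise ParseError(f"{path}: unexpected calls header {header}")
        for lineno, line in enumerate(fh, start=2):
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(_CALL_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_CALL_COLUMNS)} columns")
            fid, rep, length, nins, idx, score, label = cols
            if label not in CALL_LABELS:
                raise ParseError(f"{path}:{lineno}: unknown label {label!r}")
            calls.append(
                EssentialityCall(
                    feature_id=fid, replicon_id=rep, length_bp=int(length),
                    unique_insertions=int(nins), insertion_index=float(idx),
                    log_likelihood_score=float(score), label=label,
                )
            )
    return calls
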