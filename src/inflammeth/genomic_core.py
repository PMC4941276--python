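"""Genomic coordinate primitives and CpG context annotation.

All internal coordinates are 0-based half-open (BED convention). Array-style
probe manifests that are distributed 1-based are converted on read
(``manifest_base=1``, the default for :func:`read_manifest`).

A CpG probe is treated as a single base position (the interrogated cytosine);
overlap with a feature means that base falls inside the interval. Strand is
ignored for probe positions; gene strand is used only to place the TSS.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomePosition",
    "Interval",
    "CgiContext",
    "GeneContext",
    "FeatureSet",
    "GeneModel",
    "ProbeManifest",
    "read_feature_bed",
    "write_feature_bed",
    "read_manifest",
    "write_manifest",
    "read_gene_models",
    "write_gene_models",
    "annotate_cgi_context",
    "annotate_gene_context",
]

#: CpG-island shore extends up to this many bp from an island edge.
SHORE_MAX_BP = 2_000
#: Shelf extends from the shore edge up to this many bp; beyond is open sea.
SHELF_MAX_BP = 4_000
#: Default promoter half-width around the TSS, in bp.
PROMOTER_HALFWIDTH_BP = 2_500


class GenomePosition(NamedTuple):
    """A single 0-based base position on a named chromosome."""

    chrom: str
    pos: int

    def validate(self) -> "GenomePosition":
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        return self


class Interval(NamedTuple):
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def validate(self) -> "Interval":
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        return self

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class CgiContext(str, Enum):
    """CpG-island context of a probe: island, shore (<=2 kb), shelf (2-4 kb), open sea (>4 kb)."""

    island = "island"
    shore = "shore"
    shelf = "shelf"
    open_sea = "open_sea"


class GeneContext(str, Enum):
    """Gene context with precedence promoter > exon > intron > intergenic."""

    promoter = "promoter"
    exon = "exon"
    intron = "intron"
    intergenic = "intergenic"


class _ChromIndex:
    """Sorted-start interval index for one chromosome.

    Intervals may overlap each other, so point/interval stabs use the running
    maximum of the end coordinates: every interval with start <= x is at a
    sorted-array prefix, and the prefix cum-max of ends tells whether any of
    them extends past x. All queries are O(log n).
    """

    __slots__ = ("starts", "ends", "cummax_ends")

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.lexsort((ends, starts))
        self.starts = starts[order]
        self.ends = ends[order]
        self.cummax_ends = np.maximum.accumulate(self.ends)

    def __len__(self) -> int:
        return len(self.starts)

    def contains_point(self, pos: int) -> bool:
        idx = int(np.searchsorted(self.starts, pos, side="right"))
        return idx > 0 and int(self.cummax_ends[idx - 1]) > pos

    def overlaps_interval(self, start: int, end: int) -> bool:
        idx = int(np.searchsorted(self.starts, end, side="left"))
        return idx > 0 and int(self.cummax_ends[idx - 1]) > start

    def distance_to_point(self, pos: int) -> int:
        if self.contains_point(pos):
            return 0
        idx = int(np.searchsorted(self.starts, pos, side="right"))
        candidates = []
        if idx > 0:
            # pos lies at or beyond the rightmost covered base of the prefix;
            # half-open end, so the gap is pos - end (spec convention).
            candidates.append(pos - int(self.cummax_ends[idx - 1]))
        if idx < len(self.starts):
            candidates.append(int(self.starts[idx]) - pos)
        return min(candidates)


class FeatureSet:
    """A named, sorted collection of half-open genomic intervals.

    Supports O(log n) point-overlap, interval-overlap and nearest-distance
    queries per chromosome.
    """

    def __init__(self, name: str, intervals: Iterable[Interval | tuple] = ()):
        self.name = name
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            iv = Interval(*iv).validate()
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: dict[str, _ChromIndex] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._index[chrom] = _ChromIndex(arr[:, 0], arr[:, 1])

    @property
    def intervals(self) -> list[Interval]:
        """All intervals, sorted by (chrom, start)."""
        out: list[Interval] = []
        for chrom in sorted(self._index):
            idx = self._index[chrom]
            out.extend(
                Interval(chrom, int(s), int(e)) for s, e in zip(idx.starts, idx.ends)
            )
        return out

    @property
    def chroms(self) -> list[str]:
        return sorted(self._index)

    def __len__(self) -> int:
        return sum(len(ix) for ix in self._index.values())

    def __iter__(self):
        return iter(self.intervals)

    def overlaps(self, pos: GenomePosition | tuple) -> bool:
        """True iff some interval satisfies start <= pos < end."""
        chrom, p = GenomePosition(*pos)
        ix = self._index.get(chrom)
        return ix is not None and ix.contains_point(int(p))

    def overlaps_interval(self, query: Interval | tuple) -> bool:
        """True iff some interval shares >= 1 bp with the query interval."""
        q = Interval(*query)
        ix = self._index.get(q.chrom)
        return ix is not None and ix.overlaps_interval(q.start, q.end)

    def distance_to_nearest(self, pos: GenomePosition | tuple) -> int | None:
        """Distance in bp to the nearest interval on the same chromosome.

        0 when ``pos`` falls inside an interval; ``None`` when the chromosome
        carries no feature (caller decides how to treat it).
        """
        chrom, p = GenomePosition(*pos)
        ix = self._index.get(chrom)
        if ix is None:
            return None
        return ix.distance_to_point(int(p))


@dataclass
class GeneModel:
    """Minimal gene model: strand-aware TSS plus sorted, non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e:
                raise ValueError(f"exons of {self.gene_id} overlap")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"invalid exon [{s}, {e}) in {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent from first exon start to last exon end."""
        if not self.exons:
            return (self.tss, self.tss + 1)
        return (self.exons[0][0], self.exons[-1][1])


class ProbeManifest:
    """Array manifest mapping probe ids to genomic positions.

    Optionally carries per-probe CGI and gene context annotations (filled by
    :meth:`annotate`).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if table["probe_id"].duplicated().any():
            dupes = table.loc[table["probe_id"].duplicated(), "probe_id"].head(3).tolist()
            raise ValueError(f"duplicate probe ids in manifest, e.g. {dupes}")
        if (table["pos"] < 0).any():
            raise ValueError("manifest positions must be >= 0")
        self.table = table.reset_index(drop=True)
        self._by_id = self.table.set_index("probe_id")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def position(self, probe_id: str) -> GenomePosition:
        try:
            row = self._by_id.loc[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe id: {probe_id}") from None
        return GenomePosition(str(row["chrom"]), int(row["pos"]))

    def positions(self, probe_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """(chrom, pos) rows for the requested probes (all probes if None)."""
        if probe_ids is None:
            return self.table[["probe_id", "chrom", "pos"]].copy()
        ids = pd.Index(probe_ids)
        unknown = ids.difference(self._by_id.index)
        if len(unknown):
            raise KeyError(f"unknown probe ids, e.g. {list(unknown[:3])}")
        sub = self._by_id.loc[ids, ["chrom", "pos"]].reset_index()
        return sub

    def annotate(
        self,
        cgis: FeatureSet,
        genes: Sequence[GeneModel],
        promoter_halfwidth: int = PROMOTER_HALFWIDTH_BP,
    ) -> pd.DataFrame:
        """Attach CGI and gene context columns; returns the annotated table."""
        positions = [GenomePosition(c, int(p)) for c, p in zip(self.table["chrom"], self.table["pos"])]
        annot = _GeneAnnotator(genes, promoter_halfwidth)
        self.table["cgi_context"] = [annotate_cgi_context(gp, cgis).value for gp in positions]
        self.table["gene_context"] = [annot(gp).value for gp in positions]
        self._by_id = self.table.set_index("probe_id")
        return self.table


def annotate_cgi_context(pos: GenomePosition | tuple, cgis: FeatureSet) -> CgiContext:
    """Classify a position as island / shore / shelf / open sea.

    Island: inside a CGI. Shore: within 2 kb of one. Shelf: 2-4 kb.
    Open sea: more than 4 kb from the closest CGI (a chromosome with no CGI
    is entirely open sea).
    """
    d = cgis.distance_to_nearest(pos)
    if d is None:
        return CgiContext.open_sea
    if d == 0:
        return CgiContext.island
    if d <= SHORE_MAX_BP:
        return CgiContext.shore
    if d <= SHELF_MAX_BP:
        return CgiContext.shelf
    return CgiContext.open_sea


class _GeneAnnotator:
    """Precomputed promoter/exon/span feature sets for fast gene-context calls."""

    def __init__(self, genes: Sequence[GeneModel], promoter_halfwidth: int):
        promoters, exons, spans = [], [], []
        for g in genes:
            promoters.append((g.chrom, max(0, g.tss - promoter_halfwidth), g.tss + promoter_halfwidth + 1))
            for s, e in g.exons:
                exons.append((g.chrom, s, e))
            s, e = g.span
            spans.append((g.chrom, s, e))
        self.promoters = FeatureSet("promoters", promoters)
        self.exons = FeatureSet("exons", exons)
        self.spans = FeatureSet("spans", spans)

    def __call__(self, pos: GenomePosition | tuple) -> GeneContext:
        if self.promoters.overlaps(pos):
            return GeneContext.promoter
        if self.exons.overlaps(pos):
            return GeneContext.exon
        if self.spans.overlaps(pos):
            return GeneContext.intron
        return GeneContext.intergenic


def annotate_gene_context(
    pos: GenomePosition | tuple,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH_BP,
) -> GeneContext:
    """Classify a position with precedence promoter > exon > intron > intergenic.

    Promoter: within ``promoter_halfwidth`` bp of any TSS. Exon: inside any
    exon. Intron: inside a gene span but not an exon. Else intergenic.
    """
    return _GeneAnnotator(genes, promoter_halfwidth)(pos)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_feature_bed(path: str | Path | io.TextIOBase, name: str | None = None) -> FeatureSet:
    """Read a BED3+ file into a sorted FeatureSet.

    BED is 0-based half-open; columns beyond the third are ignored; track /
    browser / comment header lines are skipped. Malformed lines raise a
    ValueError naming the offending line number.
    """
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
        label = name if name is not None else Path(path).stem
    else:
        handle, close, label = path, False, (name or "features")
    intervals: list[Interval] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 tab-separated fields")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates {s!r}, {e!r}") from None
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise ValueError(f"line {lineno}: negative start {start}")
            intervals.append(Interval(chrom, start, end))
    finally:
        if close:
            handle.close()
    return FeatureSet(label, intervals)


def write_feature_bed(features: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in features.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_manifest(path: str | Path, manifest_base: int = 1) -> ProbeManifest:
    """Read a probe manifest TSV (columns probe_id, chrom, pos).

    ``manifest_base=1`` (default, matching array manifests) converts positions
    to internal 0-based coordinates; pass 0 for already-0-based files.
    """
    if manifest_base not in (0, 1):
        raise ValueError("manifest_base must be 0 or 1")
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    table["pos"] = table["pos"].astype(np.int64) - manifest_base
    return ProbeManifest(table)


def write_manifest(manifest: ProbeManifest, path: str | Path, manifest_base: int = 1) -> None:
    out = manifest.table.copy()
    out["pos"] = out["pos"] + manifest_base
    out.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from TSV: gene_id, chrom, strand, tss, exon_starts, exon_ends.

    Exon start/end lists are comma-separated, 0-based half-open.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for _, row in table.iterrows():
        starts = [int(x) for x in str(row["exon_starts"]).split(",") if x]
        ends = [int(x) for x in str(row["exon_ends"]).split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(f"gene {row['gene_id']}: exon_starts/exon_ends length mismatch")
        genes.append(
            GeneModel(
                gene_id=str(row["gene_id"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                tss=int(row["tss"]),
                exons=list(zip(starts, ends)),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
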