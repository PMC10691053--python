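"""Genome models and genomic interval sets.

All coordinates are 0-based half-open throughout the package (BED
convention).  A :class:`GenomeModel` holds chromosome lengths and gene
models (TSS/TTS, strand, exons, optional CDS span); a :class:`FeatureSet`
is an ordered collection of genomic intervals, the common currency for
bins, peaks and merged open-chromatin features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tts", "exons", "cds_start", "cds_end"]


@dataclass
class GenomeModel:
    """Chromosome table plus gene models.

    Parameters
    ----------
    chromosomes
        Mapping chromosome name -> length in bp.  Insertion order defines
        the canonical chromosome sort order.
    genes
        DataFrame with columns ``gene_id, chrom, strand, tss, tts, exons,
        cds_start, cds_end``.  ``tss > tts`` on the minus strand; ``exons``
        holds a list of half-open ``(start, end)`` tuples in genomic order.
        ``cds_start``/``cds_end`` are genomic (strand-agnostic) bounds of
        the coding span and may be NaN for non-coding models.
    """

    chromosomes: dict[str, int]
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if len(self.genes):
            bad = set(self.genes["chrom"]) - set(self.chromosomes)
            if bad:
                raise ValueError(f"genes on unknown chromosomes: {sorted(bad)}")

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def chrom_order(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.chromosomes)}

    def gene_spans(self) -> pd.DataFrame:
        """Per-gene genomic span [start, end) irrespective of strand."""
        g = self.genes
        start = np.minimum(g["tss"].to_numpy(), g["tts"].to_numpy())
        end = np.maximum(g["tss"].to_numpy(), g["tts"].to_numpy())
        return pd.DataFrame(
            {"gene_id": g["gene_id"], "chrom": g["chrom"], "start": start, "end": end,
             "strand": g["strand"]}
        )


@dataclass
class FeatureSet:
    """Ordered set of half-open genomic intervals.

    ``source`` optionally records, per interval, the set of clade ids that
    contributed it (filled in by peak merging).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    source: list[frozenset] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValueError("chrom/start/end length mismatch")
        if np.any(self.start >= self.end):
            raise ValueError("intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def names(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)]

    def sort(self, genome: GenomeModel | None = None) -> "FeatureSet":
        """Sorted copy, by (chromosome, start, end).

        Chromosomes follow the genome's order when given, else lexicographic.
        """
        if genome is not None:
            order_map = genome.chrom_order()
            ckey = np.array([order_map[c] for c in self.chrom])
        else:
            uniq = sorted(set(self.chrom))
            order_map = {c: i for i, c in enumerate(uniq)}
            ckey = np.array([order_map[c] for c in self.chrom])
        idx = np.lexsort((self.end, self.start, ckey))
        src = [self.source[i] for i in idx] if self.source is not None else None
        return FeatureSet(self.chrom[idx], self.start[idx], self.end[idx], src)

    def is_sorted(self) -> bool:
        for i in range(1, len(self)):
            if self.chrom[i] == self.chrom[i - 1] and self.start[i] < self.start[i - 1]:
                return False
        return True

    def is_disjoint(self) -> bool:
        """True when sorted intervals never overlap within a chromosome."""
        fs = self if self.is_sorted() else self.sort()
        for i in range(1, len(fs)):
            if fs.chrom[i] == fs.chrom[i - 1] and fs.start[i] < fs.end[i - 1]:
                return False
        return True

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})
        if self.source is not None:
            df["source"] = [",".join(map(str, sorted(s))) for s in self.source]
        return df

    def write_bed(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureSet":
        return cls(df["chrom"].to_numpy(dtype=object),
                   df["start"].to_numpy(), df["end"].to_numpy())

    @classmethod
    def read_bed(cls, path) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], comment="#")
        return cls.from_dataframe(df)


def bin_genome(genome: GenomeModel, width: int = 5000) -> FeatureSet:
    """Tile every chromosome into consecutive fixed-width windows.

    The last window of each chromosome is truncated at the chromosome end.
    The default 5 kb width is the standard first-pass binning for sparse
    single-cell chromatin data.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, length in genome.chromosomes.items():
        edges = np.arange(0, length, width, dtype=np.int64)
        chroms.extend([name] * len(edges))
        starts.extend(edges.tolist())
        ends.extend(np.minimum(edges + width, length).tolist())
    return FeatureSet(np.array(chroms, dtype=object), np.array(starts), np.array(ends))


def merge_intervals(features: FeatureSet, genome: GenomeModel | None = None,
                    book_ended: bool = True) -> FeatureSet:
    """Merge overlapping (and, by default, book-ended) intervals.

    Source clade sets of merged intervals are unioned.
    """
    if len(features) == 0:
        return FeatureSet(np.array([], dtype=object), np.array([], int), np.array([], int),
                          source=[] if features.source is not None else None)
    fs = features.sort(genome)
    has_src = fs.source is not None
    out_c: list = []
    out_s: list = []
    out_e: list = []
    out_src: list = []
    cur_c, cur_s, cur_e = fs.chrom[0], int(fs.start[0]), int(fs.end[0])
    cur_src = set(fs.source[0]) if has_src else set()
    for i in range(1, len(fs)):
        c, s, e = fs.chrom[i], int(fs.start[i]), int(fs.end[i])
        joined = c == cur_c and (s < cur_e or (book_ended and s == cur_e))
        if joined:
            cur_e = max(cur_e, e)
            if has_src:
                cur_src |= set(fs.source[i])
        else:
            out_c.append(cur_c); out_s.append(cur_s); out_e.append(cur_e)
            out_src.append(frozenset(cur_src))
            cur_c, cur_s, cur_e = c, s, e
            cur_src = set(fs.source[i]) if has_src else set()
    out_c.append(cur_c); out_s.append(cur_s); out_e.append(cur_e)
    out_src.append(frozenset(cur_src))
    return FeatureSet(np.array(out_c, dtype=object), np.array(out_s), np.array(out_e),
                      source=out_src if has_src else None)


def overlap_matrix_indices(features: FeatureSet, chrom: np.ndarray, start: np.ndarray,
                           end: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map query intervals onto sorted, disjoint features by >=1 bp overlap.

    Returns ``(query_idx, feature_idx)`` pairs; a query spanning several
    features yields one pair per feature hit.
    """
    qidx_all: list[np.ndarray] = []
    fidx_all: list[np.ndarray] = []
    feat_chrom = features.chrom
    for c in pd.unique(feat_chrom):
        fmask = feat_chrom == c
        fstart = features.start[fmask]
        fend = features.end[fmask]
        foffset = np.flatnonzero(fmask)
        qmask = chrom == c
        if not qmask.any():
            continue
        qs = start[qmask]
        qe = end[qmask]
        qoffset = np.flatnonzero(qmask)
        # first feature whose end > query start; first feature whose start >= query end
        lo = np.searchsorted(fend, qs, side="right")
        hi = np.searchsorted(fstart, qe, side="left")
        counts = np.maximum(hi - lo, 0)
        if counts.sum() == 0:
            continue
        qrep = np.repeat(qoffset, counts)
        frel = np.concatenate([np.arange(a, a + n) for a, n in zip(lo, counts) if n > 0])
        qidx_all.append(qrep)
        fidx_all.append(foffset[frel])
    if not qidx_all:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(qidx_all), np.concatenate(fidx_all)
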