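"""Per-clade peak calling and cross-clade peak merging.

Peaks are called independently from each clade's pooled fragments so that
small clades contribute their private accessible sites on equal footing,
then merged across clades into the common feature set.  The caller is a
self-contained Poisson-fold pileup caller: positions are candidate peak
bases when their coverage is at least ``min_fold`` times the genome-wide
mean and the one-sided Poisson tail probability at that mean is below
``alpha``; nearby candidates are merged and short intervals discarded.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import poisson

from .fragments import FragmentSet
from .genome import FeatureSet, GenomeModel, merge_intervals


def _pileup(starts: np.ndarray, ends: np.ndarray, counts: np.ndarray,
            length: int) -> np.ndarray:
    cov = np.zeros(length + 1)
    np.add.at(cov, np.clip(starts, 0, length), counts.astype(float))
    np.add.at(cov, np.clip(ends, 0, length), -counts.astype(float))
    return np.cumsum(cov)[:length]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_clade_peaks(fragments: list[FragmentSet], cells_in_clade,
                     genome: GenomeModel, clade_id=None, min_fold: float = 4.0,
                     min_width: int = 50, merge_gap: int = 100,
                     alpha: float = 0.05) -> FeatureSet:
    """Call peaks from the pooled fragments of one clade's cells.

    Parameters
    ----------
    fragments
        All samples' fragment sets; only records whose barcode is in
        ``cells_in_clade`` are used.
    cells_in_clade
        Barcodes belonging to the clade.
    genome
        Supplies chromosome lengths for the pileup and the genome-wide
        mean coverage.
    clade_id
        Recorded as the provenance of every returned peak.
    """
    cells = set(map(str, cells_in_clade))
    src_tag = frozenset() if clade_id is None else frozenset([clade_id])
    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in genome.chromosomes}
    total_bases = 0.0
    for fs in fragments:
        r = fs.records
        sub = r[r["barcode"].astype(str).isin(cells)]
        if sub.empty:
            continue
        total_bases += float(((sub["end"] - sub["start"]) * sub["count"]).sum())
        for c, grp in sub.groupby("chrom", sort=False):
            per_chrom[str(c)].append(
                np.stack([grp["start"].to_numpy(), grp["end"].to_numpy(),
                          grp["count"].to_numpy()]))
    if total_bases == 0:
        return FeatureSet(np.array([], dtype=object), np.array([], int),
                          np.array([], int), source=[])
    lam = total_bases / genome.total_length
    threshold_fold = min_fold * lam
    chroms, starts, ends = [], [], []
    for cname, length in genome.chromosomes.items():
        blocks = per_chrom[cname]
        if not blocks:
            continue
        arr = np.concatenate(blocks, axis=1)
        cov = _pileup(arr[0], arr[1], arr[2], length)
        # smallest integer coverage c with P(X >= c) < alpha at rate lam
        k_min = 0
        while poisson.sf(k_min - 1, lam) >= alpha:
            k_min += 1
        mask = (cov >= threshold_fold) & (cov >= k_min)
        runs = _runs(mask)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_width:
                chroms.append(cname)
                starts.append(s)
                ends.append(e)
    return FeatureSet(np.array(chroms, dtype=object), np.array(starts, int),
                      np.array(ends, int), source=[src_tag] * len(chroms))


def merge_peaks(peaksets: list[FeatureSet], genome: GenomeModel | None = None) -> FeatureSet:
    """Union of per-clade peak sets into the common feature space.

    Overlapping or book-ended intervals become one feature whose
    provenance is the union of contributing clades.
    """
    if not peaksets:
        return FeatureSet(np.array([], dtype=object), np.array([], int),
                          np.array([], int), source=[])
    chrom = np.concatenate([p.chrom for p in peaksets])
    start = np.concatenate([p.start for p in peaksets])
    end = np.concatenate([p.end for p in peaksets])
    source: list[frozenset] = []
    for p in peaksets:
        source.extend(p.source if p.source is not None else [frozenset()] * len(p))
    pooled = FeatureSet(chrom, start, end, source=source)
    return merge_intervals(pooled, genome)
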