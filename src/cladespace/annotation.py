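"""Characterization of a feature set against gene models.

Implements TSS distance distributions, meta-gene profiles, genomic
category annotation with a length-preserving shuffle baseline and Fisher
exact enrichment, pairwise set overlaps with a minimum-overlap rule, and
genome coverage / reference recovery percentages.

Category assignment uses the feature midpoint and a fixed precedence:
promoter (<=1 kb upstream) > promoter (1-10 kb) > 5' UTR > exon > intron
> 3' UTR > downstream (<=3 kb) > distal intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FeatureSet, GenomeModel, merge_intervals
from .metrics import benjamini_hochberg, fisher_exact_2x2

log = logging.getLogger(__name__)

CATEGORIES = [
    "promoter_le1kb",
    "promoter_1_10kb",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "downstream_le3kb",
    "distal_intergenic",
]


def _merge_pairs(pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    pairs = sorted(pairs)
    out = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    arr = np.array(out, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


class _RegionIndex:
    """Merged per-chromosome interval lists for fast point membership."""

    def __init__(self, by_chrom: dict[str, list[tuple[int, int]]]):
        self._idx = {c: _merge_pairs(iv) for c, iv in by_chrom.items()}

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        for c in pd.unique(chrom):
            if c not in self._idx:
                continue
            starts, ends = self._idx[c]
            if len(starts) == 0:
                continue
            m = chrom == c
            p = pos[m]
            i = np.searchsorted(starts, p, side="right") - 1
            hit = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
            out[m] = hit
        return out


def build_category_index(genome: GenomeModel) -> dict[str, _RegionIndex]:
    """Precompute category region indexes from the gene models."""
    regions: dict[str, dict[str, list[tuple[int, int]]]] = {
        cat: {} for cat in CATEGORIES[:-1]}

    def add(cat: str, chrom: str, s: int, e: int) -> None:
        if e > s:
            regions[cat].setdefault(chrom, []).append((int(s), int(e)))

    for g in genome.genes.itertuples(index=False):
        chrom, strand = g.chrom, g.strand
        span_s = min(g.tss, g.tts)
        span_e = max(g.tss, g.tts)
        if strand == "+":
            add("promoter_le1kb", chrom, g.tss - 1000, g.tss)
            add("promoter_1_10kb", chrom, g.tss - 10000, g.tss - 1000)
            add("downstream_le3kb", chrom, g.tts, g.tts + 3000)
        else:
            add("promoter_le1kb", chrom, g.tss, g.tss + 1000)
            add("promoter_1_10kb", chrom, g.tss + 1000, g.tss + 10000)
            add("downstream_le3kb", chrom, g.tts - 3000, g.tts)
        # introns: gene body minus exons (exons are in genomic order)
        prev = span_s
        for (es, ee) in sorted(g.exons):
            add("intron", chrom, prev, es)
            prev = max(prev, ee)
        add("intron", chrom, prev, span_e)
        has_cds = g.cds_start == g.cds_start and g.cds_end == g.cds_end  # NaN check
        for (es, ee) in g.exons:
            if has_cds:
                cs, ce = int(g.cds_start), int(g.cds_end)
                # exon category is the coding part; UTR categories take the rest
                add("exon", chrom, max(es, cs), min(ee, ce))
                if strand == "+":
                    utr5 = (max(es, span_s), min(ee, cs))
                    utr3 = (max(es, ce), min(ee, span_e))
                else:
                    utr5 = (max(es, ce), min(ee, span_e))
                    utr3 = (max(es, span_s), min(ee, cs))
                add("five_prime_utr", chrom, *utr5)
                add("three_prime_utr", chrom, *utr3)
            else:
                add("exon", chrom, es, ee)
    return {cat: _RegionIndex(by) for cat, by in regions.items()}


def annotate_features(features: FeatureSet, genome: GenomeModel,
                      index: dict[str, _RegionIndex] | None = None) -> np.ndarray:
    """Assign each feature a genomic category by midpoint and precedence."""
    if index is None:
        index = build_category_index(genome)
    mid = features.midpoints
    chrom = features.chrom
    out = np.array(["distal_intergenic"] * len(features), dtype=object)
    unassigned = np.ones(len(features), dtype=bool)
    for cat in CATEGORIES[:-1]:
        if not unassigned.any():
            break
        hit = index[cat].contains(chrom, mid) & unassigned
        out[hit] = cat
        unassigned &= ~hit
    return out


def _nearest_tss(features: FeatureSet, genome: GenomeModel) -> np.ndarray:
    """Signed strand-oriented distance from midpoint to nearest TSS.

    Positive values are downstream of the TSS (in the gene's direction);
    a midpoint exactly on a TSS is distance 0 (downstream by convention).
    """
    if not len(genome.genes):
        raise ValueError("genome has no genes")
    mid = features.midpoints
    dist = np.full(len(features), np.inf)
    for c in pd.unique(features.chrom):
        genes = genome.genes[genome.genes["chrom"] == c]
        m = features.chrom == c
        if genes.empty:
            continue
        tss = genes["tss"].to_numpy()[None, :]
        sgn = np.where(genes["strand"].to_numpy() == "+", 1, -1)[None, :]
        p = mid[m][:, None]
        d = np.abs(p - tss)
        j = np.argmin(d, axis=1)
        rows = np.arange(len(j))
        dist[m] = ((p[:, 0] - tss[0, j]) * sgn[0, j])
    return dist


def tss_distance_distribution(features: FeatureSet, genome: GenomeModel,
                              bins_kb=(0, 1, 3, 5, 10, 100)) -> pd.DataFrame:
    """Cumulative percentage of features by distance band around the TSS.

    Returns one row per band and direction with the percent of features in
    the band and the cumulative percent up to and including it; a final
    open-ended band collects features beyond the last edge so percents sum
    to 100.
    """
    d = _nearest_tss(features, genome)
    downstream = d >= 0
    edges = np.array(bins_kb, dtype=float) * 1000
    absd = np.abs(d)
    rows = []
    n = len(d)
    for direction, m in (("upstream", ~downstream), ("downstream", downstream)):
        band_counts = []
        for i in range(1, len(edges)):
            band = m & (absd >= edges[i - 1]) & (absd < edges[i])
            band_counts.append((f"{bins_kb[i-1]}-{bins_kb[i]}kb", int(band.sum())))
        band_counts.append((f">{bins_kb[-1]}kb", int((m & (absd >= edges[-1])).sum())))
        cum = 0.0
        for label, cnt in band_counts:
            pct = 100.0 * cnt / n
            cum += pct
            rows.append({"direction": direction, "band": label,
                         "n": cnt, "percent": pct, "cumulative_percent": cum})
    return pd.DataFrame(rows)


def metagene_profile(features: FeatureSet, genome: GenomeModel,
                     body_bins: int = 100, flank_frac: float = 0.2,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of feature midpoints along the scaled average gene.

    Each midpoint is mapped to a relative coordinate on its nearest gene:
    0 at the TSS, 1 at the TTS, linear into the flanks; midpoints farther
    than ``flank_frac`` gene lengths outside the gene are not counted.
    Returns ``(bin_edges, counts)``.
    """
    if not len(genome.genes):
        raise ValueError("genome has no genes")
    mid = features.midpoints
    rel = np.full(len(features), np.nan)
    spans = genome.gene_spans()
    for c in pd.unique(features.chrom):
        gs = spans[spans["chrom"] == c]
        m = features.chrom == c
        if gs.empty:
            continue
        start = gs["start"].to_numpy()[None, :]
        end = gs["end"].to_numpy()[None, :]
        strand = gs["strand"].to_numpy()
        p = mid[m][:, None]
        d = np.maximum.reduce([start - p, p - (end - 1), np.zeros_like(p - start)])
        j = np.argmin(d, axis=1)
        s, e = start[0, j], end[0, j]
        length = (e - s).astype(float)
        r = (mid[m] - s) / length
        neg = strand[j] == "-"
        r[neg] = 1.0 - r[neg]
        rel[m] = r
    lo, hi = -flank_frac, 1.0 + flank_frac
    n_bins = int(round(body_bins * (1 + 2 * flank_frac)))
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(rel[np.isfinite(rel)], bins=edges)
    return edges, counts


@dataclass
class EnrichmentResult:
    category: str
    observed_prop: float
    expected_prop: float
    n_shuffles: int
    odds_ratio: float
    p_value: float
    p_adj: float


def shuffle_enrichment(features: FeatureSet, genome: GenomeModel,
                       n_shuffles: int = 1000, seed: int = 0,
                       ) -> list[EnrichmentResult]:
    """Category enrichment of features against a random-position baseline.

    Each shuffle repositions every feature uniformly on its own
    chromosome, preserving length (overlaps among shuffled features are
    allowed).  Per category a 2x2 Fisher exact test compares the observed
    in/out split against the pooled shuffles; p-values are BH-adjusted
    across categories.
    """
    index = build_category_index(genome)
    lengths = features.lengths
    for i, c in enumerate(features.chrom):
        if lengths[i] > genome.chromosomes[c]:
            raise ValueError(f"feature longer than chromosome {c}")
    obs = annotate_features(features, genome, index)
    n = len(features)
    obs_counts = pd.Series(obs).value_counts().reindex(CATEGORIES, fill_value=0)
    rng = np.random.default_rng(seed)
    chrom_len = np.array([genome.chromosomes[c] for c in features.chrom], dtype=np.int64)
    shuf_counts = pd.Series(0, index=CATEGORIES, dtype=np.int64)
    prop_sums = np.zeros(len(CATEGORIES))
    for _ in range(n_shuffles):
        starts = rng.integers(0, chrom_len - lengths + 1)
        shuffled = FeatureSet(features.chrom, starts, starts + lengths)
        cats = annotate_features(shuffled, genome, index)
        cnt = pd.Series(cats).value_counts().reindex(CATEGORIES, fill_value=0)
        shuf_counts += cnt
        prop_sums += cnt.to_numpy() / n
    expected = prop_sums / n_shuffles
    total_shuf = n * n_shuffles
    results = []
    pvals = []
    for i, cat in enumerate(CATEGORIES):
        o = int(obs_counts[cat])
        s = int(shuf_counts[cat])
        odds, p = fisher_exact_2x2([[o, n - o], [s, total_shuf - s]])
        pvals.append(p)
        results.append(EnrichmentResult(cat, o / n, float(expected[i]),
                                        n_shuffles, odds, p, np.nan))
    padj = benjamini_hochberg(pvals)
    for r, q in zip(results, padj):
        r.p_adj = float(q)
    return results


@dataclass
class VennCounts:
    """Overlap bookkeeping between two feature sets.

    ``a_both``/``b_both`` count elements of each set sharing at least the
    minimum overlap with one partner; ``a_full_in_b``/``b_full_in_a``
    count fully contained elements.
    """

    a_only: int
    b_only: int
    a_both: int
    b_both: int
    a_full_in_b: int
    b_full_in_a: int


def _max_single_overlap(A: FeatureSet, B: FeatureSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-A max overlap with any single B interval, plus containment flag."""
    best = np.zeros(len(A), dtype=np.int64)
    contained = np.zeros(len(A), dtype=bool)
    bdf = {}
    for c in pd.unique(B.chrom):
        m = B.chrom == c
        order = np.argsort(B.start[m], kind="mergesort")
        bs, be = B.start[m][order], B.end[m][order]
        bdf[c] = (bs, be, np.maximum.accumulate(be))
    for i in range(len(A)):
        c = A.chrom[i]
        if c not in bdf:
            continue
        bs, be, pmax = bdf[c]
        s, e = int(A.start[i]), int(A.end[i])
        # scan left from the last B starting before A ends, while overlap possible
        j = np.searchsorted(bs, e, side="left") - 1
        while j >= 0 and pmax[j] > s:
            ov = min(e, int(be[j])) - max(s, int(bs[j]))
            if ov > best[i]:
                best[i] = ov
            if s >= bs[j] and e <= be[j]:
                contained[i] = True
            j -= 1
    return best, contained


def overlap_sets(A: FeatureSet, B: FeatureSet, min_overlap_bp: int = 100) -> VennCounts:
    """Venn-style counts of two interval sets under a minimum-overlap rule.

    An element is "in both" when it shares at least ``min_overlap_bp``
    bases with at least one single partner interval in the other set.
    """
    a_best, a_cont = _max_single_overlap(A, B)
    b_best, b_cont = _max_single_overlap(B, A)
    a_in = a_best >= min_overlap_bp
    b_in = b_best >= min_overlap_bp
    return VennCounts(
        a_only=int((~a_in).sum()), b_only=int((~b_in).sum()),
        a_both=int(a_in.sum()), b_both=int(b_in.sum()),
        a_full_in_b=int(a_cont.sum()), b_full_in_a=int(b_cont.sum()))


def coverage_fraction(features: FeatureSet, genome: GenomeModel) -> float:
    """Percent of the genome covered by the features, to one decimal."""
    fs = features
    if not fs.is_disjoint():
        log.info("coverage_fraction: merging overlapping input features")
        fs = merge_intervals(fs, genome)
    pct = 100.0 * float(fs.lengths.sum()) / genome.total_length
    return round(pct, 1)


def recovery_fraction(reference: FeatureSet, features: FeatureSet,
                      min_overlap_bp: int = 1) -> tuple[int, int, float]:
    """Fraction of reference elements recovered by the feature set.

    Returns ``(n_recovered, n_reference, percent)`` with the percent to
    one decimal; an element is recovered when some feature overlaps it by
    at least ``min_overlap_bp`` bases.
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    best, _ = _max_single_overlap(reference, features)
    n_rec = int((best >= min_overlap_bp).sum())
    return n_rec, len(reference), round(100.0 * n_rec / len(reference), 1)
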