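"""Synthetic multi-sample single-cell chromatin + expression generator.

Emulates the study design the pipeline targets: several brain-region-like
samples of barcoded ATAC fragments whose accessible sites are organized
into planted cell types sharing a common open-chromatin backbone
(shared sites) plus type-private sites, with negative-binomial
sequencing-depth variation per cell and a tunable off-site noise rate;
and matched expression matrices with positive/negative marker structure,
housekeeping genes and cell-cycle (g2m/s) signatures.  Every planted
assignment is returned as ground truth so downstream stages have an
objective accuracy surface.

Sex chromosomes are not generated; the autosomal genome is a set of
equal-length numbered chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .cell_typing import MarkerTable
from .fragments import FragmentSet
from .genome import FeatureSet, GenomeModel

PROGENITOR = "progenitor"


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure simulation.

    Defaults describe a desk-scale analogue of a multi-region embryonic
    brain experiment: a 10 Mb autosomal genome, four cell types of 100
    cells across three samples, a shared open-chromatin backbone with
    type-private sites, ~500 fragments per cell (negative binomial,
    dispersion 2) and 10% off-site noise.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    n_cell_types: int = 4
    n_cells_per_type: int = 100
    n_shared_sites: int = 200
    n_private_sites_per_type: int = 50
    site_width_bp: int = 500
    depth_mean: float = 500.0
    depth_dispersion: float = 2.0
    noise_rate: float = 0.1
    marker_genes_per_type: int = 5
    seed: int = 0
    # gene-structure and expression extensions
    n_samples: int = 3
    n_genes: int = 120
    gene_min_bp: int = 5_000
    gene_max_bp: int = 20_000
    negative_markers_per_type: int = 2
    n_housekeeping: int = 20
    n_cell_cycle: int = 10
    marker_fold: float = 8.0
    progenitor_type: int | None = None
    fragment_min_bp: int = 80
    fragment_max_bp: int = 300
    expression_mean: float = 5.0
    expression_dispersion: float = 2.0

    def validate(self) -> None:
        counts = [self.n_chromosomes, self.chrom_length_bp, self.n_cell_types,
                  self.n_cells_per_type, self.n_shared_sites,
                  self.n_private_sites_per_type, self.site_width_bp,
                  self.marker_genes_per_type, self.n_samples, self.n_genes]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.progenitor_type is not None and not (
                0 <= self.progenitor_type < self.n_cell_types):
            raise ValueError("progenitor_type out of range")

    def type_names(self) -> list[str]:
        names = [f"type{i}" for i in range(self.n_cell_types)]
        if self.progenitor_type is not None:
            names[self.progenitor_type] = PROGENITOR
        return names


@dataclass
class GroundTruth:
    """Planted assignments: per cell, per site, per gene."""

    cells: pd.DataFrame   # index barcode; cell_type, sample, progenitor
    sites: pd.DataFrame   # chrom, start, end, owner ('shared' or type name)
    genes: pd.DataFrame   # gene_id, role, cell_type

    def site_features(self, owner: str | None = None) -> FeatureSet:
        df = self.sites if owner is None else self.sites[self.sites["owner"] == owner]
        return FeatureSet(df["chrom"].to_numpy(dtype=object),
                          df["start"].to_numpy(), df["end"].to_numpy())

    def sites_for_type(self, cell_type: str) -> pd.DataFrame:
        m = (self.sites["owner"] == "shared") | (self.sites["owner"] == cell_type)
        return self.sites[m]

    def marker_table(self) -> MarkerTable:
        positive: dict[str, list[str]] = {}
        negative: dict[str, list[str]] = {}
        composites: dict[str, list[str]] = {}
        g = self.genes
        for t in sorted(self.cells["cell_type"].unique()):
            positive[t] = g.loc[(g["role"] == "marker_pos") & (g["cell_type"] == t),
                                "gene_id"].tolist()
            negative[t] = g.loc[(g["role"] == "marker_neg") & (g["cell_type"] == t),
                                "gene_id"].tolist()
        g2m = g.loc[g["role"] == "cell_cycle_g2m", "gene_id"].tolist()
        s = g.loc[g["role"] == "cell_cycle_s", "gene_id"].tolist()
        if g2m:
            composites["g2m"] = g2m
        if s:
            composites["s"] = s
        if PROGENITOR in positive and not positive[PROGENITOR]:
            positive[PROGENITOR] = [c for c in ("g2m", "s") if c in composites]
        return MarkerTable(positive, negative, composites)


def make_genome(spec: SyntheticSpec) -> GenomeModel:
    """Place non-overlapping gene models on equal-length chromosomes.

    Deterministic under ``spec.seed``.  Raises a sizing error when the
    requested genes cannot fit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chroms = {f"chr{i + 1}": spec.chrom_length_bp for i in range(spec.n_chromosomes)}
    per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per_chrom[: spec.n_genes % spec.n_chromosomes] += 1
    rows = []
    gid = 0
    for ci, (cname, clen) in enumerate(chroms.items()):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        lengths = rng.integers(spec.gene_min_bp, spec.gene_max_bp + 1, size=k)
        total = int(lengths.sum())
        free = clen - total
        if free < 0:
            raise ValueError(
                f"genome too small: {k} genes of total {total} bp exceed "
                f"{cname} length {clen} bp")
        gaps = np.sort(rng.integers(0, free + 1, size=k))
        gaps = np.diff(np.concatenate([[0], gaps]))
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start, end = pos, pos + int(lengths[j])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tts = (start, end) if strand == "+" else (end, start)
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(
                np.arange(start + 50, end - 50), size=2 * (n_exons - 1), replace=False))
            bounds = np.concatenate([[start], cuts, [end]])
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
            glen = end - start
            cds_start = start + max(glen // 5, 1)
            cds_end = end - max(glen // 5, 1)
            rows.append({"gene_id": f"gene{gid:04d}", "chrom": cname, "strand": strand,
                         "tss": tss, "tts": tts, "exons": exons,
                         "cds_start": cds_start, "cds_end": cds_end})
            gid += 1
    return GenomeModel(chroms, pd.DataFrame(rows))


def _plant_sites(spec: SyntheticSpec, genome: GenomeModel,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Disjoint site intervals on a slot grid, assigned shared/private."""
    width = spec.site_width_bp
    slot = 2 * width  # spacing guarantees pairwise disjoint sites
    slots = []
    for cname, clen in genome.chromosomes.items():
        n_slots = clen // slot
        slots.extend((cname, i * slot) for i in range(n_slots))
    n_sites = spec.n_shared_sites + spec.n_cell_types * spec.n_private_sites_per_type
    if n_sites > len(slots):
        raise ValueError(f"genome too small for {n_sites} sites of width {width}")
    pick = rng.choice(len(slots), size=n_sites, replace=False)
    owners = (["shared"] * spec.n_shared_sites
              + [t for t in spec.type_names() for _ in range(spec.n_private_sites_per_type)])
    rows = []
    for idx, owner in zip(pick, owners):
        cname, s = slots[idx]
        rows.append({"chrom": cname, "start": s, "end": s + width, "owner": owner})
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def _assign_gene_roles(spec: SyntheticSpec, genome: GenomeModel,
                       rng: np.random.Generator) -> pd.DataFrame:
    types = spec.type_names()
    needed = (len(types) * (spec.marker_genes_per_type + spec.negative_markers_per_type)
              + spec.n_housekeeping + spec.n_cell_cycle)
    gene_ids = genome.genes["gene_id"].tolist()
    if needed > len(gene_ids):
        raise ValueError(f"need {needed} genes for marker roles, have {len(gene_ids)}")
    order = rng.permutation(len(gene_ids))
    it = iter(order)
    roles = {g: ("none", "") for g in gene_ids}
    for t in types:
        if t == PROGENITOR:
            # progenitor identity is carried by the cell-cycle composites
            for _ in range(spec.marker_genes_per_type):
                next(it)
            for _ in range(spec.negative_markers_per_type):
                next(it)
            continue
        for _ in range(spec.marker_genes_per_type):
            roles[gene_ids[next(it)]] = ("marker_pos", t)
        for _ in range(spec.negative_markers_per_type):
            roles[gene_ids[next(it)]] = ("marker_neg", t)
    for _ in range(spec.n_housekeeping):
        roles[gene_ids[next(it)]] = ("housekeeping", "")
    half = spec.n_cell_cycle // 2
    for i in range(spec.n_cell_cycle):
        role = "cell_cycle_g2m" if i < half or spec.n_cell_cycle == 1 else "cell_cycle_s"
        roles[gene_ids[next(it)]] = (role, "")
    return pd.DataFrame({"gene_id": gene_ids,
                         "role": [roles[g][0] for g in gene_ids],
                         "cell_type": [roles[g][1] for g in gene_ids]})


def simulate_fragments(genome: GenomeModel, spec: SyntheticSpec,
                       ) -> tuple[list[FragmentSet], GroundTruth]:
    """Draw per-cell fragments from planted site sets.

    Each cell's fragments come from its type's accessible sites (shared
    plus type-private) with probability ``1 - noise_rate`` and uniformly
    from the genome otherwise; per-cell depth is negative binomial.
    Fragment records are sorted by coordinate within each sample.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    sites = _plant_sites(spec, genome, rng)
    gene_roles = _assign_gene_roles(spec, genome, rng)
    types = spec.type_names()
    n_cells = spec.n_cell_types * spec.n_cells_per_type
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    cell_types = np.repeat(types, spec.n_cells_per_type)
    samples = rng.choice([f"sample{i}" for i in range(spec.n_samples)], size=n_cells)
    r = spec.depth_dispersion
    p = r / (r + spec.depth_mean)
    depths = rng.negative_binomial(r, p, size=n_cells)
    depths = np.maximum(depths, 1)
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_names], dtype=np.int64)
    chrom_probs = chrom_lens / chrom_lens.sum()
    site_lookup = {t: sites[(sites["owner"] == "shared") | (sites["owner"] == t)]
                   .reset_index(drop=True) for t in types}
    per_sample: dict[str, list[pd.DataFrame]] = {s: [] for s in np.unique(samples)}
    for i in range(n_cells):
        d = int(depths[i])
        tsites = site_lookup[cell_types[i]]
        from_site = rng.random(d) >= spec.noise_rate
        lengths = rng.integers(spec.fragment_min_bp, spec.fragment_max_bp + 1, size=d)
        chroms = np.empty(d, dtype=object)
        centers = np.empty(d, dtype=np.int64)
        n_site = int(from_site.sum())
        if n_site:
            sidx = rng.integers(0, len(tsites), size=n_site)
            chroms[from_site] = tsites["chrom"].to_numpy()[sidx]
            centers[from_site] = (tsites["start"].to_numpy()[sidx]
                                  + rng.integers(0, spec.site_width_bp, size=n_site))
        n_noise = d - n_site
        if n_noise:
            cidx = rng.choice(len(chrom_names), size=n_noise, p=chrom_probs)
            chroms[~from_site] = np.array(chrom_names, dtype=object)[cidx]
            centers[~from_site] = rng.integers(0, chrom_lens[cidx])
        starts = centers - lengths // 2
        ends = starts + lengths
        clen = np.array([genome.chromosomes[c] for c in chroms], dtype=np.int64)
        starts = np.clip(starts, 0, clen - 1)
        ends = np.clip(ends, starts + 1, clen)
        per_sample[samples[i]].append(pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": ends,
             "barcode": barcodes[i], "count": 1}))
    order = genome.chrom_order()
    fragment_sets = []
    for s in sorted(per_sample):
        df = pd.concat(per_sample[s], ignore_index=True)
        fragment_sets.append(FragmentSet(df, sample=s).sort(order))
    cells = pd.DataFrame({"cell_type": cell_types, "sample": samples,
                          "progenitor": cell_types == PROGENITOR},
                         index=pd.Index(barcodes, name="barcode"))
    truth = GroundTruth(cells=cells, sites=sites, genes=gene_roles)
    return fragment_sets, truth


def simulate_expression(truth: GroundTruth, spec: SyntheticSpec) -> AnnData:
    """Negative-binomial expression with planted marker structure.

    Positive markers are up-shifted ``marker_fold``-fold in their type,
    negative markers down-shifted the same factor, housekeeping genes are
    uniform across types and cell-cycle genes are up-shifted only in
    progenitor-flagged cells.
    """
    rng = np.random.default_rng(spec.seed + 2)
    cells = truth.cells
    genes = truth.genes
    n, m = len(cells), len(genes)
    base = rng.uniform(0.5, 2.0, size=m) * spec.expression_mean
    size_factor = np.exp(rng.normal(0, 0.3, size=n))
    mean = np.outer(size_factor, base)
    ct = cells["cell_type"].to_numpy()
    prog = cells["progenitor"].to_numpy()
    for j, g in enumerate(genes.itertuples(index=False)):
        if g.role == "marker_pos":
            mean[ct == g.cell_type, j] *= spec.marker_fold
        elif g.role == "marker_neg":
            mean[ct == g.cell_type, j] /= spec.marker_fold
        elif g.role in ("cell_cycle_g2m", "cell_cycle_s"):
            mean[prog, j] *= spec.marker_fold
    r = spec.expression_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    adata = AnnData(X=sp.csr_matrix(counts.astype(np.float64)),
                    obs=cells.copy(),
                    var=genes.set_index("gene_id"))
    return adata


def write_fixtures(fragments: list[FragmentSet], expr: AnnData,
                   genome: GenomeModel, truth: GroundTruth, outdir) -> dict:
    """Serialize generated objects as plain-text fixtures.

    Fragments become per-sample sorted 5-column TSV(.gz); expression is
    MatrixMarket + barcode/gene TSVs; gene models a BED-like TSV; the
    ground truth a TSV.  Returns the path map.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fs in fragments:
        p = out / f"fragments_{fs.sample}.tsv.gz"
        fs.write(p)
        paths[f"fragments_{fs.sample}"] = p
    scipy.io.mmwrite(out / "matrix.mtx", sp.csr_matrix(expr.X))
    pd.Series(expr.obs_names).to_csv(out / "barcodes.tsv", index=False, header=False)
    pd.Series(expr.var_names).to_csv(out / "features.tsv", index=False, header=False)
    genes = genome.genes.copy()
    genes["exons"] = genes["exons"].map(
        lambda ex: ",".join(f"{s}-{e}" for s, e in ex))
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    chrom_df = pd.DataFrame({"chrom": list(genome.chromosomes),
                             "length": list(genome.chromosomes.values())})
    chrom_df.to_csv(out / "chrom_sizes.tsv", sep="\t", index=False)
    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t")
    truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    paths.update({k: out / f"{k}" for k in
                  ["matrix.mtx", "barcodes.tsv", "features.tsv", "genes.tsv",
                   "chrom_sizes.tsv", "truth_cells.tsv", "truth_sites.tsv",
                   "truth_genes.tsv"]})
    return paths


def read_genome(genes_path, chrom_sizes_path) -> GenomeModel:
    """Read back the BED-like gene table written by :func:`write_fixtures`."""
    chrom = pd.read_csv(chrom_sizes_path, sep="\t")
    genes = pd.read_csv(genes_path, sep="\t")
    genes["exons"] = genes["exons"].map(
        lambda s: [tuple(map(int, p.split("-"))) for p in str(s).split(",")])
    return GenomeModel(dict(zip(chrom["chrom"], chrom["length"])), genes)
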