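"""Synthetic bisulfite-count experiments with known ground truth.

The generator emulates the statistical structure of a plant WGBS
experiment: per-context methylation-level distributions (CG bimodal near
0 and 1, CHG intermediate, CHH low), negative-binomial read depth,
spontaneous-epimutation noise present identically in both groups (each
replicate independently redraws a site's level with a small
probability), and a treatment-restricted level shift at a subset of
genes.  Replicate counts are binomial draws from the replicate's
underlying level.  Everything is reproducible from a single seed, and a
truth table records the underlying levels and the planted signal genes
so every pipeline stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MethylomeSample, write_cx_report


@dataclass
class GenomeSpec:
    """Desk-scale synthetic genome: one 200 kbp chromosome by default."""

    chromosomes: list[tuple[str, int]] = field(default_factory=lambda: [("Chr1", 200_000)])
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1_000, 2_000)
    n_sites: int = 10_000
    #: context mix (CG, CHG, CHH); plant genomes are CHH-heavy
    context_proportions: tuple[float, float, float] = (0.25, 0.15, 0.60)

    def __post_init__(self) -> None:
        if any(length < 1 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be >= 1")
        if abs(sum(self.context_proportions) - 1.0) > 1e-9:
            raise ValueError("context proportions must sum to 1")


@dataclass
class SimulationDesign:
    """Study conditions: replication, depth, noise and planted signal."""

    n_control: int = 3
    n_treatment: int = 3
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0
    #: per-site per-replicate probability of a spontaneous level redraw
    epimutation_rate: float = 0.02
    n_signal_genes: int = 20
    effect_size: float = 0.4
    #: fraction of signal genes shifted upward (hyper) rather than downward
    hyper_fraction: float = 0.5
    #: fraction of sites within a signal gene that receive the shift
    signal_site_fraction: float = 1.0
    #: additional planted-signal classes as (n_genes, effect_size,
    #: site_fraction) triples, drawn from genes not already carrying signal;
    #: lets one experiment mix dense and sparse, strong and weak signal
    extra_signal_classes: tuple[tuple[int, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1:
            raise ValueError("need at least one control replicate")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect size must be in [0, 1]")
        if not (0.0 <= self.epimutation_rate <= 1.0):
            raise ValueError("epimutation rate must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth: per-site group levels, per-gene signal flags, design."""

    sites: pd.DataFrame = field(repr=False)
    genes: pd.DataFrame = field(repr=False)
    design: SimulationDesign = field(default_factory=SimulationDesign)

    @property
    def signal_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["is_signal"], "gene_id"])


# Beta mixture parameters of the baseline level distribution per context.
# CG: bimodal with mass near 0 and near 1 (gene-body-like); CHG:
# intermediate low; CHH: low. Tuples of (weight, a, b).
_LEVEL_MIXTURES = {
    "CG": [(0.60, 1.0, 10.0), (0.40, 10.0, 1.0)],
    "CHG": [(1.00, 1.5, 5.0)],
    "CHH": [(1.00, 1.0, 12.0)],
}


def _draw_levels(contexts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    levels = np.empty(contexts.size, dtype=float)
    for ctx, components in _LEVEL_MIXTURES.items():
        mask = contexts == ctx
        m = int(mask.sum())
        if m == 0:
            continue
        weights = np.array([w for w, _, _ in components])
        choice = rng.choice(len(components), size=m, p=weights / weights.sum())
        draw = np.empty(m)
        for i, (_, a, b) in enumerate(components):
            sel = choice == i
            draw[sel] = rng.beta(a, b, size=int(sel.sum()))
        levels[mask] = draw
    return levels


def _place_genes(genome: GenomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping genes laid left to right with even gaps."""
    rows = []
    chrom_names = [c for c, _ in genome.chromosomes]
    total_len = sum(length for _, length in genome.chromosomes)
    gene_id = 0
    for chrom, length in genome.chromosomes:
        n_here = max(1, round(genome.n_genes * length / total_len))
        n_here = min(n_here, genome.n_genes - gene_id)
        if chrom == chrom_names[-1]:
            n_here = genome.n_genes - gene_id
        if n_here <= 0:
            continue
        lo, hi = genome.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=n_here)
        if lengths.sum() > length:
            raise ValueError(f"genes do not fit on chromosome {chrom}")
        gap = (length - int(lengths.sum())) // (n_here + 1)
        cursor = 1
        for glen in lengths:
            start = cursor + gap
            end = start + int(glen) - 1
            rows.append({"gene_id": f"G{gene_id:04d}", "chrom": chrom,
                         "start": start, "end": end,
                         "strand": "+" if rng.random() < 0.5 else "-"})
            cursor = end
            gene_id += 1
    return pd.DataFrame(rows)


def simulate_experiment(genome: GenomeSpec | None = None,
                        design: SimulationDesign | None = None
                        ) -> tuple[list[MethylomeSample], TruthTable]:
    """Generate a full control/treatment experiment plus its ground truth."""
    genome = genome or GenomeSpec()
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed)

    genes = _place_genes(genome, rng)
    classes = [(design.n_signal_genes, design.effect_size,
                design.signal_site_fraction)]
    classes += [tuple(c) for c in design.extra_signal_classes]
    total_signal = sum(c[0] for c in classes)
    if total_signal > len(genes):
        raise ValueError("more signal genes requested than genes in the genome")
    pool = list(rng.choice(genes["gene_id"].to_numpy(),
                           size=total_signal, replace=False))
    gene_effect: dict[str, float] = {}
    gene_fraction: dict[str, float] = {}
    for n_class, eff, frac in classes:
        for gid in pool[:n_class]:
            gene_effect[gid] = eff
            gene_fraction[gid] = frac
        pool = pool[n_class:]
    signal_ids = np.array(sorted(gene_effect), dtype=object)
    genes["is_signal"] = genes["gene_id"].isin(gene_effect) \
        & (genes["gene_id"].map(gene_effect).fillna(0.0) > 0)
    sig_dirs = np.where(rng.random(len(signal_ids)) < design.hyper_fraction,
                        1.0, -1.0)
    gene_dir = dict(zip(signal_ids, sig_dirs))
    genes["signal_direction"] = genes["gene_id"].map(gene_dir).fillna(0.0)
    genes["effect_size"] = genes["gene_id"].map(gene_effect).fillna(0.0)
    genes["site_fraction"] = genes["gene_id"].map(gene_fraction).fillna(0.0)

    # sites: unique positions per chromosome, proportional to length
    site_rows = []
    total_len = sum(length for _, length in genome.chromosomes)
    remaining = genome.n_sites
    for i, (chrom, length) in enumerate(genome.chromosomes):
        n_here = remaining if i == len(genome.chromosomes) - 1 else \
            min(remaining, round(genome.n_sites * length / total_len))
        remaining -= n_here
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_here, replace=False))
        site_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(site_rows, ignore_index=True)
    n = len(sites)
    sites["strand"] = np.where(rng.random(n) < 0.5, "+", "-")
    sites["context"] = rng.choice(["CG", "CHG", "CHH"], size=n,
                                  p=list(genome.context_proportions))
    base_level = _draw_levels(sites["context"].to_numpy(), rng)
    sites["level_control"] = base_level

    # map sites to signal genes -> per-site shift for the treatment group
    shift = np.zeros(n)
    for row in genes[genes["is_signal"]].itertuples(index=False):
        in_gene = ((sites["chrom"] == row.chrom) & (sites["pos"] >= row.start)
                   & (sites["pos"] <= row.end)).to_numpy()
        idx = np.flatnonzero(in_gene)
        if row.site_fraction < 1.0 and idx.size:
            n_aff = max(1, round(idx.size * row.site_fraction))
            idx = rng.choice(idx, size=n_aff, replace=False)
        shift[idx] = row.signal_direction * row.effect_size
    sites["level_treatment"] = np.clip(base_level + shift, 0.0, 1.0)
    sites["is_signal_site"] = shift != 0.0

    def _replicate(sample_id: str, group: str) -> MethylomeSample:
        level = sites[f"level_{group}"].to_numpy().copy()
        if design.epimutation_rate > 0:
            flip = rng.random(n) < design.epimutation_rate
            if flip.any():
                level[flip] = _draw_levels(sites.loc[flip, "context"].to_numpy(), rng)
        p_nb = design.coverage_dispersion / (design.coverage_dispersion
                                             + design.coverage_mean)
        coverage = rng.negative_binomial(design.coverage_dispersion, p_nb, size=n)
        n_meth = rng.binomial(coverage, level)
        df = pd.DataFrame({
            "chrom": sites["chrom"], "pos": sites["pos"], "strand": sites["strand"],
            "n_meth": n_meth, "n_unmeth": coverage - n_meth,
            "context": sites["context"],
        })
        return MethylomeSample(sample_id=sample_id, group=group, sites=df)

    samples = [_replicate(f"ctl_{i + 1}", "control") for i in range(design.n_control)]
    samples += [_replicate(f"trt_{i + 1}", "treatment")
                for i in range(design.n_treatment)]
    truth = TruthTable(sites=sites, genes=genes, design=design)
    return samples, truth


def write_experiment(samples: Sequence[MethylomeSample], truth: TruthTable,
                     out_dir: str | Path) -> list[Path]:
    """Write CX reports, GFF3, sample sheet, truth table and design JSON.

    Returns the manifest (list of written paths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    sheet_rows = []
    for sample in samples:
        path = out / f"{sample.sample_id}.cx.tsv"
        write_cx_report(sample, path)
        manifest.append(path)
        sheet_rows.append({"sample_id": sample.sample_id,
                           "path": path.name, "group": sample.group})

    gff = out / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in truth.genes.itertuples(index=False):
            fh.write(f"{row.chrom}\tmethylsignal_sim\tgene\t{row.start}\t{row.end}"
                     f"\t.\t{row.strand}\t.\tID={row.gene_id}\n")
    manifest.append(gff)

    sheet = out / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)
    manifest.append(sheet)

    truth_genes = out / "truth_genes.tsv"
    truth.genes.to_csv(truth_genes, sep="\t", index=False)
    manifest.append(truth_genes)

    design_json = out / "design.json"
    design_json.write_text(json.dumps(asdict(truth.design), indent=2))
    manifest.append(design_json)
    return manifest
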