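"""Model/Results objects orchestrating the two analysis pipelines.

`MethylSignalModel` is the signal-detection analysis: coverage filter →
pooled control centroid → per-site divergence → generalized-gamma fit
per sample × context → percentile candidates → learned cutoff per
context → per-replicate DMPs → gene aggregation → density gate →
Poisson/negative-binomial LRT → BH adjustment → DMG calls.  `fit()`
returns a `MethylSignalResults` carrying every intermediate table, the
fitted distributions and cutoffs, and a `summary()` report.

`FisherBaselineModel` is the prevalent two-sample archetype on the same
inputs: pooled Fisher exact tests, a methylation-difference gate,
fixed-window DMR binning and DMR-to-gene overlap.

Both accept the same sample collection and gene table, so their gene
calls are directly comparable with `compare_results`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import baseline as bl
from . import dmg as dmg_mod
from . import dmp as dmp_mod
from .distfit import FittedDivergenceModel, FitError, select_model
from .divergence import DEFAULT_PRIOR, divergence_table, pool_centroid
from .io import CONTEXTS, MethylomeSample, filter_coverage


@dataclass
class PipelineConfig:
    """Every tunable of the two pipelines, with field-default values."""

    min_coverage: int = 4
    prior: tuple[float, float] = DEFAULT_PRIOR
    divergence_column: str = "hdiv_w"       # or "hdiv"
    families: tuple[str, ...] = ("gamma3p", "gamma2p", "weibull")
    percentile: float = 0.95
    cutoff_criterion: str = "youden"
    min_tv: float | None = None
    contexts: tuple[str, ...] = CONTEXTS
    strict_controls: bool = True
    #: compare each control to the leave-one-out centroid of the others
    loo_controls: bool = True
    #: learn the cutoff on divergence relative to each replicate's fitted
    #: percentile ("relative") or on raw divergence values ("absolute")
    cutoff_scale: str = "relative"
    # DMG stage
    dmg_min_dmps: int = 3
    dmg_min_density: float = 3.0            # DMPs per 10 kbp
    dmg_alpha: float = 0.05
    dmg_lfc_min: float = 1.0
    dmg_direction: str = "greater"
    # baseline stage
    baseline_alpha: float = 0.05
    baseline_min_diff: float = 0.20
    baseline_window: int = 100
    baseline_min_dmps: int = 3
    baseline_uniform_direction: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0.0 < self.percentile < 1.0):
            raise ValueError("percentile must be in (0, 1)")
        if self.divergence_column not in ("hdiv", "hdiv_w"):
            raise ValueError("divergence_column must be hdiv or hdiv_w")
        if self.cutoff_criterion not in dmp_mod.CRITERIA:
            raise ValueError(f"cutoff_criterion must be one of {dmp_mod.CRITERIA}")
        if self.cutoff_scale not in ("relative", "absolute"):
            raise ValueError("cutoff_scale must be relative or absolute")
        if not (0.0 < self.baseline_min_diff < 1.0):
            raise ValueError("baseline_min_diff must be in (0, 1)")
        if not set(self.contexts) <= set(CONTEXTS):
            raise ValueError(f"contexts must be drawn from {CONTEXTS}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class MethylSignalResults:
    """Fitted signal-detection analysis: estimates, diagnostics, DMG table."""

    def __init__(self, model: "MethylSignalModel", divergence: pd.DataFrame,
                 dist_models: Mapping[tuple[str, str], FittedDivergenceModel],
                 cutoffs: Mapping[str, dmp_mod.CutoffModel],
                 dmps: pd.DataFrame, gene_counts: pd.DataFrame,
                 dmg_table: pd.DataFrame, stages: list[str]):
        self.model = model
        self.config = model.config
        self.divergence = divergence
        self.dist_models = dict(dist_models)
        self.cutoffs = dict(cutoffs)
        self.dmps = dmps
        self.gene_counts = gene_counts
        self.dmg_table = dmg_table
        self.stages = stages

    @property
    def dmg_ids(self) -> set[str]:
        if self.dmg_table.empty:
            return set()
        return set(self.dmg_table.loc[self.dmg_table["is_dmg"], "gene_id"])

    def manifest(self) -> dict:
        return {
            "pipeline": "signal_detection",
            "stages": self.stages,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_samples": len(self.model.samples),
            "n_genes": len(self.model.genes),
            "n_divergence_records": int(len(self.divergence)),
            "n_dmps": int(len(self.dmps)),
            "n_genes_tested": int(len(self.dmg_table)),
            "n_dmgs": len(self.dmg_ids),
        }

    def summary(self) -> str:
        lines = ["Signal-detection methylome analysis",
                 "=" * 40,
                 f"samples: {len(self.model.samples)} "
                 f"({sum(s.group == 'control' for s in self.model.samples)} control, "
                 f"{sum(s.group == 'treatment' for s in self.model.samples)} treatment)",
                 f"divergence records: {len(self.divergence)}",
                 "",
                 "Fitted divergence distributions (per sample x context):"]
        for (sample_id, ctx), m in sorted(self.dist_models.items()):
            lines.append(f"  {sample_id:>10s} {ctx:>3s}: {m.family} "
                         f"alpha={m.alpha:.3g} psi={m.psi:.3g} delta={m.delta:.3g} "
                         f"AIC={m.aic:.1f} KS={m.ks_stat:.3f}")
        lines.append("")
        lines.append("Learned cutoffs (per context):")
        for ctx, c in sorted(self.cutoffs.items()):
            lines.append(f"  {ctx:>3s}: cutoff={c.cutoff:.4g} ({c.metric}) "
                         f"youden={c.youden:.3f} acc={c.accuracy:.3f} fdr={c.fdr:.3f}")
        lines.append("")
        lines.append(f"DMPs called: {len(self.dmps)}; genes tested: "
                     f"{len(self.dmg_table)}; DMGs: {len(self.dmg_ids)}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [("divergence.tsv", self.divergence),
                         ("dmps.tsv", self.dmps),
                         ("gene_counts.tsv", self.gene_counts.reset_index()),
                         ("dmgs.tsv", self.dmg_table)]:
            path = out / name
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
        models_path = out / "dist_models.json"
        models_path.write_text(json.dumps(
            {f"{s}|{c}": asdict(m) for (s, c), m in self.dist_models.items()},
            indent=2))
        written.append(models_path)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest(), indent=2))
        written.append(manifest_path)
        return written


class MethylSignalModel:
    """Signal-detection differential-methylation model for one experiment.

    Parameters
    ----------
    samples : sequence of MethylomeSample
        All replicates; group labels distinguish control from treatment.
    genes : DataFrame
        Gene annotation (gene_id, chrom, start, end[, strand]).
    config : PipelineConfig, optional
    """

    def __init__(self, samples: Sequence[MethylomeSample], genes: pd.DataFrame,
                 config: PipelineConfig | None = None):
        self.samples = list(samples)
        self.genes = genes.reset_index(drop=True)
        self.config = config or PipelineConfig()
        self.config.validate()
        self.controls = [s for s in self.samples if s.group == "control"]
        self.treatments = [s for s in self.samples if s.group == "treatment"]
        if not self.controls:
            raise ValueError("no control samples")
        if not self.treatments:
            raise ValueError("no treatment samples")

    @classmethod
    def from_directory(cls, sample_sheet: str | Path, gff3: str | Path,
                       config: PipelineConfig | None = None) -> "MethylSignalModel":
        from .io import load_samples, read_gff3_genes, read_sample_sheet
        sheet = read_sample_sheet(sample_sheet)
        samples = load_samples(sheet, base_dir=Path(sample_sheet).parent)
        genes = read_gff3_genes(gff3)
        return cls(samples, genes, config=config)

    def fit(self) -> MethylSignalResults:
        cfg = self.config
        stages = []

        filtered = [filter_coverage(s, cfg.min_coverage) for s in self.samples]
        stages.append("filter_coverage")
        ctl_filtered = [s for s in filtered if s.group == "control"]
        reference = pool_centroid(ctl_filtered, strict=cfg.strict_controls)
        stages.append("pool_centroid")
        div = divergence_table(filtered, reference, prior=cfg.prior,
                               min_coverage=cfg.min_coverage,
                               loo_controls=cfg.loo_controls)
        stages.append("divergence_table")

        dist_models: dict[tuple[str, str], FittedDivergenceModel] = {}
        candidate_frames = []
        for (sample_id, ctx), sub in div.groupby(["sample_id", "context"], sort=True):
            if ctx not in cfg.contexts:
                continue
            values = sub[cfg.divergence_column].to_numpy()
            try:
                m = select_model(values, families=cfg.families, seed=cfg.seed)
            except FitError as exc:
                warnings.warn(f"distribution fit failed for {sample_id}/{ctx}: {exc}",
                              stacklevel=2)
                continue
            dist_models[(sample_id, ctx)] = m
            cand = dmp_mod.potential_dmps(sub, m, prob=cfg.percentile,
                                          min_tv=cfg.min_tv,
                                          divergence_column=cfg.divergence_column)
            # divergence on each replicate's own fitted-distribution scale:
            # comparable across samples regardless of coverage differences
            cand = cand.copy()
            cand["rel_div"] = (cand[cfg.divergence_column]
                               / m.quantile(cfg.percentile))
            candidate_frames.append(cand)
        stages.append("fit_divergence_model")
        stages.append("potential_dmps")
        candidates = (pd.concat(candidate_frames, ignore_index=True)
                      if candidate_frames else div.iloc[0:0])

        cutoffs: dict[str, dmp_mod.CutoffModel] = {}
        dmp_frames = []
        score_col = ("rel_div" if cfg.cutoff_scale == "relative"
                     else cfg.divergence_column)
        for ctx in cfg.contexts:
            ctx_cand = candidates[candidates["context"] == ctx]
            if ctx_cand.empty:
                continue
            ctl_vals = ctx_cand.loc[ctx_cand["group"] == "control",
                                    score_col].to_numpy()
            trt_vals = ctx_cand.loc[ctx_cand["group"] == "treatment",
                                    score_col].to_numpy()
            try:
                cutoff = dmp_mod.learn_cutoff(ctl_vals, trt_vals,
                                              criterion=cfg.cutoff_criterion,
                                              context=ctx)
            except dmp_mod.ClassBalanceError:
                # fall back to the percentile threshold alone
                warnings.warn(
                    f"context {ctx}: one candidate class empty; falling back to the "
                    f"fitted-percentile threshold without a learned cutoff",
                    stacklevel=2)
                cutoff = dmp_mod.CutoffModel(context=ctx, cutoff=0.0,
                                             metric="percentile_fallback",
                                             accuracy=float("nan"),
                                             sensitivity=float("nan"),
                                             specificity=float("nan"),
                                             fdr=float("nan"), youden=float("nan"))
            cutoffs[ctx] = cutoff
            for sample_id, sub in ctx_cand.groupby("sample_id", sort=True):
                dmp_frames.append(dmp_mod.call_dmps(
                    sub, cutoff, divergence_column=score_col))
        stages.append("learn_cutoff")
        stages.append("call_dmps")
        dmps = (pd.concat(dmp_frames, ignore_index=True)
                if dmp_frames else candidates.iloc[0:0].assign(direction=None))

        dmp_sets = {s.sample_id: dmps[dmps["sample_id"] == s.sample_id]
                    for s in self.samples}
        gene_counts = dmg_mod.count_dmps_in_genes(dmp_sets, self.genes)
        stages.append("count_dmps_in_genes")
        stages.append("filter_density")
        groups = {s.sample_id: s.group for s in self.samples}
        table = dmg_mod.dmg_table(gene_counts, groups,
                                  min_dmps=cfg.dmg_min_dmps,
                                  min_density=cfg.dmg_min_density,
                                  alpha=cfg.dmg_alpha, lfc_min=cfg.dmg_lfc_min,
                                  direction=cfg.dmg_direction)
        stages.append("test_gene")
        stages.append("adjust_pvalues")
        stages.append("call_dmgs")
        return MethylSignalResults(self, div, dist_models, cutoffs, dmps,
                                   gene_counts, table, stages)


class FisherBaselineResults:
    """Fitted baseline analysis: site tests, DMRs, gene overlap."""

    def __init__(self, model: "FisherBaselineModel", dmps: pd.DataFrame,
                 dmrs: pd.DataFrame, dmg_ids: set[str], stages: list[str]):
        self.model = model
        self.config = model.config
        self.dmps = dmps
        self.dmrs = dmrs
        self.dmg_ids = dmg_ids
        self.stages = stages

    def manifest(self) -> dict:
        return {
            "pipeline": "fisher_baseline",
            "stages": self.stages,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_samples": len(self.model.samples),
            "n_dmps": int(len(self.dmps)),
            "n_dmrs": int(len(self.dmrs)),
            "n_dmgs": len(self.dmg_ids),
        }

    def summary(self) -> str:
        return "\n".join([
            "Fisher-exact baseline methylome analysis",
            "=" * 40,
            f"pooled-site DMPs (adj p < {self.config.baseline_alpha}, "
            f"|delta| >= {self.config.baseline_min_diff}): {len(self.dmps)}",
            f"fixed-window DMRs (window {self.config.baseline_window} bp, "
            f">= {self.config.baseline_min_dmps} DMPs): {len(self.dmrs)}",
            f"genes overlapping a DMR: {len(self.dmg_ids)}",
        ])

    def save(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [("baseline_dmps.tsv", self.dmps),
                         ("baseline_dmrs.tsv", self.dmrs)]:
            path = out / name
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
        dmg_path = out / "baseline_dmgs.tsv"
        pd.DataFrame({"gene_id": sorted(self.dmg_ids)}).to_csv(
            dmg_path, sep="\t", index=False)
        written.append(dmg_path)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest(), indent=2))
        written.append(manifest_path)
        return written


class FisherBaselineModel:
    """Prevalent-pipeline comparison model on the same experiment inputs."""

    def __init__(self, samples: Sequence[MethylomeSample], genes: pd.DataFrame,
                 config: PipelineConfig | None = None):
        self.samples = list(samples)
        self.genes = genes.reset_index(drop=True)
        self.config = config or PipelineConfig()
        self.config.validate()
        self.controls = [s for s in self.samples if s.group == "control"]
        self.treatments = [s for s in self.samples if s.group == "treatment"]
        if not self.controls or not self.treatments:
            raise ValueError("need at least one sample per group")

    def fit(self) -> FisherBaselineResults:
        cfg = self.config
        stages = []
        filtered = [filter_coverage(s, cfg.min_coverage) for s in self.samples]
        stages.append("filter_coverage")
        ctl_pool = bl.pool_group_counts([s for s in filtered if s.group == "control"])
        trt_pool = bl.pool_group_counts([s for s in filtered if s.group == "treatment"])
        stages.append("pool_groups")
        dmps = bl.call_baseline_dmps(ctl_pool, trt_pool, alpha=cfg.baseline_alpha,
                                     min_diff=cfg.baseline_min_diff,
                                     min_coverage=cfg.min_coverage)
        stages.append("call_baseline_dmps")
        dmrs = bl.bin_dmrs(dmps, window=cfg.baseline_window,
                           min_dmps=cfg.baseline_min_dmps,
                           uniform_direction=cfg.baseline_uniform_direction)
        stages.append("bin_dmrs")
        dmg_ids = bl.dmrs_to_genes(dmrs, self.genes)
        stages.append("dmrs_to_genes")
        return FisherBaselineResults(self, dmps, dmrs, dmg_ids, stages)


def compare_results(signal: MethylSignalResults | set[str],
                    baseline: FisherBaselineResults | set[str]) -> dict:
    """Venn counts, Jaccard and per-gene cross-tabulation of the two DMG sets."""
    set_a = signal.dmg_ids if hasattr(signal, "dmg_ids") else set(signal)
    set_b = baseline.dmg_ids if hasattr(baseline, "dmg_ids") else set(baseline)
    a_only, overlap, b_only, jaccard = bl.compare_gene_sets(set_a, set_b)
    genes = sorted(set_a | set_b)
    table = pd.DataFrame({
        "gene_id": genes,
        "signal_detection": [g in set_a for g in genes],
        "baseline": [g in set_b for g in genes],
    })
    return {
        "signal_only": a_only,
        "overlap": overlap,
        "baseline_only": b_only,
        "jaccard": jaccard,
        "table": table,
    }
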