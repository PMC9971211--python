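"""Differentially methylated gene (DMG) calling from per-sample DMP counts.

DMPs are aggregated inside annotated genes (1-based inclusive overlap,
strand ignored; a DMP inside two overlapping genes counts for both).
Genes passing a count/density gate — at least 3 treatment-group DMPs and
at least 3 DMPs per 10 kbp by default — are tested for a group effect on
per-sample DMP counts with the better of Poisson and negative-binomial
regression (AIC-selected; NB considered only when the pooled counts are
overdispersed), using a likelihood-ratio test with one degree of
freedom.  Benjamini–Hochberg-adjusted p < 0.05 and log2 fold change > 1
flag a DMG.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.stats.multitest import multipletests


def count_dmps_in_genes(dmp_sets: Mapping[str, pd.DataFrame],
                        genes: pd.DataFrame) -> pd.DataFrame:
    """Count each sample's DMPs inside each annotated gene.

    ``dmp_sets`` maps sample_id -> DMP table (columns chrom, pos);
    ``genes`` has columns gene_id, chrom, start, end.  A DMP at position
    p counts for gene g iff g.start <= p <= g.end on the same chromosome.
    Every gene appears in the output (zero counts included); DMPs on
    chromosomes absent from the annotation are logged and unassigned.

    Returns a DataFrame indexed by gene_id with one integer column per
    sample plus ``gene_length``.
    """
    out = pd.DataFrame(index=genes["gene_id"])
    out["gene_length"] = (genes["end"] - genes["start"] + 1).to_numpy()
    gene_chroms = set(genes["chrom"])
    for sample_id, dmps in dmp_sets.items():
        counts = np.zeros(len(genes), dtype=np.int64)
        if len(dmps):
            unknown = set(dmps["chrom"]) - gene_chroms
            if unknown:
                warnings.warn(
                    f"sample {sample_id}: DMPs on chromosome(s) {sorted(unknown)} "
                    f"absent from the annotation were not assigned to any gene",
                    stacklevel=2)
            for chrom, sub in dmps.groupby("chrom", sort=False):
                mask = (genes["chrom"] == chrom).to_numpy()
                if not mask.any():
                    continue
                pos = np.sort(sub["pos"].to_numpy())
                starts = genes.loc[mask, "start"].to_numpy()
                ends = genes.loc[mask, "end"].to_numpy()
                # DMPs in [start, end] inclusive per gene
                counts[mask] += (np.searchsorted(pos, ends, side="right")
                                 - np.searchsorted(pos, starts, side="left"))
        out[sample_id] = counts
    return out


def filter_density(counts: pd.DataFrame, treatment_samples: Sequence[str],
                   min_dmps: int = 3, min_density: float = 3.0) -> pd.Index:
    """Genes with enough pooled treatment DMPs, by count and density.

    A gene is retained iff its total treatment-group DMP count is
    >= ``min_dmps`` AND (count / gene_length) * 10,000 >= ``min_density``
    (i.e. at least ``min_density`` DMPs per 10 kbp).
    """
    if min_dmps <= 0 or min_density <= 0:
        raise ValueError("thresholds must be positive")
    trt_total = counts[list(treatment_samples)].sum(axis=1)
    density = trt_total / counts["gene_length"] * 10_000.0
    keep = (trt_total >= min_dmps) & (density >= min_density)
    return counts.index[keep]


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def _poisson_lrt(y: np.ndarray, group: np.ndarray) -> tuple[float, float, float]:
    """Closed-form grouped-Poisson LRT: (loglik_null, loglik_group, lrt)."""
    mu0 = np.full_like(y, y.mean(), dtype=float)
    mu_g = np.where(group == 1, y[group == 1].mean() if (group == 1).any() else 0.0,
                    y[group == 0].mean() if (group == 0).any() else 0.0)
    ll0 = _poisson_loglik(y, mu0)
    ll1 = _poisson_loglik(y, mu_g.astype(float))
    return ll0, ll1, max(0.0, 2.0 * (ll1 - ll0))


def _negbin_lrt(y: np.ndarray, group: np.ndarray) -> tuple[float, float, float]:
    """NB2 LRT via ML (statsmodels), dispersion estimated per model."""
    exog0 = np.ones((y.size, 1))
    exog1 = np.column_stack([np.ones(y.size), group])
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        m0 = NegativeBinomial(y, exog0).fit(disp=0, maxiter=200)
        m1 = NegativeBinomial(y, exog1).fit(disp=0, maxiter=200)
    ll0, ll1 = float(m0.llf), float(m1.llf)
    if not (np.isfinite(ll0) and np.isfinite(ll1)):
        raise RuntimeError("negative-binomial fit did not converge")
    return ll0, ll1, max(0.0, 2.0 * (ll1 - ll0))


def test_gene(counts: Sequence[float], groups: Sequence[str] | Sequence[int]) -> dict:
    """Likelihood-ratio test of a treatment effect on one gene's DMP counts.

    ``groups`` holds "control"/"treatment" labels (or 0/1).  The null
    (intercept-only) and group-effect models are fitted under Poisson and
    — when the pooled sample variance exceeds the mean — negative
    binomial; the family with the lower group-model AIC is used for the
    LRT (chi-square, 1 df).  log2fc compares group mean counts and is
    +inf when the control mean is 0 but the treatment mean is positive.
    """
    y = np.asarray(counts, dtype=float)
    g = np.asarray([1 if v in (1, "treatment") else 0 for v in groups])
    if y.size != g.size:
        raise ValueError("counts and groups differ in length")
    if not (g == 0).any() or not (g == 1).any():
        raise ValueError("need at least one sample in each group")

    mean_ctl = float(y[g == 0].mean())
    mean_trt = float(y[g == 1].mean())
    if mean_ctl == 0.0 and mean_trt == 0.0:
        log2fc = 0.0
    elif mean_ctl == 0.0:
        log2fc = float("inf")
    elif mean_trt == 0.0:
        log2fc = float("-inf")
    else:
        log2fc = float(np.log2(mean_trt / mean_ctl))

    fits = {}
    ll0_p, ll1_p, lrt_p = _poisson_lrt(y, g)
    fits["poisson"] = (ll1_p, 2 * 2 - 2 * ll1_p, lrt_p)  # k=2: intercept + group
    if y.var(ddof=1) > y.mean() and y.mean() > 0:
        try:
            ll0_nb, ll1_nb, lrt_nb = _negbin_lrt(y, g)
            fits["negbin"] = (ll1_nb, 2 * 3 - 2 * ll1_nb, lrt_nb)  # + dispersion
        except Exception:
            pass

    family_used = min(fits, key=lambda f: fits[f][1])
    _, _, lrt_stat = fits[family_used]
    p_value = float(stats.chi2.sf(lrt_stat, df=1)) if lrt_stat > 0 else 1.0
    return {
        "family_used": family_used,
        "mean_control": mean_ctl,
        "mean_treatment": mean_trt,
        "log2fc": log2fc,
        "lrt_stat": float(lrt_stat),
        "p_value": p_value,
    }


def adjust_pvalues(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def call_dmgs(results: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0,
              direction: str = "greater") -> pd.DataFrame:
    """Flag DMGs: adjusted p < alpha and log2 fold change beyond lfc_min.

    ``direction="greater"`` requires log2fc > lfc_min (treatment above
    control, the default reading of the fold-change gate);
    ``"two_sided"`` requires |log2fc| > lfc_min.
    """
    if direction not in ("greater", "two_sided"):
        raise ValueError(f"direction must be greater/two_sided, got {direction!r}")
    out = results.copy()
    fc = out["log2fc"]
    fc_pass = fc > lfc_min if direction == "greater" else fc.abs() > lfc_min
    out["is_dmg"] = (out["p_adjusted"] < alpha) & fc_pass
    return out


def dmg_table(counts: pd.DataFrame, groups: Mapping[str, str],
              min_dmps: int = 3, min_density: float = 3.0,
              alpha: float = 0.05, lfc_min: float = 1.0,
              direction: str = "greater") -> pd.DataFrame:
    """Full DMG stage: density gate, per-gene LRT, BH adjustment, calling.

    ``groups`` maps sample_id -> group label.  Returns one row per
    retained gene.
    """
    sample_ids = [c for c in counts.columns if c != "gene_length"]
    treatment = [s for s in sample_ids if groups[s] == "treatment"]
    tested = filter_density(counts, treatment, min_dmps=min_dmps,
                            min_density=min_density)
    rows = []
    labels = [groups[s] for s in sample_ids]
    for gene_id in tested:
        y = counts.loc[gene_id, sample_ids].to_numpy(dtype=float)
        try:
            res = test_gene(y, labels)
        except Exception:
            res = {"family_used": "failed", "mean_control": float("nan"),
                   "mean_treatment": float("nan"), "log2fc": 0.0,
                   "lrt_stat": 0.0, "p_value": 1.0}
        res["gene_id"] = gene_id
        rows.append(res)
    if not rows:
        return pd.DataFrame(columns=["gene_id", "family_used", "mean_control",
                                     "mean_treatment", "log2fc", "lrt_stat",
                                     "p_value", "p_adjusted", "is_dmg"])
    df = pd.DataFrame(rows)[["gene_id", "family_used", "mean_control",
                             "mean_treatment", "log2fc", "lrt_stat", "p_value"]]
    df["p_adjusted"] = adjust_pvalues(df["p_value"].to_numpy())
    return call_dmgs(df, alpha=alpha, lfc_min=lfc_min, direction=direction)
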