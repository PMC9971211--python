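"""The prevalent two-sample comparison pipeline, for contrast.

Most differential-methylation tools pool reads within group, test each
cytosine with Fisher's exact test (or a regression variant), keep sites
passing an arbitrary methylation-difference cutoff (commonly 10–40%,
here 20% by default), and aggregate DMPs into fixed-window DMRs.  This
module implements that archetype — Fisher variant only — so its gene
calls can be compared set-wise with the signal-detection pipeline's.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmg import adjust_pvalues
from .divergence import SITE_KEY
from .io import MethylomeSample


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_site_test(ctl: tuple[int, int], trt: tuple[int, int]) -> float:
    """Two-sided Fisher exact p for one site's 2x2 (meth, unmeth) table.

    Two-sided by the "sum of table probabilities <= observed" convention.
    """
    a, b = int(ctl[0]), int(ctl[1])
    c, d = int(trt[0]), int(trt[1])
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table: Fisher test undefined")
    return _fisher_cached(a, b, c, d)


_DELTA_EPS = 1e-12  # |0.6 - 0.4| < 0.2 in floats; boundary is inclusive


def delta_filter(p_ctl: float, p_trt: float, min_diff: float = 0.20) -> bool:
    """The arbitrary methylation-difference gate: |p_trt - p_ctl| >= min_diff."""
    if not (0.0 < min_diff < 1.0):
        raise ValueError(f"min_diff must be in (0, 1), got {min_diff}")
    return abs(p_trt - p_ctl) >= min_diff - _DELTA_EPS


def pool_group_counts(samples: Sequence[MethylomeSample]) -> pd.DataFrame:
    """Sum counts within a group over the union of site keys."""
    frames = [s.sites[SITE_KEY + ["n_meth", "n_unmeth"]] for s in samples]
    return (
        pd.concat(frames, ignore_index=True)
        .groupby(SITE_KEY, as_index=False, sort=False)[["n_meth", "n_unmeth"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )


def call_baseline_dmps(ctl_pool: pd.DataFrame, trt_pool: pd.DataFrame,
                       alpha: float = 0.05, min_diff: float = 0.20,
                       min_coverage: int = 4) -> pd.DataFrame:
    """Fisher-test DMPs on pooled counts at shared sites.

    Sites shared by both pools and passing coverage in both are tested;
    DMPs are those with BH-adjusted p < alpha AND an absolute difference
    in pooled methylation level >= min_diff.  Direction (hypo/hyper,
    treatment relative to control) is recorded.
    """
    ctl = ctl_pool.rename(columns={"n_meth": "ctl_meth", "n_unmeth": "ctl_unmeth"})
    trt = trt_pool.rename(columns={"n_meth": "trt_meth", "n_unmeth": "trt_unmeth"})
    merged = ctl.merge(trt, on=SITE_KEY, how="inner")
    cov_ctl = merged["ctl_meth"] + merged["ctl_unmeth"]
    cov_trt = merged["trt_meth"] + merged["trt_unmeth"]
    merged = merged[(cov_ctl >= min_coverage) & (cov_trt >= min_coverage)]
    merged = merged.reset_index(drop=True)
    if merged.empty:
        return merged.assign(p_ctl=[], p_trt=[], p_value=[], p_adjusted=[],
                             direction=[])
    pvals = np.fromiter(
        (_fisher_cached(a, b, c, d) for a, b, c, d in zip(
            merged["ctl_meth"], merged["ctl_unmeth"],
            merged["trt_meth"], merged["trt_unmeth"])),
        dtype=float, count=len(merged))
    merged["p_ctl"] = merged["ctl_meth"] / (merged["ctl_meth"] + merged["ctl_unmeth"])
    merged["p_trt"] = merged["trt_meth"] / (merged["trt_meth"] + merged["trt_unmeth"])
    merged["p_value"] = pvals
    merged["p_adjusted"] = adjust_pvalues(pvals)
    delta = merged["p_trt"] - merged["p_ctl"]
    keep = (merged["p_adjusted"] < alpha) & (delta.abs() >= min_diff - _DELTA_EPS)
    out = merged.loc[keep].reset_index(drop=True)
    out["direction"] = np.where(out["p_trt"] >= out["p_ctl"], "hyper", "hypo")
    return out


def bin_dmrs(dmps: pd.DataFrame, window: int = 100, min_dmps: int = 3,
             uniform_direction: bool = False) -> pd.DataFrame:
    """Aggregate DMPs into fixed, non-overlapping genomic tiles.

    Tiles are [k*window + 1, (k+1)*window] per chromosome (1-based
    inclusive); a tile is reported as a DMR iff it holds >= min_dmps
    DMPs, all of the same direction when ``uniform_direction`` is set.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    cols = ["chrom", "start", "end", "n_dmps", "direction"]
    if dmps.empty:
        return pd.DataFrame(columns=cols)
    df = dmps.copy()
    df["_tile"] = (df["pos"] - 1) // window
    rows = []
    for (chrom, tile), sub in df.groupby(["chrom", "_tile"], sort=True):
        if len(sub) < min_dmps:
            continue
        directions = set(sub["direction"]) if "direction" in sub.columns else {"mixed"}
        if uniform_direction and len(directions) > 1:
            continue
        rows.append({
            "chrom": chrom,
            "start": int(tile) * window + 1,
            "end": (int(tile) + 1) * window,
            "n_dmps": len(sub),
            "direction": directions.pop() if len(directions) == 1 else "mixed",
        })
    return pd.DataFrame(rows, columns=cols)


def dmrs_to_genes(dmrs: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Genes intersecting at least one DMR (the baseline's DMG notion)."""
    hit: set[str] = set()
    if dmrs.empty:
        return hit
    for chrom, sub in dmrs.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        for row in sub.itertuples(index=False):
            overlap = (g["start"] <= row.end) & (g["end"] >= row.start)
            hit.update(g.loc[overlap, "gene_id"])
    return hit


def compare_gene_sets(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, int, int, float]:
    """Venn counts and Jaccard index of two gene-id sets.

    Returns (|A only|, |A and B|, |B only|, jaccard); jaccard is 0 when
    both sets are empty.
    """
    a, b = set(set_a), set(set_b)
    inter = a & b
    union = a | b
    jaccard = len(inter) / len(union) if union else 0.0
    return (len(a - b), len(inter), len(b - a), jaccard)
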