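"""Pooled control centroid and per-site methylation divergence.

Signal detection needs a reference describing the background (non-
treatment) variation of the methylome.  Control replicates are pooled by
element-wise summation of their read counts at each cytosine; the
resulting centroid is the reference methylome.  Every sample — treatment
replicates AND the controls themselves — is then compared to that
reference site by site, yielding a squared Hellinger divergence and a
total variation distance between the two Bernoulli methylation
distributions at each cytosine.

Pooling counts (rather than averaging proportions) preserves read-depth
information: the centroid's methylation level at a site equals the
coverage-weighted mean of the control levels there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CytosineSite, MethylomeSample

#: Jeffreys pseudo-counts; applied only when converting counts to levels,
#: never stored back into count tables.
DEFAULT_PRIOR = (0.5, 0.5)

SITE_KEY = ["chrom", "pos", "strand", "context"]


class ReplicationError(ValueError):
    """Too few control replicates to estimate a reference methylome."""


@dataclass
class ReferenceMethylome:
    """Centroid of the control group: summed counts per cytosine."""

    sites: pd.DataFrame = field(repr=False)
    n_pooled: int = 1

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def pool_centroid(controls: Sequence[MethylomeSample], strict: bool = True) -> ReferenceMethylome:
    """Pool control replicates into a centroid reference methylome.

    Counts are summed element-wise over the union of site keys (a site
    absent from one replicate contributes zero).  Estimating background
    stochastic variation is not meaningful from fewer than three control
    replicates, so by default (``strict=True``) fewer than 3 controls is
    an error; with ``strict=False`` a warning is emitted and pooling
    proceeds.
    """
    if len(controls) == 0:
        raise ValueError("at least one control sample is required")
    if len(controls) < 3:
        msg = (f"reference methylome requested from only {len(controls)} control "
               f"replicate(s); at least 3 are needed to estimate background variation")
        if strict:
            raise ReplicationError(msg)
        warnings.warn(msg, stacklevel=2)
    frames = [s.sites[SITE_KEY + ["n_meth", "n_unmeth"]] for s in controls]
    pooled = (
        pd.concat(frames, ignore_index=True)
        .groupby(SITE_KEY, as_index=False, sort=False)[["n_meth", "n_unmeth"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ReferenceMethylome(sites=pooled, n_pooled=len(controls))


def methylation_level(n_meth, n_unmeth, prior: tuple[float, float] = (0.0, 0.0)):
    """Estimate a methylation level as (n_meth + a)/(coverage + a + b).

    With the default zero prior this is the maximum-likelihood
    proportion; the Jeffreys prior (0.5, 0.5) regularizes low-coverage
    sites away from exactly 0 or 1.  Accepts scalars or arrays.
    """
    a, b = prior
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    total = n_meth + n_unmeth + a + b
    if np.any(total <= 0):
        raise ValueError("undefined methylation level: zero coverage and zero prior")
    out = (n_meth + a) / total
    return out if out.ndim else float(out)


def hellinger_divergence(p, q):
    """Squared Hellinger divergence between Bernoulli(p) and Bernoulli(q).

    hdiv = (sqrt(p) - sqrt(q))**2 + (sqrt(1-p) - sqrt(1-q))**2, in [0, 2].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    out = (np.sqrt(p) - np.sqrt(q)) ** 2 + (np.sqrt(1.0 - p) - np.sqrt(1.0 - q)) ** 2
    return out if out.ndim else float(out)


def coverage_weight(n_ref, n_smp):
    """Harmonic-mean read-depth weight w = 2*n1*n2/(n1+n2).

    Reduces to n when both coverages equal n.
    """
    n_ref = np.asarray(n_ref, dtype=float)
    n_smp = np.asarray(n_smp, dtype=float)
    total = n_ref + n_smp
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(total > 0, 2.0 * n_ref * n_smp / np.where(total > 0, total, 1.0), 0.0)
    return w if w.ndim else float(w)


def site_divergence(ref_site: CytosineSite, smp_site: CytosineSite,
                    prior: tuple[float, float] = DEFAULT_PRIOR) -> dict:
    """Divergence record for one (reference site, sample site) pair."""
    if (ref_site.chrom, ref_site.pos, ref_site.strand, ref_site.context) != (
            smp_site.chrom, smp_site.pos, smp_site.strand, smp_site.context):
        raise ValueError("site keys do not match between reference and sample")
    p_ref = methylation_level(ref_site.n_meth, ref_site.n_unmeth, prior)
    p_smp = methylation_level(smp_site.n_meth, smp_site.n_unmeth, prior)
    hdiv = hellinger_divergence(p_ref, p_smp)
    w = coverage_weight(ref_site.coverage, smp_site.coverage)
    return {
        "chrom": ref_site.chrom, "pos": ref_site.pos, "strand": ref_site.strand,
        "context": ref_site.context,
        "p_ref": p_ref, "p_smp": p_smp,
        "hdiv": hdiv, "hdiv_w": w * hdiv, "tv": abs(p_smp - p_ref),
    }


def divergence_table(
    samples: Sequence[MethylomeSample],
    reference: ReferenceMethylome,
    prior: tuple[float, float] = DEFAULT_PRIOR,
    min_coverage: int = 4,
    loo_controls: bool = True,
) -> pd.DataFrame:
    """Per-site divergence of every sample (controls included) vs the reference.

    One record per (site, sample) at the intersection of site keys where
    both the reference and the sample pass ``min_coverage``.  Controls are
    deliberately included: their divergences define the null signal used
    for distribution fitting and cutoff learning.

    With ``loo_controls`` (the default), each control replicate is
    compared against the reference with its own counts subtracted — the
    leave-one-out centroid of the remaining controls.  Comparing a
    control against a pool that contains its own reads shrinks its
    divergence below that of an independent replicate, which would bias
    the learned control/treatment cutoff; leave-one-out makes the control
    divergences an honest sample of the null.  When the pool holds a
    single control the full reference is used (self-comparison).

    Columns: chrom, pos, strand, context, sample_id, group, cov_ref,
    cov_smp, p_ref, p_smp, hdiv, hdiv_w, tv.
    """
    ref_full = reference.sites.rename(
        columns={"n_meth": "ref_meth", "n_unmeth": "ref_unmeth"})

    a, b = prior
    out_frames = []
    for sample in samples:
        smp = sample.sites[SITE_KEY + ["n_meth", "n_unmeth"]].copy()
        smp["cov_smp"] = smp["n_meth"] + smp["n_unmeth"]
        smp = smp[smp["cov_smp"] >= min_coverage]
        merged = ref_full.merge(smp, on=SITE_KEY, how="inner")
        if loo_controls and sample.group == "control" and reference.n_pooled > 1:
            # subtract the control's own reads from the pooled reference
            merged["ref_meth"] = (merged["ref_meth"] - merged["n_meth"]).clip(lower=0)
            merged["ref_unmeth"] = (merged["ref_unmeth"] - merged["n_unmeth"]).clip(lower=0)
        merged["cov_ref"] = merged["ref_meth"] + merged["ref_unmeth"]
        merged = merged[merged["cov_ref"] >= min_coverage]
        if merged.empty:
            continue
        p_ref = (merged["ref_meth"] + a) / (merged["cov_ref"] + a + b)
        p_smp = (merged["n_meth"] + a) / (merged["cov_smp"] + a + b)
        hdiv = hellinger_divergence(p_ref.to_numpy(), p_smp.to_numpy())
        w = coverage_weight(merged["cov_ref"].to_numpy(), merged["cov_smp"].to_numpy())
        rec = merged[SITE_KEY + ["cov_ref", "cov_smp"]].copy()
        rec["sample_id"] = sample.sample_id
        rec["group"] = sample.group
        rec["p_ref"] = p_ref.to_numpy()
        rec["p_smp"] = p_smp.to_numpy()
        rec["hdiv"] = hdiv
        rec["hdiv_w"] = w * hdiv
        rec["tv"] = np.abs(rec["p_smp"] - rec["p_ref"])
        out_frames.append(rec)
    if not out_frames:
        warnings.warn("divergence table is empty (no shared sites passing coverage)",
                      stacklevel=2)
        return pd.DataFrame(columns=SITE_KEY + ["cov_ref", "cov_smp", "sample_id",
                                                "group", "p_ref", "p_smp",
                                                "hdiv", "hdiv_w", "tv"])
    return pd.concat(out_frames, ignore_index=True)
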