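"""Readers and writers for the file formats the pipeline touches.

Per-cytosine methylation counts travel as Bismark-style CX / cytosine
reports (7-column TSV: chromosome, 1-based position, strand, methylated
count, unmethylated count, context, trinucleotide).  Gene annotations are
GFF3; sample sheets are 3-column TSV.  All internal coordinates are
1-based inclusive, matching the source formats; the only conversion to
0-based half-open happens in the BED writer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: canonical column order of the in-memory site table
SITE_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]

# context-consistent trinucleotide placeholders used when the true
# trinucleotide is unknown (e.g. simulator output)
_TRI_PLACEHOLDER = {"CG": "CGA", "CHG": "CAG", "CHH": "CAA"}


class CxParseError(ValueError):
    """A malformed line in a CX report (carries the 1-based line number)."""


class DuplicateSiteError(ValueError):
    """Two records share the same (chrom, pos, strand) key."""


class CytosineSite(NamedTuple):
    """One cytosine: genomic address, strand, context and read counts."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass
class MethylomeSample:
    """A replicate's full set of cytosine sites plus its group label.

    ``sites`` is a DataFrame with columns ``chrom, pos, strand, n_meth,
    n_unmeth, context`` sorted by (chrom, pos) and free of duplicate
    (chrom, pos, strand) keys.
    """

    sample_id: str
    group: str
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.group not in ("control", "treatment"):
            raise ValueError(f"group must be control/treatment, got {self.group!r}")
        self.sites = _normalize_sites(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def iter_sites(self) -> Iterable[CytosineSite]:
        for row in self.sites.itertuples(index=False):
            yield CytosineSite(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.n_meth), int(row.n_unmeth),
            )


def _normalize_sites(df: pd.DataFrame) -> pd.DataFrame:
    df = df[[c for c in SITE_COLUMNS if c in df.columns] +
            [c for c in df.columns if c not in SITE_COLUMNS]].copy()
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table is missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValueError("positions must be >= 1")
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise ValueError("counts must be non-negative")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        raise ValueError(f"unknown context(s): {sorted(df.loc[bad_ctx, 'context'].unique())}")
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        raise ValueError(f"unknown strand(s): {sorted(df.loc[bad_strand, 'strand'].unique())}")
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise DuplicateSiteError(
            f"duplicate site key ({first.chrom}, {first.pos}, {first.strand})"
        )
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def read_cx_report(
    path: str | Path,
    contexts: Sequence[str] | None = None,
    sample_id: str | None = None,
    group: str = "control",
) -> MethylomeSample:
    """Read a Bismark-style cytosine report into a :class:`MethylomeSample`.

    Lines whose context is outside ``contexts`` (when given) are skipped.
    Malformed lines raise :class:`CxParseError` naming the line number;
    duplicate (chrom, pos, strand) keys raise :class:`DuplicateSiteError`.
    """
    path = Path(path)
    if contexts is not None:
        bad = set(contexts) - set(CONTEXTS)
        if bad:
            raise ValueError(f"unknown requested context(s): {sorted(bad)}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise CxParseError(f"{path.name}:{lineno}: expected >=7 fields, got {len(fields)}")
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            if context not in CONTEXTS:
                raise CxParseError(f"{path.name}:{lineno}: unknown context {context!r}")
            if contexts is not None and context not in contexts:
                continue
            if strand not in STRANDS:
                raise CxParseError(f"{path.name}:{lineno}: bad strand {strand!r}")
            try:
                pos = int(pos_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise CxParseError(f"{path.name}:{lineno}: non-integer field ({exc})") from None
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                raise CxParseError(f"{path.name}:{lineno}: out-of-range value")
            rows.append((chrom, pos, strand, n_meth, n_unmeth, context))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return MethylomeSample(
        sample_id=sample_id or path.stem, group=group, sites=df
    )


def write_cx_report(sample: MethylomeSample, path: str | Path) -> None:
    """Write a sample as a 7-column CX report (inverse of the reader)."""
    df = sample.sites
    tri = df["context"].map(_TRI_PLACEHOLDER)
    out = df[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]].copy()
    out["tri"] = tri.values
    out.to_csv(path, sep="\t", header=False, index=False)


_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Extract ``gene`` features from a GFF3 file.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand
    (1-based inclusive coordinates, as in the file).  Features other than
    ``gene`` are ignored.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise CxParseError(f"{path.name}:{lineno}: expected 9 GFF3 fields")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields[:9]
            if ftype != "gene":
                continue
            m = _GFF_ID_RE.search(attrs)
            if not m:
                raise CxParseError(f"{path.name}:{lineno}: gene feature without ID attribute")
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ValueError(f"{path.name}:{lineno}: start > end ({start} > {end})")
            rows.append((m.group(1), chrom, start, end, strand if strand in "+-." else "."))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def filter_coverage(sample: MethylomeSample, min_coverage: int = 4) -> MethylomeSample:
    """Keep sites with n_meth + n_unmeth >= min_coverage (order preserved).

    The cutoff is the usual largely-arbitrary coverage gate applied before
    any differential analysis; 4 is a common field default.
    """
    if min_coverage < 1:
        raise ValueError(f"min_coverage must be >= 1, got {min_coverage}")
    keep = (sample.sites["n_meth"] + sample.sites["n_unmeth"]) >= min_coverage
    return MethylomeSample(
        sample_id=sample.sample_id,
        group=sample.group,
        sites=sample.sites.loc[keep].reset_index(drop=True),
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with header sample_id, path, group."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "path", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = ~df["group"].isin(["control", "treatment"])
    if bad.any():
        raise ValueError(
            f"sample sheet group values must be control/treatment; got {sorted(df.loc[bad, 'group'].unique())}"
        )
    if not (df["group"] == "control").any():
        raise ValueError("sample sheet must contain at least one control row")
    return df


def load_samples(sheet: pd.DataFrame, base_dir: str | Path | None = None,
                 contexts: Sequence[str] | None = None) -> list[MethylomeSample]:
    """Load every CX report listed in a sample sheet."""
    base = Path(base_dir) if base_dir is not None else None
    samples = []
    for row in sheet.itertuples(index=False):
        p = Path(row.path)
        if base is not None and not p.is_absolute():
            p = base / p
        samples.append(read_cx_report(p, contexts=contexts,
                                      sample_id=row.sample_id, group=row.group))
    return samples


def intervals_to_bed(df: pd.DataFrame, path: str | Path,
                     name_col: str | None = None, score_col: str | None = None,
                     strand_col: str | None = None) -> None:
    """Export 1-based inclusive intervals (columns chrom, start, end) as BED6.

    This is the single place where coordinates convert to 0-based
    half-open.
    """
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64) - 1,
        "end": df["end"].astype(np.int64),
        "name": df[name_col] if name_col else ".",
        "score": df[score_col] if score_col else 0,
        "strand": df[strand_col] if strand_col else ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def sites_to_bed(df: pd.DataFrame, path: str | Path,
                 name_col: str | None = "context",
                 score_col: str | None = None) -> None:
    """Export single-cytosine records (column pos) as BED6."""
    tmp = df.copy()
    tmp["start"] = tmp["pos"]
    tmp["end"] = tmp["pos"]
    intervals_to_bed(tmp, path, name_col=name_col, score_col=score_col,
                     strand_col="strand" if "strand" in tmp.columns else None)
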