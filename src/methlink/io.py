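"""Readers and writers for every external format the pipeline touches.

Coordinate conventions, applied uniformly:

* Bismark-style coverage files carry 1-based inclusive positions
  (start == end for a single CpG).
* All internal intervals are 0-based half-open ``[start, end)``.
* BED output is 0-based half-open.

A 1-based CpG position ``p`` falls inside an internal interval ``[s, e)``
iff ``s <= p - 1 < e``.

The methylation-percentage column of coverage files is derived from the
counts and never trusted; a discrepancy beyond 0.5 percentage points
raises a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("NN", "RM", "UC")

COMPARISONS = ("RMvsNN", "RMvsUC", "UCvsNN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, pos_1based: int) -> bool:
        """True iff the 1-based position lies inside this interval."""
        return self.start <= pos_1based - 1 < self.end

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: id, chromosome, strand and 1-based TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"TSS must be a positive 1-based position, got {self.tss}")


@dataclass
class SampleSheet:
    """Sample-to-group assignment for the three cohort groups NN/RM/UC."""

    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise ValueError(
                f"unknown group labels {bad}; allowed labels are {list(GROUPS)}"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def group_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.groups))

    def members(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; allowed: {list(GROUPS)}")
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def indices(self, group: str) -> np.ndarray:
        members = set(self.members(group))
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if s in members], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups})


@dataclass
class CpGMethylation:
    """Per-CpG, per-sample methylated / total read counts.

    ``pos`` is 1-based; rows are sorted by (chrom, pos) and strictly
    increasing within each chromosome.  ``n_meth`` and ``n_total`` are
    (n_cpgs x n_samples) integer matrices; a zero total marks a missing
    observation (beta undefined there).
    """

    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list[str]
    n_meth: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.pos)
        if self.n_meth.shape != (m, len(self.sample_ids)):
            raise ValueError("n_meth shape mismatch")
        if self.n_total.shape != self.n_meth.shape:
            raise ValueError("n_total shape mismatch")
        if np.any(self.n_meth < 0) or np.any(self.n_total < 0):
            raise ValueError("negative counts")
        if np.any(self.n_meth > self.n_total):
            raise ValueError("methylated count exceeds total count")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    def beta(self) -> np.ndarray:
        """Methylation proportion matrix; NaN where total coverage is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            b = self.n_meth / self.n_total
        return np.where(self.n_total > 0, b, np.nan)

    def subset_rows(self, mask: np.ndarray) -> "CpGMethylation":
        return CpGMethylation(
            self.chrom[mask],
            self.pos[mask],
            list(self.sample_ids),
            self.n_meth[mask],
            self.n_total[mask],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CpGMethylation":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CpGMethylation(
            self.chrom,
            self.pos,
            list(sample_ids),
            self.n_meth[:, idx],
            self.n_total[:, idx],
        )

    def interval_mask(self, interval: GenomicInterval) -> np.ndarray:
        """Boolean row mask of CpGs whose 1-based pos lies in the interval."""
        return (
            (self.chrom == interval.chrom)
            & (interval.start <= self.pos - 1)
            & (self.pos - 1 < interval.end)
        )


# ---------------------------------------------------------------------------
# Bismark-style coverage files
# ---------------------------------------------------------------------------

_COV_COLUMNS = ["chrom", "start", "end", "pct", "n_meth", "n_unmeth"]


def read_bismark_coverage(
    paths: Mapping[str, Path | str], sheet: SampleSheet
) -> CpGMethylation:
    """Load per-sample coverage files into one counts matrix.

    ``paths`` maps sample id to file.  The output holds the union of
    positions across samples; absent (sample, position) cells get zero
    total coverage.  Percentages are recomputed from the counts.
    """
    missing = [s for s in sheet.sample_ids if s not in paths]
    if missing:
        raise FileNotFoundError(
            f"no coverage file supplied for sample(s): {missing}"
        )
    per_sample: dict[str, pd.DataFrame] = {}
    for sample in sheet.sample_ids:
        path = Path(paths[sample])
        if not path.exists():
            raise FileNotFoundError(
                f"coverage file for sample {sample!r} not found: {path}"
            )
        df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS, comment="#")
        if df.shape[1] != 6:
            raise FormatError(f"{path}: expected 6 tab-separated fields")
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise FormatError(f"{path}: negative counts")
        total = df["n_meth"] + df["n_unmeth"]
        with np.errstate(invalid="ignore", divide="ignore"):
            derived = np.where(total > 0, 100.0 * df["n_meth"] / total, 0.0)
        off = np.abs(derived - df["pct"].to_numpy(float)) > 0.5
        if off.any():
            warnings.warn(
                f"{path}: {int(off.sum())} rows where the methylation percentage "
                "disagrees with the counts by more than 0.5%; counts are used",
                stacklevel=2,
            )
        per_sample[sample] = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["start"].astype(int),
                "n_meth": df["n_meth"].astype(int),
                "n_total": total.astype(int),
            }
        )
    keys = pd.concat(
        [d[["chrom", "pos"]] for d in per_sample.values()], ignore_index=True
    ).drop_duplicates()
    keys = keys.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    m = len(keys)
    n = len(sheet)
    n_meth = np.zeros((m, n), dtype=int)
    n_total = np.zeros((m, n), dtype=int)
    index = pd.MultiIndex.from_frame(keys)
    for j, sample in enumerate(sheet.sample_ids):
        d = per_sample[sample].set_index(["chrom", "pos"])
        loc = index.get_indexer(d.index)
        n_meth[loc, j] = d["n_meth"].to_numpy()
        n_total[loc, j] = d["n_total"].to_numpy()
    return CpGMethylation(
        keys["chrom"].to_numpy(dtype=object),
        keys["pos"].to_numpy(dtype=int),
        list(sheet.sample_ids),
        n_meth,
        n_total,
    )


def write_bismark_coverage(meth: CpGMethylation, outdir: Path | str) -> dict[str, Path]:
    """Write one coverage file per sample; rows with zero coverage omitted."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for j, sample in enumerate(meth.sample_ids):
        keep = meth.n_total[:, j] > 0
        nm = meth.n_meth[keep, j]
        nt = meth.n_total[keep, j]
        df = pd.DataFrame(
            {
                "chrom": meth.chrom[keep],
                "start": meth.pos[keep],
                "end": meth.pos[keep],
                "pct": np.round(100.0 * nm / nt, 6),
                "n_meth": nm,
                "n_unmeth": nt - nm,
            }
        )
        path = outdir / f"{sample}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[sample] = path
    return paths


def coverage_paths_in_dir(directory: Path | str, sheet: SampleSheet) -> dict[str, Path]:
    """Expected ``<sample_id>.cov`` layout inside a coverage directory."""
    directory = Path(directory)
    return {s: directory / f"{s}.cov" for s in sheet.sample_ids}


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_sheet(path: Path | str) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"sample sheet must have a {col!r} column")
    return SampleSheet(df["sample_id"].tolist(), df["group"].tolist())


def write_sheet(sheet: SampleSheet, path: Path | str) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path: Path | str, sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Raw gene x sample count matrix; first column is gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate gene_id in counts matrix")
    values = df.to_numpy()
    if not np.all(np.isfinite(values)):
        raise FormatError("counts matrix contains missing values")
    if np.any(values < 0):
        raise FormatError("counts must be nonnegative")
    if np.any(values != np.round(values)):
        raise FormatError("counts must be integers (raw counts, not normalized)")
    df = df.astype(int)
    if sheet is not None:
        if set(df.columns) != set(sheet.sample_ids):
            raise FormatError("counts matrix samples do not match sample sheet")
        df = df[sheet.sample_ids]
    return df


def write_counts(counts: pd.DataFrame, path: Path | str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: Path | str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    for col in ("gene_id", "chrom", "strand", "tss_1based"):
        if col not in df.columns:
            raise FormatError(f"annotation must have a {col!r} column")
    if df["gene_id"].duplicated().any():
        raise FormatError("duplicate gene_id in annotation")
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss_1based))
        for r in df.itertuples()
    ]


def write_annotation(genes: Iterable[GeneModel], path: Path | str) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "tss_1based": g.tss}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DMR BED files
# ---------------------------------------------------------------------------

_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tcomparison\tn_cpgs\tstat\tp\tq"
)


def write_dmr_bed(dmrs: Sequence, path: Path | str) -> None:
    """BED6+5 with 0-based half-open coordinates; q to >= 6 significant digits."""
    lines = [_BED_HEADER]
    for i, d in enumerate(dmrs):
        iv = d.interval
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    f"dmr_{i}",
                    "0",
                    ".",
                    d.comparison,
                    str(d.n_cpgs),
                    f"{d.stat:.9g}",
                    f"{d.p:.9g}",
                    f"{d.q:.9g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dmr_bed(path: Path | str) -> list:
    """Round-trip reader for :func:`write_dmr_bed` output."""
    from .dmr import DMR  # local import to avoid a cycle

    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        out.append(
            DMR(
                interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                comparison=f[6],
                n_cpgs=int(f[7]),
                stat=float(f[8]),
                p=float(f[9]),
                q=float(f[10]),
                group_mean_beta=(np.nan, np.nan),
            )
        )
    return out
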