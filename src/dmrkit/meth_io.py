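"""Readers and writers for every on-disk format the pipeline touches.

All genomic coordinates are 0-based, half-open, everywhere: BED semantics are
native and no 1-based conversion ever happens internally. Chromosome names are
compared by exact string match (no "chr" normalization).

Formats
-------
* cytosine count table: tab-separated ``chrom pos strand context meth_reads
  total_reads``; ``#`` lines are comments. Stores raw counts (k, N) rather than
  a methylation level + coverage pair, because the downstream model consumes
  counts. Files must have ``total_reads >= 1``: an uncovered cytosine is simply
  absent ("not profiled"), never a zero row.
* BED3/BED4 interval sets (``track``/``browser`` lines skipped).
* TSS table: tab-separated ``gene_id chrom tss strand``.
* beta-value matrix: CSV, first column probe id, one column per sample, values
  in [0, 1], empty/NA cells recorded as missing; sample->group labels come from
  a separate two-column file.
* gene count matrix: tab-separated, ``gene_id`` + one integer column per sample.
* PWM: ``#``-comment header carrying the motif name, then one row of four
  whitespace-separated log-odds weights (A C G T) per motif position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_STRANDS = ("+", "-")

_COUNT_HEADER = (
    "# dmrkit cytosine count table\n"
    "# columns: chrom  pos(0-based)  strand  context  meth_reads  total_reads\n"
)


@dataclass(frozen=True)
class CytosineCount:
    """Strand-specific methylation evidence for one cytosine in one sample.

    ``meth_reads`` is the number of reads supporting methylation (k) and
    ``total_reads`` the total number of reads covering the position (N).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos} on {self.chrom}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise ValidationError(
                f"counts violate 0 <= k <= N at {self.chrom}:{self.pos}: "
                f"k={self.meth_reads}, N={self.total_reads}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with an optional label."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site of one gene (0-based position)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"negative TSS for {self.gene_id}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class BetaMatrix:
    """Array-style methylation matrix: per-probe beta values in [0, 1].

    ``values`` has shape (n_probes, n_samples); missing cells are NaN.
    ``group_labels`` is aligned with ``sample_ids``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValidationError("one group label per sample required")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("beta values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# cytosine count tables
# ---------------------------------------------------------------------------

def read_cytosine_counts(path: str | Path) -> list[CytosineCount]:
    """Parse a cytosine count table into validated records, in file order.

    Raises :class:`FormatError` (naming the line) on malformed lines and
    :class:`ValidationError` on invariant violations (k > N, N < 1).
    """
    path = Path(path)
    records: list[CytosineCount] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, context, k_s, n_s = fields
            try:
                pos, k, n = int(pos_s), int(k_s), int(n_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            if n < 1:
                raise ValidationError(
                    f"{path}:{lineno}: total_reads must be >= 1 in files; "
                    "uncovered cytosines are represented by absence"
                )
            try:
                rec = CytosineCount(chrom, pos, strand, context, k, n)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cytosine_counts(records: Iterable[CytosineCount], path: str | Path) -> None:
    """Write records in the cytosine count dialect; round-trips through the reader."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_COUNT_HEADER)
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.context}\t{r.meth_reads}\t{r.total_reads}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals (0-based half-open); track/browser lines skipped."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            if iv.name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# TSS tables and group files
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path) -> list[TssRecord]:
    """Read a tab-separated TSS table: gene_id, chrom, tss, strand."""
    path = Path(path)
    out: list[TssRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            try:
                tss = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer TSS") from exc
            try:
                out.append(TssRecord(fields[0], fields[1], tss, fields[3]))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# columns: gene_id  chrom  tss(0-based)  strand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.tss}\t{r.strand}\n")


def read_group_file(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> group file, preserving file order."""
    path = Path(path)
    design: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields (sample, group)")
            sample, group = fields
            if sample in design:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
            design[sample] = group
    return design


def write_group_file(design: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# columns: sample  group\n")
        for sample, group in design.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, group_path: str | Path) -> BetaMatrix:
    """Read a probes x samples CSV of beta values plus a sample->group file.

    Missing cells (empty/NA) stay missing (NaN), never zero. A value outside
    [0, 1] or a sample absent from the group file is an error.
    """
    df = pd.read_csv(path, index_col=0)
    groups = read_group_file(group_path)
    sample_ids = [str(c) for c in df.columns]
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValidationError(
            f"samples {missing} in {path} are absent from the group file {group_path}"
        )
    values = df.to_numpy(dtype=float)
    bad = np.isfinite(values) & ((values < 0) | (values > 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: beta value {values[i, j]} outside [0, 1] "
            f"(probe {df.index[i]!r}, sample {sample_ids[j]!r})"
        )
    return BetaMatrix(
        probe_ids=[str(p) for p in df.index],
        sample_ids=sample_ids,
        values=values,
        group_labels=[groups[s] for s in sample_ids],
    )


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, float_format="%.6g")


# ---------------------------------------------------------------------------
# gene count matrices
# ---------------------------------------------------------------------------

def read_gene_counts(path: str | Path, group_path: str | Path):
    """Read a tab-separated gene count matrix into a CountMatrix."""
    from .expression import CountMatrix  # local import avoids a module cycle

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    groups = read_group_file(group_path)
    sample_ids = [str(c) for c in df.columns]
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValidationError(f"samples {missing} absent from group file {group_path}")
    counts = df.to_numpy()
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        counts=counts,
        group_labels=[groups[s] for s in sample_ids],
    )


def write_gene_counts(matrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PWM files
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path):
    """Read a plain-text PWM: '#'-comment header (may carry the name), then
    one row of four log-odds weights (A C G T) per position."""
    from .features import PWM  # local import avoids a module cycle

    path = Path(path)
    name: str | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                comment = line.lstrip("#").strip()
                if comment and name is None:
                    name = comment.split()[0]
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 weights (A C G T)")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric weight") from exc
    if not rows:
        raise FormatError(f"{path}: PWM has no positions")
    return PWM(name=name or path.stem, matrix=np.array(rows, dtype=float))


def write_pwm(pwm, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {pwm.name}\n# columns: A C G T (log-odds)\n")
        for row in pwm.matrix:
            fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# analysis result tables (site tests, DMRs, enrichment, DE, joins)
# ---------------------------------------------------------------------------

def write_site_results(results: Sequence, sample_ids: Sequence[str],
                       control: str, case: str, path: str | Path) -> None:
    """Write the per-site test table: chrom, pos, per-sample k/N, group means,
    delta, raw/combined/adjusted p-values and the hyper/hypo/ns label."""
    path = Path(path)
    cols: dict[str, list] = {"chrom": [], "pos": []}
    for s in sample_ids:
        cols[f"k_{s}"] = []
        cols[f"N_{s}"] = []
    for name in (f"pi_{control}", f"pi_{case}", "delta", "p_raw", "p_comb", "fdr", "label"):
        cols[name] = []
    for r in results:
        cols["chrom"].append(r.site.chrom)
        cols["pos"].append(r.site.pos)
        for i, s in enumerate(sample_ids):
            cols[f"k_{s}"].append(int(r.site.meth[i]))
            cols[f"N_{s}"].append(int(r.site.total[i]))
        cols[f"pi_{control}"].append(r.pi_group[control])
        cols[f"pi_{case}"].append(r.pi_group[case])
        cols["delta"].append(r.delta)
        cols["p_raw"].append(r.p_raw)
        cols["p_comb"].append(r.p_comb)
        cols["fdr"].append(r.fdr)
        cols["label"].append(r.label)
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write("# dmrkit per-CpG differential methylation table\n")
        fh.write(f"# groups: control={control} case={case}; delta = pi_{case} - pi_{control}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_site_results(path: str | Path) -> pd.DataFrame:
    """Read a per-site table back as a DataFrame (columns as written)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_dmr_bed(dmrs: Sequence, path: str | Path) -> None:
    """BED6: name=DMR_<i>, score = round(-10*log10 best_fdr) capped at 1000."""
    path = Path(path)
    with path.open("w") as fh:
        for i, d in enumerate(dmrs, start=1):
            if d.best_fdr > 0:
                score = min(1000, int(round(-10.0 * math.log10(d.best_fdr))))
            else:
                score = 1000
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR_{i}\t{score}\t.\n")


def write_dmr_table(dmrs: Sequence, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "name": [f"DMR_{i}" for i in range(1, len(dmrs) + 1)],
            "n_cpgs": [d.n_cpgs for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "mean_delta": [d.mean_delta for d in dmrs],
            "best_fdr": [d.best_fdr for d in dmrs],
        }
    )
    with path.open("w") as fh:
        fh.write("# dmrkit differentially methylated regions\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_enrichment_table(rows: Sequence, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "feature": [r.feature_name for r in rows],
            "n_profiled": [r.n_profiled for r in rows],
            "n_hyper": [r.n_hyper for r in rows],
            "n_hypo": [r.n_hypo for r in rows],
            "frac_hyper": [r.frac_hyper for r in rows],
            "frac_hypo": [r.frac_hypo for r in rows],
        }
    )
    with path.open("w") as fh:
        fh.write("# fraction of significantly hyper-/hypomethylated CpGs among "
                 "profiled CpGs inside each feature set\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
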