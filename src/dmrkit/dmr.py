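"""Aggregation of labeled CpG sites into directional differentially
methylated regions (DMRs).

A DMR is a run of nearby significant CpGs that all moved the same way.
Consecutive significant sites with the same label, on one chromosome, with
inter-site distance at most ``max_gap_bp`` merge into one region; intervening
non-significant sites neither break the run nor count toward its size, but a
significant site of the opposite direction always breaks it (regions are
directionally coherent by construction). Runs shorter than ``min_cpgs`` are
discarded. The region span is [first CpG position, last CpG position + 2):
half-open, BED-compatible, and covering the full CpG dinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .errors import ValidationError


@dataclass(frozen=True)
class DMR:
    """Contiguous run of concordant significant CpGs."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    direction: str          # "hyper" or "hypo"
    mean_delta: float
    best_fdr: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"empty DMR {self.chrom}:{self.start}-{self.end}")
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"bad DMR direction {self.direction!r}")


class DmrSummary(NamedTuple):
    n_total: int
    n_hyper: int
    n_hypo: int


def _check_sorted(sites: Sequence) -> None:
    seen: set[str] = set()
    prev_chrom, prev_pos = None, None
    for s in sites:
        if s.chrom != prev_chrom:
            if s.chrom in seen:
                raise ValidationError("sites are not grouped/sorted by chromosome")
            seen.add(s.chrom)
            prev_chrom, prev_pos = s.chrom, s.pos
        else:
            if prev_pos is not None and s.pos <= prev_pos:
                raise ValidationError(f"sites not sorted at {s.chrom}:{s.pos}")
            prev_pos = s.pos


def call_dmrs(sites: Sequence, max_gap_bp: int = 1000, min_cpgs: int = 3) -> list[DMR]:
    """Merge runs of same-direction significant CpGs into DMRs.

    ``sites`` are labeled per-CpG results sorted by (chrom, pos); any object
    with chrom, pos, delta, fdr and label attributes works.
    """
    _check_sorted(sites)
    dmrs: list[DMR] = []
    run: list = []

    def flush() -> None:
        if len(run) >= min_cpgs:
            deltas = [s.delta for s in run]
            dmrs.append(
                DMR(
                    chrom=run[0].chrom,
                    start=run[0].pos,
                    end=run[-1].pos + 2,
                    n_cpgs=len(run),
                    direction=run[0].label,
                    mean_delta=sum(deltas) / len(deltas),
                    best_fdr=min(s.fdr for s in run),
                )
            )
        run.clear()

    for s in sites:
        if s.label not in ("hyper", "hypo"):
            continue
        if run and (
            s.chrom != run[-1].chrom
            or s.label != run[-1].label
            or s.pos - run[-1].pos > max_gap_bp
        ):
            flush()
        run.append(s)
    flush()
    return dmrs


def dmr_summary(dmrs: Sequence[DMR]) -> DmrSummary:
    """Total, hypermethylated and hypomethylated region counts."""
    n_hyper = sum(1 for d in dmrs if d.direction == "hyper")
    n_hypo = sum(1 for d in dmrs if d.direction == "hypo")
    return DmrSummary(len(dmrs), n_hyper, n_hypo)
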