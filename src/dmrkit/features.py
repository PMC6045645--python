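"""Interval arithmetic around the per-CpG results: TSS association of DMRs,
enrichment fractions of labeled CpGs within epigenomic feature sets (ChromHMM
segments, clustered TFBS), log-odds PWM scanning, and group comparison of
array-style beta-value matrices.

Enrichment follows the "fraction of affected CpGs among profiled CpGs" logic:
for each named interval set, count the profiled CpGs that fall inside any of
its intervals (membership, not multiplicity) and report the fractions of those
that were called hyper- or hypomethylated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import wilcoxon

from .errors import ValidationError
from .meth_io import BetaMatrix, GenomicInterval, TssRecord

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


@dataclass(frozen=True)
class EnrichmentRow:
    """Per-feature-set counts and fractions of hyper/hypo CpGs among profiled CpGs."""

    feature_name: str
    n_profiled: int
    n_hyper: int
    n_hypo: int

    @property
    def frac_hyper(self) -> float:
        return self.n_hyper / self.n_profiled if self.n_profiled else math.nan

    @property
    def frac_hypo(self) -> float:
        return self.n_hypo / self.n_profiled if self.n_profiled else math.nan


@dataclass(frozen=True)
class PWM:
    """Position weight matrix on the log-odds scale over {A, C, G, T}."""

    name: str
    matrix: np.ndarray      # shape (length, 4)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValidationError(f"PWM matrix must be (length>=1, 4), got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class TssAssociation:
    """A DMR lying within ``max_dist`` bp of a gene's transcription start site."""

    dmr: object
    gene_id: str
    distance: int


class GroupComparison(NamedTuple):
    mean_delta: float
    p_value: float
    n_probes_used: int


# ---------------------------------------------------------------------------
# TSS association
# ---------------------------------------------------------------------------

def _tss_distance(dmr, tss: int) -> int:
    """0 if the TSS lies inside [start, end); otherwise distance to the nearest
    covered base (end - 1 on the right edge)."""
    if dmr.start <= tss < dmr.end:
        return 0
    return min(abs(tss - dmr.start), abs(tss - (dmr.end - 1)))


def associate_tss(dmrs: Sequence, tss_records: Sequence[TssRecord],
                  max_dist_bp: int = 1000) -> list[TssAssociation]:
    """All (DMR, gene) pairs whose TSS gap is at most ``max_dist_bp``.

    A DMR may associate with several genes and a gene with several DMRs.
    Candidate TSSs are found by bisection on per-chromosome sorted positions.
    """
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss_records:
        by_chrom.setdefault(t.chrom, []).append(t)
    for recs in by_chrom.values():
        recs.sort(key=lambda t: t.tss)
    out: list[TssAssociation] = []
    for d in dmrs:
        recs = by_chrom.get(d.chrom, [])
        if not recs:
            continue
        pos = [t.tss for t in recs]
        lo = np.searchsorted(pos, d.start - max_dist_bp, side="left")
        hi = np.searchsorted(pos, d.end + max_dist_bp, side="right")
        for t in recs[lo:hi]:
            dist = _tss_distance(d, t.tss)
            if dist <= max_dist_bp:
                out.append(TssAssociation(dmr=d, gene_id=t.gene_id, distance=dist))
    return out


# ---------------------------------------------------------------------------
# interval membership and enrichment fractions
# ---------------------------------------------------------------------------

def interval_membership(positions, intervals) -> np.ndarray:
    """Boolean mask: position i lies inside at least one half-open interval.

    ``positions`` must be sorted ascending; ``intervals`` are (start, end)
    pairs or objects with start/end attributes (single chromosome). Uses a
    sorted sweep over merged intervals.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and np.any(np.diff(pos) < 0):
        raise ValidationError("positions must be sorted ascending")
    spans = sorted(
        (iv[0], iv[1]) if isinstance(iv, (tuple, list)) else (iv.start, iv.end)
        for iv in intervals
    )
    if not spans:
        return np.zeros(pos.shape, dtype=bool)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    starts = np.array([m[0] for m in merged], dtype=np.int64)
    ends = np.array([m[1] for m in merged], dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    mask = idx >= 0
    mask[mask] = pos[mask] < ends[idx[mask]]
    return mask


def group_intervals_by_name(intervals: Sequence[GenomicInterval],
                            ) -> dict[str, list[GenomicInterval]]:
    """Split one BED4-style interval list into named feature sets.

    Intervals without a name go into an "unnamed" set. Set order follows
    first appearance.
    """
    sets: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        sets.setdefault(iv.name or "unnamed", []).append(iv)
    return sets


def enrichment_fractions(results: Sequence,
                         feature_sets: dict[str, Sequence[GenomicInterval]],
                         ) -> list[EnrichmentRow]:
    """Fractions of hyper/hypo CpGs among profiled CpGs inside each feature set.

    ``results`` are labeled per-CpG records (chrom, pos, label); membership is
    counted once per CpG even when intervals of a set overlap it repeatedly.
    """
    by_chrom: dict[str, list] = {}
    for r in results:
        by_chrom.setdefault(r.chrom, []).append(r)
    for group in by_chrom.values():
        group.sort(key=lambda r: r.pos)

    rows: list[EnrichmentRow] = []
    for name, intervals in feature_sets.items():
        ivs_by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            ivs_by_chrom.setdefault(iv.chrom, []).append(iv)
        n_prof = n_hyper = n_hypo = 0
        for chrom, group in by_chrom.items():
            mask = interval_membership(
                [r.pos for r in group], ivs_by_chrom.get(chrom, [])
            )
            for r, inside in zip(group, mask):
                if inside:
                    n_prof += 1
                    if r.label == "hyper":
                        n_hyper += 1
                    elif r.label == "hypo":
                        n_hypo += 1
        rows.append(EnrichmentRow(name, n_prof, n_hyper, n_hypo))
    return rows


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def pwm_scan(sequence: str, pwm: PWM,
             score_threshold: float) -> list[tuple[int, str, float]]:
    """Scan both strands of ``sequence`` for PWM hits scoring >= threshold.

    The score of a window is the sum of per-position log-odds weights; the
    reverse strand scores the reverse complement of the window against the
    same matrix. Hits are (offset, strand, score) with 0-based forward-strand
    offsets, ordered by offset with '+' before '-'. Windows containing N are
    skipped; any other non-ACGTN character is an error.
    """
    seq = sequence.upper()
    try:
        codes = np.array([_BASE_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"sequence contains invalid character {exc.args[0]!r}") from exc
    L = pwm.length
    n_win = len(seq) - L + 1
    if n_win <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows < 0, 0, windows)
    cols = np.arange(L)
    fwd = pwm.matrix[cols, safe].sum(axis=1)
    # reverse strand: complement, read right-to-left
    rev = pwm.matrix[cols, 3 - safe[:, ::-1]].sum(axis=1)
    hits: list[tuple[int, str, float]] = []
    for off in range(n_win):
        if not valid[off]:
            continue
        if fwd[off] >= score_threshold:
            hits.append((off, "+", float(fwd[off])))
        if rev[off] >= score_threshold:
            hits.append((off, "-", float(rev[off])))
    return hits


# ---------------------------------------------------------------------------
# beta-matrix group comparison
# ---------------------------------------------------------------------------

def compare_beta_groups(matrix: BetaMatrix, control: str | None = None,
                        case: str | None = None) -> GroupComparison:
    """One global test of a group shift in an array-style beta matrix.

    Per probe, the difference of group means (case - control) is computed over
    non-missing entries; probes missing an entire group are excluded. The
    per-probe differences are then tested against zero with a two-sided
    Wilcoxon signed-rank test (normal approximation for n > 25).

    When ``control``/``case`` are omitted, the first group label encountered
    is the control and the second the case.
    """
    labels = matrix.group_labels
    uniq = list(dict.fromkeys(labels))
    if control is None or case is None:
        if len(uniq) != 2:
            raise ValidationError(f"exactly two groups required, got {uniq}")
        control, case = uniq
    cmask = np.array([g == control for g in labels])
    tmask = np.array([g == case for g in labels])
    if not cmask.any() or not tmask.any():
        raise ValidationError(f"both groups need >= 1 sample ({control!r}, {case!r})")

    vals = matrix.values
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN probe rows
        m_ctrl = np.nanmean(np.where(cmask, vals, np.nan), axis=1)
        m_case = np.nanmean(np.where(tmask, vals, np.nan), axis=1)
    usable = np.isfinite(m_ctrl) & np.isfinite(m_case)
    diffs = (m_case - m_ctrl)[usable]
    n_used = int(usable.sum())
    if n_used == 0:
        return GroupComparison(math.nan, math.nan, 0)
    mean_delta = float(diffs.mean())
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return GroupComparison(mean_delta, 1.0, n_used)
    method = "approx" if nonzero.size > 25 else "exact"
    stat = wilcoxon(nonzero, alternative="two-sided", method=method)
    return GroupComparison(mean_delta, float(stat.pvalue), n_used)
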