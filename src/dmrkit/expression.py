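"""Simplified differential expression and methylation-expression integration.

The stage mirrors the classic count-based RNA-seq workflow: per-sample size
factors by the median-of-ratios method, then a per-gene two-group test under a
negative-binomial noise model. The test here is deliberately lightweight:
gene-wise method-of-moments dispersion (no shrinkage across genes) and a Wald
test on the difference of log group means with a delta-method variance. It is
documented as a simplified stage, not a reimplementation of any particular
DE package's numerics.

Integration joins promoter DMR methylation changes with expression
fold-changes (one row per gene-DMR pair, Spearman correlation attached as
metadata) and tabulates TF binding-site methylation enrichment against the
expression change of the TF's own gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from .diffmeth import adjust_bh
from .errors import ValidationError

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Gene-level read counts: genes x samples, with per-sample group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer) and np.any(c != np.floor(c)):
            raise ValidationError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValidationError("one group label per sample required")


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential expression call."""

    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    fdr: float = math.nan


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples, computed over
    genes with all-positive counts; each sample's factor is the median ratio
    of its counts to the reference over those genes.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    c = c.astype(float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError(
            "no gene with all-positive counts; size factors are undefined"
        )
    logc = np.log(c[allpos])
    logref = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - logref, axis=0))


def _wald_one_gene(q_ctrl: np.ndarray, q_case: np.ndarray) -> tuple[float, float, float]:
    """Return (log2fc, p, base_mean) for one gene's normalized counts."""
    n1, n2 = q_ctrl.size, q_case.size
    m1, m2 = q_ctrl.mean(), q_case.mean()
    base_mean = np.concatenate([q_ctrl, q_case]).mean()
    if m1 == 0.0 and m2 == 0.0:
        return 0.0, 1.0, float(base_mean)
    # gene-wise dispersion, method of moments pooled within groups: var = mu + a*mu^2
    ss = 0.0
    sm = 0.0
    sm2 = 0.0
    for q, m, n in ((q_ctrl, m1, n1), (q_case, m2, n2)):
        if n > 1:
            ss += float(np.sum((q - m) ** 2))
            sm += (n - 1) * m
            sm2 += (n - 1) * m * m
    alpha = (ss - sm) / sm2 if sm2 > 0 else 0.0
    alpha = max(alpha, _DISPERSION_FLOOR)
    v1 = (m1 + alpha * m1 * m1) / n1
    v2 = (m2 + alpha * m2 * m2) / n2
    l1, l2 = m1 + _PSEUDOCOUNT, m2 + _PSEUDOCOUNT
    var_log = v1 / (l1 * l1) + v2 / (l2 * l2)
    log2fc = float(np.log2(l2 / l1))
    if var_log <= 0:
        p = 1.0 if log2fc == 0 else 0.0
    else:
        t = (math.log(l2) - math.log(l1)) / math.sqrt(var_log)
        p = float(2.0 * norm.sf(abs(t)))
    return log2fc, p, float(base_mean)


def nb_test(gene_counts, groups, factors, control: str, case: str,
            gene_id: str = "") -> DEResult:
    """Negative-binomial two-group test for one gene (no FDR attached)."""
    q = np.asarray(gene_counts, dtype=float) / np.asarray(factors, dtype=float)
    g = np.asarray(groups)
    log2fc, p, base_mean = _wald_one_gene(q[g == control], q[g == case])
    return DEResult(gene_id=gene_id, base_mean=base_mean, log2fc=log2fc, p=p)


def differential_expression(matrix: CountMatrix, control: str | None = None,
                            case: str | None = None) -> list[DEResult]:
    """Size-factor normalization + per-gene NB Wald tests + BH adjustment.

    When ``control``/``case`` are omitted, the first group label encountered
    is the control and the second the case.
    """
    uniq = list(dict.fromkeys(matrix.group_labels))
    if control is None or case is None:
        if len(uniq) != 2:
            raise ValidationError(f"exactly two groups required, got {uniq}")
        control, case = uniq
    g = np.asarray(matrix.group_labels)
    if (g == control).sum() == 0 or (g == case).sum() == 0:
        raise ValidationError(f"both groups need >= 1 sample ({control!r}, {case!r})")
    if len(matrix.sample_ids) < 2:
        raise ValidationError("at least two samples required")
    factors = size_factors(matrix)
    q = matrix.counts / factors
    cmask, tmask = g == control, g == case
    results: list[DEResult] = []
    for i, gene in enumerate(matrix.gene_ids):
        log2fc, p, base_mean = _wald_one_gene(q[i, cmask], q[i, tmask])
        results.append(DEResult(gene, base_mean, log2fc, p))
    fdr = adjust_bh([r.p for r in results])
    return [
        DEResult(r.gene_id, r.base_mean, r.log2fc, r.p, float(qv))
        for r, qv in zip(results, fdr)
    ]


def de_results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
        }
    )


def join_dmr_expression(tss_associations, de_results) -> pd.DataFrame:
    """Inner-join promoter DMR methylation changes with expression changes.

    One row per (association, gene) key match; a gene with several DMRs
    contributes one row per DMR. The Spearman correlation between the DMR
    methylation change and the expression log2 fold-change is attached as
    ``df.attrs['spearman_rho']`` (NaN with fewer than two rows).
    """
    assoc = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in tss_associations],
            "dmr_chrom": [a.dmr.chrom for a in tss_associations],
            "dmr_start": [a.dmr.start for a in tss_associations],
            "dmr_end": [a.dmr.end for a in tss_associations],
            "dmr_mean_delta": [a.dmr.mean_delta for a in tss_associations],
            "fdr_meth": [a.dmr.best_fdr for a in tss_associations],
            "tss_distance": [a.distance for a in tss_associations],
        }
    )
    de = de_results_to_frame(de_results).rename(columns={"fdr": "fdr_expr"})
    joined = assoc.merge(de[["gene_id", "log2fc", "fdr_expr"]], on="gene_id", how="inner")
    if len(joined) >= 2 and joined["dmr_mean_delta"].nunique() > 1 \
            and joined["log2fc"].nunique() > 1:
        rho = float(spearmanr(joined["dmr_mean_delta"], joined["log2fc"]).statistic)
    else:
        rho = math.nan
    joined.attrs["spearman_rho"] = rho
    return joined


def tf_site_expression_table(enrichment_rows, de_results,
                             tf_map: dict[str, str]) -> pd.DataFrame:
    """Per TF feature set: its methylation enrichment fractions next to the
    expression change of the TF's own gene (missing when unmapped)."""
    de_by_gene = {r.gene_id: r for r in de_results}
    rows = []
    for er in enrichment_rows:
        gene_id = tf_map.get(er.feature_name)
        de = de_by_gene.get(gene_id) if gene_id else None
        rows.append(
            {
                "feature": er.feature_name,
                "n_profiled": er.n_profiled,
                "frac_hyper": er.frac_hyper,
                "frac_hypo": er.frac_hypo,
                "gene_id": gene_id,
                "log2fc": de.log2fc if de else math.nan,
                "fdr_expr": de.fdr if de else math.nan,
            }
        )
    return pd.DataFrame(rows)
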