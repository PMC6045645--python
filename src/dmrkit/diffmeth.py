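"""Strand merging and per-CpG beta-binomial differential methylation testing.

The count model
---------------
At one CpG, in one sample, k of N bisulfite reads support methylation:

    k ~ Binomial(N, p),   p ~ Beta(alpha, beta)

so that k is beta-binomial. The Beta layer absorbs between-replicate
biological variance on top of the binomial read-sampling ("shot") noise, which
is why counts are modelled directly rather than methylation rates k/N (rates
discard the coverage information that determines their precision).

We reparameterize by mean and concentration, mu = alpha/(alpha+beta) and
phi = alpha+beta, and optimize (logit mu, log phi) unconstrained, with mu
clamped to [1e-6, 1-1e-6] and phi to [1e-2, 1e6]. The per-site test is a
likelihood-ratio test of a pooled fit (one (alpha, beta) for all samples)
against a per-group fit (separate (alpha_g, beta_g)), referred to a chi-square
with 2 df (mean and dispersion both freed); a 1-df shared-dispersion variant
is available via ``df_mode="shared"``. Site p-values are then locally combined
with an equal-weight Stouffer window (default 200 bp), BH-adjusted, and
thresholded into hyper/hypo/ns labels.

Strand merging sums the forward-strand cytosine at position p with the
reverse-strand cytosine of the same CpG dinucleotide at p+1, excluding
potentially mutated CpG sites from asymmetric artifacts; merged sites are
keyed at the forward-C position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit
from scipy.stats import chi2, norm

from .errors import DuplicateRecordError, NotFittableError, ValidationError
from .meth_io import CytosineCount

_MU_LO, _MU_HI = 1e-6, 1.0 - 1e-6
_PHI_LO, _PHI_HI = 1e-2, 1e6
_X0_LO, _X0_HI = logit(_MU_LO), logit(_MU_HI)
_X1_LO, _X1_HI = math.log(_PHI_LO), math.log(_PHI_HI)

LABELS = ("hyper", "hypo", "ns")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MergedCpGSite:
    """Strand-merged counts for one CpG across all samples (the unit of testing).

    ``pos`` is the 0-based position of the forward-strand cytosine. A site is
    testable when each group has at least one sample with coverage.
    """

    chrom: str
    pos: int
    meth: np.ndarray        # per-sample merged k
    total: np.ndarray       # per-sample merged N
    group: list[str]        # per-sample condition label
    sample_ids: list[str] = field(default_factory=list)
    testable: bool = True

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.shape != self.total.shape or len(self.group) != self.meth.size:
            raise ValidationError("per-sample arrays of one site must align")
        if np.any(self.meth < 0) or np.any(self.meth > self.total):
            raise ValidationError(f"counts violate 0 <= k <= N at {self.chrom}:{self.pos}")


@dataclass
class BetaBinomFit:
    """Maximum-likelihood Beta(alpha, beta) layer for a set of (k, N) pairs."""

    alpha: float
    beta_: float
    loglik: float
    converged: bool

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta_)

    @property
    def concentration(self) -> float:
        return self.alpha + self.beta_


@dataclass
class SiteTestResult:
    """Per-CpG effect size, p-values and significance label."""

    site: MergedCpGSite
    pi_group: dict[str, float]
    delta: float
    p_raw: float
    p_comb: float = math.nan
    fdr: float = math.nan
    label: str = "ns"
    converged: bool = True

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos


class DirectionSummary(NamedTuple):
    n_hyper: int
    n_hypo: int
    n_ns: int
    frac_hyper_among_sig: float


# ---------------------------------------------------------------------------
# strand merging and site assembly
# ---------------------------------------------------------------------------

def merge_strands(records: Iterable[CytosineCount],
                  sample_id: str | None = None) -> list[tuple[str, int, int, int]]:
    """Merge forward/reverse cytosine counts of each CpG for one sample.

    A forward-strand C at position p and the reverse-strand C of the same
    dinucleotide at p+1 are summed into one site keyed (chrom, p); unpaired
    strands pass through with their own counts at the forward-C key (a
    reverse-only cytosine at q maps to q-1). Returns (chrom, pos, k, N)
    tuples sorted by (chrom, pos).
    """
    label = f" in sample {sample_id}" if sample_id else ""
    seen: set[tuple[str, int, str]] = set()
    merged: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        ident = (rec.chrom, rec.pos, rec.strand)
        if ident in seen:
            raise DuplicateRecordError(
                f"duplicate {rec.strand}-strand record at {rec.chrom}:{rec.pos}{label}"
            )
        seen.add(ident)
        if rec.strand == "+":
            key = (rec.chrom, rec.pos)
        else:
            if rec.pos == 0:
                raise ValidationError(
                    f"reverse-strand cytosine at position 0 has no forward mate{label}"
                )
            key = (rec.chrom, rec.pos - 1)
        acc = merged.setdefault(key, [0, 0])
        acc[0] += rec.meth_reads
        acc[1] += rec.total_reads
    return [
        (chrom, pos, k, n)
        for (chrom, pos), (k, n) in sorted(merged.items())
    ]


def assemble_sites(merged_by_sample: dict[str, list[tuple[str, int, int, int]]],
                   design: dict[str, str]) -> list[MergedCpGSite]:
    """Align per-sample merged counts into MergedCpGSite records.

    ``design`` maps sample id -> group label (exactly two groups, each with at
    least one sample); its key order fixes the per-sample array order. Samples
    lacking a site get k=0, N=0; a site with an entirely uncovered group is
    emitted with ``testable=False``.
    """
    samples = list(design)
    missing = [s for s in samples if s not in merged_by_sample]
    if missing:
        raise ValidationError(f"design references unknown sample(s): {missing}")
    labels = [design[s] for s in samples]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValidationError(f"exactly two groups required, got {uniq}")

    per_sample: list[dict[tuple[str, int], tuple[int, int]]] = [
        {(c, p): (k, n) for c, p, k, n in merged_by_sample[s]} for s in samples
    ]
    keys = sorted(set().union(*[d.keys() for d in per_sample]) if per_sample else set())
    group_masks = {g: np.array([lab == g for lab in labels]) for g in uniq}

    sites: list[MergedCpGSite] = []
    for chrom, pos in keys:
        k = np.zeros(len(samples), dtype=np.int64)
        n = np.zeros(len(samples), dtype=np.int64)
        for i, d in enumerate(per_sample):
            if (chrom, pos) in d:
                k[i], n[i] = d[(chrom, pos)]
        testable = all(np.any(n[group_masks[g]] > 0) for g in uniq)
        sites.append(MergedCpGSite(chrom, pos, k, n, list(labels), list(samples), testable))
    return sites


# ---------------------------------------------------------------------------
# beta-binomial likelihood and fitting
# ---------------------------------------------------------------------------

def betabinom_loglik(k, N, alpha: float, beta_: float) -> float:
    """Log beta-binomial pmf, summed when k, N are arrays.

    log C(N,k) + logB(k+alpha, N-k+beta) - logB(alpha, beta); an empty
    observation (N=0) contributes 0.
    """
    if alpha <= 0 or beta_ <= 0:
        raise ValueError(f"alpha and beta must be positive, got ({alpha}, {beta_})")
    k = np.asarray(k, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(k < 0) or np.any(k > N):
        raise ValidationError("counts violate 0 <= k <= N")
    lc = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)
    return float(np.sum(lc + betaln(k + alpha, N - k + beta_) - betaln(alpha, beta_)))


def _unpack(x: np.ndarray) -> tuple[float, float]:
    mu = float(expit(np.clip(x[0], _X0_LO, _X0_HI)))
    phi = float(np.exp(np.clip(x[1], _X1_LO, _X1_HI)))
    return mu, phi


def _bound_penalty(x) -> float:
    # the likelihood is flat once mu/phi are clipped at their bounds; a small
    # quadratic term outside the box lets the simplex settle on the boundary
    d0 = max(0.0, x[0] - _X0_HI) + max(0.0, _X0_LO - x[0])
    d1 = max(0.0, x[1] - _X1_HI) + max(0.0, _X1_LO - x[1])
    return 10.0 * (d0 * d0 + d1 * d1)


def _nll(x, k, N, lc) -> float:
    mu, phi = _unpack(x)
    a, b = mu * phi, (1.0 - mu) * phi
    ll = float(np.sum(lc + betaln(k + a, N - k + b) - betaln(a, b)))
    return -ll + _bound_penalty(x)


def _mom_start(k: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Method-of-moments starting point in (logit mu, log phi) space."""
    mu0 = float(np.clip(k.sum() / N.sum(), 1e-3, 1.0 - 1e-3))
    rates = k / N
    var = float(np.var(rates, ddof=1)) if rates.size > 1 else 0.0
    if var > 1e-8:
        phi0 = mu0 * (1.0 - mu0) / var - 1.0
    else:
        phi0 = 100.0
    phi0 = float(np.clip(phi0, 0.1, 1e4))
    return np.array([logit(mu0), math.log(phi0)])


def _nm_multistart(fun, starts, args) -> tuple[np.ndarray, float, bool]:
    """Nelder-Mead from several starts; convergence judged by function-value
    stability (a restart from the best point improving by < 1e-6), which also
    covers flat ridges where the simplex cannot contract in x."""
    best = None
    for x0 in starts:
        res = minimize(
            fun, np.asarray(x0, dtype=float), args=args, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 300, "maxfev": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    if not converged:
        res2 = minimize(
            fun, best.x, args=args, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 150, "maxfev": 300},
        )
        if best.fun - res2.fun < 1e-6:
            converged = True
        if res2.fun < best.fun:
            best = res2
    return best.x, float(best.fun), converged


def fit_betabinom(k_vec, N_vec, extra_starts: Sequence[np.ndarray] = ()) -> BetaBinomFit:
    """Maximum-likelihood (alpha, beta) over samples, Nelder-Mead in
    (logit mu, log phi) from a method-of-moments start.

    ``extra_starts`` supplies additional starting points (used by the LRT to
    seed group fits at the pooled optimum, which guarantees the alternative
    log-likelihood never falls below the null's).
    """
    k = np.asarray(k_vec, dtype=float)
    N = np.asarray(N_vec, dtype=float)
    covered = N > 0
    if not covered.any():
        raise NotFittableError("all samples have zero coverage; nothing to fit")
    k, N = k[covered], N[covered]
    lc = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)

    best_x, best_fun, converged = _nm_multistart(
        _nll, [_mom_start(k, N), *extra_starts], (k, N, lc)
    )
    mu, phi = _unpack(best_x)
    return BetaBinomFit(
        alpha=mu * phi, beta_=(1.0 - mu) * phi,
        loglik=-float(best_fun), converged=converged,
    )


def _params_x(fit: BetaBinomFit) -> np.ndarray:
    mu = float(np.clip(fit.mean, _MU_LO, _MU_HI))
    phi = float(np.clip(fit.concentration, _PHI_LO, _PHI_HI))
    return np.array([logit(mu), math.log(phi)])


def _nll_shared(x, k, N, lc, mask1) -> float:
    """Shared-dispersion alternative: separate means, one concentration."""
    mu1 = float(expit(np.clip(x[0], _X0_LO, _X0_HI)))
    mu2 = float(expit(np.clip(x[1], _X0_LO, _X0_HI)))
    phi = float(np.exp(np.clip(x[2], _X1_LO, _X1_HI)))
    mu = np.where(mask1, mu1, mu2)
    a, b = mu * phi, (1.0 - mu) * phi
    ll = float(np.sum(lc + betaln(k + a, N - k + b) - betaln(a, b)))
    pen = _bound_penalty(np.array([x[0], x[2]])) + _bound_penalty(np.array([x[1], x[2]]))
    return -ll + pen


def lrt_site_test(site: MergedCpGSite, control: str, case: str,
                  df_mode: str = "full") -> SiteTestResult:
    """Likelihood-ratio test of one site: pooled fit vs per-group fits.

    ``df_mode="full"`` frees mean and dispersion per group (2 df);
    ``"shared"`` frees only the means around a common dispersion (1 df).
    delta is the difference of fitted group means, pi_case - pi_control.
    Non-convergence of any fit flags the result and leaves p_raw missing.
    """
    if not site.testable:
        raise ValidationError(f"site {site.chrom}:{site.pos} is not testable")
    if df_mode not in ("full", "shared"):
        raise ValueError(f"df_mode must be 'full' or 'shared', got {df_mode!r}")
    k, N = site.meth, site.total
    glab = np.array(site.group)

    null = fit_betabinom(k, N)
    x_null = _params_x(null)
    converged = null.converged

    if df_mode == "full":
        pi: dict[str, float] = {}
        ll_alt = 0.0
        for g in (control, case):
            m = glab == g
            fit_g = fit_betabinom(k[m], N[m], extra_starts=[x_null])
            pi[g] = fit_g.mean
            ll_alt += fit_g.loglik
            converged = converged and fit_g.converged
        df = 2
    else:
        covered = N > 0
        kk, NN = k[covered].astype(float), N[covered].astype(float)
        mask1 = (glab[covered] == control)
        lc = gammaln(NN + 1) - gammaln(kk + 1) - gammaln(NN - kk + 1)
        starts = [np.array([x_null[0], x_null[0], x_null[1]])]
        m1, m2 = mask1, ~mask1
        if NN[m1].sum() > 0 and NN[m2].sum() > 0:
            mom = np.array([
                logit(float(np.clip(kk[m1].sum() / NN[m1].sum(), 1e-3, 1 - 1e-3))),
                logit(float(np.clip(kk[m2].sum() / NN[m2].sum(), 1e-3, 1 - 1e-3))),
                x_null[1],
            ])
            starts.append(mom)
        best_x, best_fun, conv = _nm_multistart(
            _nll_shared, starts, (kk, NN, lc, mask1)
        )
        pi = {
            control: float(expit(np.clip(best_x[0], _X0_LO, _X0_HI))),
            case: float(expit(np.clip(best_x[1], _X0_LO, _X0_HI))),
        }
        ll_alt = -float(best_fun)
        converged = converged and conv
        df = 1

    lam = max(0.0, 2.0 * (ll_alt - null.loglik))
    p_raw = float(chi2.sf(lam, df)) if converged else math.nan
    delta = pi[case] - pi[control]
    return SiteTestResult(site=site, pi_group=pi, delta=delta,
                          p_raw=p_raw, converged=converged)


def test_sites(sites: Sequence[MergedCpGSite], control: str, case: str,
               df_mode: str = "full") -> list[SiteTestResult]:
    """Run the per-site LRT over every testable site, preserving order."""
    return [
        lrt_site_test(s, control, case, df_mode=df_mode)
        for s in sites if s.testable
    ]


# ---------------------------------------------------------------------------
# neighbor combination, FDR, labeling
# ---------------------------------------------------------------------------

def _check_sorted(results: Sequence) -> None:
    seen_chroms: set[str] = set()
    prev_chrom, prev_pos = None, None
    for r in results:
        if r.chrom != prev_chrom:
            if r.chrom in seen_chroms:
                raise ValidationError("sites are not grouped/sorted by chromosome")
            seen_chroms.add(r.chrom)
            prev_chrom, prev_pos = r.chrom, r.pos
        else:
            if prev_pos is not None and r.pos <= prev_pos:
                raise ValidationError(
                    f"sites are not sorted by position at {r.chrom}:{r.pos}"
                )
            prev_pos = r.pos


def combine_neighbors(results: Sequence[SiteTestResult],
                      window_bp: int = 200) -> Sequence[SiteTestResult]:
    """Stouffer-combine each site's p-value with its chromosome neighbors.

    For site i, z_j = Phi^{-1}(1 - p_raw,j) over all sites j on the same
    chromosome with |pos_j - pos_i| <= window_bp (i included), equal weights:
    Z = sum(z_j)/sqrt(m), p_comb = 1 - Phi(Z). Sites with missing p_raw are
    excluded from every window and get a missing p_comb. Updates in place.
    """
    _check_sorted(results)
    by_chrom: dict[str, list[SiteTestResult]] = {}
    for r in results:
        by_chrom.setdefault(r.chrom, []).append(r)
    for group in by_chrom.values():
        pos = np.array([r.pos for r in group], dtype=np.int64)
        p = np.array([r.p_raw for r in group], dtype=float)
        valid = np.isfinite(p)
        vpos = pos[valid]
        z = norm.isf(np.clip(p[valid], 1e-300, 1.0 - 1e-16))
        cz = np.concatenate([[0.0], np.cumsum(z)])
        lo = np.searchsorted(vpos, pos - window_bp, side="left")
        hi = np.searchsorted(vpos, pos + window_bp, side="right")
        for i, r in enumerate(group):
            if not valid[i]:
                r.p_comb = math.nan
                continue
            m = hi[i] - lo[i]
            Z = (cz[hi[i]] - cz[lo[i]]) / math.sqrt(m)
            r.p_comb = float(norm.sf(Z))
    return results


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, clipped at 1.

    Missing (NaN) entries are ignored (not counted in m) and returned missing.
    """
    p = np.asarray(pvals, dtype=float)
    finite = np.isfinite(p)
    if finite.any() and (p[finite].min() < 0 or p[finite].max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ps = p[finite]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[finite] = restored
    return out


def label_sites(results: Sequence[SiteTestResult], fdr_threshold: float = 0.01,
                min_delta: float = 0.1) -> Sequence[SiteTestResult]:
    """Assign hyper/hypo/ns labels from combined-p FDR and effect size."""
    for r in results:
        if math.isfinite(r.fdr) and r.fdr < fdr_threshold:
            if r.delta >= min_delta and r.delta > 0:
                r.label = "hyper"
                continue
            if r.delta <= -min_delta and r.delta < 0:
                r.label = "hypo"
                continue
        r.label = "ns"
    return results


def direction_summary(results: Sequence[SiteTestResult]) -> DirectionSummary:
    """Count labeled sites and the hypermethylated fraction among significant ones."""
    n_hyper = sum(1 for r in results if r.label == "hyper")
    n_hypo = sum(1 for r in results if r.label == "hypo")
    n_ns = len(results) - n_hyper - n_hypo
    n_sig = n_hyper + n_hypo
    frac = n_hyper / n_sig if n_sig else math.nan
    return DirectionSummary(n_hyper, n_hypo, n_ns, frac)


def run_differential(sites: Sequence[MergedCpGSite], control: str, case: str,
                     window_bp: int = 200, fdr_threshold: float = 0.01,
                     min_delta: float = 0.1, df_mode: str = "full",
                     ) -> list[SiteTestResult]:
    """Full per-site chain: LRT, neighbor combination, BH, labels."""
    results = test_sites(sites, control, case, df_mode=df_mode)
    combine_neighbors(results, window_bp=window_bp)
    fdr = adjust_bh([r.p_comb for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    label_sites(results, fdr_threshold=fdr_threshold, min_delta=min_delta)
    return results
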