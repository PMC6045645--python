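"""Known-truth generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes, at
desk scale, on pseudo-chromosomes:

* CpG positions: sorted uniform integers (minimum spacing 2) on chromosomes
  of configurable length (default one chromosome, "chrS1", 1 Mb).
* baseline methylation: the bimodal mixture 0.7*Beta(1,10) + 0.3*Beta(10,1)
  (a low promoter-like mode and a high gene-body-like mode).
* implanted DMRs: disjoint runs of >=5 consecutive CpGs whose case-group mean
  shifts by +/- delta_pi (clipped into [0.02, 0.98]). Hypermethylation regions
  are implanted at low-baseline (promoter-like) CpGs and hypomethylation
  regions at high-baseline CpGs, so the implanted shift is actually realizable
  after clipping - mirroring the biology where promoter CpGs start low and
  can gain methylation.
* RRBS-like counts: per strand, coverage ~ NegBin(mean coverage_mean/2,
  size 5); a per-sample methylation level p ~ Beta(mu*phi, (1-mu)*phi) shared
  by both strands; methylated reads ~ Binomial(N, p). The noise model matches
  the analysis model on purpose (calibration tests need a matched null); a
  lognormal misspecification switch exercises robustness.
* feature interval sets: one "enriched" set covering affected CpGs at
  ``multiplier`` times the background coverage probability, plus neutral sets.
* expression: NegBin(size 10) counts with per-sample depth factors; genes with
  a TSS at an implanted DMR receive a log2 fold-change of the opposite sign to
  their promoter methylation change.
* 450K-like beta matrices: per-probe baseline + a global group shift +
  Gaussian noise, clipped to [0, 1].

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diffmeth import MergedCpGSite
from .errors import ValidationError
from .expression import CountMatrix
from .meth_io import (
    BetaMatrix,
    CytosineCount,
    GenomicInterval,
    TssRecord,
    write_bed,
    write_beta_matrix,
    write_cytosine_counts,
    write_gene_counts,
    write_group_file,
    write_tss_table,
)

_PI_LO, _PI_HI = 0.02, 0.98


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the standard synthetic fixture."""

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_cpgs: int = 5000
    n_dmrs_hyper: int = 20
    n_dmrs_hypo: int = 10
    delta_pi: float = 0.4
    dmr_min_cpgs: int = 5
    dmr_max_cpgs: int = 8
    n_genes: int = 200
    high_mode_weight: float = 0.3   # mass of the high-methylation Beta(10,1) mode


@dataclass(frozen=True)
class AffectedRegion:
    interval: GenomicInterval
    delta_pi: float                 # signed shift of the case-group mean
    direction: str                  # "hyper" or "hypo"


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    log2fc: float
    promoter_linked: bool


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study; reproducible from (config, seed)."""

    config: SimConfig
    seed: int
    chroms: list[str]
    cpg_positions: dict[str, np.ndarray]
    baseline_pi: dict[str, np.ndarray]
    affected_regions: list[AffectedRegion]
    genes: list[GeneTruth]
    feature_truth: dict[str, dict] = field(default_factory=dict)

    def affected_mask(self, chrom: str) -> np.ndarray:
        pos = self.cpg_positions[chrom]
        mask = np.zeros(pos.shape, dtype=bool)
        for r in self.affected_regions:
            if r.interval.chrom == chrom:
                mask |= (pos >= r.interval.start) & (pos < r.interval.end)
        return mask

    def case_delta(self, chrom: str) -> np.ndarray:
        """Per-CpG signed shift applied to the case group."""
        pos = self.cpg_positions[chrom]
        delta = np.zeros(pos.shape)
        for r in self.affected_regions:
            if r.interval.chrom == chrom:
                sel = (pos >= r.interval.start) & (pos < r.interval.end)
                delta[sel] = r.delta_pi
        return delta

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
            "chroms": self.chroms,
            "cpg_positions": {c: p.tolist() for c, p in self.cpg_positions.items()},
            "baseline_pi": {c: b.tolist() for c, b in self.baseline_pi.items()},
            "affected_regions": [
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "delta_pi": r.delta_pi,
                    "direction": r.direction,
                }
                for r in self.affected_regions
            ],
            "genes": [dataclasses.asdict(g) for g in self.genes],
            "feature_truth": self.feature_truth,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig, seed: int) -> SimulationTruth:
    """Draw CpG positions, baseline methylation, implanted DMRs and genes."""
    rng = np.random.default_rng(seed)
    n_regions = config.n_dmrs_hyper + config.n_dmrs_hypo
    if n_regions * config.dmr_max_cpgs > config.n_cpgs:
        raise ValidationError("config infeasible: more DMR CpGs than CpGs")

    chroms = [f"chrS{i + 1}" for i in range(config.n_chroms)]
    per_chrom = [config.n_cpgs // config.n_chroms] * config.n_chroms
    per_chrom[0] += config.n_cpgs - sum(per_chrom)

    positions: dict[str, np.ndarray] = {}
    baseline: dict[str, np.ndarray] = {}
    for chrom, n in zip(chroms, per_chrom):
        # even positions guarantee the >=2 bp CpG spacing
        pos = np.sort(rng.choice(config.chrom_length // 2, size=n, replace=False)) * 2
        high = rng.random(n) < config.high_mode_weight
        base = np.where(high, rng.beta(10, 1, size=n), rng.beta(1, 10, size=n))
        positions[chrom] = pos.astype(np.int64)
        baseline[chrom] = base

    # implant disjoint affected regions, well separated so that calls cannot merge
    directions = ["hyper"] * config.n_dmrs_hyper + ["hypo"] * config.n_dmrs_hypo
    rng.shuffle(directions)
    regions: list[AffectedRegion] = []
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    weights = np.array(per_chrom) / config.n_cpgs
    for j, direction in enumerate(directions):
        placed = False
        for _ in range(2000):
            chrom = chroms[rng.choice(config.n_chroms, p=weights)]
            pos = positions[chrom]
            size = int(rng.integers(config.dmr_min_cpgs, config.dmr_max_cpgs + 1))
            if pos.size < size:
                continue
            i0 = int(rng.integers(0, pos.size - size + 1))
            start, end = int(pos[i0]), int(pos[i0 + size - 1]) + 2
            if any(start - 3000 < e and end + 3000 > s for s, e in used[chrom]):
                continue
            used[chrom].append((start, end))
            sel = slice(i0, i0 + size)
            if direction == "hyper":
                # promoter-like low baseline so +delta_pi survives clipping
                baseline[chrom][sel] = rng.beta(1, 10, size=size)
                delta = +config.delta_pi
            else:
                baseline[chrom][sel] = rng.beta(10, 1, size=size)
                delta = -config.delta_pi
            regions.append(
                AffectedRegion(GenomicInterval(chrom, start, end, f"region_{j + 1}"),
                               delta, direction)
            )
            placed = True
            break
        if not placed:
            raise ValidationError(
                "could not place all affected regions; config too dense"
            )

    genes: list[GeneTruth] = []
    n_linked = min(len(regions), config.n_genes)
    for i in range(n_linked):
        r = regions[i]
        tss = max(0, r.interval.start - int(rng.integers(0, 800)))
        strand = "+" if rng.random() < 0.5 else "-"
        lfc = -np.sign(r.delta_pi) * float(rng.uniform(1.0, 2.0))
        genes.append(
            GeneTruth(f"gene_{i + 1:04d}", r.interval.chrom, tss, strand, lfc, True)
        )
    for i in range(n_linked, config.n_genes):
        for _ in range(2000):
            chrom = chroms[rng.choice(config.n_chroms, p=weights)]
            tss = int(rng.integers(0, config.chrom_length))
            if all(tss < s - 2000 or tss > e + 2000 for s, e in used[chrom]):
                break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneTruth(f"gene_{i + 1:04d}", chrom, tss, strand, 0.0, False))

    return SimulationTruth(
        config=config, seed=seed, chroms=chroms, cpg_positions=positions,
        baseline_pi=baseline, affected_regions=regions, genes=genes,
    )


# ---------------------------------------------------------------------------
# RRBS-like counts
# ---------------------------------------------------------------------------

def _negbin(rng: np.random.Generator, mean, size_param: float, n: int) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (n,))
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_meth_counts(truth: SimulationTruth, n_per_group: int = 3,
                         coverage_mean: float = 30.0, dispersion_phi: float = 10.0,
                         seed: int = 0, coverage_size: float = 5.0,
                         p_mode: str = "beta",
                         ) -> tuple[dict[str, list[CytosineCount]], dict[str, str]]:
    """Strand-level CytosineCount records per sample, plus the design map.

    Per CpG and sample, both strand coverages are NegBin(coverage_mean/2,
    size=coverage_size); one methylation level p (Beta around the group mean
    with concentration ``dispersion_phi``, or the lognormal misspecification
    mode) is shared between the strands; zero-coverage strand records are
    omitted. Samples are wt_1..wt_n then mut_1..mut_n.
    """
    if coverage_mean <= 0:
        raise ValidationError("coverage_mean must be positive")
    if p_mode not in ("beta", "lognormal"):
        raise ValueError(f"p_mode must be 'beta' or 'lognormal', got {p_mode!r}")
    rng = np.random.default_rng(seed)
    design = {f"wt_{i + 1}": "wt" for i in range(n_per_group)}
    design.update({f"mut_{i + 1}": "mut" for i in range(n_per_group)})

    counts: dict[str, list[CytosineCount]] = {s: [] for s in design}
    for chrom in truth.chroms:
        pos = truth.cpg_positions[chrom]
        base = truth.baseline_pi[chrom]
        delta = truth.case_delta(chrom)
        n = pos.size
        for sample, group in design.items():
            mu = base + (delta if group == "mut" else 0.0)
            mu = np.clip(mu, _PI_LO, _PI_HI)
            if p_mode == "beta":
                p = rng.beta(mu * dispersion_phi, (1.0 - mu) * dispersion_phi)
            else:
                p = np.clip(mu * np.exp(rng.normal(0.0, 0.5, size=n)), 1e-4, 1 - 1e-4)
            nf = _negbin(rng, coverage_mean / 2.0, coverage_size, n)
            nr = _negbin(rng, coverage_mean / 2.0, coverage_size, n)
            kf = rng.binomial(nf, p)
            kr = rng.binomial(nr, p)
            recs = counts[sample]
            for i in range(n):
                if nf[i] > 0:
                    recs.append(CytosineCount(chrom, int(pos[i]), "+", "CpG",
                                              int(kf[i]), int(nf[i])))
                if nr[i] > 0:
                    recs.append(CytosineCount(chrom, int(pos[i]) + 1, "-", "CpG",
                                              int(kr[i]), int(nr[i])))
    return counts, design


def simulate_null_sites(n_sites: int, n_per_group: int = 3,
                        coverage_mean: float = 30.0, alpha: float = 3.0,
                        beta_: float = 7.0, seed: int = 0,
                        coverage_size: float = 5.0, spacing: int = 500,
                        ) -> list[MergedCpGSite]:
    """Strand-merged null sites: both groups draw p ~ Beta(alpha, beta_).

    Coverage mirrors the strand-level generator after merging: each strand
    contributes NegBin(coverage_mean/2, size=coverage_size) reads and the two
    strands are summed. Sites are spaced far apart by default so that neighbor
    combination is an identity and the per-site test can be calibrated
    directly.
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    groups = ["wt"] * n_per_group + ["mut"] * n_per_group
    samples = [f"wt_{i + 1}" for i in range(n_per_group)] + \
              [f"mut_{i + 1}" for i in range(n_per_group)]
    sites: list[MergedCpGSite] = []
    for i in range(n_sites):
        N = _negbin(rng, coverage_mean / 2.0, coverage_size, n_samples) + \
            _negbin(rng, coverage_mean / 2.0, coverage_size, n_samples)
        p = rng.beta(alpha, beta_, size=n_samples)
        k = rng.binomial(N, p)
        site = MergedCpGSite(
            chrom="chrS1", pos=i * spacing, meth=k, total=N,
            group=list(groups), sample_ids=list(samples),
            testable=bool(np.any(N[:n_per_group] > 0) and np.any(N[n_per_group:] > 0)),
        )
        sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# feature sets
# ---------------------------------------------------------------------------

def simulate_features(truth: SimulationTruth, enrichment_multiplier: float = 3.0,
                      background_prob: float = 0.15, n_neutral: int = 2,
                      seed: int = 0) -> dict[str, list[GenomicInterval]]:
    """One "enriched" feature set covering affected CpGs at ``multiplier`` times
    the background probability, plus neutral sets; records counts in
    ``truth.feature_truth``."""
    if enrichment_multiplier < 1:
        raise ValidationError("enrichment_multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[GenomicInterval]] = {}
    names = ["enriched"] + [f"neutral_{i + 1}" for i in range(n_neutral)]
    for name in names:
        intervals: list[GenomicInterval] = []
        for chrom in truth.chroms:
            pos = truth.cpg_positions[chrom]
            if name == "enriched":
                mask = truth.affected_mask(chrom)
                p_cov = np.where(mask, min(1.0, enrichment_multiplier * background_prob),
                                 background_prob)
            else:
                p_cov = np.full(pos.shape, background_prob)
            sel = rng.random(pos.size) < p_cov
            intervals.extend(
                GenomicInterval(chrom, int(p), int(p) + 2) for p in pos[sel]
            )
        sets[name] = intervals
        truth.feature_truth[name] = {
            "multiplier": enrichment_multiplier if name == "enriched" else 1.0,
            "background_prob": background_prob,
            "n_intervals": len(intervals),
        }
    return sets


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(truth: SimulationTruth, n_per_group: int = 3,
                        seed: int = 0, nb_size: float = 10.0,
                        basemean_range: tuple[float, float] = (100.0, 1000.0),
                        ) -> CountMatrix:
    """NegBin gene counts with depth factors and truth-linked fold-changes.

    The case group's mean is basemean * 2^(+log2fc/2) and the control group's
    basemean * 2^(-log2fc/2); promoter-linked genes carry a fold-change of the
    opposite sign to their promoter methylation shift (set in the truth).
    """
    rng = np.random.default_rng(seed)
    samples = [f"wt_{i + 1}" for i in range(n_per_group)] + \
              [f"mut_{i + 1}" for i in range(n_per_group)]
    labels = ["wt"] * n_per_group + ["mut"] * n_per_group
    depth = rng.uniform(0.7, 1.4, size=len(samples))
    n_genes = len(truth.genes)
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for gi, gene in enumerate(truth.genes):
        basemean = float(rng.uniform(*basemean_range))
        for si, lab in enumerate(labels):
            shift = 0.5 * gene.log2fc if lab == "mut" else -0.5 * gene.log2fc
            mean = basemean * depth[si] * (2.0 ** shift)
            counts[gi, si] = _negbin(rng, mean, nb_size, 1)[0]
    return CountMatrix(
        gene_ids=[g.gene_id for g in truth.genes],
        sample_ids=samples, counts=counts, group_labels=labels,
    )


# ---------------------------------------------------------------------------
# 450K-like beta matrices
# ---------------------------------------------------------------------------

def simulate_beta_matrix(truth: SimulationTruth, n_mut: int = 2, n_wt: int = 2,
                         global_shift: float = 0.05, noise_sd: float = 0.02,
                         seed: int = 0, n_probes: int | None = None) -> BetaMatrix:
    """Probe beta = clip(baseline + global_shift * [mutant] + N(0, noise_sd), 0, 1)."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.concatenate([truth.baseline_pi[c] for c in truth.chroms])
    if n_probes is not None:
        base = base[:n_probes]
    samples = [f"beta_wt_{i + 1}" for i in range(n_wt)] + \
              [f"beta_mut_{i + 1}" for i in range(n_mut)]
    labels = ["wt"] * n_wt + ["mut"] * n_mut
    is_mut = np.array([lab == "mut" for lab in labels], dtype=float)
    noise = rng.normal(0.0, noise_sd, size=(base.size, len(samples))) if noise_sd > 0 \
        else np.zeros((base.size, len(samples)))
    values = np.clip(base[:, None] + global_shift * is_mut[None, :] + noise, 0.0, 1.0)
    probes = [f"cg{i + 1:06d}" for i in range(base.size)]
    return BetaMatrix(probe_ids=probes, sample_ids=samples,
                      values=values, group_labels=labels)


# ---------------------------------------------------------------------------
# full dataset on disk
# ---------------------------------------------------------------------------

def write_dataset(out_dir: str | Path, config: SimConfig | None = None,
                  seed: int = 0, n_per_group: int = 3, coverage_mean: float = 30.0,
                  dispersion_phi: float = 10.0, enrichment_multiplier: float = 3.0,
                  beta_shift: float = 0.05, beta_noise_sd: float = 0.02,
                  ) -> SimulationTruth:
    """Write a complete input directory for the pipeline.

    Layout: counts/<sample>.tsv, features/<name>.bed, tss.tsv, groups.tsv,
    expression.tsv, beta.csv, beta_groups.tsv, truth.json. Sub-seeds for the
    individual generators are derived deterministically from ``seed``.
    """
    config = config or SimConfig()
    out = Path(out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    (out / "features").mkdir(parents=True, exist_ok=True)
    sub = np.random.default_rng(seed).integers(2**31, size=5)

    truth = simulate_truth(config, seed=seed)
    counts, design = simulate_meth_counts(
        truth, n_per_group=n_per_group, coverage_mean=coverage_mean,
        dispersion_phi=dispersion_phi, seed=int(sub[0]),
    )
    for sample, recs in counts.items():
        write_cytosine_counts(recs, out / "counts" / f"{sample}.tsv")
    write_group_file(design, out / "groups.tsv")

    feature_sets = simulate_features(
        truth, enrichment_multiplier=enrichment_multiplier, seed=int(sub[1])
    )
    for name, intervals in feature_sets.items():
        write_bed(intervals, out / "features" / f"{name}.bed")

    write_tss_table(
        [TssRecord(g.gene_id, g.chrom, g.tss, g.strand) for g in truth.genes],
        out / "tss.tsv",
    )

    expr = simulate_expression(truth, n_per_group=n_per_group, seed=int(sub[2]))
    write_gene_counts(expr, out / "expression.tsv")

    beta = simulate_beta_matrix(
        truth, global_shift=beta_shift, noise_sd=beta_noise_sd, seed=int(sub[3])
    )
    write_beta_matrix(beta, out / "beta.csv")
    write_group_file(
        dict(zip(beta.sample_ids, beta.group_labels)), out / "beta_groups.tsv"
    )

    (out / "truth.json").write_text(truth.to_json())
    return truth
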