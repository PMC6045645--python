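"""End-to-end analysis pipeline chaining every stage.

Order of outputs written into ``out_dir``:

1. ``sites.tsv``            per-CpG differential methylation table
2. ``dmrs.bed``             called DMRs, BED6
3. ``dmrs.tsv``             called DMRs with n_cpgs/direction/mean_delta/best_fdr
4. ``tss_associations.tsv`` DMR-to-TSS associations within tss_max_dist
5. ``enrichment.tsv``       hyper/hypo fractions per feature set
6. ``expression_de.tsv``    per-gene differential expression
7. ``meth_expression.tsv``  promoter DMR methylation vs expression join
8. ``manifest.json``        config echo, version, seed, per-output row counts

Outputs are a pure function of (inputs, config): no timestamps, no randomness,
so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .diffmeth import direction_summary, merge_strands, assemble_sites, run_differential
from .dmr import call_dmrs, dmr_summary
from .errors import PipelineError
from .expression import join_dmr_expression, differential_expression
from .features import associate_tss, enrichment_fractions
from .meth_io import (
    read_bed,
    read_cytosine_counts,
    read_gene_counts,
    read_group_file,
    read_tss_table,
    write_dmr_bed,
    write_dmr_table,
    write_enrichment_table,
    write_site_results,
)

log = logging.getLogger("dmrkit.pipeline")


def _setup_logging(out_dir: Path) -> None:
    root = logging.getLogger("dmrkit")
    root.setLevel(logging.DEBUG)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == out_dir / "run.log"
        for h in root.handlers
    )
    if not have_file:
        fh = logging.FileHandler(out_dir / "run.log", mode="w")
        fh.setLevel(logging.INFO)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in root.handlers):
        sh = logging.StreamHandler()
        sh.setLevel(logging.INFO)
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        root.addHandler(sh)


def _check_inputs(config: PipelineConfig) -> None:
    for key in ("counts_dir", "design", "features_dir", "tss", "expression"):
        p = getattr(config, key)
        if not Path(p).exists():
            raise PipelineError(f"input path for {key!r} does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle; returns the manifest."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {
        "package": "dmrkit",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "stages": [],
        "row_counts": {},
    }
    stage = "diffmeth"
    try:
        design = read_group_file(config.design)
        merged = {}
        for sample in design:
            path = Path(config.counts_dir) / f"{sample}.tsv"
            if not path.exists():
                raise PipelineError(f"no count file for sample {sample!r}: {path}")
            merged[sample] = merge_strands(read_cytosine_counts(path), sample)
        sites = assemble_sites(merged, design)
        testable = [s for s in sites if s.testable]
        if not testable:
            raise PipelineError("no testable sites: every CpG lacks coverage "
                                "in at least one group")
        log.info("diffmeth: %d merged sites, %d testable", len(sites), len(testable))
        results = run_differential(
            sites, control=config.group_control, case=config.group_case,
            window_bp=config.window_bp, fdr_threshold=config.fdr_threshold,
            min_delta=config.min_delta, df_mode=config.df_mode,
        )
        sample_ids = list(design)
        write_site_results(results, sample_ids, config.group_control,
                           config.group_case, out / "sites.tsv")
        summary = direction_summary(results)
        log.info("diffmeth: %d hyper, %d hypo, %d ns",
                 summary.n_hyper, summary.n_hypo, summary.n_ns)
        manifest["stages"].append(stage)
        manifest["row_counts"]["sites.tsv"] = len(results)
        manifest["direction_summary"] = {
            "n_hyper": summary.n_hyper, "n_hypo": summary.n_hypo,
            "n_ns": summary.n_ns,
            "frac_hyper_among_sig": summary.frac_hyper_among_sig,
        }

        stage = "dmr"
        dmrs = call_dmrs(results, max_gap_bp=config.max_gap_bp,
                         min_cpgs=config.min_cpgs)
        write_dmr_bed(dmrs, out / "dmrs.bed")
        write_dmr_table(dmrs, out / "dmrs.tsv")
        dsum = dmr_summary(dmrs)
        log.info("dmr: %d regions (%d hyper, %d hypo)", *dsum)
        manifest["stages"].append(stage)
        manifest["row_counts"]["dmrs.bed"] = len(dmrs)
        manifest["row_counts"]["dmrs.tsv"] = len(dmrs)
        manifest["dmr_summary"] = dict(dsum._asdict())

        stage = "tss_association"
        tss = read_tss_table(config.tss)
        assocs = associate_tss(dmrs, tss, max_dist_bp=config.tss_max_dist)
        dmr_index = {id(d): i + 1 for i, d in enumerate(dmrs)}
        assoc_df = pd.DataFrame(
            {
                "dmr_name": [f"DMR_{dmr_index[id(a.dmr)]}" for a in assocs],
                "chrom": [a.dmr.chrom for a in assocs],
                "start": [a.dmr.start for a in assocs],
                "end": [a.dmr.end for a in assocs],
                "direction": [a.dmr.direction for a in assocs],
                "gene_id": [a.gene_id for a in assocs],
                "distance": [a.distance for a in assocs],
            }
        )
        assoc_df.to_csv(out / "tss_associations.tsv", sep="\t", index=False)
        log.info("tss_association: %d DMR-gene pairs", len(assocs))
        manifest["stages"].append(stage)
        manifest["row_counts"]["tss_associations.tsv"] = len(assocs)

        stage = "enrichment"
        feature_sets = {}
        features_path = Path(config.features_dir)
        if features_path.is_file():
            # single BED4 with the name column grouping feature sets
            from .features import group_intervals_by_name

            feature_sets = group_intervals_by_name(read_bed(features_path))
        else:
            for bed in sorted(features_path.glob("*.bed")):
                feature_sets[bed.stem] = read_bed(bed)
        rows = enrichment_fractions(results, feature_sets)
        write_enrichment_table(rows, out / "enrichment.tsv")
        log.info("enrichment: %d feature sets", len(rows))
        manifest["stages"].append(stage)
        manifest["row_counts"]["enrichment.tsv"] = len(rows)

        stage = "expression"
        matrix = read_gene_counts(config.expression, config.design)
        de = differential_expression(matrix, control=config.group_control,
                             case=config.group_case)
        from .expression import de_results_to_frame

        de_df = de_results_to_frame(de)
        with (out / "expression_de.tsv").open("w") as fh:
            fh.write("# dmrkit differential expression (NB Wald test)\n")
            de_df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        manifest["stages"].append(stage)
        manifest["row_counts"]["expression_de.tsv"] = len(de)

        stage = "integration"
        joined = join_dmr_expression(assocs, de)
        with (out / "meth_expression.tsv").open("w") as fh:
            fh.write("# promoter DMR methylation change vs expression change\n")
            fh.write(f"# spearman_rho: {joined.attrs['spearman_rho']:.6g}\n")
            joined.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        log.info("integration: %d gene-DMR rows, spearman rho %.3f",
                 len(joined), joined.attrs["spearman_rho"])
        manifest["stages"].append(stage)
        manifest["row_counts"]["meth_expression.tsv"] = len(joined)
        manifest["spearman_rho"] = joined.attrs["spearman_rho"]
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: outputs in %s", out)
    return manifest
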