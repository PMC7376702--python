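"""End-to-end runs: read inputs, compute, write outputs with run metadata.

Each ``run_*`` function is one figure-level analysis (scan, LD, tree,
annotate, simulate). All outputs are deterministic given inputs and config;
every TSV/BED carries the config hash in a '#' header and each run writes a
metadata JSON with the concrete cutoffs, tallies and configuration, so a
rerun with the same hash reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import distance_tree, ld_analysis, popgen_stats, sweep_scan, variant_io
from .sweep_scan import ThresholdPolicy
from .synthetic_data import SimulationConfig, score_recovery, simulate_dataset, \
    write_dataset

logger = logging.getLogger("sweepscan")


@dataclass(frozen=True)
class RunConfig:
    """Scan parameters; defaults are the study's stated settings
    (10 kb windows / 5 kb step; LD pruning 50 SNPs / step 5 / r² 0.2)."""

    window_bp: int = 10_000
    step_bp: int = 5_000
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    group1: str | None = None
    group2: str | None = None
    pi_denominator: str = "span"
    merge_gap_bp: int = 0
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_threshold: float = 0.2
    ld_max_dist_bp: int = 300_000
    ld_bin_bp: int = 1_000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_metadata(path, config: RunConfig, extra: dict) -> None:
    meta = {"config": config.to_dict(), "config_hash": config.hash()}
    meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {o!r}")


def _load_inputs(vcf_path, pops_path, config: RunConfig):
    gm = variant_io.read_vcf(vcf_path)
    pops = variant_io.read_population_file(pops_path, config.group1,
                                           config.group2)
    pops = pops.restrict_to(gm)
    return gm, pops


def run_scan(vcf_path, pops_path, config: RunConfig, outdir,
             genes_path=None) -> dict:
    """Windowed Fst/pi scan → sweep regions → candidate genes.

    Writes windows.tsv, sweeps.bed (BED6, score = 1000·max Fst clamped),
    genes.tsv and metadata.json into ``outdir``; returns a result summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, pops = _load_inputs(vcf_path, pops_path, config)

    stats = popgen_stats.compute_window_stats(
        gm, pops, config.window_bp, config.step_bp, config.pi_denominator)
    cutoffs = sweep_scan.compute_thresholds(stats, config.policy)
    flagged = sweep_scan.flag_windows(stats, cutoffs)
    regions = sweep_scan.merge_windows(flagged, config.merge_gap_bp)

    genes = []
    hits = []
    if genes_path is not None:
        genes = variant_io.read_gene_annotation(genes_path)
        hits = sweep_scan.intersect_genes(regions, genes)

    chash = f"config_hash={config.hash()}"
    comments = [
        chash,
        "pi_ratio orientation: group1(selected)/group2(reference) = "
        f"{pops.group1_label}/{pops.group2_label}",
        "terminal window per chromosome ends at the last SNP rounded up to "
        "a window boundary (no contig lengths required)",
    ]
    variant_io.write_window_stats(stats, outdir / "windows.tsv", comments)

    with open(outdir / "sweeps.bed", "w") as fh:
        fh.write(f"# {chash}\n")
        for r in regions:
            score = int(min(1000, max(0, round(1000 * r.max_fst))))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.tail}\t{score}\t.\n")

    with open(outdir / "genes.tsv", "w") as fh:
        fh.write(f"# {chash}\n")
        fh.write("region_chrom\tregion_start\tregion_end\ttail\t"
                 "gene_id\tgene_start\tgene_end\toverlap_bp\n")
        for h in hits:
            fh.write(f"{h.region.chrom}\t{h.region.start}\t{h.region.end}\t"
                     f"{h.region.tail}\t{h.gene.gene_id}\t{h.gene.start}\t"
                     f"{h.gene.end}\t{h.overlap_bp}\n")

    result = {
        "n_sites": gm.n_sites,
        "n_windows": len(stats),
        "n_windows_defined": cutoffs.n_windows_used,
        "n_flagged": len(flagged),
        "n_regions": len(regions),
        "n_gene_hits": len(hits),
        "n_unique_genes": len({h.gene.gene_id for h in hits}),
        "cutoffs": dataclasses.asdict(cutoffs),
        "filter_stats": dataclasses.asdict(gm.filter_stats)
        if gm.filter_stats else None,
    }
    _write_metadata(outdir / "metadata.json", config, result)
    return {"stats": stats, "cutoffs": cutoffs, "regions": regions,
            "hits": hits, "summary": result}


def run_ld(vcf_path, config: RunConfig, outdir, sample_ids=None,
           prune: bool = False) -> dict:
    """LD-decay curve (and optionally pruning with a filtered VCF)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = variant_io.read_vcf(vcf_path)
    chash = f"config_hash={config.hash()}"

    curve = ld_analysis.ld_decay(gm, sample_ids, config.ld_max_dist_bp,
                                 config.ld_bin_bp)
    curve.to_tsv(outdir / "ld_decay.tsv", [chash])
    if int(curve.n_pairs.sum()) == 0:
        logger.warning("ld_decay: no SNP pair within %d bp",
                       config.ld_max_dist_bp)

    result = {"n_sites": gm.n_sites, "n_pairs": int(curve.n_pairs.sum())}
    if prune:
        retained = ld_analysis.ld_prune(
            gm, config.ld_window_snps, config.ld_step_snps,
            config.ld_r2_threshold)
        pruned = gm.take_sites(retained)
        with open(outdir / "retained_ids.txt", "w") as fh:
            ids = pruned.ids if pruned.ids is not None else \
                [f"{c}:{p + 1}" for c, p in zip(pruned.chrom, pruned.pos0)]
            fh.writelines(f"{i}\n" for i in ids)
        variant_io.write_vcf(pruned, outdir / "pruned.vcf")
        result["n_retained"] = len(retained)
    _write_metadata(outdir / "metadata.json", config, result)
    result["curve"] = curve
    return result


def run_tree(vcf_path, config: RunConfig, outdir, bootstrap: int = 0,
             write_is: bool = True) -> dict:
    """p-distance matrix, identity scores and NJ tree (Newick)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = variant_io.read_vcf(vcf_path)
    chash = f"config_hash={config.hash()}"

    dm = distance_tree.p_distance_matrix(gm)
    distance_tree.write_distance_matrix(dm, outdir / "p_distance.tsv",
                                        header_comments=[chash])
    if write_is:
        ids, is_mat = distance_tree.identity_score_matrix(gm)
        with open(outdir / "identity_score.tsv", "w") as fh:
            fh.write(f"# {chash}\n")
            fh.write("sample\t" + "\t".join(ids) + "\n")
            for i, name in enumerate(ids):
                fh.write(name + "\t"
                         + "\t".join(f"{x:.6g}" for x in is_mat[i]) + "\n")

    if bootstrap > 0:
        tree = distance_tree.bootstrap_support(gm, bootstrap, config.seed)
        tree.write(outdir / "nj_tree.nwk", include_support=True)
    else:
        tree = distance_tree.nj_tree(dm)
        tree.write(outdir / "nj_tree.nwk")

    result = {"n_samples": gm.n_samples, "n_sites": gm.n_sites,
              "bootstrap_replicates": bootstrap,
              "clamped_branch_length": tree.clamped_deficit}
    _write_metadata(outdir / "metadata.json", config, result)
    result["tree"] = tree
    result["distance_matrix"] = dm
    return result


def run_annotate(regions_bed, genes_path, outdir) -> dict:
    """Intersect an existing sweep-region BED with gene annotation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = []
    with variant_io._open_text(regions_bed) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            regions.append(sweep_scan.SweepRegion(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                tail=f[3].strip() if len(f) > 3 else "low",
                n_windows=0, max_fst=float("nan"),
                min_pi_ratio=float("nan"), max_pi_ratio=float("nan")))
    genes = variant_io.read_gene_annotation(genes_path)
    hits = sweep_scan.intersect_genes(regions, genes)
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("region_chrom\tregion_start\tregion_end\ttail\t"
                 "gene_id\tgene_start\tgene_end\toverlap_bp\n")
        for h in hits:
            fh.write(f"{h.region.chrom}\t{h.region.start}\t{h.region.end}\t"
                     f"{h.region.tail}\t{h.gene.gene_id}\t{h.gene.start}\t"
                     f"{h.gene.end}\t{h.overlap_bp}\n")
    return {"n_regions": len(regions), "n_gene_hits": len(hits),
            "n_unique_genes": len({h.gene.gene_id for h in hits}),
            "hits": hits}


def run_simulate(cfg: SimulationConfig, outdir, gzip_vcf: bool = False) -> dict:
    """Generate a synthetic dataset and write it with its truth."""
    ds = simulate_dataset(cfg)
    paths = write_dataset(ds, outdir, gzip_vcf=gzip_vcf)
    return {"dataset": ds, "paths": paths}


def scan_and_score(cfg: SimulationConfig, run_cfg: RunConfig, workdir) -> dict:
    """Simulate, scan through the file-based pipeline, score against truth.

    Convenience wrapper used by validation runs: returns the scan result
    plus a :class:`~sweepscan.synthetic_data.RecoveryScore`.
    """
    workdir = Path(workdir)
    sim = run_simulate(cfg, workdir / "sim")
    scan = run_scan(sim["paths"]["vcf"], sim["paths"]["pops"],
                    run_cfg, workdir / "scan", genes_path=sim["paths"]["gff"])
    score = score_recovery(scan["regions"], sim["dataset"].truth)
    return {"scan": scan, "score": score, "truth": sim["dataset"].truth}
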