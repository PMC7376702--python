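"""Synthetic two-population genotype datasets with known sweep intervals.

The generator emulates the data a two-group sweep scan consumes, at desk
scale, without forward or coalescent simulation:

* Per site, an ancestral allele frequency is drawn from a symmetric
  Beta(shape, shape) spectrum, then each group's frequency from the
  Balding–Nichols distribution Beta(p(1-F)/F, (1-p)(1-F)/F) with drift
  parameter F = ``f_bg`` (F = 0 means both groups share the ancestral
  frequency exactly).
* Inside each configured sweep interval, the selected group's frequency is
  pushed toward an allele-frequency boundary so that its expected
  heterozygosity is multiplied by the configured diversity-reduction factor
  (solving q'(1-q') = δ·q(1-q) and taking a root near 0 or 1). Pushing
  toward the far boundary (opposite the reference group) yields maximal
  differentiation, toward the near boundary minimal; the mixture weight
  between the two is calibrated by quadrature over the background spectrum
  so that the expected per-SNP Fst inside the sweep matches the configured
  target. Infeasible targets raise before any data is generated.
* Diploid genotypes are binomial draws from the group frequency, with
  i.i.d. missingness.

Sites are independent: there is no linkage structure in the main generator
(see :func:`simulate_ld_panel` for a two-haplotype panel with distance-
decaying LD used to exercise decay curves). Truth intervals with realized
frequency-level Fst and pi ratio accompany every dataset.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .variant_io import (
    GeneInterval, GenotypeMatrix, PopulationAssignment,
    write_gff3, write_population_file, write_vcf,
)

logger = logging.getLogger("sweepscan")

__all__ = [
    "SweepIntervalSpec", "SimulationConfig", "SimTruth", "SimulatedDataset",
    "RecoveryScore", "simulate_dataset", "write_dataset", "score_recovery",
    "simulate_ld_panel",
]


@dataclass(frozen=True)
class SweepIntervalSpec:
    """One planted sweep: where, how differentiated, how swept.

    ``diversity_reduction`` multiplies the selected group's expected
    heterozygosity inside the interval (0.1 = 90 % diversity loss);
    ``target_fst`` is the desired mean per-SNP Fst between the groups there.
    """

    chrom: str
    start: int
    end: int
    target_fst: float = 0.5
    diversity_reduction: float = 0.1

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")
        if not (0.0 <= self.target_fst <= 1.0):
            raise ValueError("target_fst outside [0, 1]")
        if not (0.0 < self.diversity_reduction <= 1.0):
            raise ValueError("diversity_reduction outside (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a small two-group resequencing panel: 10 diploids per
    group on one 5 Mb chromosome at one SNP per 500 bp, background
    divergence F_bg = 0.05, 2 % missing genotypes, and a single 100 kb sweep
    with 10× diversity loss in the selected group.
    """

    seed: int = 0
    n_group1: int = 10
    n_group2: int = 10
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000})
    snp_density: float = 1 / 500
    beta_shape: float = 0.8
    f_bg: float = 0.05
    sweeps: tuple[SweepIntervalSpec, ...] = field(
        default_factory=lambda: (SweepIntervalSpec("chr1", 2_000_000, 2_100_000),))
    missing_rate: float = 0.02
    group1_label: str = "black"
    group2_label: str = "nonblack"
    gene_spacing: int = 50_000
    gene_length: int = 20_000

    def __post_init__(self):
        for r, name in [(self.f_bg, "f_bg"), (self.missing_rate, "missing_rate")]:
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")
        if self.beta_shape <= 0:
            raise ValueError("beta_shape must be > 0")
        for s in self.sweeps:
            if s.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {s.chrom!r}")
            if s.end > self.chrom_lengths[s.chrom]:
                raise ValueError(f"sweep {s} exceeds chromosome length")
        for s in self.sweeps:
            _sweep_far_weight(s, self.beta_shape)  # raises if infeasible

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweeps"] = [dataclasses.asdict(s) for s in self.sweeps]
        return d


@dataclass
class TruthInterval:
    chrom: str
    start: int
    end: int
    realized_fst: float
    realized_pi_ratio: float


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    intervals: list[TruthInterval]
    config: SimulationConfig

    def write(self, bed_path, json_path) -> None:
        from .variant_io import _open_text
        with _open_text(bed_path, "wt") as fh:
            for t in self.intervals:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\tsweep\n")
        with _open_text(json_path, "wt") as fh:
            json.dump({
                "config": self.config.to_dict(),
                "intervals": [dataclasses.asdict(t) for t in self.intervals],
            }, fh, indent=2)
            fh.write("\n")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    assignment: PopulationAssignment
    genes: list[GeneInterval]
    truth: SimTruth


# ---------------------------------------------------------------------------
# sweep-push calibration
# ---------------------------------------------------------------------------


def _het_roots(q: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Near and far roots of q'(1-q') = delta * q(1-q)."""
    disc = np.sqrt(np.clip(1.0 - 4.0 * delta * q * (1.0 - q), 0.0, 1.0))
    low, high = (1.0 - disc) / 2.0, (1.0 + disc) / 2.0
    near = np.where(q <= 0.5, low, high)
    far = np.where(q <= 0.5, high, low)
    return near, far


def _closed_form_fst(p1, p2):
    s = p1 + p2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(s * (2 - s) > 0, (p1 - p2) ** 2 / (s * (2 - s)), np.nan)


def _sweep_far_weight(spec: SweepIntervalSpec, beta_shape: float) -> float:
    """Probability of pushing toward the far boundary needed to hit the
    sweep's target Fst, by quadrature over the background Beta spectrum.

    Raises ``ValueError`` when the target exceeds what full far-pushing can
    deliver at the configured diversity reduction (e.g. Fst 1 with nonzero
    residual diversity).
    """
    grid = np.linspace(0.005, 0.995, 199)
    w = sps.beta.pdf(grid, beta_shape, beta_shape)
    w /= w.sum()
    near, far = _het_roots(grid, spec.diversity_reduction)
    e_near = float(np.nansum(w * _closed_form_fst(near, grid)))
    e_far = float(np.nansum(w * _closed_form_fst(far, grid)))
    if spec.target_fst > e_far + 1e-9:
        raise ValueError(
            f"sweep target Fst {spec.target_fst} infeasible: with diversity "
            f"reduction {spec.diversity_reduction} the attainable expected "
            f"Fst is at most {e_far:.3f}"
        )
    if spec.target_fst <= e_near:
        return 0.0
    return (spec.target_fst - e_near) / (e_far - e_near)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0.0:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under ``cfg``; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sample_ids = ([f"{cfg.group1_label}_{k + 1}" for k in range(cfg.n_group1)]
                  + [f"{cfg.group2_label}_{k + 1}" for k in range(cfg.n_group2)])
    assignment = PopulationAssignment(
        {s: cfg.group1_label for s in sample_ids[:cfg.n_group1]}
        | {s: cfg.group2_label for s in sample_ids[cfg.n_group1:]},
        cfg.group1_label, cfg.group2_label,
    )

    chroms, positions, q1_all, q2_all = [], [], [], []
    truth_intervals: list[TruthInterval] = []
    for chrom, length in cfg.chrom_lengths.items():
        n_sites = int(round(cfg.snp_density * length))
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        p = np.clip(rng.beta(cfg.beta_shape, cfg.beta_shape, size=n_sites),
                    0.01, 0.99)
        q1 = _balding_nichols(rng, p, cfg.f_bg)
        q2 = _balding_nichols(rng, p, cfg.f_bg)

        for spec in (s for s in cfg.sweeps if s.chrom == chrom):
            inside = (pos >= spec.start) & (pos < spec.end)
            n_in = int(inside.sum())
            if n_in == 0:
                truth_intervals.append(TruthInterval(
                    chrom, spec.start, spec.end, float("nan"), float("nan")))
                continue
            w_far = _sweep_far_weight(spec, cfg.beta_shape)
            q = q1[inside]
            near, far = _het_roots(q, spec.diversity_reduction)
            # push away from the reference group's side, with calibrated odds
            ref_side = q2[inside] <= 0.5
            far_vs_ref = np.where(ref_side, np.maximum(near, far),
                                  np.minimum(near, far))
            near_vs_ref = np.where(ref_side, np.minimum(near, far),
                                   np.maximum(near, far))
            go_far = rng.random(n_in) < w_far
            q1[inside] = np.where(go_far, far_vs_ref, near_vs_ref)
            fst_in = _closed_form_fst(q1[inside], q2[inside])
            het1 = (2 * q1[inside] * (1 - q1[inside])).sum()
            het2 = (2 * q2[inside] * (1 - q2[inside])).sum()
            truth_intervals.append(TruthInterval(
                chrom, spec.start, spec.end,
                realized_fst=float(np.nanmean(fst_in)),
                realized_pi_ratio=float(het1 / het2) if het2 > 0 else float("nan"),
            ))

        chroms.append(np.full(n_sites, chrom, dtype=object))
        positions.append(pos)
        q1_all.append(q1)
        q2_all.append(q2)

    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    q1 = np.concatenate(q1_all)
    q2 = np.concatenate(q2_all)
    n_sites = len(pos_arr)

    dosage = np.empty((cfg.n_group1 + cfg.n_group2, n_sites), dtype=np.int8)
    dosage[:cfg.n_group1] = rng.binomial(
        2, q1[None, :], size=(cfg.n_group1, n_sites))
    dosage[cfg.n_group1:] = rng.binomial(
        2, q2[None, :], size=(cfg.n_group2, n_sites))
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = -1

    ref_alt = np.array(["A", "C", "G", "T"], dtype=object)
    ref = ref_alt[rng.integers(0, 4, size=n_sites)]
    shift = rng.integers(1, 4, size=n_sites)
    alt = ref_alt[(np.searchsorted(ref_alt, ref.astype(str)) + shift) % 4]

    gm = GenotypeMatrix(
        sample_ids=sample_ids, chrom=chrom_arr, pos0=pos_arr,
        ref=ref, alt=alt, dosage=dosage,
        ids=np.array([f"snp{k + 1}" for k in range(n_sites)], dtype=object),
    )
    genes = _tile_genes(cfg)
    truth = SimTruth(truth_intervals, cfg)
    logger.info("simulate_dataset: %d samples × %d sites, %d sweeps",
                gm.n_samples, gm.n_sites, len(truth_intervals))
    return SimulatedDataset(gm, assignment, genes, truth)


def _tile_genes(cfg: SimulationConfig) -> list[GeneInterval]:
    genes, k = [], 0
    for chrom, length in cfg.chrom_lengths.items():
        start = cfg.gene_spacing // 2
        while start + cfg.gene_length <= length:
            k += 1
            genes.append(GeneInterval(chrom, start, start + cfg.gene_length,
                                      f"gene{k:05d}"))
            start += cfg.gene_spacing
    return genes


def write_dataset(ds: SimulatedDataset, outdir, gzip_vcf: bool = False) -> dict:
    """Write VCF, population TSV, gene GFF3 and truth BED/JSON; returns the
    path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / ("sim.vcf.gz" if gzip_vcf else "sim.vcf"),
        "pops": outdir / "sim.pops.tsv",
        "gff": outdir / "sim.genes.gff3",
        "truth_bed": outdir / "sim.truth.bed",
        "truth_json": outdir / "sim.truth.json",
    }
    write_vcf(ds.genotypes, paths["vcf"],
              contig_lengths=ds.truth.config.chrom_lengths,
              extra_header=[f"##sweepscan_seed={ds.truth.config.seed}"])
    write_population_file(ds.assignment, paths["pops"])
    write_gff3(ds.genes, paths["gff"])
    ds.truth.write(paths["truth_bed"], paths["truth_json"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryScore:
    """Base-pair and interval-level agreement between called regions and
    truth. ``bp_precision`` is NaN when nothing was called."""

    bp_precision: float
    bp_recall: float
    n_truth: int
    n_recovered: int
    jaccards: list[float]


def _interval_overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def score_recovery(regions, truth: SimTruth,
                   jaccard_min: float = 0.3) -> RecoveryScore:
    """Score called sweep regions against the planted intervals.

    bp precision = overlapping bp / called bp; bp recall = overlapping bp /
    truth bp; a truth interval counts as recovered when its best
    single-region Jaccard index reaches ``jaccard_min``.
    """
    called = [(r.chrom, r.start, r.end) for r in regions]
    truths = [(t.chrom, t.start, t.end) for t in truth.intervals]
    called_bp = sum(e - s for _, s, e in called)
    truth_bp = sum(e - s for _, s, e in truths)

    overlap_bp = 0
    for tc, ts, te in truths:
        for cc, cs, ce in called:
            if cc == tc:
                overlap_bp += _interval_overlap(ts, te, cs, ce)

    jaccards, n_rec = [], 0
    for tc, ts, te in truths:
        best = 0.0
        for cc, cs, ce in called:
            if cc != tc:
                continue
            inter = _interval_overlap(ts, te, cs, ce)
            union = (te - ts) + (ce - cs) - inter
            if union > 0:
                best = max(best, inter / union)
        jaccards.append(best)
        if best >= jaccard_min:
            n_rec += 1

    return RecoveryScore(
        bp_precision=(overlap_bp / called_bp) if called_bp else float("nan"),
        bp_recall=(overlap_bp / truth_bp) if truth_bp else float("nan"),
        n_truth=len(truths),
        n_recovered=n_rec,
        jaccards=jaccards,
    )


# ---------------------------------------------------------------------------
# LD panel (decay tests)
# ---------------------------------------------------------------------------


def simulate_ld_panel(n_samples: int = 20, n_sites: int = 200,
                      length: int = 200_000, switch_scale: float = 50_000,
                      mutation_rate: float = 0.02,
                      seed: int | None = None) -> GenotypeMatrix:
    """A panel with LD decaying over ``switch_scale`` bp.

    Each of the 2·n_samples chromosomes copies one of two ancestral
    haplotypes (all-ref vs all-alt), switching between them along the
    chromosome as a Poisson process of rate 1/switch_scale, plus a small
    per-site mutation flip. Nearby sites therefore share their ancestor and
    correlate; distant sites do not.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    gaps = np.diff(pos)
    p_switch = 1.0 - np.exp(-gaps / switch_scale)
    haps = np.empty((2 * n_samples, n_sites), dtype=np.int8)
    state = rng.integers(0, 2, size=2 * n_samples)
    haps[:, 0] = state
    for k in range(1, n_sites):
        flip = rng.random(2 * n_samples) < p_switch[k - 1]
        state = np.where(flip, 1 - state, state)
        haps[:, k] = state
    mut = rng.random(haps.shape) < mutation_rate
    haps = np.where(mut, 1 - haps, haps)
    dosage = (haps[0::2] + haps[1::2]).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=[f"s{k + 1}" for k in range(n_samples)],
        chrom=np.full(n_sites, "chr1", dtype=object),
        pos0=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        dosage=dosage,
    )
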