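"""Dual-threshold sweep calling from window statistics.

A window is called part of a candidate selective sweep when it is extreme in
BOTH criteria (strict inequalities):

* windowed mean Fst above a cutoff — top-5 % empirical quantile by default,
  or a fixed value (the source study used Fst > 0.17);
* windowed pi ratio (selected/reference diversity) in a tail — below a low
  cutoff (diversity lost in the selected group, the classic sweep signature)
  or above a high cutoff (diversity lost in the reference group).

Flagged windows of the same tail are merged into regions, and regions are
intersected with gene annotations to produce the candidate-gene table.
Windows with undefined Fst or pi ratio are dropped from ranking and can
never be flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .popgen_stats import WindowStats
from .variant_io import GeneInterval

logger = logging.getLogger("sweepscan")

__all__ = [
    "ThresholdPolicy", "Cutoffs", "FlaggedWindow", "SweepRegion", "GeneHit",
    "compute_thresholds", "flag_windows", "merge_windows", "intersect_genes",
]

LOW_TAIL = "low"    # reduced diversity in the selected group (group1)
HIGH_TAIL = "high"  # reduced diversity in the reference group


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the two cutoffs are obtained.

    ``quantile`` mode (default) takes empirical quantiles of the defined
    windows: the Fst cutoff at ``fst_quantile`` and the ratio cutoffs at the
    two ``ratio`` tail quantiles. ``fixed`` mode passes the given values
    through unchanged (study defaults: Fst 0.17, ratio 0.05 / 0.95).
    ``direction`` restricts which pi-ratio tail may flag a window.
    """

    mode: str = "quantile"
    fst_quantile: float = 0.95
    fst_value: float = 0.17
    ratio_low_quantile: float = 0.05
    ratio_high_quantile: float = 0.95
    ratio_low: float = 0.05
    ratio_high: float = 0.95
    direction: str = "both"  # both | low-only | high-only

    def __post_init__(self):
        if self.mode not in ("quantile", "fixed"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.direction not in ("both", "low-only", "high-only"):
            raise ValueError(f"unknown direction filter {self.direction!r}")
        if self.mode == "quantile":
            for q in (self.fst_quantile, self.ratio_low_quantile,
                      self.ratio_high_quantile):
                if not (0.0 < q < 1.0):
                    raise ValueError(f"quantile {q} outside (0, 1)")
        else:
            for v in (self.fst_value, self.ratio_low, self.ratio_high):
                if v < 0:
                    raise ValueError(f"fixed cutoff {v} must be >= 0")


@dataclass(frozen=True)
class Cutoffs:
    """Concrete cutoffs actually applied, echoed into run metadata."""

    fst: float
    ratio_low: float
    ratio_high: float
    mode: str
    direction: str
    n_windows_used: int


@dataclass(frozen=True)
class FlaggedWindow:
    window: WindowStats
    tail: str  # LOW_TAIL or HIGH_TAIL


@dataclass
class SweepRegion:
    """Merged run of flagged windows sharing a chromosome and tail."""

    chrom: str
    start: int
    end: int
    tail: str
    n_windows: int
    max_fst: float
    min_pi_ratio: float
    max_pi_ratio: float
    gene_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneHit:
    region: SweepRegion
    gene: GeneInterval
    overlap_bp: int


def _defined(stats: Sequence[WindowStats]) -> list[WindowStats]:
    return [w for w in stats
            if not (np.isnan(w.fst_mean) or np.isnan(w.pi_ratio))]


def compute_thresholds(stats: Sequence[WindowStats],
                       policy: ThresholdPolicy) -> Cutoffs:
    """Turn a policy into concrete cutoffs over the defined windows.

    Quantiles use the linear-interpolation definition (numpy default).
    """
    defined = _defined(stats)
    if policy.mode == "fixed":
        cut = Cutoffs(policy.fst_value, policy.ratio_low, policy.ratio_high,
                      "fixed", policy.direction, len(defined))
    else:
        if not defined:
            raise ValueError("no window has both Fst and pi ratio defined")
        fst = np.array([w.fst_mean for w in defined])
        ratio = np.array([w.pi_ratio for w in defined])
        cut = Cutoffs(
            fst=float(np.quantile(fst, policy.fst_quantile)),
            ratio_low=float(np.quantile(ratio, policy.ratio_low_quantile)),
            ratio_high=float(np.quantile(ratio, policy.ratio_high_quantile)),
            mode="quantile", direction=policy.direction,
            n_windows_used=len(defined),
        )
    logger.info(
        "thresholds (%s mode over %d windows): Fst > %.6g, "
        "pi ratio < %.6g or > %.6g [%s]",
        cut.mode, cut.n_windows_used, cut.fst, cut.ratio_low, cut.ratio_high,
        cut.direction,
    )
    return cut


def flag_windows(stats: Sequence[WindowStats],
                 cutoffs: Cutoffs) -> list[FlaggedWindow]:
    """Windows extreme in both criteria, labelled by pi-ratio tail.

    Strict inequalities throughout: a window exactly at a cutoff is not
    flagged. The low tail marks diversity loss in the selected group.
    """
    flagged: list[FlaggedWindow] = []
    for w in _defined(stats):
        if not (w.fst_mean > cutoffs.fst):
            continue
        low = w.pi_ratio < cutoffs.ratio_low
        high = w.pi_ratio > cutoffs.ratio_high
        if low and cutoffs.direction != "high-only":
            flagged.append(FlaggedWindow(w, LOW_TAIL))
        elif high and cutoffs.direction != "low-only":
            flagged.append(FlaggedWindow(w, HIGH_TAIL))
    logger.info("flagged %d / %d windows", len(flagged), len(stats))
    return flagged


def merge_windows(flagged: Sequence[FlaggedWindow],
                  max_gap_bp: int = 0) -> list[SweepRegion]:
    """Merge overlapping or ≤ max_gap-separated same-chromosome, same-tail
    flagged windows into :class:`SweepRegion` records."""
    regions: list[SweepRegion] = []
    by_key: dict[tuple[str, str], list[FlaggedWindow]] = {}
    for fw in flagged:
        by_key.setdefault((fw.window.chrom, fw.tail), []).append(fw)
    for (chrom, tail), group in sorted(by_key.items()):
        group = sorted(group, key=lambda fw: fw.window.start)
        current: list[FlaggedWindow] = []
        for fw in group:
            if current and fw.window.start > current[-1].window.end + max_gap_bp:
                regions.append(_make_region(chrom, tail, current))
                current = []
            current.append(fw)
        if current:
            regions.append(_make_region(chrom, tail, current))
    regions.sort(key=lambda r: (r.chrom, r.start, r.tail))
    return regions


def _make_region(chrom: str, tail: str,
                 windows: list[FlaggedWindow]) -> SweepRegion:
    ws = [fw.window for fw in windows]
    return SweepRegion(
        chrom=chrom,
        start=min(w.start for w in ws),
        end=max(w.end for w in ws),
        tail=tail,
        n_windows=len(ws),
        max_fst=max(w.fst_mean for w in ws),
        min_pi_ratio=min(w.pi_ratio for w in ws),
        max_pi_ratio=max(w.pi_ratio for w in ws),
    )


def intersect_genes(regions: Sequence[SweepRegion],
                    genes: Sequence[GeneInterval]) -> list[GeneHit]:
    """Report every gene overlapping each region by ≥ 1 bp.

    Hits come back sorted by (region chrom, region start, gene start); each
    region's ``gene_ids`` is filled in place. Chromosome labels present only
    on one side are warned about once.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    region_chroms = {r.chrom for r in regions}
    gene_chroms = set(trees)
    only = region_chroms - gene_chroms
    if regions and genes and only:
        logger.warning(
            "no annotation on region chromosome(s) %s — check chromosome "
            "naming", ",".join(sorted(only)),
        )

    hits: list[GeneHit] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        found = []
        for iv in trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end):
            g: GeneInterval = iv.data
            overlap = min(r.end, g.end) - max(r.start, g.start)
            if overlap >= 1:
                found.append(GeneHit(r, g, overlap))
        found.sort(key=lambda h: h.gene.start)
        r.gene_ids = [h.gene.gene_id for h in found]
        hits.extend(found)
    n_unique = len({h.gene.gene_id for h in hits})
    logger.info("gene intersection: %d hits, %d unique genes over %d regions",
                len(hits), n_unique, len(regions))
    return hits
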