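"""Linkage disequilibrium: pairwise r², decay curves and greedy pruning.

r² is the squared Pearson correlation of unphased genotype dosages over
pairwise-complete samples (the Rogers–Huff composite measure — no phasing
or EM haplotype frequencies). Pruning follows the PLINK
``--indep-pairwise 50 5 0.2`` scheme: 50-SNP windows sliding by 5 SNPs
within each chromosome; whenever a retained pair in the window exceeds the
r² threshold, the downstream (larger-position) member is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger("sweepscan")

__all__ = ["DecayCurve", "genotype_r2", "ld_decay", "ld_prune"]


@dataclass
class DecayCurve:
    """Mean r² binned by inter-SNP distance.

    ``bin_edges`` has length n_bins+1 (contiguous, bp); bins with no pair
    have NaN mean.
    """

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        if len(self.bin_edges) != len(self.mean_r2) + 1:
            raise ValueError("bin_edges must be one longer than mean_r2")

    def to_tsv(self, path, header_comments=()) -> None:
        from .variant_io import _open_text
        with _open_text(path, "wt") as fh:
            for c in header_comments:
                fh.write(f"# {c}\n")
            fh.write("bin_start\tbin_end\tmean_r2\tn_pairs\n")
            for i in range(len(self.mean_r2)):
                r2 = "NA" if np.isnan(self.mean_r2[i]) else f"{self.mean_r2[i]:.6g}"
                fh.write(f"{int(self.bin_edges[i])}\t{int(self.bin_edges[i + 1])}\t"
                         f"{r2}\t{int(self.n_pairs[i])}\n")


def genotype_r2(x, y) -> float:
    """Squared dosage correlation of two sites over pairwise-complete
    samples; NaN when fewer than two complete samples remain or either site
    is monomorphic among them."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pair_r2_block(d: np.ndarray, i: int, js: np.ndarray) -> np.ndarray:
    """r² of site i against sites js, pairwise-complete; d is samples×sites."""
    out = np.empty(len(js))
    x = d[:, i]
    no_missing = (d[:, js] != MISSING).all() and (x != MISSING).all()
    if no_missing:
        xs = x - x.mean()
        vx = (xs ** 2).mean()
        Y = d[:, js]
        ys = Y - Y.mean(axis=0)
        vy = (ys ** 2).mean(axis=0)
        cov = (xs[:, None] * ys).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = cov * cov / (vx * vy)
        out[vy == 0.0] = np.nan
        if vx == 0.0:
            out[:] = np.nan
        return out
    for k, j in enumerate(js):
        out[k] = genotype_r2(x, d[:, j])
    return out


def ld_decay(gm: GenotypeMatrix, sample_ids=None, max_dist_bp: int = 300_000,
             bin_bp: int = 1_000) -> DecayCurve:
    """Bin mean r² of all same-chromosome SNP pairs by distance.

    Pairs farther apart than ``max_dist_bp`` are skipped; uncomputable pairs
    (monomorphic/too-missing) do not count. Deterministic given inputs.
    """
    if not (max_dist_bp >= bin_bp >= 1):
        raise ValueError("need max_dist_bp >= bin_bp >= 1")
    sub = gm if sample_ids is None else gm.take_samples(sample_ids)
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    d = sub.dosage.astype(float)
    for chrom in sub.chroms():
        cidx = np.flatnonzero(sub.chrom == chrom)
        pos = sub.pos0[cidx]
        for a in range(len(cidx) - 1):
            hi = int(np.searchsorted(pos, pos[a] + max_dist_bp, side="right"))
            if hi <= a + 1:
                continue
            js = cidx[a + 1:hi]
            r2 = _pair_r2_block(d, cidx[a], js)
            dist = pos[a + 1:hi] - pos[a]
            ok = ~np.isnan(r2)
            if ok.any():
                b = np.minimum((dist[ok] - 1) // bin_bp, n_bins - 1).astype(int)
                np.add.at(sums, b, r2[ok])
                np.add.at(counts, b, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DecayCurve(bin_edges=edges, mean_r2=means, n_pairs=counts)


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_threshold: float = 0.2, victim: str = "position") -> np.ndarray:
    """Greedy sliding-window pruning; returns retained site indices in
    position order.

    Within each window of ``window_snps`` consecutive sites (per
    chromosome), every retained pair is checked in order; when r² exceeds
    the threshold one member is removed — the downstream site when
    ``victim='position'`` (deterministic default) or the lower-MAF site when
    ``victim='maf'`` (PLINK's choice, position as tie-break). The window
    then slides by ``step_snps`` sites.
    """
    if window_snps <= step_snps or step_snps < 1:
        raise ValueError("need window_snps > step_snps >= 1")
    if victim not in ("position", "maf"):
        raise ValueError(f"unknown victim rule {victim!r}")

    d = gm.dosage.astype(float)
    keep = np.ones(gm.n_sites, dtype=bool)
    maf = None
    if victim == "maf":
        ok = gm.dosage != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, gm.dosage, 0).sum(axis=0) / np.maximum(
                2 * ok.sum(axis=0), 1)
        maf = np.minimum(p, 1 - p)

    for chrom in gm.chroms():
        cidx = np.flatnonzero(gm.chrom == chrom)
        start = 0
        while start < len(cidx):
            window = cidx[start:start + window_snps]
            for a_pos, a in enumerate(window):
                if not keep[a]:
                    continue
                for b in window[a_pos + 1:]:
                    if not keep[b]:
                        continue
                    r2 = genotype_r2(d[:, a], d[:, b])
                    if not np.isnan(r2) and r2 > r2_threshold:
                        if maf is not None and maf[a] < maf[b]:
                            keep[a] = False
                            break  # a gone; stop pairing it
                        keep[b] = False
            start += step_snps

    retained = np.flatnonzero(keep)
    logger.info("ld_prune: retained %d / %d sites (window %d, step %d, "
                "r2 > %g)", len(retained), gm.n_sites, window_snps,
                step_snps, r2_threshold)
    return retained
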