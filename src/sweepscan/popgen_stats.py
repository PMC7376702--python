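"""Per-SNP and windowed differentiation and diversity statistics.

The differentiation statistic is the Hudson-style per-SNP fixation index

    Fst = 1 - [p1(1-p1) + p2(1-p2)] / [(p1+p2)(1 - (p1+p2)/2)]

where p1 and p2 are the alternate-allele frequencies in the selected and
reference groups. Algebraically this equals (p1-p2)^2 / [(p1+p2)(2-p1-p2)];
it is 0 for identical frequencies, 1 for a fixed difference, and undefined
when the pooled site is monomorphic (p1=p2=0 or p1=p2=1). Note this is not
the Weir–Cockerham variance-components estimator: it uses sample allele
frequencies directly, with no finite-sample correction, and the windowed
value is the unweighted arithmetic mean over computable SNPs.

Nucleotide diversity per window is

    pi = sum_sites [ n/(n-1) * 2 p (1-p) ] / window_span_bp

with p the within-group frequency and n the non-missing chromosome count at
the site (the unbiased per-site expected heterozygosity); an alternative
per-SNP-count denominator is available. Windows are half-open [start,
start+window_bp) intervals tiled from coordinate 0 in steps of step_bp
(defaults 10 kb / 5 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .variant_io import MISSING, GenotypeMatrix, PopulationAssignment

__all__ = [
    "AlleleFrequencyPair", "WindowStats", "Window",
    "allele_frequency", "group_frequencies", "snp_fst", "snp_fst_array",
    "window_iter", "window_fst", "window_pi", "pi_ratio",
    "compute_window_stats",
]


@dataclass(frozen=True)
class AlleleFrequencyPair:
    """Alternate-allele frequency of one SNP in each group, with the
    non-missing chromosome counts the estimates used."""

    p1: float
    p2: float
    n1: int
    n2: int

    def __post_init__(self):
        for p in (self.p1, self.p2):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"allele frequency {p} outside [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("chromosome counts must be >= 1")


@dataclass
class WindowStats:
    """Statistics of one sliding window (0-based half-open, bp).

    ``fst_mean`` and ``pi_ratio`` are NaN when undefined (no computable SNP,
    or zero reference-group diversity respectively).
    """

    chrom: str
    start: int
    end: int
    n_snps_total: int
    n_snps_fst: int
    fst_mean: float
    pi_group1: float
    pi_group2: float
    pi_ratio: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Window:
    """A window's bounds plus the half-open slice of site indices it holds
    (indices into the matrix's site axis, contiguous because sites are
    position-sorted)."""

    chrom: str
    start: int
    end: int
    lo: int
    hi: int

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_snps(self) -> int:
        return self.hi - self.lo

    def site_indices(self) -> np.ndarray:
        return np.arange(self.lo, self.hi)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def allele_frequency(dosages) -> tuple[float, int]:
    """Alternate-allele frequency and non-missing chromosome count.

    frequency = (sum of alt dosages) / (2 × non-missing samples). Returns
    ``(nan, 0)`` when every genotype is missing (site uncomputable for the
    group).
    """
    d = np.asarray(dosages)
    ok = d != MISSING
    n_chrom = 2 * int(ok.sum())
    if n_chrom == 0:
        return float("nan"), 0
    return float(d[ok].sum()) / n_chrom, n_chrom


def group_frequencies(gm: GenotypeMatrix, sample_idx) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site (frequency, chromosome count) for one group."""
    d = gm.dosage[np.asarray(sample_idx, dtype=np.intp), :]
    ok = d != MISSING
    n_chrom = 2 * ok.sum(axis=0)
    alt = np.where(ok, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    return p, n_chrom.astype(np.int64)


def snp_fst(freqs: AlleleFrequencyPair | tuple[float, float]) -> float:
    """Per-SNP Fst by the printed two-population formula.

    NaN when the pooled site is monomorphic (p1=p2=0 or 1), in which case the
    site is excluded from window means.
    """
    if isinstance(freqs, AlleleFrequencyPair):
        p1, p2 = freqs.p1, freqs.p2
    else:
        p1, p2 = freqs
        for p in (p1, p2):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"allele frequency {p} outside [0, 1]")
    s = p1 + p2
    denom = s * (1.0 - s / 2.0)
    if denom == 0.0:
        return float("nan")
    fst = 1.0 - (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / denom
    return min(1.0, max(0.0, fst))  # clip float roundoff at the boundaries


def snp_fst_array(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Vectorized :func:`snp_fst`; NaN where undefined (monomorphic pooled
    site or missing frequency)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    s = p1 + p2
    denom = s * (1.0 - s / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 1.0 - (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / denom
    fst = np.where(denom == 0.0, np.nan, fst)
    return np.clip(fst, 0.0, 1.0)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def window_iter(gm: GenotypeMatrix, window_bp: int = 10_000,
                step_bp: int = 5_000) -> Iterator[Window]:
    """Tile each chromosome with half-open windows from coordinate 0.

    Windows start at 0, step_bp, 2·step_bp, …; a SNP belongs to every window
    whose interval contains its 0-based position. Windows are emitted while
    their start does not exceed the chromosome's last SNP position (i.e. the
    chromosome is treated as ending at the last SNP rounded up to a window
    boundary — no reference index is required). Chromosomes with no SNPs
    yield nothing; empty windows between SNPs are emitted with n_snps=0.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    offsets = np.flatnonzero(np.r_[True, gm.chrom[1:] != gm.chrom[:-1]]) \
        if gm.n_sites else np.array([], dtype=np.intp)
    bounds = list(offsets) + [gm.n_sites]
    for k in range(len(bounds) - 1):
        c_lo, c_hi = bounds[k], bounds[k + 1]
        chrom = gm.chrom[c_lo]
        pos = gm.pos0[c_lo:c_hi]
        last = int(pos[-1])
        start = 0
        while start <= last:
            end = start + window_bp
            lo = c_lo + int(np.searchsorted(pos, start, side="left"))
            hi = c_lo + int(np.searchsorted(pos, end, side="left"))
            yield Window(chrom, start, end, lo, hi)
            start += step_bp


def window_fst(site_fsts) -> float:
    """Unweighted mean of the computable per-SNP Fst values; NaN if none."""
    v = np.asarray(list(site_fsts), dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())


def window_pi(gm: GenotypeMatrix, sample_idx, window: Window,
              denominator: str = "span") -> float:
    """Per-bp nucleotide diversity of one group in one window.

    Sums the unbiased per-site heterozygosity n/(n-1)·2p(1-p) over the
    window's SNPs and divides by the window span (``denominator='span'``,
    default) or by the SNP count (``'snps'``). Sites with fewer than two
    non-missing chromosomes contribute 0.
    """
    p, n = group_frequencies(gm, sample_idx)
    contrib = _pi_site_contributions(p, n)
    total = float(contrib[window.lo:window.hi].sum())
    return _pi_normalize(total, window.span, window.n_snps, denominator)


def _pi_site_contributions(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
    return np.where(n >= 2, np.nan_to_num(h), 0.0)


def _pi_normalize(total: float, span: int, n_snps: int, denominator: str) -> float:
    if denominator == "span":
        return total / span
    if denominator == "snps":
        return total / n_snps if n_snps else 0.0
    raise ValueError(f"unknown pi denominator {denominator!r}")


def pi_ratio(pi1: float, pi2: float) -> float:
    """pi_group1 / pi_group2; NaN when the reference-group pi is 0 (window
    excluded from ratio thresholding)."""
    if pi1 < 0 or pi2 < 0:
        raise ValueError("nucleotide diversity cannot be negative")
    if pi2 == 0.0:
        return float("nan")
    return pi1 / pi2


# ---------------------------------------------------------------------------
# assembled scan
# ---------------------------------------------------------------------------


def compute_window_stats(gm: GenotypeMatrix, pops: PopulationAssignment,
                         window_bp: int = 10_000, step_bp: int = 5_000,
                         pi_denominator: str = "span") -> list[WindowStats]:
    """Windowed mean Fst, per-group pi and pi ratio over the whole matrix.

    Orientation: pi_ratio = pi(group1, selected) / pi(group2, reference).
    """
    idx1, idx2 = pops.indices(gm)
    p1, n1 = group_frequencies(gm, idx1)
    p2, n2 = group_frequencies(gm, idx2)
    site_fst = snp_fst_array(p1, p2)
    site_fst = np.where(np.isnan(p1) | np.isnan(p2), np.nan, site_fst)
    pi1 = _pi_site_contributions(p1, n1)
    pi2 = _pi_site_contributions(p2, n2)

    # prefix sums let each overlapping window be a pair of O(1) lookups
    fst_ok = ~np.isnan(site_fst)
    cum_fst = np.concatenate([[0.0], np.cumsum(np.where(fst_ok, site_fst, 0.0))])
    cum_n_fst = np.concatenate([[0], np.cumsum(fst_ok.astype(np.int64))])
    cum_pi1 = np.concatenate([[0.0], np.cumsum(pi1)])
    cum_pi2 = np.concatenate([[0.0], np.cumsum(pi2)])

    out: list[WindowStats] = []
    for w in window_iter(gm, window_bp, step_bp):
        n_fst = int(cum_n_fst[w.hi] - cum_n_fst[w.lo])
        fst_mean = ((cum_fst[w.hi] - cum_fst[w.lo]) / n_fst
                    if n_fst else float("nan"))
        g1 = _pi_normalize(float(cum_pi1[w.hi] - cum_pi1[w.lo]),
                           w.span, w.n_snps, pi_denominator)
        g2 = _pi_normalize(float(cum_pi2[w.hi] - cum_pi2[w.lo]),
                           w.span, w.n_snps, pi_denominator)
        out.append(WindowStats(
            chrom=w.chrom, start=w.start, end=w.end,
            n_snps_total=w.n_snps, n_snps_fst=n_fst,
            fst_mean=float(fst_mean), pi_group1=g1, pi_group2=g2,
            pi_ratio=pi_ratio(g1, g2),
        ))
    return out
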