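"""Readers and writers for the formats the pipeline touches.

VCF (via cyvcf2), BED / GFF3 gene annotations, sample→group tables and
window-statistic TSVs are converted to and from the in-memory model:

* :class:`GenotypeMatrix` — samples × biallelic SNP sites, alternate-allele
  dosage coding (0/1/2, ``-1`` = missing genotype).
* :class:`PopulationAssignment` — sample ids mapped to exactly two analysis
  groups (group1 = selected, group2 = reference).
* :class:`GeneInterval` — gene span in 0-based half-open coordinates.

All genomic coordinates are 0-based half-open internally; VCF positions are
converted on read and back on write. Multiallelic sites and non-SNP variants
are dropped, not split, because every downstream statistic is defined on
biallelic SNP frequencies. All text readers accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("sweepscan")

#: dosage sentinel for a missing genotype
MISSING = -1


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class FilterStats:
    """Tally of why VCF records were kept or excluded."""

    n_records: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    n_filter_failed: int = 0
    n_high_missingness: int = 0
    n_retained: int = 0

    @property
    def n_excluded(self) -> int:
        return (
            self.n_multiallelic
            + self.n_non_snp
            + self.n_filter_failed
            + self.n_high_missingness
        )


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a sample panel.

    ``dosage`` has shape ``(n_samples, n_sites)`` with entries in
    ``{0, 1, 2, MISSING}`` counting alternate alleles per diploid genotype.
    ``pos0`` is 0-based; positions are strictly increasing within each
    chromosome.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos0: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    ids: np.ndarray | None = None
    filter_stats: FilterStats | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos0 = np.asarray(self.pos0, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples × sites)")
        n_samples, n_sites = self.dosage.shape
        if n_samples != len(self.sample_ids):
            raise ValueError("dosage rows must match sample_ids")
        for arr, name in [(self.chrom, "chrom"), (self.pos0, "pos0"),
                          (self.ref, "ref"), (self.alt, "alt")]:
            if len(arr) != n_sites:
                raise ValueError(f"{name} length must match dosage columns")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0/1/2 or missing sentinel")
        for c in dict.fromkeys(self.chrom):
            p = self.pos0[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    @property
    def pos1(self) -> np.ndarray:
        """1-based positions as printed in VCF."""
        return self.pos0 + 1

    def chroms(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.chrom))

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos0=self.pos0[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            ids=None if self.ids is None else self.ids[idx],
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos0=self.pos0,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx, :],
            ids=self.ids,
        )


@dataclass
class PopulationAssignment:
    """Sample→group mapping with exactly two designated analysis groups."""

    assignment: dict[str, str]
    group1_label: str
    group2_label: str

    def __post_init__(self):
        if self.group1_label == self.group2_label:
            raise ValueError("group1 and group2 labels must differ")
        groups = set(self.assignment.values())
        if groups != {self.group1_label, self.group2_label}:
            raise ValueError(
                f"assignment must contain exactly the two groups "
                f"{self.group1_label!r}/{self.group2_label!r}; found {sorted(groups)}"
            )
        if not self.group1_samples or not self.group2_samples:
            raise ValueError("both groups must be non-empty")

    @property
    def group1_samples(self) -> list[str]:
        return [s for s, g in self.assignment.items() if g == self.group1_label]

    @property
    def group2_samples(self) -> list[str]:
        return [s for s, g in self.assignment.items() if g == self.group2_label]

    def restrict_to(self, gm: GenotypeMatrix) -> "PopulationAssignment":
        """Drop assigned samples absent from ``gm`` (warning each)."""
        present = set(gm.sample_ids)
        kept = {}
        for s, g in self.assignment.items():
            if s in present:
                kept[s] = g
            else:
                warnings.warn(f"assigned sample {s!r} absent from VCF; ignored")
        unassigned = [s for s in gm.sample_ids if s not in kept]
        if unassigned:
            logger.info(
                "%d VCF samples unassigned to a group (excluded from group "
                "statistics): %s", len(unassigned), ",".join(unassigned)
            )
        return PopulationAssignment(kept, self.group1_label, self.group2_label)

    def indices(self, gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
        return (gm.sample_index(self.group1_samples),
                gm.sample_index(self.group2_samples))


@dataclass
class GeneInterval:
    """A gene span in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str
    source_line: int = 0

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end {self.end} <= start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class SiteFilters:
    """Site-level QC applied on VCF read.

    Defaults: biallelic SNPs only, per-site genotype missingness ≤ 20 %,
    FILTER column PASS/'.'.
    """

    max_missing: float = 0.2
    require_pass: bool = True


def read_vcf(path, filters: SiteFilters | None = None) -> GenotypeMatrix:
    """Read a GT-bearing VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP sites passing ``filters`` are retained; exclusions are
    tallied in the returned matrix's ``filter_stats`` and logged. Diploid
    genotypes are collapsed to alternate-allele dosage; missing calls
    (``./.``) become the missing sentinel.
    """
    from cyvcf2 import VCF

    filters = filters or SiteFilters()
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as e:  # cyvcf2 raises bare exceptions on parse failure
        raise ValueError(f"cannot open VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")

    stats = FilterStats()
    chrom, pos0, ref, alt, ids, rows = [], [], [], [], [], []
    n_samples = len(samples)
    iterator = iter(vcf)
    while True:
        try:
            v = next(iterator)
        except StopIteration:
            break
        except Exception as e:
            raise ValueError(
                f"malformed VCF {path} after record {stats.n_records}: {e}"
            ) from e
        stats.n_records += 1
        if len(v.ALT) != 1:
            stats.n_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or \
                v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            stats.n_non_snp += 1
            continue
        if filters.require_pass and v.FILTER is not None:
            # cyvcf2 reports None for PASS and '.'
            stats.n_filter_failed += 1
            continue
        # gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        n_missing = int((g == MISSING).sum())
        if n_missing > filters.max_missing * n_samples:
            stats.n_high_missingness += 1
            continue
        stats.n_retained += 1
        chrom.append(v.CHROM)
        pos0.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        ids.append(v.ID or ".")
        rows.append(g)
    vcf.close()

    logger.info(
        "read_vcf %s: %d records, retained %d (excluded: %d multiallelic, "
        "%d non-SNP, %d filter-failed, %d high-missingness)",
        path, stats.n_records, stats.n_retained, stats.n_multiallelic,
        stats.n_non_snp, stats.n_filter_failed, stats.n_high_missingness,
    )
    dosage = (np.array(rows, dtype=np.int8).T if rows
              else np.empty((n_samples, 0), dtype=np.int8))
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chrom, dtype=object),
        pos0=np.array(pos0, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
        ids=np.array(ids, dtype=object),
        filter_stats=stats,
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None,
              extra_header: Sequence[str] = ()) -> None:
    """Write the matrix back out as a minimal VCFv4.2 (gzip if path ends .gz)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for c in gm.chroms():
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        ids = gm.ids if gm.ids is not None else ["."] * gm.n_sites
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.dosage[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos0[j] + 1}\t{ids[j]}\t{gm.ref[j]}\t"
                     f"{gm.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# population table
# ---------------------------------------------------------------------------


def read_population_file(path, group1: str | None = None,
                         group2: str | None = None) -> PopulationAssignment:
    """Read a two-column ``sample_id<TAB>group`` table.

    With ``group1``/``group2`` given, samples in other groups are dropped
    with a warning; otherwise the file must contain exactly two groups and
    group1 is the group of the first listed sample (the selected group).
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group'")
            sample, group = parts[0], parts[1]
            if sample in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            mapping[sample] = group

    groups = list(dict.fromkeys(mapping.values()))
    if group1 is not None and group2 is not None:
        for g in (group1, group2):
            if g not in groups:
                raise ValueError(f"group {g!r} not present in {path}")
        dropped = {s for s, g in mapping.items() if g not in (group1, group2)}
        if dropped:
            warnings.warn(
                f"{len(dropped)} samples in groups other than "
                f"{group1!r}/{group2!r} ignored"
            )
        mapping = {s: g for s, g in mapping.items() if g in (group1, group2)}
    else:
        if len(groups) != 2:
            raise ValueError(
                f"{path}: sweep scan needs exactly two groups, found "
                f"{len(groups)}: {groups}"
            )
        group1, group2 = groups
    return PopulationAssignment(mapping, group1, group2)


def write_population_file(assignment: PopulationAssignment, path) -> None:
    with _open_text(path, "wt") as fh:
        for s, g in assignment.assignment.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def _gff3_attr(attrs: str, keys=("ID", "gene_id", "Name")) -> str | None:
    for part in attrs.strip().rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def read_gene_annotation(path, feature_type: str = "gene") -> list[GeneInterval]:
    """Read genes from BED (0-based half-open) or GFF3 (1-based inclusive).

    The format is autodetected from the extension; GFF3 rows are restricted
    to ``feature_type``. All intervals are normalized to 0-based half-open;
    rows that are empty after normalization are rejected with a warning.
    """
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    is_bed = name.endswith(".bed")
    is_gff = name.endswith((".gff", ".gff3", ".gtf"))
    if not (is_bed or is_gff):
        raise ValueError(f"cannot detect annotation format of {path} "
                         "(expected .bed or .gff/.gff3)")

    genes: list[GeneInterval] = []
    n_rejected = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if is_bed:
                    if len(f) < 3:
                        raise ValueError("fewer than 3 BED columns")
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    gene_id = f[3] if len(f) > 3 and f[3] else f"bed_{lineno}"
                else:
                    if len(f) < 9:
                        raise ValueError("fewer than 9 GFF3 columns")
                    if f[2] != feature_type:
                        continue
                    chrom = f[0]
                    start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
                    gene_id = _gff3_attr(f[8]) or f"gff_{lineno}"
                genes.append(GeneInterval(chrom, start, end, gene_id, lineno))
            except ValueError as e:
                n_rejected += 1
                warnings.warn(f"{path}:{lineno}: rejected record ({e})")
    if n_rejected:
        logger.info("read_gene_annotation %s: rejected %d records", path, n_rejected)
    return genes


def write_gff3(genes: Sequence[GeneInterval], path,
               source: str = "sweepscan") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                     f"ID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# window-statistics TSV
# ---------------------------------------------------------------------------

_WINDOW_COLUMNS = ("chrom", "start", "end", "n_snps", "n_snps_fst",
                   "fst_mean", "pi_group1", "pi_group2", "pi_ratio")


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "NA"
    return format(float(x), ".6g")


def write_window_stats(stats, path, header_comments: Sequence[str] = ()) -> None:
    """Write per-window statistics as TSV (6 significant digits, NA for
    undefined), sorted by (chrom, start); '#'-prefixed metadata first."""
    rows = sorted(stats, key=lambda w: (w.chrom, w.start))
    with _open_text(path, "wt") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(_WINDOW_COLUMNS) + "\n")
        for w in rows:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps_total}\t{w.n_snps_fst}\t"
                f"{_fmt(w.fst_mean)}\t{_fmt(w.pi_group1)}\t{_fmt(w.pi_group2)}\t"
                f"{_fmt(w.pi_ratio)}\n"
            )


def read_window_stats(path) -> list:
    """Read back a TSV written by :func:`write_window_stats`."""
    from .popgen_stats import WindowStats

    out = []
    with _open_text(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if tuple(header) != _WINDOW_COLUMNS:
                    raise ValueError(f"{path}: unexpected columns {header}")
                continue
            f = line.split("\t")
            num = lambda s: float("nan") if s == "NA" else float(s)
            out.append(WindowStats(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                n_snps_total=int(f[3]), n_snps_fst=int(f[4]),
                fst_mean=num(f[5]), pi_group1=num(f[6]), pi_group2=num(f[7]),
                pi_ratio=num(f[8]),
            ))
    return out
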