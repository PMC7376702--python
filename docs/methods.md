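# Methods

This note documents the models, estimators, numerical conventions and
deliberate design choices behind `sweepscan`, and what its synthetic-data
validation does and does not demonstrate.

## Data model and coordinates

All statistics operate on a `GenotypeMatrix`: samples × biallelic SNP
sites, coded as alternate-allele dosage 0/1/2 with `-1` for a missing
genotype. Internally every coordinate is 0-based half-open; VCF's 1-based
positions are converted on read and back on write, and GFF3's 1-based
inclusive intervals are normalized on read. This keeps window arithmetic,
interval merging and gene intersection on a single convention.

Site-level QC on VCF read keeps biallelic SNPs (single-nucleotide REF and
ALT) with FILTER PASS/'.' and per-site genotype missingness ≤ 20 %;
multiallelic sites and indels are dropped, not split, because the
downstream statistics are defined on biallelic allele frequencies. Missing
genotypes reduce the per-site chromosome count rather than being imputed,
which keeps frequency estimates unbiased without imputation machinery.
Both thresholds are exposed (`SiteFilters`).

## Differentiation: the per-SNP fixation index

The scan uses the two-population estimator

    Fst = 1 − [p1(1−p1) + p2(1−p2)] / [(p1+p2)(1 − (p1+p2)/2)]

evaluated exactly as written, with p the sample alternate-allele frequency
in each group. Algebraically this is the Hudson-style form
(p1−p2)²/[(p1+p2)(2−p1−p2)] — a property the test suite exploits as an
independent oracle. Two consequences worth noting:

* It is **not** the Weir–Cockerham variance-components estimator: there is
  no finite-sample correction, so under panmixia its expectation is
  ≈ 1/(2·n̄) per SNP (≈ 0.025 for 10+10 diploids), not 0. The null-
  calibration validation accounts for this floor.
* The value is undefined when the pooled site is monomorphic
  (p1 = p2 ∈ {0, 1}); such sites are excluded from window means rather
  than scored 0.

Windowed Fst is the **unweighted arithmetic mean** over computable SNPs in
the window. A ratio-of-sums estimator is deliberately not used; the
windowed quantity here is defined as the average of per-SNP values.

Floating-point note: near fixation (p → 1) the printed form loses ~1e-11
to cancellation in the (1 − s/2) term relative to the closed form; values
are clipped to [0, 1] to absorb boundary roundoff.

## Diversity and the π ratio

Per window and group, nucleotide diversity is

    π = Σ_sites [ n/(n−1) · 2 p (1−p) ] / L

with n the non-missing chromosome count at the site (the n/(n−1) factor
is the unbiased expected-heterozygosity correction) and L the window span
in bp. Sites with n < 2 contribute 0 and are tallied. An alternative
denominator — the window's SNP count — is available
(`pi_denominator="snps"`) since windowed-π conventions differ between
tools; span is the default. The π ratio is oriented
selected/reference (group1/group2), configurable, and recorded in output
metadata; a zero reference-group π yields an undefined ratio and the
window is excluded from ratio thresholding.

## Windows

Windows tile each chromosome from coordinate 0 in `step_bp` increments
(defaults 10 kb span, 5 kb step); a SNP belongs to every window whose
half-open interval contains it, so with the default 2× overlap each SNP
informs two windows. Without contig lengths in the VCF header, the last
window per chromosome ends at the last SNP position rounded up to a window
boundary; this is stated in the output TSV header. Chromosomes without
SNPs produce no windows; empty windows between SNPs are emitted with
n_snps = 0 but are dropped from threshold ranking (their Fst is
undefined).

## Sweep calling

Two criteria, both strict inequalities, must hold simultaneously:
windowed Fst above the Fst cutoff, and π ratio below the low cutoff or
above the high cutoff. Cutoff modes:

* **quantile** (default): empirical quantiles over windows with both
  statistics defined — Fst at 0.95, ratio tails at 0.05/0.95 — using the
  linear-interpolation quantile definition. The top-5 % Fst criterion is
  the primary published convention for this kind of scan, which is why
  quantile is the default mode.
* **fixed**: pass-through values (conventional defaults Fst 0.17, ratio
  0.05/0.95). Fixed ratio cutoffs of 0.05/0.95 are much stricter than 5 %
  empirical tails when the ratio distribution is centred near 1; both
  modes are provided because published descriptions often conflate the
  two readings, and the concrete cutoffs actually applied are always
  echoed to the metadata.

Ties at a cutoff are excluded (strict ">" as conventionally printed). The
low tail (diversity lost in the selected group) is the classic signature
of positive selection in that group; the high tail is reported
symmetrically and a direction filter can restrict to either. Flagged
windows of the same chromosome and tail merge when overlapping or
separated by ≤ `merge_gap_bp` (default 0). A gene is reported for a region
on ≥ 1 bp overlap (half-open arithmetic, intervaltree-backed, verified
against a quadratic brute force).

## LD

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples — the composite (Rogers–Huff) measure, chosen
because the pipeline sees unphased genotypes; no EM haplotype estimation
is performed. Pairs are uncomputable when either site is monomorphic among
complete samples or fewer than two complete samples remain.

Decay curves bin all same-chromosome pairs within `max_dist_bp` (default
300 kb, 1 kb bins — axis scales for such figures are tool-specific, so the
binning here is the package's own and documented in the output). Pruning
implements the greedy sliding-window scheme (50 SNPs, step 5, r² > 0.2
defaults): within each window every retained pair is checked in order and
the downstream (larger-position) member of an offending pair is removed —
a deterministic tie-break; the lower-MAF victim rule used by PLINK is
available as an option. Windows never span chromosomes.

## Distances and trees

Individual-level distance is the allele-sharing p-distance
(mean |dosage_i − dosage_j|/2 over pairwise-complete sites), the natural
per-individual metric for a SNP panel; the whole-genome identity score is
defined as its complement IS = 1 − p-distance (unit diagonal). This IS
definition is declared, not derived from any external formula. A
population-level Nei (1972) standard distance over group allele
frequencies is provided as an alternative metric for group-level trees.

Neighbor joining follows Saitou–Nei exactly: join the pair minimizing
Q(i,j) = (r−2)d(i,j) − S_i − S_j, closed-form branch lengths, matrix
reduction, central trifurcation at three nodes. Determinism and
input-order invariance come from processing taxa in sorted-label order and
keeping active nodes canonically ordered, so equal inputs give
byte-identical Newick (children serialized smallest-leaf-first, branch
lengths at 10 significant digits). Negative branch lengths — possible on
non-additive input — are clamped to 0 with the total deficit recorded on
the tree. On additive matrices the algorithm provably recovers the
generating topology and branch lengths; the tests verify this to 1e-9 and
additionally cross-check topologies against scikit-bio's independent NJ
implementation. Bootstrap support resamples sites with replacement,
rebuilds the tree per replicate, and reports the percentage of replicates
containing each internal bipartition; the replicate count and seed are
caller-controlled.

## Synthetic data

The generator emulates the inputs of a two-group sweep scan at desk scale:

* **Background.** Per site, an ancestral frequency from a symmetric
  Beta(0.8, 0.8) spectrum (clipped to [0.01, 0.99]), then each group's
  frequency from the Balding–Nichols distribution with drift parameter
  F_bg (default 0.05, a realistic between-breed divergence; F_bg = 0
  makes the groups share frequencies exactly). Diploid genotypes are
  binomial draws; missingness is i.i.d. at 2 % by default.
* **Sweeps.** Inside a sweep interval the selected group's frequency is
  moved to a root of q′(1−q′) = δ·q(1−q), where δ is the configured
  diversity-reduction factor (default 0.1), toward either the
  frequency boundary near the reference group's allele or the far one.
  The far/near mixing probability is calibrated once per sweep, by
  quadrature over the background Beta spectrum, so the expected per-SNP
  Fst in the interval matches the configured target (default 0.5).
  Targets beyond what full far-pushing can deliver (e.g. Fst = 1 with
  δ > 0) raise before generation.
* **Defaults** define the reference study conditions used throughout
  validation: 10 diploids per group, one 5 Mb chromosome, one SNP per
  500 bp, one 100 kb sweep. These sizes keep a full 20-replicate
  recovery study in the order of seconds while giving each window ~20
  SNPs, enough for stable window statistics.
* Genes are tiled uniformly (20 kb genes every 50 kb) so some overlap any
  planted sweep. One seed governs all draws; identical configs produce
  byte-identical VCFs. Truth files record each interval with its realized
  frequency-level Fst and π ratio.

**What this does not emulate:** linkage structure (main-generator sites
are independent — a separate two-ancestor copying panel with
distance-decaying LD exists only for exercising decay curves), demographic
history (bottlenecks, migration, growth), genotyping error beyond
missingness, and multiallelic/indel variation. Passing recovery tests
therefore shows the scan's statistics and thresholds behave correctly on
frequency-shifted data of realistic size, not that the pipeline's power on
real resequencing data matches any particular study.

## Recovery scoring

Called regions vs truth: bp precision = overlap/called bp, bp recall =
overlap/truth bp; an interval counts as recovered when its best
single-region Jaccard index reaches 0.3 (configurable). With no calls,
precision is undefined (NaN) rather than 1.

## Pipeline conventions

Every run writes a metadata JSON with the full configuration, a 16-hex
SHA-256 config hash (also stamped as a `#` header into each TSV/BED), the
concrete cutoffs applied, and exclusion tallies. Reruns with identical
inputs and config reproduce outputs byte-for-byte. Floats in TSVs are
written at 6 significant digits with `NA` for undefined values; the
window-stats reader/writer round-trips exactly at that precision.

## Known limitations

* The per-SNP estimator's sampling floor (no finite-sample correction)
  means genome-wide mean Fst is biased upward at small sample sizes; the
  quantile thresholds are rank-based and unaffected, but fixed-value
  cutoffs should account for it.
* Windowed mean-of-SNP-Fst weights every SNP equally regardless of
  informativeness; low-frequency SNPs add noise to window means.
* The LD decay implementation scores all pairs exactly (no subsampling);
  for very dense panels over long ranges it is the slowest stage.
* NJ is O(n³) over samples — fine for resequencing panels (tens of
  samples), not for thousands.
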