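# Methods

This note documents the models, rules and numerical choices behind
`mirmarker`, in the order data flows through the pipeline.

## Read quantification

Reads are processed as: 3' adapter trim → length filter → collapse → map →
normalize.

* **Adapter trimming** is exact-match: the read is cut before the leftmost
  position where a prefix of the adapter of at least `min_overlap`
  (default 6) bases matches, including adapter prefixes running off the
  read's 3' end. No error tolerance — deterministic and sufficient for
  libraries whose adapters are ligated verbatim, which is what the
  synthetic generator produces. Quality-based trimming is out of scope.
* **Length filter**: sequences shorter than 16 nt are discarded (mature
  miRNAs are 21–25 nt; shorter fragments are mostly degradation and
  adapter dimers).
* **Mapping** assigns each unique sequence to the mature-miRNA reference
  entries at minimal Hamming distance over every same-length window of
  every reference sequence, up to `max_mismatch = 2`. `N` never matches
  anything, including another `N`. When k references tie at the minimal
  distance the read's multiplicity is split 1/k each — the only choice
  that conserves read mass and is order-independent. The reference is a
  mature-miRNA FASTA rather than a genome: genome-scale alignment is a
  non-goal, and within one run all downstream ratios are invariant to the
  choice of denominator universe.
* **Normalization**: RPM = count / total_mapped x 1e6. `CountTable`
  accepts an explicit `total_mapped` per sample for tables that hold only
  a subset of what mapped (see the simulator below); by default it uses
  column sums, in which case per-sample RPM sums to 1e6 exactly.
* **Spike-ins**: an optional second reference catches reads that fail the
  main one; spike hits are tallied separately and excluded from
  `total_mapped`.

## Differential calls

Three rules, deliberately threshold-based (no dispersion estimation, no
shrinkage — the procedures being validated are thresholds by
construction):

* **DS vote rule.** Ratios `r_s = R^BC_s / R^N` per tumor sample against
  one pooled normal. Tiers (2, 1/2), (3, 1/3), (4, 1/4) — the lower cut is
  exactly the reciprocal of the upper. `r_s = ∞` (pooled normal zero,
  tumor non-zero) votes up at every tier: a marker absent from normal
  tissue but expressed in tumors is directional evidence, not missing
  data. Samples with 0/0 are excluded from voting; a miRNA with every
  sample excluded is *not assessed*. MIXED (non-zero vote tie) is kept
  distinct from NEUTRAL (no votes); concordance treats both as
  non-directional.
* **SSH rule.** The gate "total normalized reads ≥ 10" is read as the sum
  across the two subtracted libraries (the weaker reading; a per-library
  mode is available via `total_mode="each"`). Fold boundaries are
  inclusive: ratio exactly 1.5 (or 1/1.5) is a call.
* **MA rule.** The published criterion names only "p < 0.01"; the test is
  not specified. We use Welch's two-sided t on log2 intensities — the
  minimal standard choice for unequal-variance two-group comparison —
  isolated behind `location_test()` so it can be swapped. Degenerate
  zero-variance groups return p = 1 when means are equal, p = 0 otherwise.
  No multiple-testing correction is applied, matching the per-gene
  threshold practice being emulated; the joint fold+p criterion is
  empirically far stricter than the test alone (≈0.4% null call rate at
  our default noise, vs the nominal 1%).

## Marker scoring

`Sn` counts tumor samples crossing the tier cut in the marker's published
direction, over non-excluded samples. `Sp` requires per-normal ratios; in
a pooled-normal design none exist natively, so each individual normal is
ratioed against the mean of the *other* normals (leave-one-out). This Sp
is a reconstruction — the validation literature reports (Sp+Sn)/2 values
without defining Sp for pooled designs — and is therefore optional: with
only a pooled normal, evaluations carry Sn alone and AUC is undefined.
`AUC = (Sp+Sn)/2` with *valuable* meaning strictly greater than 0.7.
CONTRADICTORY markers are scored twice, once per direction.

## Concordance and congruence

A single directional-match predicate serves both published-vs-observed and
method-vs-method comparisons: UP/DOWN calls match an equal published
direction, CONTRADICTORY published matches either, NEUTRAL/MIXED are
non-directional. Per-method concordance uses all assessed markers in the
denominator (non-directional calls count as non-agreeing).

Congruence cells partition the markers assessed by ≥ 2 methods. With three
or more methods, two disjoint agreeing groups can coexist (e.g. DS+SSH say
UP while MA+PUBLISHED say DOWN), so a partition needs a rule: each marker
goes to its *largest* directional agreement group, ties broken in favour
of the group containing PUBLISHED, then the UP group; a CONTRADICTORY
published status joins the winning group; groups smaller than two fall
into the empty cell ("no two methods agree"). qRT-PCR enters as just
another method's calls — no dedicated machinery.

## Synthetic data

The generator emulates the study design the pipeline targets: 9 tumor
libraries vs one pooled normal of 6 members, microarray groups of 8 vs 4,
one SSH library pair.

* **Counts**: negative binomial via gamma-Poisson, var = μ + αμ², with
  dispersion α = 0.05 (between-sample biological variability of ~22% CV);
  α = 0 degenerates to Poisson. The pooled normal is the sum of member
  draws at depth/6 each — the in-silico equivalent of pooling RNA and
  sequencing once, which averages member biology (effective dispersion
  α/6) without increasing depth.
* **Denominator**: `total_mapped` is set to the nominal depth, not the
  column sum. The simulated markers are a minority of everything mapping
  to a genome, so the normalization denominator is dominated by
  unmodelled RNA and does not move with the planted fold changes;
  expected RPM ratios therefore equal the true fold. Normalizing to the
  in-table sum would compress every ratio by the compositional factor
  Σaf/Σa.
* **Abundances**: log-uniform between 2,000 and 16,000 RPM (expected
  counts 200–1,600 at the default depth of 1e5). This models the markers
  a deep-sequencing assay actually assesses — the well-detected ones; in
  the motivating setting nearly two-thirds of catalogued markers were
  simply absent from the sequencing data. Markers below robust detection
  are modelled as absent (not assessed), not as low-count noise.
* **Fold changes**: defaults 4.0 up / 0.25 down for 20% + 20% of miRNAs.
* **Arrays**: log-normal intensities, tumor means shifted by log2(fold),
  default log2 SD 0.5.
* **SSH**: per-miRNA Bernoulli capture (default probability 0.4, matching
  the ~40% of markers the assay could assess); uncaptured miRNAs yield
  0/0 pairs. This models the dropout of poly(A)-primed libraries, not any
  systematic direction bias.
* **Reads**: each count becomes the mature sequence with independent
  per-base substitutions plus the full adapter. At 1% error and 22 nt,
  P(> 2 errors) ≈ 1.3e-3, so quantification recovers ≥ 99% of reads.

**What passing on synthetic data does and does not show.** The generators
share their truth with the catalogue, so concordance on simulated runs is
high across *all* methods — the pipeline machinery is validated, but the
empirical finding that array and SSH platforms disagree with literature on
real tissue is a property of real data (probe chemistry, poly(A) bias
direction, cohort composition) that this simulation does not attempt to
reproduce. Likewise isomiRs, ligation bias and novel miRNAs are not
modelled.

**A calibration fact worth knowing.** The DS vote rule is decided by a
single stray vote (1 up / 0 down ⇒ UP). Under NB dispersion 0.05 the
per-sample probability that a truly unchanged miRNA crosses a 2-fold cut
has a floor of roughly 0.004–0.007 even at high counts (the gamma left
tail), so with 9 samples about 4–6% of neutral miRNAs acquire a direction
regardless of depth. The ~5% false-direction rate seen in
`examples/05_simulate_and_recover.py` is this floor, not a defect; it is
also why the vote rule benefits from the stricter tiers.

## Problem sizes and determinism

Tests and examples run at desk scale: 1e4–1e5 reads per library for
read-level paths (chosen so the exhaustive window mapper stays in seconds),
1e5 for count-level simulations, 500 probes for null calibrations. All
generators are bit-reproducible under a fixed numpy seed; the pipeline
itself is deterministic given its inputs, and two `run-all` invocations
with the same config produce byte-identical files (no timestamps in any
output; JSON keys sorted; fixed float formats).

## Bundled catalogue

`mirmarker/data/bladder_marker_catalogue.tsv` reproduces the schema of the
public bladder-cancer miRNA marker database (102 rows: 95 expression, 7
methylation markers). The ~45 names recoverable from the literature
summary carry their reported directions and citations; the remainder are
synthetic fillers, labelled as such in the `note` column. Name
canonicalization lower-cases, strips the species prefix and internal
separators, but keeps -5p/-3p arm suffixes: the literature mixes
conventions (miR199A2, Let7c), and merging distinct mature arms would be
a real error while case/punctuation variation is not.
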