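# Methods

## Model and assumptions

The screen treats promoter CpG-island hypermethylation as a silencing
mechanism detectable by the coincidence of three signals in the same cell
line: elevated percent methylation relative to a non-malignant reference,
reduced constitutive mRNA expression relative to that reference, and
re-expression once DNA methyltransferase is inhibited. No causal model is
fitted; the method is a deterministic filter cascade over per-gene,
per-sample values linked by official gene symbol (uppercased exact match;
symbols present in some matrices but not all are reported, never silently
dropped).

Assumptions worth making explicit:

- methylation and expression are comparable across platforms only through
  the shared reference column (melanocyte pool), which is why both the
  delta and the expression ratio are reference-relative;
- a single methylation value per gene is meaningful — multi-probe genes are
  collapsed (mean by default, max for an "any probe methylated" reading)
  before the cascade;
- ubiquitous reactivation after drug treatment reflects stress response or
  lineage-wide silencing, not tumour-specific events, and is removed;
- EpiTYPER units are atomic: the assay cannot resolve individual CpGs
  within a cleavage fragment, so no deconvolution is attempted.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| beta denominator offset | 0 | intensity | stabilising constant; 0 reproduces the plain ratio, platform pipelines often use a positive value |
| expression floor | 0.1 | linear expression | avoids log of values at the detection floor |
| delta threshold `meth_min` | 60 | percentage points | hypermethylation call, inclusive (60.0 passes) |
| down-regulation `downreg_fold` | 4 | fold | ratio ≤ 1/4, inclusive (exactly 4-fold counts) |
| joint samples `min_samples` | 2 | count | both signals must co-occur in this many lines |
| re-expression per line | 2 | fold | strict >; exactly 2.0 does not count |
| mean re-expression `reexpr_mean_min` | 4 | fold | strict >; arithmetic mean of fold ratios (geometric available) |
| false-positive rule | Δ ≥ 60 in ≥ 2 lines with FC ≤ 2 there | — | quantifies "methylated on the chip but no re-expression"; the source gives examples, not numbers, so all three constants are exposed |
| unit QC `max_error` | 10 | percent | strict <: error 10.0 is dropped; overlap-flagged units always dropped |
| amplicon informativeness | panel > 20, reference < 10 | percent | both strict |
| site selection `site_min` | 20 | percent | inclusive ≥; reuses the informativeness level because no separate number is stated for "high methylation ratios" |
| methylation groups | [0,20], (20,50], (50,100] | percent | half-open boundaries make the printed labels disjoint; only the 50 boundary (">50%") is externally forced |
| correlation formula | standard | — | p-values default to t = r·√((n−2)/(1−r²)) with n−2 df; the published variant t = r/((1−r²)/n) is always reported alongside because it differs from the textbook standard error (likely a typo) and would overstate significance |

Strictness conventions follow the wording each rule was published with:
"≥ 60%" is inclusive, "> 2-fold"/"> 4" are strict, "estimated error smaller
than 10%" makes the QC cut strict-below.

## Synthetic data: what it emulates and what it does not

`SyntheticConfig` defaults describe the study conditions: 11 tumour lines
plus one reference pool, 500 genes of which 20 are planted as silenced,
planted methylation centred at 80% against a 5% background (sd 5), 8-fold
expression suppression, 10-fold mean re-expression, penetrance 0.5 (each
planted gene methylated in ⌈0.5·11⌉ = 6 lines), two amplicons of five CpG
units per gene, and 10% of units spoiled for QC. Methylation noise is
normal on the percent scale clamped to [0,100] (a beta-distribution noise
model would avoid the clamp but is indistinguishable to threshold-based
filters); expression and fold-change noise are log-normal with sd 0.4 on
log2. The reference expression column is the unsuppressed per-gene mean.
The ground truth is a separate manifest no pipeline stage reads.

What the generator does **not** emulate: probe-level intensity noise and
background correction, cross-hybridisation, probe–gene annotation errors,
stromal contamination of tumours (which dilutes observed methylation),
partial or heterogeneous methylation within an amplicon, and correlated
noise between platforms. Passing tests therefore demonstrate that the
cascade recovers a planted, well-separated signature under clean
conditions — they bound implementation correctness, not the screen's
sensitivity on real arrays.

With these defaults the planted/background separation is large relative to
the noise (Δ ≈ 75 vs threshold 60, ratio ≈ 0.125 vs 0.25, mean FC ≈ 6 vs
4), so recovery of ≥ 19/20 planted genes with zero background candidates is
the expected behaviour, not a tuned outcome; background genes sit ~10
standard deviations below the delta threshold.

## Numerical choices and degenerate inputs

- Zero beta denominator → missing, not 0 and not an error: "no signal"
  propagates explicitly.
- Median centering order is sample-then-gene, as stated for the original
  normalisation. Note the two passes do not commute in general, and the
  second pass can shift sample medians slightly off zero; the guarantee of
  zero sample medians holds after the sample pass. The composite is
  invariant to per-sample additive offsets.
- Missing fold changes: a line with missing FC can never count as
  reactivated, so a gene with a missing line is conservatively retained by
  the ubiquitous-removal filter; the panel mean uses available lines only.
- Correlation: pairwise-complete pairs; fewer than 3 pairs or a constant
  vector → untested (missing r) rather than an arbitrary value; |r| = 1 →
  p = 0 with an exact-monotone flag since the t statistic diverges.
- Cascade ties: output ordering is (qualifying samples desc, mean FC desc,
  symbol asc), making reports deterministic.
- EpiTYPER: an amplicon with no unit surviving QC is "uninformative: no
  data"; a gene whose amplicons are all uninformative gets no call (the
  real screen discarded such genes as showing no differential
  methylation); a panel sample with no surviving unit is missing for that
  sample only. Percent inputs outside [0,100] raise a data error.

## Design choices where the design was open

- The 26→12 exclusion bookkeeping is published with two mutually
  inconsistent lists (different "orf"-style symbols and retained genes
  between the results narrative and the methods narrative), so no
  exclusion list is hard-coded beyond the uncontested oncogene and
  previously-identified sets; "unannotated" is an explicit user list plus
  an optional regex for orf/FLJ/CCDC/LOC/KIAA-style names.
- The downstream bench-validation step (qRT-PCR confirmation and CpG-island
  presence, 12→10 genes) depends on wet-lab data not modelled here; it is
  representable only as a user-supplied keep-list filter.
- Whether "CpG sites" in the final site selection means units or individual
  CpGs is ambiguous at the source; sites are counted as CpGs (sum of
  `n_cpgs` over retained units) while selection operates on units, and the
  per-unit threshold is configurable.
- The 4-fold down-regulation is evaluated on linear ratios (the log2
  centered view is produced for inspection but not used in the filter);
  with ratio ≤ 1/4 ⇔ log2 ratio ≤ −2 the two are equivalent at the default
  threshold.
- Null calibration of the correlation test uses 1000 replicates of 11
  paired samples (the methylation panel size); at n = 11 the t
  approximation to the Spearman null is discrete but the KS distance to
  uniform stays well under the 0.08 criterion.

## Problem sizes

The default test and acceptance conditions are 500 genes × 11 lines (+
reference), 20 planted genes, 2 amplicons × 5 units per gene (~66,000 unit
records), and 1000 null replicates — the full suite runs in well under a
minute on one core, which is the package's intended desk scale. Larger
panels only change runtimes linearly in genes × samples.

## Known limitations

- Symbol-based linking inherits annotation-era drift between platforms;
  unmatched symbols are reported but not rescued by aliases.
- The cascade is a hard-threshold method: genes sitting at a boundary
  (e.g. Δ = 59.9) are invisible to it by design, and no significance is
  attached to candidate membership.
- The published headline counts of the original screen (8,144 re-expressed
  genes, 3,125 after ubiquitous removal, 26 integrated candidates) require
  the deposited multi-accession array data; the `fetch` helper can retrieve
  the series matrices, but the package does not bundle or reproduce those
  counts offline. The re-expression bookkeeping is reported as three counts
  so any discrepancy on real data is visible rather than resolved.
- The as-printed significance formula is reported but deliberately not used
  for p-values; users comparing against the original p<0.005 claims should
  note the formulas differ.
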