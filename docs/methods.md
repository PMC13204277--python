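# Methods

## Problem setting

Small, deeply phenotyped cohorts (here: ten adults with
pharmacoresistant genetic generalized epilepsy, whole-genome sequenced)
cannot support association statistics. The pipeline instead implements a
descriptive screen: variants carried by most of the cohort *and*
predicted damaging are advanced, their allele frequencies are contrasted
with external reference cohorts, and the implicated genes are checked
against a clinical panel. Everything downstream of variant calling and
annotation is in scope; alignment, calling, and the annotation tools
themselves (ANNOVAR/snpEff-style) are not — annotations are consumed as
input columns.

## Variant identity and I/O

A variant is `(chrom, pos, ref, alt)` with exactly one alt allele;
multi-allelic VCF records are split before keying, preserving the
record's full AD vector and the alt's allele index so allele balance and
genotype carriage stay computable per split allele. No left-alignment or
normalization is applied: per-sample output of a single caller is
internally consistent, and exact string equality is the join rule
against the annotation table (whose coordinates are therefore expected
in VCF convention). Chromosome names are compared verbatim; natural
chromosome order (1–22, X, Y, MT) is used only for sorting output.
Symbolic alts (`<NON_REF>`, `<DEL>`, …) and spanning deletions (`*`)
carry no testable allele identity and are skipped but counted.

## QC filtering

A call is removed when site QUAL < 100, DP < 20, or the best-supported
alternate allele's depth fraction is < 1/6 — all strict inequalities, so
boundary values survive. "Quality score" is the site-level QUAL (not
GQ), and the fraction's denominator is the site DP by default
(`sum_ad` available for callers whose DP drifts from the AD sum). A call
with missing AD skips the fraction criterion rather than being dropped;
the event is counted. Failure reasons are accumulated, not
short-circuited, so QC summaries report every criterion a call failed.
Filtering is per sample: a variant can survive in some samples only.

## Sharing and recurrence

Presence means the called genotype carries the keyed alt allele (het or
hom); `presence="record"` counts any surviving call, and a missing
genotype (`./.`) counts as absent. The sharing spectrum reports exact
and cumulative counts of variants by carrier number. The default
recurrence cutoff is ⌈0.8·n⌉ samples. The Wilson score interval
(two-sided, normal quantile z = Φ⁻¹(0.975) ≈ 1.959964, no continuity
correction) justifies the cutoff: its lower bound for 8/10 is 0.4902,
so a variant that recurrent plausibly has population prevalence above
49%. At zero successes the closed form returns exactly 0.

## Deleteriousness

Nine predictors vote (SIFT, PolyPhen2 HDIV/HVAR, LRT, MutationTaster,
MutationAssessor, FATHMM, and the two ensembles MetaSVM-radial and
MetaLR). The default rubric follows dbNSFP code conventions: D
everywhere, plus P (possibly damaging) for PolyPhen2, A for
MutationTaster, H/M for MutationAssessor. The rubric is fully
configurable because the upstream database release's code dialect is an
assumption, not a fact we can verify from annotation output alone.
Missing codes never vote and never rescale — votes are absolute counts
out of nine. Unknown codes count as benign with a warning.

The prioritization rule has two arms joined by OR: HIGH impact
(loss-of-function), or nonsynonymous SNV with at least one ensemble
classifier deleterious. The "at least one" (OR) reading of the ensemble
pair is the default since either classifier flagging a missense variant
suffices for a screen of this kind; `ensemble_mode="and"` gives the
stricter conjunction. The ensemble arm deliberately applies only to
missense SNVs — ensemble deleterious codes on any other class never
fire it.

## Frequency comparison

Observed successes default to alt *allele* counts over 2n chromosomes
(trials = 20 for n = 10); carrier counts over n individuals are a
configuration switch, since reference tables report allele frequencies
but either convention is defensible at this scale. Two-sided p-values
use the exact binomial minimum-likelihood convention (sum of all
outcome probabilities not exceeding that of the observed outcome),
delegated to `scipy.stats.binomtest` and verified against exhaustive
enumeration for all n ≤ 12 in the tests. Degenerate reference
frequencies (exactly 0 or 1) are handled outside scipy: the forced
outcome gives p = 1, anything else is a probability-zero event reported
as the smallest positive double with a warning, never dropped silently.
Variants with no reported frequency in any reference are excluded from
testing and listed separately.

BH adjustment (statsmodels step-up, hand-verified) is applied within
each reference cohort's family separately, so a reference covering few
variants is not penalized by another covering many. Note BH is *not*
idempotent on arbitrary adjusted lists; its fixed points are flat
(constant) adjusted vectors, which is what the tests assert alongside
the adj ≥ raw and permutation-equivariance properties. Ancestry
composition uses the same machinery with individuals as trials.

## Reporting

Prioritized = recurrent ∩ deleterious, computed as set intersection
with deterministic (natural-order) output. Multi-gene annotation
strings are split on ';' and each symbol counted once. Panel overlap is
a case-insensitive, whitespace-trimmed exact-symbol intersection — no
alias or HGNC resolution, because none is defensible without a
versioned alias source. Recurrent-but-unannotated variants are counted
in diagnostics; they can never be advanced since deleteriousness
requires annotation evidence.

The demographic summary recomputes statistics from the shipped
ten-patient table: mean onset 13.7 y (range 4–31), median 3 past and 3
current antiseizure-drug regimens, 7 female, tonic–clonic + absence
semiology in 50%. The table's age column has arithmetic mean 34.2 y;
summaries always report the computed value from the table rather than
any externally quoted figure.

## Synthetic cohorts

The generator emits the exact dialects the pipeline reads (VCF 4.2,
multianno-style annotation TSV, per-cohort reference AF TSVs, panel
TXT, ancestry TSV, patient TSV, JSON manifest), deterministically from
a single integer seed (one `numpy` Generator stream; byte-identical
bundles per seed; two synthetic chromosomes with collision-free
positions keep keys unique).

Defaults encode the study conditions the pipeline assumes:

* **n = 10 samples**, 2000 background variants at the default scale
  (large enough for a stable spectrum, small enough for sub-second
  bundles).
* **Sharing distribution** over k = 1..10 anchored at 37.2% singletons,
  13.7% doubletons, ~1% at k = 9 and 3.6% fully shared, with the
  cumulative share at k ≥ 8 near 5%, interpolated smoothly in between.
* **Functional-class mix** dominated by intergenic (54.7%) and intronic
  (34.9%) sites with a ~0.6% exonic sliver; **vote mix** with 78.1% of
  exonic SNVs drawing zero deleterious votes and a long thin tail to
  nine.
* **Genotypes**: carriers are het with probability 0.8, hom-alt 0.2;
  AD is drawn binomially around the genotype's expected allele balance,
  which exercises the allele-balance filter realistically.
* **QC failure fractions** (default 3% per criterion) are planted as
  mutually exclusive call fates, each constructed to fail exactly its
  criterion, so empirical failure rates estimate the configured ones.
* **Planted variants** (default 7: four loss-of-function, three
  ensemble-missense, carrier counts 8–10, three with cohort frequency
  far above their reference AF) define the ground truth.

Closure is structural, not statistical: planted carrier calls always
pass QC, background variants generated in ≥ 8 samples are never given a
deleterious annotation (no HIGH impact; ensemble codes pinned benign;
the rare recurrent "splicing" draw is re-classed intronic), and QC can
only lower carrier counts — so the prioritized set equals the planted
set exactly, at every seed. Background reference AFs are set to the
frequency implied by the variant's carrier count (k·1.2/2n under the
het/hom mix), making background variants approximately null in the
frequency comparison; ~5% of background variants get no reference AF to
exercise the exclusion path.

What the generator does **not** emulate: linkage disequilibrium,
mutation-rate heterogeneity, caller-specific artifacts, multi-allelic
sites (exercised instead by hand-written fixtures in the tests), indel
re-coordination between VCF and annotation conventions, and any
relatedness structure. Passing tests therefore demonstrate the
correctness of the pipeline's logic under its stated assumptions, not
robustness to every pathology of real callsets.

## Problem sizes in the test suite

Unit tests run on fixtures of tens to hundreds of records. The
distribution-recovery properties use 5000–6000 background variants with
QC failures disabled (spectrum χ² goodness of fit at α = 0.01; failure
fractions recovered within ±2 percentage points). Ground-truth closure
runs the full pipeline on 20 independent seeds at 250 background
variants each. Exact-binomial enumeration checks are exhaustive for all
n ≤ 12; the null-calibration check simulates 2000 variants at their
reference frequencies and verifies the raw test's rejection rate stays
at or below the nominal α = 0.05 (exact-test conservatism).

## Known limitations

* Exact-key joining means annotation produced under different indel
  normalization than the VCFs will silently fail to join; such variants
  remain in sharing but can never be prioritized (they surface in the
  unannotated-recurrent diagnostic count).
* The rubric defaults assume current dbNSFP code letters; older
  releases with numeric codes need a custom rubric.
* Panel overlap is string-identity only; gene symbol drift across
  nomenclature versions will cause false negatives.
* With n = 10, the frequency comparisons are descriptive: the exact
  test is conservative and BH is applied per reference, but sampling
  variance at 20 chromosomes dominates, and results should be read as
  flags, not effect estimates.
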