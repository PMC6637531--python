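# Methods

This note documents the models and procedures implemented in `novex`,
the assumptions behind them, the tunable parameters and their defaults,
what the synthetic-data generator does and does not emulate, and the
numerical choices that were genuinely open.

## Event calling from splice junctions

Exonization — the recruitment of intronic (frequently transposon-derived)
sequence as a new internal exon — leaves a characteristic signature in
junction-level RNA-seq data: two unannotated exon-exon junctions that
subdivide one annotated intron, each anchored on one side to a known exon
boundary. `novex` works entirely at this junction level; it does not
re-align reads or build splice graphs, and junction tables (chrom, intron
start, intron end, strand, unique count, multimapped count; STAR
`SJ.out.tab` dialect, 1-based inclusive) are the input contract.

Internally all coordinates are 0-based half-open on the forward genome
strand; GTF converts at the boundary and BED passes through natively. A
junction is identified by its intron interval (first intronic base, one
past the last intronic base). Junction records shorter than 30 nt are
rejected as likely indel artifacts; unstranded input rows inherit the
strand of the host gene. Only uniquely mapped junction reads are counted
as event support.

A candidate's six acceptance criteria are re-validated independently of
how the candidate was enumerated, so hand-constructed candidates receive
complete verdicts too. The support threshold (criterion 1) is applied to
the *summed* inclusion reads of the two flanking junctions, with both
junctions required to be observed at least once — a deliberate
junction-level reading of "supported by at least 5 reads" for a method
that does not model read reassignment across a splice graph. "Absent in
controls" (criterion 3) means zero reads at either flanking junction in
every control sample — conservative by design: a single control read
disqualifies novelty, which is stricter than re-running the caller on the
controls. PSI uses the standard cassette-exon junction estimator
`m/(m+e)` with `m` the mean of the two inclusion junction counts; it is
undefined (not zero) when `m + e = 0`.

Repeat overlap requires ≥ 20% of the novel exon's length to be covered by
a repeat copy; among qualifying repeats the largest overlap wins, with
alphabetical family-name tie-break (the tie-break is a declared choice —
any deterministic rule would do). Families whose name contains "Alu" are
grouped into class `Alu`; other families stand as their own class.

Detection saturation is measured by binomial thinning: each junction
count is resampled as Binomial(n, p) at fraction p (seeded per fraction),
the full caller is re-run, and the percentage of full-depth reference
events (Alu-class by default) recovered is reported. At p = 1 the
subsample is the identity, so recovery is exactly 100%.

## Intron features and the logistic model

The feature extractor produces one row per intron: host introns of
accepted events are labeled `exonized`; all other introns of expressed
genes (TPM > 1) form the background. Features, with units:

- `intron_length` (nt), `gc` (fraction), `tss_distance` (nt, strand-aware
  distance from the intron's 5′ end to the gene's TSS),
  `relative_gene_position` (intron midpoint along the gene span, 0 at the
  TSS side).
- `ss5_score`, `ss3_score` (log2-odds bits): position-weight-matrix
  scores. The PWMs are trained on the annotation's own junctions — the
  5′ss window is 3 exonic + 6 intronic nt, the 3′ss window 20 intronic +
  3 exonic nt — as log2 odds against a uniform background with +1
  pseudocounts. This PWM scorer deliberately replaces external
  maximum-entropy/SVM splice-site tools: the features feed a *relative*
  comparison between intron classes, for which a locally trained PWM is
  an adequate and fully self-contained scorer. The substitution is named
  per-column in the feature metadata sidecar.
- `ss_dist` (nt): the span between the best-scoring internal (cryptic)
  acceptor/donor pair inside the intron. This quantity is defined
  uniformly for both classes and, for host introns of real events,
  recovers the novel exon's length; it is flagged as an interpretation in
  the metadata sidecar because "splice-site distance" admits several
  readings.
- Branch-region statistics over the 20–500 nt window upstream of the
  3′ss (for exonized introns, upstream of the *novel exon's* acceptor;
  for background introns, upstream of the intron's own 3′ss): `bp_num`
  counts strict matches to the branchpoint consensus yUnAy (branch
  adenosine fourth); `bp_scr` is (consensus-matching positions)/5 times a
  positional weight `1 − |dist − 25|/475` clamped to [0, 1], maximized
  over candidates — a declared heuristic standing in for SVM-based
  branchpoint scoring; `ppt_len`/`ppt_scr` describe the longest
  ≥ 80%-pyrimidine stretch between the best branchpoint and the 3′ss;
  `agez_len` is the AG-free gap upstream of the 3′ss AG. Regions shorter
  than 23 nt are flagged undefined.
- `transposon_overlap` (0/1; optionally expanded to per-class Alu/L1/Other
  indicators), and, when tracks are supplied, `nucleosome_occ` (mean
  bedGraph value over the novel exon ± 100 nt, or a 320-nt intron-center
  window for background introns) and `tad_boundary_dist` (nt to the
  nearest boundary midpoint). Missing tracks drop the feature model-wide
  and are recorded in the metadata.

The classifier is a binomial GLM with intercept. Continuous features are
z-scored (making coefficients scale-invariant); binary indicators are
left unscaled so their coefficients stay on the log-odds-per-indicator
scale. Significance is the GLM coefficient z-statistic's two-sided
p-value. Model quality is ROC AUC on a held-out stratified 10% split
(seeded); stratification protects the small test split from losing a
class. Perfect separation — expected on clean synthetic tables — falls
back to a ridge-stabilized fit with a warning flag and NaN p-values
rather than failing.

## Splicing-efficiency dynamics

For pulse-chase data at t ∈ {0, 15, 30, 60} min, the splicing index at a
splice junction is split/(split + non-split). θ per intron is the
unweighted mean of the 5′ and 3′ junction indices (the combiner is a
declared choice; the two indices estimate the same quantity from the two
ends of the intron) and requires ≥ 5 reads of coverage at both junctions
at that time point. The summary statistic

SED = 1/((1.001 − θ₀)·(1.001 − θ₆₀))

is computed exactly as written; the 0.001 offset bounds it in
[1/1.001², 10⁶]. Speed classes come from k-means (k = 5, 10 restarts,
seeded) on the four-dimensional θ trajectory — not on the SED scalar, so
the grouping reflects kinetic shape — with clusters ordered by mean SED
descending and labeled *very fast* through *very slow*. Group comparisons
(exonized host introns vs expressed background) use the two-sided
Wilcoxon rank-sum on SED.

## EM assignment of multimapped reads

Reads over repeat copies multimap (at most 10 candidate loci per read are
considered; reads above that are discarded upstream). Fractional
assignment uses an EM in which host-gene expression enters as a Dirichlet
prior on the per-locus read-generating weights θ:

- E-step: γ(r, l) ∝ θ_l over the read's candidate loci (uniquely mapped
  reads pinned at weight 1);
- M-step: θ_l = (α·p_l + Σ_r γ(r, l)) / (α + N), with p the
  TPM-normalized expression shares and α the prior strength in
  pseudo-reads (default 1).

This form was chosen over a pure data-likelihood EM because symmetric
multimapping data carry no information of their own about the split: a
maximum-likelihood EM on such data either stalls or collapses to a
winner-take-all corner, whereas the prior-anchored update has the natural
fixed points — a single ambiguous read converges exactly to the
expression shares, fully symmetric read sets converge to the prior, and
partially unique data pull the estimate toward the data term (α becomes
negligible as informative reads accumulate). Read mass is conserved at
every iteration, and with equal host TPMs the update reduces to
symmetric multiplicity-weighted assignment. Reads whose candidate hosts
all have zero TPM fall back to uniform weights and are flagged.

Coverage is reported per locus as fractional-overlap mass × 10⁶ /
(library size × locus length), i.e. reads-per-million per nucleotide.
Meta-profiles aggregate per-base coverage at positions relative to anchor
5′ ends (strand-flipped for − anchors; window ± 300 nt by default, one
repeat length) and are normalized so that the mean over the outermost 10%
of window positions (both tails combined) equals 1 — "relative coverage"
with flank mean 1. This flank normalization is a declared choice among
several plausible ones.

The peak-calling step of dedicated m6a pipelines (IP-vs-input
negative-binomial models) is intentionally out of scope: the statistics
here need coverage, and externally called peak BEDs are accepted as
optional input.

## Downstream statistics

Gene-set enrichment is the upper-tail hypergeometric test of query genes
against an expressed background (TPM > 1), with gene sets (GMT format)
restricted to the background before the term-size filter (5–2000 members,
inclusive) and Benjamini-Hochberg correction across retained terms.
Engagement shifts use Δ = (post − pre)/max(post, pre) per fraction
(defined as 0 when both are 0, and antisymmetric under pre/post swap);
shift = Δpoly − Δtotal, binned by novel-exon Δψ at edges
{≤0, (0,0.05], (0.05,0.15], (0.15,0.3], >0.3} (declared — the bin edges
are not fully determined by convention), with a rank-sum between the
extreme bins. Cohort deltas are per-case-sample percentage changes
against the control median (undefined and flagged when that median is 0),
with a rank-sum group comparison.

## The synthetic-data generator

The generator is first-class, tested code: it emits a complete toy study
whose ground truth exercises every stage.

What it emulates: multi-exon genes on both strands; designated host
introns that are long (1600 nt vs 400 nt) and GC-rich (0.60 vs 0.45),
carrying 300-nt Alu-like repeat copies (a fixed synthetic consensus with
a cryptic branchpoint/acceptor/donor embedded — *not* a Repbase
consensus) at ~5% per-copy divergence; planted novel cassette exons
(110 nt) inside those repeats with strong or degenerate splice sites;
annotated splice sites written from the same consensus words the PWM
should learn, with 15% per-position noise (GT/AG cores fixed);
control/perturbed junction tables at mean depth 20 where perturbed
samples carry inclusion counts `round(2·depth·ψ*)` split across the two
flanking junctions and exclusion `round(depth·(1−ψ*))`, and controls
carry none; pulse-chase counts following saturating kinetics
θ*(t) = θ₀ + θmax·(1 − e^(−t/τ)) for five classes (plant host introns
pinned to *very slow*, mirroring the association between exonization and
slow excision), with a few low-depth introns to exercise the coverage
rule; and multimapped 50-nt reads over homologous repeat copies with
true source loci drawn proportional to host TPM (default 30:10, i.e.
3:1) and 30% unique mappability — a conservative, realistic figure for
50-nt reads over copies at ~5% divergence, and enough informative reads
that the recovered split is a stable estimate.

Two count modes: `exact` (deterministic rounded counts; recovery has a
closed-form expectation) and `poisson` (counts drawn from the
corresponding Poisson/binomial laws). All outputs flow from a single
config seed and are byte-reproducible; sample-table sidecars store
relative paths so identical seeds give identical bundles anywhere.

What it does **not** emulate — and hence what passing tests do not show
about real data: read-level sequence errors and mappability structure,
fragment-length and positional coverage biases, transcript-support-level
heterogeneity and alternative transcript structures (one transcript per
gene), overlapping genes, expression-dependent junction depth, partial or
truncated repeat insertions, and real Alu sequence evolution. Recovery of
planted events at sensitivity 1/FDR 0 demonstrates the correctness of the
calling logic under its stated model, not calling performance on noisy
real libraries.

## Numerical choices and degenerate inputs

- PSI and splicing indices are undefined (None), not 0, without evidence.
- SED respects its theoretical bounds up to floating-point rounding at
  the extreme θ = 1 corner (~2×10⁻⁷ relative); checks use relative
  tolerance there.
- k-means on identical trajectories collapses clusters; the run completes
  and labels follow the mean-SED ordering of whatever clusters remain.
- EM convergence is max |Δθ| < 10⁻⁶ with a 100-iteration cap.
- Enrichment terms are size-filtered *after* background restriction;
  query genes outside the background are an error, not silently dropped.
- The pipeline validates its config up front (exit code 3 from the CLI),
  aborts with the failing stage's name (exit code 4) while retaining
  partial outputs, and stamps every summary with a hash of the resolved
  config. Summaries round floats to 6 digits for byte-stable reruns.

## Problem sizes

Default study conditions: 20 genes × 3 introns, 10 planted events
(ψ* cycling through {0.5, 0.3, 0.7, 0.15, 0.9}), 3 control + 3 perturbed
samples at depth 20, 60 time-course introns, 1000 multimapped reads over
2 loci. Recovery and saturation checks use a 50-plant variant of the same
20-gene genome; the logistic parameter-recovery simulation uses n = 5000
introns with a planted transposon log-odds of 2.0. These sizes were
chosen so every planted structure is recoverable with comfortable
statistical margins while the whole pipeline remains a desk-scale
computation.

## Known limitations

Only cassette-type novel exons are called (no intron retention,
alternative 5′/3′ sites, mutually exclusive exons, or multi-exon
insertions). Junction tables are the input contract — there is no
BAM-to-junction extraction. Splice-site and branchpoint scores are
self-trained substitutes, suitable for within-dataset comparisons rather
than absolute site-strength calibration. Transcript-support-level
filtering is not implemented (the toy annotation carries no TSL
attributes). The m6a module quantifies coverage but does not call peaks.
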