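# Methods

This note records the models, parameter choices and design decisions behind
`ctdnatrack`, and what the synthetic cohorts do and do not establish about
behavior on real sequencing data.

## Scope and data model

The package starts at per-sample somatic variant calls (VCF v4.2 with
per-sample allelic depths). Read alignment, deduplication and raw calling
are upstream and out of scope. VAF is always recomputed as
`alt / (alt + ref)` from the AD field — never taken from an AF tag — so that
every downstream computation shares one definition. Coordinates are 1-based
inclusive throughout; multi-allelic records are split into one call per ALT
with AD matched positionally, which keeps per-variant VAF well defined.
Records below a per-allele depth floor (default 100, far below the ~3000x
design depth) are dropped and counted. Copy-number information enters as a
per-variant logR INFO key (default `LOGR`); a missing logR means diploid.

## Germline and CHIP filtering

Four steps, in order, per patient; a removed variant keeps the label of the
first step that failed it, and per-sample accounting must satisfy
`input = removed + passing` (checked on every run):

1. **Common germline**: population allele frequency ≥ 0.1% (threshold
   inclusive) in the population table removes the variant. The threshold is
   on the *population* frequency; removing variants *rarer* than 0.1% would
   delete nearly all somatic calls and contradict the step's purpose.
2. **Matched normal**: more than 2 supporting reads in the patient's white
   blood cells removes the variant. This covers true germline alleles and
   clonal hematopoiesis alike; no separate CHIP classifier exists or is
   needed.
3. **Private germline**: a variant detected (alt reads > 0) at *every* time
   point with VAF strictly above 20% at every time point is removed from
   all of the patient's samples — a germline allele cannot be somatic at
   another draw. An undetected time point vetoes removal: absence anywhere
   is strong evidence against germline origin. The rule still applies to a
   single-draw series (with a logged caution).
4. **Review flag**: a maximum VAF change above 2% across the series flags
   the variant (the stand-in for a manual inspection step); nothing is
   removed.

Thresholds (0.001, 2 reads, 0.20, 0.02) are config-exposed. Step 3 is the
patient-combined alternative to capping each sample's MSAF at 20%: because
it pools all draws, a genuinely high-burden sample can keep its large VAFs
as long as the variant dips somewhere in the series. The trade-off is real:
a clonal mutation in a patient whose tumor fraction never leaves the >40%
prevalence band is indistinguishable from a private germline allele under
this rule and will be removed. The simulator's founder-prevalence default
(below) respects that regime.

## Burden metrics

**MSAF** is the maximum VAF among passing variants of a sample (0 for an
empty set), with all effect classes included — synonymous variants carry
the same tumor-fraction information. No per-sample cap is applied; the
patient-global 20% rule above already serves that role. **bTMB** is the
count of passing variants divided by panel megabases (default panel 637 kb,
so 21 variants ≡ 32.97/Mb). Synonymous variants are counted by default (a
`nonsynonymous_only` switch exists); the baseline draw's bTMB is the value
used for survival splits, since on-treatment burden reflects response
rather than the tumor's intrinsic mutation load. The per-patient mean MSAF
averages all draws unless a window is requested.

## Clonal deconvolution

Mutations are clustered across all of a patient's draws jointly under a
Dirichlet-process binomial mixture:

* emission: `alt_it ~ Binomial(depth_it, φ_kt · m_i / c_it)` with
  multiplicity m fixed at 1 (only total copy number is available) and
  c from logR discretization (`< −0.25 → 1`, `> 0.25 → 3`, boundaries and
  missing → 2);
* prior: Chinese restaurant process with concentration α = 1.0 (fixed, not
  hyper-sampled; config-exposed) and φ_kt ~ Uniform(0,1) independently per
  cluster and draw;
* φ is interpreted as prevalence within circulating tumor-derived DNA; no
  separate purity term is modeled;
* a variant undetected at a draw contributes alt = 0 with that sample's
  median depth as trials — it is never dropped;
* patients need at least 3 draws (config-exposed) for a stable estimate.

Inference is Gibbs sampling: assignments are resampled against each
occupied cluster's current φ, and the weight for opening a new cluster uses
the *exact* prior-predictive marginal of the mutation, obtained by
integrating φ numerically on a 201-point grid (binomial coefficients cancel
throughout and are dropped). This marginal — rather than Monte-Carlo
auxiliary components — is what keeps split moves well mixed; the chain also
starts from singletons so early sweeps only need to merge. After each
sweep, every cluster's φ trajectory is refreshed by griddy Gibbs on the
same grid (resolution 0.005, far below the binomial standard error at
3000x). Defaults: 5000 iterations, 1000 burn-in, thinning 5.

The reported clustering is the consensus of the posterior co-clustering
(similarity) matrix: average-linkage hierarchical clustering on
1 − similarity, cut at 0.5. Reported φ trajectories and 95% credible
intervals are grid-posterior summaries *conditional on the consensus
partition*, making the output deterministic for a fixed seed. Cluster ids
are ordered by descending mean prevalence and are otherwise arbitrary; all
comparisons in the test suite are label-free (partition equality or pair
accuracy).

For ≤ 8 mutations an exact alternative scores every set partition (CRP
prior × grid-integrated marginal likelihood) and returns the MAP partition;
the test suite requires the Gibbs consensus to match it on ≥ 9/10 seeded
small instances.

## Clone trees, emergence, lead time

The crossing rule (descendant prevalence ≤ ancestor prevalence at every
draw) and its sum-up corollary (children's prevalences sum to ≤ the
parent's) were applied by manual reasoning in the analyses this package
systematizes; here they are a deterministic greedy algorithm so the
reconstruction is reproducible:

* clusters sorted by descending mean φ; each attaches to the already-placed
  parent with the smallest mean φ that satisfies both constraints within
  tolerance ε = 0.02 (about 3 binomial standard errors at 3000x;
  config-exposed);
* among equally-ranked valid parents, a parent whose own detection day
  precedes the child's is preferred — late appearance is evidence the
  mutation arose inside an established clone;
* a cluster with no valid parent attaches to the implicit germline root
  (prevalence 1 everywhere); a post-hoc validator re-checks every edge and
  every node's child-sum and records per-edge status.

Trend sub-clustering splits a cluster's mutations by the sign of their VAF
change over a chosen window, then by connected components of pairwise
trajectory correlation (threshold 0, i.e. only anti-correlated trajectories
separate); ties and member order are fixed by genomic coordinate.

**Emergence** of a clone is the earliest sampled day at which its
prevalence exceeds a detection floor (default 0.01) and a run of 2
consecutive rising intervals ends at or after that day; monotone-decreasing
or sub-floor trajectories yield none. **Lead time** is the first
progressive-disease (PD) scan day minus the emergence day, reported as-is
(negative if emergence follows PD, undefined without a PD scan).
Lesion association is reported purely as sign agreement between per-cluster
prevalence changes and lesion-diameter changes over matched intervals — an
association report, not a causal claim.

## Outcome statistics

* **Mann-Whitney U**: exact for combined n ≤ 20 by convolution over the
  tied-rank multiset (midranks; two-sided p = 2·min(tail) capped at 1);
  tie-corrected normal approximation with continuity correction beyond.
  The test suite checks the exact path against an independent brute-force
  enumeration of rank arrangements.
* **Spearman**: scipy's implementation (average ranks, t-approximation);
  constant vectors are rejected.
* **Kaplan-Meier / log-rank**: product-limit estimate and the standard
  observed-minus-expected chi-square (1 df) with hypergeometric variance,
  written out directly and cross-checked against lifelines in the tests.
  The survival split is at the cohort median of baseline bTMB with ties
  assigned to the low group (config-exposed); a Cox model is deliberately
  out of scope.
* Sample-to-group mapping for the response comparison: each on-treatment
  draw is labeled by the response assessment of its scan interval (the
  first scan at or after the draw), giving the PR vs SD/PD sample-level
  comparison (32 of 44 samples under the default cohort design — baselines
  are excluded); a patient-level mean-MSAF comparison is also emitted.
  No multiple-testing correction is applied.

## The cohort simulator

The generator emulates the serial-monitoring study design end to end and is
the source of every test fixture. Defaults are the study conditions:

* **Cohort shape**: 12 patients, 44 draws — seven short courses (2 draws)
  and five clustering-eligible courses; the three relapse patients get the
  longest follow-up (7 draws, mirroring the index relapse case such studies
  center on), the eligible responder 5 and the eligible progressor 4.
  Draw intervals are uniform on 14–35 days (relapse courses 21–35, so the
  follow-up span always covers the planted pre-progression window).
* **Clone structure**: 2–4 clones per patient, each a uniformly random
  attachment to an earlier clone; 4–6 mutations per clone (founders carry
  TP53/CDKN2A-style driver labels from a synthetic 329-gene panel list);
  the mutation load is calibrated so the cohort's median baseline bTMB sits
  near 21/Mb.
* **Trajectories**: the founder follows the archetype — exponential decay
  (responder; time constant 40–80 days), ±8% oscillation (stable), capped
  exponential growth (progressor), or decay-then-regrowth (relapse).
  Children are time-varying shares of their parent (siblings' shares
  oscillate with distinct phases so sibling trajectories cross — pinning
  the planted topology and keeping clusters separable; a single child
  tracks its parent proportionally); sibling shares sum to ≤ 0.85 of the
  parent, so crossing and sum constraints hold exactly by construction.
* **Founder prevalence**: U(0.10, 0.35). The upper end is set by the
  patient-global 20% VAF rule: a stable founder above φ ≈ 0.4 would sit
  above 20% VAF at every draw and be (correctly) removed as private
  germline, which is the documented failure mode of that rule.
* **Relapse construction**: a non-founder resistance clone emerges 60–120
  days before the planted progression day (the last draw), creeps at a
  low, molecularly detectable prevalence (1.3→2%), then accelerates over
  the final ~35 days to 1.6x the prevalence at which the lesion-diameter
  progression criterion is met — the threshold being solved by fixed-point
  iteration on the *total* tumor fraction, since the growing clone itself
  moves the diameter nadir. The resistance prevalence is added to all of
  its ancestors (its cells carry their mutations too); late second hits
  inside the resistance clone ramp up after a further delay.
* **Read counts**: depth ~ Poisson(3000); alt ~ Binomial(depth, φ·m/c);
  a site with zero alt reads is not emitted in that draw's VCF, as a caller
  would not report it. No sequencing-error model beyond binomial sampling:
  molecular-identifier deduplication is assumed to have removed error
  reads. Planted logR copy-number shifts are off by default
  (config-exposed rate).
* **Confounders**: per patient, 5 germline heterozygous SNPs (VAF ≈ 0.5,
  population AF drawn ≥ 0.001), 2 CHIP variants (plasma VAF 1–5%,
  white-blood-cell support > 2 reads), and 1 private germline allele (VAF
  ≈ 0.5, absent from both the database and the normal — only the 20% rule
  can catch it).
* **Clinical coupling**: lesion diameter sum
  `base_cm · (0.4 + 2·tf(t)) / (0.4 + 2·tf(0))`, with the baseline size
  itself log-normally dispersed around 2 + 30·φ0 cm (σ = 1.0) — bulky
  disease sheds more ctDNA, and the dispersion is calibrated so the pooled
  MSAF-diameter Spearman correlation centers near 0.45, the regime reported
  for real serial cohorts. Measurement noise is Gaussian and proportional
  to the current true diameter (default 10%): a noise floor fixed at 10%
  *of baseline* would imply ~20% scan-to-scan error on post-response
  diameters and generate progression calls no reading workflow would make.
* **Response labels**: PR at ≥ 30% decrease from baseline; PD at ≥ 20%
  increase from the running nadir *and* ≥ 0.5 cm absolute, and — following
  the immune-modified criteria's confirmation requirement — only when the
  next scan also exceeds the threshold (a terminal exceedance stands).
  Progression is dated at the confirming scan, matching the
  scan-confirmed-relapse comparator used for lead-time claims. PFS is the
  PD day (event) or last scan day (censored). Full iUPD/iCPD bookkeeping
  and new-lesion events are not modeled.

Identical config and seed give byte-identical output files; the truth file
covers every emitted variant (origin, clone, per-clone trajectories, tree,
true emergence and progression days).

### What the synthetic cohorts do not show

The simulator draws reads from exactly the binomial model the
deconvolution assumes — passing tests demonstrate correct inference under
the model, not robustness to overdispersion, strand artifacts, mapping
error, panel dropout, or subclonal copy-number change, none of which are
generated. Sibling-clone trajectories are constructed to be separable and
to cross; real clones can be irresolvably collinear, and tree recovery on
real data will be correspondingly worse, especially below ~5% prevalence
where the ε = 0.02 tolerance swamps the signal. Clinical labels come from
a one-dimensional diameter model; real response assessment integrates new
lesions and reader judgment.

## Numerical choices and degenerate inputs

φ grids use 201 points on [0,1]; success probabilities are clipped to
[1e-12, 1 − 1e-12] before logs. Empty variant sets yield MSAF 0, bTMB 0,
and an empty cluster result; a single mutation forms one cluster whose φ
tracks its VAF·c/m within binomial error. Exhaustive partition enumeration
refuses instances with more than 10 mutations (Bell growth). Tree
construction and the simulator break all ties deterministically (genomic
coordinate, cluster id, patient order), so identical inputs give identical
outputs everywhere.

## Problem sizes in the validation suites

The acceptance script and test suite run, per invocation: one default
12-patient cohort end to end (filtering, metrics, statistics, clustering of
the 5 eligible patients at full sampler defaults); 10 six-mutation
instances checked against the exact MAP enumeration; 20 two-cluster
replicates (20 mutations × 3 draws at 3000x) for prevalence-recovery error;
20 planted 3–5-clone trees for topology recovery; and a 16-patient relapse
cohort for the lead-time median. These sizes give stable rates and medians
while keeping a full run in the low minutes on a single core.
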