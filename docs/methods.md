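# Methods

## The internal Z-score

Given a gene × sample expression matrix restricted to a TF catalog, each
sample column is standardised against its own mean and standard deviation
over the catalog genes (sample sd, n−1 denominator):

    z_i = (x_i − x̄) / s

The score is a *within-sample* rank-like weight: it says how strongly a TF is
expressed relative to the other catalog TFs in the same profile. Because no
cross-sample statistic enters, the score is exactly invariant to positive
per-sample scale factors (library size, FPKM vs TPM vs array intensity), and
cohorts measured on different platforms can be analysed without joint
normalisation. The package asserts the contract (column mean 0, sd 1, within
1e-9) on every computed matrix.

**Input scale.** The method itself does not prescribe a scale. By default
values are transformed x → log2(x+1) before standardisation, because the
per-sample sd on linear normalized counts is dominated by a handful of
extreme genes and the resulting z compresses everything else toward zero.
The flag is explicit (`log2_transform`) and recorded in provenance; matrices
flagged as already log-scale refuse a second transform.

**Degenerate columns.** A zero-variance column has no defined z. The default
is a hard error (silently dropping samples would change cohort composition
behind the analyst's back); `drop_degenerate=True` removes and logs them.

## Trimmed-mean lineage scores

Per TF and lineage group, the score is the trimmed mean of the group's
z-values with spreadsheet TRIMMEAN semantics: for total trim fraction t
(default 0.2), k = ⌊n·t/2⌋ values are dropped from each end of the sorted
values and the remaining S = n − 2k averaged. This rounding rule (total
excluded count rounded down to the nearest even integer) is adopted because
the procedure is defined by equivalence with `TRIMMEAN(range, 0.2)`; it also
degrades gracefully — a single-sample group returns its value (k = 0). The
implementation uses a correctly-rounded sum (`math.fsum`) so results do not
depend on accumulation order; tests check exact agreement with an
independent sort-and-slice reference and with `scipy.stats.trim_mean`
(identical truncation rule at t/2 per side).

## Grouping criteria and consolidation

With threshold θ > 0 on the trimmed-mean scores (Z_ad, Z_NE):

* SHARED iff Z_ad > θ and Z_NE > θ
* AD iff Z_ad − Z_NE > θ and Z_NE < θ
* NE iff Z_ad < θ and Z_NE − Z_ad > θ
* UNCLASSIFIED otherwise.

The three named predicates are pairwise mutually exclusive for any θ > 0
(AD and SHARED disagree on Z_NE vs θ; NE and SHARED on Z_ad vs θ; AD and NE
on the sign of Z_ad − Z_NE), so the four categories partition score space —
a property test checks this over random pairs. Inequalities are strict;
boundary ties fall to UNCLASSIFIED, which is deterministic and conservative.
UNCLASSIFIED is an explicit category so the partition is testable, even
though only the three named sets are usually reported.

θ defaults to 0.2, the scale at which an internal Z separates
low-abundance from reliably expressed TFs in bulk RNA-seq (roughly 20
normalized reads); it is a single shared, configurable constant per run. A
footnote in the classification prose describes AD-TFs as "moderate or low"
in the other lineage while the formal rule only bounds Z_NE < θ; the formal
rule is implemented.

Cross-cohort consolidation is plain set intersection per category, which is
order-invariant, monotone (adding a cohort never grows a set) and a subset
of every contributor. Consolidation is where the method buys its
specificity: trimmed-mean sampling noise at desk-scale cohorts (30+20
samples) puts ~5% of null background genes past θ in one cohort
(sd(Z_ad − Z_NE) ≈ 0.15), but the chance of the same false call replicating
in an independent cohort is the square of that. Within-lineage ranking
orders AD by Z_ad, NE by Z_NE and SHARED by min(Z_ad, Z_NE), descending,
with alphabetical tie-breaks; across cohorts the per-cohort scores are
averaged first (a reporting convenience, not part of the classification).

## Sample pre-selection

Cohorts are screened to unambiguous AR+/NE− adenocarcinoma and AR−/NE+
neuroendocrine samples before scoring. Each sample receives two panel
scores — the mean internal Z of an AR-axis panel (default {AR, KLK3}) and an
NE-axis panel (default {CHGA, NCAM1}, i.e. chromogranin A and CD56) — and is
kept as ADENO iff the AR score clears the selection threshold (default 0)
while the NE score does not, NEPC for the mirror image, and EXCLUDED when
both or neither clear it. Panels and threshold are configurable; the
defaults are the standard AR-pathway and NE-phenotype indicator proteins.
Scoring panels on internal Z (not raw expression) makes selection inherit
the per-sample scale invariance. Selection labels only gate which samples
enter the group trimmed means; the z-matrix itself is computed for every
sample independently.

## Longitudinal analysis and the dormancy screen

An ordered series (e.g. a PDX line followed from adenocarcinoma baseline
through post-castration timepoints to neuroendocrine relapse) is scored per
timepoint: internal Z per sample, then a trimmed mean over a timepoint's
replicates; a single-graft timepoint keeps its value. Set trajectories are
unweighted means over a TF set's rows. Phase segmentation labels each
timepoint ADENO_LIKE (AD trajectory ≥ θ, NE below), NE_LIKE (mirror) or
DORMANT (both below); both programs high at once is not a state the
three-phase model admits and raises an error naming the timepoint. Phase
labels attach to timepoints; the de-/re-differentiation transitions are
reported as the label changes between consecutive timepoints.

The dormancy screen flags a TF iff its dormant-timepoint score exceeds an
absolute floor (default 0.2) **and** exceeds the score at every terminal
stage (baseline and relapse, by default) by more than δ (default 0.2);
flagged TFs are ranked by descending dormant score. The intermediate
8-week-style timepoint is not part of the default screen but can be added as
a terminal. The published screen criteria are given graphically rather than
as formulas, so the conjunction above — absolute floor plus margin over both
terminal stages — is the most literal reading of "heightened weighted
expression during the dormant phase compared to terminal stages"; every
constant is configurable. Published dormant-TF counts depend on the real
series and the exact thresholds used there and are treated as calibration
references, not reproduction targets.

## The synthetic generators

**Cohort.** Log-normal expression: per gene a log2 baseline b_g ~
N(μ_b = 5, 1); planted lineage TFs sit at b_g + Δ in their own lineage and
b_g − Δ in the other (a lineage-specific TF is *on* in one lineage and *off*
in the other — planting only an up-shift would leave high-baseline planted
TFs well expressed in the off lineage, which contradicts what the label
means); shared TFs add Δ everywhere; background genes are untouched.
Gaussian noise σ on the log2 scale, then linear-scale emission with
independent per-sample scale factors exp(N(0, σ_s)). Marker-panel genes are
members of the planted lineage sets. Defaults: 300 genes, 30+20 samples,
Δ = 2, σ = 0.5, σ_s = 0.3 — a desk-scale cohort with realistic noise where
single-cohort classification visibly over-calls and consolidation is needed,
mirroring the method's own design. Scale factors are drawn last from the
generator stream, so σ_s = 0 with the same seed reproduces identical
baselines/noise — the end-to-end scale-invariance test relies on this.

The generative model is Gaussian-on-log2 rather than negative-binomial
counts: the method consumes pre-normalized expression, and the log-normal
family exercises exactly the assumptions the pipeline makes. The planted
set sizes (20 AD, 20 NE, 30 shared of 300) are larger fractions than a real
TF catalog would carry; they are chosen to give stable precision/recall
estimates at desk scale, not to match published set sizes.

**Series.** Four timepoints, one graft each by default. Planted profiles are
anchored at the catalog baseline mean so on/off levels are controlled in z
units: AD TFs high (+Δ/2) only at the first timepoint, NE TFs only at the
last, a transient castration-response group only at the second (such early
spikes are seen in real post-castration series), and dormant TFs rise to
+δ_d/2 at the dormant timepoint from a −Δ/2 off-level. The transient group
also serves a numerical purpose: with one elevated 20-gene group per
timepoint, the per-column standardisation statistics stay near-constant
along the series. Without it, the planted groups shift each column's
mean/sd differently per timepoint and background genes' z drift by up to
~0.25 between timepoints — a genuine compositional sensitivity of
within-sample standardisation worth knowing about when interpreting small
margins on real data. Default series noise is technical-scale (σ = 0.02,
log2): single grafts of one tumor line, and the default demonstrates the
screen's *correctness* (exact recovery of the planted set), not its
statistical power. With biological-scale noise (σ ≈ 0.3–0.5) an exact-set
screen at δ = 0.2 over hundreds of TFs would necessarily carry false
positives; raise σ to study that regime.

What the generators do not emulate: count overdispersion, gene-gene
correlation structure, batch effects beyond a scalar per-sample factor,
intermediate/amphicrine phenotypes, and real cohort sizes or platform mixes.
Passing tests therefore certify the algorithmic contracts (standardisation,
trimming, classification, screening, enrichment) under the stated model,
not performance on any particular clinical cohort.

## Two-class GSEA validator

Canonical weighted-KS formulation. Ranking metric: signal-to-noise
(μ_A − μ_B)/(σ_A + σ_B) with each group sd floored at 0.2·|μ| of its group
(the desktop-tool convention; a zero denominator yields score 0), or
difference-of-means for tiny groups; descending order, alphabetical
tie-breaks. Enrichment score: running sum incrementing at members by
|score|^p (p = 1 default) normalised over the set, decrementing at
non-members by 1/(N − N_hit); ES is the signed extremum, leading edge the
members at or before it. Significance: phenotype permutations preserving
group sizes; when the number of distinct label splits equals the requested
permutation count the splits are enumerated exhaustively (exact null), and
when it is smaller the analysis falls back to gene-set permutation with a
warning. NES divides ES by the mean |ES| of same-sign permutations of the
same set; nominal p is the same-sign tail fraction; FDR q follows the
pooled-NES procedure (null tail fraction over observed tail fraction,
clipped at 1). The conventional decision rule q < 0.25 is exposed as
`GseaResult.significant`. Everything is deterministic given a seed.

All defaults (metric, p = 1, 1000 phenotype permutations) follow the
canonical desktop formulation, since published analyses this validator
mirrors were run with that tool; each is a flag.

## Numerical choices and edge cases

* Strict inequalities everywhere a threshold appears; ties are conservative
  (UNCLASSIFIED / not flagged / EXCLUDED).
* Duplicate gene rows after symbol normalisation (uppercase, strip;
  hyphenated symbols kept) collapse by arithmetic mean with a logged
  warning — order-independent and the common multi-probe situation; no
  alias-database resolution is attempted.
* Gene symbols and sample ids must be unique after normalisation; matrices
  must be finite, non-negative unless flagged log-scale.
* trimmed_mean(v, 0) is exactly the arithmetic mean; k = 0 whenever
  n·t/2 < 1.
* Outputs embed the resolved parameter set and input checksums as `#` header
  comments, so published thresholds are auditable from the files alone.

## Problem sizes

Tests and the acceptance script run on 300-gene, 50-sample synthetic
cohorts, four-timepoint series, and 200-gene GSEA instances with 1000
permutations; the whole suite completes in seconds. These sizes are the
package's chosen desk-scale study conditions; the algorithms are vectorised
over genes and scale linearly in genes × samples × permutations.

## Known limitations

* The internal Z is relative to the catalog: changing the catalog changes
  every score in a sample, and strong compositional shifts (many catalog
  genes moving together) leak into the scores of unchanged genes (see the
  series-generator discussion above).
* Classification at θ on small groups inherits trimmed-mean sampling noise;
  single-cohort set sizes should not be interpreted without a replicate
  cohort or a confidence analysis.
* No batch correction or cross-cohort expression merging is provided —
  deliberately: cohorts combine only at the set-overlap level.
* The dormancy screen is a deterministic predicate, not a test with an
  error rate; on noisy series the margins δ and floor should be chosen with
  the replicate structure in mind.
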