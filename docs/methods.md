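# Methods

## Cohort model and data contracts

The unit of analysis is a cohort of fecal 16S rRNA samples in four roles:
`recipient_pre` / `recipient_post` (one pair per FMT recipient cat),
`donor` (one or more samples per donor identity; a donor identity may be a
pooled pair of cohabiting cats), and `healthy` (a reference population).
Counts live in a samples × ASVs integer matrix; every sample must carry a
metadata row and, when phylogenetic diversity is requested, every ASV must
map to a leaf of a rooted, branch-length-bearing tree.

Quality control is a per-sample read-depth floor (default 8600 reads)
applied at load time.  Dropping a sample never alters the counts of the
remaining samples, and is always logged.  Tables may alternatively contain
relative abundances (`proportions=True`), in which case count-only
operations (the singleton/doubleton filter) refuse to run rather than
silently producing nonsense.

Required metadata per recipient: the four host predictors used throughout
— FMT response (`responder`/`non_responder`), initial clinical signs
(diarrhea, constipation, vomiting + diarrhea, vomiting + constipation),
prior antibiotic exposure (yes/no) and dry-kibble consumption (yes/no) —
plus age (years) and sex.  Each stage validates the columns it uses and
fails fast with the offending sample or term named.

## Diversity

* **Alpha**: richness = ASVs with positive count; Pielou's evenness =
  Shannon entropy (natural log, on proportions) / ln(richness), undefined
  for single-ASV samples; Faith's PD = total branch length of the minimal
  subtree spanning the root and the leaves present (the stem to the root is
  included by default, toggleable).  No rarefaction anywhere.
* **Beta**: Bray–Curtis on proportions after removing ASVs whose
  dataset-wide total count is ≤ 2; Aitchison = Euclidean distance between
  CLR rows.  The rare-ASV filter applies to beta diversity only (a flag
  extends it to alpha).
* **CLR pseudocount**: rows are closed to proportions, then every cell
  receives `pseudocount × (smallest non-zero proportion of the row)`
  (default 0.5, i.e. half the row's detection limit — the multiplicative-
  replacement convention) before a final closure.  This keeps the transform
  exactly scale-invariant (a requirement tested to 1e-10) while perturbing
  observed ratios far less than an absolute offset would.

## Permutation inference

PERMANOVA uses the Gower-centered inner-product matrix
`G = −½ C D² C` and projection traces: for a model matrix X,
`SS(model) = tr(H_X G)`.  Marginal mode (the default) scores each term as
the SS difference between the full model and the model with that term
removed; sequential mode accumulates terms in order, in which case term
R² values plus the residual partition the total exactly.  The pseudo-F
permutes sample labels (rows/columns of G); `p = (1+b)/(1+m)` so p is never
0.  `n_perm="exact"` enumerates all n! permutations and reports the exact
fraction (identity included) — used by the enumeration oracle test.
Sample order is canonicalised internally so p-values are invariant to the
caller's row ordering.  On Euclidean distances of univariate data the
pseudo-F reproduces the classical one-way ANOVA F to 1e-10 (tested), and
multi-term marginal output matches vegan's `adonis2(by="margin")` (tested
via Rscript).

PERMDISP embeds samples by PCoA keeping all axes; distances to group
centroids subtract the squared contribution of negative-eigenvalue axes
(imaginary-part correction) and are compared by one-way ANOVA F with a
label-permutation p-value.  PCoA reports all eigenvalues, dropping
negative-eigenvalue axes from the returned coordinates.  Kruskal–Wallis is
the standard tie-corrected rank test (scipy), with the all-values-identical
degenerate case mapped to H = 0, p = 1.

Pairwise PERMANOVA runs one two-group test per level pair, skipping levels
with < 2 samples with a warning; Holm adjustment by default (the study
design states α = 0.05 but no pairwise correction; Holm is the
conservative default, `bh`/`none` available).

## Engraftment

Presence is abundance strictly greater than a threshold (default 0, to be
raised for proportion tables with rounding noise).  A donor identity's pool
is the union of its samples' presence sets by default (the inclusive
reading for multi-sample donors; intersection is available).  Recipients
are compared only to their assigned donor.  For recipient *i*:

* eligible = donor pool minus pre-FMT presence set,
* engrafted = post-FMT ∩ donor pool, minus pre-FMT,
* rate = |engrafted| / |eligible|, kept in [0,1] internally.

`pre_shared + eligible = pool size` is an exact partition (tested).  An
empty eligible set flags the recipient and excludes it from summaries with
a warning.  The taxonomy breakdown pools engrafted (recipient, ASV) events
across recipients and reports genus percentages summing to 100; "commonly
shared" ASVs are those engrafting in strictly more than a threshold
(default 10) of recipients.

## Similarity shift

Dyads pair each recipient with every healthy cat whose age differs by at
most 1 year (inclusive) and whose kibble flag matches — many-to-many, not
1:1, and only recipient-vs-healthy distances are ever used.  Similarity is
`1 − Bray–Curtis` (bounded, the default and the scale used for group
figures); Aitchison has no bounded similarity so the negative distance
serves as a documented surrogate.  Δ = post-similarity − pre-similarity per
dyad; swapping the pre/post labels negates every Δ exactly (tested).
Group summaries average at dyad level by default (recipient-weighted mode
available).  The Δ model is an OLS of dyad Δ on the four host predictors;
per-term inference uses the Gaussian profile likelihood ratio
`n·ln(SSR_reduced/SSR_full)` against χ² with df = dropped columns.  Dyads
sharing a recipient are treated as independent observations, mirroring the
dyad-level design; this overstates the effective n, a known limitation.

## Genus-level shifts

ASV proportions are collapsed by genus with sentinel
`unclassified <rank>` labels kept distinct.  The tested set is
(core ∪ pathogenic) ∩ prevalence-filtered: core = genera present in ≥ 55%
of healthy samples (computed from the cohort's healthy population, or
supplied directly from an external reference list); pathogenic = a
configured six-genus list (default Veillonella, Desulfovibrio, Escherichia,
Campylobacter, Streptococcus, Helicobacter); the final filter keeps genera
present in ≥ 10% of recipient samples (pre and post pooled; all boundaries
inclusive).  Per genus, Δ relative abundance (post − pre, in fractions) is
modelled like the Δ-similarity model; across-genus multiplicity is left
uncorrected by design, with Tukey (studentized-range) adjustment applied
only within multi-level factors.  The χ² reference for the LRT is
asymptotic: at n ≈ 30 recipients per-term type-I error runs near 0.10
rather than 0.05 (measured), approaching nominal by n ≈ 120 — flagged
rather than hidden, since the LRT is the analysis the design prescribes.

## Synthetic cohort generator

The generator emulates the study's data structure, not its biology:

* **Shape defaults**: 46 recipients (paired pre/post), 10 donor cats
  forming 8 donor identities — 6 individuals with 1,1,1,1,2,6 samples and
  2 pooled pairs (two cats mixed 50:50 before normalisation) with 3 and 5
  samples — and 113 healthy cats.  Recipient covariates follow the study's
  marginal frequencies (41/17/33/9% clinical signs, 52% antibiotics, 56%
  kibble, 56% male); ages are N(10.23, 4.03) truncated to [1, 19] years
  and rounded to 0.1 (owner-reported precision); healthy ages uniformly
  cover the recipients' realised range so dyad matching is feasible.
* **Communities**: each host draws an ASV subset (donors 350, recipients
  250, healthy 250 of an 800-ASV pool) and a symmetric Dirichlet
  composition (concentration 0.7 — moderately uneven).  Each recipient's
  pre-FMT subset shares a fraction (default 0.35) with its donor's support.
  Group-level composition multipliers (clinical signs, kibble) perturb
  genus proportions before renormalisation, giving PERMANOVA something to
  detect; `post_covariate_effects` applies multipliers to post samples
  only, the hook used by planted-effect power tests.
* **Engraftment**: each eligible donor ASV engrafts independently with
  probability `true_engraftment_prob` (default 0.13; scalar or
  per-recipient vector), added to the post community at its donor
  abundance and renormalised.  The realised sets are recorded as ground
  truth.
* **Reads**: library sizes are lognormal (mean 50 000, σ = 0.25, floored
  at 1000 — safely above the QC floor), counts multinomial.  A `noiseless`
  mode renders every community member with ≥ 1 read, so measured presence
  sets equal the truth exactly — the basis of the truth-consistency tests.

What the generator does **not** emulate: sequencing error and chimeras,
PCR/primer bias, strain-level dynamics, overdispersed (non-multinomial)
count noise, and any real taxon co-occurrence structure.  Passing tests
therefore demonstrate correctness of the estimators on communities with
known truth, not robustness to those artefacts.  Finite read depth biases
measured engraftment downward (dropout hides rare engrafted ASVs — roughly
(k/N)^a for pool size k, depth N, concentration a), which is why
truth-recovery tests use deep sequencing and the bias direction is itself
asserted.

## Numerical and degenerate-input choices

Hat matrices use the pseudoinverse, so rank-deficient blocks are detected
(aliased terms raise, naming the terms).  Permutation p-values use the
(1+b)/(1+m) estimator except in exact-enumeration mode.  Distance matrices
are symmetrised to 1e-12 and validated (zero diagonal, non-negativity).
Zero-sum samples are hard errors for proportions/CLR.  Eigenvalues within
1e-9 of zero (relative) are treated as zero in PCoA/PERMDISP.  Constant
predictors, single-level factors, groups of size 1 (PERMDISP) and
recipients without a pre/post pair are hard errors at the module level;
the pipeline orchestrator degrades gracefully where the design allows
(PERMDISP on a singleton clinical-sign group is skipped with a recorded
warning; unmatched recipients are reported and omitted from dyads).

## Reproducibility

A single seed drives the generator, every permutation test and the
pipeline; runs are bit-for-bit reproducible and the pipeline manifest
records package version, config, outputs and SHA-256 checksums.  Resumed
runs reuse the simulated cohort only when those checksums match.
Problem sizes in the test suite are scaled-down cohorts (12–25 recipients,
240-ASV pools) for the property and null-calibration tests, and the full
study-shaped cohort (46/10/113, 800 ASVs) for end-to-end headline
recomputation; both complete in seconds per stage on one CPU.
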