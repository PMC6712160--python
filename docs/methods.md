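# Methods

`triplexnet` reconstructs competing-endogenous-RNA (ceRNA, "sponge")
structure from a transcripts-by-samples expression matrix in four stages:
preprocessing, per-transcript sparse regression, typed clique mining, and
clinical association screens.  A seeded synthetic-cohort generator supplies
planted ground truth so every stage is testable without external data.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Preprocessing

Input is an RPKM-scale non-negative matrix with a biotype label (mRNA,
lncRNA, miRNA) per transcript.  Zeros are replaced by the transcript's own
minimum nonzero value before the log2 transform.  The per-transcript rule
is the default because a matrix-wide minimum would compress the dynamic
range of low-abundance transcripts; a `global` policy is available as a
switch.  All-zero transcripts admit no replacement value and are dropped
(with their ids logged); zero-variance transcripts are dropped because they
break both least-squares fits and median splits.  Replacement is idempotent
and the log2 transform is rank-preserving per transcript; samples are never
removed.

## Streamwise VIF regression

For each target transcript y the package approximately minimises the
l0-penalised least-squares objective
`||y − Xβ||² + λ₀·Σᵢ 1{βᵢ≠0}`
over all other transcripts X, with the sparsity penalty expressed through
an alpha-investing significance budget rather than an explicit λ₀:

1. **Marginal screen.** Candidates are ordered by decreasing |Pearson r|
   with the target, computed on a pre-sampled subset of
   `subsample_size = 200` samples (all samples when n ≤ 200).  Ties break
   to the lexicographically smaller id so runs are reproducible.
2. **Streamwise testing.** Candidates are streamed in screen order.  For
   candidate x the t-statistic of x against the current residual is
   computed.  Because the residual is orthogonal to the already-selected
   set S, the marginal coefficient is attenuated by (1 − ρ²), where ρ² is
   the R² of x on S; the naive statistic is therefore corrected to
   t/√(1 − ρ²) (equivalently, the coefficient's variance is corrected by
   the variance inflation factor 1/(1 − ρ²)).  ρ² is estimated on the same
   pre-sampled subset via an incrementally maintained orthonormal basis of
   the selected columns, so the per-candidate cost is O(|S|·subsample).
3. **Alpha-investing.** The j-th test is run at level αⱼ = wⱼ/(2j).
   Wealth starts at `w0 = 0.05`, every test costs its bid (αⱼ/(1 − αⱼ)),
   and each acceptance pays back `payout = 0.05`.  This controls the marginal
   false-discovery rate over the unbounded candidate stream.
4. **Backward sweep.** After the stream, regulators whose full-model
   t-test p exceeds the final alpha level are removed one at a time (worst
   first, refitting after each removal).
5. **Scoring.** Final coefficients are the ordinary least-squares fit of
   the selected set on the full data.  Goodness-of-fit is the adjusted
   R² = 1 − (1 − R²)(n − 1)/(n − p − 1), where p is the number of
   *selected* regulators — with tens of thousands of candidates the
   adjustment is only meaningful (indeed only defined) for the selected
   count.

Models with adjusted R² strictly greater than `r2_threshold = 0.8`
contribute undirected edges between their target and each selected
regulator.  Directionality is discarded deliberately: without time-course
data the regressions establish association, not causal direction.
Duplicate edges keep the largest supporting adjusted R²; transcripts
appearing in no kept model stay out of the node set, and the edge set is
invariant to the order in which models are merged.

Degenerate inputs: constant targets and candidates are rejected/skipped; a
candidate that is numerically collinear with the selected set (ρ² at
machine-one, or a rank-deficient trial fit) is dropped with a warning —
the later-added candidate loses.  A perfect fit (zero residual) stops the
stream.

## Typed clique mining

A *triplet* is a triangle whose three nodes are exactly one mRNA, one
lncRNA and one miRNA; a *four-clique* is a K4 whose biotype multiset covers
all three biotypes.  Enumeration is by node-ordered adjacency intersection
(each triangle emitted once as u < v < w, each K4 once as its sorted
quadruple), not by maximal-clique listing, because all small cliques are
wanted whether or not they are maximal.  Every valid four-clique provably
contains a typed triplet (choose one node per biotype; all pairs are clique
edges), and the test suite asserts both enumerators against brute-force
enumeration over all node triples/quadruples.  Cross-cohort overlap of
triplet lists matches on typed identifier keys only — no alias resolution
is attempted, and an empty overlap between two large lists triggers a
namespace warning.

## Survival and stage screens

* **Per RNA.**  Patients are split at the median expression; values equal
  to the median join the HIGH group.  The two Kaplan–Meier curves are
  compared with the log-rank test (lifelines).  The flag is 1 iff p < 0.05.
* **Per triplet.**  A Cox proportional-hazards model with the three
  (log2-scale, continuous) member expressions is evaluated with the global
  score test at β = 0 (3 df, Breslow tie handling).  The score test needs
  no iterative fitting, is invariant to affine transforms of the
  covariates, and with a single binary covariate reduces exactly to the
  two-group log-rank statistic on tie-free data — the suite cross-checks
  this equivalence against lifelines to 1e-6.  A `median` coding switch
  replaces each covariate by its 0/1 median split for sensitivity checks.
  A singular information matrix is ridge-stabilised (ε on the diagonal)
  and flagged.
* **Stage.**  One-way ANOVA of expression across stages II/III/IV; samples
  with missing stage are excluded from the ANOVA only (they keep their
  survival data).  At least two stage groups with two or more samples are
  required, otherwise the p-value is reported missing and the flag is 0.
* **Triplet-level stage flag.**  "Stage significant" is not intrinsically
  defined for a triplet; the default requires ALL three members to be
  stage-significant, with an `any` option.  A triplet is *both
  significant* when the multivariate survival flag and the triplet stage
  flag are both 1.
* Flags use raw p < 0.05 throughout; Benjamini–Hochberg q-values are
  emitted alongside for reference but never drive a flag.

## Synthetic cohort generator

The generator emulates the statistical shape of a tumour RNA-seq
compilation at desk scale.  Defaults (the study conditions used by the
tests): 200 mRNA / 100 lncRNA / 30 miRNA — preserving the real
mRNA ≫ lncRNA ≫ miRNA ordering — over 200 samples; 12 planted triplets;
`effect_loading = 5`, `noise_sd = 0.2` (log2 units); 1% structural zeros;
six hazard-wired and six stage-wired RNAs; stage probabilities
proportional to 20/323/60 for II/III/IV with 4/407 missing, matching a
real ovarian-cancer cohort's stage mix.

**Sponge model.**  Each planted triplet draws two correlated
standard-normal latent factors u and w (corr = `factor_corr` = 0.5) per
sample; on the log2 scale the lncRNA loads +λ on u, the miRNA −λ on w,
and the mRNA λ/√2 on (u + w), plus independent N(0, `noise_sd`) noise and
a transcript-specific baseline ~ N(3, 1.5).  This yields the sponge sign
pattern (mRNA–lncRNA positive, miRNA negative against both) symmetrically
in all three pairs, and — unlike a single shared factor, which makes the
members conditionally independent given any one partner — leaves each
member with partner-specific signal, so conditional (partial-correlation)
selection can detect *every* edge of the triangle.  With a single factor
each regression would stop after one partner and the third edge of most
triangles would be unrecoverable in principle.

**Zeros.**  The lowest `zero_rate` fraction of each transcript's values is
reported as zero, emulating a detection limit rather than missingness at
random; min-nonzero replacement then lands near the censoring point.  The
default is 1%, appropriate for a compilation already filtered to expressed
transcripts.

**Survival.**  Times are exponential with rate (ln 2/36 months) ·
exp(`hazard_coef` · centred mean log2 expression of the hazard-wired
RNAs); censoring is an independent Bernoulli(`censor_rate`) with uniform
censoring times — the simplest proportional-hazards-consistent scheme.
The hazard-wired RNAs are the mRNA members of the first triplets, so
survival signal propagates into whole cliques, which is what the
annotation screen is supposed to detect.

**Stage.**  A latent II/III/IV stage is drawn for every sample (the
missing label masks it without removing it), and stage-wired RNAs —
background mRNAs, disjoint from the triplets — gain `stage_shift` = 0.5
log2 units per ordinal step.  The shift is strongly detectable by ANOVA
(effect 2.5× the noise SD) but deliberately small enough that the
co-expression it induces *among* stage RNAs stays below the network's
adjusted-R² filter: stage is an annotation channel, not a hidden source of
network edges.

**What the benchmark does not emulate:** library-size artefacts, batch
effects, count noise (values are log-normal, not negative binomial),
overlapping or hierarchical regulatory modules, miRNA-specific
normalisation quirks, and covariate-dependent censoring.  Passing the
planted-recovery tests therefore demonstrates correctness of the machinery
under clean sponge structure, not performance on real tumour data.

## Numerical and design notes

* All randomness flows from explicit integer seeds; per-target seeds are
  CRC32 hashes of (global seed, target id), so serial and parallel fits
  agree bit-for-bit and outputs are reproducible byte-for-byte.
* The 0.8 adjusted-R² cutoff is applied strictly (a model at exactly 0.8
  is excluded); median ties go HIGH — both boundaries are pinned by tests.
* The streamwise selector is benchmarked against exhaustive best-subset
  selection under BIC on 12-candidate problems at SNR 25.  These problems
  use n = 10,000 samples: the BIC oracle admits a null regressor whenever
  its t² exceeds ln n, so at small n the *oracle itself* overfits often
  enough (e.g. ~25% of problems at n = 100 with ~10 null candidates) to
  make agreement meaningless; at n = 10,000 the oracle is stable and the
  comparison measures the selector.
* On the default cohort the pipeline recovers ~100% of planted triplets.
  Reported edges include a small residue (~1–2%) of spurious regulators:
  survivors of the backward sweep need a full-model p below ~2–6 × 10⁻⁵,
  and with ~300 null candidates against ~36 kept models per cohort a few
  such chance alignments per ten cohorts are expected — each additionally
  multiplied across sibling models, because every member's residual
  contains the other members' noise vectors.  An exhaustive best-subset
  oracle would admit the same regressors (their t² far exceeds ln n), so
  this residue reflects the statistical limit of the conditions, not a
  defect of the streamwise approximation.
* Table bookkeeping percentages are stored at full precision and displayed
  at one decimal place, or two below 10%.

## Known limitations

* `fit_all_targets` is serial; per-target seeding makes it trivially
  parallelisable, but no executor is wired in.
* Clique mining is exact enumeration; it is linear in (edges × degree) and
  fine for the networks produced here, but k > 4 cliques and quasi-cliques
  are out of scope.
* The Cox screen offers no stratification or adjustment covariates and no
  competing-risk handling.
* Stage labels are limited to II/III/IV (plus missing), mirroring the
  cohort the generator emulates.
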