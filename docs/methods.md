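# Methods

This note documents the models and procedures implemented in `sh2pep`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Peptide representation

A peptide instance is the 7-residue window at offsets −2..+4 around a
phosphotyrosine, following the standard alignment convention for SH2 ligand
data. The six flanking residues are one-hot encoded position-major with a
fixed alphabetical amino-acid order inside each 20-slot block, giving a
120-dimensional binary vector; the central Tyr is constant and carries no
information, so it is never encoded. The PSSM pathway uses the same layout
with the cysteine slot removed (19 × 6 = 114), matching the convention of
weight matrices trained on oriented peptide array libraries, where Cys is
excluded for chemical reasons.

Two boundary conventions are package choices rather than field standards:
windows truncated by a protein terminus are padded with `-`, and padded
positions encode as all-zero blocks (so a truncated window simply carries
fewer bits); ambiguity codes (B/J/O/U/X/Z) also encode as zero blocks with
a warning rather than an error, since proteome FASTA files routinely
contain them. Encoding is injective on pad-free windows and `decode`
inverts it exactly.

## Dataset compilation

Interaction tables mix two evidence types. Affinity rows (apparent
dissociation constant, nM) are labeled by the binding threshold
K_d < 2000 nM (strict inequality; 2000 nM itself is non-binding). Explicit
±1 labels pass through; when a row carries both and they disagree, the
explicit label wins with a warning — the affinity is assumed to be the
rawer measurement. Label 0 marks unlabeled-pool rows (peptides observed in
an assay with no definitive interaction call); a row with neither label nor
affinity is malformed.

Compilation then: (1) collapses positives duplicated across sources,
treating the designated primary (peptide-array) source as authoritative and
counting the residual unique positives per secondary source; (2) discards
every (domain, peptide) pair carrying both a positive and a negative label
across sources — a disagreement discredits both measurements; (3) groups by
domain and (4) drops domains with fewer than 40 positives (configurable),
below which the richer models cannot be fit reliably. Record identity for
steps 1–2 is the exact case-normalized 7-mer window within a domain; only
exact duplicates are collapsed, as near-duplicate (homology-based)
redundancy removal is not well defined at the 7-mer level. The bookkeeping
is conserved — input rows partition into retained, conflict-discarded and
duplicate-collapsed — and `sh2pep.replay` exercises this arithmetic on
tables materialized from summary marginal counts alone.

## The classifier

Each domain's predictor is a soft-margin SVM with the inhomogeneous
polynomial kernel K(x, z) = (x·z + c0)^d, c0 = 1 by default. The
inhomogeneous form is used so that the degree-d feature space contains all
monomials *up to* degree d: degree 2 then strictly extends the linear
model with all position-pair products, which is what lets it express joint
(AND) and mutually exclusive (XOR) residue requirements. c0 is configurable
so homogeneous kernels can be tested. The quadratic program is delegated to
scikit-learn/libsvm (tolerance 1e−3, deterministic for fixed inputs); the
fitted model is stored as its kernel expansion — support vectors, dual
coefficients αᵢyᵢ, bias — in a versioned JSON container, so serialized
models reproduce decision values to machine precision without the training
library. Tests verify the kernel against an explicit monomial feature map
(d ≤ 2) and the dual expansion against explicit primal weights (d = 1).

Hyper-parameter grids default to d ∈ {1, 2, 3} and
C ∈ {0.01, 0.1, 1, 10, 100}, spanning under- to over-regularized fits and
keeping the linear model available where it genuinely suffices.

## Model selection and evaluation

Performance measures are sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP) — undefined ratios reported as absent, never coerced
to 0 — plus AUC ROC (equal to the normalized Mann–Whitney U statistic,
ties counted half) and AUC PR (step-wise interpolation / average precision,
unbiased under ties; linear interpolation of PR points is deliberately
avoided). A matched-specificity comparison utility returns the smallest
decision threshold whose specificity meets a comparator's, with the
sensitivity there.

Selection is nested: the outer loop is a stratified 5-fold cross-validation
repeated 5 times (alternatively ten 75/25 stratified random splits); on
each outer training set every (d, C) pair is scored by inner 10-fold
cross-validated AUC ROC, and the most frequent winner across outer folds is
the final configuration, evaluated on the outer held-out folds. Ties in the
vote break toward smaller degree, then smaller C (parsimony). Fold
assignment is seeded and reproducible; fold counts shrink with a warning
when a class is smaller than the fold count.

One caveat worth recording: because the inhomogeneous degree-2 kernel nests
the linear features, its inner-CV AUC on purely additive problems matches
the linear model's to within noise, so max-AUC selection picks d = 2 about
as often as d = 1 on such data. The protocol does not systematically prefer
the simpler model unless the tie is exact; the tie-break, not a preference
margin, is the only parsimony device, and a preference margin was
deliberately not added because it would second-guess the selection
objective.

## Rebalancing by self-training

For domains where verified negatives are scarce, the pipeline mines the
unlabeled pool instead of inventing synthetic minority instances (the
peptides exist; only their labels are missing — so estimating membership in
the negative concept is both easier and biologically safer than
interpolating new sequences):

* negatives in excess → duplicate positives (seeded, with replacement) to
  parity; zero mining iterations;
* balanced → returned unchanged (fixed point);
* positives in excess → duplicate negatives to parity for training only,
  fit, score the pool, move the `batch_fraction` (default 0.25) of the
  remaining deficit (minimum 1) with the *lowest* decision values into the
  real negative set, refit, iterate.

Confidence is the raw signed decision value — distance from the separating
hyperplane — with ties broken by stable pool order. The loop terminates at
parity, pool exhaustion or `max_iterations` (default 20), the latter two
flagged with a warning and topped up by duplication. No pool peptide is
mined twice; the per-iteration trace (counts, batch sizes, pool remaining)
is kept on the result. The batch fraction, refit-each-iteration schedule
and absence of a confidence cutoff are loop-control choices the underlying
idea leaves free; they are configurable and logged. The `random_resample`
baseline draws the needed negatives uniformly from the pool instead, so
the measured gap between treatments isolates the value of confidence-based
mining.

## PSSM baseline

The comparison baseline scores vec(W)·x on the Cys-free encoding, with
W[a, j] = freq(a at j | positives) − freq(a at j | background) — the
difference vector between the positive set's center of mass and the overall
population's. The baseline's original description also applies an
information-theoretic transform whose exact form is not recoverable; the
frequency-difference matrix is the default here, with a log-odds transform
(pseudocount 1) available behind a flag, and both documented as
interpretations rather than reproductions. Classification divides the raw
score by a reference score S_ref, set so that the top `percentile` % of a
large background window population (≥ 100 windows required) scores at or
above it; relative score ≥ 1 (boundary inclusive) predicts binding. The
default percentile 4.5 is the mean of the 3.5% and 5.5% values estimated on
two representative domains in the baseline's original calibration, and is
configurable. Calibration fails loudly if S_ref is non-positive, i.e. if
the matrix does not separate its positives from the background at the
requested percentile.

Being a linear functional of the encoding, the PSSM is structurally blind
to pairwise dependencies — on the balanced XOR testbed it scores at chance
while the degree-2 SVM separates perfectly, which is the mechanism (not
merely an empirical observation) behind the kernel model's advantage.

## Synthetic data

The generator produces per-domain problems with the statistical structure
the method is designed for. A `BindingRule` scores a window as additive
(offset, residue) weights plus pairwise terms over residue *sets* — AND
(both positions in-set) or XOR (exactly one) — with a single residue as the
singleton special case; binding is score ≥ threshold, and observed labels
flip with a symmetric `noise_rate` (symmetry chosen over asymmetric noise
absent any reason to prefer a direction). `make_rule` calibrates the
threshold so a background peptide is positive with the requested prevalence
(default 0.1, a realistic order for per-domain binder frequency).
`sample_problem` rejection-samples exact class counts within a budget
(default 10⁶ draws, failing loudly for infeasible rules) and attaches an
unlabeled background pool whose hidden labels remain recomputable — the
oracle used to audit mined negatives and scan recoveries. The background
residue distribution is uniform over the 20 amino acids by default, with an
optional frequency table; no attempt is made to mimic the human
phosphoproteome's composition.

The XOR testbed deserves its own note. For a linear model to be exactly at
chance, every single (position, residue) indicator must split the classes
50/50, which forces the XOR sets to cover half the background alphabet.
Over the full 20-letter alphabet that means 400 residue-pair cells at the
interacting positions — too thin at n = 500/class for any learner to
recover (measured degree-2 held-out AUC ≈ 0.70). `make_xor_rule` therefore
draws a small working alphabet (default 4 residues), splits it in half per
position, and returns the matching uniform background table; this keeps the
16 pair cells well populated, the linear model provably at chance, and the
degree-2 model at AUC ≈ 1.0. The mixed-rule domain panels use AND terms
over 6-residue sets (effect +3.0) on top of weak additive structure
(scale 0.5), so the pairwise term matters without making the problem
linearly trivial.

What passing these tests shows — and does not. The synthetic conditions
reproduce the *structural* features real SH2 data is known for (imbalance
up to 15:1, label noise, non-additive dependencies, a large unlabeled
pool); they do not reproduce real amino-acid composition, correlated
experimental error between sources, or homology structure among peptides.
Results on them validate the machinery (the rebalancer mines true
negatives, the kernel sees dependencies the PSSM cannot, the scan recovers
planted binders behind its filters); they are not performance estimates for
any real domain.

## Scan stage

Site coordinates are 1-based on the protein sequence (UniProt convention).
Localization matching is exact term-string equality — ontology-ancestor
expansion is left to preprocessing, since annotation term sets can be
closed under ancestors before loading. Proteins with no localization
annotation are skipped entirely (absence of annotation is not evidence of
co-localization). Ranking ties break lexicographically by (protein, site)
for determinism; the top-k cutoff (default 50) applies per domain, and the
promiscuity report lists peptides predicted positive by more than the
threshold (default 40) distinct domains. The three filters commute — the
eligible set is their intersection — which the tests assert on random
fixtures.

## Problem sizes and numerical choices

Simulation-backed checks run at sizes chosen to make their effects
unambiguous while keeping the suite quick on a single CPU: n = 500/class
for the XOR separation, 51 simulated domains at n = 300/class for the
mixed-rule panel, 20 seeded replicates of the 150/10/1000 imbalanced
configuration for the rebalancing comparison, and 3 planted binders among
60 decoys for scan recovery. Kernel-vs-feature-map agreement is asserted to
1e−8, dual-vs-primal to 1e−8, serialization round-trips to 1e−12, AUC
against brute-force pair counting to 1e−12; SVM training tolerance is 1e−3
throughout. Decision values of exactly 0 classify as binding (+1).

## Known limitations

* The compiler's conflict unit is the (domain, peptide) pair; it cannot
  arbitrate between more than two evidence tiers (a source-reliability
  model would be needed).
* The rebalancer assumes the pool is negative-dominated; on pools rich in
  true binders, mined "confident negatives" would poison the negative set
  — the purity audit exists precisely because the synthetic oracle makes it
  measurable, which real data would not.
* Model selection is per-domain and independent; no information is shared
  across domains (no multi-task structure).
* The scan scores only verified phosphosites; it cannot propose novel
  phosphorylation events.
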