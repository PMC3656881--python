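# sh2pep

Per-domain prediction of SH2 domain–phosphopeptide interactions with
regularized polynomial-kernel support-vector machines, a self-training
rebalancing pipeline for heavily imbalanced training data, a SMALI-style
PSSM baseline, and a filtered proteome-scan stage.

## The problem

SH2 domains are the largest family of phosphotyrosine-recognition modules:
each binds a specific subset of pTyr-containing linear peptides, and mapping
those preferences is central to understanding tyrosine-kinase signaling.
High-throughput measurements of domain–peptide binding have three awkward
properties for model fitting:

* **imbalance** — confirmed interactions (positives) can outnumber verified
  non-interactions by up to 15:1, because peptide-array experiments report
  only positives while affinity measurements are scarce;
* **noise** — microarray affinities have low signal-to-noise, and different
  experiments disagree;
* **non-additivity** — binding can require the *joint* presence of residues
  at two positions (neither sufficient alone), or their mutual exclusion,
  which no position-specific scoring matrix (PSSM) can express.

## The model

A candidate peptide is the 7-mer window at offsets −2..+4 around the pTyr
(offset 0). The six flanking residues are one-hot encoded position-major
into x ∈ {0,1}^120 (20 amino acids × 6 positions; the constant central Tyr
is not encoded). Each domain gets a soft-margin SVM with the inhomogeneous
polynomial kernel

    K(x, z) = (x·z + 1)^d,        f(x) = Σᵢ αᵢ yᵢ K(xᵢ, x) + b,

where degree d controls the order of inter-position dependencies the model
can express (d = 1 is an ordinary linear model, d = 2 adds all
position-pair products — implicitly C(120+3−1, 3) ≈ 3·10⁵ monomials at
d = 3 without materializing them) and cost C sets the regularization.
(d, C) are chosen by a nested protocol: stratified 5-fold outer CV repeated
5 times, with the inner 10-fold cross-validated AUC ROC picking a winner
per outer training set and the modal pair winning overall.

Training data are compiled from heterogeneous sources: affinity rows become
labels via the K_d < 2000 nM binding threshold, cross-source duplicate
positives are collapsed, contradictory (domain, peptide) pairs are
discarded from both sides, and domains with fewer than 40 positives are
dropped. Imbalanced domains are then rebalanced: excess negatives are met
by duplicating positives; excess positives trigger iterative *negative
mining* — train on parity-oversampled negatives, score the unlabeled
peptide pool, absorb the most confidently negative peptides (lowest
decision values), refit, repeat until parity.

The comparison baseline is a 19×6 weight matrix (Cys-free, 114-dim
encoding) scoring vec(W)·x, classified by *relative score* = raw score /
reference score ≥ 1, with the reference calibrated so the top 4.5% of a
background window population reaches it.

Trained models are applied proteome-wide only to (domain, site) pairs that
pass three eligibility filters — tyrosine residue, experimentally verified
phosphosite, shared subcellular-localization term — then ranked per domain
by decision value; peptides predicted to bind more than 40 domains are
flagged as promiscuous.

## Worked example

`examples/04_rebalance_imbalanced.py` builds a synthetic domain with a
known binding rule (additive preferences plus one AND dependency), samples
a 15:1 imbalanced training set with a 1000-peptide unlabeled pool, and
compares three treatments on a balanced held-out set:

```
untreated          specificity 0.00  sensitivity 1.00
random re-sample   specificity 0.87  sensitivity 0.81
self-training      specificity 0.49  sensitivity 0.98

mined 140 pool peptides over 16 iterations; 100% are true non-binders by the generating rule.
```

The untreated model collapses onto the majority class (everything predicted
binding); random re-sampling restores specificity but sacrifices
sensitivity; confidence-based mining raises specificity over the untreated
model while keeping sensitivity near the random-resample treatment's
ceiling — and every mined peptide can be audited against the generating
rule. The other scripts in `examples/` walk through encoding, simulation,
compilation, model selection, the PSSM baseline and the proteome scan the
same way; each prints the numbers it computes with a line on what they
mean.

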