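"""Generate a synthetic SH2 domain with known ground truth.

A binding rule combines additive position preferences with a non-additive
AND term (two residues required jointly), mirroring the dependency
structure real domains show.  Sampling produces an imbalanced labeled set
(here 15:1 positives:negatives) plus an unlabeled peptide pool, with every
hidden label recomputable from the rule — the oracle all downstream tests
use.
"""

from sh2pep import make_rule, sample_problem

rule = make_rule(seed=1, n_pairwise=1, noise_rate=0.0, prevalence=0.1)
term = rule.pairwise_terms[0]
print(f"rule: additive weights on all (offset, residue) pairs, plus an {term.kind} "
      f"term linking offsets {term.offset_i:+d} and {term.offset_j:+d} "
      f"(effect {term.effect:+.1f})")

prob = sample_problem(rule, n_pos=150, n_neg=10, n_unlabeled=1000, seed=7)
print(f"sampled {len(prob.positives)} positives, {len(prob.negatives)} negatives "
      f"(imbalance {prob.imbalance:.0f}:1), pool of {len(prob.unlabeled_pool)}")

hidden_neg = sum(rule.label(p) == -1 for p in prob.unlabeled_pool)
print(f"hidden pool composition (oracle): {hidden_neg} true non-binders, "
      f"{len(prob.unlabeled_pool) - hidden_neg} true binders — "
      "the rebalancer must mine the former without seeing these labels")
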