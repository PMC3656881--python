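"""Self-training rebalancing of a 15:1 imbalanced domain.

Three treatments of the same data are compared on a held-out balanced test
set: no treatment, random re-sampling from the pool, and iterative
negative mining (train, score the pool, absorb the most confidently
negative peptides, repeat until parity).
"""

import numpy as np

from sh2pep import (
    RebalanceConfig,
    SVMConfig,
    confusion,
    encode_many,
    make_rule,
    random_resample,
    rebalance,
    sample_problem,
    train,
)

rule = make_rule(300, n_pairwise=1, additive_scale=0.5)
prob = sample_problem(rule, 150, 10, 1000, seed=400)
test = sample_problem(rule, 200, 200, 0, seed=500)

Xp, Xn = encode_many(prob.positives), encode_many(prob.negatives)
Xpool = encode_many(prob.unlabeled_pool)
Xt = encode_many(test.positives + test.negatives)
yt = np.concatenate([np.ones(200), -np.ones(200)])
cfg = SVMConfig(degree=2, C=1.0)


def report(name, model):
    cm = confusion(model.decision_values(Xt), yt)
    print(f"{name:<18} specificity {cm.specificity:.2f}  sensitivity {cm.sensitivity:.2f}")


report("untreated", train(Xp, Xn, cfg))
rp, rn = random_resample(Xp, Xn, Xpool, seed=0)
report("random re-sample", train(rp, rn, cfg))
res = rebalance(Xp, Xn, Xpool, config=RebalanceConfig(seed=0))
report("self-training", res.model)

mined = [prob.unlabeled_pool[i] for i in res.mined_indices]
purity = np.mean([rule.label(p) == -1 for p in mined])
print(f"\nmined {len(mined)} pool peptides over {res.n_iterations} iterations; "
      f"{purity:.0%} are true non-binders by the generating rule.")
print("Untreated models over-predict binding (specificity collapses); random "
      "re-sampling restores specificity at a large sensitivity cost; mining "
      "confident negatives recovers specificity while keeping sensitivity high.")
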