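"""Iterative self-training rebalancing of imbalanced domain datasets.

For many SH2 domains the confirmed positive interactions outnumber the
experimentally verified negatives by a wide margin (up to 15:1), while a
large pool of peptides with no definitive interaction evidence sits unused.
Rather than inventing synthetic minority instances, the pipeline mines that
pool for peptides the current model is most confident are non-binders:

* negatives in excess -> simply duplicate positive instances to parity
  (over-sampling; no information is thrown away);
* positives in excess -> duplicate the negatives to parity, train an
  initial model, score the whole unlabeled pool, move the peptides with the
  lowest decision values into the negative set, refit, and iterate until
  the real (non-duplicated) negatives reach parity.

Confidence is the raw signed decision value — the distance from the
separating hyperplane — with ties broken by stable pool order.  Each
iteration adds a batch sized as a fraction of the remaining deficit
(minimum 1), so the loop terminates within ``max_iterations`` or when the
pool runs dry, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .svm import SVMConfig, SVMModel, train

ModelFactory = Callable[[np.ndarray, np.ndarray], SVMModel]


@dataclass(frozen=True)
class RebalanceConfig:
    """Loop control for the self-training rebalancer."""

    batch_fraction: float = 0.25
    max_iterations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.batch_fraction <= 1.0:
            raise ValueError("batch_fraction must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RebalanceResult:
    """Balanced training material plus the mining audit trail."""

    X_pos: np.ndarray
    X_neg: np.ndarray
    mined_indices: np.ndarray  # positions into the original unlabeled pool
    mined_decision_values: np.ndarray
    n_iterations: int
    trace: List[dict] = field(default_factory=list)
    pool_exhausted: bool = False
    hit_max_iterations: bool = False
    model: Optional[SVMModel] = None  # final model trained on the balanced set

    @property
    def balanced(self) -> bool:
        return len(self.X_pos) == len(self.X_neg)


def _oversample(X: np.ndarray, n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Duplicate rows (with replacement, seeded) until ``n_target`` rows."""
    extra = rng.choice(len(X), size=n_target - len(X), replace=True)
    return np.vstack([X, X[extra]])


def default_model_factory(config: SVMConfig = SVMConfig(degree=2), seed: int = 0) -> ModelFactory:
    def factory(X_pos: np.ndarray, X_neg: np.ndarray) -> SVMModel:
        return train(X_pos, X_neg, config, seed=seed)

    return factory


def rebalance(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    X_pool: np.ndarray,
    model_factory: Optional[ModelFactory] = None,
    config: RebalanceConfig = RebalanceConfig(),
) -> RebalanceResult:
    """Balance a domain dataset by over-sampling or negative mining.

    ``X_pos``/``X_neg`` are encoded labeled peptides; ``X_pool`` the encoded
    unlabeled pool.  Returns the balanced class matrices, the mined pool
    rows with their decision values, and the final model trained on the
    balanced set.
    """
    X_pos = np.atleast_2d(np.asarray(X_pos, dtype=float))
    X_neg = np.atleast_2d(np.asarray(X_neg, dtype=float))
    X_pool = np.asarray(X_pool, dtype=float)
    if X_pool.size == 0:
        X_pool = np.zeros((0, X_pos.shape[1]))
    if len(X_pos) == 0 or len(X_neg) == 0:
        raise ValueError("rebalancing requires at least one instance of each class")
    if model_factory is None:
        model_factory = default_model_factory(seed=config.seed)
    rng = np.random.default_rng(config.seed)

    # Right branch: negatives in excess -> duplicate positives.
    if len(X_pos) < len(X_neg):
        bal_pos = _oversample(X_pos, len(X_neg), rng)
        model = model_factory(bal_pos, X_neg)
        return RebalanceResult(
            X_pos=bal_pos,
            X_neg=X_neg,
            mined_indices=np.empty(0, dtype=int),
            mined_decision_values=np.empty(0),
            n_iterations=0,
            model=model,
        )

    # Already balanced: fixed point.
    if len(X_pos) == len(X_neg):
        model = model_factory(X_pos, X_neg)
        return RebalanceResult(
            X_pos=X_pos,
            X_neg=X_neg,
            mined_indices=np.empty(0, dtype=int),
            mined_decision_values=np.empty(0),
            n_iterations=0,
            model=model,
        )

    # Left branch: positives in excess -> mine confident negatives from the pool.
    if len(X_pool) == 0:
        raise ValueError("positives are in excess but the unlabeled pool is empty")

    real_neg = X_neg
    available = np.arange(len(X_pool))  # pool indices not yet mined
    mined_idx: List[int] = []
    mined_dv: List[float] = []
    trace: List[dict] = []
    n_iter = 0
    pool_exhausted = False

    while len(real_neg) < len(X_pos) and n_iter < config.max_iterations:
        if len(available) == 0:
            pool_exhausted = True
            break
        n_iter += 1
        # train on positives vs negatives over-sampled to parity
        train_neg = _oversample(real_neg, len(X_pos), rng) if len(real_neg) < len(X_pos) else real_neg
        model = model_factory(X_pos, train_neg)
        dv = model.decision_values(X_pool[available])
        deficit = len(X_pos) - len(real_neg)
        batch = min(max(1, int(round(config.batch_fraction * deficit))), deficit, len(available))
        # most confidently negative = smallest decision values; stable order on ties
        order = np.argsort(dv, kind="stable")[:batch]
        chosen = available[order]
        mined_idx.extend(chosen.tolist())
        mined_dv.extend(dv[order].tolist())
        real_neg = np.vstack([real_neg, X_pool[chosen]])
        available = np.setdiff1d(available, chosen, assume_unique=True)
        trace.append(
            {
                "iteration": n_iter,
                "n_pos": int(len(X_pos)),
                "n_real_neg": int(len(real_neg)),
                "batch": int(batch),
                "pool_remaining": int(len(available)),
            }
        )

    hit_max = len(real_neg) < len(X_pos) and not pool_exhausted
    # final model on the balanced (or best-effort) set
    final_neg = _oversample(real_neg, len(X_pos), rng) if len(real_neg) < len(X_pos) else real_neg
    model = model_factory(X_pos, final_neg)
    if pool_exhausted or hit_max:
        import warnings

        warnings.warn(
            f"rebalancing stopped short of parity ({len(real_neg)}/{len(X_pos)} negatives); "
            + ("pool exhausted" if pool_exhausted else "max_iterations reached"),
            stacklevel=2,
        )
    return RebalanceResult(
        X_pos=X_pos,
        X_neg=final_neg,
        mined_indices=np.asarray(mined_idx, dtype=int),
        mined_decision_values=np.asarray(mined_dv),
        n_iterations=n_iter,
        trace=trace,
        pool_exhausted=pool_exhausted,
        hit_max_iterations=hit_max,
        model=model,
    )


def random_resample(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    X_pool: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline treatment: balance with uniformly sampled pool peptides.

    Where self-training mines the pool for *confident* negatives, this
    comparison draws the needed negatives uniformly at random from the pool
    (falling back to over-sampling when the pool is too small), so any
    performance gap isolates the value of confidence-based mining.
    """
    rng = np.random.default_rng(seed)
    if len(X_pos) <= len(X_neg):
        return _oversample(X_pos, len(X_neg), rng), X_neg
    need = len(X_pos) - len(X_neg)
    if len(X_pool) >= need:
        pick = rng.choice(len(X_pool), size=need, replace=False)
        return X_pos, np.vstack([X_neg, X_pool[pick]])
    return X_pos, _oversample(X_neg, len(X_pos), rng)
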