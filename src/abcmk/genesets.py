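"""Case/control machinery for contrasting gene sets.

To ask whether a gene class (say, virus-interacting proteins) adapts faster
than the genomic background, the background must be matched on confounders
that themselves shape adaptation rates (expression, recombination, GC3, PPI
degree, length, immune annotation, ...).  The control builder grows a
multiset of pool genes whose per-feature means track the test-set means
within a relative tolerance, capping how often any single gene may repeat;
repeated builds under different seeds give the null replicates for an
empirical p-value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampling import ObservedCounts

__all__ = ["GeneRecord", "build_control_set", "empirical_pvalue"]


@dataclass
class GeneRecord:
    """One gene: identifier, confounder features, optional count data."""

    gene_id: str
    features: dict[str, float]
    counts: ObservedCounts | None = None

    def __post_init__(self):
        if not all(np.isfinite(list(self.features.values()))):
            raise ValueError(f"non-finite feature for gene {self.gene_id}")


def _within(mean, target, tol):
    # relative tolerance, with an absolute fallback for near-zero targets
    scale = np.maximum(np.abs(target), 1e-12)
    return np.abs(mean - target) <= tol * scale


def build_control_set(
    test: pd.DataFrame,
    pool: pd.DataFrame,
    features,
    target_size: int,
    seed: int,
    match_tol: float = 0.05,
    max_gene_frac: float = 0.012,
    max_passes: int = 200,
) -> list[str]:
    """Greedy confounder-matched control multiset.

    ``test`` and ``pool`` are feature tables indexed by gene id (disjoint).
    Candidates are streamed in seeded random order, with replacement across
    passes; a candidate is added when, for every feature, the running control
    mean either stays within ``match_tol`` (relative) of the test mean or
    moves strictly closer to it, and the candidate's multiplicity stays below
    ``max_gene_frac`` of the target size.  The returned list of gene ids has
    length ``target_size`` and passes the mean-matching audit; growth that
    stalls raises, naming the binding feature(s).
    """
    features = list(features)
    if pool.index.isin(test.index).any():
        raise ValueError("control pool must be disjoint from the test set")
    missing = [f for f in features if f not in pool.columns or f not in test.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    target = test[features].mean().to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    X = pool[features].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("pool features must be finite")
    ids = pool.index.to_numpy()
    cap = max(1, int(np.floor(max_gene_frac * target_size)))
    scale = np.maximum(np.abs(target), 1e-12)
    batch = min(64, len(ids))
    # largest single-gene influence on a feature mean, used as a granularity
    # slack so that discrete features (e.g. binary immune status) cannot
    # deadlock the growth of a small set
    influence = np.max(np.abs(X - target) / scale)

    def worst_dev(s, k):
        return np.max(np.abs(s / k - target) / scale) if k else np.inf

    chosen: list[int] = []
    counts = np.zeros(len(ids), dtype=int)
    sums = np.zeros(len(features))
    stalls = 0
    while len(chosen) < target_size:
        open_idx = np.flatnonzero(counts < cap)
        if open_idx.size == 0:
            raise RuntimeError(
                f"per-gene cap exhausted the pool at {len(chosen)}/{target_size}"
            )
        cand = rng.choice(open_idx, size=min(batch, open_idx.size), replace=False)
        new_means = (sums + X[cand]) / (len(chosen) + 1)
        dev = np.max(np.abs(new_means - target) / scale, axis=1)
        best, best_dev = cand[np.argmin(dev)], dev.min()
        slack = influence / (len(chosen) + 1)
        if best_dev > max(match_tol, worst_dev(sums, len(chosen))) + slack:
            stalls += 1
            if stalls > max_passes:
                w = np.abs(sums / max(len(chosen), 1) - target) / scale
                bad = [f for f, d in zip(features, w) if d > match_tol]
                raise RuntimeError(
                    f"control-set growth stalled at {len(chosen)}/{target_size}; "
                    f"binding feature(s): {bad or features}"
                )
            continue
        chosen.append(best)
        counts[best] += 1
        sums += X[best]
    # polish: random swap repairs until the audit tolerance holds
    for _ in range(50 * target_size):
        if worst_dev(sums, target_size) <= match_tol:
            break
        j = rng.integers(target_size)
        repl = rng.choice(np.flatnonzero(counts < cap))
        trial = sums - X[chosen[j]] + X[repl]
        if worst_dev(trial, target_size) < worst_dev(sums, target_size):
            counts[chosen[j]] -= 1
            counts[repl] += 1
            chosen[j] = repl
            sums = trial
    ok = _within(sums / target_size, target, match_tol)
    if not ok.all():
        bad = [f for f, o in zip(features, ok) if not o]
        raise RuntimeError(f"final control means violate tolerance on: {bad}")
    return [ids[i] for i in chosen]


def empirical_pvalue(observed_stat: float, null_stats, alternative: str = "greater") -> float:
    """Add-one empirical p-value against a null replicate distribution.

    ``p = (1 + #{null >= obs}) / (1 + n_null)`` for the upper tail; the
    add-one keeps p bounded away from zero (999 nulls floor at 0.001).
    """
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size < 1:
        raise ValueError("need at least one null replicate")
    if alternative == "greater":
        k = int(np.sum(null_stats >= observed_stat))
    elif alternative == "less":
        k = int(np.sum(null_stats <= observed_stat))
    elif alternative == "two-sided":
        k = int(2 * min(np.sum(null_stats >= observed_stat),
                        np.sum(null_stats <= observed_stat)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, (1.0 + k) / (1.0 + null_stats.size))
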