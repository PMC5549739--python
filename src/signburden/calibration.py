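"""Operating characteristics of the sign test under the simulator.

Replicated neutral runs estimate the empirical type-I error (the exact
binomial test is conservative because the critical value is discrete);
replicated selection runs estimate power across the logit shift delta.
Replicates work on the frequency scale — truth frequencies plus binomial
allele-count sampling — which is distributionally identical to drawing full
Hardy–Weinberg genotype matrices and far cheaper.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .seltest import sign_test_counts
from .simulate import SimConfig, draw_frequencies, sample_group_frequencies


def replicate_pvalues(config: SimConfig, n_reps: int, seed: int) -> np.ndarray:
    """One-sided sign-test p-value per simulated replicate."""
    root = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        truth = draw_frequencies(config, rng)
        fa, fb = sample_group_frequencies(truth, config.n_per_pop, rng)
        informative = fa != fb
        n_inf = int(informative.sum())
        n_higher = int((fa > fb).sum())
        pvals[r] = sign_test_counts(n_higher, n_inf) if n_inf else 1.0
    return pvals


def rejection_rate(config: SimConfig, n_reps: int, seed: int, alpha: float = 0.05) -> float:
    """Fraction of replicates with p < alpha: type-I error when delta = 0,
    power otherwise."""
    return float(np.mean(replicate_pvalues(config, n_reps, seed) < alpha))


def power_curve(
    base: SimConfig, deltas, n_reps: int, seed: int, alpha: float = 0.05
) -> dict[float, float]:
    """Empirical rejection rate at each delta (same seeds across deltas)."""
    return {
        float(d): rejection_rate(replace(base, delta=float(d)), n_reps, seed, alpha)
        for d in deltas
    }
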