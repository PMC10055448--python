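"""Shared statistical primitives: permutation tests and circular statistics."""

from __future__ import annotations

import numpy as np


def permutation_diff_of_means(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator | None = 0,
    statistic=None,
) -> tuple[float, float]:
    """One-sided permutation test of g(mean(a)) - g(mean(b)) > 0.

    Trial labels are permuted across the pooled samples, keeping group sizes.
    Samples may be scalars (shape (n,)) or traces (shape (n, n_times));
    ``statistic`` g maps the per-group mean to a scalar (identity for
    scalars, e.g. RMS over time for traces).  Group means under permutation
    are computed by a selection-matrix product, so traces stay cheap.  The
    p-value uses add-one smoothing, p = (1 + #{perm >= observed}) / (n_perm + 1),
    so it is never exactly zero.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if statistic is None:
        statistic = lambda m: m
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(statistic(a.mean(axis=0)) - statistic(b.mean(axis=0)))
    pooled = np.concatenate([a, b], axis=0)
    n_a, n_b = len(a), len(b)
    n_tot = n_a + n_b
    order = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    sel = np.zeros((n_perm, n_tot))
    np.put_along_axis(sel, order[:, :n_a], 1.0, axis=1)
    sum_a = sel @ pooled.reshape(n_tot, -1)
    total = pooled.reshape(n_tot, -1).sum(axis=0)
    mean_a = (sum_a / n_a).reshape((n_perm,) + pooled.shape[1:])
    mean_b = ((total - sum_a) / n_b).reshape((n_perm,) + pooled.shape[1:])
    perm_stats = _apply_rowwise(statistic, mean_a) - _apply_rowwise(statistic, mean_b)
    p = (1.0 + np.sum(perm_stats >= observed)) / (n_perm + 1.0)
    return observed, float(p)


def _apply_rowwise(statistic, means: np.ndarray) -> np.ndarray:
    """Apply g to each permutation's group mean; vectorized when g allows."""
    out = statistic(means)
    out = np.asarray(out, dtype=float)
    if out.shape != means.shape[:1]:
        out = np.array([statistic(m) for m in means], dtype=float)
    return out


def resultant_length(phases: np.ndarray) -> float:
    """Length of the mean unit phasor of a set of angles (radians)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        return float("nan")
    return float(np.abs(np.exp(1j * phases).mean()))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for non-uniformity of circular data.

    Returns (Z, p) with Z = n R^2 and the standard small-sample approximation
    p = exp(-Z) * (1 + (2Z - Z^2)/(4n)), clipped to (0, 1].
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    r = resultant_length(phases)
    z = n * r * r
    p = np.exp(-z) * (1.0 + (2.0 * z - z * z) / (4.0 * n))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))
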