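"""Group-contrast sparsification of band connectivity matrices.

Each edge is tested with a two-tailed nonparametric permutation t-test
between groups (pooled-variance Student statistic, free label shuffles shared
across edges); edges with uncorrected p < alpha are retained and all other
entries zeroed in every subject's matrix.  Uncorrected thresholding at this
stage is deliberate; the no-threshold (bypass) pipeline is the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EdgeStats",
    "SparseBandConnectivity",
    "permutation_ttest",
    "edge_permutation_test",
    "apply_sparsity_mask",
]


@dataclass
class EdgeStats:
    band: str
    t_obs: np.ndarray  # (R, R)
    p_perm: np.ndarray  # (R, R), in (0, 1]
    n_perm: int
    seed: int


@dataclass
class SparseBandConnectivity:
    band: str
    matrices: np.ndarray  # (n_subjects, R, R) with non-significant entries 0
    mask: np.ndarray  # (R, R) boolean retained-edge matrix
    alpha: float

    @property
    def retained_count(self) -> int:
        return int(self.mask.sum())


def _pooled_t(low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t statistic per column of (n, k) arrays.
    Degenerate columns (zero pooled variance) yield t = 0."""
    n1, n2 = low.shape[0], high.shape[0]
    m1, m2 = low.mean(axis=0), high.mean(axis=0)
    ss = ((low - m1) ** 2).sum(axis=0) + ((high - m2) ** 2).sum(axis=0)
    pooled = np.maximum(ss, 0.0) / (n1 + n2 - 2)
    denom = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def permutation_ttest(
    low: np.ndarray,
    high: np.ndarray,
    n_perm: int,
    seed: int,
    *,
    chunk: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized permutation t-test on (n_subjects, k) value arrays.

    One shared sequence of n_perm free label shuffles is applied to every
    column (valid because each column's null uses only its own statistic).
    Returns (t_obs, p) with the exact-test convention
    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), so p is always > 0.
    Degenerate columns (zero pooled variance) get t = 0, p = 1.
    """
    low = np.atleast_2d(np.asarray(low, dtype=float))
    high = np.atleast_2d(np.asarray(high, dtype=float))
    if low.shape[1] != high.shape[1]:
        raise ValueError("value arrays not conformable")
    n1 = low.shape[0]
    data = np.vstack([low, high])
    n = data.shape[0]
    t_obs = _pooled_t(low, high)
    degenerate = t_obs == 0.0

    rng = np.random.default_rng(seed)
    exceed = np.zeros(data.shape[1], dtype=np.int64)
    abs_obs = np.abs(t_obs)
    d2 = data ** 2
    tot1 = data.sum(axis=0)
    tot2 = d2.sum(axis=0)
    n2 = n - n1
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # (m, n) 0/1 indicator of membership in the shuffled "low" group
        ind = np.zeros((m, n))
        for r in range(m):
            ind[r, rng.permutation(n)[:n1]] = 1.0
        s1l = ind @ data  # (m, k) per-permutation low-group sums
        s2l = ind @ d2
        m1 = s1l / n1
        m2 = (tot1 - s1l) / n2
        ss = (s2l - n1 * m1 ** 2) + ((tot2 - s2l) - n2 * m2 ** 2)
        pooled = np.maximum(ss, 0.0) / (n - 2)
        denom = np.sqrt(pooled * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = (m1 - m2) / denom
        t_p[~np.isfinite(t_p)] = 0.0
        exceed += (np.abs(t_p) >= abs_obs).sum(axis=0)
        done += m
    p = (1 + exceed) / (n_perm + 1)
    # zero-pooled-variance columns are uninformative by convention
    p[degenerate & (np.ptp(data, axis=0) == 0)] = 1.0
    return t_obs, p


def edge_permutation_test(
    low: np.ndarray | list,
    high: np.ndarray | list,
    n_perm: int = 5000,
    seed: int = 0,
    *,
    band: str = "",
) -> EdgeStats:
    """Edgewise two-tailed permutation t-test between group adjacency stacks.

    ``low`` and ``high`` are lists/stacks of R x R adjacency matrices.  The
    diagonal is ignored (t = 0, p = 1 by convention).
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if low.ndim != 3 or high.ndim != 3 or low.shape[1:] != high.shape[1:]:
        raise ValueError("need non-empty stacks of conformable matrices")
    if low.shape[0] == 0 or high.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    R = low.shape[1]
    off = ~np.eye(R, dtype=bool)
    t_flat, p_flat = permutation_ttest(low[:, off], high[:, off], n_perm, seed)
    t_obs = np.zeros((R, R))
    p_perm = np.ones((R, R))
    t_obs[off] = t_flat
    p_perm[off] = p_flat
    return EdgeStats(band=band, t_obs=t_obs, p_perm=p_perm,
                     n_perm=n_perm, seed=seed)


def apply_sparsity_mask(
    subjects: np.ndarray | list,
    stats: EdgeStats | None,
    alpha: float = 0.05,
    *,
    bypass: bool = False,
) -> SparseBandConnectivity:
    """Zero all edges whose permutation p >= alpha in every subject's matrix.

    The retained-edge mask is shared by all subjects.  With ``bypass=True``
    (the no-threshold control pipeline) matrices are returned unchanged and
    the mask covers every off-diagonal edge.
    """
    subjects = np.asarray(subjects, dtype=float)
    if subjects.ndim != 3:
        raise ValueError("subjects must stack to (n, R, R)")
    R = subjects.shape[1]
    off = ~np.eye(R, dtype=bool)
    if bypass:
        band = stats.band if stats is not None else ""
        return SparseBandConnectivity(band=band, matrices=subjects.copy(),
                                      mask=off.copy(), alpha=alpha)
    if stats is None:
        raise ValueError("stats required unless bypass=True")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if stats.p_perm.shape != (R, R):
        raise ValueError("stats were computed on a different atlas size")
    mask = (stats.p_perm < alpha) & off
    return SparseBandConnectivity(band=stats.band,
                                  matrices=subjects * mask[None],
                                  mask=mask, alpha=alpha)
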