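"""Cluster-based permutation testing for one-sample (sign-flip) designs.

Supra-threshold pixels (|t| above the two-tailed critical value at the
cluster-forming alpha) are grouped by 4-neighbour adjacency (1-D chains
for vectors), each cluster's mass is the sum of its t values, and the
null is the distribution of the maximum same-sign cluster mass over random
whole-subject sign flips.  Reported p values are doubled (one-sided test
per sign, Bonferroni over the two signs), so they live in (0, 2] and are
significant below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats


@dataclass
class Cluster:
    mask: np.ndarray
    sign: int
    cluster_mass: float
    p_value_doubled: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    tmap: np.ndarray
    n_permutations: int
    alpha: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value_doubled < 0.05]


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _cluster_masses(tmap: np.ndarray, tc: float) -> tuple[list[tuple[np.ndarray, float]], list[tuple[np.ndarray, float]]]:
    pos, neg = [], []
    lab, nlab = ndimage.label(tmap > tc)
    for i in range(1, nlab + 1):
        m = lab == i
        pos.append((m, float(tmap[m].sum())))
    lab, nlab = ndimage.label(tmap < -tc)
    for i in range(1, nlab + 1):
        m = lab == i
        neg.append((m, float(tmap[m].sum())))
    return pos, neg


def _max_masses(tmap: np.ndarray, tc: float) -> tuple[float, float]:
    pos, neg = 0.0, 0.0
    lab, nlab = ndimage.label(tmap > tc)
    if nlab:
        pos = max(float(tmap[lab == i].sum()) for i in range(1, nlab + 1))
    lab, nlab = ndimage.label(tmap < -tc)
    if nlab:
        neg = min(float(tmap[lab == i].sum()) for i in range(1, nlab + 1))
    return pos, neg


def cluster_permutation_1samp(
    data: np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Test subject maps (n_subjects x grid...) against zero.

    ``data`` may be 1-D-per-subject (e.g. PETH bins) or 2-D-per-subject
    (time-frequency maps); adjacency is the grid's orthogonal
    neighbourhood.
    """
    data = np.asarray(data, float)
    n = data.shape[0]
    if n < 5:
        raise ValueError("cluster permutation test needs at least 5 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tc = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))
    t_obs = _t_one_sample(data)
    pos, neg = _cluster_masses(t_obs, tc)

    # sign-flip null: sums of squares are flip-invariant, so only the mean
    # changes; recompute t from flipped means and the fixed sum of squares
    flat = data.reshape(n, -1)
    sumsq = (flat**2).sum(axis=0)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    shape = data.shape[1:]
    for p in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n)
        mean = (signs @ flat) / n
        var = (sumsq - n * mean**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t = np.where(np.isfinite(t), t, 0.0).reshape(shape)
        null_pos[p], null_neg[p] = _max_masses(t, tc)

    clusters = []
    for mask, mass in pos:
        p_raw = (1.0 + float(np.sum(null_pos >= mass))) / (n_perm + 1.0)
        clusters.append(Cluster(mask=mask, sign=+1, cluster_mass=mass, p_value_doubled=min(2.0 * p_raw, 2.0)))
    for mask, mass in neg:
        p_raw = (1.0 + float(np.sum(null_neg <= mass))) / (n_perm + 1.0)
        clusters.append(Cluster(mask=mask, sign=-1, cluster_mass=mass, p_value_doubled=min(2.0 * p_raw, 2.0)))
    clusters.sort(key=lambda c: abs(c.cluster_mass), reverse=True)
    return ClusterResult(clusters=clusters, tmap=t_obs, n_permutations=n_perm, alpha=cluster_alpha)
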