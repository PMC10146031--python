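"""Evaluation statistics for the correction: Bray-Curtis dissimilarity,
non-metric multidimensional scaling, Procrustes superimposition with a
permutation test, PAM (k=1) medoid, and the medoid-convergence statistics
dE and Ebar.

The evaluation geometry follows the convergence analysis: the pre- and
post-correction community tables of a pair of datasets are each ordinated
by NMDS, the post configuration is superimposed on the pre configuration by
Procrustes (both centred and scaled to unit sum of squares), the medoid
``m`` of the pre-correction points is found by PAM, and each sample's
correction effectiveness is

    dE = d(m, a) - d(m, b)

where ``b``/``a`` are the sample's pre/post positions in the shared space.
Negative dE means the sample converged toward the pre-treatment medoid.
The overall effectiveness between dataset groups g1, g2 is the difference
of group means, Ebar(g1, g2) = mean(dE_g1) - mean(dE_g2); here too negative
values mean similarity improved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from isc.asv import AbundanceTable


@dataclass
class DistanceMatrix:
    matrix: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape / id mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (m < -1e-12).any():
            raise ValueError("negative distances")


@dataclass
class Ordination:
    coords: np.ndarray          # (n, k)
    stress: float               # Kruskal stress-1
    ids: list[str]
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class ProcrustesResult:
    m2: float
    p: float
    reference: np.ndarray       # standardized pre configuration
    aligned: np.ndarray         # post configuration after superimposition


def bray_curtis(table: AbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns:
    BC(x, y) = 1 - 2 * sum(min(x_i, y_i)) / (sum x + sum y)."""
    df = table.counts if isinstance(table, AbundanceTable) else table
    x = df.to_numpy(dtype=float).T  # samples x features
    zero = x.sum(axis=1) == 0
    if zero.any():
        bad = [df.columns[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample(s): Bray-Curtis undefined for {bad}")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          [str(c) for c in df.columns])


def pcoa_coords(d: DistanceMatrix | np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (metric) principal-coordinates embedding, used to seed the
    non-metric fit."""
    D = d.matrix if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))


def nmds(d: DistanceMatrix, k: int = 2, seed: int = 0,
         max_iter: int = 200, eps: float = 1e-6) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1 with isotonic regression
    on dissimilarity ranks.

    The fit is seeded from the classical PCoA configuration rather than
    random starts: community tables whose sample groups share no features
    have blocks of tied maximal dissimilarities, for which randomly started
    non-metric scaling converges to the well-known degenerate solution that
    collapses each group to a point.  Seeding from the metric embedding
    keeps the between/within structure while the monotone-regression polish
    still optimizes rank agreement.  Deterministic (``seed`` is accepted
    for interface uniformity; the fit uses no randomness).
    """
    n = len(d.ids)
    if n < 4:
        raise ValueError("NMDS needs at least 4 samples")
    init = pcoa_coords(d, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, stress = smacof(
            d.matrix,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            normalized_stress=True,
            random_state=int(seed) % (2**31),
        )
    return Ordination(coords, float(stress), list(d.ids))


def procrustes(x: Ordination | np.ndarray, y: Ordination | np.ndarray,
               permutations: int = 999, seed: int = 0) -> ProcrustesResult:
    """Procrustes superimposition of configuration ``y`` onto ``x``.

    Both configurations are centred and scaled to unit sum of squares and
    the optimal rotation/reflection applied, giving the goodness-of-fit
    M2 in [0, 1] (0 = perfect congruence).  The permutation p-value counts
    row permutations of ``y`` achieving an M2 at most the observed one,
    with the +1 correction, so p is never smaller than
    1 / (permutations + 1).
    """
    X = x.coords if isinstance(x, Ordination) else np.asarray(x, float)
    Y = y.coords if isinstance(y, Ordination) else np.asarray(y, float)
    if X.shape != Y.shape:
        raise ValueError(f"configuration shapes differ: {X.shape} vs {Y.shape}")
    if (isinstance(x, Ordination) and isinstance(y, Ordination)
            and x.ids != y.ids):
        raise ValueError("sample ids of the two ordinations do not match")
    ref, aligned, m2 = _scipy_procrustes(X, Y)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(permutations):
        perm = rng.permutation(Y.shape[0])
        _, _, m2p = _scipy_procrustes(X, Y[perm])
        if m2p <= m2:
            n_le += 1
    p = (1 + n_le) / (1 + permutations)
    return ProcrustesResult(float(m2), float(p), ref, aligned)


def medoid(points: np.ndarray) -> int:
    """PAM with k=1: index of the observed point minimizing the summed
    Euclidean distance to all points; ties go to the lowest index."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need an (n, d) array with n >= 1")
    d = squareform(pdist(pts))
    return int(np.argmin(d.sum(axis=1)))


def delta_e(m: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Effectiveness of the correction for one sample:
    d(m, a) - d(m, b), post minus pre distance to the medoid ``m``."""
    m = np.asarray(m, float)
    return float(np.linalg.norm(m - np.asarray(a, float))
                 - np.linalg.norm(m - np.asarray(b, float)))


def mean_effectiveness(de_g1, de_g2) -> float:
    """Ebar(g1, g2) = mean(dE_g1) - mean(dE_g2); antisymmetric in its
    arguments, negative when g1 converged more than g2."""
    de_g1 = np.asarray(de_g1, float)
    de_g2 = np.asarray(de_g2, float)
    if de_g1.size == 0 or de_g2.size == 0:
        raise ValueError("empty dE vector")
    return float(de_g1.mean() - de_g2.mean())


def test_delta_e(de) -> float:
    """Two-sided one-sample t-test of mean(dE) = 0.

    With zero variance the t statistic is undefined; that degenerate case
    returns p = 1 when the mean is 0 and p = 0 otherwise.
    """
    de = np.asarray(de, float)
    if de.size < 3:
        raise ValueError("need at least 3 values")
    if np.allclose(de.std(ddof=1), 0.0):
        return 1.0 if np.isclose(de.mean(), 0.0) else 0.0
    return float(sps.ttest_1samp(de, 0.0).pvalue)


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def pairwise_matrix(groups: dict[str, np.ndarray],
                    holm: bool = False) -> pd.DataFrame:
    """Ebar, Welch p and a significance code for every ordered group pair.

    Rows are ``g1`` in the Ebar(g1, g2) sense.  Groups with fewer than 3
    samples are excluded with a warning.  ``holm`` applies a Holm step-down
    adjustment across the unordered pairs before coding significance.
    """
    usable = {}
    for g, v in groups.items():
        v = np.asarray(v, float)
        if v.size < 3:
            warnings.warn(f"group {g!r} has < 3 samples; excluded")
            continue
        usable[g] = v
    if len(usable) < 2:
        raise ValueError("need at least 2 usable groups")
    names = list(usable)
    rows = []
    raw_p: dict[frozenset, float] = {}
    for g1 in names:
        for g2 in names:
            if g1 == g2:
                continue
            key = frozenset((g1, g2))
            if key not in raw_p:
                raw_p[key] = float(
                    sps.ttest_ind(usable[g1], usable[g2],
                                  equal_var=False).pvalue
                )
            rows.append(
                [g1, g2, mean_effectiveness(usable[g1], usable[g2]),
                 raw_p[key]]
            )
    df = pd.DataFrame(rows, columns=["g1", "g2", "ebar", "p"])
    if holm:
        adj = _holm({k: v for k, v in raw_p.items()})
        df["p_adj"] = [adj[frozenset((r.g1, r.g2))]
                       for r in df.itertuples(index=False)]
        df["stars"] = df["p_adj"].map(stars)
    else:
        df["stars"] = df["p"].map(stars)
    return df


def _holm(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj = {}
    running = 0.0
    for i, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[key] = running
    return adj


def length_effect_correlation(length_by_group: dict[str, float],
                              ebar_by_pair: dict[tuple[str, str], float],
                              ) -> tuple[float, float]:
    """Spearman correlation between the absolute amplicon-length difference
    of each dataset pair and its Ebar.

    ``ebar_by_pair`` keys are (g1, g2) tuples in the Ebar(g1, g2) order.
    A negative rho means larger scale differences were corrected more.
    """
    if len(ebar_by_pair) < 3:
        raise ValueError("need at least 3 pairs")
    dlen, ebar = [], []
    for (g1, g2), e in ebar_by_pair.items():
        dlen.append(abs(length_by_group[g1] - length_by_group[g2]))
        ebar.append(e)
    if np.allclose(np.std(ebar), 0.0) or np.allclose(np.std(dlen), 0.0):
        raise ValueError("correlation undefined: constant input")
    rho, p = sps.spearmanr(dlen, ebar)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# paired-dataset evaluation
# ---------------------------------------------------------------------------

@dataclass
class PairEvaluation:
    """Full convergence evaluation of one dataset pair (or any sample set
    with a pre and a post table)."""

    ids: list[str]
    groups: dict[str, str]
    pre: Ordination
    post: Ordination
    proc: ProcrustesResult
    medoid_index: int
    delta_e: pd.Series          # per sample, aligned space
    t_p: float                  # one-sample t-test of all dE vs 0
    ebar: float | None          # Ebar(g1, g2) when exactly two groups
    welch_p: float | None

    @property
    def m2(self) -> float:
        return self.proc.m2


def evaluate_pair(pre: AbundanceTable, post: AbundanceTable,
                  groups: dict[str, str] | None = None,
                  permutations: int = 999,
                  seed: int = 0, space: str = "nmds") -> PairEvaluation:
    """Run the whole evaluation chain on matching pre/post tables.

    Both tables must cover the same sample ids.  Separate NMDS ordinations
    of the two Bray-Curtis matrices are superimposed by Procrustes; the
    medoid comes from the pre-correction configuration; dE is computed per
    sample in the standardized aligned space.  With ``space="braycurtis"``
    dE is instead computed directly on dissimilarities: the medoid sample
    is the PAM (k=1) medoid of the pre-correction Bray-Curtis matrix and
    dE_i = BC_post(m, i) - BC_pre(m, i) (the ordinations and M2 are still
    reported).  When ``groups`` assigns the samples to exactly two dataset
    groups, Ebar and the Welch two-sample p-value between the two dE
    vectors are filled in, taking g1 to be the group that appears first
    among the sample columns of ``pre``.
    """
    if space not in ("nmds", "braycurtis"):
        raise ValueError(f"unknown evaluation space {space!r}")
    ids = [str(c) for c in pre.counts.columns]
    if set(ids) != {str(c) for c in post.counts.columns}:
        raise ValueError("pre and post tables cover different samples")
    post_counts = post.counts[ids]
    d_pre = bray_curtis(pre.counts)
    d_post = bray_curtis(post_counts)
    ord_pre = nmds(d_pre, seed=seed)
    ord_post = nmds(d_post, seed=seed + 1)
    proc = procrustes(ord_pre, ord_post, permutations=permutations,
                      seed=seed + 2)
    if space == "nmds":
        mi = medoid(proc.reference)
        m = proc.reference[mi]
        de_vals = [delta_e(m, proc.aligned[i], proc.reference[i])
                   for i in range(len(ids))]
    else:
        mi = int(np.argmin(d_pre.matrix.sum(axis=1)))
        de_vals = list(d_post.matrix[mi] - d_pre.matrix[mi])
    de = pd.Series(de_vals, index=ids, name="delta_e")
    t_p = test_delta_e(de.to_numpy())
    ebar = welch_p = None
    groups = dict(groups or {})
    if groups:
        order = list(dict.fromkeys(groups[s] for s in ids))
        if len(order) == 2:
            g1, g2 = order
            v1 = de[[s for s in ids if groups[s] == g1]].to_numpy()
            v2 = de[[s for s in ids if groups[s] == g2]].to_numpy()
            ebar = mean_effectiveness(v1, v2)
            welch_p = float(sps.ttest_ind(v1, v2, equal_var=False).pvalue)
    return PairEvaluation(ids, groups, ord_pre, ord_post, proc, mi, de,
                          t_p, ebar, welch_p)
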