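"""Distance-based population divergence: MDS and (pairwise) PERMANOVA.

Population-level divergence is visualised by classical (Torgerson) metric
MDS on the matrix of distances between population allele-frequency
profiles.  Statistical significance of group differences is assessed by
PERMANOVA on individual-level dosage distances: the total sum of squared
inter-point distances is partitioned into between- and within-group
components,

    SS_T = (1/N) Σ_{i<j} d²_ij,
    SS_W = Σ_g (1/n_g) Σ_{i<j ∈ g} d²_ij,
    SS_B = SS_T − SS_W,
    F = (SS_B/(a−1)) / (SS_W/(N−a)),      R² = SS_B / SS_T,

with significance from uniform random label permutations and the add-one
estimator p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations).  Pairwise
mode runs one two-group test per population pair on the restricted
sub-matrix and Hochberg-adjusts across pairs.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .comparison import hochberg_adjust

__all__ = [
    "DistanceMatrix",
    "MdsEmbedding",
    "PermanovaResult",
    "population_profile_matrix",
    "distance_matrix",
    "dosage_distance_matrix",
    "classical_mds",
    "permanova",
    "pairwise_permanova",
    "permanova_results_frame",
]

logger = logging.getLogger(__name__)

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "bray-curtis": "braycurtis"}


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarities with zero diagonal."""

    labels: list[str]
    d: np.ndarray
    metric_name: str = "euclidean"
    is_metric: bool = True

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} for {n} labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def subset(self, index: np.ndarray) -> "DistanceMatrix":
        index = np.asarray(index)
        return DistanceMatrix(
            labels=[self.labels[i] for i in index],
            d=self.d[np.ix_(index, index)],
            metric_name=self.metric_name,
            is_metric=self.is_metric,
        )


def population_profile_matrix(
    af_table: pd.DataFrame,
    populations: list[str],
    variants: list[str],
) -> pd.DataFrame:
    """Population × variant allele-frequency profile matrix.

    Cells with no entry in ``af_table`` (population not observed at that
    variant) are filled with frequency 0, with a logged note.
    """
    if len(variants) == 0:
        raise ValueError("empty variant list")
    if "af" not in af_table.columns:
        af_table = af_table.assign(af=af_table["alt_count"] / af_table["called_alleles"])
    wide = af_table.pivot_table(index="population", columns="variant", values="af")
    out = wide.reindex(index=populations, columns=variants)
    n_missing = int(out.isna().sum().sum())
    if n_missing:
        logger.info("profile matrix: %d unobserved cells filled with AF 0", n_missing)
        out = out.fillna(0.0)
    return out


def distance_matrix(profiles, metric: str = "euclidean", labels=None) -> DistanceMatrix:
    """Pairwise dissimilarities between profile rows under the chosen metric."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if isinstance(profiles, pd.DataFrame):
        labels = list(profiles.index) if labels is None else labels
        X = profiles.values
    else:
        X = np.asarray(profiles, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    if np.isnan(X).any():
        raise ValueError("profiles contain undefined values")
    d = squareform(pdist(X, metric=_METRICS[metric]))
    return DistanceMatrix(
        labels=list(labels), d=d, metric_name=metric, is_metric=metric != "bray-curtis"
    )


def dosage_distance_matrix(gm, metric: str = "euclidean") -> DistanceMatrix:
    """Individual-level distances over dosage vectors, tolerant of missing.

    Missing dosages are handled pairwise-complete: each pair's distance is
    computed over features called in both samples and rescaled by
    (n_features / n_used) on the squared-distance (euclidean) or absolute
    (manhattan) scale.  Pairs with no shared called feature get distance 0
    with a warning.
    """
    if metric not in ("euclidean", "manhattan"):
        raise ValueError("dosage distances support euclidean or manhattan")
    X = gm.dosage
    if not np.isnan(X).any():
        return distance_matrix(X, metric=metric, labels=list(gm.sample_ids))
    n, m = X.shape
    d = np.zeros((n, n))
    called = ~np.isnan(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            used = int(both.sum())
            if used == 0:
                warnings.warn(f"samples {i},{j}: no shared called features; distance 0")
                continue
            diff = X[i, both] - X[j, both]
            if metric == "euclidean":
                d[i, j] = np.sqrt((diff**2).sum() * m / used)
            else:
                d[i, j] = np.abs(diff).sum() * m / used
            d[j, i] = d[i, j]
    return DistanceMatrix(labels=list(gm.sample_ids), d=d, metric_name=metric)


@dataclass
class MdsEmbedding:
    """Classical-MDS coordinates with the eigenvalue spectrum."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    goodness: float


def classical_mds(D: DistanceMatrix, k: int = 2) -> MdsEmbedding:
    """Torgerson metric MDS.

    Doubly centre the squared-distance matrix (B = −½ J D² J), take the
    top-k eigenpairs, and scale eigenvectors by the square roots of their
    (nonnegative) eigenvalues.  If fewer than k positive eigenvalues exist,
    the embedding is truncated with a warning.  ``goodness`` is the
    fraction of positive eigenvalue mass captured by the returned axes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.d**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-9, 1e-12 * max(abs(evals[0]), 1.0)) if n else 0.0
    n_pos = int((evals > tol).sum())
    k_eff = min(k, max(n_pos, 0), n - 1 if n > 1 else 0)
    if k_eff < k:
        warnings.warn(
            f"requested {k} dimensions but only {k_eff} positive eigenvalues; truncating"
        )
    coords = evecs[:, :k_eff] * np.sqrt(np.maximum(evals[:k_eff], 0.0))
    # deterministic axis orientation: largest-|loading| entry positive
    for a in range(k_eff):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    pos_mass = evals[evals > 0].sum()
    goodness = float(evals[:k_eff].sum() / pos_mass) if pos_mass > 0 else 0.0
    frame = pd.DataFrame(
        coords, index=D.labels, columns=[f"dim{i + 1}" for i in range(k_eff)]
    )
    return MdsEmbedding(coordinates=frame, eigenvalues=evals, goodness=goodness)


@dataclass
class PermanovaResult:
    """One PERMANOVA test: variance partition and permutation p."""

    label: str
    r2: float
    f_stat: float
    p_raw: float
    n_total: int
    n_groups: int
    n_permutations: int
    seed: int
    group_sizes: dict[str, int] = field(default_factory=dict)
    p_adjusted: float | None = None


def _ss_within(d2: np.ndarray, indices: list[np.ndarray]) -> float:
    return sum(float(d2[np.ix_(g, g)].sum()) / (2 * len(g)) for g in indices)


def _permanova_stats(d2: np.ndarray, indices: list[np.ndarray]) -> tuple[float, float]:
    n = d2.shape[0]
    a = len(indices)
    ss_total = float(d2.sum()) / (2 * n)
    ss_within = _ss_within(d2, indices)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, float(np.clip(r2, 0.0, 1.0))


def _two_group_permuted_f(
    d2: np.ndarray,
    n1: int,
    n_permutations: int,
    rng: np.random.Generator,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Permuted pseudo-F values for the two-group case, vectorised.

    With z the 0/1 indicator of the first group, the within-group sums are
    quadratic forms z'Az and (1-z)'A(1-z) in the squared-distance matrix A,
    so all permutations reduce to one matrix product.  When ``observed`` is
    given it is evaluated through the same arithmetic as the permutations
    (prepended as the first entry), so exact relabeling ties compare equal.
    """
    n = d2.shape[0]
    n2 = n - n1
    # each row of `order` is a uniform random permutation; first n1 → group 1
    order = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n1]
    zt = np.zeros((n_permutations, n))
    np.put_along_axis(zt, order, 1.0, axis=1)
    if observed is not None:
        zt = np.vstack([observed, zt])  # column 0 carries the observed grouping
    z = zt.T
    total = d2.sum()
    row_sums = d2.sum(axis=1)
    q1 = np.einsum("np,np->p", z, d2 @ z)  # z'Az per permutation
    q2 = total - 2 * (row_sums @ z) + q1
    ss_within = q1 / (2 * n1) + q2 / (2 * n2)
    ss_total = total / (2 * n)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / (n - 2))
    f[np.isnan(f)] = 0.0
    return f


def permanova(
    D: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    label: str | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA with a uniform label-permutation null.

    The permutation p uses the add-one estimator, so its floor is
    1/(n_permutations + 1).  F and R² are invariant to relabeling entities
    and to rescaling all distances by a common positive constant.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != D.n:
        raise ValueError("one group label required per entity")
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    indices = [np.flatnonzero(labels == g) for g in groups]
    if any(len(g) == 0 for g in indices):
        raise ValueError("every group needs at least one entity")

    d2 = D.d**2
    f_obs, r2 = _permanova_stats(d2, indices)

    sizes = [len(g) for g in indices]
    rng = np.random.default_rng(seed)
    if len(groups) == 2:
        z_obs = np.zeros(D.n)
        z_obs[indices[0]] = 1.0
        f_all = _two_group_permuted_f(d2, sizes[0], n_permutations, rng, observed=z_obs)
        count = int((f_all[1:] >= f_all[0]).sum())
    else:
        count = 0
        perm = np.arange(D.n)
        for _ in range(n_permutations):
            rng.shuffle(perm)
            start = 0
            perm_idx = []
            for s in sizes:
                perm_idx.append(perm[start : start + s])
                start += s
            f_p, _ = _permanova_stats(d2, perm_idx)
            if f_p >= f_obs:
                count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(
        label=label or " vs ".join(map(str, groups)),
        r2=float(r2),
        f_stat=float(f_obs),
        p_raw=float(p),
        n_total=D.n,
        n_groups=len(groups),
        n_permutations=n_permutations,
        seed=seed,
        group_sizes={str(g): len(idx) for g, idx in zip(groups, indices)},
    )


def pairwise_permanova(
    D: DistanceMatrix,
    labels,
    pairs: list[tuple[str, str]] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    adjust: str = "hochberg",
) -> list[PermanovaResult]:
    """Two-group PERMANOVA per population pair, Hochberg-adjusted.

    Each pair's test runs on the distance sub-matrix restricted to that
    pair's entities, with an independent permutation stream derived from
    the base seed and the pair's index.
    """
    labels = np.asarray(labels, dtype=object)
    if pairs is None:
        groups = list(dict.fromkeys(labels))
        pairs = list(itertools.combinations(groups, 2))
    results = []
    for i, (g1, g2) in enumerate(pairs):
        idx = np.flatnonzero((labels == g1) | (labels == g2))
        if not ((labels[idx] == g1).any() and (labels[idx] == g2).any()):
            raise ValueError(f"pair ({g1}, {g2}) has an empty group")
        sub = D.subset(idx)
        pair_seed = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        res = permanova(
            sub,
            labels[idx],
            n_permutations=n_permutations,
            seed=pair_seed,
            label=f"{g1} vs {g2}",
        )
        results.append(res)
    if adjust == "hochberg" and results:
        adj = hochberg_adjust([r.p_raw for r in results])
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    elif adjust not in ("hochberg", "none"):
        raise ValueError("adjust must be 'hochberg' or 'none'")
    return results


def permanova_results_frame(results: list[PermanovaResult]) -> pd.DataFrame:
    """Tabulate pairwise results (pair, R², F, p_raw, p_adjusted, sizes)."""
    return pd.DataFrame(
        [
            {
                "pair": r.label,
                "r2": r.r2,
                "f": r.f_stat,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "n_total": r.n_total,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )
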