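"""Sample-wise t-tests with cluster-based permutation correction.

Family-wise error across time samples or electrodes is controlled by the
max-statistic permutation scheme: samples exceeding an uncorrected
threshold are grouped into contiguous (time) or connected (electrode
graph) clusters of common sign, each cluster is scored by its summed t,
and the observed cluster masses are compared against the distribution of
the maximum cluster mass under random relabelling — subject-level sign
flips for one-sample/paired designs, group-label exchange for unpaired
designs. When the full sign-flip group is no larger than the requested
permutation count, it is enumerated exhaustively and the p-values are
exact; otherwise random permutations are drawn and p-values use the
(b + 1) / (n_perm + 1) convention, which avoids p = 0 and stays exact
under exchangeability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class Cluster:
    """One supra-threshold cluster."""

    members: np.ndarray      # sample indices (time) or electrode indices
    mass: float              # sum of t over members
    p: float
    sign: int                # +1 or -1

    def bounds(self) -> tuple[int, int]:
        return int(self.members.min()), int(self.members.max())


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float
    seed: int | None
    kind: str = "time"       # "time" or "topo"
    exhaustive: bool = False
    t_observed: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "n_permutations": int(self.n_permutations),
            "cluster_alpha": float(self.cluster_alpha),
            "seed": self.seed,
            "exhaustive": bool(self.exhaustive),
            "clusters": [
                {"members": c.members.tolist(), "mass": float(c.mass),
                 "p": float(c.p), "sign": int(c.sign)}
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def ttest_series(values: np.ndarray, null_value: float = 0.0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One-sample two-sided t against ``null_value`` per sample.

    ``values`` is subjects x samples. Zero-variance samples yield t = +-inf
    (nonzero mean) or 0 (mean equal to the null); both are returned as-is
    rather than raised, so degenerate samples remain visible.
    """
    x = np.asarray(values, dtype=float) - null_value
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a subjects x samples array with >= 2 subjects")
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    p = 2 * sps.t.sf(np.abs(t), n - 1)
    return t, p


def _contiguous_clusters(supra: np.ndarray) -> list[np.ndarray]:
    """Index arrays of maximal runs of True."""
    if not np.any(supra):
        return []
    padded = np.r_[False, supra, False]
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    return [np.arange(s, e) for s, e in zip(starts, ends)]


def _signed_clusters_1d(t: np.ndarray, t_crit: float):
    """(members, mass, sign) for positive and negative clusters."""
    out = []
    for sign in (1, -1):
        for members in _contiguous_clusters(sign * t > t_crit):
            out.append((members, float(t[members].sum()), sign))
    return out


def _max_cluster_mass_1d(t: np.ndarray, t_crit: float) -> float:
    best = 0.0
    for _, mass, _ in _signed_clusters_1d(t, t_crit):
        best = max(best, abs(mass))
    return best


def _sign_matrix(n_subjects: int, n_perm: int, rng: np.random.Generator,
                 ) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix (P x S); exhaustive when 2^S <= n_perm."""
    if n_subjects <= 20 and 2 ** n_subjects <= n_perm:
        bits = np.arange(2 ** n_subjects)[:, None] >> np.arange(n_subjects)
        return np.where(bits & 1, -1.0, 1.0), True
    return rng.choice([-1.0, 1.0], size=(n_perm, n_subjects)), False


def _t_for_signs(x: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t for every sign-flip row. x: (S, T), signs: (P, S)."""
    n = x.shape[0]
    mean = signs @ x / n
    ss = (x ** 2).sum(axis=0)  # invariant under sign flips
    var = (ss - n * mean ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def cluster_permutation_time(values: np.ndarray, null_value: float = 0.0,
                             cluster_alpha: float = 0.05, n_perm: int = 1000,
                             seed: int | None = None) -> ClusterResult:
    """Cluster-corrected one-sample test over contiguous time samples.

    Samples with uncorrected two-sided p below ``cluster_alpha`` are
    grouped into contiguous same-sign clusters; each observed cluster's
    |sum of t| is compared to the permutation distribution of the maximum
    |cluster mass| under subject-level sign flips of (values - null_value).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    x = np.asarray(values, dtype=float) - null_value
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a subjects x samples array with >= 2 subjects")
    n = x.shape[0]
    t_crit = sps.t.ppf(1 - cluster_alpha / 2, n - 1)

    t_obs, _ = ttest_series(x, 0.0)
    observed = _signed_clusters_1d(t_obs, t_crit)

    signs, exhaustive = _sign_matrix(n, n_perm, np.random.default_rng(seed))
    t_perm = _t_for_signs(x, signs)
    null_max = np.array([_max_cluster_mass_1d(row, t_crit) for row in t_perm])

    clusters = []
    for members, mass, sign in observed:
        b = int(np.sum(null_max >= abs(mass) - 1e-12))
        p = b / len(signs) if exhaustive else (b + 1) / (n_perm + 1)
        clusters.append(Cluster(members=members, mass=mass, p=p, sign=sign))
    return ClusterResult(clusters=clusters, n_permutations=len(signs),
                         cluster_alpha=cluster_alpha, seed=seed, kind="time",
                         exhaustive=exhaustive, t_observed=t_obs)


# ---------------------------------------------------------------------------
# electrode-space clustering


def _graph_clusters(t: np.ndarray, t_crit: float, adjacency: np.ndarray):
    """Connected same-sign supra-threshold components on the montage."""
    out = []
    for sign in (1, -1):
        mask = sign * t > t_crit
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        sub = adjacency[np.ix_(idx, idx)]
        n_comp, comp = connected_components(csr_matrix(sub), directed=False)
        for ci in range(n_comp):
            members = idx[comp == ci]
            out.append((members, float(t[members].sum()), sign))
    return out


def _max_cluster_mass_graph(t: np.ndarray, t_crit: float,
                            adjacency: np.ndarray) -> float:
    best = 0.0
    for _, mass, _ in _graph_clusters(t, t_crit, adjacency):
        best = max(best, abs(mass))
    return best


def _unpaired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp * (1 / na + 1 / nb))
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def cluster_permutation_topo(values_a: np.ndarray,
                             values_b: np.ndarray | float | None,
                             adjacency: np.ndarray,
                             cluster_alpha: float = 0.05, n_perm: int = 1000,
                             seed: int | None = None) -> ClusterResult:
    """Cluster-corrected test over electrode neighbourhoods.

    One-sample/paired design: ``values_b`` is None, a scalar null value,
    or a matching subjects x electrodes array (paired difference); the
    permutation unit is a subject-level sign flip. Unpaired design:
    ``values_b`` is a second group's subjects x electrodes array; the
    permutation unit is group-label exchange. Clusters are connected
    components (over ``adjacency``) of supra-threshold electrodes with a
    common sign.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    m = a.shape[1]
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (m, m):
        raise ValueError(
            f"adjacency must cover all {m} electrodes (got "
            f"{adjacency.shape}); electrodes missing from the graph cannot "
            f"be clustered")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    rng = np.random.default_rng(seed)

    paired = (values_b is None or np.isscalar(values_b)
              or np.asarray(values_b).ndim < 2)
    if paired:
        x = a - (0.0 if values_b is None else np.asarray(values_b, dtype=float))
        if x.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        n = x.shape[0]
        t_crit = sps.t.ppf(1 - cluster_alpha / 2, n - 1)
        t_obs, _ = ttest_series(x, 0.0)
        signs, exhaustive = _sign_matrix(n, n_perm, rng)
        t_perm = _t_for_signs(x, signs)
        null_max = np.array(
            [_max_cluster_mass_graph(row, t_crit, adjacency) for row in t_perm])
        denom, add = (len(signs), 0) if exhaustive else (n_perm + 1, 1)
    else:
        b = np.asarray(values_b, dtype=float)
        if b.shape[1] != m:
            raise ValueError("groups must share the electrode axis")
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("need at least 2 subjects per group")
        na = a.shape[0]
        pooled = np.vstack([a, b])
        dof = pooled.shape[0] - 2
        t_crit = sps.t.ppf(1 - cluster_alpha / 2, dof)
        t_obs = _unpaired_t(a, b)
        exhaustive = False
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_i = _unpaired_t(pooled[perm[:na]], pooled[perm[na:]])
            null_max[i] = _max_cluster_mass_graph(t_i, t_crit, adjacency)
        denom, add = n_perm + 1, 1

    clusters = []
    for members, mass, sign in _graph_clusters(t_obs, t_crit, adjacency):
        count = int(np.sum(null_max >= abs(mass) - 1e-12))
        clusters.append(Cluster(members=members, mass=mass,
                                p=(count + add) / denom, sign=sign))
    return ClusterResult(clusters=clusters, n_permutations=len(null_max),
                         cluster_alpha=cluster_alpha, seed=seed, kind="topo",
                         exhaustive=exhaustive, t_observed=t_obs)
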