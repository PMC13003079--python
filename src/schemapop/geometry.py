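"""Population geometry: pseudo-ensembles, 3-D embedding, centroid separations.

Pseudo-populations are assembled across animals by aligning trials of the
same trial type (8 odors x {non-match, match} = 16 types), treating
simultaneity as exchangeable within a type.  Each animal's columns are
standardized independently.  Rule-level separation is measured as a
variance-normalized Euclidean distance between the centroids of the two
classes of a rule's dichotomy in a 3-D embedding, with robustness assessed
by leave-one-subject-out (LOSO) recomputation and significance by a
permutation null built from shuffling trial-type labels within each animal
before assembly (Holm-Bonferroni corrected across sessions).

The embedding backend is pluggable: "umap" gives the nonlinear embedding
used for visualization; "linear" is a deterministic 3-component PCA so that
every downstream statistic is exactly reproducible and testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .taskgen import CUE_ID, NON_MATCH

_EPS = 1e-12


class EmbeddingFailure(ValueError):
    pass


@dataclass
class PseudoPopulation:
    """Type-aligned trials x units matrix pooled across rats."""

    X: np.ndarray                 # (n_types * n_per_type, total units), standardized
    type_index: np.ndarray        # row labels, canonical 0-15 ordering
    rat_ids: list                 # per-column rat id
    n_trials_per_type: int
    included_types: np.ndarray


@dataclass
class Embedding3D:
    coords: np.ndarray            # (n_rows, 3)
    method: str
    seed: int | None


@dataclass
class PermutationNull:
    statistic: str
    observed: float
    null: np.ndarray
    n_perm: int

    @property
    def p_upper(self) -> float:
        return float((1 + np.sum(self.null >= self.observed)) / (1 + self.n_perm))

    @property
    def p_lower(self) -> float:
        return float((1 + np.sum(self.null <= self.observed)) / (1 + self.n_perm))

    @property
    def p_two_tailed(self) -> float:
        return float(min(1.0, 2.0 * min(self.p_upper, self.p_lower)))


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def build_pseudopopulation(
    matrices_by_rat: dict,
    n_trials_per_type: int | None = None,
    seed=None,
    max_trials_per_type: int = 20,
) -> PseudoPopulation:
    """Assemble a pseudo-population from per-rat (rates, type_index) data.

    ``matrices_by_rat`` maps rat id -> (rates array (n_trials, n_units),
    type_index array).  Types absent from any rat are excluded with a
    warning.  Within each rat, ``n_trials_per_type`` trials of each type are
    subsampled without replacement (default: the minimum count available
    across rats and types, capped at ``max_trials_per_type``).  Columns are
    standardized to mean 0 / SD 1 per rat independently.
    """
    rng = np.random.default_rng(seed)
    rats = list(matrices_by_rat)
    counts = {}
    for rat in rats:
        _, types = matrices_by_rat[rat]
        vals, cnt = np.unique(np.asarray(types), return_counts=True)
        counts[rat] = dict(zip(vals.tolist(), cnt.tolist()))
    all_types = sorted(set().union(*(set(c) for c in counts.values())))
    included = [t for t in all_types if all(t in counts[r] for r in rats)]
    if len(included) < len(all_types):
        warnings.warn(
            f"excluded trial types missing in some rats: "
            f"{sorted(set(all_types) - set(included))}"
        )
    if not included:
        raise ValueError("no trial type is present in every rat")
    min_avail = min(counts[r][t] for r in rats for t in included)
    if n_trials_per_type is None:
        n_trials_per_type = min(min_avail, max_trials_per_type)
    elif n_trials_per_type > min_avail:
        warnings.warn(
            f"n_trials_per_type reduced from {n_trials_per_type} to {min_avail}"
        )
        n_trials_per_type = min_avail

    blocks, rat_cols = [], []
    for rat in rats:
        rates, types = matrices_by_rat[rat]
        rates = np.asarray(rates, dtype=float)
        types = np.asarray(types)
        rows = []
        for t in included:
            idx = np.flatnonzero(types == t)
            take = rng.choice(idx, size=n_trials_per_type, replace=False)
            rows.append(rates[take])
        block = np.vstack(rows)
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        blocks.append((block - mu) / sd)
        rat_cols.extend([rat] * rates.shape[1])
    X = np.hstack(blocks)
    type_rows = np.repeat(np.asarray(included), n_trials_per_type)
    return PseudoPopulation(
        X=X, type_index=type_rows, rat_ids=rat_cols,
        n_trials_per_type=n_trials_per_type,
        included_types=np.asarray(included),
    )


def embed_3d(X, method: str = "umap", seed=None) -> Embedding3D:
    """Embed rows of X into 3 dimensions.

    ``method="umap"`` uses the stochastic nonlinear embedder;
    ``method="linear"`` is a deterministic 3-component PCA with a fixed sign
    convention (largest-magnitude loading positive) so repeated runs are
    bit-identical.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 rows to embed")
    if np.allclose(X.std(axis=0), 0.0):
        raise EmbeddingFailure("constant matrix cannot be embedded")
    if method == "linear":
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        k = min(3, Vt.shape[0])
        comps = Vt[:k]
        signs = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
        comps = comps * signs[:, None]
        coords = Xc @ comps.T
        if k < 3:
            coords = np.pad(coords, ((0, 0), (0, 3 - k)))
        return Embedding3D(coords=coords, method="linear", seed=seed)
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=3, random_state=seed)
        return Embedding3D(coords=reducer.fit_transform(X), method="umap", seed=seed)
    raise ValueError(f"unknown embedding method {method!r}")


def centroid_distance(coords, mask_a, mask_b) -> float:
    """Variance-normalized Euclidean distance between two group centroids.

    d = sqrt(sum_k (mu_ak - mu_bk)^2 / s_k^2) over embedding dimensions k,
    with s_k^2 the pooled within-group variance along dimension k
    (epsilon-floored with a warning when degenerate).
    """
    coords = np.asarray(coords, dtype=float)
    a, b = coords[np.asarray(mask_a, bool)], coords[np.asarray(mask_b, bool)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    na, nb = len(a), len(b)
    pooled = (
        a.var(axis=0, ddof=0) * na + b.var(axis=0, ddof=0) * nb
    ) / max(na + nb - 2, 1)
    if np.any(pooled <= _EPS):
        warnings.warn("zero pooled variance in an embedding dimension; epsilon-floored")
        pooled = np.maximum(pooled, _EPS)
    return float(np.sqrt(np.sum((mu_a - mu_b) ** 2 / pooled)))


def type_centroids(coords, type_index):
    """Mean embedding per trial type; returns (types, centroid matrix)."""
    types = np.unique(type_index)
    cents = np.vstack([coords[type_index == t].mean(axis=0) for t in types])
    return types, cents


def ward_dendrogram(centroids) -> np.ndarray:
    """Ward linkage matrix over type centroids (scipy format)."""
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) < 2:
        raise ValueError("need at least 2 centroids")
    return linkage(centroids, method="ward")


def two_cluster_cut(link: np.ndarray) -> np.ndarray:
    """Leaf memberships of the first 2-cluster cut of a linkage matrix."""
    return fcluster(link, t=2, criterion="maxclust")


def rule_masks(type_index, rule: str):
    """Class masks of a rule's dichotomy from canonical type indices."""
    type_index = np.asarray(type_index)
    if rule == NON_MATCH:
        a = type_index < 8            # non-match configurations
    elif rule == CUE_ID:
        a = (type_index % 8) < 4      # odors 1-4 in either configuration
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return a, ~a


def rule_separation(pop: PseudoPopulation, rule: str, backend="linear", seed=None) -> float:
    emb = embed_3d(pop.X, method=backend, seed=seed)
    a, b = rule_masks(pop.type_index, rule)
    return centroid_distance(emb.coords, a, b)


def _shuffled(matrices_by_rat, rng):
    return {
        rat: (rates, rng.permutation(np.asarray(types)))
        for rat, (rates, types) in matrices_by_rat.items()
    }


def loso_rule_separation(
    matrices_by_rat: dict,
    rule: str,
    n_perm: int = 1000,
    n_trials_per_type: int | None = None,
    backend: str = "linear",
    seed=None,
) -> tuple:
    """LOSO mean rule separation and its permutation null for one session.

    For each left-out rat the pseudo-population is rebuilt from the others,
    embedded, and the rule separation recomputed; the session value is the
    mean over iterations.  The null repeats the whole procedure after
    shuffling trial-type labels within each rat.  With a single rat, LOSO
    degenerates to the full sample (warned).
    """
    rats = list(matrices_by_rat)
    rng = np.random.default_rng(seed)

    def _loso_mean(data):
        if len(rats) < 2:
            warnings.warn("single rat: LOSO degenerates to the full sample")
            subsets = [rats]
        else:
            subsets = [[r for r in rats if r != left_out] for left_out in rats]
        vals = []
        for subset in subsets:
            pop = build_pseudopopulation(
                {r: data[r] for r in subset},
                n_trials_per_type=n_trials_per_type,
                seed=rng.integers(2**31),
            )
            vals.append(rule_separation(pop, rule, backend=backend,
                                        seed=int(rng.integers(2**31))))
        return float(np.mean(vals))

    observed = _loso_mean(matrices_by_rat)
    null = np.array([_loso_mean(_shuffled(matrices_by_rat, rng))
                     for _ in range(n_perm)])
    return observed, PermutationNull(
        statistic=f"loso_separation[{rule}]", observed=observed,
        null=null, n_perm=n_perm,
    )


def session_set_pvalues(nulls: list) -> pd.DataFrame:
    """Two-tailed p per session with Holm-Bonferroni correction across the set."""
    raw = [n.p_two_tailed for n in nulls]
    adj = holm_bonferroni(raw)
    return pd.DataFrame(
        dict(statistic=[n.statistic for n in nulls],
             observed=[n.observed for n in nulls],
             p_raw=raw, p_holm=adj)
    )


def group_difference_test(
    loso1: float, loso2: float, null1: np.ndarray, null2: np.ndarray
) -> tuple:
    """Two-tailed p for a group difference in LOSO means.

    The observed difference is compared against the elementwise difference
    of the two groups' permutation nulls.
    """
    null1, null2 = np.asarray(null1), np.asarray(null2)
    if null1.shape != null2.shape:
        raise ValueError("null distributions must have matching sizes")
    obs = loso1 - loso2
    diff = null1 - null2
    pn = PermutationNull("group_difference", obs, diff, len(diff))
    return obs, pn.p_two_tailed, pn
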