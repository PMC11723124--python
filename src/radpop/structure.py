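"""Population structure: PCA, K-selection by BIC, DAPC, bootstrap UPGMA.

The workflow mirrors the adegenet-style analysis of a SNP dosage matrix:

1. missing dosages are imputed with the locus mean,
2. PCA (centered, optionally scaled) summarizes genetic variation,
3. K-means over the PC scores is scored with ``BIC(K) = n ln(WSS_K / n) +
   K ln(n)`` and the chosen K is the smallest value before the BIC curve
   increases,
4. DAPC = linear discriminant analysis on retained PCs; squared
   back-projected discriminant coefficients per locus ("loadings")
   identify group-discriminating SNPs, selected by a 2-means changepoint
   on the loading distribution,
5. sample clustering by UPGMA on Euclidean dosage distances with
   locus-bootstrap clade supports.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .vcfio import VariantMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # loci x components
    explained_variance: np.ndarray  # fraction per component


@dataclass
class DapcResult:
    k: int
    group_assignments: dict[str, str]
    memberships: np.ndarray  # samples x groups, posterior probabilities
    groups: list[str]
    n_pca_retained: int
    snp_loadings: np.ndarray  # loci x discriminant axes, columns sum to 1
    discriminant_snps: list[int] = field(default_factory=list)
    bic_curve: dict[int, float] = field(default_factory=dict)
    _center: np.ndarray | None = None  # training locus means
    _basis: np.ndarray | None = None  # loci x n_pca PC basis
    _lda: LinearDiscriminantAnalysis | None = None

    def predict_memberships(self, vm: VariantMatrix) -> np.ndarray:
        """Posterior group memberships for new samples of the same loci."""
        if self._lda is None:
            raise ValueError("result does not carry the fitted model")
        x = impute_missing_by_locus_mean(vm.dosage_matrix())
        scores = (x - self._center) @ self._basis
        return self._lda.predict_proba(scores)


@dataclass
class Dendrogram:
    """Rooted ultrametric tree with bootstrap supports per internal clade."""

    newick: str
    leaves: list[str]
    clades: list[frozenset]  # internal clades (leaf-name sets), root excluded
    supports: dict[frozenset, float]  # clade -> bootstrap %
    heights: dict[frozenset, float]  # clade -> merge height
    distance_name: str = "euclidean"

    def support_of(self, members) -> float:
        return self.supports[frozenset(members)]


# ---------------------------------------------------------------------------
# imputation and PCA
# ---------------------------------------------------------------------------


def impute_missing_by_locus_mean(dosages: np.ndarray) -> np.ndarray:
    """Replace NaN entries of a samples x loci matrix with the locus mean."""
    x = np.array(dosages, dtype=float)
    all_missing = np.isnan(x).all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"{int(all_missing.sum())} loci have no observed calls; "
            "apply a call-rate filter first"
        )
    means = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = means[idx[1]]
    return x


def _dosage_for_analysis(vm: VariantMatrix) -> np.ndarray:
    return impute_missing_by_locus_mean(vm.dosage_matrix())


def pca(vm: VariantMatrix, n_components: int, scale: bool = False) -> PcaResult:
    """PCA of the (imputed, centered) samples x loci dosage matrix.

    Uses singular-value decomposition; scores = U S, loadings = V.
    Component signs are fixed so the largest-magnitude loading of each
    component is positive; explained_variance fractions are relative to
    the total dosage variance (they sum to <= 1).
    """
    if vm.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    if n_components > min(vm.n_samples, vm.n_loci):
        raise ValueError("n_components exceeds min(n_samples, n_loci)")
    x = _dosage_for_analysis(vm)
    return pca_matrix(x, n_components, scale=scale)


def pca_matrix(x: np.ndarray, n_components: int, scale: bool = False) -> PcaResult:
    """PCA of an arbitrary complete samples x features matrix."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    if scale:
        sd = xc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[c]))
        if vt[c, i] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    total_var = (xc**2).sum() / (n - 1)
    ev = (s**2 / (n - 1)) / total_var if total_var > 0 else np.zeros_like(s)
    return PcaResult(scores=u * s, loadings=vt.T, explained_variance=ev)


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------


def find_clusters(
    scores: np.ndarray, k_max: int, n_starts: int = 20, seed: int | None = 0
) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    """K-means over ``scores`` for K = 1..k_max with a BIC per K.

    Best of ``n_starts`` k-means++ runs per K (fixed seed);
    ``BIC(K) = n ln(WSS_K / n) + K ln(n)`` with WSS the total
    within-cluster sum of squares.  Returns (bic_curve, assignments per K).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of samples")
    bic: dict[int, float] = {}
    assign: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            center = scores.mean(axis=0)
            wss = float(((scores - center) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, n_init=n_starts, init="k-means++", random_state=seed
            ).fit(scores)
            wss = float(km.inertia_)
            labels = km.labels_
        wss = max(wss, 1e-12)  # degenerate perfect fit
        bic[k] = n * np.log(wss / n) + k * np.log(n)
        assign[k] = labels
    return bic, assign


def choose_k(bic_curve: dict[int, float]) -> int:
    """Smallest K before the BIC curve increases.

    Returns the smallest K with ``BIC(K+1) > BIC(K)``; if the curve is
    strictly decreasing throughout, returns the largest K with a warning.
    """
    ks = sorted(bic_curve)
    for k in ks[:-1]:
        if bic_curve[k + 1] > bic_curve[k]:
            return k
    warnings.warn("BIC strictly decreasing; returning k_max", stacklevel=2)
    return ks[-1]


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


def dapc(
    vm: VariantMatrix,
    groups: dict[str, str],
    n_pca: int | None = None,
    n_da: int | None = None,
) -> DapcResult:
    """Discriminant analysis of principal components.

    The dosage matrix is reduced to ``n_pca`` axes (auto: smallest number
    covering 80% of variance, capped at n_samples/3) and a linear
    discriminant model is fit on the group labels.  Memberships are the
    per-sample posterior probabilities; ``snp_loadings`` are the squared
    discriminant coefficients back-projected to loci, normalized to sum 1
    per axis.
    """
    labels = [groups[s] for s in vm.samples if s in groups]
    names = [s for s in vm.samples if s in groups]
    if len(set(labels)) < 2:
        raise ValueError("DAPC needs at least two groups")
    for g in set(labels):
        if labels.count(g) < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
    sub = vm.subset_samples(names)
    x = _dosage_for_analysis(sub)
    n, n_groups = len(names), len(set(labels))

    max_comp = min(n - 1, sub.n_loci)
    full = pca_matrix(x, max_comp)
    if n_pca is None:
        cum = np.cumsum(full.explained_variance)
        n_pca = int(np.searchsorted(cum, 0.80) + 1)
        n_pca = max(1, min(n_pca, n // 3, n - n_groups - 1))
    elif n_pca >= n - n_groups:  # overfitting guard
        raise ValueError(
            f"n_pca={n_pca} >= n_samples - n_groups = {n - n_groups}; "
            "reduce retained axes"
        )
    if n_pca > max_comp:
        raise ValueError("n_pca exceeds available components")
    scores = full.scores[:, :n_pca]

    lda = LinearDiscriminantAnalysis(n_components=n_da, solver="eigen")
    lda.fit(scores, labels)
    memberships = lda.predict_proba(scores)
    n_axes = lda.scalings_.shape[1] if n_da is None else n_da
    n_axes = min(n_axes, n_groups - 1)
    scalings = lda.scalings_[:, :n_axes]

    # back-project discriminant coefficients from PC space to loci
    coef = full.loadings[:, :n_pca] @ scalings  # loci x axes
    load = coef**2
    col = load.sum(axis=0)
    col[col == 0] = 1.0
    load = load / col

    return DapcResult(
        k=n_groups,
        group_assignments=dict(zip(names, labels)),
        memberships=memberships,
        groups=list(lda.classes_),
        n_pca_retained=n_pca,
        snp_loadings=load,
        _center=x.mean(axis=0),
        _basis=full.loadings[:, :n_pca],
        _lda=lda,
    )


def discriminant_snps(
    result: DapcResult, method: str = "changepoint", quantile: float = 0.99
) -> list[int]:
    """Select group-discriminating loci from DAPC loadings.

    ``changepoint`` (default): 2-means clustering of the per-locus loading
    magnitude (square root of the squared-coefficient loading, a
    variance-stabilizing scale for the heavily skewed loading
    distribution); the upper cluster is selected.  ``quantile``: loci
    above the given loading quantile.  Returns locus indices into the
    matrix the DAPC was fit on.
    """
    load = result.snp_loadings.sum(axis=1)
    if np.allclose(load, load[0]):
        warnings.warn("all loadings equal; no discriminant SNPs", stacklevel=2)
        return []
    if method == "changepoint":
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(np.sqrt(load)[:, None])
        upper = int(np.argmax(km.cluster_centers_.ravel()))
        return list(np.flatnonzero(km.labels_ == upper))
    if method == "quantile":
        thr = np.quantile(load, quantile)
        return list(np.flatnonzero(load > thr))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# UPGMA with bootstrap supports
# ---------------------------------------------------------------------------


def _upgma(dist: np.ndarray, names: list[str]):
    """UPGMA agglomeration; returns (clades, heights, newick).

    Merge heights are half the average-linkage distance (ultrametric).
    Ties are broken deterministically by the lexicographically smallest
    (min-leaf, min-leaf) label pair.
    """
    n = len(names)
    active: dict[int, frozenset] = {i: frozenset([names[i]]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights_by_id = {i: 0.0 for i in range(n)}
    newick_by_id = {i: names[i] for i in range(n)}
    d = {
        (i, j): float(dist[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }
    clades: list[frozenset] = []
    heights: dict[frozenset, float] = {}
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        best = None
        best_key = None
        for i, j in itertools.combinations(sorted(ids), 2):
            dij = d[(min(i, j), max(i, j))]
            key = (dij, tuple(sorted((min(active[i]), min(active[j])))))
            if best is None or key < best_key:
                best, best_key = (i, j), key
        i, j = best
        h = best_key[0] / 2.0
        merged = active[i] | active[j]
        # newick children ordered by min leaf for determinism
        kids = sorted([i, j], key=lambda c: min(active[c]))
        parts = []
        for c in kids:
            bl = h - heights_by_id[c]
            parts.append(f"{newick_by_id[c]}:{bl:.10g}")
        nid = next_id
        next_id += 1
        newick_by_id[nid] = "(" + ",".join(parts) + ")"
        active[nid] = merged
        sizes[nid] = sizes[i] + sizes[j]
        heights_by_id[nid] = h
        clades.append(merged)
        heights[merged] = h
        for k in ids:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            dnk = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            d[(min(nid, k), max(nid, k))] = dnk
        ids = [k for k in ids if k not in (i, j)] + [nid]
    root = ids[0]
    return clades, heights, newick_by_id[root]


def upgma_from_distances(dist: np.ndarray, names: list[str]):
    """UPGMA on an explicit symmetric distance matrix.

    Returns ``(clades, heights, newick)`` where ``clades`` are the merged
    leaf-name sets in merge order, ``heights`` maps each clade to its
    ultrametric merge height (half the average-linkage distance) and
    ``newick`` carries branch lengths.  Ties break on the smallest
    lexicographic leaf-label pair, so the output is deterministic.
    """
    return _upgma(np.asarray(dist, dtype=float), list(names))


def upgma_tree(
    vm: VariantMatrix,
    distance: str = "euclidean",
    n_boot: int = 100,
    seed: int | None = 0,
) -> Dendrogram:
    """Bootstrap UPGMA dendrogram of samples on dosage Euclidean distances.

    Distances are Euclidean on the locus-mean-imputed dosage matrix.
    Bootstrap resamples loci with replacement ``n_boot`` times; the
    support of each original internal clade is the percentage of
    replicates whose UPGMA tree contains that clade.  The Newick string
    carries supports as internal-node labels.
    """
    if distance != "euclidean":
        raise ValueError("only euclidean distance is supported")
    if vm.n_samples < 3:
        raise ValueError("need at least three samples")
    x = _dosage_for_analysis(vm)
    names = list(vm.samples)
    dist = squareform(pdist(x, metric="euclidean"))
    clades, heights, _ = _upgma(dist, names)

    counts = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, x.shape[1], size=x.shape[1])
        bd = squareform(pdist(x[:, idx], metric="euclidean"))
        bclades, _, _ = _upgma(bd, names)
        bset = set(bclades)
        for c in counts:
            if c in bset:
                counts[c] += 1
    supports = {
        c: 100.0 * counts[c] / n_boot if n_boot > 0 else float("nan")
        for c in clades
    }

    newick = _newick_with_supports(dist, names, supports)
    internal = [c for c in clades if len(c) < len(names)]
    return Dendrogram(
        newick=newick,
        leaves=names,
        clades=internal,
        supports={c: supports[c] for c in internal},
        heights=heights,
        distance_name=distance,
    )


def _newick_with_supports(dist, names, supports) -> str:
    """Re-run UPGMA emitting supports as internal node labels."""
    n = len(names)
    active = {i: frozenset([names[i]]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights_by_id = {i: 0.0 for i in range(n)}
    newick_by_id = {i: names[i] for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i, j in itertools.combinations(range(n), 2)}
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        best, best_key = None, None
        for i, j in itertools.combinations(sorted(ids), 2):
            dij = d[(min(i, j), max(i, j))]
            key = (dij, tuple(sorted((min(active[i]), min(active[j])))))
            if best is None or key < best_key:
                best, best_key = (i, j), key
        i, j = best
        h = best_key[0] / 2.0
        merged = active[i] | active[j]
        kids = sorted([i, j], key=lambda c: min(active[c]))
        parts = [f"{newick_by_id[c]}:{h - heights_by_id[c]:.10g}" for c in kids]
        nid = next_id
        next_id += 1
        label = ""
        if len(merged) < n and merged in supports:
            label = f"{supports[merged]:.0f}"
        newick_by_id[nid] = "(" + ",".join(parts) + ")" + label
        active[nid] = merged
        sizes[nid] = sizes[i] + sizes[j]
        heights_by_id[nid] = h
        for k in ids:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(min(nid, k), max(nid, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        ids = [k for k in ids if k not in (i, j)] + [nid]
    return newick_by_id[ids[0]] + ";"
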