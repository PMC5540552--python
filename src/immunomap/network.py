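"""Weighted coexpression network construction and module extraction.

The pipeline: Spearman correlation of covariate-adjusted expression ->
soft threshold (|cor|^beta, beta from the scale-free topology criterion
or an explicit override) -> topological overlap similarity -> average
linkage (UPGMA) clustering of the overlap dissimilarity -> a
deterministic height cut with a minimum module size -> eigengene
computation and iterative merging of modules whose eigengenes cluster
below a fixed height.

The tree cut replaces heuristic branch-splitting with a fully specified
rule: cut the dendrogram at a single height (by default the
balance-weighted largest gap in the sorted merge heights, or an explicit
quantile of the merge heights) and keep every resulting cluster with at
least ``min_module_size`` leaves as a module; everything else is
background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

logger = logging.getLogger("immunomap.network")

BACKGROUND = "background"


@dataclass
class Network:
    """Correlation / adjacency / topological-overlap view of one dataset."""

    cor: pd.DataFrame
    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    dissimilarity: pd.DataFrame
    dendrogram: np.ndarray  # scipy linkage matrix
    scale_free_r2: float | None = None


@dataclass
class ModuleSet:
    """Probe -> module assignment with eigengenes and memberships."""

    assignment: pd.Series                 # probe -> label or background
    eigengenes: pd.DataFrame              # samples x modules, unit variance
    kme: pd.DataFrame                     # probes x modules
    variance_explained: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def probes_of(self, module: str) -> pd.Index:
        return self.assignment.index[self.assignment == module]


def spearman_correlation(expression_adjusted: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between all probe pairs (probes x samples input).

    Constant probes are dropped with a warning; ties get average ranks.
    """
    if expression_adjusted.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    X = expression_adjusted.to_numpy(float)
    const = X.std(axis=1) == 0
    if const.any():
        names = list(expression_adjusted.index[const])
        msg = f"dropping {const.sum()} constant probe(s): {names[:5]}..."
        logger.warning(msg)
        warnings.warn(msg)
        expression_adjusted = expression_adjusted.loc[~const]
        X = X[~const]
    ranks = rankdata(X, axis=1)
    cor = np.corrcoef(ranks)
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=expression_adjusted.index,
                        columns=expression_adjusted.index)


def scale_free_fit(cor: np.ndarray, beta: int, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log-log degree-distribution fit for one power.

    Connectivity k_i = sum_{j != i} |cor_ij|^beta is split into
    ``n_bins`` equal-occupancy bins; within each bin the point density
    (count / bin width / total) is regressed on the mean connectivity,
    both on log10 scales.
    """
    a = np.abs(cor) ** beta
    k = a.sum(axis=1) - np.diag(a)
    if np.all(k == 0):
        raise ValueError("all-zero connectivity")
    order = np.argsort(k)
    bins = np.array_split(order, n_bins)
    xs, ys = [], []
    for b in bins:
        if len(b) == 0:
            continue
        kb = k[b]
        width = max(kb.max() - kb.min(), 1e-12)
        density = len(b) / (width * len(k))
        if kb.mean() <= 0 or density <= 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(density))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def select_power(cor: pd.DataFrame, candidate_powers=range(1, 21),
                 r2_threshold: float = 0.85, override: int | None = None
                 ) -> tuple[int, float]:
    """Pick the soft-threshold power by the scale-free topology criterion.

    Returns ``(beta, r2)``: the smallest candidate whose log-log degree
    fit reaches ``r2_threshold`` with a negative slope, the best-R^2
    candidate (with a warning) if none qualifies, or ``override``
    unchanged when given.
    """
    C = cor.to_numpy(float)
    if override is not None:
        r2, _ = scale_free_fit(C, int(override))
        return int(override), r2
    best_beta, best_r2 = None, -np.inf
    for beta in candidate_powers:
        r2, slope = scale_free_fit(C, int(beta))
        if slope < 0 and r2 >= r2_threshold:
            return int(beta), r2
        if r2 > best_r2:
            best_beta, best_r2 = int(beta), r2
    warnings.warn(f"no candidate power reached R^2 >= {r2_threshold}; "
                  f"using argmax R^2 = {best_beta} (R^2 = {best_r2:.3f})")
    return best_beta, best_r2


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap similarity.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    TOM_ii = 1.
    """
    A = adjacency.to_numpy(float) if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency, float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0                      # includes no u=i / u=j terms (zero diagonal)
    k = A0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A0) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def average_linkage(dissimilarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    """UPGMA agglomeration of a square symmetric dissimilarity (scipy linkage)."""
    D = dissimilarity.to_numpy(float) if isinstance(dissimilarity, pd.DataFrame) \
        else np.asarray(dissimilarity, float)
    if np.isnan(D).any():
        raise ValueError("dissimilarity contains NaN")
    condensed = squareform(D, checks=False)
    return linkage(condensed, method="average")


def _adaptive_cut_height(heights: np.ndarray) -> float:
    """Balance-weighted largest-gap cut height.

    Tightly coexpressing probe sets agglomerate in a low band of merge
    heights while unstructured probes pile up in a dense band near the
    maximum dissimilarity. The cut is placed in the gap of the sorted
    merge heights maximizing gap * q, where q is the fraction of merges
    below the gap, restricted to gaps whose midpoint lies in the upper
    half of the height range (the q weight discounts spurious gaps among
    the few earliest merges of a tight cluster; the range restriction
    keeps the cut above the structured band). Returns the gap midpoint;
    deterministic.
    """
    h = np.sort(heights)
    n = len(h)
    if n < 2:
        return float(h[-1]) if n else 0.0
    gaps = np.diff(h)
    q = np.arange(1, n) / n
    # candidate boundaries live in the upper half of the height range:
    # the unstructured bulk always agglomerates near the maximum
    # dissimilarity, while gaps between the first few merges of a tight
    # cluster are spurious
    midpoints = 0.5 * (h[:-1] + h[1:])
    upper = midpoints >= h[0] + 0.5 * (h[-1] - h[0])
    score = gaps * q
    if upper.any():
        score = np.where(upper, score, -np.inf)
    i = int(np.argmax(score))
    return float(0.5 * (h[i] + h[i + 1]))


def extract_modules(dendrogram: np.ndarray, leaves: pd.Index,
                    min_module_size: int = 10, cut_quantile: float | None = None
                    ) -> pd.Series:
    """Deterministic height cut of the dendrogram.

    With ``cut_quantile`` given, the tree is cut at that quantile of the
    merge heights; by default the cut height is chosen adaptively at the
    balance-weighted largest gap in the sorted merge heights (see
    ``_adaptive_cut_height``). Clusters with at least ``min_module_size``
    leaves become modules (labelled M1, M2, ... by decreasing size), the
    rest is background.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be at least 2")
    heights = dendrogram[:, 2]
    if cut_quantile is not None:
        h_star = float(np.quantile(heights, cut_quantile))
    else:
        h_star = _adaptive_cut_height(heights)
    labels = fcluster(dendrogram, t=h_star, criterion="distance")
    assignment = pd.Series(BACKGROUND, index=leaves, name="module", dtype=object)
    counts = pd.Series(labels).value_counts()
    big = counts[counts >= min_module_size].sort_values(ascending=False)
    n_small = int((~pd.Series(labels).isin(big.index)).sum())
    logger.info("extract_modules: cut at %.4g -> %d clusters, %d modules, %d background probes",
                h_star, len(counts), len(big), n_small)
    for rank, cl in enumerate(big.index, start=1):
        assignment[labels == cl] = f"M{rank}"
    return assignment


def compute_eigengene(expression_adjusted: pd.DataFrame, probe_set
                      ) -> tuple[pd.Series, float]:
    """First-principal-component summary of a probe set.

    Probes are standardized to mean 0, SD 1; the eigengene is the first
    PC score vector scaled to unit variance, sign-fixed so its mean
    correlation with member probes is non-negative. Returns
    ``(eigengene, variance_explained)`` with variance_explained the
    leading correlation-matrix eigenvalue over the number of probes.
    """
    probe_set = pd.Index(probe_set)
    missing = probe_set.difference(expression_adjusted.index)
    if len(missing):
        raise KeyError(f"probes not in expression data: {list(missing)}")
    X = expression_adjusted.loc[probe_set].to_numpy(float)  # probes x samples
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        dropped = list(probe_set[sd == 0])
        warnings.warn(f"dropping {len(dropped)} constant probe(s) from eigengene")
        X = X[sd != 0]
        probe_set = probe_set[sd != 0]
        sd = sd[sd != 0]
    if X.shape[0] == 0:
        raise ValueError("no non-constant probes left in module")
    if X.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    Z = ((X.T - X.mean(axis=1)) / sd)           # samples x probes, standardized
    n = Z.shape[0]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    lam1 = S[0] ** 2 / (n - 1)
    eig = scores / scores.std(ddof=1)
    kme = Z.T @ eig / (n - 1)                   # cor of standardized probes with eigengene
    if kme.mean() < 0:
        eig = -eig
    eigengene = pd.Series(eig, index=expression_adjusted.columns, name="eigengene")
    return eigengene, float(lam1 / Z.shape[1])


def _module_set(expression_adjusted: pd.DataFrame, assignment: pd.Series) -> ModuleSet:
    modules = sorted(set(assignment) - {BACKGROUND},
                     key=lambda m: (-int((assignment == m).sum()), m))
    eigs, ve = {}, {}
    for m in modules:
        e, v = compute_eigengene(expression_adjusted, assignment.index[assignment == m])
        eigs[m], ve[m] = e, v
    eigengenes = pd.DataFrame(eigs, index=expression_adjusted.columns)
    # kME for every probe against every module eigengene
    X = expression_adjusted.to_numpy(float)
    Z = ((X.T - X.mean(axis=1)) / X.std(axis=1, ddof=1))
    n = Z.shape[0]
    kme = pd.DataFrame(Z.T @ eigengenes.to_numpy() / (n - 1),
                       index=expression_adjusted.index, columns=modules)
    return ModuleSet(assignment=assignment.copy(), eigengenes=eigengenes, kme=kme,
                     variance_explained=pd.Series(ve, dtype=float))


def merge_modules(module_set: ModuleSet, expression_adjusted: pd.DataFrame,
                  merge_height: float = 0.2) -> ModuleSet:
    """Iteratively merge modules whose eigengenes cluster below ``merge_height``.

    Eigengenes are clustered by 1 - Pearson correlation with average
    linkage; every group joined below the height is collapsed into one
    module, eigengenes are recomputed, and the process repeats until no
    merge occurs. Final eigengenes and kME are recomputed.
    """
    assignment = module_set.assignment.copy()
    while True:
        ms = _module_set(expression_adjusted, assignment)
        modules = ms.modules
        if len(modules) <= 1:
            return ms
        E = ms.eigengenes.to_numpy(float)
        diss = 1.0 - np.corrcoef(E.T)
        np.fill_diagonal(diss, 0.0)
        Z = linkage(squareform(np.clip(diss, 0, None), checks=False), method="average")
        groups = fcluster(Z, t=merge_height, criterion="distance")
        if len(set(groups)) == len(modules):
            return ms
        logger.info("merge_modules: %d modules -> %d groups", len(modules), len(set(groups)))
        for g in set(groups):
            members = [modules[i] for i in range(len(modules)) if groups[i] == g]
            if len(members) > 1:
                keep = members[0]
                for other in members[1:]:
                    assignment[assignment == other] = keep


def detect_modules(expression_adjusted: pd.DataFrame, beta: int | None = None,
                   r2_threshold: float = 0.85, min_module_size: int = 10,
                   cut_quantile: float | None = None, merge_height: float = 0.2
                   ) -> tuple[Network, ModuleSet]:
    """Full discovery pipeline: correlation -> power -> TOM -> UPGMA ->
    quantile cut -> eigengene merge. Returns the network and module set."""
    cor = spearman_correlation(expression_adjusted)
    beta_sel, r2 = select_power(cor, r2_threshold=r2_threshold, override=beta)
    adjacency = np.abs(cor) ** beta_sel
    tom = tom_similarity(adjacency)
    diss = 1.0 - tom
    Z = average_linkage(diss)
    raw = extract_modules(Z, cor.index, min_module_size=min_module_size,
                          cut_quantile=cut_quantile)
    net = Network(cor=cor, beta=beta_sel, adjacency=adjacency, tom=tom,
                  dissimilarity=diss, dendrogram=Z, scale_free_r2=r2)
    if (raw != BACKGROUND).sum() == 0:
        logger.warning("no module found")
        empty = ModuleSet(assignment=raw,
                          eigengenes=pd.DataFrame(index=expression_adjusted.columns),
                          kme=pd.DataFrame(index=expression_adjusted.index))
        return net, empty
    ms = merge_modules(_module_set(expression_adjusted.loc[cor.index], raw),
                       expression_adjusted.loc[cor.index], merge_height=merge_height)
    return net, ms
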