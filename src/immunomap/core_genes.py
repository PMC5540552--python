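"""Core-gene extraction by a two-sided permutation test on module membership.

For each replicated module, the null distribution of module membership
(kME, the Pearson correlation between a probe and the module eigengene)
is the set of memberships of all non-module probes against that
eigengene. For a module probe, b is the smaller of the counts of null
memberships at or above / at or below the probe's own membership (ties
count on both sides, conservatively), and v is the null size. The raw
one-sided p-value uses the exact permutation estimator

    p_raw = (b + 1) / (v + 1) - integral_0^{0.5/(v+1)} F(b; v, x) dx

where F(b; v, x) is the binomial CDF (probability of at most b
exceedances in v draws at per-draw probability x); the subtracted
integral removes the upward bias of the +1 estimator. The returned
p-value is min(1, 2 * p_raw) for the two-sided test. Probes with
FDR-adjusted p < alpha in both cohorts are core.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import binom

from .associations import bh_fdr

logger = logging.getLogger("immunomap.core_genes")


def module_membership(probe_values: pd.Series | np.ndarray,
                      eigengene: pd.Series | np.ndarray) -> float:
    """Pearson correlation between a probe's expression and a module eigengene."""
    x = np.asarray(probe_values, float)
    y = np.asarray(eigengene, float)
    if x.shape != y.shape:
        raise ValueError("probe and eigengene must cover the same samples")
    if x.std() == 0:
        raise ValueError("constant probe: module membership undefined")
    return float(np.corrcoef(x, y)[0, 1])


def permutation_pvalue(b: int, v: int, two_sided: bool = True) -> float:
    """Exact permutation p-value estimator with finite-permutation bias correction.

    ``b``: exceedance count (the smaller tail); ``v``: null-draw count.
    The integral is evaluated by adaptive quadrature to 1e-12 absolute
    tolerance; for b = 0 the closed form
    (1 - (1 - c)^(v+1)) / (v + 1), c = 0.5/(v+1), is used.
    """
    b, v = int(b), int(v)
    if v < 1:
        raise ValueError("v must be at least 1")
    if b < 0 or b > v:
        raise ValueError("b must satisfy 0 <= b <= v")
    c = 0.5 / (v + 1)
    if b == 0:
        integral = (1.0 - (1.0 - c) ** (v + 1)) / (v + 1)
    elif b == v:
        integral = c  # CDF is identically 1
    else:
        integral, _ = quad(lambda x: binom.cdf(b, v, x), 0.0, c,
                           epsabs=1e-12, limit=200)
    p_raw = (b + 1.0) / (v + 1.0) - integral
    p = 2.0 * p_raw if two_sided else p_raw
    return float(min(1.0, p))


def core_gene_scan(module_sets: dict, expression_adjusted: dict,
                   fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Two-cohort core-gene scan.

    Parameters
    ----------
    module_sets : dataset name -> ModuleSet; the module definitions (from
        discovery) must use shared probe identifiers across datasets. The
        first dataset's assignment defines module probe sets; eigengenes
        are recomputed per dataset via each ModuleSet's eigengenes table.
    expression_adjusted : dataset name -> probes x samples matrix.

    Returns a tidy frame with one row per (dataset, module, probe):
    kME, b, v, raw two-sided p, per-module BH-adjusted p, per-dataset
    core flag, and the final flag (core in every dataset).
    """
    datasets = list(module_sets)
    if len(datasets) < 1:
        raise ValueError("at least one dataset is required")
    ref = module_sets[datasets[0]]
    rows = []
    for ds in datasets:
        expr = expression_adjusted[ds]
        eigengenes = module_sets[ds].eigengenes
        X = expr.to_numpy(float)
        sd = X.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.all():
            logger.warning("excluding %d constant probe(s) in %s", (~ok).sum(), ds)
        Z = ((X[ok].T - X[ok].mean(axis=1)) / sd[ok])  # samples x probes
        probes = expr.index[ok]
        n = Z.shape[0]
        for module in eigengenes.columns:
            members = ref.assignment.index[ref.assignment == module]
            members = members.intersection(probes)
            e = eigengenes[module].to_numpy(float)
            e = (e - e.mean()) / e.std(ddof=1)
            kme_all = pd.Series(Z.T @ e / (n - 1), index=probes)
            null = kme_all.drop(members, errors="ignore").to_numpy()
            v = len(null)
            if v == 0:
                raise ValueError(f"module {module} has no non-module probes in {ds}")
            null_sorted = np.sort(null)
            k = kme_all[members].to_numpy()
            n_ge = v - np.searchsorted(null_sorted, k, side="left")
            n_le = np.searchsorted(null_sorted, k, side="right")
            b = np.minimum(n_ge, n_le)
            pvals = np.array([permutation_pvalue(int(bi), v) for bi in b])
            padj = bh_fdr(pvals)
            for probe, kk, bi, p, pa in zip(members, k, b, pvals, padj):
                rows.append({"dataset": ds, "module": module, "probe": probe,
                             "kme": kk, "b": int(bi), "v": v, "p": p, "p_adj": pa,
                             "core_in_dataset": pa < fdr_alpha})
    result = pd.DataFrame(rows)
    final = result.groupby(["module", "probe"])["core_in_dataset"].agg(
        lambda s: bool(s.all()) and len(s) == len(datasets))
    result = result.merge(final.rename("core").reset_index(), on=["module", "probe"])
    return result


def core_sets(scan: pd.DataFrame) -> dict[str, list]:
    """Module -> sorted list of core probes, from a core_gene_scan result."""
    out = {}
    for module, grp in scan[scan["core"]].groupby("module"):
        out[module] = sorted(grp["probe"].unique())
    return out
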