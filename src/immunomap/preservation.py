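"""Permutation test of seven module preservation statistics.

A discovery module is tested for preservation in an independent dataset
by comparing seven density and connectivity statistics of the module's
probes against an empirical null built from random probe sets of equal
size drawn from the test dataset's non-module probes. A module is
declared preserved when all seven one-sided permutation p-values fall
below alpha.

With corD / corT the module submatrices of the discovery / test
correlation matrices, aD = |corD|^beta_discovery, aT = |corT|^beta_test,
uD / uT the node contributions (correlation of each probe with the
module eigengene computed in that dataset, obtained as sqrt(lambda_1)
times the leading eigenvector of the correlation submatrix), and
kD / kT the intramodular weighted degrees (row sums of the off-diagonal
adjacency):

    avg_weight  = mean off-diagonal aT
    coherence   = mean(uT^2)
    avg_cor     = mean over pairs of corT * sign(corD)
    avg_contrib = mean over probes of uT * sign(uD)
    cor_cor     = Pearson cor of lower-triangle corD vs corT
    cor_degree  = Pearson cor of kD vs kT
    cor_contrib = Pearson cor of uD vs uT

The sign-aware forms penalize anti-correlated "replication".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("immunomap.preservation")

STATISTICS = ("avg_weight", "coherence", "avg_cor", "avg_contrib",
              "cor_cor", "cor_degree", "cor_contrib")


@dataclass
class PreservationResult:
    observed: pd.DataFrame    # modules x 7 statistics
    p_values: pd.DataFrame    # modules x 7 statistics
    n_permutations: int
    alpha: float

    @property
    def preserved(self) -> pd.Series:
        return (self.p_values < self.alpha).all(axis=1)


def _node_contribution(cor_sub: np.ndarray) -> np.ndarray:
    """kME of each probe against the probe set's own eigengene, from the
    correlation submatrix: sqrt(lambda_1) * v_1, sign-fixed to mean >= 0."""
    vals, vecs = np.linalg.eigh(cor_sub)
    lam1 = vals[-1]
    u = np.sqrt(max(lam1, 0.0)) * vecs[:, -1]
    if u.mean() < 0:
        u = -u
    return u


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _stats_from_submatrices(corD: np.ndarray, corT: np.ndarray,
                            beta_discovery: int, beta_test: int) -> np.ndarray:
    m = corD.shape[0]
    iu = np.triu_indices(m, k=1)
    aD = np.abs(corD) ** beta_discovery
    aT = np.abs(corT) ** beta_test
    np.fill_diagonal(aD, 0.0)
    np.fill_diagonal(aT, 0.0)
    kD = aD.sum(axis=1)
    kT = aT.sum(axis=1)
    uD = _node_contribution(corD)
    uT = _node_contribution(corT)
    avg_weight = float(aT[iu].mean())
    coherence = float((uT ** 2).mean())
    avg_cor = float((corT[iu] * np.sign(corD[iu])).mean())
    avg_contrib = float((uT * np.sign(uD)).mean())
    cor_cor = _pearson(corD[iu], corT[iu])
    cor_degree = _pearson(kD, kT)
    cor_contrib = _pearson(uD, uT)
    return np.array([avg_weight, coherence, avg_cor, avg_contrib,
                     cor_cor, cor_degree, cor_contrib])


def preservation_statistics(discovery_cor: pd.DataFrame, test_cor: pd.DataFrame,
                            probe_set, beta_discovery: int, beta_test: int
                            ) -> pd.Series:
    """The seven observed statistics for one probe set."""
    probe_set = pd.Index(probe_set)
    if len(probe_set) < 2:
        raise ValueError("probe_set must contain at least 2 probes")
    missing = probe_set.difference(test_cor.index)
    if len(missing):
        raise KeyError(f"probes missing in test dataset: {list(missing)}")
    missing_d = probe_set.difference(discovery_cor.index)
    if len(missing_d):
        raise KeyError(f"probes missing in discovery dataset: {list(missing_d)}")
    corD = discovery_cor.loc[probe_set, probe_set].to_numpy(float)
    corT = test_cor.loc[probe_set, probe_set].to_numpy(float)
    vals = _stats_from_submatrices(corD, corT, beta_discovery, beta_test)
    return pd.Series(vals, index=list(STATISTICS))


def permutation_preservation(discovery_cor: pd.DataFrame, test_cor: pd.DataFrame,
                             assignment: pd.Series, beta_discovery: int,
                             beta_test: int, n_perm: int = 20000,
                             alpha: float = 0.001, seed: int | None = 0,
                             background_label: str = "background"
                             ) -> PreservationResult:
    """Permutation preservation test for every module in ``assignment``.

    Nulls draw ``n_perm`` probe sets of matching size, without
    replacement per draw, from the test-dataset probes outside the
    module; p = (#{null >= observed} + 1) / (n_perm + 1), one-sided
    greater, per statistic. Exactly reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    modules = sorted(set(assignment) - {background_label})
    test_probes = test_cor.index
    CT = test_cor.to_numpy(float)
    obs_rows, p_rows = {}, {}
    for module in modules:
        probe_set = assignment.index[assignment == module]
        obs = preservation_statistics(discovery_cor, test_cor, probe_set,
                                      beta_discovery, beta_test)
        corD = discovery_cor.loc[probe_set, probe_set].to_numpy(float)
        pool = np.where(~test_probes.isin(probe_set))[0]
        m = len(probe_set)
        if len(pool) < m:
            raise ValueError(f"module {module} larger than available null probes")
        exceed = np.zeros(len(STATISTICS))
        for _ in range(n_perm):
            draw = rng.choice(pool, size=m, replace=False)
            corT_null = CT[np.ix_(draw, draw)]
            null_vals = _stats_from_submatrices(corD, corT_null,
                                                beta_discovery, beta_test)
            exceed += null_vals >= obs.to_numpy()
        p_rows[module] = (exceed + 1.0) / (n_perm + 1.0)
        obs_rows[module] = obs.to_numpy()
        logger.info("preservation %s: min p = %.3g", module, p_rows[module].min())
    observed = pd.DataFrame(obs_rows, index=list(STATISTICS)).T
    p_values = pd.DataFrame(p_rows, index=list(STATISTICS)).T
    return PreservationResult(observed=observed, p_values=p_values,
                              n_permutations=n_perm, alpha=alpha)


def correlation_structure_similarity(dataset_a: pd.DataFrame,
                                     dataset_b: pd.DataFrame,
                                     variable_set=None) -> float:
    """Pearson correlation between the lower-triangle correlation vectors
    of two datasets (samples x variables) over their shared variables."""
    if variable_set is None:
        variable_set = dataset_a.columns.intersection(dataset_b.columns)
    variable_set = pd.Index(variable_set)
    if len(variable_set) < 3:
        raise ValueError("at least 3 shared variables are required")
    ca = np.corrcoef(dataset_a[variable_set].to_numpy(float).T)
    cb = np.corrcoef(dataset_b[variable_set].to_numpy(float).T)
    il = np.tril_indices(len(variable_set), k=-1)
    return _pearson(ca[il], cb[il])
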