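"""Module-QTL and cis/trans eQTL scans with meta-analysis.

Per cohort, a module eigengene (or a probe's expression) is regressed on
the minor-allele dosage of each SNP under an additive model, adjusting
for age, sex and the first ten genetic principal components computed
from an LD-pruned standardized dosage matrix. Cohort p-values are
combined by the sample-size-weighted Z-score method
(z_i = sign_i * Phi^-1(1 - p_i/2), Z = sum sqrt(n_i) z_i / sqrt(sum n_i))
with genome-wide significance at 5e-8. cis/trans classification: cis
when the SNP lies within 1 Mb of the probe interval, trans when on a
different chromosome or more than 5 Mb away; the 1-5 Mb gap zone is
"neither" and excluded. cis significance uses a label-shuffling
permutation test on the meta p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("immunomap.qtl")

GENOME_WIDE = 5e-8
CIS_WINDOW = 1_000_000
TRANS_DISTANCE = 5_000_000


# ---------------------------------------------------------------------------
# genotype preparation
# ---------------------------------------------------------------------------

def _maf(dosages: np.ndarray) -> np.ndarray:
    freq = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def ld_prune(dosages: pd.DataFrame, positions: pd.DataFrame,
             window: int = 50, step: int = 5, r2_max: float = 0.2) -> pd.Index:
    """Greedy sliding-window LD pruning; returns the retained SNP ids.

    Monomorphic SNPs are excluded beforehand with a warning. Within each
    window of ``window`` SNPs (advancing by ``step``), while any pair has
    squared Pearson correlation above ``r2_max``, the member with the
    lower MAF is removed (ties: the later position). Deterministic.
    """
    if dosages.shape[1] < 2:
        raise ValueError("at least 2 SNPs are required")
    D = dosages.to_numpy(float)
    sd = np.nanstd(D, axis=0)
    mono = sd == 0
    if mono.any():
        import warnings
        warnings.warn(f"excluding {mono.sum()} monomorphic SNP(s) before pruning")
        dosages = dosages.loc[:, ~mono]
        D = D[:, ~mono]
    snps = list(dosages.columns)
    # order SNPs by (chrom, pos) so windows are genomic
    pos = positions.loc[snps]
    order = np.lexsort((pos["pos"].to_numpy(), pos["chrom"].astype(str).to_numpy()))
    snps = [snps[i] for i in order]
    D = D[:, order]
    mafs = _maf(D)
    pos_by_snp = {s: int(positions.loc[s, "pos"]) for s in snps}

    removed = set()
    start = 0
    while start < len(snps):
        idx = [i for i in range(start, min(start + window, len(snps)))
               if snps[i] not in removed]
        if len(idx) > 1:
            sub = D[:, idx]
            r = np.corrcoef(sub.T)
            while True:
                r2 = r ** 2
                np.fill_diagonal(r2, 0.0)
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                gi, gj = idx[i], idx[j]
                cand = (gi, gj)
                m_i, m_j = mafs[gi], mafs[gj]
                if m_i < m_j:
                    drop = gi
                elif m_j < m_i:
                    drop = gj
                else:
                    drop = max(cand, key=lambda g: pos_by_snp[snps[g]])
                removed.add(snps[drop])
                keep_mask = [g != drop for g in idx]
                idx = [g for g in idx if g != drop]
                if len(idx) < 2:
                    break
                r = r[np.ix_(keep_mask, keep_mask)]
        start += step
    kept = [s for s in snps if s not in removed]
    logger.info("ld_prune: kept %d / %d SNPs", len(kept), len(snps))
    return pd.Index(kept)


def genetic_pcs(dosages_pruned: pd.DataFrame, n_components: int = 10) -> pd.DataFrame:
    """Top principal-component scores of the standardized dosage matrix.

    Columns are orthogonal and ordered by decreasing eigenvalue.
    """
    if dosages_pruned.shape[0] < n_components:
        raise ValueError(f"fewer than {n_components} samples")
    if dosages_pruned.shape[1] < n_components:
        raise ValueError(f"fewer than {n_components} pruned SNPs")
    D = dosages_pruned.to_numpy(float)
    sd = D.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic SNP in pruned set")
    Z = (D - D.mean(axis=0)) / sd
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    return pd.DataFrame(scores, index=dosages_pruned.index,
                        columns=[f"PC{i + 1}" for i in range(n_components)])


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------

def _design(covariates: pd.DataFrame | None, pcs: pd.DataFrame | None,
            index: pd.Index) -> np.ndarray:
    cols = [np.ones(len(index))]
    for frame in (covariates, pcs):
        if frame is not None and frame.shape[1]:
            cols.append(frame.loc[index].to_numpy(float))
    return np.column_stack(cols)


def _fwl_scan(y: np.ndarray, G: np.ndarray, X: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column regression of y on [X, g] via Frisch-Waugh-Lovell.

    Returns (beta, se, p) arrays over the columns of G; identical to full
    OLS with residual df = n - X.shape[1] - 1.
    """
    n, k = X.shape
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gg = (G_r ** 2).sum(axis=0)
    df = n - k - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (G_r * y_r[:, None]).sum(axis=0) / gg
        rss = (y_r @ y_r) - beta ** 2 * gg
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / gg)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def mqtl_scan(eigengene: pd.Series, dosages: pd.DataFrame,
              covariates: pd.DataFrame | None = None,
              pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Additive-model scan of one outcome against every SNP.

    Per-SNP OLS of the outcome on dosage plus covariates/PCs; missing
    dosages are handled complete-case per SNP. SNPs with zero dosage
    variance in the analysis subset are skipped with a log line.
    Returns a frame indexed by SNP with beta, se, p, n, maf.
    """
    samples = eigengene.index
    y = eigengene.to_numpy(float)
    X = _design(covariates, pcs, samples)
    G = dosages.loc[samples].to_numpy(float)
    out = pd.DataFrame(index=dosages.columns,
                       columns=["beta", "se", "p", "n", "maf"], dtype=float)
    has_nan = np.isnan(G).any(axis=0)
    sd = np.nanstd(G, axis=0)
    skip = sd == 0
    if skip.any():
        logger.info("mqtl_scan: skipping %d zero-variance SNP(s)", int(skip.sum()))
    full = ~has_nan & ~skip
    if full.any():
        beta, se, p = _fwl_scan(y, G[:, full], X)
        out.loc[dosages.columns[full], "beta"] = beta
        out.loc[dosages.columns[full], "se"] = se
        out.loc[dosages.columns[full], "p"] = p
        out.loc[dosages.columns[full], "n"] = len(y)
    for j in np.where(has_nan & ~skip)[0]:
        m = ~np.isnan(G[:, j])
        if G[m, j].std() == 0:
            continue
        beta, se, p = _fwl_scan(y[m], G[m, j][:, None], X[m])
        out.iloc[j, :4] = [beta[0], se[0], p[0], int(m.sum())]
    out["maf"] = _maf(G)
    return out.dropna(subset=["p"])


def weighted_z_meta(studies) -> tuple[float, float]:
    """Sample-size-weighted Z-score meta-analysis of (p, effect_sign, n) triples.

    Returns (Z, two-sided meta p).
    """
    studies = list(studies)
    zs, ns = [], []
    for p, sign, n in studies:
        if not (0 < p <= 1):
            raise ValueError("p-values must lie in (0, 1]; for p = 0 pass the "
                             "underlying test statistic instead")
        if sign not in (-1, 1):
            raise ValueError("effect_sign must be -1 or +1")
        if n < 1:
            raise ValueError("n must be at least 1")
        zs.append(sign * stats.norm.isf(p / 2.0))
        ns.append(float(n))
    zs, ns = np.asarray(zs), np.asarray(ns)
    Z = float((np.sqrt(ns) * zs).sum() / np.sqrt(ns.sum()))
    p_meta = float(2.0 * stats.norm.sf(abs(Z)))
    return Z, p_meta


def meta_scan(per_cohort: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-cohort mqtl_scan results by weighted-Z over shared SNPs."""
    shared = per_cohort[0].index
    for df in per_cohort[1:]:
        shared = shared.intersection(df.index)
    rows = {}
    for snp in shared:
        studies = [(df.loc[snp, "p"], 1 if df.loc[snp, "beta"] >= 0 else -1,
                    df.loc[snp, "n"]) for df in per_cohort]
        studies = [(max(p, np.nextafter(0, 1)), s, n) for p, s, n in studies]
        rows[snp] = weighted_z_meta(studies)
    out = pd.DataFrame(rows, index=["meta_z", "meta_p"]).T
    out.index.name = per_cohort[0].index.name
    return out


# ---------------------------------------------------------------------------
# cis / trans classification and eQTL scans
# ---------------------------------------------------------------------------

def classify_locus(snp_chrom: str, snp_pos: int, probe_chrom: str,
                   probe_start: int, probe_end: int) -> str:
    """cis / trans / neither for a SNP against a probe interval.

    cis: same chromosome and distance to the nearest interval boundary
    <= 1 Mb (0 inside); trans: different chromosome or distance > 5 Mb;
    the 1-5 Mb gap zone is "neither".
    """
    for c in (snp_chrom, probe_chrom):
        if not isinstance(c, str) or not c:
            raise ValueError(f"unknown chromosome: {c!r}")
    if snp_chrom != probe_chrom:
        return "trans"
    if probe_start <= snp_pos <= probe_end:
        distance = 0
    else:
        distance = min(abs(snp_pos - probe_start), abs(snp_pos - probe_end))
    if distance <= CIS_WINDOW:
        return "cis"
    if distance > TRANS_DISTANCE:
        return "trans"
    return "neither"


def trans_eqtl(snp: str, module_probes, cohorts: list[dict],
               gw_threshold: float = GENOME_WIDE) -> pd.DataFrame:
    """Weighted-Z meta eQTL scan of one mQTL against trans-classified probes.

    Each cohort dict carries ``expression`` (probes x samples),
    ``dosages``, optional ``covariates`` and ``pcs``, plus
    ``probe_positions`` / ``snp_positions``. Probes classified cis or in
    the gap zone are excluded. Returns probe-indexed meta results with
    the significance flag at ``gw_threshold``.
    """
    pp = cohorts[0]["probe_positions"]
    sp = cohorts[0]["snp_positions"]
    schrom, spos = sp.loc[snp, "chrom"], int(sp.loc[snp, "pos"])
    targets = [probe for probe in module_probes
               if classify_locus(schrom, spos, pp.loc[probe, "chrom"],
                                 int(pp.loc[probe, "start"]),
                                 int(pp.loc[probe, "end"])) == "trans"]
    if not targets:
        logger.info("trans_eqtl %s: no trans probes", snp)
        return pd.DataFrame(columns=["meta_z", "meta_p", "significant"])
    rows = {}
    for probe in targets:
        studies = []
        for c in cohorts:
            y = c["expression"].loc[probe]
            res = mqtl_scan(y, c["dosages"][[snp]], c.get("covariates"), c.get("pcs"))
            p = max(float(res.loc[snp, "p"]), np.nextafter(0, 1))
            sign = 1 if res.loc[snp, "beta"] >= 0 else -1
            studies.append((p, sign, res.loc[snp, "n"]))
        rows[probe] = weighted_z_meta(studies)
    out = pd.DataFrame(rows, index=["meta_z", "meta_p"]).T
    out["significant"] = out["meta_p"] < gw_threshold
    return out


def cis_eqtl_permutation(snp: str, probe: str, cohorts: list[dict],
                         n_perm: int = 10000, seed: int | None = 0) -> float:
    """Label-shuffling permutation p-value for a cis pair, meta-analyzed.

    For each permutation the expression sample labels are shuffled (one
    shared shuffle-index stream from the seed, applied per cohort), the
    per-cohort models refit, and the permuted per-cohort p-values
    combined by weighted-Z; the empirical p-value is
    (#{meta-p_perm <= meta-p_observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    prep = []
    obs_studies = []
    for c in cohorts:
        y = c["expression"].loc[probe].to_numpy(float)
        samples = c["expression"].columns
        X = _design(c.get("covariates"), c.get("pcs"), samples)
        g = c["dosages"].loc[samples, snp].to_numpy(float)[:, None]
        beta, se, p = _fwl_scan(y, g, X)
        obs_studies.append((max(float(p[0]), np.nextafter(0, 1)),
                            1 if beta[0] >= 0 else -1, len(y)))
        prep.append((y, g, X))
    _, p_obs = weighted_z_meta(obs_studies)
    hits = 0
    for _ in range(n_perm):
        studies = []
        for (y, g, X), (_, _, n) in zip(prep, obs_studies):
            perm = rng.permutation(len(y))
            beta, se, p = _fwl_scan(y[perm], g, X)
            studies.append((max(float(p[0]), np.nextafter(0, 1)),
                            1 if beta[0] >= 0 else -1, n))
        _, p_perm = weighted_z_meta(studies)
        if p_perm <= p_obs:
            hits += 1
    return (hits + 1.0) / (n_perm + 1.0)


def conditional_scan(eigengene: pd.Series, dosages: pd.DataFrame,
                     covariates: pd.DataFrame | None, pcs: pd.DataFrame | None,
                     condition_on: pd.DataFrame | None) -> pd.DataFrame:
    """Re-run an mQTL scan with conditioning variables added as covariates.

    Returns the scan with the conditioning applied; with an empty
    conditioning set this is the identity.
    """
    if condition_on is None or condition_on.shape[1] == 0:
        return mqtl_scan(eigengene, dosages, covariates, pcs)
    missing = condition_on.index.symmetric_difference(eigengene.index)
    if len(missing):
        raise ValueError("conditioning variable missing for some samples")
    cov = condition_on if covariates is None else covariates.join(condition_on)
    return mqtl_scan(eigengene, dosages, cov, pcs)
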