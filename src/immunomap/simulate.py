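"""Synthetic two-cohort multi-omic data generator.

Emulates the study design that the rest of the package analyses: two
population cohorts of unequal size sharing planted gene-coexpression
modules (a latent-factor model), a follow-up re-sampling of a subset of
cohort 1, metabolite measures linearly coupled to the module factors,
and SNPs with additive trans effects on module factors (mQTLs) plus a
handful of cis effects on single probes.

Model
-----
For each planted module ``m`` a per-sample latent factor is drawn as

    f_m = gamma * (dosage - 2*MAF) + 0.1*age_std + 0.1*sex_std + N(0, 1)

and each member probe ``g`` is expressed as

    x_g = lambda_g * f_m + noise_sd * N(0, 1)

with loadings ``lambda_g`` scattered around ``loading_mean`` and a 10%
random sign flip so that modules are imperfect. Background probes are
pure noise. Metabolite measures designated as associated with module
``m`` are readouts of the standardized factor,

    met_j = b * f_m_std + 0.1*age_std + 0.1*sex_std + sqrt(1 - b^2) * N(0, 1)

so the planted standardized effect equals ``b`` exactly. Genotypes are
drawn in Hardy-Weinberg proportions with independent SNPs except one
planted LD block (allelic correlation ~0.9, r^2 ~0.8). Cell counts are
generated correlated (r ~ 0.3) with designated module factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("immunomap.simulate")

BACKGROUND = "background"

_COVAR_EFFECT = 0.1  # direct age/sex effect (SD units) on factors and metabolites
_CELL_COUNT_R = 0.3  # correlation of cell counts with their designated factor
_LD_BLOCK_SIZE = 4
_LD_ALLELIC_R = 0.9  # allele-copy correlation, giving dosage r^2 ~ 0.8
_SIGN_FLIP_FRAC = 0.1
_LOADING_JITTER = 0.2


class ConfigurationError(ValueError):
    """A SimulationConfig invariant was violated; names the offending field."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated study: a discovery cohort of 500, a
    replication cohort of 1500, a 200-sample follow-up of cohort 1,
    2000 probes carrying 8 planted modules, 160 metabolite measures
    (159 + CRP) and 500 SNPs.
    """

    n_cohort1: int = 500
    n_cohort2: int = 1500
    n_followup: int = 200
    n_genes: int = 2000
    n_modules: int = 8
    module_sizes: list[int] | None = None  # drawn from 10..150 when None
    loading_mean: float = 0.7
    noise_sd: float = 1.0
    n_metabolites: int = 160
    n_assoc_metabolites_per_module: int = 5
    metabolite_effect: float = 0.3
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    mqtl_effect: float = 0.25
    n_cis_eqtl: int = 3
    cis_effect: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cohort1", "n_cohort2", "n_followup", "n_genes",
                     "n_modules", "n_metabolites", "n_snps"):
            if int(getattr(self, name)) < 0 or (
                    name not in ("n_modules",) and int(getattr(self, name)) == 0):
                raise ConfigurationError(f"{name} must be positive")
        if self.module_sizes is not None:
            if len(self.module_sizes) != self.n_modules:
                raise ConfigurationError("module_sizes length must equal n_modules")
            if any(s <= 0 for s in self.module_sizes):
                raise ConfigurationError("module_sizes entries must be positive")
            if sum(self.module_sizes) > self.n_genes:
                raise ConfigurationError("module_sizes sum exceeds n_genes")
        if self.n_followup > self.n_cohort1:
            raise ConfigurationError("n_followup exceeds n_cohort1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_assoc_metabolites_per_module * max(self.n_modules, 0) > self.n_metabolites:
            raise ConfigurationError(
                "n_assoc_metabolites_per_module * n_modules exceeds n_metabolites")


@dataclass
class CohortData:
    """Matched tables for one cohort at one time point, aligned on sample IDs."""

    expression: pd.DataFrame      # probes x samples
    metabolites: pd.DataFrame     # samples x measures
    genotypes: pd.DataFrame       # samples x SNPs, dosages in [0, 2]
    covariates: pd.DataFrame      # samples x {age, sex[, oc_use]}
    cell_counts: pd.DataFrame     # samples x {leukocytes, platelets}
    probe_positions: pd.DataFrame  # probe_id -> chrom, start, end (1-based incl.)
    snp_positions: pd.DataFrame    # snp_id -> chrom, pos (1-based)

    @property
    def samples(self) -> pd.Index:
        return self.covariates.index

    def validate(self) -> None:
        s = list(self.samples)
        for name in ("metabolites", "genotypes", "cell_counts"):
            if list(getattr(self, name).index) != s:
                raise ValueError(f"sample identifiers of {name} do not match covariates")
        if list(self.expression.columns) != s:
            raise ValueError("expression columns do not match covariates samples")
        if self.expression.index.duplicated().any():
            raise ValueError("duplicated probe identifiers")
        if self.genotypes.columns.duplicated().any():
            raise ValueError("duplicated SNP identifiers")
        dos = self.genotypes.to_numpy(float)
        if np.nanmin(dos) < 0 or np.nanmax(dos) > 2:
            raise ValueError("dosages outside [0, 2]")


@dataclass
class TruthTable:
    """Planted parameters, for recovery testing of every downstream stage."""

    module_membership: pd.Series          # probe -> module label or background
    loadings: pd.Series                   # probe -> signed loading (module probes)
    metabolite_effects: pd.DataFrame      # module, measure, b
    mqtl_effects: pd.DataFrame            # snp, module, gamma
    cis_effects: pd.DataFrame             # snp, probe, effect
    factor_values: dict = field(default_factory=dict)  # cohort -> samples x modules


def _draw_module_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    if config.module_sizes is not None:
        return [int(s) for s in config.module_sizes]
    sizes = []
    budget = config.n_genes
    for _ in range(config.n_modules):
        s = int(rng.integers(10, 151))
        sizes.append(s)
    total = sum(sizes)
    if total > budget:
        # shrink proportionally but keep >= 10
        sizes = [max(10, int(s * budget / (total + config.n_modules))) for s in sizes]
        if sum(sizes) > budget:
            raise ConfigurationError("n_genes too small for n_modules of size >= 10")
    return sizes


def _hardy_weinberg_genotypes(rng, n_samples, mafs):
    return rng.binomial(1, mafs, size=(n_samples, len(mafs))) + \
        rng.binomial(1, mafs, size=(n_samples, len(mafs)))


def _ld_block_genotypes(rng, anchor_alleles, maf):
    """Copy each allele of the anchor with prob r, else redraw; dosage r^2 ~ r_allele^2."""
    a1, a2 = anchor_alleles
    keep1 = rng.random(a1.shape) < _LD_ALLELIC_R
    keep2 = rng.random(a2.shape) < _LD_ALLELIC_R
    b1 = np.where(keep1, a1, rng.binomial(1, maf, a1.shape))
    b2 = np.where(keep2, a2, rng.binomial(1, maf, a2.shape))
    return b1 + b2


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def generate_cohorts(config: SimulationConfig) -> tuple[CohortData, CohortData, CohortData, TruthTable]:
    """Generate cohort 1, cohort 2, and the follow-up of a cohort-1 subset.

    All three datasets share the same planted parameters (memberships,
    loadings, effect sizes, QTL positions and cohort-1 genotypes for the
    follow-up) with independent noise. Fully deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = _draw_module_sizes(config, rng)
    modules = [f"M{i + 1}" for i in range(config.n_modules)]
    probes = pd.Index([f"probe{i + 1:05d}" for i in range(config.n_genes)], name="probe_id")

    membership = pd.Series(BACKGROUND, index=probes, name="module")
    order = rng.permutation(config.n_genes)
    pos = 0
    for m, s in zip(modules, sizes):
        membership.iloc[order[pos:pos + s]] = m
        pos += s

    loadings = pd.Series(0.0, index=probes, name="loading")
    in_mod = membership != BACKGROUND
    lam = config.loading_mean + rng.uniform(-_LOADING_JITTER, _LOADING_JITTER, in_mod.sum())
    signs = np.where(rng.random(in_mod.sum()) < _SIGN_FLIP_FRAC, -1.0, 1.0)
    loadings[in_mod] = lam * signs

    # ---- genome layout: each module's probes contiguous on its own chromosome,
    # background probes on chr20..22; SNPs spread over chr1..19.
    chrom = np.empty(config.n_genes, dtype=object)
    start = np.zeros(config.n_genes, dtype=int)
    for i, m in enumerate(modules):
        idx = np.where(membership.to_numpy() == m)[0]
        chrom[idx] = f"chr{i + 1}"
        start[idx] = 1_000_000 + 10_000 * np.arange(len(idx))
    bg_idx = np.where(~in_mod.to_numpy())[0]
    for j, gi in enumerate(bg_idx):
        chrom[gi] = f"chr{20 + (j % 3)}"
        start[gi] = 1_000_000 + 10_000 * (j // 3)
    probe_positions = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + 49}, index=probes)

    snps = pd.Index([f"rs{i + 1:06d}" for i in range(config.n_snps)], name="snp_id")
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, config.n_snps)
    snp_chrom = np.array([f"chr{10 + (i % 10)}" for i in range(config.n_snps)], dtype=object)
    snp_pos = 50_000_000 + 100_000 * (np.arange(config.n_snps) // 10)

    # planted effects -------------------------------------------------------
    n_mqtl = min(config.n_modules, config.n_snps)
    mqtl_rows = []
    for i in range(n_mqtl):
        # place the mQTL SNP on a different chromosome than its module's probes
        snp_i = i
        snp_chrom[snp_i] = f"chr{15 + (i % 5)}"
        mqtl_rows.append({"snp": snps[snp_i], "module": modules[i],
                          "gamma": config.mqtl_effect})
    mqtl_effects = pd.DataFrame(mqtl_rows, columns=["snp", "module", "gamma"])

    cis_rows = []
    n_cis = min(config.n_cis_eqtl, config.n_snps - n_mqtl, config.n_genes)
    cis_probe_idx = rng.choice(np.where(in_mod.to_numpy())[0], size=n_cis, replace=False) \
        if in_mod.sum() >= n_cis else rng.choice(config.n_genes, size=n_cis, replace=False)
    for j in range(n_cis):
        snp_i = n_mqtl + j
        gi = int(cis_probe_idx[j])
        snp_chrom[snp_i] = probe_positions["chrom"].iloc[gi]
        snp_pos[snp_i] = int(probe_positions["start"].iloc[gi]) + 5_000  # well inside 1 Mb
        cis_rows.append({"snp": snps[snp_i], "probe": probes[gi],
                         "effect": config.cis_effect})
    cis_effects = pd.DataFrame(cis_rows, columns=["snp", "probe", "effect"])

    # LD block: last _LD_BLOCK_SIZE SNPs tag the preceding anchor SNP; placed
    # contiguously on one chromosome so window-based pruning sees the block
    if config.n_snps > _LD_BLOCK_SIZE + n_mqtl + n_cis:
        ld_anchor = config.n_snps - _LD_BLOCK_SIZE - 1
        for t in range(_LD_BLOCK_SIZE + 1):
            snp_chrom[ld_anchor + t] = "chr19"
            snp_pos[ld_anchor + t] = 90_000_000 + 10_000 * t
    else:
        ld_anchor = None

    snp_positions = pd.DataFrame({"chrom": snp_chrom, "pos": snp_pos}, index=snps)

    met_names = [f"met{j + 1:03d}" for j in range(config.n_metabolites - 1)] + ["CRP"]
    met_rows = []
    k = config.n_assoc_metabolites_per_module
    for i, m in enumerate(modules):
        for j in range(k):
            met_rows.append({"module": m, "measure": met_names[i * k + j],
                             "b": config.metabolite_effect})
    metabolite_effects = pd.DataFrame(met_rows, columns=["module", "measure", "b"])

    truth = TruthTable(module_membership=membership, loadings=loadings,
                       metabolite_effects=metabolite_effects,
                       mqtl_effects=mqtl_effects, cis_effects=cis_effects)

    def _draw_cohort(name, n_samples, genotypes=None, covariates=None,
                     with_oc=True) -> CohortData:
        sample_ids = pd.Index([f"{name}_S{i + 1:05d}" for i in range(n_samples)],
                              name="sample_id")
        if genotypes is None:
            alleles1 = rng.binomial(1, mafs, size=(n_samples, config.n_snps))
            alleles2 = rng.binomial(1, mafs, size=(n_samples, config.n_snps))
            dos = alleles1 + alleles2
            if ld_anchor is not None:
                anchor = (alleles1[:, ld_anchor], alleles2[:, ld_anchor])
                for t in range(_LD_BLOCK_SIZE):
                    dos[:, ld_anchor + 1 + t] = _ld_block_genotypes(
                        rng, anchor, mafs[ld_anchor])
            genotypes = pd.DataFrame(dos.astype(float), index=sample_ids, columns=snps)
        else:
            genotypes = genotypes.copy()
            genotypes.index = sample_ids
        if covariates is None:
            age = rng.uniform(25, 74, n_samples)
            sex = rng.binomial(1, 0.5, n_samples).astype(float)
            cov = {"age": age, "sex": sex}
            if with_oc:
                cov["oc_use"] = (sex * rng.binomial(1, 0.2, n_samples)).astype(float)
            covariates = pd.DataFrame(cov, index=sample_ids)
        else:
            covariates = covariates.copy()
            covariates.index = sample_ids

        age_std = _standardize(covariates["age"].to_numpy())
        sex_std = _standardize(covariates["sex"].to_numpy())

        factors = np.empty((n_samples, config.n_modules))
        for i, m in enumerate(modules):
            f = _COVAR_EFFECT * age_std + _COVAR_EFFECT * sex_std + rng.normal(0, 1, n_samples)
            hit = mqtl_effects[mqtl_effects["module"] == m]
            for _, row in hit.iterrows():
                g = genotypes[row["snp"]].to_numpy()
                f = f + row["gamma"] * (g - g.mean())
            factors[:, i] = f
        factors_df = pd.DataFrame(factors, index=sample_ids, columns=modules)

        expr = config.noise_sd * rng.normal(0, 1, (config.n_genes, n_samples))
        lam_vec = loadings.to_numpy()
        mem = membership.to_numpy()
        for i, m in enumerate(modules):
            idx = np.where(mem == m)[0]
            expr[idx, :] += np.outer(lam_vec[idx], factors[:, i])
        for _, row in cis_effects.iterrows():
            gi = probes.get_loc(row["probe"])
            g = genotypes[row["snp"]].to_numpy()
            expr[gi, :] += row["effect"] * (g - g.mean())
        expression = pd.DataFrame(expr, index=probes, columns=sample_ids)

        mets = np.empty((n_samples, config.n_metabolites))
        assoc = {(r["module"], r["measure"]): r["b"] for _, r in metabolite_effects.iterrows()}
        fstd = {m: _standardize(factors[:, i]) for i, m in enumerate(modules)}
        for j, mn in enumerate(met_names):
            e = rng.normal(0, 1, n_samples)
            b_tot = 0.0
            signal = np.zeros(n_samples)
            for i, m in enumerate(modules):
                b = assoc.get((m, mn), 0.0)
                if b:
                    signal += b * fstd[m]
                    b_tot += b * b
            mets[:, j] = signal + _COVAR_EFFECT * age_std + _COVAR_EFFECT * sex_std \
                + math.sqrt(max(1.0 - b_tot, 0.05)) * e
        metabolites = pd.DataFrame(mets, index=sample_ids, columns=met_names)

        # cell counts track designated module factors (module 1 -> leukocytes,
        # module 2 -> platelets when present)
        def _counts(i_mod, base):
            e = rng.normal(0, 1, n_samples)
            if config.n_modules > i_mod:
                z = _CELL_COUNT_R * fstd[modules[i_mod]] + \
                    math.sqrt(1 - _CELL_COUNT_R ** 2) * e
            else:
                z = e
            return base * np.exp(0.2 * z)

        cell_counts = pd.DataFrame(
            {"leukocytes": _counts(0, 6.0), "platelets": _counts(1, 250.0)},
            index=sample_ids)

        data = CohortData(expression=expression, metabolites=metabolites,
                          genotypes=genotypes, covariates=covariates,
                          cell_counts=cell_counts, probe_positions=probe_positions,
                          snp_positions=snp_positions)
        truth.factor_values[name] = factors_df
        return data

    cohort1 = _draw_cohort("C1", config.n_cohort1)
    cohort2 = _draw_cohort("C2", config.n_cohort2)
    # follow-up: first n_followup cohort-1 samples, genotypes fixed, ages +7 years,
    # oral-contraceptive information unavailable at follow-up
    fu_samples = cohort1.samples[:config.n_followup]
    fu_geno = cohort1.genotypes.loc[fu_samples]
    fu_cov = cohort1.covariates.loc[fu_samples, ["age", "sex"]].copy()
    fu_cov["age"] = fu_cov["age"] + 7.0
    followup = _draw_cohort("FU", config.n_followup, genotypes=fu_geno,
                            covariates=fu_cov, with_oc=False)
    return cohort1, cohort2, followup, truth


# ---------------------------------------------------------------------------
# on-disk representation: TSVs + VCF 4.2 with a DS FORMAT field
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_cohort(data: CohortData, directory) -> dict[str, Path]:
    """Write one cohort as TSVs plus a dosage VCF; exact round-trip with read_cohort."""
    if len(data.samples) == 0:
        raise ValueError("cannot write a cohort with an empty sample set")
    data.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, index_label in (
            ("expression", data.expression, "probe_id"),
            ("metabolites", data.metabolites, "sample_id"),
            ("covariates", data.covariates, "sample_id"),
            ("cell_counts", data.cell_counts, "sample_id"),
            ("probe_positions", data.probe_positions, "probe_id"),
            ("snp_positions", data.snp_positions, "snp_id")):
        p = d / f"{name}.tsv"
        df.to_csv(p, sep="\t", index_label=index_label, float_format=_FLOAT_FMT,
                  na_rep="NA")
        paths[name] = p

    vcf = d / "genotypes.vcf"
    samples = list(data.samples)
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(data.snp_positions["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in data.genotypes.columns:
            chrom = data.snp_positions.loc[snp, "chrom"]
            pos = int(data.snp_positions.loc[snp, "pos"])
            doses = data.genotypes[snp].to_numpy()
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tDS\t"
                     + "\t".join(_fmt(x) for x in doses) + "\n")
    paths["genotypes"] = vcf
    return paths


def read_cohort(directory) -> CohortData:
    """Read a cohort directory written by write_cohort (VCF parsed with cyvcf2)."""
    import cyvcf2

    d = Path(directory)
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    expression.columns.name = "sample_id"
    metabolites = pd.read_csv(d / "metabolites.tsv", sep="\t", index_col=0)
    covariates = pd.read_csv(d / "covariates.tsv", sep="\t", index_col=0).astype(float)
    cell_counts = pd.read_csv(d / "cell_counts.tsv", sep="\t", index_col=0)
    probe_positions = pd.read_csv(d / "probe_positions.tsv", sep="\t", index_col=0)
    snp_positions = pd.read_csv(d / "snp_positions.tsv", sep="\t", index_col=0)

    reader = cyvcf2.VCF(str(d / "genotypes.vcf"))
    samples = list(reader.samples)
    ids, rows = [], []
    for variant in reader:
        ids.append(variant.ID)
        rows.append(np.asarray(variant.format("DS"), dtype=float).ravel())
    reader.close()
    genotypes = pd.DataFrame(np.asarray(rows).T, index=pd.Index(samples, name="sample_id"),
                             columns=pd.Index(ids, name="snp_id"))
    genotypes = genotypes.astype(float)
    return CohortData(expression=expression, metabolites=metabolites,
                      genotypes=genotypes, covariates=covariates,
                      cell_counts=cell_counts, probe_positions=probe_positions,
                      snp_positions=snp_positions)
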