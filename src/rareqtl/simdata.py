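"""Synthetic genotype / covariate / trait simulator.

Generates a study in the style of the restricted workshop design it stands
in for: 697 unrelated subjects drawn from 7 populations, gene regions made
mostly of rare variants, causal minor alleles that all push the trait in
one direction, covariate effects (sex, age, smoking, population), one
associated trait panel (Q1-like) and one pure-null panel (Q4-like), with a
single genotype panel shared by all trait replicates.

Haplotypes are produced by a latent first-order autoregressive Gaussian
process thresholded at per-variant allele frequencies, which yields
tunable adjacent-variant LD (including rare-common LD); per-population
logit-scale frequency jitter induces real stratification.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from rareqtl.io import (
    CovariateTable,
    GenotypeMatrix,
    TraitPanel,
    VariantInfo,
    write_covariates,
    write_gene_map,
    write_matrix,
    write_traits,
    write_vcf,
)

__all__ = [
    "CovariateEffects",
    "GeneSpec",
    "SimulatedGenotypes",
    "SimulationConfig",
    "gaw17_gene_specs",
    "load_config",
    "save_config",
    "simulate_covariates",
    "simulate_genotypes",
    "simulate_traits",
    "write_dataset",
]


@dataclass
class GeneSpec:
    """Architecture of one simulated gene region.

    The first ``n_causal_rare`` rare variants and first ``n_causal_common``
    common variants are causal with per-minor-allele effects ``beta_rare``
    and ``beta_common`` (non-negative: same-direction design).
    """

    gene: str
    n_rare: int
    n_causal_rare: int = 0
    n_common: int = 0
    n_causal_common: int = 0
    rare_maf_range: tuple[float, float] = (0.001, 0.009)
    common_maf_range: tuple[float, float] = (0.05, 0.35)
    beta_rare: float = 0.0
    beta_common: float = 0.0
    ld_rho: float = 0.2

    def __post_init__(self) -> None:
        if self.n_causal_rare > self.n_rare:
            raise ValueError(f"{self.gene}: n_causal_rare > n_rare")
        if self.n_causal_common > self.n_common:
            raise ValueError(f"{self.gene}: n_causal_common > n_common")
        if self.beta_rare < 0 or self.beta_common < 0:
            raise ValueError(f"{self.gene}: betas must be non-negative")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"{self.gene}: ld_rho must be in [0, 1)")
        for lo, hi in (self.rare_maf_range, self.common_maf_range):
            if not 0.0 < lo <= hi <= 0.5:
                if self.n_rare or self.n_common:
                    raise ValueError(f"{self.gene}: MAF ranges must lie in (0, 0.5]")

    @property
    def n_variants(self) -> int:
        return self.n_rare + self.n_common


@dataclass
class CovariateEffects:
    """Covariate contributions to the trait linear predictor (trait units)."""

    sex: float = 0.5
    age: float = 0.01
    smoking: float = 0.3
    population_shifts: list[float] | None = None

    def shifts(self, n_populations: int) -> np.ndarray:
        if self.population_shifts is not None:
            arr = np.asarray(self.population_shifts, dtype=float)
            if arr.size != n_populations:
                raise ValueError("population_shifts length != n_populations")
            return arr
        # symmetric spread around zero by default
        return 0.3 * (np.arange(n_populations) - (n_populations - 1) / 2.0)


@dataclass
class SimulationConfig:
    """Full study design: sample, populations, genes, effects, replicates."""

    gene_specs: list[GeneSpec] = field(default_factory=list)
    n_subjects: int = 697
    n_populations: int = 7
    population_weights: list[float] | None = None
    n_null_genes: int = 0
    null_gene_template: GeneSpec | None = None
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    noise_sd: float = 1.0
    n_replicates: int = 200
    strat_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.population_weights is not None:
            w = np.asarray(self.population_weights, dtype=float)
            if w.size != self.n_populations:
                raise ValueError("population_weights length != n_populations")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("population_weights must be non-negative and sum to 1")

    def weights(self) -> np.ndarray:
        if self.population_weights is None:
            return np.full(self.n_populations, 1.0 / self.n_populations)
        return np.asarray(self.population_weights, dtype=float)

    def all_gene_specs(self) -> list[GeneSpec]:
        """Configured genes plus ``n_null_genes`` effect-free filler genes."""
        specs = list(self.gene_specs)
        template = self.null_gene_template or GeneSpec(
            gene="NULL",
            n_rare=8,
            n_common=4,
            rare_maf_range=(0.001, 0.009),
            common_maf_range=(0.05, 0.3),
            ld_rho=0.2,
        )
        for i in range(self.n_null_genes):
            specs.append(
                dataclasses.replace(
                    template,
                    gene=f"NULL{i + 1:04d}",
                    n_causal_rare=0,
                    n_causal_common=0,
                    beta_rare=0.0,
                    beta_common=0.0,
                )
            )
        return specs


@dataclass
class SimulatedGenotypes:
    """Genotype panel plus the simulation truth needed to build traits."""

    genotypes: GenotypeMatrix
    variant_info: list[VariantInfo]
    causal_betas: dict[str, float]  # variant_id -> per-minor-allele effect


def _population_labels(config: SimulationConfig, seed: int) -> np.ndarray:
    """Population assignment shared by genotype and covariate simulation."""
    rng = np.random.default_rng([seed, 7919])
    return rng.choice(config.n_populations, size=config.n_subjects, p=config.weights())


def _gene_variants(
    spec: GeneSpec, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Variant ids, spec frequencies and causal betas for one gene, with the
    rare/common order shuffled so AR(1) adjacency mixes the two classes."""
    ids, freqs, betas = [], [], []
    for i in range(spec.n_rare):
        ids.append(f"{spec.gene}_r{i + 1}")
        freqs.append(rng.uniform(*spec.rare_maf_range))
        betas.append(spec.beta_rare if i < spec.n_causal_rare else 0.0)
    for i in range(spec.n_common):
        ids.append(f"{spec.gene}_c{i + 1}")
        freqs.append(rng.uniform(*spec.common_maf_range))
        betas.append(spec.beta_common if i < spec.n_causal_common else 0.0)
    order = rng.permutation(len(ids))
    return (
        [ids[j] for j in order],
        np.asarray(freqs)[order],
        np.asarray(betas)[order],
    )


def simulate_genotypes(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedGenotypes:
    """Simulate the genotype panel (fixed across trait replicates).

    Per gene: spec allele frequencies are drawn from the configured ranges,
    jittered per population on the logit scale (stratification), and two
    haplotypes per subject are generated from a latent AR(1) Gaussian with
    parameter ``ld_rho``.  Realized sample MAFs are recomputed afterwards,
    so a spec-rare variant may drift across a cutoff.
    """
    seed = config.seed if seed is None else seed
    specs = config.all_gene_specs()
    if not specs:
        raise ValueError("no gene specs configured")
    pops = _population_labels(config, seed)
    n = config.n_subjects
    rng = np.random.default_rng([seed, 11])

    variant_ids: list[str] = []
    genes: list[str] = []
    betas_all: list[float] = []
    columns: list[np.ndarray] = []
    for spec in specs:
        if spec.n_variants == 0:
            continue
        ids, freqs, betas = _gene_variants(spec, rng)
        m = len(ids)
        if (2 * n * freqs < 1.0).any():
            warnings.warn(
                f"gene {spec.gene}: some spec MAFs imply expected minor-allele "
                f"count < 1 at n={n}; variants may be monomorphic",
                stacklevel=2,
            )
        # per-population frequency jitter on the logit scale
        f_pop = expit(
            logit(freqs)[None, :]
            + rng.normal(0.0, config.strat_sd, size=(config.n_populations, m))
        )
        f_pop = np.clip(f_pop, 1e-6, 0.5)
        thresholds = norm.ppf(f_pop)  # (n_pop, m)

        dosage = np.zeros((n, m), dtype=np.int8)
        rho = spec.ld_rho
        scale = np.sqrt(1.0 - rho**2)
        for p in range(config.n_populations):
            rows = np.flatnonzero(pops == p)
            if rows.size == 0:
                continue
            nh = 2 * rows.size
            Z = np.empty((nh, m))
            Z[:, 0] = rng.standard_normal(nh)
            for j in range(1, m):
                Z[:, j] = rho * Z[:, j - 1] + scale * rng.standard_normal(nh)
            hap = (Z < thresholds[p][None, :]).astype(np.int8)
            dosage[rows] = hap[: rows.size] + hap[rows.size :]
        variant_ids.extend(ids)
        genes.extend([spec.gene] * m)
        betas_all.extend(betas)
        columns.append(dosage)

    dosage = np.concatenate(columns, axis=1)
    # orient to the minor allele (jitter can push a 0.5-range variant over)
    p_hat = dosage.mean(axis=0) / 2.0
    flip = p_hat > 0.5
    dosage[:, flip] = 2 - dosage[:, flip]
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(subject_ids, variant_ids, dosage)
    mafs = gm.mafs()
    info = [
        VariantInfo(variant_id=v, gene=g, maf=float(m_))
        for v, g, m_ in zip(variant_ids, genes, mafs)
    ]
    causal = {
        v: float(b) for v, b in zip(variant_ids, betas_all) if b > 0.0
    }
    return SimulatedGenotypes(genotypes=gm, variant_info=info, causal_betas=causal)


def simulate_covariates(
    config: SimulationConfig, seed: int | None = None
) -> CovariateTable:
    """Sex ~ Bernoulli(0.5), age ~ Normal(50, 10) truncated to [18, 90],
    smoking ~ Bernoulli(0.3), population from the configured weights."""
    seed = config.seed if seed is None else seed
    pops = _population_labels(config, seed)
    rng = np.random.default_rng([seed, 13])
    n = config.n_subjects
    sex = rng.binomial(1, 0.5, size=n)
    a, b = (18.0 - 50.0) / 10.0, (90.0 - 50.0) / 10.0
    age = truncnorm.rvs(a, b, loc=50.0, scale=10.0, size=n, random_state=rng)
    smoking = rng.binomial(1, 0.3, size=n)
    return CovariateTable(
        subject_ids=[f"S{i + 1:04d}" for i in range(n)],
        sex=sex,
        age=age,
        smoking=smoking,
        population=np.array([f"P{p + 1}" for p in pops]),
    )


def simulate_traits(
    sim: SimulatedGenotypes,
    covariates: CovariateTable,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[TraitPanel, TraitPanel]:
    """Simulate the associated (Q1-like) and null (Q4-like) trait panels.

    Both share the covariate linear predictor; the associated panel adds
    ``sum(beta_v * dosage_v)`` over causal variants.  Noise is redrawn per
    replicate; genotypes stay fixed.
    """
    seed = config.seed if seed is None else seed
    gm = sim.genotypes
    if covariates.subject_ids != gm.subject_ids:
        raise ValueError("covariates are not aligned with genotypes")
    n, R = gm.n_subjects, config.n_replicates
    eff = config.covariate_effects
    pop_levels = sorted(np.unique(covariates.population).tolist())
    shifts = eff.shifts(len(pop_levels))
    pop_idx = np.searchsorted(pop_levels, covariates.population)
    lp = (
        eff.sex * covariates.sex
        + eff.age * covariates.age
        + eff.smoking * covariates.smoking
        + shifts[pop_idx]
    )
    genetic = np.zeros(n)
    for vid, beta in sim.causal_betas.items():
        genetic += beta * gm.column(vid)

    rng = np.random.default_rng([seed, 17])
    q1 = lp[:, None] + genetic[:, None] + rng.normal(0.0, config.noise_sd, (n, R))
    q4 = lp[:, None] + rng.normal(0.0, config.noise_sd, (n, R))
    return (
        TraitPanel("Q1like", gm.subject_ids, q1),
        TraitPanel("Q4like", gm.subject_ids, q4),
    )


# ---------------------------------------------------------------------------
# Presets: nine risk-gene architectures (causal/total counts per cutoff)
# ---------------------------------------------------------------------------

# gene -> cutoff -> ((causal_rare, n_rare), (causal_common, n_common))
_RISK_GENE_TABLE: dict[str, dict[float, tuple[tuple[int, int], tuple[int, int]]]] = {
    "ARNT":   {0.005: ((4, 14), (1, 4)),  0.01: ((4, 15), (1, 3)),  0.05: ((5, 17), (0, 1))},
    "ELAVL4": {0.005: ((2, 7), (0, 3)),   0.01: ((2, 7), (0, 3)),   0.05: ((2, 8), (0, 2))},
    "FLT1":   {0.005: ((8, 24), (3, 11)), 0.01: ((8, 25), (3, 10)), 0.05: ((10, 32), (1, 3))},
    "FLT4":   {0.005: ((2, 8), (0, 2)),   0.01: ((2, 8), (0, 2)),   0.05: ((2, 10), (0, 0))},
    "HIF1A":  {0.005: ((3, 6), (1, 2)),   0.01: ((3, 7), (1, 1)),   0.05: ((4, 8), (0, 0))},
    "HIF3A":  {0.005: ((3, 13), (0, 8)),  0.01: ((3, 15), (0, 6)),  0.05: ((3, 17), (0, 4))},
    "KDR":    {0.005: ((8, 14), (2, 2)),  0.01: ((8, 14), (2, 2)),  0.05: ((9, 15), (1, 1))},
    "VEGFA":  {0.005: ((1, 5), (0, 1)),   0.01: ((1, 5), (0, 1)),   0.05: ((1, 6), (0, 0))},
    "VEGFC":  {0.005: ((1, 1), (0, 0)),   0.01: ((1, 1), (0, 0)),   0.05: ((1, 1), (0, 0))},
}


def gaw17_gene_specs(
    cutoff: float = 0.01,
    beta_rare: float = 0.5,
    beta_common: float = 0.3,
    ld_rho: float = 0.3,
) -> list[GeneSpec]:
    """The nine risk-gene architectures at one MAF cutoff.

    Causal/total variant counts follow the published per-gene table; effect
    sizes are free parameters (the source data's betas are not public).
    """
    if cutoff not in (0.005, 0.01, 0.05):
        raise ValueError("cutoff must be one of 0.005, 0.01, 0.05")
    specs = []
    for gene, by_cut in _RISK_GENE_TABLE.items():
        (cr, nr), (cc, nc) = by_cut[cutoff]
        specs.append(
            GeneSpec(
                gene=gene,
                n_rare=nr,
                n_causal_rare=cr,
                n_common=nc,
                n_causal_common=cc,
                rare_maf_range=(max(0.0008, cutoff / 10.0), 0.9 * cutoff),
                common_maf_range=(max(0.05, 2.0 * cutoff), 0.35),
                beta_rare=beta_rare if cr else 0.0,
                beta_common=beta_common if cc else 0.0,
                ld_rho=ld_rho,
            )
        )
    return specs


def null_study_config(
    n_genes: int = 110,
    n_replicates: int = 100,
    n_subjects: int = 697,
    seed: int = 0,
    ld_rho: float = 0.2,
) -> SimulationConfig:
    """Pure-null calibration study: genes with a spectrum of variant
    frequencies so every MAF cutoff yields both rare and common variants,
    no genetic effects, covariates + stratification on.

    Spec frequencies span (0.0015, 0.015) for the 'rare pool' plus five
    unambiguously common variants per gene; as the cutoff rises from 0.005
    to 0.05 the realized common set shrinks, which is what drives the
    selection-noise trend in the LASSO strategy.
    """
    template = GeneSpec(
        gene="NULL",
        n_rare=14,
        n_common=5,
        rare_maf_range=(0.0015, 0.015),
        common_maf_range=(0.06, 0.30),
        ld_rho=ld_rho,
    )
    return SimulationConfig(
        gene_specs=[],
        n_null_genes=n_genes,
        null_gene_template=template,
        n_subjects=n_subjects,
        n_replicates=n_replicates,
        seed=seed,
    )


def mixed_null_study_config(
    n_genes: int = 150,
    n_replicates: int = 30,
    n_subjects: int = 697,
    seed: int = 0,
    ld_rho: float = 0.2,
) -> SimulationConfig:
    """Exome-like pure-null study with heterogeneous gene sizes.

    Half the genes are tiny (1-4 rare variants, at most one common), a
    third medium, the rest large with many common variants — mimicking the
    genome-wide pool the empirical null is derived from, where most gene
    regions give the selection step nothing to work with.
    """
    rng = np.random.default_rng([seed, 23])
    specs = []
    for i in range(n_genes):
        u = rng.uniform()
        if u < 0.5:
            n_rare, n_common = int(rng.integers(1, 5)), int(rng.integers(0, 2))
        elif u < 0.8:
            n_rare, n_common = int(rng.integers(5, 11)), int(rng.integers(2, 5))
        else:
            n_rare, n_common = int(rng.integers(12, 19)), int(rng.integers(6, 13))
        specs.append(
            GeneSpec(
                gene=f"NULL{i + 1:04d}",
                n_rare=n_rare,
                n_common=n_common,
                rare_maf_range=(0.0015, 0.015),
                common_maf_range=(0.06, 0.30),
                ld_rho=ld_rho,
            )
        )
    return SimulationConfig(
        gene_specs=specs,
        n_subjects=n_subjects,
        n_replicates=n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization and dataset writing
# ---------------------------------------------------------------------------


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    for gs in d["gene_specs"]:
        gs["rare_maf_range"] = list(gs["rare_maf_range"])
        gs["common_maf_range"] = list(gs["common_maf_range"])
    if d["null_gene_template"] is not None:
        t = d["null_gene_template"]
        t["rare_maf_range"] = list(t["rare_maf_range"])
        t["common_maf_range"] = list(t["common_maf_range"])
    return d


def _spec_from_dict(d: dict) -> GeneSpec:
    d = dict(d)
    d["rare_maf_range"] = tuple(d.get("rare_maf_range", (0.001, 0.009)))
    d["common_maf_range"] = tuple(d.get("common_maf_range", (0.05, 0.35)))
    return GeneSpec(**d)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["gene_specs"] = [_spec_from_dict(g) for g in d.get("gene_specs", [])]
    if d.get("null_gene_template") is not None:
        d["null_gene_template"] = _spec_from_dict(d["null_gene_template"])
    if d.get("covariate_effects") is not None:
        d["covariate_effects"] = CovariateEffects(**d["covariate_effects"])
    return SimulationConfig(**d)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        return config_from_dict(d)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid simulation config {path}: {exc}") from exc


def write_dataset(
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int | None = None,
    genotype_format: str = "matrix",
) -> dict[str, Path]:
    """Simulate a full study and write it in the formats the I/O module
    reads.  Returns the mapping of artifact name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    sim = simulate_genotypes(config, seed)
    cov = simulate_covariates(config, seed)
    q1, q4 = simulate_traits(sim, cov, config, seed)

    paths: dict[str, Path] = {}
    if genotype_format == "matrix":
        paths["genotypes"] = out / "genotypes.tsv"
        write_matrix(sim.genotypes, paths["genotypes"])
    elif genotype_format == "vcf":
        paths["genotypes"] = out / "genotypes.vcf"
        write_vcf(sim.genotypes, paths["genotypes"])
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")
    paths["gene_map"] = out / "gene_map.tsv"
    write_gene_map(sim.variant_info, paths["gene_map"])
    paths["covariates"] = out / "covariates.tsv"
    write_covariates(cov, paths["covariates"])
    paths["trait_q1"] = out / "trait_q1like.tsv"
    write_traits(q1, paths["trait_q1"])
    paths["trait_q4"] = out / "trait_q4like.tsv"
    write_traits(q4, paths["trait_q4"])
    paths["truth"] = out / "causal_truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("variant_id\tbeta\n")
        for vid, beta in sim.causal_betas.items():
            fh.write(f"{vid}\t{beta}\n")
    return paths
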