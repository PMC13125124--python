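"""Synthetic RIL populations with planted QTL and multi-environment phenotypes.

The generator emulates a biparental soybean-style design: two fully
homozygous inbred parents that differ at every simulated SNP, a panel of
near-homozygous recombinant inbred lines (RILs) produced by repeated
selfing with Haldane (no-interference) meiosis, and plot-level phenotypes
from a randomized complete block design replicated across environments.

Phenotypes decompose as

    y(ril, env, block, trait) = mu_t + sum_q beta_qt * x(ril, q)
                                + g_poly(ril, t) + E(env, t)
                                + GEI(ril, env, t) + B(env, block, t) + eps

where x is the fraction of parent-B origin at the QTL position (0, 0.5 or
1), ``g_poly`` is a multivariate-normal polygenic value correlated across
traits, and the remaining terms are independent normals with configured
variances.  Planted QTL and the true parental-origin mosaic are returned
as a truth set for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genofilter import GenotypeMatrix

__all__ = [
    "PlantedQtl",
    "SimConfig",
    "TruthSet",
    "default_config",
    "simulate_genotypes",
    "simulate_phenotypes",
]

DEFAULT_TRAITS = ["protein", "cysteine", "methionine", "threonine", "lysine"]

# Trait scales loosely matching published soybean seed-composition ranges
# (% dry seed weight): means and genetic standard deviations.
_TRAIT_MEANS = {
    "protein": 43.5,
    "cysteine": 0.56,
    "methionine": 0.55,
    "threonine": 1.60,
    "lysine": 2.72,
}
_TRAIT_SD_G = {
    "protein": 1.10,
    "cysteine": 0.030,
    "methionine": 0.020,
    "threonine": 0.050,
    "lysine": 0.090,
}


@dataclass
class PlantedQtl:
    """A planted additive locus: ``effects[trait]`` is the trait shift per
    unit of parent-B origin fraction at ``position_bp``."""

    chrom: str
    position_bp: int
    effects: dict[str, float]


@dataclass
class SimConfig:
    n_chromosomes: int = 20
    chr_length_bp: int = 40_000_000
    snps_per_chr: int = 1000
    map_length_cM: float = 100.0
    n_rils: int = 150
    generations_selfing: int = 6
    n_environments: int = 4
    n_blocks: int = 2
    traits: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    trait_means: dict[str, float] = field(default_factory=dict)
    var_G: dict[str, float] = field(default_factory=dict)
    var_E: dict[str, float] = field(default_factory=dict)
    var_GEI: dict[str, float] = field(default_factory=dict)
    var_block: dict[str, float] = field(default_factory=dict)
    var_error: dict[str, float] = field(default_factory=dict)
    trait_cor: np.ndarray | None = None
    qtl: list[PlantedQtl] = field(default_factory=list)
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chr_length_bp, self.n_environments, self.n_blocks) <= 0:
            raise ValueError("dimensions must be positive")
        if self.snps_per_chr < 2:
            raise ValueError("snps_per_chr must be >= 2")
        if self.n_rils < 2:
            raise ValueError("n_rils must be >= 2")
        if self.map_length_cM < 0 or self.generations_selfing < 0:
            raise ValueError("map length and selfing generations must be non-negative")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.error_rate < 1:
            raise ValueError("rates must be in [0, 1)")
        k = len(self.traits)
        for comp in (self.var_G, self.var_E, self.var_GEI, self.var_block, self.var_error):
            for t, v in comp.items():
                if v < 0:
                    raise ValueError(f"negative variance for trait {t!r}")
        if self.trait_cor is None:
            self.trait_cor = np.eye(k)
        self.trait_cor = np.asarray(self.trait_cor, dtype=float)
        if self.trait_cor.shape != (k, k):
            raise ValueError("trait_cor shape must match number of traits")
        if not np.allclose(self.trait_cor, self.trait_cor.T):
            raise ValueError("trait_cor must be symmetric")
        if not np.allclose(np.diag(self.trait_cor), 1.0):
            raise ValueError("trait_cor must have unit diagonal")
        if np.linalg.eigvalsh(self.trait_cor).min() < -1e-8:
            raise ValueError("trait_cor must be positive semi-definite")
        for q in self.qtl:
            if not 1 <= q.position_bp <= self.chr_length_bp:
                raise ValueError(f"QTL position {q.position_bp} outside chromosome")

    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def environments(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_environments)]

    def ril_ids(self) -> list[str]:
        return [f"RIL{i + 1:03d}" for i in range(self.n_rils)]


@dataclass
class TruthSet:
    """Ground truth of a simulation run: the planted QTL, the parent-B
    origin dosage (0/1/2) of every RIL at every SNP, origin fractions at
    the QTL positions, and realized variance components per trait."""

    qtl: list[PlantedQtl]
    origin_dosage: np.ndarray  # (n_loci, n_rils) int8, counts of parent-B alleles
    qtl_fraction: np.ndarray  # (n_qtl, n_rils) in {0, 0.5, 1}
    realized_components: dict[str, dict[str, float]] = field(default_factory=dict)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-style defaults at desk scale: 20 chromosomes, 150 RILs,
    4 environments x 2 blocks, 5 positively correlated traits whose
    variance components give entry-mean heritability around 0.85, and
    three shared-effect QTL."""
    traits = list(DEFAULT_TRAITS)
    var_g = {t: _TRAIT_SD_G[t] ** 2 for t in traits}
    cfg = dict(
        traits=traits,
        trait_means=dict(_TRAIT_MEANS),
        var_G=var_g,
        var_E={t: v for t, v in var_g.items()},
        var_GEI={t: 0.5 * v for t, v in var_g.items()},
        var_block={t: 0.1 * v for t, v in var_g.items()},
        var_error={t: 0.7 * v for t, v in var_g.items()},
        trait_cor=np.full((5, 5), 0.6) + 0.4 * np.eye(5),
        qtl=[
            PlantedQtl("Chr01", 30_000_000, {t: 0.5 * _TRAIT_SD_G[t] for t in traits}),
            PlantedQtl("Chr02", 9_500_000, {t: 0.5 * _TRAIT_SD_G[t] for t in traits}),
            PlantedQtl("Chr15", 18_000_000, {t: 0.5 * _TRAIT_SD_G[t] for t in traits}),
        ],
        missing_rate=0.02,
        error_rate=0.002,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def _unique_sorted_positions(rng: np.random.Generator, length_bp: int, k: int) -> np.ndarray:
    """k distinct sorted 1-based positions; rejection sampling keeps memory
    O(k) even on long chromosomes."""
    if k > length_bp:
        raise ValueError("more SNPs requested than basepairs")
    pool = np.unique(rng.integers(1, length_bp + 1, size=2 * k + 16))
    while pool.size < k:
        pool = np.unique(np.concatenate([pool, rng.integers(1, length_bp + 1, size=2 * k)]))
    return np.sort(rng.permutation(pool)[:k])


def _meiosis(h1: np.ndarray, h2: np.ndarray, grid: np.ndarray, length_bp: int,
             map_cM: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a pair of homologs evaluated on a position grid.

    Crossover count is Poisson(map_cM / 100) with positions uniform along
    the chromosome (Haldane model); the gamete alternates between homologs
    at each crossover."""
    k = rng.poisson(map_cM / 100.0)
    start = rng.integers(2)
    if k == 0:
        return h1 if start == 0 else h2
    xs = np.sort(rng.uniform(0, length_bp, size=k))
    phase = (start + np.searchsorted(xs, grid)) % 2
    return np.where(phase == 0, h1, h2)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate parents and RIL genotypes.

    Parent A ("P1") carries the reference allele and parent B ("P2") the
    alternate allele at every SNP.  Each RIL starts as the F1 and is
    advanced by ``generations_selfing`` rounds of self-fertilisation, so
    residual heterozygosity is (1/2)^generations in expectation.  Optional
    missing-call and genotyping-error rates corrupt the emitted calls but
    never the returned truth mosaic.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 101])
    chroms = config.chrom_names()
    bases = np.array(list("ACGT"))

    loci_frames = []
    snp_grids = []
    qtl_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for qi, q in enumerate(config.qtl):
        if q.chrom not in qtl_by_chrom:
            raise ValueError(f"QTL chromosome {q.chrom!r} not simulated")
        qtl_by_chrom[q.chrom].append(qi)

    for chrom in chroms:
        pos = _unique_sorted_positions(rng, config.chr_length_bp, config.snps_per_chr)
        ref_idx = rng.integers(0, 4, size=config.snps_per_chr)
        alt_idx = (ref_idx + rng.integers(1, 4, size=config.snps_per_chr)) % 4
        loci_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": bases[ref_idx], "alt": bases[alt_idx]}
            )
        )
        snp_grids.append(pos.astype(float))

    n_loci = config.n_chromosomes * config.snps_per_chr
    n_qtl = len(config.qtl)
    origin = np.zeros((n_loci, config.n_rils), dtype=np.int8)
    qtl_frac = np.zeros((n_qtl, config.n_rils))

    for r in range(config.n_rils):
        offset = 0
        for ci, chrom in enumerate(chroms):
            qidx = qtl_by_chrom[chrom]
            grid = np.concatenate([snp_grids[ci], [float(config.qtl[qi].position_bp) for qi in qidx]])
            order = np.argsort(grid, kind="stable")
            grid_sorted = grid[order]
            h1 = np.zeros(grid_sorted.size, dtype=np.int8)
            h2 = np.ones(grid_sorted.size, dtype=np.int8)
            for _ in range(config.generations_selfing):
                g1 = _meiosis(h1, h2, grid_sorted, config.chr_length_bp, config.map_length_cM, rng)
                g2 = _meiosis(h1, h2, grid_sorted, config.chr_length_bp, config.map_length_cM, rng)
                h1, h2 = g1, g2
            dose_sorted = (h1 + h2).astype(np.int8)
            dose = np.empty_like(dose_sorted)
            dose[order] = dose_sorted
            origin[offset : offset + config.snps_per_chr, r] = dose[: config.snps_per_chr]
            for j, qi in enumerate(qidx):
                qtl_frac[qi, r] = dose[config.snps_per_chr + j] / 2.0
            offset += config.snps_per_chr

    calls = origin.copy()
    if config.error_rate > 0:
        err = rng.random(calls.shape) < config.error_rate
        calls = np.where(err, rng.integers(0, 3, size=calls.shape, dtype=np.int8), calls)
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate, np.int8(-1), calls)

    parents = np.concatenate(
        [np.zeros((n_loci, 1), dtype=np.int8), np.full((n_loci, 1), 2, dtype=np.int8)], axis=1
    )
    G = GenotypeMatrix(
        loci=pd.concat(loci_frames, ignore_index=True),
        samples=["P1", "P2"] + config.ril_ids(),
        calls=np.concatenate([parents, calls], axis=1),
    )
    truth = TruthSet(qtl=list(config.qtl), origin_dosage=origin, qtl_fraction=qtl_frac)
    return G, truth


def simulate_phenotypes(G: GenotypeMatrix, truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Simulate plot-level phenotypes for every (RIL, environment, block).

    Returns a long DataFrame with columns ril, environment, block, trait,
    value.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 202])
    traits = config.traits
    k = len(traits)
    n = config.n_rils
    chrom_set = set(G.loci["chrom"])
    for q in truth.qtl:
        if q.chrom not in chrom_set or not (G.loci["chrom"] == q.chrom).any():
            raise ValueError(f"QTL at {q.chrom}:{q.position_bp} has no simulated SNP on its chromosome")

    sd_g = np.sqrt([config.var_G.get(t, 0.0) for t in traits])
    cov = np.outer(sd_g, sd_g) * config.trait_cor
    g_poly = rng.multivariate_normal(np.zeros(k), cov, size=n, method="svd")  # (n, k)

    genetic = g_poly.copy()
    for qi, q in enumerate(truth.qtl):
        x = truth.qtl_fraction[qi]  # (n,)
        beta = np.array([q.effects.get(t, 0.0) for t in traits])
        genetic += np.outer(x, beta)

    envs = config.environments()
    e, b = config.n_environments, config.n_blocks
    env_eff = rng.standard_normal((e, k)) * np.sqrt([config.var_E.get(t, 0.0) for t in traits])
    blk_eff = rng.standard_normal((e, b, k)) * np.sqrt([config.var_block.get(t, 0.0) for t in traits])
    gei_eff = rng.standard_normal((n, e, k)) * np.sqrt([config.var_GEI.get(t, 0.0) for t in traits])
    eps = rng.standard_normal((n, e, b, k)) * np.sqrt([config.var_error.get(t, 0.0) for t in traits])
    mu = np.array([config.trait_means.get(t, 0.0) for t in traits])

    y = (
        mu[None, None, None, :]
        + genetic[:, None, None, :]
        + env_eff[None, :, None, :]
        + gei_eff[:, :, None, :]
        + blk_eff[None, :, :, :]
        + eps
    )

    rils = config.ril_ids()
    idx = pd.MultiIndex.from_product(
        [rils, envs, [f"B{i + 1}" for i in range(b)], traits],
        names=["ril", "environment", "block", "trait"],
    )
    long = pd.DataFrame({"value": y.reshape(-1)}, index=idx).reset_index()

    truth.realized_components = {
        t: {
            "var_G": float(np.var(genetic[:, j], ddof=1)),
            "var_GEI": float(np.var(gei_eff[:, :, j], ddof=1)),
            "var_error": float(np.var(eps[:, :, :, j], ddof=1)),
        }
        for j, t in enumerate(traits)
    }
    return long
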