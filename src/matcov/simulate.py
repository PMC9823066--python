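"""Synthetic mother-offspring cohort generator.

Implements the generative model behind the four-variable maternal/fetal
decomposition: each of two offspring phenotypes (birthweight ``bw`` and a
later-life cardiometabolic trait ``trait``) receives additive contributions
from the offspring's own (fetal) genome and from the mother's genome. The
four per-SNP standardized effect columns (F_BW, M_BW, F_T, M_T) are drawn
from a zero-mean multivariate normal whose covariance is the latent genetic
covariance matrix ``psi_true`` divided by the number of causal SNPs, so the
aggregate genetic (co)variances equal ``psi_true`` by construction.

Genotypes are simulated as haplotypes with within-block linkage
disequilibrium from a latent autoregressive Gaussian copula thresholded at
the allele-frequency quantile. Offspring receive one maternal haplotype
(chosen independently per LD block, i.e. free recombination between blocks
and none within) and one paternal haplotype. Because blocks are mutually
independent, the transmitted paternal haplotype is distributionally
identical to a fresh population haplotype, so fathers are never stored.
This yields the biometric mother-offspring genotype correlation of 0.5 at
every SNP under random mating.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_psd, spawn_rng

LATENT_NAMES = ("F_BW", "M_BW", "F_T", "M_T")

#: Default latent genetic covariance (order F_BW, M_BW, F_T, M_T).
#: Diagonal heritabilities are in the range reported for birthweight and
#: common cardiometabolic traits (roughly 0.05-0.15 on the observed scale);
#: the fetal birthweight-trait covariance is negative (fetal-insulin-type
#: pleiotropy) and the maternal one positive (Barker-type mechanism).
DEFAULT_PSI = np.array(
    [
        [0.15, 0.03, -0.04, 0.00],
        [0.03, 0.10, 0.00, 0.02],
        [-0.04, 0.00, 0.15, 0.01],
        [0.00, 0.02, 0.01, 0.05],
    ]
)

# covariate distributions are fixed; only the effect sizes are configurable
_COV_VAR = {"sex": 0.25, "age": 75.0, "batch": 0.25}  # sex +-0.5; age U(40,70); batch 0/1
DEFAULT_COVARIATE_EFFECTS = {
    "bw": {"sex": 0.10, "age": 0.0, "batch": 0.04},
    "trait": {"sex": 0.10, "age": 0.005, "batch": 0.04},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_pairs : genotyped mother-offspring pairs (the proxy-GWAS cohort).
    n_own : individuals in the own-genotype/own-phenotype cohort.
    m_snps : SNP count; must be divisible by ``ld_block_size``.
    maf : minor allele frequency specification: a scalar in (0, 0.5], a
        (low, high) tuple for per-SNP uniform draws, or an array of length
        ``m_snps``.
    ld_block_size : SNPs per LD block.
    ld_rho : adjacent-SNP latent (copula) correlation within a block, in
        [0, 1): a scalar applied to every block, or a (low, high) tuple for
        per-block uniform draws. The default range gives LD scores spanning
        roughly 1-12, emulating the strong heterogeneity of LD across the
        genome that LD score regression leans on for identification.
    prop_causal : fraction of SNPs with nonzero effects.
    psi_true : 4x4 symmetric PSD latent genetic covariance, order
        (F_BW, M_BW, F_T, M_T).
    env_var : per-trait residual variance ``{"bw": float, "trait": float}``;
        ``None`` completes each trait's variance budget to 1.
    covariate_effects : per-trait fixed effects of sex/age/batch.
    overlap : if True the own cohort is the offspring of the pair cohort
        (sample overlap between the two GWAS designs, as in a single-cohort
        family study).
    seed : integer seed; identical seeds reproduce bit-identical cohorts.
    """

    n_pairs: int = 20_000
    n_own: int = 20_000
    m_snps: int = 20_000
    maf: float | tuple | np.ndarray = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float | tuple = (0.0, 0.95)
    prop_causal: float = 1.0
    psi_true: np.ndarray = field(default_factory=lambda: DEFAULT_PSI.copy())
    env_var: dict | None = None
    covariate_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    overlap: bool = True
    seed: int = 0

    def __post_init__(self):
        self.psi_true = np.asarray(self.psi_true, dtype=float)
        if self.psi_true.shape != (4, 4):
            raise ValueError("psi_true must be 4x4 (order F_BW, M_BW, F_T, M_T)")
        check_psd(self.psi_true, "psi_true")
        rho = np.atleast_1d(np.asarray(self.ld_rho, dtype=float))
        if np.any(rho < 0) or np.any(rho >= 1):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.m_snps % self.ld_block_size != 0:
            raise ValueError("m_snps must be divisible by ld_block_size")
        if not 0 <= self.prop_causal <= 1:
            raise ValueError("prop_causal must be in [0, 1]")
        f = self.snp_freqs(np.random.default_rng(0))  # validation only
        if np.any(f <= 0) or np.any(f > 0.5):
            raise ValueError("allele frequencies must lie in (0, 0.5]")

    def snp_freqs(self, rng: np.random.Generator) -> np.ndarray:
        """Per-SNP population allele frequencies implied by ``maf``."""
        if np.isscalar(self.maf):
            return np.full(self.m_snps, float(self.maf))
        maf = np.asarray(self.maf, dtype=float)
        if maf.shape == (2,) and maf[0] < maf[1]:
            return rng.uniform(maf[0], maf[1], size=self.m_snps)
        if maf.shape == (self.m_snps,):
            return maf
        raise ValueError("maf must be a scalar, a (low, high) tuple, or length m_snps")

    def block_rhos(self, rng: np.random.Generator) -> np.ndarray:
        """Per-block copula correlations implied by ``ld_rho``."""
        n_blocks = self.m_snps // self.ld_block_size
        if np.isscalar(self.ld_rho):
            return np.full(n_blocks, float(self.ld_rho))
        lo, hi = self.ld_rho
        return rng.uniform(lo, hi, size=n_blocks)

    def structure(self) -> tuple[np.ndarray, np.ndarray]:
        """(freqs, block rhos): the population LD structure for this seed.

        Drawn from a dedicated stream so a reference panel simulated for the
        same config shares the structure while its haplotypes stay
        independent of the cohort's.
        """
        rng = spawn_rng(self.seed, 0)
        return self.snp_freqs(rng), self.block_rhos(rng)


@dataclass
class PairCohort:
    """A simulated cohort of genotyped mother-offspring pairs.

    ``own_dosages``/``own_phenotypes`` describe the own-phenotype GWAS
    cohort; under ``overlap=True`` they alias the offspring arrays.
    """

    config: SimConfig
    snp_map: pd.DataFrame
    mother_dosages: np.ndarray
    offspring_dosages: np.ndarray
    phenotypes: pd.DataFrame | None = None
    true_effects: np.ndarray | None = None
    own_dosages: np.ndarray | None = None
    own_phenotypes: pd.DataFrame | None = None
    own_mother_dosages: np.ndarray | None = None

    @property
    def psi_true(self) -> np.ndarray:
        return self.config.psi_true


def _haplotype_block(rng, n_sets, b, rho, thresholds):
    """(3, n_sets, b) haplotype alleles: two maternal + one paternal.

    The latent AR(1) recursion runs along contiguous rows of a (b, 3n)
    array; thresholding reuses the boolean buffer as int8 (same memory
    layout) to avoid a 1-byte-per-element copy.
    """
    e = rng.standard_normal((b, 3 * n_sets), dtype=np.float32)
    if rho > 0 and b > 1:
        s = np.float32(np.sqrt(1.0 - rho * rho))
        r = np.float32(rho)
        for k in range(1, b):
            e[k] *= s
            e[k] += r * e[k - 1]
    bits = np.less(e, thresholds.astype(np.float32)[:, None]).view(np.int8)
    return np.ascontiguousarray(bits.T).reshape(3, n_sets, b)


def _simulate_pairs(rng, n, cfg, freqs, rhos):
    """Mother and offspring dosage matrices for n pairs."""
    b = cfg.ld_block_size
    thr = stats.norm.ppf(freqs)
    mother = np.empty((n, cfg.m_snps), dtype=np.int8)
    offspring = np.empty((n, cfg.m_snps), dtype=np.int8)
    for blk, start in enumerate(range(0, cfg.m_snps, b)):
        m1, m2, pat = _haplotype_block(rng, n, b, rhos[blk], thr[start : start + b])
        # one maternal haplotype transmitted intact per block
        choice = rng.integers(0, 2, size=n).astype(bool)
        transmitted = np.where(choice[:, None], m2, m1)
        mother[:, start : start + b] = m1 + m2
        offspring[:, start : start + b] = transmitted + pat
    return mother, offspring


def simulate_reference_panel(config: SimConfig, n_ref: int) -> np.ndarray:
    """Independent genotype panel sharing the cohort's population structure.

    Same allele frequencies and per-block LD as the cohort of this config
    (the structure stream is keyed by the seed alone), but haplotypes drawn
    from a separate stream: an external LD reference, as in standard LD
    score regression practice.
    """
    freqs, rhos = config.structure()
    rng = spawn_rng(config.seed, 5)
    b = config.ld_block_size
    thr = stats.norm.ppf(freqs)
    out = np.empty((n_ref, config.m_snps), dtype=np.int8)
    for blk, start in enumerate(range(0, config.m_snps, b)):
        e = rng.standard_normal((b, 2 * n_ref), dtype=np.float32)
        rho = rhos[blk]
        if rho > 0 and b > 1:
            s, r = np.float32(np.sqrt(1 - rho * rho)), np.float32(rho)
            for k in range(1, b):
                e[k] *= s
                e[k] += r * e[k - 1]
        bits = np.less(e, thr[start : start + b].astype(np.float32)[:, None]).view(np.int8)
        hap = np.ascontiguousarray(bits.T)
        out[:, start : start + b] = hap[:n_ref] + hap[n_ref:]
    return out


def simulate_genotypes(config: SimConfig) -> PairCohort:
    """Generate genotypes and the SNP map (no phenotypes yet).

    Under ``overlap=False`` an independent second set of pairs of size
    ``n_own`` is generated for the own cohort; its mothers are kept (they
    are needed to form the maternal contribution to own phenotypes) but are
    not part of any GWAS.
    """
    rng = spawn_rng(config.seed, 1)
    freqs, rhos = config.structure()
    snp_map = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(config.m_snps)],
            "IDX": np.arange(config.m_snps),
            "A1": "A",
            "A2": "G",
            "FRQ": freqs,
        }
    )
    mother, offspring = _simulate_pairs(rng, config.n_pairs, config, freqs, rhos)
    cohort = PairCohort(config, snp_map, mother, offspring)
    if config.overlap:
        cohort.own_dosages = offspring
        if config.n_own > config.n_pairs:
            raise ValueError("overlap=True requires n_own <= n_pairs")
    elif config.n_own > 0:
        own_mother, own = _simulate_pairs(rng, config.n_own, config, freqs, rhos)
        cohort.own_dosages = own
        cohort.own_mother_dosages = own_mother
    return cohort


def simulate_effects(config: SimConfig) -> np.ndarray:
    """Per-SNP standardized effects, m_snps x 4 (F_BW, M_BW, F_T, M_T).

    Causal rows are iid 4-variate normal with covariance
    ``psi_true / n_causal`` so that the sum over SNPs of outer products of
    effect rows has expectation ``psi_true``.
    """
    check_psd(config.psi_true, "psi_true")
    rng = spawn_rng(config.seed, 2)
    beta = np.zeros((config.m_snps, 4))
    n_causal = max(1, int(round(config.prop_causal * config.m_snps)))
    causal = rng.choice(config.m_snps, size=n_causal, replace=False)
    w, u = np.linalg.eigh(config.psi_true)
    factor = u * np.sqrt(np.clip(w, 0, None))
    beta[np.sort(causal)] = rng.standard_normal((n_causal, 4)) @ factor.T / np.sqrt(n_causal)
    return beta


def _genetic_value(dosages, freqs, beta, chunk=4096):
    """dosages @ beta on the standardized-genotype scale, chunked over SNPs.

    ``beta`` may have several columns (one genetic value per column, single
    pass over the genotype matrix).
    """
    beta = np.atleast_2d(beta.T).T  # (m,) -> (m, 1)
    n = dosages.shape[0]
    out = np.zeros((n, beta.shape[1]))
    sd = np.sqrt(2 * freqs * (1 - freqs))
    for s in range(0, dosages.shape[1], chunk):
        x = dosages[:, s : s + chunk].astype(np.float32)
        b = (beta[s : s + chunk] / sd[s : s + chunk, None]).astype(np.float32)
        out += x @ b - (2 * freqs[s : s + chunk]) @ b
    return out


def _covariates(rng, n):
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n) - 0.5,
            "age": rng.uniform(40, 70, size=n),
            "batch": rng.integers(0, 2, size=n).astype(float),
        }
    )


def _trait_budget(cfg: SimConfig, trait: str) -> tuple[float, float]:
    """(genetic variance, covariate variance) for one trait."""
    i, j = (0, 1) if trait == "bw" else (2, 3)
    psi = cfg.psi_true
    # var = psi_FF + psi_MM + 2 * 0.5 * psi_FM  (mother-offspring corr 0.5)
    g = psi[i, i] + psi[j, j] + psi[i, j]
    c = sum(b * b * _COV_VAR[k] for k, b in cfg.covariate_effects[trait].items())
    return g, c


def residual_variances(config: SimConfig) -> dict:
    """Residual variance per trait; errors if the variance budget exceeds 1."""
    out = {}
    for trait in ("bw", "trait"):
        g, c = _trait_budget(config, trait)
        if config.env_var is not None:
            e = float(config.env_var[trait])
        else:
            e = 1.0 - g - c
        if g + c + e > 1 + 1e-9 or e < 0:
            raise ValueError(
                f"variance budget for {trait} exceeds 1: "
                f"genetic {g:.4f} + covariates {c:.4f} + residual {e:.4f}"
            )
        out[trait] = e
    return out


def _phenotype_table(rng, cfg, own_dos, mother_dos, freqs, beta, env):
    n = own_dos.shape[0]
    cov = _covariates(rng, n)
    tab = cov.copy()
    fetal = _genetic_value(own_dos, freqs, beta[:, [0, 2]])
    maternal = _genetic_value(mother_dos, freqs, beta[:, [1, 3]])
    for col, trait in enumerate(("bw", "trait")):
        y = fetal[:, col] + maternal[:, col]
        for k, b in cfg.covariate_effects[trait].items():
            y += b * cov[k].to_numpy()
        y += rng.standard_normal(n) * np.sqrt(env[trait])
        tab[trait] = y
    tab.insert(0, "iid", [f"i{k}" for k in range(n)])
    return tab


def simulate_phenotypes(cohort: PairCohort, true_effects: np.ndarray,
                        config: SimConfig | None = None) -> PairCohort:
    """Attach phenotypes to a genotyped cohort (completes the PairCohort).

    Offspring phenotype = standardized own dosages . fetal effects
    + standardized maternal dosages . maternal effects + covariate effects
    + independent Gaussian residual completing the variance budget.
    """
    cfg = config or cohort.config
    if true_effects.shape != (cfg.m_snps, 4):
        raise ValueError("true_effects must be m_snps x 4")
    env = residual_variances(cfg)
    rng = spawn_rng(cfg.seed, 3)
    freqs = cohort.snp_map["FRQ"].to_numpy()
    cohort.true_effects = true_effects
    cohort.phenotypes = _phenotype_table(
        rng, cfg, cohort.offspring_dosages, cohort.mother_dosages, freqs, true_effects, env
    )
    if cfg.overlap:
        cohort.own_phenotypes = cohort.phenotypes
    elif cohort.own_dosages is not None:
        cohort.own_phenotypes = _phenotype_table(
            rng, cfg, cohort.own_dosages, cohort.own_mother_dosages, freqs, true_effects, env
        )
    return cohort


def simulate_cohort(config: SimConfig) -> PairCohort:
    """Full pipeline: genotypes, effects, phenotypes."""
    cohort = simulate_genotypes(config)
    return simulate_phenotypes(cohort, simulate_effects(config), config)


def mendelian_violations(mother_dosages, offspring_dosages) -> int:
    """Count transmissions impossible under Mendelian inheritance.

    A homozygous mother must transmit her allele, so (mother 0, offspring 2)
    and (mother 2, offspring 0) cannot occur whatever the father carries.
    """
    m = np.asarray(mother_dosages)
    o = np.asarray(offspring_dosages)
    return int(np.count_nonzero((m == 0) & (o == 2)) + np.count_nonzero((m == 2) & (o == 0)))


def write_cohort(cohort: PairCohort, out_dir: str | Path) -> None:
    """Write the cohort as plain tab-delimited files (SNPs x individuals)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mat in (("mother_dosages", cohort.mother_dosages),
                      ("offspring_dosages", cohort.offspring_dosages)):
        pd.DataFrame(mat.T).to_csv(out / f"{name}.tsv", sep="\t", index=False, header=False)
    cohort.snp_map.to_csv(out / "snp_map.tsv", sep="\t", index=False)
    if cohort.phenotypes is not None:
        cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    if cohort.true_effects is not None:
        cols = [f"beta_{n}" for n in LATENT_NAMES]
        pd.DataFrame(cohort.true_effects, columns=cols).to_csv(
            out / "true_effects.tsv", sep="\t", index=False
        )
        pd.DataFrame(cohort.psi_true, index=LATENT_NAMES, columns=LATENT_NAMES).to_csv(
            out / "psi_true.tsv", sep="\t"
        )


def read_cohort(in_dir: str | Path, config: SimConfig | None = None) -> PairCohort:
    """Read a cohort written by :func:`write_cohort`."""
    p = Path(in_dir)
    snp_map = pd.read_csv(p / "snp_map.tsv", sep="\t")
    mother = pd.read_csv(p / "mother_dosages.tsv", sep="\t", header=None).to_numpy(np.int8).T
    off = pd.read_csv(p / "offspring_dosages.tsv", sep="\t", header=None).to_numpy(np.int8).T
    cfg = config or SimConfig(
        n_pairs=mother.shape[0], n_own=off.shape[0], m_snps=mother.shape[1],
        ld_block_size=mother.shape[1],
    )
    cohort = PairCohort(cfg, snp_map, mother, off, own_dosages=off)
    phen = p / "phenotypes.tsv"
    if phen.exists():
        cohort.phenotypes = pd.read_csv(phen, sep="\t")
        cohort.own_phenotypes = cohort.phenotypes
    eff = p / "true_effects.tsv"
    if eff.exists():
        cohort.true_effects = pd.read_csv(eff, sep="\t").to_numpy()
    return cohort


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a flat mapping (CLI/config-file entry point)."""
    d = dict(d)
    if "psi_true" in d:
        d["psi_true"] = np.asarray(d["psi_true"], dtype=float)
    if "maf" in d and isinstance(d["maf"], (list, tuple)):
        d["maf"] = tuple(d["maf"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**d)
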