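"""End-to-end orchestration: simulate -> GWAS -> LDSC -> SEM -> reports.

A single run produces the four summary-statistics sets (own birthweight,
offspring birthweight via maternal genotype, own trait, offspring trait via
maternal genotype), the genetic covariance stack (S, V), the fitted latent
model, and flat report tables: SNP heritabilities with the Z > 4
reliability note, latent heritabilities, the six genetic covariances and
genetic correlations with delta-method 95% CIs and out-of-bounds flags, and
a truth-vs-estimate appendix when the cohort carries ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import sem
from ._utils import vech, vech_indices
from .gwas import run_gwas_multi
from .ldsc import CovarianceStack, LDScores, build_S_V, compute_ld_scores, write_stack
from .sem import FitResult, fit_sem, genetic_correlations
from .simulate import (PairCohort, SimConfig, config_from_dict, simulate_cohort,
    simulate_reference_panel)
from .sumstats import SumStats, write_sumstats

COVARIATES = ["sex", "age", "batch"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (one birthweight-trait pair)."""

    sim: SimConfig = field(default_factory=SimConfig)
    trait_label: str = "SBP"
    n_blocks: int = 200
    ld_window: int | None = None  # default: the simulator's LD block size
    n_ref: int = 2000  # LD reference subsample of the mothers
    sem_method: str = "dwls"
    out_dir: str | None = None
    seed: int | None = None  # overrides sim.seed when set

    def __post_init__(self):
        if self.seed is not None and self.seed != self.sim.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.seed = self.sim.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = config_from_dict(raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"]["psi_true"] = np.asarray(d["sim"]["psi_true"]).tolist()
        if isinstance(d["sim"].get("maf"), np.ndarray):
            d["sim"]["maf"] = d["sim"]["maf"].tolist()
        d.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunBundle:
    config: RunConfig
    cohort: PairCohort
    sumstats: dict
    ld: LDScores
    stack: CovarianceStack
    fit: FitResult
    tables: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def gwas_quartet(cohort: PairCohort, trait_label: str = "T") -> dict:
    """The four association scans of the two-generation design.

    Own-genotype GWAS use the own cohort; proxy GWAS pair maternal dosages
    with offspring phenotypes in the pair cohort.
    """
    own = run_gwas_multi(
        cohort.own_dosages, cohort.own_phenotypes[["bw", "trait"]],
        cohort.own_phenotypes[COVARIATES], snp_map=cohort.snp_map, design="own",
    )
    proxy = run_gwas_multi(
        cohort.mother_dosages, cohort.phenotypes[["bw", "trait"]],
        cohort.phenotypes[COVARIATES], snp_map=cohort.snp_map, design="proxy",
    )
    out = {"BW": own["bw"], "T": own["trait"],
           "BW_M": proxy["bw"], "T_M": proxy["trait"]}
    for key, ss in out.items():
        ss.trait = key
    return out


def ld_reference(cohort: PairCohort, n_ref: int, window: int) -> LDScores:
    """LD scores from an independent reference panel that shares the
    cohort's population structure (external reference, as in standard
    LDSC practice)."""
    panel = simulate_reference_panel(cohort.config, n_ref)
    return compute_ld_scores(panel, window, snp_map=cohort.snp_map)


def report_tables(fit: FitResult, stack: CovarianceStack,
                  psi_true: np.ndarray | None = None) -> dict:
    """Paper-shaped flat tables from a completed fit."""
    k = stack.k
    se = stack.se_matrix()
    h2 = np.diag(stack.S)
    h2_se = np.diag(se)
    z = h2 / h2_se
    tables = {
        "snp_h2": pd.DataFrame({
            "gwas": stack.labels,
            "h2": h2, "se": h2_se, "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "reliable_z_gt_4": z > 4,
        }),
        "intercepts": pd.DataFrame(stack.intercepts, index=stack.labels,
                                   columns=stack.labels).reset_index(names="gwas"),
        "latent_parameters": fit.summary(),
    }
    cov_rows = fit.summary().iloc[[e for e, (i, j) in enumerate(sem.PAIRS) if i != j]]
    tables["genetic_covariances"] = cov_rows.reset_index(drop=True)
    tables["genetic_correlations"] = genetic_correlations(fit)
    if psi_true is not None:
        truth = vech(psi_true)
        tables["truth_appendix"] = pd.DataFrame({
            "parameter": sem.PARAM_NAMES,
            "truth": truth,
            "estimate": fit.theta,
            "se": fit.se,
            "within_2se": np.abs(fit.theta - truth) <= 2 * fit.se,
        })
    return tables


def run_end_to_end(config: RunConfig) -> RunBundle:
    """Run the full pipeline; any stage failure aborts with the stage name
    after persisting the artifacts already produced (when out_dir is set)."""
    out = Path(config.out_dir) if config.out_dir else None
    produced: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage boundary
            if out is not None:
                _persist(produced, out, config)
            raise StageError(name, exc) from exc

    cohort = stage("simulate", lambda: simulate_cohort(config.sim))
    produced["cohort"] = cohort
    ss = stage("gwas", lambda: gwas_quartet(cohort, config.trait_label))
    produced["sumstats"] = ss
    window = config.ld_window or config.sim.ld_block_size
    ld = stage("ldscores", lambda: ld_reference(cohort, config.n_ref, window))
    produced["ld"] = ld
    order = ["BW", "BW_M", "T", "T_M"]
    stack = stage("ldsc", lambda: build_S_V([ss[k] for k in order], ld,
                                            n_blocks=config.n_blocks))
    stack.labels = ["BW", "BW_M", config.trait_label, f"{config.trait_label}_M"]
    produced["stack"] = stack
    fit = stage("sem", lambda: fit_sem(stack, method=config.sem_method))
    produced["fit"] = fit
    tables = stage("report", lambda: report_tables(fit, stack, psi_true=cohort.psi_true))
    bundle = RunBundle(config, cohort, ss, ld, stack, fit, tables)
    if out is not None:
        _persist(produced, out, config, tables)
    return bundle


def _persist(produced: dict, out: Path, config: RunConfig, tables: dict | None = None):
    out.mkdir(parents=True, exist_ok=True)
    header = f"# seed={config.seed}\tconfig={config.digest()}\n"
    for name, ss in produced.get("sumstats", {}).items():
        write_sumstats(ss, out / f"sumstats_{name}.tsv")
    if "ld" in produced:
        produced["ld"].table.to_csv(out / "ldscores.tsv", sep="\t", index=False, na_rep="NA")
    if "stack" in produced:
        write_stack(produced["stack"], out / "stack")
    for name, tab in (tables or {}).items():
        path = out / f"table_{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            tab.to_csv(fh, sep="\t", index=False, na_rep="NA")
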