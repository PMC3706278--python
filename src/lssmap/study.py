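"""Simulation studies: type I error, power and localization benchmarks.

A replicate couples one coalescent chromosome with one OU-evolved trait:
haplotypes are simulated, a causal SNP with minor allele frequency in
[0.10, 0.30] is chosen, the trait evolves along the true genealogy at that
SNP with the optimum switching at the causal mutation, and diploid trait
values are the haplotype averages.  Null replicates set theta2 = theta1 so
the trait keeps its phylogenetic covariance but carries no association.
Each replicate is scanned with the permutation test and a chromosome is
called detected when its chromosome-level p-value falls below the nominal
level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coalescent import (
    EmptyReplicateError,
    NoEligibleLocusError,
    SimPopConfig,
    choose_disease_locus,
    simulate_haplotypes,
)
from .io import HaplotypeMatrix, TraitTable
from .significance import ScanConfig, chromosome_scan, localization_distance
from .traits import OUConfig, diploid_traits, simulate_trait_on_tree

logger = logging.getLogger("lssmap")

__all__ = ["StudyConfig", "simulate_qtl_replicate", "run_cell", "run_power_study", "compare_methods"]

_MAX_REDRAWS = 20


@dataclass
class StudyConfig:
    """Grid and sizes for a power/type-I-error study."""

    replicates: int = 100
    permutations: int = 200
    kmax: int = 15
    alpha_grid: tuple[float, ...] = (5.0, 7.5, 10.0)
    sigmaY_grid: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    structured: bool = False
    null_model: bool = False
    alpha_level: float = 0.05
    master_seed: int = 0
    methods: tuple[str, ...] = ("lss", "independence")
    sim: SimPopConfig = field(default_factory=SimPopConfig)


def simulate_qtl_replicate(
    sim_config: SimPopConfig,
    ou_config: OUConfig,
    rng: np.random.Generator,
    null_model: bool = False,
) -> tuple[HaplotypeMatrix, TraitTable, int | None]:
    """One (haplotypes, traits, true bp) replicate; re-draws empty/ineligible ones.

    Under the null model the trait is simulated with a single optimum
    (theta2 = theta1) along a genealogy drawn from an independent coalescent
    replicate, so it keeps its phylogenetic covariance structure but carries
    no information about the scanned chromosome; no causal position is
    returned.
    """
    for _ in range(_MAX_REDRAWS):
        seed = int(rng.integers(1, 2**31))
        try:
            rep = simulate_haplotypes(replace(sim_config, seed=seed))
            if null_model:
                aux = simulate_haplotypes(
                    replace(sim_config, seed=int(rng.integers(1, 2**31)))
                )
                snp = int(rng.integers(aux.haplotypes.n_snps))
            else:
                snp = choose_disease_locus(rep, rng)
        except (EmptyReplicateError, NoEligibleLocusError):
            continue
        if null_model:
            genealogy = aux.genealogy_at(snp)
            ou = replace(ou_config, theta2=ou_config.theta1)
            hap_values = simulate_trait_on_tree(genealogy, ou, rng)
            true_bp = None
        else:
            genealogy = rep.genealogy_at(snp)
            node, age = rep.mutation_at(snp)
            hap_values = simulate_trait_on_tree(
                genealogy, ou_config, rng, mutation_node=node, mutation_time=age
            )
            true_bp = int(rep.haplotypes.positions[snp])
        traits = diploid_traits(hap_values, rep.haplotypes.hap_to_individual)
        return rep.haplotypes, traits, true_bp
    raise RuntimeError("failed to simulate a usable replicate after re-draws")


def run_cell(
    alpha: float,
    sigma_Y: float,
    config: StudyConfig,
) -> pd.DataFrame:
    """All replicates of one (alpha, sigma_Y) grid cell; one row per method."""
    rng = np.random.default_rng([config.master_seed, int(alpha * 10), int(sigma_Y)])
    ou = OUConfig(alpha=alpha, sigma_Y=sigma_Y)
    sim = replace(config.sim, structured=config.structured)
    records = []
    for r in range(config.replicates):
        matrix, traits, true_bp = simulate_qtl_replicate(
            sim, ou, rng, null_model=config.null_model
        )
        scan_seed = int(rng.integers(1, 2**31))
        for method in config.methods:
            scan = chromosome_scan(
                matrix,
                traits,
                ScanConfig(
                    kmax=config.kmax,
                    n_permutations=config.permutations,
                    seed=scan_seed,
                    method=method,
                ),
            )
            records.append(
                {
                    "alpha": alpha,
                    "sigma_Y": sigma_Y,
                    "replicate": r,
                    "method": method,
                    "chromosome_pvalue": scan.chromosome_pvalue,
                    "detected": scan.chromosome_pvalue < config.alpha_level,
                    "loc_dist": (
                        np.nan if true_bp is None else localization_distance(scan, true_bp)
                    ),
                }
            )
        logger.debug("cell alpha=%s sigma=%s replicate %d/%d", alpha, sigma_Y, r + 1, config.replicates)
    return pd.DataFrame.from_records(records)


def run_power_study(config: StudyConfig) -> pd.DataFrame:
    """Rejection rate and mean localization distance over the parameter grid.

    Reports type I error when ``config.null_model`` is set, power otherwise;
    LocDist is averaged over all replicates (detected or not).  With a fixed
    ``master_seed`` the full table is reproducible.
    """
    cells = []
    for alpha in config.alpha_grid:
        for sigma_Y in config.sigmaY_grid:
            per_rep = run_cell(alpha, sigma_Y, config)
            for method, grp in per_rep.groupby("method", sort=False):
                cells.append(
                    {
                        "alpha": alpha,
                        "sigma_Y": sigma_Y,
                        "method": method,
                        "rejection_rate": grp["detected"].mean(),
                        "mean_loc_dist": grp["loc_dist"].mean(),
                        "replicates": len(grp),
                    }
                )
            logger.info("finished cell alpha=%s sigma_Y=%s", alpha, sigma_Y)
    return pd.DataFrame.from_records(cells)


def compare_methods(per_replicate: pd.DataFrame, alpha_level: float = 0.05) -> dict:
    """Per-replicate detection concordance of the LSS and independence scores.

    Expects the per-replicate frame from :func:`run_cell` with both methods
    present; returns the 2x2 detection counts and which method localized the
    causal SNP better.
    """
    wide_det = per_replicate.pivot_table(
        index="replicate", columns="method", values="detected", aggfunc="first"
    ).astype(bool)
    wide_loc = per_replicate.pivot_table(
        index="replicate", columns="method", values="loc_dist", aggfunc="first"
    )
    both = int((wide_det["lss"] & wide_det["independence"]).sum())
    neither = int((~wide_det["lss"] & ~wide_det["independence"]).sum())
    only_lss = int((wide_det["lss"] & ~wide_det["independence"]).sum())
    only_ind = int((~wide_det["lss"] & wide_det["independence"]).sum())
    better_lss = int((wide_loc["lss"] < wide_loc["independence"]).sum())
    better_ind = int((wide_loc["independence"] < wide_loc["lss"]).sum())
    return {
        "both": both,
        "neither": neither,
        "only_lss": only_lss,
        "only_independence": only_ind,
        "better_localized_lss": better_lss,
        "better_localized_independence": better_ind,
        "replicates": int(wide_det.shape[0]),
    }
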