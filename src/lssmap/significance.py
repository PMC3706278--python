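"""Permutation-based significance for chromosome scans.

At every SNP the local tree is built once from the genotypes and the score
statistic is computed for the observed traits and for ``B`` permuted trait
tables.  Permutation is at the individual level (both haplotype tips of an
individual receive the same permuted value) and the same ``B`` permutations
are reused across all SNPs, which makes the chromosome-level max-statistic
null coherent.  P-values are the proportion of permuted data sets scoring
strictly higher than the observed data (divisor ``B``, so p = 0 is
attainable): per locus against the locus score, per chromosome against the
maximum score over loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HaplotypeMatrix, TraitTable
from .local_tree import build_local_tree
from .score import score_profile

logger = logging.getLogger("lssmap")

__all__ = ["ScanConfig", "ScanResult", "permute_traits", "chromosome_scan", "localization_distance"]


@dataclass
class ScanConfig:
    """Settings for a chromosome scan."""

    kmax: int = 15
    n_permutations: int = 200
    seed: int = 0
    method: str = "lss"  # "lss" or "independence"
    keep_scores: bool = False  # retain the full S x (B+1) score matrix


@dataclass
class ScanResult:
    """Per-SNP scores and permutation p-values for one chromosome."""

    positions: np.ndarray
    lss: np.ndarray
    best_k: np.ndarray
    locus_pvalues: np.ndarray
    chromosome_pvalue: float
    max_snp_position: int
    n_permutations: int
    seed: int
    method: str = "lss"
    perm_max_scores: np.ndarray | None = field(default=None, repr=False)
    scores: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "lss": self.lss,
                "best_k": self.best_k,
                "locus_pvalue": self.locus_pvalues,
            }
        )


def permute_traits(traits: TraitTable, rng: np.random.Generator) -> TraitTable:
    """Shuffle trait values across individuals (identifiers keep their order)."""
    perm = rng.permutation(len(traits))
    return TraitTable(list(traits.identifiers), traits.values[perm])


def chromosome_scan(matrix: HaplotypeMatrix, traits: TraitTable, config: ScanConfig) -> ScanResult:
    """Score every SNP and assess significance by permutation.

    Local trees depend on genotypes only, so each tree is built once and all
    ``B + 1`` trait vectors (observed first) are scored against it in one
    vectorised pass.
    """
    if matrix.n_hap != 2 * len(traits):
        raise ValueError(
            f"matrix has {matrix.n_hap} haplotypes but traits cover {len(traits)} individuals"
        )
    B = config.n_permutations
    if B < 1:
        raise ValueError("need at least one permutation")
    if config.method not in ("lss", "independence"):
        raise ValueError(f"unknown method {config.method!r}")

    rng = np.random.default_rng(config.seed)
    n_ind = len(traits)
    perms = np.stack([rng.permutation(n_ind) for _ in range(B)])  # same perms for all SNPs
    Ymat = np.empty((matrix.n_hap, B + 1))
    Ymat[:, 0] = traits.tip_values()
    Ymat[:, 1:] = np.repeat(traits.values[perms].T, 2, axis=0)

    S = matrix.n_snps
    scores = np.empty((S, B + 1))
    best_k = np.empty(S, dtype=np.int64)
    identity = config.method == "independence"
    for s in range(S):
        tree = build_local_tree(matrix, s)
        profile = score_profile(tree, Ymat, config.kmax, identity=identity)
        scores[s] = profile.max(axis=0)
        best_k[s] = int(np.argmax(profile[:, 0])) + 1
        if s % 25 == 0:
            logger.debug("scored SNP %d/%d (window %s)", s + 1, S, tree.window)

    obs = scores[:, 0]
    locus_p = np.mean(scores[:, 1:] > obs[:, None], axis=1)
    perm_max = scores[:, 1:].max(axis=0)
    chrom_p = float(np.mean(perm_max > obs.max()))
    max_pos = int(matrix.positions[int(np.argmax(obs))])
    return ScanResult(
        positions=matrix.positions.copy(),
        lss=obs,
        best_k=best_k,
        locus_pvalues=locus_p,
        chromosome_pvalue=chrom_p,
        max_snp_position=max_pos,
        n_permutations=B,
        seed=config.seed,
        method=config.method,
        perm_max_scores=perm_max,
        scores=scores if config.keep_scores else None,
    )


def localization_distance(scan: ScanResult, true_bp: int) -> int:
    """|bp of the maximally scored SNP - bp of the true locus|."""
    return abs(int(scan.max_snp_position) - int(true_bp))
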