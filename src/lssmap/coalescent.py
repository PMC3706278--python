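"""Coalescent simulation of phased SNP data, with optional population structure.

Haplotypes are simulated under the neutral coalescent with recombination
(Hudson model, as in ms) and infinite-sites binary mutations with ancestral
state 0.  Default parameters describe the study conditions: diploid
effective size N0 = 20,000, mutation rate 2e-10 per bp per generation,
recombination 1e-8 per bp per generation, a 1 Mb chromosome and 50 diploid
individuals (100 haplotypes) — giving a Watterson expectation of about 83
segregating sites per replicate.

The structured scenario splits the sample into six equal subpopulations that
merge pairwise at cumulative divergence times 0.1, 0.1, 0.1, 0.2 and 1.0 in
coalescent units of 4*N0 generations, with no gene flow after a split.

Genealogies are kept as a tskit tree sequence; marginal genealogies are
exported with node times converted to units of 4*N0 generations so that they
feed directly into the trait simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

from .io import HaplotypeMatrix

__all__ = [
    "SimPopConfig",
    "SimReplicate",
    "Genealogy",
    "simulate_haplotypes",
    "choose_disease_locus",
    "NoEligibleLocusError",
    "EmptyReplicateError",
]

#: structured-scenario cumulative divergence times, units of 4*N0 generations
STRUCTURED_SPLIT_TIMES = (0.1, 0.1, 0.1, 0.2, 1.0)
N_SUBPOPULATIONS = 6


class NoEligibleLocusError(RuntimeError):
    """No SNP falls in the required minor-allele-frequency window."""


class EmptyReplicateError(RuntimeError):
    """A replicate produced zero segregating sites; the caller should re-draw."""


@dataclass
class SimPopConfig:
    """Coalescent simulation parameters (defaults = the study conditions)."""

    N0: float = 20_000.0
    mu: float = 2.0e-10
    nu: float = 1.0e-8
    length_bp: int = 1_000_000
    n_individuals: int = 50
    structured: bool = False
    split_times: tuple[float, ...] = STRUCTURED_SPLIT_TIMES
    seed: int = 1


@dataclass
class Genealogy:
    """Rooted genealogy at one SNP, times in coalescent units (4*N0 gens).

    ``parent[u]`` is the parent node of ``u`` (-1 at the root), ``time[u]``
    the age of node ``u``, and ``samples`` lists the tip node ids in
    haplotype-row order.
    """

    parent: np.ndarray
    time: np.ndarray
    samples: np.ndarray

    def __post_init__(self):
        self.children: list[list[int]] = [[] for _ in range(len(self.parent))]
        for u, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(u)
        used = self._reachable()
        roots = [u for u in used if self.parent[u] < 0]
        if len(roots) != 1:
            raise ValueError(f"genealogy must have exactly one root, found {len(roots)}")
        self.root = roots[0]

    def _reachable(self) -> set[int]:
        used = set(int(s) for s in self.samples)
        for s in self.samples:
            u = int(s)
            while self.parent[u] >= 0:
                u = int(self.parent[u])
                used.add(u)
        return used

    def descendants(self, node: int) -> set[int]:
        out = set()
        stack = [node]
        while stack:
            u = stack.pop()
            out.add(u)
            stack.extend(self.children[u])
        return out

    @classmethod
    def from_tskit(cls, tree: tskit.Tree, time_scale: float) -> "Genealogy":
        ts = tree.tree_sequence
        n_nodes = ts.num_nodes
        parent = np.full(n_nodes, -1, dtype=np.int64)
        for u in tree.nodes():
            parent[u] = tree.parent(u)
        time = ts.tables.nodes.time / time_scale
        return cls(parent=parent, time=np.asarray(time), samples=np.asarray(ts.samples()))


@dataclass
class SimReplicate:
    """One simulated chromosome plus its genealogical truth."""

    haplotypes: HaplotypeMatrix
    tree_sequence: tskit.TreeSequence = field(repr=False)
    config: SimPopConfig
    site_ids: np.ndarray = field(repr=False)  # tskit site id per retained SNP
    disease_snp_index: int | None = None

    def genealogy_at(self, snp_index: int) -> Genealogy:
        """Marginal genealogy at a SNP, times in 4*N0-generation units."""
        site = self.tree_sequence.site(int(self.site_ids[snp_index]))
        tree = self.tree_sequence.at(site.position)
        return Genealogy.from_tskit(tree, time_scale=4.0 * self.config.N0)

    def mutation_at(self, snp_index: int) -> tuple[int, float]:
        """(node, age) of the mutation at a SNP, age in 4*N0 units."""
        site = self.tree_sequence.site(int(self.site_ids[snp_index]))
        mut = site.mutations[0]
        return int(mut.node), float(mut.time) / (4.0 * self.config.N0)


def _demography(config: SimPopConfig) -> msprime.Demography:
    dem = msprime.Demography()
    for i in range(N_SUBPOPULATIONS):
        dem.add_population(name=f"pop{i}", initial_size=config.N0)
    # pairwise merges: (pop0,pop1) (pop2,pop3) (pop4,pop5) at the first three
    # cumulative times, then the two internal ancestors, then the root
    t = [4.0 * config.N0 * x for x in config.split_times]
    for name in ("anc01", "anc23", "anc45", "anc03", "root"):
        dem.add_population(name=name, initial_size=config.N0)
    dem.add_population_split(time=t[0], derived=["pop0", "pop1"], ancestral="anc01")
    dem.add_population_split(time=t[1], derived=["pop2", "pop3"], ancestral="anc23")
    dem.add_population_split(time=t[2], derived=["pop4", "pop5"], ancestral="anc45")
    dem.add_population_split(time=t[3], derived=["anc01", "anc23"], ancestral="anc03")
    dem.add_population_split(time=t[4], derived=["anc03", "anc45"], ancestral="root")
    dem.sort_events()
    return dem


def _sample_sizes(n_individuals: int) -> list[int]:
    base, extra = divmod(n_individuals, N_SUBPOPULATIONS)
    return [base + (1 if i < extra else 0) for i in range(N_SUBPOPULATIONS)]


def _integer_positions(raw: np.ndarray, length_bp: int) -> np.ndarray:
    """Map continuous site positions to distinct increasing 1-based integers."""
    pos = np.floor(raw).astype(np.int64) + 1
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def simulate_haplotypes(config: SimPopConfig) -> SimReplicate:
    """Simulate one replicate: genealogies, mutations, binary haplotypes."""
    rng = np.random.default_rng(config.seed)
    anc_seed, mut_seed = (int(x) for x in rng.integers(1, 2**31, size=2))
    if config.structured:
        demography = _demography(config)
        samples = {
            f"pop{i}": n for i, n in enumerate(_sample_sizes(config.n_individuals)) if n > 0
        }
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=config.length_bp,
            recombination_rate=config.nu,
            ploidy=2,
            random_seed=anc_seed,
        )
    else:
        ts = msprime.sim_ancestry(
            samples=config.n_individuals,
            population_size=config.N0,
            sequence_length=config.length_bp,
            recombination_rate=config.nu,
            ploidy=2,
            random_seed=anc_seed,
        )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=mut_seed,
    )
    if ts.num_sites == 0:
        raise EmptyReplicateError("zero segregating sites")

    G = ts.genotype_matrix().T  # n_hap x S
    poly = (G.min(axis=0) == 0) & (G.max(axis=0) == 1)
    site_ids = np.flatnonzero(poly)
    G = G[:, poly]
    raw_pos = np.array([ts.site(int(i)).position for i in site_ids])
    positions = _integer_positions(raw_pos, config.length_bp)
    matrix = HaplotypeMatrix(G.astype(np.int8), positions)
    return SimReplicate(
        haplotypes=matrix, tree_sequence=ts, config=config, site_ids=site_ids
    )


def choose_disease_locus(
    rep: SimReplicate,
    rng: np.random.Generator,
    maf_lo: float = 0.10,
    maf_hi: float = 0.30,
) -> int:
    """Uniform draw among SNPs with minor allele frequency in [maf_lo, maf_hi]."""
    maf = rep.haplotypes.minor_allele_frequencies()
    eligible = np.flatnonzero((maf >= maf_lo) & (maf <= maf_hi))
    if eligible.size == 0:
        raise NoEligibleLocusError("no eligible disease locus in the MAF window")
    return int(rng.choice(eligible))
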