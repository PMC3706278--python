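"""Quantitative trait simulation along a genealogy (state-switching OU).

Traits evolve root-to-tips along the genealogy at the causal SNP under an
Ornstein-Uhlenbeck process

    dY(t) = alpha (theta - Y(t)) dt + sigma_Y dB(t)

whose optimum switches with the SNP state carried by the lineage (the
Generalized Hansen model): theta = theta1 on the ancestral background and
theta2 below the mutation.  Two lineages share their trait value until they
split and evolve independently afterwards.  Each branch segment of constant
optimum is drawn from the exact Gaussian OU transition (no Euler
discretization):

    Y(t+s) | Y(t) ~ N(theta + (Y(t) - theta) e^{-alpha s},
                      sigma_Y^2 (1 - e^{-2 alpha s}) / (2 alpha)).

Branch durations are the genealogy's coalescent times (units of 4*N0
generations) used directly as OU time.  Diploid trait values are the average
of an individual's two haplotype values (additive/codominant model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent import Genealogy
from .io import TraitTable

__all__ = ["OUConfig", "ou_transition", "simulate_trait_on_tree", "diploid_traits"]


@dataclass
class OUConfig:
    """Ornstein-Uhlenbeck parameters (defaults = the study conditions).

    alpha is the selection strength toward the optimum per unit time, sigma_Y
    the diffusion standard deviation per sqrt(unit time); theta1/theta2 are
    the optima for SNP states 0 and 1.  The root starts at the ancestral
    optimum theta1.
    """

    alpha: float = 10.0
    sigma_Y: float = 10.0
    theta1: float = 80.0
    theta2: float = 100.0
    y_root: float | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.sigma_Y <= 0:
            raise ValueError("sigma_Y must be > 0")

    @property
    def root_value(self) -> float:
        return self.theta1 if self.y_root is None else self.y_root


def ou_transition(
    y0, t: float, alpha: float, theta: float, sigma_Y: float, rng: np.random.Generator
):
    """Exact OU transition over a constant-optimum interval of duration t.

    Vectorised over ``y0``; returns ``y0`` exactly at t = 0 and is numerically
    stable in the Brownian limit alpha -> 0 (variance -> sigma_Y^2 t).
    """
    if t < 0:
        raise ValueError("duration must be >= 0")
    y0 = np.asarray(y0, dtype=np.float64)
    if t == 0:
        return y0 if y0.ndim else float(y0)
    decay = np.exp(-alpha * t)
    mean = theta + (y0 - theta) * decay
    var = sigma_Y**2 * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha)
    out = rng.normal(mean, np.sqrt(var))
    return out if y0.ndim else float(out)


def simulate_trait_on_tree(
    tree: Genealogy,
    ou: OUConfig,
    rng: np.random.Generator,
    mutation_node: int | None = None,
    mutation_time: float | None = None,
) -> np.ndarray:
    """Per-haplotype trait values from a root-to-tips OU traversal.

    ``mutation_node`` is the child node of the edge carrying the causal
    mutation and ``mutation_time`` the mutation's age (within that edge); all
    lineage segments below the mutation evolve toward theta2, all others
    toward theta1.  With ``mutation_node=None`` (or theta2 == theta1) the
    optimum is constant — the null model.
    """
    carriers: set[int] = set()
    if mutation_node is not None:
        if tree.parent[mutation_node] < 0:
            raise ValueError("mutation node must have a parent edge")
        if mutation_time is None:
            # place the mutation uniformly on its edge when no age is recorded
            lo = tree.time[mutation_node]
            hi = tree.time[tree.parent[mutation_node]]
            mutation_time = float(rng.uniform(lo, hi))
        lo = tree.time[mutation_node]
        hi = tree.time[tree.parent[mutation_node]]
        if not (lo <= mutation_time <= hi):
            raise ValueError(
                f"mutation age {mutation_time} outside edge [{lo}, {hi}]"
            )
        carriers = tree.descendants(mutation_node)

    values = np.empty(len(tree.parent))
    values[tree.root] = ou.root_value
    order = [tree.root]
    stack = list(tree.children[tree.root])
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(tree.children[u])
    for u in order[1:]:
        p = tree.parent[u]
        t_hi, t_lo = float(tree.time[p]), float(tree.time[u])
        y = values[p]
        if mutation_node is not None and u == mutation_node and mutation_time < t_hi:
            # optimum switches part-way down the mutation's edge
            y = ou_transition(y, t_hi - mutation_time, ou.alpha, ou.theta1, ou.sigma_Y, rng)
            y = ou_transition(y, mutation_time - t_lo, ou.alpha, ou.theta2, ou.sigma_Y, rng)
        else:
            theta = ou.theta2 if u in carriers else ou.theta1
            y = ou_transition(y, t_hi - t_lo, ou.alpha, theta, ou.sigma_Y, rng)
        values[u] = y
    return values[tree.samples]


def diploid_traits(hap_values: np.ndarray, hap_to_individual: np.ndarray) -> TraitTable:
    """Additive diplotype values: mean of each individual's two haplotypes."""
    hap_values = np.asarray(hap_values, dtype=np.float64)
    hap_to_individual = np.asarray(hap_to_individual)
    if len(hap_values) % 2 != 0:
        raise ValueError("number of haplotypes must be even")
    individuals = np.unique(hap_to_individual)
    means = np.array([hap_values[hap_to_individual == i].mean() for i in individuals])
    return TraitTable([f"ind{int(i)}" for i in individuals], means)
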