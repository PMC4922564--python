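"""Genetic-programming integration of evidence matrices.

Individuals are addition-only expression trees whose leaves name evidence
matrices; a matrix appearing m times contributes with integer coefficient m,
so an individual is an integer-weighted sum such as

    S = interpro + neighborhood + 3 strAliScr

applied entrywise to the normalized matrices. Fitness is the active-site MI
of the spectral clustering of the combined matrix. Evolution uses tournament
selection, subtree crossover, subtree-replacement mutation, reproduction and
single elitism; the K-means seed is held fixed within a run so selection
compares individuals rather than clustering draws.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .evidence import EvidenceMatrix
from .mi import overall_mi
from .pockets import ActiveSiteAlignment
from .spectral import ClusterAssignment, build_affinity, spectral_cluster


class GPError(ValueError):
    pass


# Trees are nested tuples: ("+", left, right) or ("leaf", name).

def _tree_leaves(tree) -> list[str]:
    if tree[0] == "leaf":
        return [tree[1]]
    return _tree_leaves(tree[1]) + _tree_leaves(tree[2])


def _tree_depth(tree) -> int:
    if tree[0] == "leaf":
        return 1
    return 1 + max(_tree_depth(tree[1]), _tree_depth(tree[2]))


def _subtrees(tree, path=()):
    yield path, tree
    if tree[0] == "+":
        yield from _subtrees(tree[1], path + (1,))
        yield from _subtrees(tree[2], path + (2,))


def _replace_subtree(tree, path, new):
    if not path:
        return new
    branch = path[0]
    left, right = tree[1], tree[2]
    if branch == 1:
        return ("+", _replace_subtree(left, path[1:], new), right)
    return ("+", left, _replace_subtree(right, path[1:], new))


def _random_tree(rng: random.Random, names: Sequence[str], max_depth: int):
    """Grow-style random addition tree over matrix-name leaves."""
    if max_depth <= 1 or rng.random() < 0.4:
        return ("leaf", rng.choice(names))
    return ("+", _random_tree(rng, names, max_depth - 1),
            _random_tree(rng, names, max_depth - 1))


@dataclass
class CombinationIndividual:
    """An integer-weighted sum of evidence matrices (the GP genome)."""

    genome: tuple

    def __post_init__(self) -> None:
        if not _tree_leaves(self.genome):
            raise GPError("individual must reference at least one matrix")

    @property
    def coefficients(self) -> dict[str, int]:
        coeffs: dict[str, int] = {}
        for name in _tree_leaves(self.genome):
            coeffs[name] = coeffs.get(name, 0) + 1
        return coeffs

    @classmethod
    def from_coefficients(cls, coefficients: Mapping[str, int]
                          ) -> "CombinationIndividual":
        leaves = [("leaf", name) for name, c in sorted(coefficients.items())
                  for _ in range(int(c)) if c > 0]
        if not leaves:
            raise GPError("at least one positive coefficient required")
        tree = leaves[0]
        for leaf in leaves[1:]:
            tree = ("+", tree, leaf)
        return cls(genome=tree)


def render_equation(ind: CombinationIndividual) -> str:
    """Printable equation: coefficient-prefixed terms joined by ' + ',
    coefficient 1 omitted, terms in lexicographic (printed-table) order."""
    parts = []
    for name, coeff in sorted(ind.coefficients.items()):
        parts.append(name if coeff == 1 else f"{coeff}{name}")
    return " + ".join(parts)


def parse_equation(text: str) -> CombinationIndividual:
    import re

    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise GPError(f"empty term in equation {text!r}")
        m = re.fullmatch(r"(\d*)\s*([A-Za-z]\w*)", term)
        if not m:
            raise GPError(f"unparseable term {term!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        coeffs[name] = coeffs.get(name, 0) + coeff
    return CombinationIndividual.from_coefficients(coeffs)


def combine_matrices(coefficients: Mapping[str, int],
                     matrices: Mapping[str, EvidenceMatrix]) -> np.ndarray:
    unknown = set(coefficients) - set(matrices)
    if unknown:
        raise GPError(f"coefficients for unknown matrices: {sorted(unknown)}")
    combined = None
    for name, coeff in coefficients.items():
        if coeff == 0:
            continue
        m = matrices[name]
        if not m.normalized:
            raise GPError(f"matrix {name!r} must be normalized before integration")
        term = coeff * m.values
        combined = term if combined is None else combined + term
    if combined is None:
        raise GPError("all coefficients are zero")
    return combined


def evaluate_individual(ind: CombinationIndividual,
                        matrices: Mapping[str, EvidenceMatrix],
                        msa: ActiveSiteAlignment, k: int, seed: int
                        ) -> tuple[float, ClusterAssignment]:
    """Entrywise-combine, spectrally cluster, and score by overall MI."""
    ids = next(iter(matrices.values())).ids
    combined = combine_matrices(ind.coefficients, matrices)
    assignment = spectral_cluster(build_affinity(combined), ids, k, seed)
    report = overall_mi(msa, assignment)
    return report.overall, assignment


@dataclass
class GPConfig:
    population_size: int = 50
    generations: int = 30
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    reproduction_rate: float = 0.1
    tournament_size: int = 3
    max_depth: int = 6
    elites: int = 1
    seed: int = 0
    k: int = 2

    def __post_init__(self) -> None:
        rates = self.crossover_rate + self.mutation_rate + self.reproduction_rate
        if not math.isclose(rates, 1.0, abs_tol=1e-9):
            raise GPError(f"operator rates must sum to 1 (got {rates})")
        if self.population_size < 2:
            raise GPError("population size must be at least 2")


def crossover(a: CombinationIndividual, b: CombinationIndividual,
              rng: random.Random, max_depth: int = 6
              ) -> tuple[CombinationIndividual, CombinationIndividual]:
    """Swap random subtrees; offspring violating depth revert to the parents."""
    path_a, sub_a = rng.choice(list(_subtrees(a.genome)))
    path_b, sub_b = rng.choice(list(_subtrees(b.genome)))
    child_a = _replace_subtree(a.genome, path_a, sub_b)
    child_b = _replace_subtree(b.genome, path_b, sub_a)
    out = []
    for child, parent in ((child_a, a), (child_b, b)):
        if _tree_depth(child) > max_depth:
            out.append(CombinationIndividual(genome=parent.genome))
        else:
            out.append(CombinationIndividual(genome=child))
    return out[0], out[1]


def mutate(a: CombinationIndividual, names: Sequence[str], rng: random.Random,
           max_depth: int = 6) -> CombinationIndividual:
    """Replace a random subtree with a fresh random addition tree."""
    path, _ = rng.choice(list(_subtrees(a.genome)))
    depth_budget = max(1, max_depth - len(path))
    new_sub = _random_tree(rng, list(names), min(3, depth_budget))
    child = _replace_subtree(a.genome, path, new_sub)
    if _tree_depth(child) > max_depth:
        return CombinationIndividual(genome=a.genome)
    return CombinationIndividual(genome=child)


@dataclass
class EvolutionResult:
    best: CombinationIndividual
    fitness: float
    assignment: ClusterAssignment
    history: list[float]          # per-generation best fitness (non-decreasing)
    cluster_seed: int = 0         # the K-means seed all evaluations shared
    equation: str = field(init=False)

    def __post_init__(self) -> None:
        self.equation = render_equation(self.best)


def evolve(matrices: Mapping[str, EvidenceMatrix], msa: ActiveSiteAlignment,
           config: GPConfig) -> EvolutionResult:
    """Evolve matrix combinations to maximize clustering MI.

    Fitness evaluations are memoized on the coefficient vector, since the
    combined matrix (and hence the clustering) depends only on it.
    """
    if not matrices:
        raise GPError("no evidence matrices to integrate")
    names = sorted(matrices)
    rng = random.Random(config.seed)
    cluster_seed = rng.randrange(2**31)  # one clustering seed per run

    cache: dict[tuple, tuple[float, ClusterAssignment]] = {}

    def fitness_of(ind: CombinationIndividual) -> tuple[float, ClusterAssignment]:
        key = tuple(sorted(ind.coefficients.items()))
        if key not in cache:
            cache[key] = evaluate_individual(ind, matrices, msa, config.k,
                                             cluster_seed)
        return cache[key]

    population = [CombinationIndividual(_random_tree(rng, names, config.max_depth))
                  for _ in range(config.population_size)]
    scored = [(fitness_of(ind)[0], ind) for ind in population]
    history: list[float] = []

    def tournament() -> CombinationIndividual:
        pick = rng.sample(range(len(scored)), min(config.tournament_size, len(scored)))
        best_i = max(pick, key=lambda i: scored[i][0])
        return scored[best_i][1]

    for _generation in range(config.generations):
        scored.sort(key=lambda t: -t[0])
        history.append(scored[0][0])
        next_pop: list[CombinationIndividual] = [
            CombinationIndividual(genome=scored[i][1].genome)
            for i in range(config.elites)]
        while len(next_pop) < config.population_size:
            op = rng.random()
            if op < config.crossover_rate:
                c1, c2 = crossover(tournament(), tournament(), rng, config.max_depth)
                next_pop.append(c1)
                if len(next_pop) < config.population_size:
                    next_pop.append(c2)
            elif op < config.crossover_rate + config.mutation_rate:
                next_pop.append(mutate(tournament(), names, rng, config.max_depth))
            else:
                next_pop.append(CombinationIndividual(genome=tournament().genome))
        scored = [(fitness_of(ind)[0], ind) for ind in next_pop]

    scored.sort(key=lambda t: -t[0])
    history.append(scored[0][0])
    best_fitness, best = scored[0]
    _, assignment = fitness_of(best)
    return EvolutionResult(best=best, fitness=best_fitness,
                           assignment=assignment, history=history,
                           cluster_seed=cluster_seed)


__all__ = [
    "GPError", "CombinationIndividual", "GPConfig", "EvolutionResult",
    "render_equation", "parse_equation", "combine_matrices",
    "evaluate_individual", "crossover", "mutate", "evolve",
]
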