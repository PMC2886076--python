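"""Genome distances, strain grouping, divergence dating and repeat-count correlation.

Distances are p-distances (fraction of differing columns) on concatenated
core-gene alignments; at the ~2x10^-4 distances of interest, multiple-hit
corrections change nothing at the precision used, but a Jukes-Cantor toggle
is provided.  Two divergence-time estimators are implemented: a molecular
clock (t = d / mu, default mu = 7.6x10^-10 substitutions/site/year) and an
extremely conservative neutral-accumulation model in generations, where the
per-site per-generation input of polymorphism is (U/G)(1 + rho) with genomic
mutation rate U, genome size G and a recombination-to-mutation polymorphism
ratio rho.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "StrainGroup",
    "DivergenceParams",
    "DivergenceEstimate",
    "CorrelationResult",
    "p_distance",
    "distance_matrix",
    "group_close_strains",
    "clock_years",
    "neutral_generations",
    "repeat_correlation",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if (self.d < 0).any() or not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric and non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


@dataclass
class StrainGroup:
    members: list[str]
    representative: str


@dataclass
class DivergenceParams:
    mu_year: float = 7.6e-10          # substitutions/site/year
    U: float = 1e-3                   # genomic mutations/generation
    G: float = 5e6                    # genome size (bp)
    rho_ratio: float = 2.5            # recombination:mutation polymorphism input
    gen_hours: float = 40.0           # hours per generation in nature
    hours_per_year: float = 8766.0    # Julian year

    def __post_init__(self) -> None:
        for name in ("mu_year", "U", "G", "rho_ratio", "gen_hours", "hours_per_year"):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mu_year <= 0 or self.U <= 0 or self.G <= 0:
            raise ValueError("rates and genome size must be strictly positive")


@dataclass
class DivergenceEstimate:
    d: float
    years_clock: float
    generations_neutral: float
    years_neutral: float


@dataclass
class CorrelationResult:
    r_squared: float
    p_perm: float
    n: int


def p_distance(seq_a: str, seq_b: str, jukes_cantor: bool = False) -> float:
    """Fraction of differing columns between equal-length aligned sequences.

    Columns containing a gap or N in either sequence are excluded.  The
    optional Jukes-Cantor correction matters only at distances far above the
    grouping threshold used here.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("p_distance requires equal-length alignments")
    compared = mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    p = mismatches / compared
    if jukes_cantor:
        if p >= 0.75:
            raise ValueError("p-distance too large for Jukes-Cantor correction")
        return -0.75 * np.log(1 - 4 * p / 3)
    return p


def distance_matrix(core_seqs: dict[str, str], jukes_cantor: bool = False) -> DistanceMatrix:
    """All-pairs p-distances on per-genome concatenated core alignments."""
    labels = sorted(core_seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(core_seqs[labels[i]], core_seqs[labels[j]],
                                           jukes_cantor)
    return DistanceMatrix(labels=labels, d=d)


def group_close_strains(D: DistanceMatrix, threshold: float = 0.0002) -> list[StrainGroup]:
    """Single-linkage components of the graph with edges d < threshold.

    Returns a partition of the genome set; each group's representative is its
    lexicographically first member.
    """
    n = len(D.labels)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if D.d[i, j] < threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i, label in enumerate(D.labels):
        comps.setdefault(find(i), []).append(label)
    groups = [StrainGroup(members=sorted(m), representative=sorted(m)[0])
              for m in comps.values()]
    groups.sort(key=lambda g: g.representative)
    return groups


def clock_years(d: float, mu_year: float = 7.6e-10) -> float:
    """Molecular-clock divergence time in years: t = d / mu."""
    if mu_year <= 0:
        raise ValueError("mu_year must be positive")
    if d < 0:
        raise ValueError("d must be non-negative")
    return d / mu_year


def neutral_generations(
    d: float, params: Optional[DivergenceParams] = None
) -> tuple[float, float]:
    """Conservative neutral dating: (generations, years) to accumulate d.

    The per-site per-generation input of polymorphism is
    r = (U / G) * (1 + rho_ratio); generations = d / r, converted to years
    with the configured generation time.
    """
    params = params or DivergenceParams()
    if d < 0:
        raise ValueError("d must be non-negative")
    r = (params.U / params.G) * (1.0 + params.rho_ratio)
    generations = d / r
    years = generations * params.gen_hours / params.hours_per_year
    return generations, years


def divergence_estimate(d: float, params: Optional[DivergenceParams] = None) -> DivergenceEstimate:
    params = params or DivergenceParams()
    gens, years_n = neutral_generations(d, params)
    return DivergenceEstimate(
        d=d, years_clock=clock_years(d, params.mu_year),
        generations_neutral=gens, years_neutral=years_n,
    )


def repeat_correlation(
    counts_x: Sequence[float],
    counts_y: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Squared Pearson correlation of paired repeat counts with a permutation p.

    ``p_perm`` is the one-sided, add-one-smoothed fraction of label
    permutations whose r-squared reaches the observed value.
    """
    x = np.asarray(counts_x, dtype=float)
    y = np.asarray(counts_y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("repeat_correlation requires >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r-squared undefined for constant input")

    def r2(a: np.ndarray, b: np.ndarray) -> float:
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)

    obs = r2(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r2(x, rng.permutation(y)) >= obs:
            hits += 1
    return CorrelationResult(r_squared=obs, p_perm=(hits + 1) / (n_perm + 1), n=x.size)
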