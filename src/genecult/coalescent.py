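"""Bespoke coalescent simulators and summary statistics.

Two demographic models, both simulated backwards in continuous time with
exact exponential waiting times:

* an equilibrium (optionally hierarchical) island model — ``n_demes`` demes
  of constant diploid size exchanging migrants, with a higher within-group
  than between-group rate in the hierarchical case.  This supplies the null
  distribution for the F_ST outlier test.
* a three-deme settlement demography for the peopling of the Americas:
  present-day demes of 830 diploids that merge, between 6,350 and 18,000
  years ago, into a single ancestral population of 70-830 diploids, each
  deme shrinking exponentially backwards from its present size to the
  ancestral size at the split.

A single mutation (island model) or a fixed number of fully linked mutations
(settlement regions) is placed uniformly at random on total branch length —
the infinite-sites, fixed-S construction — so every simulated locus is
polymorphic in the pooled sample by construction.  Summaries are unbiased
expected heterozygosity and the allele-count ANOVA F_ST (global ratio-of-sums
across loci, plus all deme pairs).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .fstats import fst_components

__all__ = [
    "IslandModelConfig",
    "SettlementDemography",
    "Genealogy",
    "SimulatedLocus",
    "LocusSet",
    "SummaryStats",
    "simulate_island_snp",
    "simulate_settlement_region",
    "summarize_loci",
    "place_mutations",
    "migration_for_target_fst",
]


def migration_for_target_fst(target_fst: float, deme_size: float, n_demes: int) -> float:
    """Per-generation migration rate hitting a target equilibrium F_ST.

    Inverts the finite-island expectation F_ST = 1 / (1 + 4Nm (D/(D-1))^2).
    """
    if not 0.0 < target_fst < 1.0:
        raise DomainError("target_fst must be in (0, 1)")
    corr = (n_demes / (n_demes - 1.0)) ** 2
    return (1.0 / target_fst - 1.0) / (4.0 * deme_size * corr)


@dataclass
class IslandModelConfig:
    """Equilibrium (hierarchical) island model.

    ``m_within``/``m_between`` are each lineage's total per-generation
    probabilities of migrating to some deme of the same group / of another
    group (``m_within >= m_between``).  Alternatively ``target_fst`` solves
    for a uniform (non-hierarchical) migration rate.  ``sample_spec`` lists
    (deme index, diploid individuals sampled).
    """

    n_demes: int = 100
    n_groups: int = 2
    deme_size: int = 50
    m_within: float | None = None
    m_between: float | None = None
    sample_spec: Sequence[tuple[int, int]] = ((0, 10),)
    target_fst: float | None = None

    def __post_init__(self) -> None:
        if self.n_demes % self.n_groups != 0:
            raise ValidationError("n_groups must divide n_demes evenly")
        if self.target_fst is not None and self.m_within is None:
            m = migration_for_target_fst(self.target_fst, self.deme_size, self.n_demes)
            self.m_within = self.m_between = m
        if self.m_within is None:
            raise ValidationError("specify m_within/m_between or target_fst")
        if self.m_between is None:
            self.m_between = self.m_within
        for m in (self.m_within, self.m_between):
            if not 0.0 <= m <= 1.0:
                raise ValidationError("migration rates must lie in [0, 1]")
        if self.m_between > self.m_within:
            raise ValidationError("hierarchy requires m_within >= m_between")
        for deme, d in self.sample_spec:
            if not 0 <= deme < self.n_demes:
                raise ValidationError(f"sampled deme {deme} outside 0..{self.n_demes - 1}")
            if d > self.deme_size:
                raise ValidationError(f"sample of {d} diploids exceeds deme size {self.deme_size}")

    @property
    def demes_per_group(self) -> int:
        return self.n_demes // self.n_groups


@dataclass
class SettlementDemography:
    """Three-deme settlement model with uniform priors on split time and
    ancestral size; all sizes are diploids, times in years before present."""

    n_demes: int = 3
    present_size: int = 830
    ancestral_size_range: tuple[float, float] = (70.0, 830.0)
    split_time_range_years: tuple[float, float] = (6_350.0, 18_000.0)
    generation_years: float = 25.0
    migration_post_split: float = 0.0

    def __post_init__(self) -> None:
        if self.ancestral_size_range[0] > self.ancestral_size_range[1]:
            raise ValidationError("ancestral_size_range must be ordered")
        if self.split_time_range_years[0] > self.split_time_range_years[1]:
            raise ValidationError("split_time_range_years must be ordered")
        if min(self.present_size, *self.ancestral_size_range) <= 0:
            raise ValidationError("population sizes must be positive")


#: Default per-deme diploid sample sizes, mirroring the study's panels of
#: Mesoamerican agriculturalists (68), Andean agriculturalists (35) and
#: South American hunter-gatherers/foragers (23).
DEFAULT_SETTLEMENT_SAMPLES = (68, 35, 23)


@dataclass
class Genealogy:
    """Coalescent tree: ``parent[u]``/``time[u]`` per node, tips first."""

    parent: np.ndarray
    time: np.ndarray
    tip_deme: np.ndarray  # deme label per tip

    @property
    def n_tips(self) -> int:
        return len(self.tip_deme)

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        nodes = np.arange(self.root)
        return self.time[self.parent[nodes]] - self.time[nodes]

    def descendant_tips(self, node: int) -> np.ndarray:
        children: list[list[int]] = [[] for _ in range(len(self.parent))]
        for u in range(self.root):
            children[self.parent[u]].append(u)
        out = []
        stack = [node]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(u)
            else:
                stack.extend(children[u])
        return np.array(sorted(out))

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())


@dataclass
class SimulatedLocus:
    """Per-sampled-deme derived-allele counts for one SNP."""

    deme_ids: np.ndarray
    n_alleles: np.ndarray  # chromosomes sampled per deme
    derived: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.derived > self.n_alleles) or np.any(self.derived < 0):
            raise ValidationError("derived counts must lie in [0, sample size]")


@dataclass
class LocusSet:
    """A stack of loci sharing one sampling layout (loci x demes)."""

    deme_ids: np.ndarray
    n_alleles: np.ndarray  # per deme
    derived: np.ndarray  # (n_loci, n_demes)

    @classmethod
    def from_loci(cls, loci: Sequence[SimulatedLocus]) -> "LocusSet":
        first = loci[0]
        return cls(
            deme_ids=first.deme_ids,
            n_alleles=first.n_alleles,
            derived=np.vstack([l.derived for l in loci]),
        )

    @property
    def n_loci(self) -> int:
        return self.derived.shape[0]


@dataclass
class SummaryStats:
    """He / F_ST summary vector of a locus set (the S and S* vectors).

    Layout of :meth:`as_vector` is fixed: ``mean_he``, ``global_fst``, then
    pairwise F_ST for deme pairs (i, j), i < j, in deme order.
    """

    mean_he: float
    global_fst: float
    pairwise_fst: np.ndarray
    per_locus_he: np.ndarray
    labels: list[str] = field(default_factory=list)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.mean_he, self.global_fst], self.pairwise_fst])

    def vector_labels(self) -> list[str]:
        return ["mean_he", "global_fst"] + self.labels


def _as_rng(seed) -> random.Random:
    if isinstance(seed, random.Random):
        return seed
    if isinstance(seed, np.random.Generator):
        return random.Random(int(seed.integers(0, 2**31 - 1)))
    return random.Random(seed)


def place_mutations(gen: Genealogy, n_mutations: int, rng) -> list[np.ndarray]:
    """Drop mutations uniformly on total branch length; returns carrier tip sets.

    Every branch subtends a proper, non-empty subset of tips, so each
    mutation is polymorphic in the pooled sample.
    """
    rng = _as_rng(rng)
    lengths = gen.branch_lengths()
    cum = np.cumsum(lengths)
    total = cum[-1]
    out = []
    for _ in range(n_mutations):
        node = int(np.searchsorted(cum, rng.random() * total, side="right"))
        out.append(gen.descendant_tips(node))
    return out


def _counts_from_tips(gen: Genealogy, tip_sets, sampled_demes):
    sizes = np.array([(gen.tip_deme == d).sum() for d in sampled_demes])
    derived = np.zeros((len(tip_sets), len(sampled_demes)), int)
    for k, tips in enumerate(tip_sets):
        demes_of = gen.tip_deme[tips]
        for j, d in enumerate(sampled_demes):
            derived[k, j] = int((demes_of == d).sum())
    return sizes, derived


def simulate_island_genealogy(config: IslandModelConfig, seed=None) -> Genealogy:
    """Structured-coalescent genealogy of the sampled chromosomes.

    Migration moves single lineages backwards between demes; coalescence
    occurs at rate k(k-1)/2 per deme per 2N generations.  Pure Gillespie
    event loop; time is in generations.
    """
    rng = _as_rng(seed)
    tip_demes = []
    for deme, diploids in config.sample_spec:
        tip_demes.extend([deme] * (2 * diploids))
    n = len(tip_demes)
    if n < 2:
        raise ValidationError("need at least two sampled chromosomes")
    m_tot = config.m_within + (config.m_between if config.n_groups > 1 else 0.0)
    if m_tot == 0.0 and len({d for d, _ in config.sample_spec}) > 1:
        raise DomainError("zero migration with a multi-deme sample cannot coalesce")

    parent = [-1] * (2 * n - 1)
    times = [0.0] * (2 * n - 1)
    # per-deme lineage lists; lineage = node id
    demes: dict[int, list[int]] = {}
    for i, d in enumerate(tip_demes):
        demes.setdefault(d, []).append(i)
    active = list(range(n))  # flat list for uniform lineage choice
    where = {i: tip_demes[i] for i in range(n)}
    coal_weight = sum(k * (k - 1) for k in (len(v) for v in demes.values()))
    two_n = 2.0 * config.deme_size
    dpg = config.demes_per_group
    t = 0.0
    next_node = n
    exp = rng.expovariate
    while len(active) > 1:
        coal_rate = coal_weight / (2.0 * two_n)  # sum_d k(k-1)/2 / 2N
        mig_rate = len(active) * m_tot
        total = coal_rate + mig_rate
        t += exp(total)
        if rng.random() * total < coal_rate:
            # choose deme proportional to k(k-1)
            r = rng.random() * coal_weight
            acc = 0.0
            for d, lin in demes.items():
                k = len(lin)
                acc += k * (k - 1)
                if r < acc:
                    break
            i = rng.randrange(len(lin))
            j = rng.randrange(len(lin) - 1)
            if j >= i:
                j += 1
            a, b = lin[i], lin[j]
            k = len(lin)
            coal_weight += (k - 1) * (k - 2) - k * (k - 1)
            lin.remove(a)
            lin.remove(b)
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            times[node] = t
            lin.append(node)
            active.remove(a)
            active.remove(b)
            active.append(node)
            where[node] = d
            del where[a], where[b]
            if not lin:
                del demes[d]
        else:
            lin_id = active[rng.randrange(len(active))]
            src = where[lin_id]
            if config.n_groups > 1 and rng.random() * m_tot >= config.m_within:
                # between-group move: uniform among demes of other groups
                g = src // dpg
                tgt = rng.randrange(config.n_demes - dpg)
                tgt_group, off = divmod(tgt, dpg)
                if tgt_group >= g:
                    tgt_group += 1
                dst = tgt_group * dpg + off
            else:
                # within-group move: uniform among the group's other demes
                if dpg == 1:
                    continue  # singleton group: within-group move is a no-op
                g = src // dpg
                off = rng.randrange(dpg - 1)
                if off >= src % dpg:
                    off += 1
                dst = g * dpg + off
            k_src = len(demes[src])
            coal_weight -= 2 * (k_src - 1)
            demes[src].remove(lin_id)
            if not demes[src]:
                del demes[src]
            dst_list = demes.setdefault(dst, [])
            coal_weight += 2 * len(dst_list)
            dst_list.append(lin_id)
            where[lin_id] = dst
    return Genealogy(
        parent=np.array(parent), time=np.array(times), tip_deme=np.array(tip_demes)
    )


def simulate_island_snp(config: IslandModelConfig, seed=None) -> SimulatedLocus:
    """One island-model SNP: genealogy plus a single uniform mutation."""
    rng = _as_rng(seed)
    gen = simulate_island_genealogy(config, rng)
    tips = place_mutations(gen, 1, rng)
    sampled = [d for d, _ in config.sample_spec]
    sizes, derived = _counts_from_tips(gen, tips, sampled)
    return SimulatedLocus(deme_ids=np.array(sampled), n_alleles=sizes, derived=derived[0])


def _coalesce_growing(lineages, t0, t_end, n0, beta, parent, times, next_node, rng):
    """Coalesce within one deme whose backward size is n0 * exp(-beta * tau),
    stopping at t_end; returns surviving lineages and next free node id."""
    tau = t0
    while len(lineages) > 1:
        k = len(lineages)
        C = k * (k - 1) / 2.0
        E = rng.expovariate(1.0)
        if beta > 0:
            arg = math.exp(beta * tau) + 2.0 * n0 * beta * E / C
            tau_next = math.log(arg) / beta
        else:
            tau_next = tau + 2.0 * n0 * E / C
        if tau_next >= t_end:
            return lineages, next_node
        tau = tau_next
        i = rng.randrange(k)
        j = rng.randrange(k - 1)
        if j >= i:
            j += 1
        a, b = lineages[i], lineages[j]
        node = next_node
        next_node += 1
        parent[a] = parent[b] = node
        times[node] = tau
        lineages = [x for x in lineages if x not in (a, b)]
        lineages.append(node)
    return lineages, next_node


def simulate_settlement_genealogy(
    params: SettlementDemography,
    sample_sizes: Sequence[int],
    rng,
    split_time_gens: float,
    ancestral_size: float,
) -> Genealogy:
    """Genealogy under the settlement demography for given draws."""
    rng = _as_rng(rng)
    tip_demes = np.repeat(np.arange(len(sample_sizes)), [2 * s for s in sample_sizes])
    n = len(tip_demes)
    parent = [-1] * (2 * n - 1)
    times = [0.0] * (2 * n - 1)
    next_node = n
    beta = math.log(params.present_size / ancestral_size) / split_time_gens
    survivors = []
    for d in range(len(sample_sizes)):
        lineages = [i for i in range(n) if tip_demes[i] == d]
        lineages, next_node = _coalesce_growing(
            lineages, 0.0, split_time_gens, 2.0 * params.present_size, beta,
            parent, times, next_node, rng,
        )
        survivors.extend(lineages)
    # ancestral phase: constant size
    tau = split_time_gens
    lineages = survivors
    while len(lineages) > 1:
        k = len(lineages)
        tau += rng.expovariate(k * (k - 1) / 2.0 / (2.0 * ancestral_size))
        i = rng.randrange(k)
        j = rng.randrange(k - 1)
        if j >= i:
            j += 1
        a, b = lineages[i], lineages[j]
        node = next_node
        next_node += 1
        parent[a] = parent[b] = node
        times[node] = tau
        lineages = [x for x in lineages if x not in (a, b)]
        lineages.append(node)
    return Genealogy(
        parent=np.array(parent[: 2 * n - 1]),
        time=np.array(times[: 2 * n - 1]),
        tip_deme=tip_demes,
    )


def simulate_settlement_region(
    params: SettlementDemography,
    n_snps: int = 20,
    sample_sizes: Sequence[int] = DEFAULT_SETTLEMENT_SAMPLES,
    seed=None,
    linked: bool = True,
) -> LocusSet:
    """One simulated region of ``n_snps`` biallelic markers.

    Split time and ancestral size are drawn uniformly from their ranges;
    with ``linked=True`` (default) all markers share one genealogy, else
    each marker gets an independent genealogy under the same draws.  Samples
    larger than the present deme can still coalesce; a note is logged.
    """
    if n_snps < 1:
        raise ValidationError("n_snps must be >= 1")
    rng = _as_rng(seed)
    lo_t, hi_t = params.split_time_range_years
    split_gens = (lo_t + (hi_t - lo_t) * rng.random()) / params.generation_years
    lo_n, hi_n = params.ancestral_size_range
    anc = lo_n + (hi_n - lo_n) * rng.random()
    sampled = list(range(len(sample_sizes)))
    if linked:
        gen = simulate_settlement_genealogy(params, sample_sizes, rng, split_gens, anc)
        tip_sets = place_mutations(gen, n_snps, rng)
        sizes, derived = _counts_from_tips(gen, tip_sets, sampled)
    else:
        rows = []
        for _ in range(n_snps):
            gen = simulate_settlement_genealogy(params, sample_sizes, rng, split_gens, anc)
            tips = place_mutations(gen, 1, rng)
            sizes, row = _counts_from_tips(gen, tips, sampled)
            rows.append(row[0])
        derived = np.vstack(rows)
    return LocusSet(deme_ids=np.array(sampled), n_alleles=sizes, derived=derived)


def summarize_loci(loci: LocusSet, deme_names: Sequence[str] | None = None) -> SummaryStats:
    """He / F_ST summaries of a locus set.

    Per-locus unbiased heterozygosity is averaged within demes then across
    demes and loci; global F_ST is the across-loci ratio-of-sums of the
    allele-count ANOVA components; pairwise F_ST likewise per deme pair.
    Monomorphic loci contribute He = 0 and zero components to the ratios.
    """
    sizes = np.asarray(loci.n_alleles, float)
    derived = np.asarray(loci.derived, float)
    L, D = derived.shape
    p = derived / sizes[None, :]
    he = 2.0 * p * (1.0 - p) * (sizes / (sizes - 1.0))[None, :]
    per_locus_he = he.mean(axis=1)
    num = den = 0.0
    for k in range(L):
        s_a, s_w = fst_components(sizes, derived[k])
        num += s_a
        den += s_a + s_w
    global_fst = num / den if den != 0 else np.nan
    pairs = [(i, j) for i in range(D) for j in range(D) if i < j]
    pw = []
    for i, j in pairs:
        num = den = 0.0
        for k in range(L):
            s_a, s_w = fst_components(sizes[[i, j]], derived[k][[i, j]])
            num += s_a
            den += s_a + s_w
        pw.append(num / den if den != 0 else np.nan)
    names = list(deme_names) if deme_names else [str(d) for d in loci.deme_ids]
    labels = [f"fst_{names[i]}_{names[j]}" for i, j in pairs]
    return SummaryStats(
        mean_he=float(per_locus_he.mean()),
        global_fst=float(global_fst),
        pairwise_fst=np.array(pw),
        per_locus_he=per_locus_he,
        labels=labels,
    )
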