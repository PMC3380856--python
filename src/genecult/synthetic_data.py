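"""Synthetic-data generators with the statistical structure the analyses assume.

Three generators make every stage of the pipeline testable without any
external download:

* :func:`simulate_drift_table` — forward Wright-Fisher drift of one SNP in a
  structured metapopulation, with optional additive viability selection in
  one designated group (the selective-sweep scenario);
* :func:`simulate_age_panel` — haplotype panels around a focal derived
  allele of known age: an intra-allelic genealogy under exponential growth
  of the allele class, with recombination eroding each flanking marker's
  association along the tree;
* :func:`fixtures` — the packaged transcriptions of the study's population
  genotype table and Zea-pollen date table.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .allele_age import HaplotypePanel
from .coalescent import LocusSet, _coalesce_growing
from .errors import ValidationError
from .geneculture import PollenRecord, read_pollen_table
from .popdata import PopulationRecord, PopulationTable, read_population_table

__all__ = [
    "DriftScenario",
    "AgePanelScenario",
    "Fixtures",
    "simulate_drift_table",
    "simulate_drift_locus_set",
    "simulate_age_panel",
    "fixtures",
]

#: Populations per subdivision in the source study's Table 1 layout.
STUDY_GROUP_SIZES = {
    "mesoamerican_agriculturalist": 16,
    "andean_agriculturalist": 7,
    "sa_hunter_gatherer": 27,
}


@dataclass
class DriftScenario:
    """Forward-drift scenario for one biallelic SNP in a grouped metapopulation.

    Defaults emulate the study conditions: the three subsistence
    subdivisions with their Table 1 population counts, demes of 830
    diploids (the settlement-model effective size), 400 generations
    (10,000 years at 25 y/generation) and weak gene flow.  ``selection_s``
    applies additive viability selection (fitnesses 1, 1+s/2, 1+s for the
    alt allele) in ``selected_group`` only.
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(STUDY_GROUP_SIZES))
    founder_frequency: float = 0.1
    generations: int = 400
    deme_size: int = 830
    migration: float = 0.01
    selection_s: float = 0.0
    selected_group: str | None = None
    sample_n: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.selection_s <= 1.0:
            raise ValidationError("selection coefficient must lie in [-1, 1]")
        if min(self.generations, self.deme_size, self.sample_n) <= 0:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.migration <= 1.0:
            raise ValidationError("migration must lie in [0, 1]")
        if self.selection_s != 0.0 and self.selected_group is None:
            self.selected_group = next(iter(self.group_sizes))


def _evolve_frequencies(scenario: DriftScenario, rng: np.random.Generator) -> dict[str, np.ndarray]:
    groups = list(scenario.group_sizes)
    p = {g: np.full(scenario.group_sizes[g], scenario.founder_frequency) for g in groups}
    two_n = 2 * scenario.deme_size
    s = scenario.selection_s
    for _ in range(scenario.generations):
        all_p = np.concatenate([p[g] for g in groups])
        meta = all_p.mean()
        for g in groups:
            q = (1.0 - scenario.migration) * p[g] + scenario.migration * meta
            if s != 0.0 and g == scenario.selected_group:
                w_bar = q**2 * (1 + s) + 2 * q * (1 - q) * (1 + s / 2) + (1 - q) ** 2
                q = (q**2 * (1 + s) + q * (1 - q) * (1 + s / 2)) / w_bar
            p[g] = rng.binomial(two_n, q) / two_n
    return p


def simulate_drift_table(scenario: DriftScenario) -> PopulationTable:
    """Forward Wright-Fisher simulation returning a genotype-count table.

    Migration mixes each deme toward the metapopulation mean frequency,
    viability selection acts in the designated group, binomial drift
    resamples each deme, and final genotype counts are drawn multinomially
    under Hardy-Weinberg at each deme's final frequency.  Fixation and loss
    are allowed.
    """
    rng = np.random.default_rng(scenario.seed)
    p = _evolve_frequencies(scenario, rng)
    records = []
    for g, freqs in p.items():
        for i, pf in enumerate(freqs):
            probs = [(1 - pf) ** 2, 2 * pf * (1 - pf), pf**2]
            n_rr, n_ra, n_aa = rng.multinomial(scenario.sample_n, probs)
            records.append(
                PopulationRecord(
                    name=f"{g}_{i}", subdivision=g, n=scenario.sample_n,
                    n_rr=int(n_rr), n_ra=int(n_ra), n_aa=int(n_aa),
                )
            )
    return PopulationTable(records, locus_id="synthetic_drift")


def simulate_drift_locus_set(
    scenario: DriftScenario,
    n_loci: int,
    founder_range: tuple[float, float] = (0.05, 0.95),
) -> LocusSet:
    """Stack of independent drift loci as per-deme allele counts.

    One deme per group; each locus draws its founder frequency uniformly
    from ``founder_range`` (standing variation) and evolves independently
    under the same demography (and selection, if any).  Alt-allele counts
    are binomial draws from each deme's final frequency.
    """
    rng = np.random.default_rng(scenario.seed)
    groups = list(scenario.group_sizes)
    one_per_group = {g: 1 for g in groups}
    sizes = np.full(len(groups), 2 * scenario.sample_n)
    rows = []
    for _ in range(n_loci):
        f0 = rng.uniform(*founder_range)
        sub = DriftScenario(
            group_sizes=one_per_group,
            founder_frequency=f0,
            generations=scenario.generations,
            deme_size=scenario.deme_size,
            migration=scenario.migration,
            selection_s=scenario.selection_s,
            selected_group=scenario.selected_group,
            sample_n=scenario.sample_n,
        )
        p = _evolve_frequencies(sub, rng)
        rows.append([rng.binomial(2 * scenario.sample_n, p[g][0]) for g in groups])
    return LocusSet(
        deme_ids=np.arange(len(groups)), n_alleles=sizes, derived=np.array(rows)
    )


def apply_sweep_to_locus_set(
    loci: LocusSet,
    deme_index: int,
    s: float,
    generations: int,
    deme_size: int = 830,
    seed: int | None = None,
) -> LocusSet:
    """Overlay a directional sweep on one deme of a neutral locus set.

    Emulates selection linked to every marker of the region in one deme
    (e.g. a sweep in Mesoamerica after the settlement split): each locus's
    frequency in that deme is evolved forward ``generations`` generations
    under additive viability selection (fitnesses 1, 1+s/2, 1+s) with
    binomial drift at ``deme_size`` diploids, then the deme's sample counts
    are redrawn binomially.  Loci without the derived allele in that deme
    are left untouched (nothing to select).  Other demes are unchanged, so
    a swept set is directly comparable, pair by pair, with its neutral
    original.
    """
    rng = np.random.default_rng(seed)
    derived = loci.derived.copy()
    n_al = int(loci.n_alleles[deme_index])
    two_n = 2 * deme_size
    for k in range(loci.n_loci):
        p = derived[k, deme_index] / n_al
        if p == 0.0:
            continue
        for _ in range(generations):
            w_bar = p**2 * (1 + s) + 2 * p * (1 - p) * (1 + s / 2) + (1 - p) ** 2
            p = (p**2 * (1 + s) + p * (1 - p) * (1 + s / 2)) / w_bar
            p = rng.binomial(two_n, p) / two_n
            if p in (0.0, 1.0):
                break
        derived[k, deme_index] = rng.binomial(n_al, p)
    return LocusSet(deme_ids=loci.deme_ids, n_alleles=loci.n_alleles, derived=derived)


@dataclass
class AgePanelScenario:
    """Haplotype-panel scenario around a derived allele of known age.

    Defaults mirror the study's LD-dating setting: 19 flanking markers,
    population growth 0.005 per generation and a sampled fraction of
    0.0002 (which sets the present-day size of the allele class, and hence
    how star-like the intra-allelic genealogy is).  ``background_freq``
    gives the frequency of the ancestral-haplotype allele among
    non-carrier chromosomes.
    """

    true_age_generations: float = 300.0
    n_carriers: int = 40
    n_noncarriers: int = 160
    rec_frac: np.ndarray = field(
        default_factory=lambda: np.geomspace(2e-4, 1e-2, 19)
    )
    background_freq: np.ndarray = field(
        default_factory=lambda: np.linspace(0.2, 0.8, 19)
    )
    growth_rate: float = 0.005
    sampled_fraction: float = 0.0002
    seed: int | None = None

    def __post_init__(self) -> None:
        self.rec_frac = np.asarray(self.rec_frac, float)
        self.background_freq = np.asarray(self.background_freq, float)
        if self.true_age_generations <= 0:
            raise ValidationError("true age must be positive")
        if np.any((self.rec_frac < 0) | (self.rec_frac > 0.5)):
            raise ValidationError("recombination fractions must lie in [0, 0.5]")
        if self.rec_frac.shape != self.background_freq.shape:
            raise ValidationError("rec_frac and background_freq must have equal length")


def _intra_allelic_tree(n: int, age: float, class_size: float, rng: random.Random):
    """Genealogy of n carrier lineages inside an exponentially growing allele
    class that had a single copy ``age`` generations ago.  Lineages that have
    not coalesced by the allele's origin join the founder there."""
    parent = [-1] * (2 * n - 1)
    times = [0.0] * (2 * n - 1)
    growth = math.log(class_size) / age  # class shrinks to 1 copy at the origin
    # _coalesce_growing takes a diploid size; the allele class is counted in
    # chromosomes, so pass half its size to get pair rate k(k-1)/2 / class.
    lineages, next_node = _coalesce_growing(
        list(range(n)), 0.0, age, class_size / 2.0, growth, parent, times, next_node=n, rng=rng
    )
    while len(lineages) > 1:  # founding: remaining lineages meet at the origin
        a, b = lineages[0], lineages[1]
        node = next_node
        next_node += 1
        parent[a] = parent[b] = node
        times[node] = age
        lineages = lineages[2:] + [node]
    return np.array(parent), np.array(times)


def simulate_age_panel(scenario: AgePanelScenario) -> HaplotypePanel:
    """Simulate a phased haplotype panel around a derived allele of known age.

    Carrier chromosomes descend from one founding haplotype (allele 1 at
    every marker); on each branch of their intra-allelic genealogy, marker
    i recombines onto the population background with probability
    1 - exp(-c_i * branch length), after which the allele is a background
    draw.  Non-carriers are independent background draws.
    """
    rng = random.Random(scenario.seed)
    n = scenario.n_carriers
    M = len(scenario.rec_frac)
    class_size = max(n / scenario.sampled_fraction, n + 1.0)
    parent, times = _intra_allelic_tree(n, scenario.true_age_generations, class_size, rng)
    root = len(parent) - 1
    children: list[list[int]] = [[] for _ in range(len(parent))]
    for u in range(root):
        children[parent[u]].append(u)
    stem = scenario.true_age_generations - times[root]  # origin to sample MRCA
    carr_markers = np.empty((n, M), dtype=int)
    for j, (c, b) in enumerate(zip(scenario.rec_frac, scenario.background_freq)):
        state = [0] * len(parent)  # 1 while still on the ancestral haplotype
        # the stem branch from the founding mutation down to the MRCA decays too
        state[root] = 1 if rng.random() < math.exp(-c * stem) else 2
        stack = [root]
        while stack:
            u = stack.pop()
            for v in children[u]:
                length = times[u] - times[v]
                if state[u] == 1 and rng.random() < 1.0 - math.exp(-c * length):
                    state[v] = 2  # recombined onto background
                else:
                    state[v] = state[u]
                stack.append(v)
        for tip in range(n):
            if state[tip] == 1:
                carr_markers[tip, j] = 1
            else:
                carr_markers[tip, j] = 1 if rng.random() < b else 0
    non_markers = np.array(
        [
            [1 if rng.random() < b else 0 for b in scenario.background_freq]
            for _ in range(scenario.n_noncarriers)
        ],
        dtype=int,
    ).reshape(scenario.n_noncarriers, M)
    markers = np.vstack([carr_markers, non_markers])
    carrier = np.zeros(n + scenario.n_noncarriers, bool)
    carrier[:n] = True
    return HaplotypePanel(
        carrier=carrier,
        markers=markers,
        rec_frac=scenario.rec_frac.copy(),
        ancestral_haplotype=np.ones(M, int),
    )


@dataclass(frozen=True)
class Fixtures:
    table1: PopulationTable
    table2: list[PollenRecord]


def fixtures() -> Fixtures:
    """The packaged study tables: genotype counts and Zea pollen dates."""
    data = resources.files("genecult") / "data"
    with resources.as_file(data / "table1.csv") as p:
        table1 = read_population_table(p, locus_id="ABCA1_Arg230Cys")
    with resources.as_file(data / "table2.csv") as p:
        table2 = read_pollen_table(p)
    return Fixtures(table1=table1, table2=table2)
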