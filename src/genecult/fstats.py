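"""Hierarchical AMOVA and F-statistics on single-SNP allele-count data.

The model is the standard allele-level nested analysis of variance: each
diploid individual contributes its two alleles as exchangeable observations,
and allelic variance is partitioned among groups of populations (F_CT), among
populations within groups (F_SC) and within populations, with fixation
indices formed from the variance components exactly as in the classical
AMOVA framework.  Significance is assessed by permutation: whole populations
are permuted among groups for F_CT, individuals among populations for F_SC
and F_ST.  Negative variance components are retained in results and clamped
to zero only in percentage-of-variance displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .popdata import FrequencyMatrix, PopulationTable

__all__ = [
    "AmovaResult",
    "amova",
    "within_group_fst",
    "pairwise_fst",
    "allele_count_fst",
    "fst_components",
]


@dataclass
class AmovaResult:
    """Variance components, fixation indices and permutation p-values."""

    sigma_among_groups: float
    sigma_among_pops_within: float
    sigma_within_pops: float
    fct: float
    fsc: float
    fst: float
    p_fct: float | None = None
    p_fsc: float | None = None
    p_fst: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    monomorphic: bool = False

    @property
    def percent_variance(self) -> tuple[float, float, float]:
        """Percentages of total variance, components clamped at zero."""
        comps = np.clip(
            [self.sigma_among_groups, self.sigma_among_pops_within, self.sigma_within_pops],
            0.0,
            None,
        )
        total = comps.sum()
        if total == 0:
            return (0.0, 0.0, 0.0)
        return tuple(100.0 * comps / total)  # type: ignore[return-value]


def _nested_components(sizes_by_group, alts_by_group):
    """Variance components of the allele-level nested ANOVA.

    ``sizes_by_group``/``alts_by_group``: one array per group of per-population
    allele sample sizes and alt-allele counts.  Returns (sigma_a, sigma_b,
    sigma_c) for among-groups / among-populations-within / within-populations.
    Uses the unequal-size expected-mean-square coefficients of the nested
    design.
    """
    G = len(sizes_by_group)
    P = sum(len(s) for s in sizes_by_group)
    N = float(sum(s.sum() for s in sizes_by_group))
    A = float(sum(a.sum() for a in alts_by_group))
    pbar = A / N
    ss_ag = ss_ap = ss_wp = 0.0
    s_n2_over_ng = s_ng2 = s_n2 = 0.0
    for n, a in zip(sizes_by_group, alts_by_group):
        n = np.asarray(n, float)
        a = np.asarray(a, float)
        ng = n.sum()
        p = a / n
        pg = a.sum() / ng
        ss_ag += ng * (pg - pbar) ** 2
        ss_ap += float((n * (p - pg) ** 2).sum())
        ss_wp += float((n * p * (1.0 - p)).sum())
        s_n2_over_ng += float((n**2).sum()) / ng
        s_ng2 += ng**2
        s_n2 += float((n**2).sum())
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ss_wp / df_wp
    sigma_c = ms_wp
    if df_ap > 0:
        n1 = (N - s_n2_over_ng) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:  # one population per group: no within-group level
        sigma_b = 0.0
    if df_ag > 0:
        n2 = (s_n2_over_ng - s_n2 / N) / df_ag
        n3 = (N - s_ng2 / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = np.nan
    return sigma_a, sigma_b, sigma_c


def fst_components(n_alleles: Sequence[float], alt_counts: Sequence[float]) -> tuple[float, float]:
    """One-level ANOVA components (sigma_among, sigma_within) for allele counts.

    The ratio sigma_a / (sigma_a + sigma_w) is the multi-population F_ST
    estimator; summing components across loci before taking the ratio gives
    the standard multi-locus (ratio-of-sums) estimator.
    """
    n = np.asarray(n_alleles, float)
    a = np.asarray(alt_counts, float)
    if len(n) < 2:
        raise ValidationError("F_ST needs at least two populations")
    N = n.sum()
    P = len(n)
    p = a / n
    pbar = a.sum() / N
    ms_ap = float((n * (p - pbar) ** 2).sum()) / (P - 1)
    ms_wp = float((n * p * (1.0 - p)).sum()) / (N - P)
    nc = (N - float((n**2).sum()) / N) / (P - 1)
    sigma_a = (ms_ap - ms_wp) / nc
    return sigma_a, ms_wp


def allele_count_fst(n_alleles: Sequence[float], alt_counts: Sequence[float]) -> float:
    """Multi-population F_ST from allele sample sizes and alt counts (raw, unclamped)."""
    sigma_a, sigma_w = fst_components(n_alleles, alt_counts)
    tot = sigma_a + sigma_w
    return float("nan") if tot == 0 else sigma_a / tot


def _dosage_vectors(table: PopulationTable) -> list[np.ndarray]:
    """Per-population vectors of individual alt-allele dosages (0/1/2)."""
    return [
        np.repeat([0, 1, 2], [r.n_rr, r.n_ra, r.n_aa]).astype(np.int64) for r in table
    ]


def _group_arrays(table: PopulationTable, grouping: Mapping[str, str]):
    order: dict[str, list[int]] = {}
    for i, r in enumerate(table):
        order.setdefault(grouping[r.name], []).append(i)
    sizes = np.array([r.n_alleles for r in table], float)
    alts = np.array([r.alt_count for r in table], float)
    idx_by_group = [np.array(ix) for ix in order.values()]
    return sizes, alts, idx_by_group


def amova(
    table: PopulationTable,
    grouping: Mapping[str, str] | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical allele-level AMOVA with permutation p-values.

    ``grouping`` maps population name to group label; by default each
    record's subdivision label is used.  ``p_fct`` permutes whole populations
    among groups, ``p_fsc`` permutes individuals among populations within
    groups, ``p_fst`` permutes individuals among all populations; all
    p-values include the observed statistic in numerator and denominator.
    """
    if grouping is None:
        grouping = {r.name: r.subdivision for r in table}
    groups = sorted(set(grouping.values()))
    sizes, alts, idx_by_group = _group_arrays(table, grouping)
    if alts.sum() == 0 or alts.sum() == sizes.sum():
        return AmovaResult(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, monomorphic=True, seed=seed
        )
    if len(groups) == 1:
        # one group: F_CT undefined, the one-level F_ST is still meaningful
        sigma_a, sigma_w = fst_components(sizes, alts)
        fst = sigma_a / (sigma_a + sigma_w)
        p_fst = None
        if n_permutations > 0:
            rng = np.random.default_rng(seed)
            pool = np.concatenate(_dosage_vectors(table))
            cuts = np.cumsum([r.n for r in table])[:-1]
            hits = 1
            for _ in range(n_permutations):
                shuffled = rng.permutation(pool)
                alts_perm = np.array([seg.sum() for seg in np.split(shuffled, cuts)], float)
                if allele_count_fst(sizes, alts_perm) >= fst:
                    hits += 1
            p_fst = hits / (n_permutations + 1)
        return AmovaResult(
            sigma_among_groups=np.nan,
            sigma_among_pops_within=sigma_a,
            sigma_within_pops=sigma_w,
            fct=np.nan,
            fsc=fst,
            fst=fst,
            p_fsc=p_fst,
            p_fst=p_fst,
            n_permutations=n_permutations,
            seed=seed,
        )

    def _ratio(num, den):
        return num / den if den != 0 else float("nan")

    def hier_stats(idx_groups):
        sa, sb, sc = _nested_components(
            [sizes[ix] for ix in idx_groups], [alts[ix] for ix in idx_groups]
        )
        tot = sa + sb + sc
        return sa, sb, sc, _ratio(sa, tot), _ratio(sb, sb + sc), _ratio(sa + sb, tot)

    sa, sb, sc, fct, fsc, fst = hier_stats(idx_by_group)

    p_fct = p_fsc = p_fst = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        group_sizes = [len(ix) for ix in idx_by_group]
        splits = np.cumsum(group_sizes)[:-1]
        hits_fct = 1
        for _ in range(n_permutations):
            perm = rng.permutation(len(table))
            idx_perm = np.split(perm, splits)
            if hier_stats(idx_perm)[3] >= fct:
                hits_fct += 1
        p_fct = hits_fct / (n_permutations + 1)

        dosages = _dosage_vectors(table)
        n_ind = np.array([r.n for r in table])
        # F_SC: shuffle individuals within each group, keep population sizes
        hits_fsc = 1
        pooled = [np.concatenate([dosages[i] for i in ix]) for ix in idx_by_group]
        for _ in range(n_permutations):
            alts_perm = alts.copy()
            for ix, pool in zip(idx_by_group, pooled):
                shuffled = rng.permutation(pool)
                cuts = np.cumsum(n_ind[ix])[:-1]
                alts_perm[ix] = [seg.sum() for seg in np.split(shuffled, cuts)]
            sa_, sb_, sc_ = _nested_components(
                [sizes[ix] for ix in idx_by_group], [alts_perm[ix] for ix in idx_by_group]
            )
            if sb_ / (sb_ + sc_) >= fsc:
                hits_fsc += 1
        p_fsc = hits_fsc / (n_permutations + 1)

        # F_ST: shuffle individuals among all populations
        hits_fst = 1
        pool_all = np.concatenate(dosages)
        cuts_all = np.cumsum(n_ind)[:-1]
        for _ in range(n_permutations):
            shuffled = rng.permutation(pool_all)
            alts_perm = np.array([seg.sum() for seg in np.split(shuffled, cuts_all)], float)
            sa_, sb_, sc_ = _nested_components(
                [sizes[ix] for ix in idx_by_group], [alts_perm[ix] for ix in idx_by_group]
            )
            if (sa_ + sb_) / (sa_ + sb_ + sc_) >= fst:
                hits_fst += 1
        p_fst = hits_fst / (n_permutations + 1)

    return AmovaResult(
        sigma_among_groups=sa,
        sigma_among_pops_within=sb,
        sigma_within_pops=sc,
        fct=fct,
        fsc=fsc,
        fst=fst,
        p_fct=p_fct,
        p_fsc=p_fsc,
        p_fst=p_fst,
        n_permutations=n_permutations,
        seed=seed,
    )


def within_group_fst(
    table: PopulationTable,
    group: str,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """One-level AMOVA F_ST among the populations of one subdivision.

    Permutes individuals among the group's populations; returns (fst, p).
    """
    sub = table.subset(group)
    if len(sub) < 2:
        raise ValidationError(f"group {group!r} has fewer than two populations")
    sizes = np.array([r.n_alleles for r in sub], float)
    alts = np.array([r.alt_count for r in sub], float)
    fst = allele_count_fst(sizes, alts)
    if n_permutations <= 0:
        return fst, None
    rng = np.random.default_rng(seed)
    pool = np.concatenate(_dosage_vectors(sub))
    cuts = np.cumsum([r.n for r in sub])[:-1]
    hits = 1
    for _ in range(n_permutations):
        shuffled = rng.permutation(pool)
        alts_perm = np.array([seg.sum() for seg in np.split(shuffled, cuts)], float)
        if allele_count_fst(sizes, alts_perm) >= fst:
            hits += 1
    return fst, hits / (n_permutations + 1)


def pairwise_fst(data: PopulationTable | FrequencyMatrix) -> pd.DataFrame:
    """Two-population F_ST for every pair, raw (negative estimates retained).

    For a multi-locus :class:`FrequencyMatrix` each pair's estimate is the
    ratio-of-sums across loci; pairs with a missing cell at some locus use
    the loci observed in both populations and are NaN when none remain.
    """
    if isinstance(data, PopulationTable):
        names = [r.name for r in data]
        sizes = np.array([[r.n_alleles for r in data]], float)
        freqs = np.array([[r.alt_count / r.n_alleles for r in data]], float)
    else:
        names = data.populations
        sizes = data.n_alleles.to_numpy(float)
        freqs = data.freq.to_numpy(float)
    P = len(names)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            ok = ~np.isnan(freqs[:, i]) & ~np.isnan(freqs[:, j])
            num = den = 0.0
            for k in np.flatnonzero(ok):
                n = np.array([sizes[k, i], sizes[k, j]])
                a = np.array([freqs[k, i] * sizes[k, i], freqs[k, j] * sizes[k, j]])
                s_a, s_w = fst_components(n, a)
                num += s_a
                den += s_a + s_w
            out[i, j] = out[j, i] = num / den if den != 0 and ok.any() else np.nan
    return pd.DataFrame(out, index=names, columns=names)
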