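"""F_ST-outlier detection against an island-model null (fdist-style).

The null is a cloud of (He, F_ST) pairs from single-SNP coalescent
simulations of a (hierarchical) island model.  A locus's p-value conditions
on heterozygosity: null points are weighted by a Gaussian kernel on the
distance between their He and the observed He, and the p-value is the
weighted proportion of null F_ST values at least as large as observed
(upper tail; a two-tailed option doubles the smaller tail).  Add-one
smoothing keeps p strictly positive: with kernel weights normalised to 1 at
zero distance, p = (sum w_i I_i + 1) / (sum w_i + 1), so a locus above every
null point reports the floor 1 / (effective n + 1).  Exactly-tied null
points count half (mid-p), which keeps the null p-value distribution close
to uniform despite the discreteness of single-SNP F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import IslandModelConfig, LocusSet, simulate_island_snp
from .errors import DomainError, ValidationError
from .fstats import allele_count_fst
from .popdata import FrequencyMatrix, expected_heterozygosity

__all__ = ["NullCloud", "OutlierReport", "build_null", "kde_pvalue", "outlier_scan", "locus_he_fst"]


@dataclass
class NullCloud:
    """(He, F_ST) pairs simulated under the island-model null."""

    he: np.ndarray
    fst: np.ndarray
    config: IslandModelConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.he = np.asarray(self.he, float)
        self.fst = np.asarray(self.fst, float)
        if self.he.shape != self.fst.shape or self.he.size == 0:
            raise ValidationError("null cloud needs matching, non-empty he/fst arrays")

    @property
    def n_sims(self) -> int:
        return self.he.size


@dataclass
class OutlierReport:
    """Per-locus outlier calls plus conditional-quantile envelope curves."""

    table: pd.DataFrame  # locus, he, fst, p_value, outlier
    envelope: pd.DataFrame  # he_grid, q025, q50, q975
    alpha: float
    excluded: dict[str, str] = field(default_factory=dict)


def build_null(config: IslandModelConfig, n_sims: int = 50_000, seed: int | None = None) -> NullCloud:
    """Simulate ``n_sims`` independent null SNPs and summarise each to (He, F_ST)."""
    rng = np.random.default_rng(seed)
    import random as _random

    prng = _random.Random(int(rng.integers(0, 2**31 - 1)))
    he = np.empty(n_sims)
    fst = np.empty(n_sims)
    for i in range(n_sims):
        loc = simulate_island_snp(config, prng)
        p = loc.derived / loc.n_alleles
        he[i] = np.mean(
            [expected_heterozygosity(pi, int(na), unbiased=True) for pi, na in zip(p, loc.n_alleles)]
        )
        fst[i] = allele_count_fst(loc.n_alleles, loc.derived)
    return NullCloud(he=he, fst=fst, config=config, seed=seed)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * n ** (-0.2)


def kde_pvalue(
    observed: tuple[float, float],
    null: NullCloud,
    bandwidth: float | str = "silverman",
    tail: str = "upper",
    tie_break: str = "mid",
    rng: np.random.Generator | None = None,
) -> float:
    """He-conditional kernel-weighted p-value of an observed (He, F_ST) point.

    ``tie_break="mid"`` (default) gives the deterministic mid-p;
    ``"random"`` draws the classical randomized p-value (uniform under the
    null even though single-SNP F_ST is discrete), which is the appropriate
    choice when assessing calibration.
    """
    he_obs, fst_obs = observed
    if null.n_sims < 2 or np.allclose(null.he, null.he[0]) and np.allclose(null.fst, null.fst[0]):
        raise DomainError("degenerate null cloud")
    h = _silverman_bandwidth(null.he) if bandwidth == "silverman" else float(bandwidth)
    w = np.exp(-0.5 * ((null.he - he_obs) / h) ** 2)
    if w.sum() < 1e-6:  # observed He far outside the null support
        import warnings

        warnings.warn("observed He outside null support; nearest-neighbourhood fallback", stacklevel=2)
        nearest = np.argsort(np.abs(null.he - he_obs))[: max(50, null.n_sims // 100)]
        w = np.zeros_like(w)
        w[nearest] = 1.0
    # tied null points: mid-p counts them half; the randomized variant
    # spreads them (and the add-one smoothing mass) uniformly
    w_gt = w[null.fst > fst_obs].sum()
    w_eq = w[null.fst == fst_obs].sum()
    if tie_break == "mid":
        # deterministic mid-p; the add-one smoothing keeps the floor 1/(n_eff+1)
        upper = (w_gt + 0.5 * w_eq + 1.0) / (w.sum() + 1.0)
        u = 0.5
    elif tie_break == "random":
        u = float((rng or np.random.default_rng()).random())
        upper = (w_gt + u * (w_eq + 1.0)) / (w.sum() + 1.0)
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    if tail == "upper":
        return float(upper)
    if tail == "two":
        w_lt = w[null.fst < fst_obs].sum()
        lower = (w_lt + (1.0 - u) * w_eq + u) / (w.sum() + 1.0)
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError(f"unknown tail {tail!r}")


def locus_he_fst(sizes: np.ndarray, derived: np.ndarray) -> tuple[float, float]:
    """(mean unbiased He, F_ST) of a single locus from per-deme counts."""
    p = derived / sizes
    he = float(
        np.mean([expected_heterozygosity(pi, int(n), unbiased=True) for pi, n in zip(p, sizes)])
    )
    return he, allele_count_fst(sizes, derived)


def outlier_scan(
    observed: FrequencyMatrix | LocusSet,
    null: NullCloud,
    alpha: float = 0.05,
    bandwidth: float | str = "silverman",
    tail: str = "upper",
    he_grid: np.ndarray | None = None,
) -> OutlierReport:
    """Scan loci for excess differentiation given their heterozygosity.

    Loci with missing cells or monomorphic in the pooled sample are excluded
    and listed with their reason.  The envelope reports kernel-weighted
    conditional quantiles {0.025, 0.5, 0.975} of null F_ST over a He grid.
    """
    rows = []
    excluded: dict[str, str] = {}
    if isinstance(observed, FrequencyMatrix):
        loci = observed.loci
        freq = observed.freq.to_numpy(float)
        sizes_m = observed.n_alleles.to_numpy(float)
        for k, locus in enumerate(loci):
            f, s = freq[k], sizes_m[k]
            if np.isnan(f).any():
                excluded[str(locus)] = "missing cells"
                continue
            derived = f * s
            if derived.sum() == 0 or derived.sum() == s.sum():
                excluded[str(locus)] = "monomorphic in pooled sample"
                continue
            rows.append((str(locus), *locus_he_fst(s, derived)))
    else:
        sizes = np.asarray(observed.n_alleles, float)
        for k in range(observed.n_loci):
            derived = observed.derived[k].astype(float)
            if derived.sum() == 0 or derived.sum() == sizes.sum():
                excluded[f"locus_{k}"] = "monomorphic in pooled sample"
                continue
            rows.append((f"locus_{k}", *locus_he_fst(sizes, derived)))
    if not rows:
        raise ValidationError("no analysable locus")
    table = pd.DataFrame(rows, columns=["locus", "he", "fst"])
    table["p_value"] = [
        kde_pvalue((he, fst), null, bandwidth=bandwidth, tail=tail)
        for he, fst in zip(table.he, table.fst)
    ]
    table["outlier"] = table.p_value < alpha

    if he_grid is None:
        he_grid = np.linspace(null.he.min(), null.he.max(), 25)
    h = _silverman_bandwidth(null.he) if bandwidth == "silverman" else float(bandwidth)
    env_rows = []
    order = np.argsort(null.fst)
    fst_sorted = null.fst[order]
    for he0 in he_grid:
        w = np.exp(-0.5 * ((null.he[order] - he0) / h) ** 2)
        cw = np.cumsum(w)
        if cw[-1] == 0:
            env_rows.append((he0, np.nan, np.nan, np.nan))
            continue
        qs = [fst_sorted[np.searchsorted(cw, q * cw[-1])] for q in (0.025, 0.5, 0.975)]
        env_rows.append((he0, *qs))
    envelope = pd.DataFrame(env_rows, columns=["he", "q025", "q50", "q975"])
    return OutlierReport(table=table, envelope=envelope, alpha=alpha, excluded=excluded)
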