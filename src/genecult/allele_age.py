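"""Allele-age estimation.

Two families of estimators for the age of a derived allele:

* the frequency method: under neutrality and stationarity the expected age of
  an allele at population frequency p is E(t1) = [-2p/(1-p)] ln(p), in units
  of 2N generations;
* intra-allelic linkage-disequilibrium decay: chromosomes carrying the focal
  allele start on one ancestral haplotype, and recombination at rate c per
  generation erodes the association with each flanking marker as exp(-c t).
  A moment estimator inverts that decay for a single marker, and a
  Metropolis-Hastings sampler combines all markers in a composite likelihood
  with a coalescent-motivated prior.

Ages are reported simultaneously in 2N units, generations and years; the
conversion uses the diploid effective size and generation time carried by
:class:`DemographyParams`, so the time convention is always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "DemographyParams",
    "AgeEstimate",
    "HaplotypePanel",
    "kimura_ohta_age",
    "moment_ld_age",
    "mcmc_ld_age",
    "induced_age_prior",
    "read_haplotype_panel",
]


@dataclass(frozen=True)
class DemographyParams:
    """Demographic constants for age conversions and the LD-age prior.

    Defaults follow the source study's settings for the peopling of the
    Americas: diploid effective size 720, 25-year generations, population
    growth 0.005 per generation, and a sampled fraction of 0.0002.
    """

    n_effective: float = 720.0
    generation_years: float = 25.0
    growth_rate: float = 0.005
    sampled_fraction: float = 0.0002

    def __post_init__(self) -> None:
        if min(self.n_effective, self.generation_years, self.growth_rate, self.sampled_fraction) <= 0:
            raise DomainError("all demographic parameters must be positive")
        if self.sampled_fraction > 1:
            raise DomainError("sampled_fraction cannot exceed 1")


@dataclass
class AgeEstimate:
    """Allele age with its time convention made explicit."""

    age_2N_units: float
    age_generations: float
    age_years: float
    method: str
    ci_low: float | None = None  # years
    ci_high: float | None = None
    posterior_samples: np.ndarray | None = None  # generations
    notes: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.age_generations)


def _estimate(generations: float, params: DemographyParams, method: str, **kw) -> AgeEstimate:
    return AgeEstimate(
        age_2N_units=generations / (2.0 * params.n_effective),
        age_generations=generations,
        age_years=generations * params.generation_years,
        method=method,
        **kw,
    )


@dataclass
class HaplotypePanel:
    """Phased chromosomes around a focal biallelic site.

    ``carrier`` flags chromosomes bearing the focal derived allele;
    ``markers`` holds the allele state (small ints) at M flanking SNPs;
    ``rec_frac`` gives each marker's recombination fraction to the focal
    site.  The ancestral (founding) haplotype may be supplied; otherwise the
    modal allele among carriers is used marker by marker.
    """

    carrier: np.ndarray
    markers: np.ndarray
    rec_frac: np.ndarray
    ancestral_haplotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.carrier = np.asarray(self.carrier, bool)
        self.markers = np.asarray(self.markers)
        self.rec_frac = np.asarray(self.rec_frac, float)
        if self.markers.ndim != 2 or self.markers.shape[0] != self.carrier.shape[0]:
            raise ValidationError("markers must be (n_chromosomes, n_markers)")
        if self.markers.shape[1] != self.rec_frac.shape[0]:
            raise ValidationError("rec_frac length must match marker count")
        if not self.carrier.any():
            raise ValidationError("panel needs at least one carrier chromosome")
        if np.any((self.rec_frac < 0) | (self.rec_frac > 0.5)):
            raise ValidationError("recombination fractions must lie in [0, 0.5]")
        if self.ancestral_haplotype is not None:
            self.ancestral_haplotype = np.asarray(self.ancestral_haplotype)
            if self.ancestral_haplotype.shape[0] != self.markers.shape[1]:
                raise ValidationError("ancestral haplotype length must match marker count")

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    @property
    def n_carriers(self) -> int:
        return int(self.carrier.sum())

    def ancestral(self) -> np.ndarray:
        """Ancestral marker alleles: supplied, else per-marker carrier mode."""
        if self.ancestral_haplotype is not None:
            return self.ancestral_haplotype
        carr = self.markers[self.carrier]
        return np.array(
            [np.bincount(carr[:, j].astype(int)).argmax() for j in range(self.n_markers)]
        )

    def background_freq(self, anc: np.ndarray) -> np.ndarray:
        """Frequency of the ancestral-haplotype allele among non-carriers.

        Falls back to 0.5 for a marker with no non-carrier data.
        """
        non = self.markers[~self.carrier]
        if non.shape[0] == 0:
            return np.full(self.n_markers, 0.5)
        return (non == anc[None, :]).mean(axis=0)


def kimura_ohta_age(p: float, params: DemographyParams | None = None) -> AgeEstimate:
    """Expected age of a neutral allele from its frequency.

    E(t1) = [-2p/(1-p)] ln(p) in units of 2N generations (natural log);
    strictly increasing in p, with limit 2 as p -> 1.
    """
    params = params or DemographyParams()
    if not 0.0 < p < 1.0:
        raise DomainError("allele age from frequency is undefined at p=0 or p=1")
    age_2n = (-2.0 * p / (1.0 - p)) * np.log(p)
    gens = age_2n * 2.0 * params.n_effective
    return AgeEstimate(
        age_2N_units=age_2n,
        age_generations=gens,
        age_years=gens * params.generation_years,
        method="kimura_ohta",
    )


def moment_ld_age(
    panel: HaplotypePanel, marker: int, params: DemographyParams | None = None
) -> AgeEstimate:
    """Single-marker moment estimator of allele age from LD decay.

    With y the proportion of carrier chromosomes retaining the ancestral
    allele at the marker, corrected for the background frequency q of that
    allele (y' = (y - q) / (1 - q)), the decay model y' = exp(-c t) inverts
    to t = -ln(y') / c generations.  y' >= 1 clamps to age 0; y' <= 0 yields
    an undefined estimate.
    """
    params = params or DemographyParams()
    c = float(panel.rec_frac[marker])
    if c == 0.0:
        raise DomainError(f"uninformative marker {marker}: recombination fraction is 0")
    anc = panel.ancestral()
    y = float((panel.markers[panel.carrier, marker] == anc[marker]).mean())
    q = float(panel.background_freq(anc)[marker])
    y_prime = (y - q) / (1.0 - q) if q < 1.0 else np.nan
    if not np.isfinite(y_prime) or y_prime <= 0.0:
        return _estimate(
            float("nan"), params, "moment_ld", notes=["undefined: corrected retention <= 0"]
        )
    t_hat = 0.0 if y_prime >= 1.0 else -np.log(y_prime) / c
    return _estimate(t_hat, params, "moment_ld")


def induced_age_prior(params: DemographyParams, n_carriers: int, log_sd: float = 1.5):
    """Prior on allele age induced by growth and the sampled fraction.

    Under deterministic exponential growth at rate r, an allele observed on
    k sampled chromosomes from a fraction f of the population has of order
    K = k/f copies today, which a single founding copy reaches in
    ln(K)/r generations; that point anchors the prior median.  Because a
    selected allele grows faster than its host population, the prior is kept
    weakly informative (lognormal, default log-sd 1.5).  Returns a frozen
    scipy distribution over age in generations.
    """
    K = max(n_carriers / params.sampled_fraction, np.e)
    t_median = np.log(K) / params.growth_rate
    return stats.lognorm(s=log_sd, scale=t_median)


def _marker_retention_counts(panel: HaplotypePanel):
    anc = panel.ancestral()
    q = panel.background_freq(anc)
    carr = panel.markers[panel.carrier]
    n_anc = (carr == anc[None, :]).sum(axis=0).astype(float)
    n_tot = np.full(panel.n_markers, carr.shape[0], float)
    return n_anc, n_tot, q


def mcmc_ld_age(
    panel: HaplotypePanel,
    params: DemographyParams | None = None,
    iterations: int = 100_000,
    burn_in: int | None = None,
    seed: int | None = None,
) -> AgeEstimate:
    """Composite-likelihood Metropolis-Hastings sampler for allele age.

    The intra-allelic genealogy is approximated by two layers: a stem — the
    interval between the founding mutation and the carriers' most recent
    common ancestor, a fraction ``phi`` of the age — and a star-like
    genealogy of depth ``(1-phi) t`` below the MRCA.  Marker by marker, a
    recombination on the stem (probability 1 - exp(-c phi t)) replaces the
    whole carrier class by background alleles; otherwise each carrier
    retains the ancestral allele with probability
    exp(-c (1-phi) t) + (1 - exp(-c (1-phi) t)) q, where q is the
    background frequency.  The sampler walks (log t, logit phi) jointly
    under the :func:`induced_age_prior` on t and a flat prior on phi, with
    proposal scales adapted during burn-in toward 20-50% acceptance.
    Returns the posterior mean as the point estimate with the central 95%
    credible interval, the posterior mode in ``notes``, and the full
    post-burn-in age chain.  Markers with zero recombination fraction
    contribute a flat likelihood, so an entirely uninformative panel
    reproduces the prior.
    """
    params = params or DemographyParams()
    burn_in = iterations // 5 if burn_in is None else burn_in
    if iterations <= burn_in:
        raise DomainError("iterations must exceed burn_in")
    if panel.n_markers == 0:
        raise DomainError("zero informative markers")
    n_anc, n_tot, q = _marker_retention_counts(panel)
    c = panel.rec_frac
    from scipy.special import gammaln

    lchoose = gammaln(n_tot + 1) - gammaln(n_anc + 1) - gammaln(n_tot - n_anc + 1)
    q_c = np.clip(q, 1e-12, 1.0 - 1e-12)
    lb_bg_all = lchoose + n_anc * np.log(q_c) + (n_tot - n_anc) * np.log(1.0 - q_c)

    def loglik(t: float, phi: float) -> float:
        # the allele's age t splits into a stem (fraction phi, from the
        # founding mutation to the carriers' MRCA) and the genealogy depth
        # below the MRCA: a marker that recombines on the stem sends every
        # carrier to the background, otherwise carriers decay from the
        # ancestral haplotype over the remaining (1-phi) t generations
        depth = (1.0 - phi) * t
        decay = np.exp(-c * depth)
        pi = np.clip(decay + (1.0 - decay) * q, 1e-12, 1.0 - 1e-12)
        lb_tree = lchoose + n_anc * np.log(pi) + (n_tot - n_anc) * np.log(1.0 - pi)
        w = np.exp(-c * phi * t)
        m = np.maximum(lb_tree, lb_bg_all)
        mix = w * np.exp(lb_tree - m) + (1.0 - w) * np.exp(lb_bg_all - m)
        return float(np.sum(m + np.log(np.clip(mix, 1e-300, None))))

    prior = induced_age_prior(params, panel.n_carriers)
    mu = np.log(prior.kwds["scale"])  # lognormal log-median
    sig = prior.kwds["s"]

    def logpost(t: float, lphi: float) -> float:
        phi = 1.0 / (1.0 + np.exp(-lphi))
        lt = np.log(t)
        # lognormal age prior; flat prior on the stem fraction (Jacobian term)
        return loglik(t, phi) - lt - (lt - mu) ** 2 / (2.0 * sig**2) + np.log(phi * (1.0 - phi))

    rng = np.random.default_rng(seed)
    t = float(prior.median())
    lphi = -1.0
    lp = logpost(t, lphi)
    scale = 0.5
    scale_phi = 0.8
    accepts = 0
    window_accepts = 0
    samples = np.empty(iterations - burn_in)
    for it in range(iterations):
        prop = t * np.exp(scale * rng.standard_normal())
        lphi_prop = lphi + scale_phi * rng.standard_normal()
        # lognormal RW on t: Hastings ratio contributes log(prop/t)
        lp_prop = logpost(prop, lphi_prop)
        if np.log(rng.random()) < lp_prop - lp + np.log(prop / t):
            t, lphi, lp = prop, lphi_prop, lp_prop
            accepts += 1
            window_accepts += 1
        if it < burn_in and (it + 1) % 200 == 0:  # adapt toward 20-50% acceptance
            rate = window_accepts / 200.0
            if rate < 0.20:
                scale *= 0.7
                scale_phi *= 0.7
            elif rate > 0.50:
                scale *= 1.4
                scale_phi *= 1.4
            window_accepts = 0
        if it >= burn_in:
            samples[it - burn_in] = t
    acc_rate = accepts / iterations
    notes = []
    if acc_rate < 0.01 or acc_rate > 0.99:
        notes.append(f"non-mixing chain: acceptance rate {acc_rate:.3f}")
    sub = samples[:: max(1, len(samples) // 2000)]
    kde = stats.gaussian_kde(sub)
    grid = np.quantile(samples, np.linspace(0.005, 0.995, 200))
    mode = float(grid[np.argmax(kde(grid))])
    lo, hi = np.percentile(samples, [2.5, 97.5])
    notes.append(f"posterior mode {mode:.1f} generations; acceptance {acc_rate:.2f}")
    est = _estimate(float(samples.mean()), params, "mcmc_ld", notes=notes)
    est.ci_low = lo * params.generation_years
    est.ci_high = hi * params.generation_years
    est.posterior_samples = samples
    return est


def read_haplotype_panel(panel_path: str | Path, map_path: str | Path) -> HaplotypePanel:
    """Read a chromosome TSV (id, carrier, marker columns) and a marker map TSV."""
    panel = pd.read_csv(panel_path, sep="\t")
    mmap = pd.read_csv(map_path, sep="\t")
    if "carrier" not in panel.columns:
        raise ValidationError("panel file needs a 'carrier' column")
    if "rec_frac" not in mmap.columns or "marker" not in mmap.columns:
        raise ValidationError("marker map needs 'marker' and 'rec_frac' columns")
    marker_cols = [c for c in panel.columns if c in set(mmap["marker"].astype(str))]
    if not marker_cols:
        raise ValidationError("no marker columns shared between panel and map")
    rec = mmap.set_index(mmap["marker"].astype(str)).loc[marker_cols, "rec_frac"].to_numpy(float)
    return HaplotypePanel(
        carrier=panel["carrier"].to_numpy(bool),
        markers=panel[marker_cols].to_numpy(int),
        rec_frac=rec,
    )
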