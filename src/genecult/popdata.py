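"""Single-SNP population genotype tables and elementary frequency statistics.

The central object is a :class:`PopulationTable`: an ordered collection of
populations, each carrying the three genotype counts of one biallelic SNP
(here the ABCA1 Arg230Cys variant, rs9282541) together with a subdivision
label describing ancient subsistence mode (Mesoamerican agriculturalist,
Andean agriculturalist, or South American hunter-gatherer/forager).  Allele
frequencies are obtained by direct counting, never by model fitting, and are
kept at full precision internally; two-decimal rounding happens only at
display time via :func:`display_round`.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The three subsistence subdivisions used in the source study.  The label set
#: is open: synthetic scenarios may define their own.
DEFAULT_SUBDIVISIONS = (
    "mesoamerican_agriculturalist",
    "andean_agriculturalist",
    "sa_hunter_gatherer",
)

REQUIRED_COLUMNS = ("population", "subdivision", "n", "n_rr", "n_ra", "n_aa")
OPTIONAL_COLUMNS = ("country", "lat", "lon", "printed_freq")


@dataclass(frozen=True)
class PopulationRecord:
    """Genotype counts of one biallelic SNP in one population.

    ``n_rr``, ``n_ra``, ``n_aa`` are the ref/ref, ref/alt and alt/alt genotype
    counts; they must sum to ``n``.  Coordinates and country are metadata only
    and never enter any statistic.
    """

    name: str
    subdivision: str
    n: int
    n_rr: int
    n_ra: int
    n_aa: int
    country: str | None = None
    lat: float | None = None
    lon: float | None = None
    printed_freq: float | None = None

    def __post_init__(self) -> None:
        if min(self.n, self.n_rr, self.n_ra, self.n_aa) < 0:
            raise ValidationError(f"negative count in population {self.name!r}")
        if self.n_rr + self.n_ra + self.n_aa != self.n:
            raise ValidationError(
                f"genotype counts {self.n_rr}/{self.n_ra}/{self.n_aa} do not sum "
                f"to n={self.n} for population {self.name!r}"
            )

    @property
    def alt_count(self) -> int:
        """Number of alt alleles among the 2n sampled chromosomes."""
        return self.n_ra + 2 * self.n_aa

    @property
    def n_alleles(self) -> int:
        return 2 * self.n


@dataclass(frozen=True)
class AlleleFrequencies:
    """Direct-count allele frequencies of one population sample."""

    p_ref: float
    p_alt: float
    n_alleles: int

    def __post_init__(self) -> None:
        if abs(self.p_ref + self.p_alt - 1.0) > 1e-12:
            raise ValidationError("p_ref + p_alt must equal 1")
        if self.n_alleles % 2 != 0:
            raise ValidationError("n_alleles must be even (diploid samples)")


@dataclass
class PopulationTable:
    """Ordered list of :class:`PopulationRecord` for one locus."""

    records: list[PopulationRecord]
    locus_id: str = "locus"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("no populations")
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate population names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subdivisions(self) -> list[str]:
        """Distinct subdivision labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subdivision, None)
        return list(seen)

    def subset(self, subdivision: str) -> "PopulationTable":
        recs = [r for r in self.records if r.subdivision == subdivision]
        if not recs:
            raise KeyError(
                f"unknown subdivision {subdivision!r}; valid labels: {self.subdivisions()}"
            )
        return PopulationTable(recs, locus_id=self.locus_id)

    def get(self, name: str) -> PopulationRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(f"population {name!r} not in table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class FrequencyMatrix:
    """Alt-allele frequencies of many loci in many populations.

    ``freq`` is a loci x populations DataFrame of frequencies in [0, 1];
    ``n_alleles`` holds the matching per-cell allele sample sizes (2n).
    Missing cells are NaN in both and are flagged, never silently zero.
    """

    freq: pd.DataFrame
    n_alleles: pd.DataFrame
    subdivision: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.freq.columns) != list(self.n_alleles.columns) or list(
            self.freq.index
        ) != list(self.n_alleles.index):
            raise SchemaError("frequency and sample-size matrices must share layout")
        vals = self.freq.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValidationError("frequencies outside [0, 1]")
        sz = self.n_alleles.to_numpy(float)
        if np.any(~np.isnan(vals) & ~(sz > 0)):
            raise ValidationError("sample size must be > 0 wherever a frequency is present")

    @property
    def loci(self) -> list[str]:
        return list(self.freq.index)

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    def complete_loci(self) -> list[str]:
        """Loci with no missing cell."""
        return list(self.freq.index[~self.freq.isna().any(axis=1)])


def display_round(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding used for report-time display of frequencies."""
    return float(Decimal(repr(float(x))).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


def read_population_table(
    path: str | Path, dialect: str | None = None, locus_id: str = "locus"
) -> PopulationTable:
    """Read a population genotype table from CSV or TSV.

    The documented header is ``population, subdivision, country, lat, lon, n,
    n_rr, n_ra, n_aa`` (``country``/``lat``/``lon`` optional, extra columns
    ignored).  ``dialect`` forces ``"csv"`` or ``"tsv"``; by default the file
    extension decides.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path.name}")
    if df.empty:
        raise ValidationError("no populations")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PopulationRecord(
                name=str(row.population),
                subdivision=str(row.subdivision),
                n=int(row.n),
                n_rr=int(row.n_rr),
                n_ra=int(row.n_ra),
                n_aa=int(row.n_aa),
                country=str(row.country) if "country" in df.columns else None,
                lat=float(row.lat) if "lat" in df.columns and pd.notna(row.lat) else None,
                lon=float(row.lon) if "lon" in df.columns and pd.notna(row.lon) else None,
                printed_freq=float(row.printed_freq)
                if "printed_freq" in df.columns and pd.notna(row.printed_freq)
                else None,
            )
        )
    return PopulationTable(records, locus_id=locus_id)


def read_vcf_biallelic(
    path: str | Path,
    locus: str,
    sample_map: Mapping[str, tuple[str, str]],
) -> PopulationTable:
    """Aggregate genotype counts for one biallelic VCF site into a table.

    ``locus`` is ``"chrom:pos"`` (1-based).  ``sample_map`` maps VCF sample
    names to ``(population, subdivision)``.  Missing genotypes reduce the
    population's ``n`` rather than being imputed; unmapped samples are
    excluded with a logged warning.
    """
    import pysam

    chrom, _, pos_s = locus.partition(":")
    if not pos_s:
        raise ValueError(f"locus must be 'chrom:pos', got {locus!r}")
    pos = int(pos_s)
    vf = pysam.VariantFile(str(path))
    rec = None
    for r in vf.fetch() if vf.index is not None else vf:
        if r.chrom == chrom and r.pos == pos:
            rec = r
            break
    if rec is None:
        raise ValidationError(f"locus not found: {locus}")
    if rec.alts is None or len(rec.alts) != 1:
        raise ValidationError(f"site {locus} is not biallelic")
    counts: dict[str, list] = {}
    for sample, call in rec.samples.items():
        if sample not in sample_map:
            msg = f"sample {sample!r} not in sample map; excluded"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        pop, subdiv = sample_map[sample]
        slot = counts.setdefault(pop, [subdiv, 0, 0, 0])
        gt = call.get("GT")
        if gt is None or any(a is None for a in gt):
            continue  # missing genotype: drop the individual from n
        n_alt = sum(1 for a in gt if a != 0)
        slot[1 + n_alt] += 1
    records = [
        PopulationRecord(
            name=pop, subdivision=subdiv, n=n_rr + n_ra + n_aa, n_rr=n_rr, n_ra=n_ra, n_aa=n_aa
        )
        for pop, (subdiv, n_rr, n_ra, n_aa) in counts.items()
    ]
    return PopulationTable(records, locus_id=locus)


def allele_frequency(rec: PopulationRecord) -> AlleleFrequencies:
    """Alt-allele frequency by direct counting: (n_ra + 2 n_aa) / 2n."""
    if rec.n == 0:
        raise DomainError(f"allele frequency undefined for empty sample {rec.name!r}")
    p_alt = rec.alt_count / rec.n_alleles
    return AlleleFrequencies(p_ref=1.0 - p_alt, p_alt=p_alt, n_alleles=rec.n_alleles)


def expected_heterozygosity(p: float, n_alleles: int | None = None, unbiased: bool = False) -> float:
    """Expected heterozygosity 2p(1-p), optionally bias-corrected by 2n/(2n-1)."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"allele frequency {p} outside [0, 1]")
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        if n_alleles is None or n_alleles < 2:
            raise DomainError("unbiased heterozygosity needs n_alleles >= 2")
        he *= n_alleles / (n_alleles - 1)
    return he


def subdivision_mean_frequency(table: PopulationTable, subdivision: str) -> float:
    """Unweighted arithmetic mean of per-population alt frequencies in a subdivision."""
    sub = table.subset(subdivision)
    return float(np.mean([allele_frequency(r).p_alt for r in sub]))


def total_sample_size(table: PopulationTable, subset: str | None = None) -> int:
    """Sum of sampled individuals, optionally restricted to one subdivision."""
    if subset is None:
        return sum(r.n for r in table)
    return sum(r.n for r in table if r.subdivision == subset)


def table_to_frequency_matrix(tables: Mapping[str, PopulationTable]) -> FrequencyMatrix:
    """Stack single-locus tables (locus id -> table) into a FrequencyMatrix."""
    pops: list[str] = []
    subdiv: dict[str, str] = {}
    for t in tables.values():
        for r in t:
            if r.name not in subdiv:
                pops.append(r.name)
                subdiv[r.name] = r.subdivision
    freq = pd.DataFrame(index=list(tables), columns=pops, dtype=float)
    size = pd.DataFrame(index=list(tables), columns=pops, dtype=float)
    for locus, t in tables.items():
        for r in t:
            freq.loc[locus, r.name] = allele_frequency(r).p_alt
            size.loc[locus, r.name] = r.n_alleles
    return FrequencyMatrix(freq=freq, n_alleles=size, subdivision=subdiv)


def read_frequency_matrix(
    freq_path: str | Path,
    sizes_path: str | Path,
    subdivision: Mapping[str, str] | None = None,
) -> FrequencyMatrix:
    """Read a loci x populations frequency CSV plus its companion allele-size CSV."""
    freq = pd.read_csv(freq_path, index_col=0)
    size = pd.read_csv(sizes_path, index_col=0)
    return FrequencyMatrix(freq=freq, n_alleles=size, subdivision=dict(subdivision or {}))


def write_frequency_matrix(fm: FrequencyMatrix, freq_path: str | Path, sizes_path: str | Path) -> None:
    fm.freq.to_csv(freq_path)
    fm.n_alleles.to_csv(sizes_path)
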