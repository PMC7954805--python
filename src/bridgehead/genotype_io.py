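"""Genotype containers, VCF input/output, and the SNP filtering cascade.

The central object is :class:`GenotypeMatrix`: a samples x sites matrix of
diploid alternate-allele dosages (0, 1, 2, or -1 for missing) plus site
metadata.  Filtering follows the conventional reduced-representation
pipeline for population-genetic analyses: site-level filters (presence,
minor-allele count, biallelic), then individual-level call-rate filtering,
then LD thinning with sliding-window pairwise r^2 pruning.

Positions are 1-based (VCF convention).  Half-calls such as ``./1`` are
treated as missing; non-diploid genotypes raise :class:`PloidyError`.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for a missing diploid call in dosage matrices.
MISSING: int = -1

#: Canonical ordering of the native genetic groups plus the introduced range.
#: The native order follows the divergence topology (Aleutians off the
#: Alaska-British Columbia lineage, which is off the Coastal lineage; then
#: the North/South lineage pair).
NATIVE_GROUPS: tuple[str, ...] = ("ALE", "AKBC", "COAST", "NORTH", "SOUTH")
ALL_GROUPS: tuple[str, ...] = NATIVE_GROUPS + ("UK",)


class VcfFormatError(ValueError):
    """Raised for malformed VCF input."""


class PloidyError(ValueError):
    """Raised when a genotype is not diploid, naming the sample and site."""


class ConfigError(ValueError):
    """Raised for out-of-range filter thresholds."""


SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "kind"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP calls with missingness.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, kind`` where ``kind``
        is ``"variant"`` or ``"invariant"``.  ``pos`` is 1-based.
    calls
        ``int8`` array of shape ``(n_samples, n_sites)`` holding
        alternate-allele dosages in ``{0, 1, 2}`` or :data:`MISSING`.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(self.samples) == 0:
            raise ValueError("GenotypeMatrix requires at least one sample")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, shape (n_samples, n_sites)."""
        return self.calls == MISSING

    def missing_rate(self) -> float:
        """Overall fraction of missing calls."""
        return float(self.missing_mask().mean())

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt count, total non-missing haploid count)."""
        present = self.calls != MISSING
        alt = np.where(present, self.calls, 0).sum(axis=0)
        n_hap = 2 * present.sum(axis=0)
        return alt.astype(np.int64), n_hap.astype(np.int64)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.sites.iloc[idx].reset_index(drop=True),
            self.calls[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.samples[i] for i in np.atleast_1d(idx)],
            self.sites.copy(),
            self.calls[np.atleast_1d(idx), :],
        )


@dataclass
class FilterReport:
    """Counts and thresholds for one stage of the filtering cascade."""

    stage: str
    n_sites_in: int
    n_sites_out: int
    n_samples_in: int
    n_samples_out: int
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_sites_in": self.n_sites_in,
            "n_sites_out": self.n_sites_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "thresholds": self.thresholds,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


class PopulationMap:
    """Mapping sample -> (population, genetic group).

    Genetic groups are the demes of the demographic models: the five native
    groups plus UK, with OTHER for unassigned samples.
    """

    def __init__(self, entries: dict[str, tuple[str, str]]):
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, sample: str) -> bool:
        return sample in self._entries

    def __eq__(self, other) -> bool:
        return isinstance(other, PopulationMap) and self._entries == other._entries

    @property
    def samples(self) -> list[str]:
        return list(self._entries)

    def population_of(self, sample: str) -> str:
        return self._entries[sample][0]

    def group_of(self, sample: str) -> str:
        return self._entries[sample][1]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop, _ in self._entries.values():
            seen.setdefault(pop, None)
        return list(seen)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, grp in self._entries.values():
            seen.setdefault(grp, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for _, grp in self._entries.values():
            sizes[grp] = sizes.get(grp, 0) + 1
        return sizes

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for pop, _ in self._entries.values():
            sizes[pop] = sizes.get(pop, 0) + 1
        return sizes

    def samples_of_population(self, pop: str) -> list[str]:
        return [s for s, (p, _) in self._entries.items() if p == pop]

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s, (_, g) in self._entries.items() if g == group]

    def aligned_to(self, samples: list[str]) -> "PopulationMap":
        """Restrict/extend to a sample list; unmapped samples become OTHER."""
        entries = {}
        n_unmapped = 0
        for s in samples:
            if s in self._entries:
                entries[s] = self._entries[s]
            else:
                entries[s] = ("UNKNOWN", "OTHER")
                n_unmapped += 1
        if n_unmapped:
            warnings.warn(
                f"{n_unmapped} samples absent from population map; "
                "assigned to group OTHER"
            )
        return PopulationMap(entries)

    def items(self):
        return self._entries.items()


# ---------------------------------------------------------------------------
# VCF input / output


def read_vcf(path: str, keep_invariant: bool = False) -> GenotypeMatrix:
    """Load a VCF 4.x file (plain or gzipped) into a :class:`GenotypeMatrix`.

    Records without an ALT allele are invariant; they are skipped unless
    ``keep_invariant`` is set.  Multiallelic records are loaded (flagged as
    variant) with the dosage of the *first* alternate allele; genotypes
    carrying a higher-numbered allele are set missing.  Downstream
    ``biallelic_only`` filtering drops such records entirely.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files") from exc

    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:
        raise VcfFormatError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"VCF {path!r} declares no samples")

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    kinds: list[str] = []
    n_alts: list[int] = []
    columns: list[np.ndarray] = []

    for var in vcf:
        alt_alleles = var.ALT
        invariant = len(alt_alleles) == 0
        if invariant and not keep_invariant:
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise PloidyError(
                    f"non-diploid genotype for sample {samples[i]!r} at "
                    f"{var.CHROM}:{var.POS} (ploidy {len(alleles)})"
                )
            a, b = alleles
            if a < 0 or b < 0:
                col[i] = MISSING  # includes half-calls like ./1
            elif a > 1 or b > 1:
                col[i] = MISSING  # allele beyond the first ALT
            else:
                col[i] = a + b
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(",".join(alt_alleles) if alt_alleles else ".")
        kinds.append("invariant" if invariant else "variant")
        n_alts.append(len(alt_alleles))
        columns.append(col)

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "kind": kinds,
            "n_alt": np.asarray(n_alts, dtype=np.int64),
        }
    )
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a matrix as a minimal VCF 4.2 with GT-only genotype fields."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bridgehead\n")
        for chrom in pd.unique(gm.sites["chrom"]):
            max_pos = int(gm.sites.loc[gm.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_sites):
            site = gm.sites.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t"
                f"PASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filtering cascade: sites -> individuals -> LD


def filter_sites(
    gm: GenotypeMatrix,
    min_presence: float = 0.75,
    min_mac: int = 3,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop sites by presence, minor-allele count, and allele number.

    A site is retained when its non-missing call fraction is at least
    ``min_presence``, its minor-allele count over non-missing haploid calls
    is at least ``min_mac``, and (if ``biallelic_only``) it has exactly one
    ALT allele or is invariant.  Invariant sites are exempt from the MAC
    filter only through ``min_mac=0``, which is the setting used for
    diversity datasets that retain monomorphic loci.
    """
    if not 0.0 <= min_presence <= 1.0:
        raise ConfigError(f"min_presence must be in [0, 1], got {min_presence}")
    if min_mac < 0:
        raise ConfigError(f"min_mac must be >= 0, got {min_mac}")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")

    present = gm.calls != MISSING
    presence = present.mean(axis=0)
    alt, n_hap = gm.allele_counts()
    mac = np.minimum(alt, n_hap - alt)

    keep = presence >= min_presence
    keep &= mac >= min_mac
    if biallelic_only and "n_alt" in gm.sites.columns:
        keep &= gm.sites["n_alt"].to_numpy() <= 1
    idx = np.flatnonzero(keep)
    out = gm.take_sites(idx)
    report = FilterReport(
        stage="filter_sites",
        n_sites_in=gm.n_sites,
        n_sites_out=out.n_sites,
        n_samples_in=gm.n_samples,
        n_samples_out=out.n_samples,
        thresholds={
            "min_presence": min_presence,
            "min_mac": min_mac,
            "biallelic_only": biallelic_only,
        },
    )
    log.info("filter_sites: %d -> %d sites", gm.n_sites, out.n_sites)
    return out, report


def filter_individuals(
    gm: GenotypeMatrix, min_call: float = 0.5
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop samples whose genotyped fraction over current sites is < min_call."""
    if not 0.0 <= min_call <= 1.0:
        raise ConfigError(f"min_call must be in [0, 1], got {min_call}")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    call_rate = (gm.calls != MISSING).mean(axis=1)
    idx = np.flatnonzero(call_rate >= min_call)
    if idx.size == 0:
        raise ValueError("all samples removed by the call-rate filter")
    out = gm.take_samples(idx)
    report = FilterReport(
        stage="filter_individuals",
        n_sites_in=gm.n_sites,
        n_sites_out=out.n_sites,
        n_samples_in=gm.n_samples,
        n_samples_out=out.n_samples,
        thresholds={"min_call": min_call},
    )
    log.info("filter_individuals: %d -> %d samples", gm.n_samples, out.n_samples)
    return out, report


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared calls.

    Pairs with fewer than two jointly non-missing samples, or with a
    monomorphic vector among them, yield 0 (treated as unlinked).
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(np.float64)
    yv = y[ok].astype(np.float64)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return r * r


def ld_thin(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Sliding-window LD pruning of sites with pairwise dosage r^2 > r2_max.

    Windows are measured in SNP counts and advance by ``step`` SNPs within
    each chromosome.  Within a window, retained pairs are scanned in site
    order and the *later* member of any offending pair is dropped — a
    deterministic greedy sweep with no randomness.
    """
    if window < 2:
        raise ConfigError(f"window must be >= 2 SNPs, got {window}")
    if step < 1:
        raise ConfigError(f"step must be >= 1, got {step}")
    if not 0.0 <= r2_max <= 1.0:
        raise ConfigError(f"r2_max must be in [0, 1], got {r2_max}")

    removed = np.zeros(gm.n_sites, dtype=bool)
    chrom_arr = gm.sites["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        site_idx = np.flatnonzero(chrom_arr == chrom)
        n = site_idx.size
        start = 0
        while start < n:
            window_sites = site_idx[start : start + window]
            active = [s for s in window_sites if not removed[s]]
            for a_pos, i in enumerate(active):
                if removed[i]:
                    continue
                for j in active[a_pos + 1 :]:
                    if removed[j]:
                        continue
                    if _dosage_r2(gm.calls[:, i], gm.calls[:, j]) > r2_max:
                        removed[j] = True
            if start + window >= n:
                break
            start += step

    idx = np.flatnonzero(~removed)
    out = gm.take_sites(idx)
    report = FilterReport(
        stage="ld_thin",
        n_sites_in=gm.n_sites,
        n_sites_out=out.n_sites,
        n_samples_in=gm.n_samples,
        n_samples_out=out.n_samples,
        thresholds={"window": window, "step": step, "r2_max": r2_max},
    )
    log.info("ld_thin: %d -> %d sites", gm.n_sites, out.n_sites)
    return out, report


# ---------------------------------------------------------------------------
# Population maps


def read_popmap(path: str) -> PopulationMap:
    """Read a 2- or 3-column delimited sample/population/group map.

    With two columns the population doubles as the genetic group.
    """
    entries: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                sample, pop = parts
                group = pop
            elif len(parts) == 3:
                sample, pop, group = parts
            else:
                raise VcfFormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            if sample in entries:
                raise ValueError(f"duplicate sample {sample!r} in population map")
            entries[sample] = (pop, group)
    return PopulationMap(entries)


def write_popmap(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, (pop, group) in popmap.items():
            fh.write(f"{sample}\t{pop}\t{group}\n")
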