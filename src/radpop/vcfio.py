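"""Multi-sample VCF input/output and genotype-level / locus-level filtering.

The central container is :class:`VariantMatrix`, a loci x samples grid of
genotype calls stored as dense integer arrays.  Genotypes are kept as *alt
allele dosage* plus the call ploidy (number of alleles in the GT field), so
mixed-ploidy cohorts (2n/3n/4n in one file) are first-class.  Missing data is
a distinct sentinel (``MISSING = -1``) and is never conflated with dosage 0;
unknown DP/GQ/AD use the same sentinel.

Filters mirror a standard RAD-seq SNP cleaning chain: per-call depth/quality
thresholds (DP > 10, GQ > 20 by default, strict inequalities), a per-locus
call-rate floor, removal of loci whose mean depth is an outlier of the
across-locus depth distribution, and restriction to biallelic SNPs.  All
filters return new matrices and never mutate retained calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: sentinel for missing genotype / unknown DP, GQ or AD
MISSING = -1

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised for malformed or unsupported VCF records."""


@dataclass(frozen=True)
class LocusRecord:
    """One variant site: chromosome, 1-based position and the two alleles."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    identifier: str = ""

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and "," not in self.alt
            and self.ref in _BASES
            and self.alt in _BASES
            and self.ref != self.alt
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class VariantMatrix:
    """Loci x samples genotype store with per-call DP, GQ and allele depths.

    Attributes
    ----------
    loci:
        Ordered list of :class:`LocusRecord`.
    samples:
        Ordered sample identifiers.
    dosage:
        ``(n_loci, n_samples)`` int16 array of alt-allele dosages;
        ``MISSING`` marks a missing call.
    call_ploidy:
        Number of alleles in the GT field per call (``MISSING`` where the
        call is missing).
    dp, gq:
        Total read depth and genotype quality (``MISSING`` = unknown).
    ad_ref, ad_alt:
        Ref/alt allele read depths (``MISSING`` = unknown).
    """

    loci: list[LocusRecord]
    samples: list[str]
    dosage: np.ndarray
    call_ploidy: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.loci), len(self.samples))
        for name in ("dosage", "call_ploidy", "dp", "gq", "ad_ref", "ad_alt"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )

    # -- basic introspection -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (loci x samples) mask of missing calls."""
        return self.dosage == MISSING

    def copy(self) -> "VariantMatrix":
        return VariantMatrix(
            loci=list(self.loci),
            samples=list(self.samples),
            dosage=self.dosage.copy(),
            call_ploidy=self.call_ploidy.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            ad_ref=self.ad_ref.copy(),
            ad_alt=self.ad_alt.copy(),
        )

    def subset_loci(self, keep: np.ndarray) -> "VariantMatrix":
        """New matrix restricted to loci where ``keep`` is True (or an
        integer index array); locus order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return VariantMatrix(
            loci=[self.loci[i] for i in idx],
            samples=list(self.samples),
            dosage=self.dosage[idx].copy(),
            call_ploidy=self.call_ploidy[idx].copy(),
            dp=self.dp[idx].copy(),
            gq=self.gq[idx].copy(),
            ad_ref=self.ad_ref[idx].copy(),
            ad_alt=self.ad_alt[idx].copy(),
        )

    def subset_samples(self, names: list[str]) -> "VariantMatrix":
        idx = [self.sample_index(s) for s in names]
        return VariantMatrix(
            loci=list(self.loci),
            samples=list(names),
            dosage=self.dosage[:, idx].copy(),
            call_ploidy=self.call_ploidy[:, idx].copy(),
            dp=self.dp[:, idx].copy(),
            gq=self.gq[:, idx].copy(),
            ad_ref=self.ad_ref[:, idx].copy(),
            ad_alt=self.ad_alt[:, idx].copy(),
        )

    def dosage_matrix(self, dtype=float) -> np.ndarray:
        """Samples x loci dosage matrix with NaN for missing calls."""
        m = self.dosage.T.astype(dtype)
        m[self.dosage.T == MISSING] = np.nan
        return m

    def equals(self, other: "VariantMatrix") -> bool:
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and bool(np.array_equal(self.dosage, other.dosage))
            and bool(np.array_equal(self.call_ploidy, other.call_ploidy))
            and bool(np.array_equal(self.dp, other.dp))
            and bool(np.array_equal(self.gq, other.gq))
            and bool(np.array_equal(self.ad_ref, other.ad_ref))
            and bool(np.array_equal(self.ad_alt, other.ad_alt))
        )


@dataclass
class PopulationMap:
    """Sample -> population label, with optional family / phenotype labels."""

    assignments: dict[str, str]
    family: dict[str, str] = field(default_factory=dict)
    phenotype: dict[str, str] = field(default_factory=dict)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def validate_against(self, vm: VariantMatrix) -> None:
        missing = [s for s in self.assignments if s not in vm.samples]
        if missing:
            raise ValueError(
                f"samples in population map absent from matrix: {missing[:5]}"
            )
        if not self.assignments:
            raise ValueError("population map is empty")

    @classmethod
    def read(cls, path) -> "PopulationMap":
        """Read a 2+-column TSV: sample_id, population[, family[, phenotype]]."""
        assignments: dict[str, str] = {}
        family: dict[str, str] = {}
        phenotype: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"population map line lacks label: {line!r}")
                sample, pop = parts[0], parts[1]
                assignments[sample] = pop
                if len(parts) > 2 and parts[2]:
                    family[sample] = parts[2]
                if len(parts) > 3 and parts[3]:
                    phenotype[sample] = parts[3]
        return cls(assignments=assignments, family=family, phenotype=phenotype)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.assignments.items():
                fam = self.family.get(sample, "")
                phe = self.phenotype.get(sample, "")
                fh.write(f"{sample}\t{pop}\t{fam}\t{phe}\n")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def read_vcf(path, skip_non_snps: bool = False) -> VariantMatrix:
    """Read a multi-sample VCF (.vcf or .vcf.gz) into a :class:`VariantMatrix`.

    GT of any ploidy (e.g. ``0/1/1/1``) is parsed to alt dosage + call
    ploidy.  Absent DP/GQ/AD are stored as the ``MISSING`` sentinel and
    ``./.`` as a missing call.  Non-SNP or multiallelic records raise a
    :class:`VcfParseError` naming the site unless ``skip_non_snps`` is set,
    in which case they are kept as (unfilterable) records so that
    :func:`filter_biallelic_snps` can drop them explicitly.

    Parameters
    ----------
    path:
        VCF 4.x path; bgzip compression is handled transparently.
    skip_non_snps:
        If True, records that are not biallelic SNPs are silently skipped
        instead of raising.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        loci: list[LocusRecord] = []
        rows_dos, rows_pl, rows_dp, rows_gq, rows_ar, rows_aa = [], [], [], [], [], []
        for rec in vf:
            alts = rec.alts or ()
            ref = rec.ref or ""
            if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1:
                if skip_non_snps:
                    continue
                raise VcfParseError(
                    f"record {rec.chrom}:{rec.pos} is not a biallelic SNP "
                    f"(REF={ref!r} ALT={','.join(alts) or '.'}); "
                    "pass skip_non_snps=True to drop such records"
                )
            loci.append(
                LocusRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alts[0],
                    identifier=rec.id or "",
                )
            )
            dos = np.full(len(samples), MISSING, dtype=np.int16)
            pl = np.full(len(samples), MISSING, dtype=np.int16)
            dp = np.full(len(samples), MISSING, dtype=np.int32)
            gq = np.full(len(samples), MISSING, dtype=np.int32)
            ar = np.full(len(samples), MISSING, dtype=np.int32)
            aa = np.full(len(samples), MISSING, dtype=np.int32)
            for j, name in enumerate(samples):
                call = rec.samples[name]
                gt = call.get("GT")
                if gt is not None and len(gt) > 0 and all(a is not None for a in gt):
                    pl[j] = len(gt)
                    dos[j] = sum(1 for a in gt if a != 0)
                v = call.get("DP")
                if v is not None:
                    dp[j] = int(v)
                v = call.get("GQ")
                if v is not None:
                    gq[j] = int(v)
                v = call.get("AD")
                if v is not None and len(v) >= 2 and v[0] is not None and v[1] is not None:
                    ar[j] = int(v[0])
                    aa[j] = int(v[1])
            rows_dos.append(dos)
            rows_pl.append(pl)
            rows_dp.append(dp)
            rows_gq.append(gq)
            rows_ar.append(ar)
            rows_aa.append(aa)

    def stack(rows, dtype):
        if rows:
            return np.vstack(rows)
        return np.empty((0, len(samples)), dtype=dtype)

    return VariantMatrix(
        loci=loci,
        samples=samples,
        dosage=stack(rows_dos, np.int16),
        call_ploidy=stack(rows_pl, np.int16),
        dp=stack(rows_dp, np.int32),
        gq=stack(rows_gq, np.int32),
        ad_ref=stack(rows_ar, np.int32),
        ad_alt=stack(rows_aa, np.int32),
    )


def write_vcf(vm: VariantMatrix, path) -> None:
    """Write ``vm`` as VCF 4.2 with GT:DP:GQ:AD.

    A dosage ``d`` at call ploidy ``k`` is written as an unphased k-allele
    GT with the ``d`` alt alleles last (d=2, k=4 -> ``0/0/1/1``); missing
    calls are written ``./.``.  A ``.gz`` suffix selects bgzip output.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    for chrom in dict.fromkeys(l.chrom for l in vm.loci):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in vm.samples:
        header.add_sample(s)

    mode = "wz" if str(path).endswith(".gz") else "w"
    with pysam.VariantFile(str(path), mode, header=header) as out:
        for i, locus in enumerate(vm.loci):
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos,
                alleles=(locus.ref, locus.alt),
                id=locus.identifier or None,
            )
            for j, s in enumerate(vm.samples):
                call = rec.samples[s]
                d = int(vm.dosage[i, j])
                if d == MISSING:
                    call["GT"] = (None, None)
                else:
                    k = int(vm.call_ploidy[i, j])
                    call["GT"] = tuple([0] * (k - d) + [1] * d)
                    call.phased = False
                if vm.dp[i, j] != MISSING:
                    call["DP"] = int(vm.dp[i, j])
                if vm.gq[i, j] != MISSING:
                    call["GQ"] = int(vm.gq[i, j])
                if vm.ad_ref[i, j] != MISSING and vm.ad_alt[i, j] != MISSING:
                    call["AD"] = (int(vm.ad_ref[i, j]), int(vm.ad_alt[i, j]))
            out.write(rec)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def apply_call_filters(vm: VariantMatrix, min_dp: int = 10, min_gq: int = 20) -> VariantMatrix:
    """Set calls to missing unless DP > ``min_dp`` AND GQ > ``min_gq``.

    Inequalities are strict: a call with DP exactly ``min_dp`` fails.  Calls
    with unknown DP or GQ fail (conservative).  The locus set is unchanged.
    """
    out = vm.copy()
    fail = (out.dp <= min_dp) | (out.gq <= min_gq)  # MISSING == -1 fails both
    out.dosage[fail] = MISSING
    out.call_ploidy[fail] = MISSING
    return out


def filter_loci_by_callrate(vm: VariantMatrix, min_rate: float = 0.95) -> VariantMatrix:
    """Keep loci whose non-missing call fraction is >= ``min_rate``."""
    if not (0 < min_rate <= 1):
        raise ValueError("min_rate must be in (0, 1]")
    if vm.n_samples == 0:
        return vm.copy()
    called = (vm.dosage != MISSING).sum(axis=1) / vm.n_samples
    return vm.subset_loci(called >= min_rate)


def filter_loci_by_depth_normality(vm: VariantMatrix, k_sd: float = 2.0) -> VariantMatrix:
    """Drop poorly covered and oversaturated loci.

    Each locus' mean depth (over calls with known DP) is compared with the
    across-locus distribution of those means: loci outside
    ``mean +- k_sd * sd`` are removed.  With zero spread all loci are kept.
    """
    dp = vm.dp.astype(float)
    dp[vm.dp == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        locus_mean = np.nanmean(dp, axis=1)
    usable = ~np.isnan(locus_mean)
    if not usable.any():
        logger.warning("no locus has any known DP; depth filter is a no-op")
        return vm.copy()
    mu = float(np.mean(locus_mean[usable]))
    sigma = float(np.std(locus_mean[usable]))
    if sigma == 0.0:
        logger.warning("zero spread in per-locus mean depth; keeping all loci")
        return vm.copy()
    keep = usable & (locus_mean >= mu - k_sd * sigma) & (locus_mean <= mu + k_sd * sigma)
    return vm.subset_loci(keep)


def filter_biallelic_snps(vm: VariantMatrix) -> VariantMatrix:
    """Keep loci that are biallelic single-base SNPs."""
    keep = np.array([l.is_biallelic_snp for l in vm.loci], dtype=bool)
    return vm.subset_loci(keep)
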