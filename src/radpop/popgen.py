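"""Population diversity, differentiation and pairwise relatedness.

Implements the classical SNP-panel statistics for a cohort split into
populations:

* per-population observed heterozygosity Ho, gene diversity Hs (Nei's
  small-sample correction) and the inbreeding coefficient
  FIS = 1 - Ho/Hs (ratio of locus means),
* pairwise Fst via the Weir & Cockerham (1984) theta variance-component
  estimator (ratio of sums over loci), with Nei's Gst-style
  (Ht - Hs)/Ht as a cross-check alternative,
* PLINK-style method-of-moments identity-by-descent estimates per sample
  pair: observed IBS-state counts are inverted against their
  allele-frequency expectations to P(IBD = 0, 1, 2), truncated to [0, 1]
  and renormalized; PI_HAT = k1/2 + k2.

All statistics are computed on diploid-coded genotype dosages: polyploid
calls contribute via dosage / call-ploidy allele counts to frequencies, but
IBD is defined only for diploid calls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcfio import MISSING, PopulationMap, VariantMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiversityStats:
    """Per-population (Ho, Hs, FIS) plus the per-locus table behind them."""

    per_population: dict[str, tuple[float, float, float]]
    per_locus: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"population": k, "Ho": v[0], "Hs": v[1], "FIS": v[2]}
                for k, v in self.per_population.items()
            ]
        )


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray
    estimator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class IBDMatrix:
    samples: list[str]
    pi_hat: np.ndarray
    k0: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    n_loci: np.ndarray
    low_confidence: np.ndarray = field(default=None)

    def get(self, a: str, b: str) -> float:
        return float(self.pi_hat[self.samples.index(a), self.samples.index(b)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(len(self.samples)), 2):
            rows.append(
                {
                    "sample1": self.samples[i],
                    "sample2": self.samples[j],
                    "k0": self.k0[i, j],
                    "k1": self.k1[i, j],
                    "k2": self.k2[i, j],
                    "pi_hat": self.pi_hat[i, j],
                    "n_loci": int(self.n_loci[i, j]),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_freqs(vm: VariantMatrix, pm: PopulationMap) -> dict[str, pd.DataFrame]:
    """Per-population alt allele frequencies.

    For each population and locus: ``p = sum(dosage) / sum(call_ploidy)``
    over non-missing calls; NaN where the population has no call.  Returns
    population -> DataFrame with columns ``p`` (alt frequency), ``n``
    (genotyped individuals) and ``an`` (allele number).
    """
    pm.validate_against(vm)
    out: dict[str, pd.DataFrame] = {}
    for pop in pm.populations():
        idx = [vm.sample_index(s) for s in pm.samples_in(pop)]
        dos = vm.dosage[:, idx].astype(float)
        pl = vm.call_ploidy[:, idx].astype(float)
        miss = vm.dosage[:, idx] == MISSING
        dos[miss] = 0.0
        pl[miss] = 0.0
        an = pl.sum(axis=1)
        ac = dos.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        out[pop] = pd.DataFrame(
            {"p": p, "n": (~miss).sum(axis=1), "an": an}
        )
    return out


def _pop_locus_arrays(vm: VariantMatrix, pm: PopulationMap, pop: str):
    """Per-locus (n, p, het fraction) for one population."""
    idx = [vm.sample_index(s) for s in pm.samples_in(pop)]
    dos = vm.dosage[:, idx]
    pl = vm.call_ploidy[:, idx]
    miss = dos == MISSING
    n = (~miss).sum(axis=1).astype(float)
    dosf = np.where(miss, 0, dos).astype(float)
    plf = np.where(miss, 0, pl).astype(float)
    an = plf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, dosf.sum(axis=1) / np.maximum(an, 1), np.nan)
    het = ((dos > 0) & (dos < pl) & ~miss).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, ho


def basic_stats(vm: VariantMatrix, pm: PopulationMap) -> DiversityStats:
    """Ho, Hs and FIS per population (Nei's small-sample corrections).

    Per locus with ``n`` genotyped individuals and alt frequency ``p``:
    ``Ho_l`` is the observed heterozygote fraction and
    ``Hs_l = n/(n-1) * (1 - p^2 - q^2 - Ho_l/(2n))``.  Population values
    are locus means; ``FIS = 1 - mean(Ho_l)/mean(Hs_l)`` (ratio of means).
    Populations where every locus is monomorphic get Hs = 0 and FIS = NaN.
    """
    pm.validate_against(vm)
    per_pop: dict[str, tuple[float, float, float]] = {}
    locus_rows = []
    for pop in pm.populations():
        n, p, ho = _pop_locus_arrays(vm, pm, pop)
        ok = (n >= 2) & ~np.isnan(p)
        nn, pp, hh = n[ok], p[ok], ho[ok]
        hs = (nn / (nn - 1.0)) * (1.0 - pp**2 - (1.0 - pp) ** 2 - hh / (2.0 * nn))
        ho_bar = float(np.mean(hh)) if hh.size else float("nan")
        hs_bar = float(np.mean(hs)) if hs.size else float("nan")
        fis = 1.0 - ho_bar / hs_bar if hs_bar and hs_bar > 0 else float("nan")
        per_pop[pop] = (ho_bar, hs_bar if hs.size else float("nan"), fis)
        locus_rows.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "locus": np.flatnonzero(ok),
                    "n": nn,
                    "p": pp,
                    "Ho": hh,
                    "Hs": hs,
                }
            )
        )
    per_locus = pd.concat(locus_rows, ignore_index=True) if locus_rows else None
    return DiversityStats(per_population=per_pop, per_locus=per_locus)


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------


def _wc_theta_pair(n1, p1, h1, n2, p2, h2) -> float:
    """Weir & Cockerham (1984) theta for two populations, ratio of sums.

    Per-locus variance components: a (among populations), b (among
    individuals within populations), c (within individuals), combined as
    sum(a) / sum(a + b + c) over loci.
    """
    ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    n1, p1, h1 = n1[ok], p1[ok], h1[ok]
    n2, p2, h2 = n2[ok], p2[ok], h2[ok]
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    poly = (pbar > 0) & (pbar < 1)
    inner = pbar * (1 - pbar) - ((r - 1.0) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    num = a[poly].sum()
    den = (a + b + c)[poly].sum()
    return float(num / den) if den != 0 else float("nan")


def _nei_fst_pair(n1, p1, h1, n2, p2, h2) -> float:
    """Nei (1987) Fst: (Ht' - Hs)/Ht' with small-sample Hs correction and
    the deme-number correction Dst' = r/(r-1) (Ht - Hs)."""
    ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    n1, p1, h1 = n1[ok], p1[ok], h1[ok]
    n2, p2, h2 = n2[ok], p2[ok], h2[ok]
    r = 2.0
    hs1 = (n1 / (n1 - 1.0)) * (1 - p1**2 - (1 - p1) ** 2 - h1 / (2 * n1))
    hs2 = (n2 / (n2 - 1.0)) * (1 - p2**2 - (1 - p2) ** 2 - h2 / (2 * n2))
    hs = (hs1 + hs2) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - pbar**2 - (1.0 - pbar) ** 2
    poly = (pbar > 0) & (pbar < 1)
    dst_p = (r / (r - 1.0)) * (ht - hs)  # corrected among-population diversity
    ht_p = hs + dst_p
    den = ht_p[poly].sum()
    if den == 0:
        return float("nan")
    return float(dst_p[poly].sum() / den)


def pairwise_fst(
    vm: VariantMatrix, pm: PopulationMap, estimator: str = "weir_cockerham"
) -> FstMatrix:
    """Pairwise Fst between all populations in ``pm``.

    ``estimator`` is ``"weir_cockerham"`` (default; 1984 theta) or
    ``"nei87"``.  Loci monomorphic across a pair are skipped.  The matrix
    is symmetric with a zero diagonal; small negative estimates (unbiased
    estimator) are reported as-is.
    """
    if estimator not in ("weir_cockerham", "nei87"):
        raise ValueError(f"unknown estimator {estimator!r}")
    pm.validate_against(vm)
    pops = pm.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    arrays = {pop: _pop_locus_arrays(vm, pm, pop) for pop in pops}
    k = len(pops)
    values = np.zeros((k, k))
    fn = _wc_theta_pair if estimator == "weir_cockerham" else _nei_fst_pair
    for i, j in itertools.combinations(range(k), 2):
        v = fn(*arrays[pops[i]], *arrays[pops[j]])
        values[i, j] = values[j, i] = v
    return FstMatrix(labels=pops, values=values, estimator=estimator)


# ---------------------------------------------------------------------------
# IBD (method of moments)
# ---------------------------------------------------------------------------


def ibd_estimates(
    vm: VariantMatrix,
    freq_source: str = "whole_panel",
    pm: PopulationMap | None = None,
    min_loci: int = 50,
) -> IBDMatrix:
    """PLINK-style method-of-moments IBD for every diploid sample pair.

    For a pair sharing L non-missing diploid calls, the observed counts of
    IBS states 0/1/2 are compared with their expectations given the alt
    allele frequency p at each locus:

    ==========  ==============================  ============  =====
    state       E[. | IBD=0]                    E[. | IBD=1]  IBD=2
    ==========  ==============================  ============  =====
    IBS0        2 p^2 q^2                       0             0
    IBS1        4 p^3 q + 4 p q^3               2 p q         0
    IBS2        p^4 + q^4 + 4 p^2 q^2           p^2 + q^2     1
    ==========  ==============================  ============  =====

    Solving top-down gives k0, k1, k2, truncated to [0, 1] and
    renormalized; PI_HAT = k1/2 + k2.  Samples with any non-diploid call
    are excluded with a warning.  Monomorphic loci carry no IBD
    information and are dropped.  Pairs with fewer than ``min_loci``
    shared loci are flagged low-confidence.

    ``freq_source``: ``"whole_panel"`` (default, PLINK convention) or
    ``"per_population"`` (requires ``pm``; frequencies estimated within
    each sample's population — only pairs in the same population are then
    estimated, others are NaN).
    """
    if freq_source not in ("whole_panel", "per_population"):
        raise ValueError(f"unknown freq_source {freq_source!r}")
    if freq_source == "per_population" and pm is None:
        raise ValueError("per_population frequencies require a PopulationMap")

    diploid = []
    for j, s in enumerate(vm.samples):
        pl = vm.call_ploidy[:, j]
        known = pl != MISSING
        if known.any() and (pl[known] != 2).any():
            logger.warning("sample %s has non-diploid calls; excluded from IBD", s)
            continue
        diploid.append(s)
    sub = vm.subset_samples(diploid)
    ns = len(diploid)
    nl = sub.n_loci
    dos = sub.dosage.astype(float)  # loci x samples
    miss = sub.dosage == MISSING
    dos[miss] = np.nan

    def panel_freq(matrix_dos, matrix_miss):
        an = 2.0 * (~matrix_miss).sum(axis=1)
        ac = np.nansum(matrix_dos, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    if freq_source == "whole_panel":
        p_for = {s: None for s in diploid}
        p_global = panel_freq(dos, miss)
    else:
        pm.validate_against(vm)
        p_by_pop = {}
        for pop in pm.populations():
            members = [s for s in pm.samples_in(pop) if s in diploid]
            idx = [diploid.index(s) for s in members]
            p_by_pop[pop] = panel_freq(dos[:, idx], miss[:, idx]) if idx else None
        p_for = {s: pm.assignments.get(s) for s in diploid}

    pi_hat = np.full((ns, ns), np.nan)
    k0m = np.full((ns, ns), np.nan)
    k1m = np.full((ns, ns), np.nan)
    k2m = np.full((ns, ns), np.nan)
    nlm = np.zeros((ns, ns), dtype=int)
    lowconf = np.zeros((ns, ns), dtype=bool)
    np.fill_diagonal(pi_hat, 1.0)
    np.fill_diagonal(k2m, 1.0)
    np.fill_diagonal(k1m, 0.0)
    np.fill_diagonal(k0m, 0.0)

    for i, j in itertools.combinations(range(ns), 2):
        if freq_source == "per_population":
            pop_i, pop_j = p_for[diploid[i]], p_for[diploid[j]]
            if pop_i is None or pop_i != pop_j or p_by_pop.get(pop_i) is None:
                continue
            p = p_by_pop[pop_i]
        else:
            p = p_global
        di, dj = dos[:, i], dos[:, j]
        ok = ~np.isnan(di) & ~np.isnan(dj) & ~np.isnan(p) & (p > 0) & (p < 1)
        L = int(ok.sum())
        nlm[i, j] = nlm[j, i] = L
        if L == 0:
            continue
        pi, q = p[ok], 1.0 - p[ok]
        a, b = di[ok], dj[ok]
        diff = np.abs(a - b)
        n_ibs0 = float((diff == 2).sum())
        n_ibs1 = float((diff == 1).sum())
        n_ibs2 = float((diff == 0).sum())
        e0_0 = (2.0 * pi**2 * q**2).sum()
        e1_0 = (4.0 * pi**3 * q + 4.0 * pi * q**3).sum()
        e2_0 = (pi**4 + q**4 + 4.0 * pi**2 * q**2).sum()
        e1_1 = (2.0 * pi * q).sum()
        e2_1 = (pi**2 + q**2).sum()
        k0 = n_ibs0 / e0_0 if e0_0 > 0 else 0.0
        k1 = (n_ibs1 - k0 * e1_0) / e1_1 if e1_1 > 0 else 0.0
        k2 = (n_ibs2 - k0 * e2_0 - k1 * e2_1) / L
        ks = np.clip(np.array([k0, k1, k2]), 0.0, 1.0)
        total = ks.sum()
        if total > 0:
            ks = ks / total
        k0m[i, j] = k0m[j, i] = ks[0]
        k1m[i, j] = k1m[j, i] = ks[1]
        k2m[i, j] = k2m[j, i] = ks[2]
        pi_hat[i, j] = pi_hat[j, i] = ks[1] / 2.0 + ks[2]
        if L < min_loci:
            lowconf[i, j] = lowconf[j, i] = True

    return IBDMatrix(
        samples=diploid,
        pi_hat=pi_hat,
        k0=k0m,
        k1=k1m,
        k2=k2m,
        n_loci=nlm,
        low_confidence=lowconf,
    )
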