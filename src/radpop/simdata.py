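"""Synthetic multi-ploidy RAD-seq cohorts with known ground truth.

The generator emulates the statistical structure of a divergent-species
SNP panel so every analysis stage can be verified against simulated truth:

* population divergence under the Balding-Nichols model — per-locus
  ancestral frequency p ~ Uniform(0.05, 0.95), population frequency
  ~ Beta(p (1-F)/F, (1-p)(1-F)/F) with divergence parameter F,
* within-population inbreeding — with probability FIS an individual's
  genotype at a locus is fully autozygous (dosage 0 or ploidy), otherwise
  Binomial(ploidy, p_pop),
* mixed ploidy (2n/3n/4n per sample) with GT emitted at the true ploidy,
* half-sib families from a single diploid mother and free pollination,
* a two-group phenotype contrast: trait loci whose alt frequency in the
  second group is shifted by ``delta``,
* a read model: DP ~ NegativeBinomial(depth_mean, dispersion), alternate
  reads ~ Binomial(DP, mu_d) with mu_d = d/m (1-e) + (1-d/m) e, and GQ
  derived from genuine binomial genotype likelihoods (phred gap between
  the two best genotypes, capped at 99).

Linkage disequilibrium, RAD locus dropout and reference-sequence emission
are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vcfio import MISSING, LocusRecord, PopulationMap, VariantMatrix

_BASE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("A", "T"), ("C", "G")]


@dataclass
class PopulationConfig:
    label: str
    n_samples: int
    divergence: float = 0.1  # Balding-Nichols F
    inbreeding: float = 0.0  # FIS
    ploidy: int | list[int] = 2  # scalar or per-sample list


@dataclass
class FamilyConfig:
    population: str
    mother_index: int  # index within that population's samples
    n_offspring: int = 5


@dataclass
class TraitConfig:
    n_trait_loci: int = 73
    delta: float = 0.6  # allele-frequency gap between phenotype groups
    group_labels: tuple[str, str] = ("dropping", "non_dropping")
    population: str | None = None  # restrict contrast to one population
    group_fraction: float = 0.5


@dataclass
class SimConfig:
    n_loci: int = 1000
    populations: list[PopulationConfig] = field(
        default_factory=lambda: [PopulationConfig("pop1", 20)]
    )
    families: list[FamilyConfig] = field(default_factory=list)
    trait: TraitConfig | None = None
    depth_mean: float = 60.0
    depth_dispersion: float = 10.0  # NegBin size parameter
    error_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_loci <= 0:
            problems.append("n_loci must be positive")
        if self.depth_mean <= 0:
            problems.append("depth_mean must be positive")
        if self.depth_dispersion <= 0:
            problems.append("depth_dispersion must be positive")
        if not (0 <= self.error_rate < 0.5):
            problems.append("error_rate must be in [0, 0.5)")
        if not self.populations:
            problems.append("at least one population required")
        for pc in self.populations:
            if not (0 <= pc.divergence < 1):
                problems.append(f"{pc.label}: divergence F must be in [0, 1)")
            if not (0 <= pc.inbreeding < 1):
                problems.append(f"{pc.label}: inbreeding FIS must be in [0, 1)")
            if pc.n_samples < 1:
                problems.append(f"{pc.label}: n_samples must be >= 1")
            ploidies = pc.ploidy if isinstance(pc.ploidy, list) else [pc.ploidy]
            if any(m < 2 for m in ploidies):
                problems.append(f"{pc.label}: ploidy must be >= 2")
            if isinstance(pc.ploidy, list) and len(pc.ploidy) != pc.n_samples:
                problems.append(f"{pc.label}: ploidy list length != n_samples")
        if self.trait and not (0 <= self.trait.delta <= 1):
            problems.append("trait delta must be in [0, 1]")
        labels = [pc.label for pc in self.populations]
        for fam in self.families:
            if fam.population not in labels:
                problems.append(f"family references unknown population {fam.population!r}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimTruth:
    """Ground truth record used as the oracle in recovery tests."""

    ancestral_freqs: np.ndarray  # n_loci
    population_freqs: dict[str, np.ndarray]  # label -> n_loci
    genotypes: pd.DataFrame  # samples x loci true dosages
    ploidies: dict[str, int]
    populations: dict[str, str]
    pedigree: dict[str, str] = field(default_factory=dict)  # child -> mother
    families: dict[str, str] = field(default_factory=dict)  # sample -> family id
    trait_loci: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    phenotypes: dict[str, str] = field(default_factory=dict)

    def population_map(self) -> PopulationMap:
        return PopulationMap(
            assignments=dict(self.populations),
            family=dict(self.families),
            phenotype=dict(self.phenotypes),
        )


def _negbin_dp(rng: np.random.Generator, mean: float, size_param: float, n: int):
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _genotype_gq_vector(
    alt: np.ndarray, dp: np.ndarray, ploidy: int, error_rate: float
) -> np.ndarray:
    """GQ per site: phred gap between the two best genotype likelihoods.

    Likelihoods are Binomial(dp, mu_g) over genotypes g = 0..ploidy with
    error-adjusted means; capped at 99, 0 where there are no reads.
    """
    from scipy.special import gammaln

    g = np.arange(ploidy + 1)
    mu = g / ploidy * (1 - error_rate) + (1 - g / ploidy) * error_rate
    a = alt[:, None].astype(float)
    n = dp[:, None].astype(float)
    ll = (
        gammaln(n + 1)
        - gammaln(a + 1)
        - gammaln(n - a + 1)
        + a * np.log(mu[None, :])
        + (n - a) * np.log1p(-mu[None, :])
    )
    phred = -10.0 * ll / np.log(10.0)
    part = np.partition(phred, 1, axis=1)
    gq = np.minimum(np.rint(part[:, 1] - part[:, 0]), 99).astype(np.int32)
    gq[dp == 0] = 0
    return gq


def simulate_cohort(config: SimConfig) -> tuple[VariantMatrix, SimTruth]:
    """Simulate a cohort VCF-equivalent matrix plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_loci

    p_anc = rng.uniform(0.05, 0.95, size=L)
    pop_freqs: dict[str, np.ndarray] = {}
    for pc in config.populations:
        f = pc.divergence
        if f == 0:
            pop_freqs[pc.label] = p_anc.copy()
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            pop_freqs[pc.label] = rng.beta(a, b)

    trait_loci = np.array([], dtype=int)
    phenotypes: dict[str, str] = {}
    if config.trait is not None:
        trait_loci = rng.choice(L, size=config.trait.n_trait_loci, replace=False)
        trait_loci.sort()

    samples: list[str] = []
    ploidies: dict[str, int] = {}
    populations: dict[str, str] = {}
    dosage_rows: dict[str, np.ndarray] = {}
    by_pop_samples: dict[str, list[str]] = {}

    for pc in config.populations:
        freqs = pop_freqs[pc.label]
        ploidy_list = (
            pc.ploidy if isinstance(pc.ploidy, list) else [pc.ploidy] * pc.n_samples
        )
        group_b: set[int] = set()
        if config.trait is not None and (
            config.trait.population in (None, pc.label)
        ):
            n_b = int(round(pc.n_samples * (1 - config.trait.group_fraction)))
            group_b = set(range(pc.n_samples - n_b, pc.n_samples))
        for i in range(pc.n_samples):
            name = f"{pc.label}_{i:03d}"
            m = ploidy_list[i]
            in_b = i in group_b
            p_i = freqs.copy()
            if config.trait is not None and in_b:
                p_i[trait_loci] = np.minimum(1.0, p_i[trait_loci] + config.trait.delta)
            dosage = rng.binomial(m, p_i)
            if pc.inbreeding > 0:
                auto = rng.random(L) < pc.inbreeding
                fixed = (rng.random(L) < p_i).astype(int) * m
                dosage = np.where(auto, fixed, dosage)
            samples.append(name)
            ploidies[name] = m
            populations[name] = pc.label
            dosage_rows[name] = dosage
            by_pop_samples.setdefault(pc.label, []).append(name)
            if config.trait is not None and config.trait.population in (None, pc.label):
                phenotypes[name] = (
                    config.trait.group_labels[1] if in_b else config.trait.group_labels[0]
                )

    pedigree: dict[str, str] = {}
    families: dict[str, str] = {}
    for fi, fam in enumerate(config.families):
        mother = by_pop_samples[fam.population][fam.mother_index]
        if ploidies[mother] != 2:
            raise ValueError(f"family mother {mother} is not diploid")
        fam_id = f"fam{fi}"
        families[mother] = fam_id
        kids, links = simulate_family(
            pop_freqs[fam.population],
            dosage_rows[mother],
            fam.n_offspring,
            seed=int(rng.integers(0, 2**31 - 1)),
            prefix=f"{mother}_off",
        )
        for child, dos in kids.items():
            samples.append(child)
            ploidies[child] = 2
            populations[child] = fam.population
            dosage_rows[child] = dos
            pedigree[child] = links[child]
            families[child] = fam_id

    # read model
    ns = len(samples)
    dosage = np.full((L, ns), MISSING, dtype=np.int16)
    call_ploidy = np.full((L, ns), MISSING, dtype=np.int16)
    dp_arr = np.full((L, ns), MISSING, dtype=np.int32)
    gq_arr = np.full((L, ns), MISSING, dtype=np.int32)
    ad_ref = np.full((L, ns), MISSING, dtype=np.int32)
    ad_alt = np.full((L, ns), MISSING, dtype=np.int32)
    e = config.error_rate
    for j, name in enumerate(samples):
        m = ploidies[name]
        d = dosage_rows[name]
        dp = _negbin_dp(rng, config.depth_mean, config.depth_dispersion, L)
        mu = d / m * (1 - e) + (1 - d / m) * e
        alt = rng.binomial(dp, mu)
        dosage[:, j] = d
        call_ploidy[:, j] = m
        dp_arr[:, j] = dp
        ad_alt[:, j] = alt
        ad_ref[:, j] = dp - alt
        gq_arr[:, j] = _genotype_gq_vector(alt, dp, m, e)

    loci = []
    for i in range(L):
        ref, alt_b = _BASE_PAIRS[int(rng.integers(0, len(_BASE_PAIRS)))]
        loci.append(LocusRecord(chrom="chr1", pos=i * 100 + 1, ref=ref, alt=alt_b))

    vm = VariantMatrix(
        loci=loci,
        samples=samples,
        dosage=dosage,
        call_ploidy=call_ploidy,
        dp=dp_arr,
        gq=gq_arr,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )
    truth = SimTruth(
        ancestral_freqs=p_anc,
        population_freqs=pop_freqs,
        genotypes=pd.DataFrame(
            {s: dosage_rows[s] for s in samples}
        ).T,
        ploidies=ploidies,
        populations=populations,
        pedigree=pedigree,
        families=families,
        trait_loci=trait_loci,
        phenotypes=phenotypes,
    )
    return vm, truth


def simulate_family(
    population_freqs: np.ndarray,
    mother_dosages: np.ndarray,
    n_offspring: int,
    seed: int = 0,
    prefix: str = "off",
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Half-sib offspring of one diploid mother under free pollination.

    Each offspring receives one gamete from the mother (allele drawn per
    locus with probability dosage/2) and one from the population allele
    frequencies.  Returns (child -> dosage array, child -> mother-tag
    pedigree links keyed by the prefix).
    """
    mother_dosages = np.asarray(mother_dosages)
    if mother_dosages.max(initial=0) > 2:
        raise ValueError("only diploid mothers are supported")
    rng = np.random.default_rng(seed)
    L = population_freqs.shape[0]
    kids: dict[str, np.ndarray] = {}
    links: dict[str, str] = {}
    mother_tag = prefix.rsplit("_off", 1)[0]
    for c in range(n_offspring):
        maternal = (rng.random(L) < mother_dosages / 2.0).astype(np.int16)
        paternal = (rng.random(L) < population_freqs).astype(np.int16)
        name = f"{prefix}{c}"
        kids[name] = maternal + paternal
        links[name] = mother_tag
    return kids, links


def write_truth(truth: SimTruth, out_dir) -> None:
    """Write truth tables (ploidies, pedigree, trait loci, frequencies) as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample": list(truth.ploidies),
            "ploidy": [truth.ploidies[s] for s in truth.ploidies],
            "population": [truth.populations[s] for s in truth.ploidies],
            "family": [truth.families.get(s, "") for s in truth.ploidies],
            "phenotype": [truth.phenotypes.get(s, "") for s in truth.ploidies],
        }
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"child": list(truth.pedigree), "mother": list(truth.pedigree.values())}
    ).to_csv(out / "pedigree.tsv", sep="\t", index=False)
    pd.DataFrame({"trait_locus": truth.trait_loci}).to_csv(
        out / "trait_loci.tsv", sep="\t", index=False
    )
    freq = pd.DataFrame(truth.population_freqs)
    freq.insert(0, "ancestral", truth.ancestral_freqs)
    freq.to_csv(out / "population_freqs.tsv", sep="\t", index=False)


def read_truth_samples(path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "samples.tsv", sep="\t", keep_default_na=False)
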