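"""End-to-end analysis pipeline: filter -> ploidy -> stats -> structure [-> annotate].

A :class:`RunConfig` (optionally loaded from YAML) drives a fixed stage
order; every output lands in one directory together with a machine-readable
manifest (seed, thresholds, input checksums, per-stage row counts) so that
repeated runs with the same inputs and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import ploidy as pl
from . import popgen, structure, vcfio

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    vcf: str
    population_map: str
    out_dir: str
    min_dp: int = 10
    min_gq: int = 20
    call_rate: float = 0.95
    depth_k_sd: float = 2.0
    ploidy_candidates: list[int] = field(default_factory=lambda: [2, 3, 4])
    min_het_sites: int = 200
    k_max: int = 8
    n_boot: int = 100
    seed: int = 0
    skip_call_filters: bool = False
    gff: str | None = None
    fasta: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for label, p in (("vcf", self.vcf), ("population_map", self.population_map)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        for label, p in (("gff", self.gff), ("fasta", self.fasta)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the report directory.

    Stages (fixed order): read + biallelic filter, per-call DP/GQ filter,
    call-rate filter, depth-normality filter, write filtered VCF, ploidy
    calls, diversity/Fst/IBD, PCA + K selection + DAPC + UPGMA tree,
    optional effect annotation.  A stage failure aborts with the stage
    name; outputs written so far are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {
            "vcf_sha256": _sha256(config.vcf),
            "population_map_sha256": _sha256(config.population_map),
        },
        "stages": {},
    }
    stage = "read_vcf"
    try:
        vm = vcfio.read_vcf(config.vcf, skip_non_snps=True)
        pm = vcfio.PopulationMap.read(config.population_map)
        manifest["stages"][stage] = {"loci": vm.n_loci, "samples": vm.n_samples}

        stage = "filter"
        vm = vcfio.filter_biallelic_snps(vm)
        if not config.skip_call_filters:
            vm = vcfio.apply_call_filters(vm, min_dp=config.min_dp, min_gq=config.min_gq)
        vm = vcfio.filter_loci_by_callrate(vm, min_rate=config.call_rate)
        vm = vcfio.filter_loci_by_depth_normality(vm, k_sd=config.depth_k_sd)
        manifest["stages"][stage] = {"loci": vm.n_loci, "samples": vm.n_samples}
        vcfio.write_vcf(vm, out / "filtered.vcf")

        stage = "ploidy"
        ploidy_table = pl.call_ploidy_all(
            vm,
            candidates=set(config.ploidy_candidates),
            min_het_sites=config.min_het_sites,
        )
        ploidy_table.to_csv(out / "ploidy.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"rows": len(ploidy_table)}

        stage = "popgen"
        stats = popgen.basic_stats(vm, pm)
        stats.to_frame().to_csv(out / "diversity.tsv", sep="\t", index=False)
        n_pops = len(pm.populations())
        if n_pops >= 2:
            fst = popgen.pairwise_fst(vm, pm)
            fst.to_frame().to_csv(out / "fst.tsv", sep="\t")
        ibd = popgen.ibd_estimates(vm)
        ibd.to_frame().to_csv(out / "ibd.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "populations": n_pops,
            "ibd_pairs": len(ibd.samples) * (len(ibd.samples) - 1) // 2,
        }

        stage = "structure"
        n_comp = min(10, vm.n_samples - 1, vm.n_loci)
        pca_res = structure.pca(vm, n_components=n_comp)
        import pandas as pd

        pd.DataFrame(
            pca_res.scores,
            index=vm.samples,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        ).to_csv(out / "pca_scores.tsv", sep="\t")
        # K selection needs a high-dimensional score matrix (see docs)
        k_scores = structure.pca(
            vm, n_components=min(40, vm.n_samples - 1, vm.n_loci)
        ).scores
        k_max = min(config.k_max, vm.n_samples - 1)
        bic, assign = structure.find_clusters(k_scores, k_max=k_max, seed=config.seed)
        k = structure.choose_k(bic)
        pd.DataFrame(
            {"K": sorted(bic), "BIC": [bic[kk] for kk in sorted(bic)]}
        ).to_csv(out / "bic_curve.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample": vm.samples, "cluster": assign[k]}
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        dres = structure.dapc(vm, pm.assignments)
        pd.DataFrame(
            dres.memberships, index=list(dres.group_assignments), columns=dres.groups
        ).to_csv(out / "dapc_memberships.tsv", sep="\t")
        snps = structure.discriminant_snps(dres)
        pd.DataFrame(
            {
                "locus_index": snps,
                "chrom": [vm.loci[i].chrom for i in snps],
                "pos": [vm.loci[i].pos for i in snps],
            }
        ).to_csv(out / "discriminant_snps.tsv", sep="\t", index=False)
        tree = structure.upgma_tree(vm, n_boot=config.n_boot, seed=config.seed)
        (out / "upgma.nwk").write_text(tree.newick + "\n")
        manifest["stages"][stage] = {"chosen_k": k, "discriminant_snps": len(snps)}

        if config.gff and config.fasta:
            stage = "annotate"
            index = ann.load_annotation(config.gff, config.fasta)
            labels = ann.classify_all(vm.loci, index)
            ann.effect_summary(labels).to_csv(
                out / "effect_summary.tsv", sep="\t", index=False
            )
            manifest["stages"][stage] = {"variants": len(labels)}
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
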