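"""Lightweight variant-effect classification against a GFF3 gene annotation.

Assigns every biallelic SNP exactly one effect category using a
most-severe-first precedence, the subset of SnpEff's sequence-ontology
vocabulary needed for genome-region summaries:

    stop_gained / stop_lost > missense_variant > synonymous_variant >
    5'/3' UTR > intron_variant > intragenic_variant (inside a gene but in
    no transcript feature) > upstream/downstream_gene_variant (within a
    configurable strand-aware window, 5 kb default) > intergenic_variant

Coding effects are computed by substituting the alternate base into the
strand-corrected codon and translating with the standard genetic code.
This is deliberately not a full annotator: no splice-site classes, no
MNV/indel effects, no transcript-database curation.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .vcfio import LocusRecord

logger = logging.getLogger(__name__)

#: categories ordered most-severe first
SEVERITY_ORDER = [
    "stop_gained",
    "stop_lost",
    "missense_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "intragenic_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
]
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


class ReferenceMismatchError(ValueError):
    """Variant REF base disagrees with the reference FASTA."""


@dataclass(frozen=True)
class EffectLabel:
    category: str
    gene: str = ""


@dataclass
class _Transcript:
    id: str
    gene: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]
    start: int = 0
    end: int = 0


class GeneModelIndex:
    """Per-chromosome interval index of genes and transcript features.

    Transcripts whose total CDS length is not a multiple of three are
    dropped with a warning (frame cannot be established for the simplified
    phase-0 model used here).
    """

    def __init__(self, genes, transcripts, fasta: Fasta):
        self.genes = genes  # gene id -> (chrom, start, end, strand)
        self.transcripts = transcripts  # gene id -> list of _Transcript
        self.fasta = fasta
        self._tree: dict[str, IntervalTree] = {}
        for gid, (chrom, start, end, _strand) in genes.items():
            self._tree.setdefault(chrom, IntervalTree())
            self._tree[chrom].addi(start, end + 1, gid)

    def genes_overlapping(self, chrom: str, pos: int) -> list[str]:
        tree = self._tree.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos])

    def genes_near(self, chrom: str, pos: int, window: int) -> list[str]:
        tree = self._tree.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree[pos - window : pos + window + 1]})

    def ref_base(self, chrom: str, pos: int) -> str:
        return str(self.fasta[chrom][pos - 1 : pos]).upper()

    def ref_base_range(self, chrom: str, start: int, end: int) -> str:
        """Reference sequence on [start, end], 1-based inclusive."""
        return str(self.fasta[chrom][start - 1 : end]).upper()


def _spans(db, parent_id, featuretype) -> list[tuple[int, int]]:
    return sorted(
        (f.start, f.end) for f in db.children(parent_id, featuretype=featuretype)
    )


def load_annotation(gff_path, fasta_path) -> GeneModelIndex:
    """Build a :class:`GeneModelIndex` from GFF3 + FASTA.

    Requires gene/mRNA/exon/CDS features (UTRs optional).  Raises if a
    gene's chromosome is missing from the FASTA.
    """
    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = {}
        transcripts: dict[str, list[_Transcript]] = {}
        for gene in db.features_of_type("gene"):
            if gene.seqid not in fasta:
                raise ValueError(
                    f"chromosome {gene.seqid!r} of gene {gene.id} missing from FASTA"
                )
            genes[gene.id] = (gene.seqid, gene.start, gene.end, gene.strand)
            transcripts[gene.id] = []
            for mrna in db.children(gene.id, featuretype="mRNA"):
                cds = _spans(db, mrna.id, "CDS")
                total = sum(e - s + 1 for s, e in cds)
                if cds and total % 3 != 0:
                    logger.warning(
                        "transcript %s dropped: CDS length %d not divisible by 3",
                        mrna.id,
                        total,
                    )
                    continue
                transcripts[gene.id].append(
                    _Transcript(
                        id=mrna.id,
                        gene=gene.id,
                        strand=mrna.strand,
                        exons=_spans(db, mrna.id, "exon"),
                        cds=cds,
                        utr5=_spans(db, mrna.id, "five_prime_UTR"),
                        utr3=_spans(db, mrna.id, "three_prime_UTR"),
                        start=mrna.start,
                        end=mrna.end,
                    )
                )
    return GeneModelIndex(genes, transcripts, fasta)


def _in_spans(pos: int, spans) -> bool:
    return any(s <= pos <= e for s, e in spans)


def _coding_effect(locus: LocusRecord, tx: _Transcript, index: GeneModelIndex) -> str:
    """Effect of substituting alt into the codon containing the SNP."""
    cds_seq = "".join(
        index.ref_base_range(locus.chrom, s, e) for s, e in tx.cds
    )
    offset = 0
    pos_in_cds = None
    for s, e in tx.cds:
        if s <= locus.pos <= e:
            pos_in_cds = offset + (locus.pos - s)
            break
        offset += e - s + 1
    assert pos_in_cds is not None
    alt_seq = cds_seq[:pos_in_cds] + locus.alt + cds_seq[pos_in_cds + 1 :]
    if tx.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        alt_seq = str(Seq(alt_seq).reverse_complement())
        pos_in_cds = len(cds_seq) - 1 - pos_in_cds
    codon_i = pos_in_cds // 3
    ref_codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = alt_seq[codon_i * 3 : codon_i * 3 + 3]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous_variant"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense_variant"


def classify_variant(
    locus: LocusRecord, index: GeneModelIndex, updown_bp: int = 5000
) -> EffectLabel:
    """Assign the single most severe effect category to one SNP."""
    ref = index.ref_base(locus.chrom, locus.pos)
    if ref != locus.ref:
        raise ReferenceMismatchError(
            f"{locus}: VCF REF {locus.ref!r} != FASTA base {ref!r}"
        )

    candidates: list[EffectLabel] = []
    overlapping = index.genes_overlapping(locus.chrom, locus.pos)
    for gid in overlapping:
        txs = index.transcripts.get(gid, [])
        in_tx_feature = False
        for tx in txs:
            if not (tx.start <= locus.pos <= tx.end):
                continue
            if _in_spans(locus.pos, tx.cds):
                candidates.append(EffectLabel(_coding_effect(locus, tx, index), gid))
                in_tx_feature = True
            elif _in_spans(locus.pos, tx.utr5):
                candidates.append(EffectLabel("5_prime_UTR_variant", gid))
                in_tx_feature = True
            elif _in_spans(locus.pos, tx.utr3):
                candidates.append(EffectLabel("3_prime_UTR_variant", gid))
                in_tx_feature = True
            elif _in_spans(locus.pos, tx.exons):
                # exon outside CDS/UTR features: treat as UTR by side
                side = _utr_side(locus.pos, tx)
                candidates.append(EffectLabel(side, gid))
                in_tx_feature = True
            else:
                candidates.append(EffectLabel("intron_variant", gid))
                in_tx_feature = True
        if not in_tx_feature:
            candidates.append(EffectLabel("intragenic_variant", gid))

    if not candidates:
        for gid in index.genes_near(locus.chrom, locus.pos, updown_bp):
            chrom, start, end, strand = index.genes[gid]
            if locus.pos < start:
                cat = "upstream_gene_variant" if strand == "+" else "downstream_gene_variant"
            elif locus.pos > end:
                cat = "downstream_gene_variant" if strand == "+" else "upstream_gene_variant"
            else:
                continue
            candidates.append(EffectLabel(cat, gid))

    if not candidates:
        return EffectLabel("intergenic_variant", "")
    return min(candidates, key=lambda c: _RANK[c.category])


def _utr_side(pos: int, tx: _Transcript) -> str:
    """UTR category for exonic non-CDS position relative to the CDS span."""
    if not tx.cds:
        return "5_prime_UTR_variant"
    cds_start = min(s for s, _ in tx.cds)
    cds_end = max(e for _, e in tx.cds)
    before = pos < cds_start
    if tx.strand == "+":
        return "5_prime_UTR_variant" if before else "3_prime_UTR_variant"
    return "3_prime_UTR_variant" if before else "5_prime_UTR_variant"


def classify_all(loci, index: GeneModelIndex, updown_bp: int = 5000) -> list[EffectLabel]:
    return [classify_variant(l, index, updown_bp=updown_bp) for l in loci]


def effect_summary(labels) -> "pd.DataFrame":
    """Percentage of SNPs per effect category (zero-count categories omitted)."""
    import pandas as pd

    if not labels:
        raise ValueError("no labels to summarize")
    counts = pd.Series([l.category for l in labels]).value_counts()
    pct = (counts / counts.sum() * 100).round(2)
    df = pd.DataFrame({"category": pct.index, "count": counts.values, "percent": pct.values})
    order = df["category"].map(_RANK)
    return df.assign(_o=order).sort_values("_o").drop(columns="_o").reset_index(drop=True)
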