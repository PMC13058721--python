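"""Genome partition into feature classes and site-to-feature assignment.

The seven classes — promoter, 5'UTR, exon, intron, 3'UTR, downstream,
intergenic — tile the genome: every base maps to exactly one class under the
precedence rule 5'UTR > 3'UTR > exon > intron > promoter > downstream >
intergenic, with ties between genes at equal precedence broken by the
lexicographically smaller gene id. The enrichment null model is adenine
content, counted on both strands (#A + #T of the forward sequence), because
6mA occurs only on adenines and sites are called per strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .types import (
    FEATURES_BY_PRECEDENCE,
    FEATURE_CODE,
    GeneModel,
    GenomeSequence,
    Interval,
    MethylationSite,
    RepeatInterval,
    SiteAnnotation,
    TE_CLASSES,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

GENE_BODY_FEATURES = ("5'UTR", "exon", "intron", "3'UTR")


@dataclass
class PartitionConfig:
    """Feature-partition geometry.

    promoter_bp
        Upstream window from the TSS in the direction of transcription;
        1000 by default, with 500 and 2000 as the standard robustness
        alternatives.
    downstream_bp
        Window past the TES; 300 by default.
    """

    promoter_bp: int = 1000
    downstream_bp: int = 300

    def __post_init__(self) -> None:
        if self.promoter_bp <= 0 or self.downstream_bp <= 0:
            raise ValueError("promoter_bp and downstream_bp must be positive")


def gene_subregions(gene: GeneModel) -> Dict[str, List[Interval]]:
    """Per-gene sub-intervals for exon (minus UTRs), intron and the UTRs."""
    start, end = gene.span
    utrs = list(gene.utr5) + list(gene.utr3)
    exon = subtract_intervals(gene.exons, utrs)
    intron = subtract_intervals([(start, end)], gene.exons)
    return {
        "5'UTR": merge_intervals(gene.utr5),
        "3'UTR": merge_intervals(gene.utr3),
        "exon": exon,
        "intron": intron,
    }


def flank_intervals(
    gene: GeneModel, config: PartitionConfig, chrom_len: int
) -> Dict[str, List[Interval]]:
    """Promoter and downstream windows, strand-aware and clipped."""
    start, end = gene.span
    if gene.strand == "+":
        promoter = (start - config.promoter_bp, start)
        downstream = (end, end + config.downstream_bp)
    else:
        promoter = (end, end + config.promoter_bp)
        downstream = (start - config.downstream_bp, start)
    out: Dict[str, List[Interval]] = {}
    for name, (s, e) in (("promoter", promoter), ("downstream", downstream)):
        s_clip, e_clip = max(0, s), min(chrom_len, e)
        if (s_clip, e_clip) != (s, e):
            logger.debug(
                "gene %s: %s window truncated to chromosome", gene.gene_id, name
            )
        out[name] = [(s_clip, e_clip)] if s_clip < e_clip else []
    return out


class FeaturePartition:
    """Per-base feature labels and owning gene for a whole genome."""

    def __init__(
        self,
        labels: Dict[str, np.ndarray],
        gene_idx: Dict[str, np.ndarray],
        gene_ids: List[str],
        config: PartitionConfig,
    ):
        self.labels = labels
        self.gene_idx = gene_idx
        self.gene_ids = gene_ids
        self.config = config

    def feature_of(self, chrom: str, pos: int) -> str:
        return FEATURES_BY_PRECEDENCE[self.labels[chrom][pos]]

    def gene_of(self, chrom: str, pos: int) -> Optional[str]:
        idx = self.gene_idx[chrom][pos]
        return self.gene_ids[idx] if idx >= 0 else None

    def feature_bp(self) -> Dict[str, int]:
        counts = np.zeros(len(FEATURES_BY_PRECEDENCE), dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(FEATURES_BY_PRECEDENCE))
        return {f: int(counts[FEATURE_CODE[f]]) for f in FEATURES_BY_PRECEDENCE}

    def feature_intervals(self, chrom: str, feature: str) -> List[Interval]:
        """Maximal runs of one feature class on a chromosome (for BED export)."""
        arr = self.labels[chrom] == FEATURE_CODE[feature]
        if not arr.any():
            return []
        d = np.diff(arr.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if arr[0]:
            starts.insert(0, 0)
        if arr[-1]:
            ends.append(arr.size)
        return list(zip(starts, ends))


def build_partition(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    config: Optional[PartitionConfig] = None,
) -> FeaturePartition:
    """Label every genomic base with exactly one feature class.

    Classes are painted in ascending precedence so higher-precedence classes
    overwrite lower ones; within one class, genes are painted in reverse
    lexicographic order so the lexicographically smaller gene id wins ties.
    """
    config = config or PartitionConfig()
    labels = {
        c: np.zeros(n, dtype=np.uint8) for c, n in genome.lengths.items()
    }
    gene_idx = {
        c: np.full(n, -1, dtype=np.int32) for c, n in genome.lengths.items()
    }
    gene_order = sorted(genes, key=lambda g: g.gene_id, reverse=True)
    gene_ids = [g.gene_id for g in sorted(genes, key=lambda g: g.gene_id)]
    id_to_idx = {gid: i for i, gid in enumerate(gene_ids)}

    paint_order = [f for f in FEATURES_BY_PRECEDENCE if f != "intergenic"]
    per_gene: List[Tuple[GeneModel, Dict[str, List[Interval]]]] = []
    for g in gene_order:
        if g.chrom not in labels:
            raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        regions = gene_subregions(g)
        regions.update(flank_intervals(g, config, len(labels[g.chrom])))
        per_gene.append((g, regions))

    for feature in paint_order:
        code = FEATURE_CODE[feature]
        for g, regions in per_gene:
            lab, gidx = labels[g.chrom], gene_idx[g.chrom]
            idx = id_to_idx[g.gene_id]
            for s, e in regions.get(feature, []):
                s, e = max(0, s), min(lab.size, e)
                if s < e:
                    lab[s:e] = code
                    gidx[s:e] = idx
    return FeaturePartition(labels, gene_idx, gene_ids, config)


def count_adenines(
    genome: GenomeSequence, partition: FeaturePartition
) -> Dict[str, int]:
    """Strand-summed adenine count per feature class (#A + #T per base)."""
    counts = np.zeros(len(FEATURES_BY_PRECEDENCE), dtype=np.int64)
    for chrom, lab in partition.labels.items():
        arr = genome.array(chrom)
        mask = (arr == ord("A")) | (arr == ord("T"))
        counts += np.bincount(lab[mask], minlength=len(FEATURES_BY_PRECEDENCE))
    return {f: int(counts[FEATURE_CODE[f]]) for f in FEATURES_BY_PRECEDENCE}


def assign_sites(
    sites: Sequence[MethylationSite], partition: FeaturePartition
) -> List[SiteAnnotation]:
    """Label each site with the feature class of its base (and owning gene)."""
    out: List[SiteAnnotation] = []
    for s in sites:
        if s.chrom not in partition.labels:
            raise KeyError(f"site on unknown chromosome {s.chrom!r}")
        feature = partition.feature_of(s.chrom, s.pos0)
        gene_id = (
            partition.gene_of(s.chrom, s.pos0) if feature != "intergenic" else None
        )
        out.append(SiteAnnotation(site=s, feature=feature, gene_id=gene_id))
    return out


def composition(annotations: Sequence[SiteAnnotation]) -> Dict[str, float]:
    """Proportion of sites per feature class (sums to exactly 1)."""
    n = len(annotations)
    if n == 0:
        return {f: 0.0 for f in FEATURES_BY_PRECEDENCE}
    counts = {f: 0 for f in FEATURES_BY_PRECEDENCE}
    for a in annotations:
        counts[a.feature] += 1
    return {f: counts[f] / n for f in FEATURES_BY_PRECEDENCE}


_TE_RANK = {cls: i for i, cls in enumerate(TE_CLASSES)}


def assign_te(
    annotations: Sequence[SiteAnnotation], repeats: Sequence[RepeatInterval]
) -> Dict[str, float]:
    """Attach TE classes to annotated sites; return the TE composition.

    A site overlapping several repeats takes the class of the smallest
    covering interval; remaining ties go to the class earlier in
    LINE > SINE > LTR > SimpleRepeat > Other. Proportions are over *all*
    sites, so the non-TE remainder is reported under ``none``.
    """
    trees: Dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.te_class)
    counts = {cls: 0 for cls in TE_CLASSES}
    n_none = 0
    for a in annotations:
        tree = trees.get(a.site.chrom)
        hits = tree[a.site.pos0] if tree is not None else set()
        if not hits:
            a.te_class = None
            n_none += 1
            continue
        best = min(hits, key=lambda iv: (iv.end - iv.begin, _TE_RANK[iv.data]))
        a.te_class = best.data
        counts[best.data] += 1
    n = len(annotations)
    comp = {cls: (counts[cls] / n if n else 0.0) for cls in TE_CLASSES}
    comp["none"] = n_none / n if n else 0.0
    return comp


@dataclass
class MethylatedGeneSummary:
    counts: Dict[str, int] = field(default_factory=dict)
    totals: Dict[str, int] = field(default_factory=dict)
    percentages: Dict[str, float] = field(default_factory=dict)
    methylated_gene_ids: List[str] = field(default_factory=list)


def genes_with_sites(
    annotations: Sequence[SiteAnnotation], genes: Sequence[GeneModel]
) -> MethylatedGeneSummary:
    """Count genes carrying >= 1 gene-body 6mA site, split by biotype.

    Gene body means 5'UTR/exon/intron/3'UTR; a site only in a gene's promoter
    or downstream window does not make the gene methylated.
    """
    body = set(GENE_BODY_FEATURES)
    methylated = {
        a.gene_id for a in annotations if a.feature in body and a.gene_id
    }
    summary = MethylatedGeneSummary()
    for biotype in ("coding", "noncoding"):
        members = [g.gene_id for g in genes if g.biotype == biotype]
        hit = sum(1 for gid in members if gid in methylated)
        summary.counts[biotype] = hit
        summary.totals[biotype] = len(members)
        summary.percentages[biotype] = (
            100.0 * hit / len(members) if members else float("nan")
        )
    summary.methylated_gene_ids = sorted(
        methylated & {g.gene_id for g in genes}
    )
    return summary
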