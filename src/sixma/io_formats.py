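"""Readers and writers for every external format the pipeline touches.

Coordinate conventions: everything in memory is 0-based half-open. GFF3 and
the PacBio modifications-GFF dialect are 1-based inclusive on disk; BED is
0-based half-open. Conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    ExpressionRecord,
    GeneModel,
    GenomeSequence,
    Interval,
    MethylationSite,
    RepeatInterval,
    TE_CLASSES,
    TruthSite,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

_VALID = set(b"ACGTN")


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file into memory, uppercased.

    Characters outside {A, C, G, T, N} are mapped to N (with a logged count);
    duplicate headers and empty files are errors.
    """
    sequences: Dict[str, str] = {}
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seq = str(rec.seq).upper()
        raw = seq.encode("ascii")
        bad = [i for i, b in enumerate(raw) if b not in _VALID]
        if bad:
            arr = bytearray(raw)
            for i in bad:
                arr[i] = ord("N")
            n_mapped += len(bad)
            seq = arr.decode("ascii")
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    if n_mapped:
        logger.warning("mapped %d non-ACGTN characters to N", n_mapped)
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene annotation (GFF3)
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR"}


def _derive_utrs(
    exons: Sequence[Interval], cds: Sequence[Interval], strand: str
) -> Tuple[List[Interval], List[Interval]]:
    """UTRs as exonic bases upstream/downstream of the CDS extent."""
    if not cds:
        return [], []
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left = subtract_intervals(exons, [(cds_start, max(e for _, e in exons))])
    right = subtract_intervals(exons, [(min(s for s, _ in exons), cds_end)])
    if strand == "+":
        return left, right
    return right, left


def read_gff3_genes(path) -> List[GeneModel]:
    """Parse gene models from a GFF3 annotation.

    Genes with multiple mRNAs are collapsed to the isoform with the longest
    exonic span (logged). Coordinates are converted from 1-based inclusive to
    0-based half-open; tss/tes are oriented by strand. UTRs are taken from
    explicit UTR features when present, otherwise derived from exon/CDS.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    n_multi = 0
    for gene in db.features_of_type("gene"):
        if gene.strand not in "+-":
            raise ValueError(f"gene {gene.id}: unknown strand {gene.strand!r}")
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        if not mrnas:
            mrnas = [gene]  # gene with direct exon children (or none)
        best = None
        for mrna in mrnas:
            exons = [
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon")
            ]
            if not exons:
                exons = [(mrna.start - 1, mrna.end)]
            exons = merge_intervals(exons)
            cds = merge_intervals(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            utr5 = merge_intervals(
                (f.start - 1, f.end)
                for f in db.children(mrna)
                if f.featuretype in _UTR5_TYPES
            )
            utr3 = merge_intervals(
                (f.start - 1, f.end)
                for f in db.children(mrna)
                if f.featuretype in _UTR3_TYPES
            )
            exonic_bp = sum(e - s for s, e in exons)
            if best is None or exonic_bp > best[0]:
                best = (exonic_bp, exons, cds, utr5, utr3)
        if len(mrnas) > 1:
            n_multi += 1
        _, exons, cds, utr5, utr3 = best
        gene_start, gene_end = gene.start - 1, gene.end
        for s, e in exons:
            if s < gene_start or e > gene_end:
                raise ValueError(
                    f"gene {gene.id}: exon [{s},{e}) outside gene span"
                )
        if not utr5 and not utr3 and cds:
            utr5, utr3 = _derive_utrs(exons, cds, gene.strand)
        span_start = min(s for s, _ in exons)
        span_end = max(e for _, e in exons)
        if gene.strand == "+":
            tss, tes = span_start, span_end
        else:
            tss, tes = span_end - 1, span_start - 1
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tss=tss,
                tes=tes,
                exons=exons,
                cds=list(cds),
                utr5=list(utr5),
                utr3=list(utr3),
            )
        )
    if n_multi:
        logger.info(
            "collapsed %d multi-isoform genes to their longest exonic span", n_multi
        )
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path) -> None:
    """Emit gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            row = [g.chrom, "sixma", None, None, None, ".", g.strand, "."]

            def line(ftype: str, s: int, e: int, attrs: str) -> str:
                row[2], row[3], row[4] = ftype, str(s + 1), str(e)
                return "\t".join(row[:8] + [attrs]) + "\n"

            fh.write(line("gene", start, end, f"ID={g.gene_id}"))
            mrna_id = f"{g.gene_id}.t1"
            fh.write(line("mRNA", start, end, f"ID={mrna_id};Parent={g.gene_id}"))
            for s, e in g.exons:
                fh.write(line("exon", s, e, f"Parent={mrna_id}"))
            for s, e in g.cds:
                fh.write(line("CDS", s, e, f"Parent={mrna_id}"))
            for s, e in g.utr5:
                fh.write(line("five_prime_UTR", s, e, f"Parent={mrna_id}"))
            for s, e in g.utr3:
                fh.write(line("three_prime_UTR", s, e, f"Parent={mrna_id}"))


# ---------------------------------------------------------------------------
# PacBio modifications-GFF dialect
# ---------------------------------------------------------------------------

_MOD_TYPES = {"m6A", "modified_base"}


def _parse_attrs(field: str) -> Dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_modifications_gff(path) -> List[MethylationSite]:
    """Parse a base-modification GFF (the kinetics caller's output dialect).

    Expected attributes: ``coverage``, ``IPDRatio``, ``identificationQv`` and
    optionally ``frac`` and ``context``. Positions are converted from 1-based
    to 0-based.
    """
    sites: List[MethylationSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start, _end, _score, strand, _phase, attrs = fields
            if ftype not in _MOD_TYPES:
                continue
            a = _parse_attrs(attrs)
            try:
                coverage = int(a["coverage"])
                ipd_ratio = float(a["IPDRatio"])
                qv = float(a["identificationQv"])
                frac = float(a["frac"]) if "frac" in a else None
                pos0 = int(start) - 1
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"line {lineno}: bad or missing attribute ({exc})"
                ) from exc
            sites.append(
                MethylationSite(
                    chrom=chrom,
                    pos0=pos0,
                    strand=strand,
                    coverage=coverage,
                    ipd_ratio=ipd_ratio,
                    ident_qv=qv,
                    fraction=frac,
                    context9=a.get("context"),
                )
            )
    return sites


def write_sites_gff(sites: Sequence[MethylationSite], path) -> None:
    """Write sites in the modifications-GFF dialect (1-based positions).

    Round-trips losslessly through :func:`read_modifications_gff`; float
    attributes are written with 17 significant digits so values survive the
    trip bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("##source sixma kinetics_caller\n")
        for s in sites:
            attrs = [
                f"coverage={s.coverage}",
                f"IPDRatio={s.ipd_ratio:.17g}",
                f"identificationQv={s.ident_qv:.17g}",
            ]
            if s.fraction is not None:
                attrs.append(f"frac={s.fraction:.17g}")
            if s.context9 is not None:
                attrs.append(f"context={s.context9}")
            fh.write(
                "\t".join(
                    [
                        s.chrom,
                        "kinModCall",
                        "m6A",
                        str(s.pos0 + 1),
                        str(s.pos0 + 1),
                        f"{s.ident_qv:.0f}",
                        s.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def validate_sites_against_genome(
    sites: Sequence[MethylationSite], genome: GenomeSequence
) -> List[MethylationSite]:
    """Drop sites off-chromosome or not on an adenine of their strand.

    The number of rejected records is logged; valid records pass through
    unchanged, order preserved.
    """
    kept: List[MethylationSite] = []
    n_bad = 0
    for s in sites:
        if s.chrom not in genome or not 0 <= s.pos0 < len(genome.sequences[s.chrom]):
            n_bad += 1
            continue
        base = genome.base(s.chrom, s.pos0)
        expected = "A" if s.strand == "+" else "T"
        if base != expected:
            n_bad += 1
            continue
        kept.append(s)
    if n_bad:
        logger.warning("rejected %d sites off-chromosome or not on adenine", n_bad)
    return kept


# ---------------------------------------------------------------------------
# simple tables
# ---------------------------------------------------------------------------


def read_expression_tsv(path) -> List[ExpressionRecord]:
    """TSV with header columns gene_id, tpm. Negative TPM is an error."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in expression table: {dup!r}")
    return [
        ExpressionRecord(gene_id=str(r.gene_id), tpm=float(r.tpm))
        for r in df.itertuples()
    ]


def write_expression_tsv(records: Sequence[ExpressionRecord], path) -> None:
    pd.DataFrame(
        {"gene_id": [r.gene_id for r in records], "tpm": [r.tpm for r in records]}
    ).to_csv(path, sep="\t", index=False)


def read_repeat_bed(path) -> List[RepeatInterval]:
    """BED4: chrom, start, end (0-based half-open), TE class in column 4.

    Unknown classes are mapped to ``Other`` with a logged warning.
    """
    out: List[RepeatInterval] = []
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: BED4 requires 4 columns")
            chrom, start, end, te_class = fields[:4]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(
                    f"line {lineno}: malformed interval {start} >= {end}"
                )
            if te_class not in TE_CLASSES:
                n_unknown += 1
                te_class = "Other"
            out.append(RepeatInterval(chrom, start, end, te_class))
    if n_unknown:
        logger.warning("mapped %d unknown TE classes to Other", n_unknown)
    return out


def write_repeat_bed(repeats: Sequence[RepeatInterval], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.te_class}\n")


def read_term_map(path) -> Dict[str, List[str]]:
    """TSV gene_id -> comma-separated term list (no header required)."""
    mapping: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected gene_id<TAB>terms")
            gene_id, terms = fields[0], fields[1]
            if gene_id == "gene_id":  # optional header
                continue
            mapping[gene_id] = [t for t in terms.split(",") if t]
    return mapping


def write_term_map(mapping: Dict[str, List[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterms\n")
        for gene_id, terms in mapping.items():
            fh.write(f"{gene_id}\t{','.join(terms)}\n")


def read_truth_tsv(path) -> List[TruthSite]:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
    return [
        TruthSite(
            chrom=str(r.chrom),
            pos0=int(r.pos0),
            strand=str(r.strand),
            true_fraction=float(r.fraction),
            feature_label=str(r.feature),
            te_label=str(r.te) if r.te else None,
        )
        for r in df.itertuples()
    ]


def write_truth_tsv(truth: Sequence[TruthSite], path) -> None:
    pd.DataFrame(
        {
            "chrom": [t.chrom for t in truth],
            "pos0": [t.pos0 for t in truth],
            "strand": [t.strand for t in truth],
            "fraction": [t.true_fraction for t in truth],
            "feature": [t.feature_label for t in truth],
            "te": [t.te_label or "" for t in truth],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
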