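"""Shared domain containers for the 6mA profiling pipeline.

All genomic intervals stored on these objects are 0-based half-open
``[start, end)``; conversion to the 1-based inclusive GFF convention (or
back) happens only inside :mod:`sixma.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]

#: closed vocabulary of transposable-element classes
TE_CLASSES = ("LINE", "SINE", "LTR", "SimpleRepeat", "Other")

#: feature vocabulary, ordered by genomic-partition precedence (low -> high)
FEATURES_BY_PRECEDENCE = (
    "intergenic",
    "downstream",
    "promoter",
    "intron",
    "exon",
    "3'UTR",
    "5'UTR",
)
FEATURE_CODE = {name: code for code, name in enumerate(FEATURES_BY_PRECEDENCE)}

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


class GenomeSequence:
    """Uppercase per-chromosome sequences over the {A, C, G, T, N} alphabet.

    Parameters
    ----------
    sequences
        Mapping of unique chromosome name to uppercase sequence string.
    """

    def __init__(self, sequences: Dict[str, str]):
        if not sequences:
            raise ValueError("genome has no chromosomes")
        self.sequences: Dict[str, str] = dict(sequences)
        self._arrays: Dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> List[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.sequences[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[chrom]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    def strand_adenine_count(self) -> int:
        """Adenines counted on both strands: #A + #T of the forward sequence.

        This is the denominator of the genome-wide 6mA/A density: every
        forward A is an adenine on the + strand and every forward T is an
        adenine on the - strand.
        """
        total = 0
        for chrom in self.sequences:
            arr = self.array(chrom)
            total += int(np.count_nonzero((arr == ord("A")) | (arr == ord("T"))))
        return total


@dataclass
class GeneModel:
    """One gene, represented by a single (longest) transcript isoform.

    ``tss`` is the 0-based index of the first transcribed base; ``tes`` is one
    past the last transcribed base *in the direction of transcription* (for a
    + strand gene spanning ``[100, 200)``: tss=100, tes=200; for the - strand
    equivalent: tss=199, tes=99).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: List[Interval]
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def biotype(self) -> str:
        return "coding" if self.cds else "noncoding"

    @property
    def span(self) -> Interval:
        """Genomic extent [start, end) of the transcribed region."""
        if self.strand == "+":
            return (self.tss, self.tes)
        return (self.tes + 1, self.tss + 1)

    @property
    def body_length(self) -> int:
        s, e = self.span
        return e - s


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int
    te_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed repeat interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"gene {self.gene_id}: negative TPM {self.tpm}")


@dataclass
class MethylationSite:
    """One called 6mA position with its kinetic evidence.

    ``fraction`` is the estimated methylated fraction of molecules in [0, 1],
    or ``None`` when unknown; ``context9`` is the strand-oriented 9-mer
    centered on the modified adenine, or ``None`` near chromosome ends.
    """

    chrom: str
    pos0: int
    strand: str
    coverage: int
    ipd_ratio: float
    ident_qv: float
    fraction: Optional[float] = None
    context9: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.ipd_ratio <= 0:
            raise ValueError("ipdRatio must be > 0")
        if self.ident_qv < 0:
            raise ValueError("identification QV must be >= 0")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class SubreadKinetics:
    """Per-subread inter-pulse durations observed at one adenine position.

    ``mu0``/``sigma0`` parameterize the expected unmodified log-IPD
    (lognormal baseline) at this position.
    """

    chrom: str
    pos0: int
    strand: str
    ipds: np.ndarray
    mu0: float
    sigma0: float

    def __post_init__(self) -> None:
        self.ipds = np.asarray(self.ipds, dtype=float)
        if self.ipds.size and self.ipds.min() <= 0:
            raise ValueError("IPDs must be positive")

    @property
    def coverage(self) -> int:
        return int(self.ipds.size)


class ChromosomeKinetics:
    """Kinetics for all strand-adenines of one chromosome, in flat arrays.

    Positions are stored per strand-adenine (forward A on +, forward T on -)
    with a ragged IPD layout: observation ``i`` owns
    ``ipds[offsets[i]:offsets[i + 1]]``.
    """

    def __init__(
        self,
        chrom: str,
        pos: np.ndarray,
        strand: np.ndarray,
        coverage: np.ndarray,
        ipds: np.ndarray,
        mu0: float,
        sigma0: float,
    ):
        self.chrom = chrom
        self.pos = np.asarray(pos, dtype=np.int64)
        self.strand = np.asarray(strand)  # bool: True for '-'
        self.coverage = np.asarray(coverage, dtype=np.int64)
        self.ipds = np.asarray(ipds)
        self.offsets = np.concatenate([[0], np.cumsum(self.coverage)])
        if self.offsets[-1] != self.ipds.size:
            raise ValueError("coverage does not match IPD array length")
        self.mu0 = float(mu0)
        self.sigma0 = float(sigma0)

    def __len__(self) -> int:
        return self.pos.size

    def site(self, i: int) -> SubreadKinetics:
        lo, hi = self.offsets[i], self.offsets[i + 1]
        return SubreadKinetics(
            chrom=self.chrom,
            pos0=int(self.pos[i]),
            strand="-" if self.strand[i] else "+",
            ipds=self.ipds[lo:hi].astype(float),
            mu0=self.mu0,
            sigma0=self.sigma0,
        )


@dataclass(frozen=True)
class TruthSite:
    """A planted 6mA site: the simulator's ground truth for recovery tests."""

    chrom: str
    pos0: int
    strand: str
    true_fraction: float
    feature_label: str
    te_label: Optional[str] = None


@dataclass
class SiteAnnotation:
    """A called site labeled with its (single) feature class and TE overlap."""

    site: MethylationSite
    feature: str
    gene_id: Optional[str] = None
    te_class: Optional[str] = None


def merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: List[Interval] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(
    a: Sequence[Interval], b: Sequence[Interval]
) -> List[Interval]:
    """Set difference a \\ b on half-open intervals; both need not be sorted."""
    out: List[Interval] = []
    b_merged = merge_intervals(b)
    for s, e in merge_intervals(a):
        cur = s
        for bs, be in b_merged:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out
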