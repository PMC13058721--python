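"""Strand-oriented flanking-sequence extraction and position weight matrices.

The default window is 4 bp on each side of the methylated adenine (9 bp
total); on the - strand the forward window is reverse-complemented so the
center always reads A in the site's orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import GenomeSequence, MethylationSite, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


@dataclass
class MotifConfig:
    flank_k: int = 4

    def __post_init__(self) -> None:
        if self.flank_k < 1:
            raise ValueError("flank_k must be >= 1")

    @property
    def width(self) -> int:
        return 2 * self.flank_k + 1


def extract_flanks(
    sites: Sequence[MethylationSite],
    genome: GenomeSequence,
    config: Optional[MotifConfig] = None,
) -> List[str]:
    """Oriented (2k+1)-mers centered on each site's adenine.

    Windows truncated by a chromosome end are dropped with a logged count; a
    non-A center after orientation indicates upstream corruption and raises.
    """
    config = config or MotifConfig()
    k = config.flank_k
    flanks: List[str] = []
    n_dropped = 0
    for s in sites:
        seq = genome.sequences[s.chrom]
        if s.pos0 - k < 0 or s.pos0 + k + 1 > len(seq):
            n_dropped += 1
            continue
        window = seq[s.pos0 - k : s.pos0 + k + 1]
        if s.strand == "-":
            window = revcomp(window)
        if window[k] != "A":
            raise ValueError(
                f"site {s.chrom}:{s.pos0}({s.strand}) centers on "
                f"{window[k]!r}, not A"
            )
        flanks.append(window)
    if n_dropped:
        logger.info("dropped %d flanks truncated by chromosome ends", n_dropped)
    return flanks


@dataclass
class PWM:
    """Per-position base counts and frequencies over a fixed window."""

    counts: np.ndarray  # (width, 4) ints, columns A/C/G/T
    n_sequences: int

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (2 - Shannon entropy)."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def consensus(self, threshold: float = 0.5) -> str:
        """Degenerate IUPAC consensus: per position, the smallest base set
        (greedy by frequency) whose cumulative frequency reaches ``threshold``.
        """
        out = []
        for row in self.frequencies:
            order = np.argsort(row)[::-1]
            chosen, cum = set(), 0.0
            for b in order:
                chosen.add(BASES[b])
                cum += row[b]
                if cum >= threshold:
                    break
            out.append(_IUPAC[frozenset(chosen)])
        return "".join(out)

    def to_frame(self) -> pd.DataFrame:
        f = self.frequencies
        k = self.width // 2
        return pd.DataFrame(
            {
                "position": np.arange(-k, k + 1),
                **{b: f[:, i] for i, b in enumerate(BASES)},
            }
        )


def build_pwm(flanks: Sequence[str]) -> PWM:
    """Raw count/frequency PWM from equal-length sequences (no pseudocount)."""
    if not flanks:
        raise ValueError("cannot build a PWM from zero sequences")
    width = len(flanks[0])
    if any(len(f) != width for f in flanks):
        raise ValueError("flank length mismatch")
    arr = np.frombuffer("".join(flanks).encode("ascii"), dtype=np.uint8).reshape(
        len(flanks), width
    )
    counts = np.zeros((width, 4), dtype=np.int64)
    for i, b in enumerate(BASES):
        counts[:, i] = (arr == ord(b)).sum(axis=0)
    return PWM(counts=counts, n_sequences=len(flanks))
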