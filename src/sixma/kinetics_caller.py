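"""Call 6mA sites from per-adenine subread inter-pulse durations (IPDs).

Model: unmodified IPDs at a position are lognormal with log-mean ``mu0`` and
log-sd ``sigma0``; N6-methylation multiplies the median IPD. The aggregate
signal is the geometric-mean IPD ratio, exp(mean(log IPD) - mu0), and the
identification QV is a Phred score -10*log10(p) from a one-sided one-sample
t-test of the log-IPDs against mu0 (a simple, defensible surrogate for a
production caller's in-silico control model). A high-confidence site must
clear all three of: coverage >= 30, QV >= 20, IPD ratio >= 1.5 (boundaries
inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import (
    ChromosomeKinetics,
    GenomeSequence,
    MethylationSite,
    SubreadKinetics,
    revcomp,
)

logger = logging.getLogger(__name__)

#: p-values are floored here so QVs stay finite
P_FLOOR = 1e-300


@dataclass
class CallerThresholds:
    """High-confidence site filter (all boundaries inclusive)."""

    min_coverage: int = 30
    min_qv: float = 20.0
    min_ipd_ratio: float = 1.5
    #: optional dataset-level gate: kinetics tables whose mean coverage falls
    #: below this are skipped entirely (0 disables the gate)
    min_dataset_mean_coverage: float = 0.0

    def __post_init__(self) -> None:
        if (
            self.min_coverage < 0
            or self.min_qv < 0
            or self.min_ipd_ratio < 0
            or self.min_dataset_mean_coverage < 0
        ):
            raise ValueError("thresholds must be non-negative")

    def passes(self, coverage: int, qv: float, ipd_ratio: float) -> bool:
        return (
            coverage >= self.min_coverage
            and qv >= self.min_qv
            and ipd_ratio >= self.min_ipd_ratio
        )


def aggregate_ipd(
    k: SubreadKinetics, method: str = "geometric"
) -> Tuple[int, float, float]:
    """Aggregate one position's subread IPDs.

    Returns ``(coverage, mean_log_ipd, ipd_ratio)`` where the ratio is the
    geometric-mean IPD over the expected unmodified IPD, i.e.
    ``exp(mean(log ipds) - mu0)``. ``method="arithmetic"`` instead divides the
    arithmetic mean IPD by the baseline lognormal mean.
    """
    if k.coverage < 1:
        raise ValueError("cannot aggregate empty IPD list")
    logs = np.log(k.ipds)
    mean_log = float(logs.mean())
    if method == "geometric":
        ratio = math.exp(mean_log - k.mu0)
    elif method == "arithmetic":
        baseline_mean = math.exp(k.mu0 + 0.5 * k.sigma0**2)
        ratio = float(k.ipds.mean()) / baseline_mean
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return k.coverage, mean_log, ratio


def _qv_from_stats(
    mean_log: np.ndarray, var_log: np.ndarray, n: np.ndarray, mu0: float
) -> np.ndarray:
    """Vectorized one-sided one-sample t-test QV against the log baseline."""
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_log / n)
        t = (mean_log - mu0) / se
    # zero-variance samples: all observations identical; the shift direction
    # alone decides the tail
    zero = se == 0
    t = np.where(zero & (mean_log > mu0), np.inf, t)
    t = np.where(zero & (mean_log <= mu0), 0.0, t)
    p = stats.t.sf(t, df=n - 1)
    p = np.maximum(p, P_FLOOR)
    return -10.0 * np.log10(p)


def score_site(k: SubreadKinetics) -> float:
    """Identification QV for one position (Phred scale).

    One-sided (greater) one-sample t-test of log IPDs against ``mu0``;
    requires coverage >= 2 for a defined variance.
    """
    if k.coverage < 2:
        raise ValueError("identification QV needs coverage >= 2")
    logs = np.log(k.ipds)
    qv = _qv_from_stats(
        np.array([logs.mean()]),
        np.array([logs.var(ddof=1)]),
        np.array([k.coverage]),
        k.mu0,
    )
    return float(qv[0])


def estimate_fraction(mean_log_ipd: float, mu0: float, m: float) -> float:
    """Methylated-fraction estimate from the aggregate log-IPD shift.

    Linear interpolation between the unmodified baseline (shift 0 -> 0) and
    the fully modified level (shift ln(m) -> 1), clipped to [0, 1].
    """
    if m <= 1:
        raise ValueError("modification multiplier must exceed 1")
    return float(np.clip((mean_log_ipd - mu0) / math.log(m), 0.0, 1.0))


def _context9(genome: GenomeSequence, chrom: str, pos: int, strand: str, k: int = 4):
    seq = genome.sequences[chrom]
    if pos - k < 0 or pos + k + 1 > len(seq):
        return None
    window = seq[pos - k : pos + k + 1]
    return window if strand == "+" else revcomp(window)


def call_sites(
    kinetics: Iterable[ChromosomeKinetics],
    genome: GenomeSequence,
    thresholds: CallerThresholds | None = None,
    fraction_multiplier: float = 3.0,
) -> List[MethylationSite]:
    """Call high-confidence 6mA sites from per-position kinetics.

    Only positions that are adenines on the stated strand are considered
    (others are skipped with a logged count). The per-site fraction is
    estimated with :func:`estimate_fraction` using ``fraction_multiplier`` as
    the assumed fully-modified IPD multiplier.
    """
    thresholds = thresholds or CallerThresholds()
    if fraction_multiplier <= 1:
        raise ValueError("fraction_multiplier must exceed 1")
    sites: List[MethylationSite] = []
    n_skipped = 0
    for table in kinetics:
        if (
            thresholds.min_dataset_mean_coverage > 0
            and len(table)
            and table.coverage.mean() < thresholds.min_dataset_mean_coverage
        ):
            logger.warning(
                "skipping %s: mean coverage %.1f below dataset gate %.1f",
                table.chrom,
                table.coverage.mean(),
                thresholds.min_dataset_mean_coverage,
            )
            continue
        arr = genome.array(table.chrom)
        want = np.where(table.strand, ord("T"), ord("A"))
        on_adenine = arr[table.pos] == want
        n_skipped += int((~on_adenine).sum())

        logs = np.log(table.ipds, dtype=np.float64)
        n = table.coverage.astype(np.float64)
        sums = np.add.reduceat(logs, table.offsets[:-1])
        sums_sq = np.add.reduceat(logs**2, table.offsets[:-1])
        # positions with zero coverage contribute empty reduceat segments;
        # they can never pass the coverage filter, mask them out
        scorable = (table.coverage >= 2) & on_adenine
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_log = sums / n
            var_log = np.maximum(sums_sq - n * mean_log**2, 0.0) / (n - 1)
        qv = np.full(len(table), 0.0)
        qv[scorable] = _qv_from_stats(
            mean_log[scorable], var_log[scorable], n[scorable], table.mu0
        )
        ratio = np.exp(mean_log - table.mu0)
        keep = (
            scorable
            & (table.coverage >= thresholds.min_coverage)
            & (qv >= thresholds.min_qv)
            & (ratio >= thresholds.min_ipd_ratio)
        )
        log_m = math.log(fraction_multiplier)
        for i in np.flatnonzero(keep):
            strand = "-" if table.strand[i] else "+"
            pos = int(table.pos[i])
            sites.append(
                MethylationSite(
                    chrom=table.chrom,
                    pos0=pos,
                    strand=strand,
                    coverage=int(table.coverage[i]),
                    ipd_ratio=float(ratio[i]),
                    ident_qv=float(qv[i]),
                    fraction=float(
                        np.clip((mean_log[i] - table.mu0) / log_m, 0.0, 1.0)
                    ),
                    context9=_context9(genome, table.chrom, pos, strand),
                )
            )
    if n_skipped:
        logger.info("skipped %d kinetics positions not on strand-adenines", n_skipped)
    sites.sort(key=lambda s: (s.chrom, s.pos0, s.strand))
    return sites


def filter_sites(
    sites: Sequence[MethylationSite], thresholds: CallerThresholds | None = None
) -> List[MethylationSite]:
    """Apply the three-way inclusive high-confidence filter to parsed sites.

    Order preserved; idempotent.
    """
    thresholds = thresholds or CallerThresholds()
    return [
        s
        for s in sites
        if thresholds.passes(s.coverage, s.ident_qv, s.ipd_ratio)
    ]


def genome_density(
    sites: Sequence[MethylationSite], genome: GenomeSequence
) -> float:
    """Genome-wide 6mA/A density as a percentage.

    Denominator is the number of strand-adenines, i.e. #A + #T of the forward
    sequence.
    """
    total_a = genome.strand_adenine_count()
    if total_a == 0:
        raise ValueError("genome contains no adenines")
    return 100.0 * len(sites) / total_a
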