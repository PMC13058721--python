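"""Adenine-background enrichment statistics and methylation-level summaries.

The null model: 6mA occurs only on adenines, so a feature's expected site
count is its share of genomic adenines times the total number of sites,
expected_f = (A_f / A_total) * N. Enrichment is observed/expected and
significance comes from a two-sided Fisher's exact test on the 2x2 table of
(methylated, unmethylated adenines) x (in feature, elsewhere), with BH FDR
correction within each family of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import MethylationSite, GenomeSequence, SiteAnnotation

logger = logging.getLogger(__name__)


def expected_counts(
    adenine_counts: Dict[str, int], n_total_sites: int
) -> Dict[str, float]:
    """Expected per-feature site counts under the adenine-content null."""
    if n_total_sites < 0:
        raise ValueError("total site count must be non-negative")
    a_total = sum(adenine_counts.values())
    if a_total <= 0:
        raise ValueError("no adenines in the partition")
    return {
        f: (a_f / a_total) * n_total_sites for f, a_f in adenine_counts.items()
    }


def fisher_enrichment(observed_f: int, a_f: int, n: int, a_total: int) -> float:
    """Two-sided Fisher's exact p for one feature against the adenine null.

    The 2x2 table is [[observed_f, n - observed_f],
    [a_f - observed_f, (a_total - a_f) - (n - observed_f)]].
    """
    table = [
        [observed_f, n - observed_f],
        [a_f - observed_f, (a_total - a_f) - (n - observed_f)],
    ]
    if min(min(row) for row in table) < 0:
        raise ValueError(f"negative cell in contingency table {table}")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order restored to the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def significance_stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return "ns"


def enrichment_table(
    observed: Dict[str, int], adenine_counts: Dict[str, int]
) -> pd.DataFrame:
    """Observed/expected/ratio/p/q table for one family of classes.

    Classes absent from ``observed`` count as 0. A class with no adenines has
    expected 0 and an undefined (NaN) ratio; its Fisher test degenerates to
    p = 1.
    """
    n = sum(observed.values())
    a_total = sum(adenine_counts.values())
    exp = expected_counts(adenine_counts, n)
    rows = []
    for feature, a_f in adenine_counts.items():
        obs = observed.get(feature, 0)
        e = exp[feature]
        rows.append(
            {
                "feature": feature,
                "observed": obs,
                "adenines": a_f,
                "expected": e,
                "ratio": obs / e if e > 0 else float("nan"),
                "p": fisher_enrichment(obs, a_f, n, a_total),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["stars"] = df["q"].map(significance_stars)
    return df


@dataclass
class LevelCategories:
    """Methylated-fraction categories: low <= 0.3 < medium < 0.7 <= high."""

    low_max: float = 0.3
    high_min: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_max < self.high_min <= 1.0:
            raise ValueError("level category cuts must satisfy 0 <= low < high <= 1")

    def categorize(self, fraction: float) -> str:
        if fraction <= self.low_max:
            return "low"
        if fraction >= self.high_min:
            return "high"
        return "medium"

    @property
    def names(self) -> Tuple[str, str, str]:
        return ("low", "medium", "high")


def level_distribution(
    annotations: Sequence[SiteAnnotation],
    categories: Optional[LevelCategories] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-feature fraction summaries and per-category site counts.

    Sites with unknown fraction are excluded (logged count). Returns a
    (feature summary DataFrame, category count dict) pair.
    """
    categories = categories or LevelCategories()
    known = [a for a in annotations if a.site.fraction is not None]
    n_unknown = len(annotations) - len(known)
    if n_unknown:
        logger.info("excluded %d sites with unknown fraction", n_unknown)
    cat_counts = {name: 0 for name in categories.names}
    per_feature: Dict[str, List[float]] = {}
    for a in known:
        cat_counts[categories.categorize(a.site.fraction)] += 1
        per_feature.setdefault(a.feature, []).append(a.site.fraction)
    rows = []
    for feature, fracs in sorted(per_feature.items()):
        arr = np.asarray(fracs)
        rows.append(
            {
                "feature": feature,
                "n": arr.size,
                "q1": float(np.percentile(arr, 25)),
                "median": float(np.median(arr)),
                "q3": float(np.percentile(arr, 75)),
                "mean": float(arr.mean()),
            }
        )
    return pd.DataFrame(rows), cat_counts


def density_tracks(
    sites: Sequence[MethylationSite],
    genome: GenomeSequence,
    window_bp: int = 100_000,
    categories: Optional[LevelCategories] = None,
) -> pd.DataFrame:
    """Per-window, per-level-category site counts tiling each chromosome.

    The underlying table for a chromosome-level density plot; sites with
    unknown fraction are excluded.
    """
    if window_bp < 1000:
        raise ValueError("window_bp must be at least 1 kb")
    categories = categories or LevelCategories()
    rows = []
    by_chrom: Dict[str, List[MethylationSite]] = {}
    for s in sites:
        if s.fraction is not None:
            by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, length in genome.lengths.items():
        edges = np.arange(0, length + window_bp, window_bp)
        edges[-1] = max(edges[-1], length)
        n_windows = len(edges) - 1
        counts = {name: np.zeros(n_windows, dtype=int) for name in categories.names}
        for s in by_chrom.get(chrom, []):
            w = min(s.pos0 // window_bp, n_windows - 1)
            counts[categories.categorize(s.fraction)][w] += 1
        for w in range(n_windows):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(edges[w]),
                    "end": int(min(edges[w + 1], length)),
                    **{name: int(counts[name][w]) for name in categories.names},
                }
            )
    return pd.DataFrame(rows)
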