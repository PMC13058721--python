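"""Join per-gene 6mA occupancy with expression and test their association.

Occupancy per gene region (promoter, gene body, exon, intron) is reported
both as a density (sites/kb) and as the mean methylated fraction; quartile
grouping, Welch t-tests on log2(TPM+1), Pearson/Spearman correlations, a
length-normalized metagene profile, hyper/hypo-methylated x highly-expressed
gene classification and hypergeometric term enrichment sit on top.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_stats import bh_fdr
from .feature_annotation import (
    GENE_BODY_FEATURES,
    FeaturePartition,
    flank_intervals,
    gene_subregions,
)
from .types import (
    ExpressionRecord,
    GeneModel,
    GenomeSequence,
    Interval,
    SiteAnnotation,
)

logger = logging.getLogger(__name__)

REGIONS = ("promoter", "gene_body", "exon", "intron")

# partition feature classes contributing to each per-gene region
_REGION_FEATURES = {
    "promoter": {"promoter"},
    "gene_body": set(GENE_BODY_FEATURES),
    "exon": {"exon"},
    "intron": {"intron"},
}


def _interval_bp(ivs: Sequence[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def _interval_adenines(genome: GenomeSequence, chrom: str, ivs) -> int:
    arr = genome.array(chrom)
    total = 0
    for s, e in ivs:
        seg = arr[s:e]
        total += int(np.count_nonzero((seg == ord("A")) | (seg == ord("T"))))
    return total


def gene_region_metrics(
    annotations: Sequence[SiteAnnotation],
    partition: FeaturePartition,
    genes: Sequence[GeneModel],
    expression: Sequence[ExpressionRecord],
    genome: GenomeSequence,
) -> pd.DataFrame:
    """Per-gene, per-region 6mA occupancy metrics joined to TPM.

    Columns per region r: ``site_count_r``, ``length_r`` (bp),
    ``adenines_r``, ``density_r`` (sites/kb, NaN for zero-length regions) and
    ``mean_fraction_r`` (NaN when the region has no sites with a known
    fraction). Genes missing from the expression table get TPM 0 (logged).
    Adds ``log2_tpm`` and top/bottom-decile expression flags.
    """
    tpm = {r.gene_id: r.tpm for r in expression}
    n_missing = sum(1 for g in genes if g.gene_id not in tpm)
    if n_missing:
        logger.info("%d genes without expression records; TPM set to 0", n_missing)

    counts: Dict[str, Dict[str, int]] = {
        g.gene_id: {r: 0 for r in REGIONS} for g in genes
    }
    frac_sums: Dict[str, Dict[str, List[float]]] = {
        g.gene_id: {r: [] for r in REGIONS} for g in genes
    }
    for a in annotations:
        if a.gene_id is None or a.gene_id not in counts:
            continue
        for region, features in _REGION_FEATURES.items():
            if a.feature in features:
                counts[a.gene_id][region] += 1
                if a.site.fraction is not None:
                    frac_sums[a.gene_id][region].append(a.site.fraction)

    rows = []
    for g in genes:
        regions = gene_subregions(g)
        chrom_len = len(genome.sequences[g.chrom])
        flanks = flank_intervals(g, partition.config, chrom_len)
        start, end = g.span
        region_ivs = {
            "promoter": flanks["promoter"],
            "gene_body": [(start, end)],
            "exon": regions["exon"],
            "intron": regions["intron"],
        }
        row: Dict[str, object] = {"gene_id": g.gene_id, "biotype": g.biotype}
        for region in REGIONS:
            ivs = region_ivs[region]
            length = _interval_bp(ivs)
            n_sites = counts[g.gene_id][region]
            fracs = frac_sums[g.gene_id][region]
            row[f"site_count_{region}"] = n_sites
            row[f"length_{region}"] = length
            row[f"adenines_{region}"] = _interval_adenines(genome, g.chrom, ivs)
            row[f"density_{region}"] = (
                1000.0 * n_sites / length if length > 0 else float("nan")
            )
            row[f"mean_fraction_{region}"] = (
                float(np.mean(fracs)) if fracs else float("nan")
            )
        row["tpm"] = tpm.get(g.gene_id, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["log2_tpm"] = np.log2(df["tpm"] + 1.0)
    hi_cut = df["tpm"].quantile(0.9)
    lo_cut = df["tpm"].quantile(0.1)
    df["top10_expression"] = df["tpm"] > hi_cut
    df["bottom10_expression"] = df["tpm"] < lo_cut
    return df


def quartile_bins(
    profiles: pd.DataFrame, region: str, metric: str = "density"
) -> pd.Series:
    """Q1-Q4 labels (lowest to highest) of a per-gene occupancy metric.

    Cuts fall at the 25/50/75 percentiles of the metric among genes with a
    defined value; ties go to the lower quartile. Returns a Series indexed by
    gene_id; genes with an undefined metric are excluded.
    """
    col = f"{metric}_{region}"
    values = profiles.set_index("gene_id")[col].dropna()
    if len(values) < 4:
        raise ValueError(f"quartile binning needs >= 4 genes with defined {col}")
    cuts = np.percentile(values.to_numpy(), [25, 50, 75])
    if cuts[0] == cuts[2]:
        logger.warning("metric %s is (nearly) constant; most genes fall in Q1", col)
    ranks = sum((values.to_numpy() > c).astype(int) for c in cuts)
    return pd.Series(
        [f"Q{r + 1}" for r in ranks], index=values.index, name="quartile"
    )


@dataclass
class WelchResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


def welch_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Welch two-sample t-test returning (t, df, p).

    Degenerate identical samples (both variances zero, equal means) return
    t=0, p=1 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return math.inf if x.mean() > y.mean() else -math.inf, float(
            x.size + y.size - 2
        ), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_expression(
    profiles: pd.DataFrame,
    grouping: Mapping[str, str],
    value: str = "log2_tpm",
) -> List[WelchResult]:
    """Welch t-tests of ``value`` between every pair of groups.

    ``grouping`` maps gene_id to a group label (e.g. the output of
    :func:`quartile_bins`); groups with fewer than 2 genes raise.
    """
    indexed = profiles.set_index("gene_id")
    groups: Dict[str, np.ndarray] = {}
    for label in sorted(set(grouping.values())):
        members = [gid for gid, lab in grouping.items() if lab == label]
        vals = indexed.loc[members, value].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 usable genes")
        groups[label] = vals
    labels = sorted(groups)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t, dof, p = welch_test(groups[a], groups[b])
            out.append(
                WelchResult(
                    group_a=a,
                    group_b=b,
                    n_a=groups[a].size,
                    n_b=groups[b].size,
                    mean_a=float(groups[a].mean()),
                    mean_b=float(groups[b].mean()),
                    t=t,
                    df=dof,
                    p=p,
                )
            )
    return out


@dataclass
class CorrelationResult:
    region: str
    metric: str
    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def occupancy_expression_correlation(
    profiles: pd.DataFrame, region: str, metric: str = "density"
) -> CorrelationResult:
    """Pearson (primary) and Spearman correlation of occupancy vs log2(TPM+1)."""
    col = f"{metric}_{region}"
    df = profiles[[col, "log2_tpm"]].dropna()
    if len(df) < 10:
        raise ValueError("correlation needs >= 10 genes with defined metric")
    x = df[col].to_numpy()
    y = df["log2_tpm"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero variance in %s or expression; correlation undefined", col)
        return CorrelationResult(
            region, metric, len(df), float("nan"), float("nan"), float("nan"),
            float("nan"),
        )
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return CorrelationResult(
        region, metric, len(df), float(pr), float(pp), float(sr), float(sp)
    )


@dataclass
class MetageneProfile:
    """Site frequencies over upstream flank + normalized body + downstream."""

    n_bins_flank: int
    n_bins_body: int
    flank_bp: int
    counts: np.ndarray
    n_genes: int
    n_sites: int

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)

    @property
    def bin_labels(self) -> List[str]:
        return (
            [f"up{i + 1}" for i in range(self.n_bins_flank)]
            + [f"body{i + 1}" for i in range(self.n_bins_body)]
            + [f"down{i + 1}" for i in range(self.n_bins_flank)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_labels,
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )


def metagene_profile(
    annotations: Sequence[SiteAnnotation],
    genes: Sequence[GeneModel],
    n_bins_body: int = 20,
    n_bins_flank: int = 10,
    flank_bp: int = 1000,
) -> MetageneProfile:
    """Aggregate site positions over a normalized gene model.

    Each gene contributes a fixed-width upstream flank, a length-normalized
    body split into ``n_bins_body`` bins and a fixed-width downstream flank,
    all oriented by strand. Genes with body length < ``n_bins_body`` are
    skipped. The returned frequency profile sums to 1 (when any site binned).
    """
    pos_by_chrom: Dict[str, np.ndarray] = {}
    for chrom in {a.site.chrom for a in annotations}:
        pos_by_chrom[chrom] = np.sort(
            np.array([a.site.pos0 for a in annotations if a.site.chrom == chrom])
        )
    total_bins = 2 * n_bins_flank + n_bins_body
    counts = np.zeros(total_bins, dtype=np.int64)
    n_genes_used = 0
    for g in genes:
        if g.body_length < n_bins_body:
            continue
        n_genes_used += 1
        start, end = g.span
        positions = pos_by_chrom.get(g.chrom)
        if positions is None:
            continue
        lo = np.searchsorted(positions, start - flank_bp)
        hi = np.searchsorted(positions, end + flank_bp)
        for pos in positions[lo:hi]:
            # oriented distance from the 5' end of the window
            if g.strand == "+":
                rel = pos - start
            else:
                rel = (end - 1) - pos
            if rel < 0:  # upstream flank
                b = int((rel + flank_bp) * n_bins_flank // flank_bp)
                if b < 0:
                    continue
            elif rel >= g.body_length:  # downstream flank
                d = rel - g.body_length
                if d >= flank_bp:
                    continue
                b = n_bins_flank + n_bins_body + int(d * n_bins_flank // flank_bp)
            else:
                b = n_bins_flank + int(rel * n_bins_body // g.body_length)
            counts[b] += 1
    return MetageneProfile(
        n_bins_flank=n_bins_flank,
        n_bins_body=n_bins_body,
        flank_bp=flank_bp,
        counts=counts,
        n_genes=n_genes_used,
        n_sites=int(counts.sum()),
    )


@dataclass
class ClassifierConfig:
    """Hyper/hypo-methylated x highly-expressed classification settings."""

    top_quantile: float = 0.10
    bottom_quantile: float = 0.10
    expression_gate: str = "mean"  # or "median"
    body_level_metric: str = "mean_fraction"  # or "density"

    def __post_init__(self) -> None:
        for q in (self.top_quantile, self.bottom_quantile):
            if not 0.0 < q < 0.5:
                raise ValueError("quantiles must lie in (0, 0.5)")
        if self.expression_gate not in ("mean", "median"):
            raise ValueError("expression_gate must be 'mean' or 'median'")
        if self.body_level_metric not in ("mean_fraction", "density"):
            raise ValueError("body_level_metric must be 'mean_fraction' or 'density'")


def classify_genes(
    profiles: pd.DataFrame, config: Optional[ClassifierConfig] = None
) -> Dict[str, Set[str]]:
    """Hypermethylated-highly-expressed and hypomethylated-highly-expressed sets.

    The expression gate (TPM above the mean over all genes) is applied first;
    the top/bottom deciles of the gene-body methylation level are computed
    among all genes with a defined metric. Each set is the intersection of
    the gate and the respective decile; the two sets are disjoint.
    """
    config = config or ClassifierConfig()
    col = f"{config.body_level_metric}_gene_body"
    gate_stat = (
        profiles["tpm"].mean()
        if config.expression_gate == "mean"
        else profiles["tpm"].median()
    )
    gated = set(profiles.loc[profiles["tpm"] > gate_stat, "gene_id"])
    defined = profiles[["gene_id", col]].dropna()
    n_excluded = len(profiles) - len(defined)
    if n_excluded:
        logger.info("%d genes without defined %s excluded from deciles", n_excluded, col)
    if defined.empty:
        return {"hyper_high": set(), "hypo_high": set()}
    values = defined[col].to_numpy()
    hi_cut = np.quantile(values, 1.0 - config.top_quantile)
    lo_cut = np.quantile(values, config.bottom_quantile)
    top = set(defined.loc[defined[col] >= hi_cut, "gene_id"])
    bottom = set(defined.loc[defined[col] <= lo_cut, "gene_id"])
    overlap = top & bottom
    if overlap:
        logger.warning(
            "%d genes fall in both deciles (degenerate metric); dropped", len(overlap)
        )
        top -= overlap
        bottom -= overlap
    return {"hyper_high": top & gated, "hypo_high": bottom & gated}


def term_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH correction.

    For each term with K background genes annotated, p = P(X >= k) where X is
    hypergeometric(N, K, n) — N background genes, n set genes, k of them
    carrying the term. Terms with K = 0 are skipped; ``significant`` flags
    q < 0.05.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    n_bg = len(background)
    n_set = len(gene_set)
    term_genes: Dict[str, Set[str]] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term, members in sorted(term_genes.items()):
        big_k = len(members)
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_set))
        rows.append(
            {"term": term, "k": k, "n": n_set, "K": big_k, "N": n_bg, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] < 0.05
    else:
        df["q"] = []
        df["significant"] = []
    return df
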