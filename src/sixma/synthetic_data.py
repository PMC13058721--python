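"""Synthetic genomes with planted 6mA truth, subread kinetics and expression.

The generator emulates the data a 6mA profiling study consumes: an annotated
multi-gene genome (exon/intron/UTR structure with introns ~15x longer than
exons, TE intervals), planted methylation sites with controlled per-feature
composition and per-site methylated fraction, per-adenine lognormal subread
IPD observations, and TPM values coupled positively to gene-body 6mA and
negatively to promoter 6mA. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .feature_annotation import (
    FeaturePartition,
    PartitionConfig,
    build_partition,
    GENE_BODY_FEATURES,
)
from .types import (
    ChromosomeKinetics,
    ExpressionRecord,
    FEATURES_BY_PRECEDENCE,
    FEATURE_CODE,
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

# stage tags mixed into the seed sequence so each generator draws an
# independent, reproducible stream
_STAGE_GENOME = 1
_STAGE_ANNOTATION = 2
_STAGE_PLANT = 3
_STAGE_KINETICS = 4
_STAGE_EXPRESSION = 5
_STAGE_TERMS = 6

# TE length ranges (bp) used when placing repeat intervals
_TE_LENGTHS = {
    "LINE": (800, 5000),
    "SINE": (100, 350),
    "LTR": (300, 3000),
    "SimpleRepeat": (50, 400),
    "Other": (100, 1000),
}


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-condition defaults.

    The planted density default (0.13% of strand-adenines) and the default
    feature composition (42% intronic, gene bodies holding about half of all
    sites) mirror the genome-wide summary a limpet-scale 6mA profile shows;
    the kinetic defaults (lognormal log-sd 0.6, modified-median multiplier 3,
    coverage ~= 40-50x) are stand-ins chosen to give a realistically strong
    but not saturating single-site signal, and are fully configurable.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len_bp: int = 400_000
    gc: float = 0.4
    n_genes: int = 30
    exon_count_mean: float = 4.0
    exon_len_mean: float = 150.0
    intron_exon_ratio: float = 15.0
    noncoding_fraction: float = 0.1
    mean_gap_bp: float = 3000.0
    te_fraction: Dict[str, float] = field(
        default_factory=lambda: {
            "LINE": 0.06,
            "SINE": 0.03,
            "LTR": 0.02,
            "SimpleRepeat": 0.01,
            "Other": 0.01,
        }
    )
    planted_density: float = 0.0013
    feature_composition: Optional[Dict[str, float]] = field(
        default_factory=lambda: {
            "promoter": 0.05,
            "5'UTR": 0.01,
            "exon": 0.06,
            "intron": 0.42,
            "3'UTR": 0.01,
            "downstream": 0.02,
            "intergenic": 0.43,
        }
    )
    fraction_distribution: Tuple = ("beta", 4.0, 4.0)
    coverage_mean: float = 50.0
    coverage_model: str = "poisson"  # or "fixed"
    ipd_baseline_logmean: float = 0.0
    ipd_baseline_logsd: float = 0.6
    ipd_modified_multiplier: float = 3.0
    beta_body: float = 1.0
    beta_promoter: float = -1.0
    expression_alpha: float = 3.0
    expression_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.planted_density <= 0.05:
            raise ValueError("planted_density must lie in (0, 0.05]")
        if self.feature_composition is not None:
            bad = set(self.feature_composition) - set(FEATURES_BY_PRECEDENCE)
            if bad:
                raise ValueError(f"unknown feature classes: {sorted(bad)}")
            total = sum(self.feature_composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("feature_composition must sum to 1")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        if self.coverage_model not in ("poisson", "fixed"):
            raise ValueError("coverage_model must be 'poisson' or 'fixed'")

    def draw_fractions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind = self.fraction_distribution[0]
        if kind == "beta":
            _, a, b = self.fraction_distribution
            return rng.beta(a, b, size=n)
        if kind == "fixed":
            return np.full(n, float(self.fraction_distribution[1]))
        if kind == "uniform":
            return rng.uniform(0.0, 1.0, size=n)
        raise ValueError(f"unknown fraction distribution {kind!r}")


def largest_remainder(n: int, proportions: Dict[str, float]) -> Dict[str, int]:
    """Integer apportionment of ``n`` by largest-remainder rounding.

    Ties in the fractional parts are broken by key order, making the result
    deterministic. Counts sum to exactly ``n``.
    """
    keys = list(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), keys.index(k)))
    for k in order[:short]:
        counts[k] += 1
    return counts


def simulate_genome(config: SimulationConfig) -> GenomeSequence:
    """i.i.d. random genome at the configured GC content."""
    if config.chrom_len_bp < 1000:
        raise ValueError("chromosome length must be at least 1 kb")
    rng = _rng(config.seed, _STAGE_GENOME)
    at = (1.0 - config.gc) / 2.0
    gcp = config.gc / 2.0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for i in range(config.n_chrom):
        draw = rng.choice(bases, size=config.chrom_len_bp, p=[at, gcp, gcp, at])
        sequences[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return GenomeSequence(sequences)


def _gene_structure(
    rng: np.random.Generator, config: SimulationConfig
) -> Tuple[List[int], List[int]]:
    """Draw exon and intron lengths for one gene (lognormal, mean-matched)."""
    n_exons = 1 + rng.poisson(max(config.exon_count_mean - 1.0, 0.0))
    sigma = 0.5  # moderate spread of segment lengths

    def draw(n: int, mean: float) -> List[int]:
        mu = math.log(mean) - 0.5 * sigma**2
        return [max(10, int(round(x))) for x in rng.lognormal(mu, sigma, size=n)]

    exon_lens = draw(n_exons, config.exon_len_mean)
    intron_lens = draw(
        n_exons - 1, config.exon_len_mean * config.intron_exon_ratio
    )
    return exon_lens, intron_lens


def _lay_out_gene(
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    exon_lens: List[int],
    intron_lens: List[int],
    coding: bool,
    rng: np.random.Generator,
) -> GeneModel:
    exons: List[Interval] = []
    cursor = start
    for i, el in enumerate(exon_lens):
        exons.append((cursor, cursor + el))
        cursor += el
        if i < len(intron_lens):
            cursor += intron_lens[i]
    end = cursor
    utr5: List[Interval] = []
    utr3: List[Interval] = []
    cds: List[Interval] = []
    exonic_bp = sum(e - s for s, e in exons)
    if coding:
        max_utr = max(exonic_bp // 4, 1)
        u5 = int(rng.integers(0, min(max_utr, 150) + 1))
        u3 = int(rng.integers(0, min(max_utr, 200) + 1))
        if u5 + u3 >= exonic_bp:
            u5 = u3 = 0

        def take(n_bases: int, from_left: bool) -> List[Interval]:
            taken: List[Interval] = []
            remaining = n_bases
            seq = exons if from_left else exons[::-1]
            for s, e in seq:
                if remaining <= 0:
                    break
                grab = min(remaining, e - s)
                taken.append((s, s + grab) if from_left else (e - grab, e))
                remaining -= grab
            return merge_intervals(taken)

        left, right = (u5, u3) if strand == "+" else (u3, u5)
        left_ivs = take(left, from_left=True)
        right_ivs = take(right, from_left=False)
        utr5, utr3 = (
            (left_ivs, right_ivs) if strand == "+" else (right_ivs, left_ivs)
        )
        cds = subtract_intervals(exons, left_ivs + right_ivs)
    tss, tes = (start, end) if strand == "+" else (end - 1, start - 1)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        tes=tes,
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )


def simulate_annotation(
    genome: GenomeSequence, config: SimulationConfig
) -> Tuple[List[GeneModel], List[RepeatInterval]]:
    """Place non-overlapping genes (with 2 kb-capable flank gaps) and TEs.

    Genes are distributed across chromosomes proportionally to length; TE
    intervals are placed in intergenic and intronic space at the configured
    per-class genome fractions.
    """
    rng = _rng(config.seed, _STAGE_ANNOTATION)
    margin = 2300  # room for a 2 kb promoter plus downstream window
    lengths = genome.lengths
    total_bp = sum(lengths.values())
    share = largest_remainder(
        config.n_genes, {c: lengths[c] / total_bp for c in lengths}
    )
    genes: List[GeneModel] = []
    width = max(4, len(str(config.n_genes)))
    gi = 0
    for chrom, n_here in share.items():
        cursor = margin
        for _ in range(n_here):
            exon_lens, intron_lens = _gene_structure(rng, config)
            span = sum(exon_lens) + sum(intron_lens)
            # neighbours each need their own 2 kb flank -> 2x margin between spans
            gap = 2 * margin + int(rng.exponential(config.mean_gap_bp))
            if cursor + span + margin > lengths[chrom]:
                raise ValueError(
                    f"n_genes={config.n_genes} does not fit on the genome "
                    f"(ran out of space on {chrom})"
                )
            gi += 1
            genes.append(
                _lay_out_gene(
                    gene_id=f"g{gi:0{width}d}",
                    chrom=chrom,
                    start=cursor,
                    strand="+" if rng.random() < 0.5 else "-",
                    exon_lens=exon_lens,
                    intron_lens=intron_lens,
                    coding=rng.random() >= config.noncoding_fraction,
                    rng=rng,
                )
            )
            cursor = genes[-1].span[1] + gap
    repeats = _place_repeats(genome, genes, config, rng)
    return genes, repeats


def _place_repeats(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> List[RepeatInterval]:
    if not any(config.te_fraction.values()):
        return []
    flank = 2300
    allowed: Dict[str, List[Interval]] = {}
    for chrom, n in genome.lengths.items():
        blocked: List[Interval] = []
        for g in genes:
            if g.chrom != chrom:
                continue
            s, e = g.span
            blocked.append((max(0, s - flank), min(n, e + flank)))
            # re-open intronic space inside the gene
        intergenic = subtract_intervals([(0, n)], blocked)
        introns: List[Interval] = []
        for g in genes:
            if g.chrom == chrom:
                introns.extend(subtract_intervals([g.span], g.exons))
        allowed[chrom] = merge_intervals(intergenic + introns)
    repeats: List[RepeatInterval] = []
    total_bp = len(genome)
    for te_class in TE_CLASSES:
        target = int(config.te_fraction.get(te_class, 0.0) * total_bp)
        if target <= 0:
            continue
        lo, hi = _TE_LENGTHS[te_class]
        placed = 0
        attempts = 0
        while placed < target and attempts < 20 * config.n_genes + 2000:
            attempts += 1
            chrom = str(rng.choice(list(allowed)))
            slots = allowed[chrom]
            if not slots:
                continue
            weights = np.array([e - s for s, e in slots], dtype=float)
            slot_i = int(rng.choice(len(slots), p=weights / weights.sum()))
            s, e = slots[slot_i]
            te_len = int(rng.integers(lo, hi + 1))
            if e - s < te_len:
                continue
            start = int(rng.integers(s, e - te_len + 1))
            repeats.append(RepeatInterval(chrom, start, start + te_len, te_class))
            # split the slot so repeats never overlap
            slots.pop(slot_i)
            if start - s > 0:
                slots.append((s, start))
            if e - (start + te_len) > 0:
                slots.append((start + te_len, e))
            placed += te_len
    repeats.sort(key=lambda r: (r.chrom, r.start))
    return repeats


def _adenine_candidates(
    genome: GenomeSequence, partition: FeaturePartition
) -> pd.DataFrame:
    """All strand-adenine positions with their feature code."""
    frames = []
    for chrom in genome.chroms:
        arr = genome.array(chrom)
        lab = partition.labels[chrom]
        for base, strand in ((ord("A"), "+"), (ord("T"), "-")):
            pos = np.flatnonzero(arr == base)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos0": pos,
                        "strand": strand,
                        "feature": lab[pos],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def plant_6mA(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatInterval],
    config: SimulationConfig,
    n_sites: Optional[int] = None,
    partition: Optional[FeaturePartition] = None,
) -> List[TruthSite]:
    """Plant 6mA truth sites on adenines with exact per-class composition.

    Total count is ``round(planted_density * strand_adenines)`` unless
    ``n_sites`` is given; class counts follow the configured composition by
    largest-remainder rounding and positions are sampled uniformly without
    replacement among the class's adenines. With
    ``config.feature_composition=None`` sites are planted uniformly over all
    adenines.
    """
    rng = _rng(config.seed, _STAGE_PLANT)
    partition = partition or build_partition(genome, genes, PartitionConfig())
    cand = _adenine_candidates(genome, partition)
    total_a = len(cand)
    if total_a == 0:
        raise ValueError("genome contains no adenines; nothing to plant on")
    n_total = int(n_sites) if n_sites is not None else int(round(config.planted_density * total_a))
    if config.feature_composition is None:
        chosen_idx = rng.choice(total_a, size=n_total, replace=False)
    else:
        counts = largest_remainder(n_total, config.feature_composition)
        chosen: List[np.ndarray] = []
        for feature, k in counts.items():
            if k == 0:
                continue
            pool = cand.index[cand["feature"] == FEATURE_CODE[feature]].to_numpy()
            if pool.size < k:
                raise ValueError(
                    f"feature class {feature!r} has only {pool.size} adenines, "
                    f"cannot plant {k} sites"
                )
            chosen.append(rng.choice(pool, size=k, replace=False))
        chosen_idx = np.concatenate(chosen) if chosen else np.array([], dtype=int)
    picked = cand.loc[chosen_idx]
    fractions = config.draw_fractions(rng, len(picked))
    trees: Dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.te_class)
    truth: List[TruthSite] = []
    for (row, frac) in zip(picked.itertuples(), fractions):
        tree = trees.get(row.chrom)
        hits = tree[row.pos0] if tree is not None else set()
        te_label = None
        if hits:
            te_label = min(
                hits,
                key=lambda iv: (iv.end - iv.begin, TE_CLASSES.index(iv.data)),
            ).data
        truth.append(
            TruthSite(
                chrom=row.chrom,
                pos0=int(row.pos0),
                strand=row.strand,
                true_fraction=float(frac),
                feature_label=FEATURES_BY_PRECEDENCE[row.feature],
                te_label=te_label,
            )
        )
    truth.sort(key=lambda t: (t.chrom, t.pos0, t.strand))
    return truth


def simulate_kinetics(
    genome: GenomeSequence,
    truth: Sequence[TruthSite],
    config: SimulationConfig,
) -> List[ChromosomeKinetics]:
    """Lognormal subread IPDs for every strand-adenine of the genome.

    At a truth site with methylated fraction f each subread is modified with
    probability f; a modified subread's log-IPD is shifted by ln(m) where m
    is the configured modified-median multiplier (m > 1 required).
    """
    m = config.ipd_modified_multiplier
    if m <= 1:
        raise ValueError("ipd_modified_multiplier must exceed 1")
    rng = _rng(config.seed, _STAGE_KINETICS)
    mu0 = config.ipd_baseline_logmean
    sigma0 = config.ipd_baseline_logsd
    truth_by_chrom: Dict[str, List[TruthSite]] = {}
    for t in truth:
        truth_by_chrom.setdefault(t.chrom, []).append(t)
    tables: List[ChromosomeKinetics] = []
    for chrom in genome.chroms:
        arr = genome.array(chrom)
        pos_plus = np.flatnonzero(arr == ord("A"))
        pos_minus = np.flatnonzero(arr == ord("T"))
        pos = np.concatenate([pos_plus, pos_minus])
        strand = np.concatenate(
            [np.zeros(pos_plus.size, bool), np.ones(pos_minus.size, bool)]
        )
        n_pos = pos.size
        if config.coverage_model == "fixed":
            coverage = np.full(n_pos, int(round(config.coverage_mean)), np.int64)
        else:
            coverage = np.maximum(rng.poisson(config.coverage_mean, n_pos), 1)
        offsets = np.concatenate([[0], np.cumsum(coverage)])
        logs = rng.normal(mu0, sigma0, size=int(offsets[-1]))
        log_m = math.log(m)
        for t in truth_by_chrom.get(chrom, []):
            block = pos_minus if t.strand == "-" else pos_plus
            base_off = pos_plus.size if t.strand == "-" else 0
            j = int(np.searchsorted(block, t.pos0))
            if j >= block.size or block[j] != t.pos0:
                raise ValueError(
                    f"truth site {t.chrom}:{t.pos0}({t.strand}) is not on an "
                    "adenine of the generated genome"
                )
            i = base_off + j
            lo, hi = offsets[i], offsets[i + 1]
            modified = rng.random(hi - lo) < t.true_fraction
            logs[lo:hi] += log_m * modified
        tables.append(
            ChromosomeKinetics(
                chrom=chrom,
                pos=pos,
                strand=strand,
                coverage=coverage,
                ipds=np.exp(logs).astype(np.float32),
                mu0=mu0,
                sigma0=sigma0,
            )
        )
    return tables


def truth_gene_occupancy(
    truth: Sequence[TruthSite],
    genes: Sequence[GeneModel],
    partition: FeaturePartition,
    promoter_bp: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene planted gene-body and promoter densities (sites per kb)."""
    promoter_bp = promoter_bp or partition.config.promoter_bp
    body = set(GENE_BODY_FEATURES)
    body_counts: Dict[str, int] = {g.gene_id: 0 for g in genes}
    prom_counts: Dict[str, int] = {g.gene_id: 0 for g in genes}
    for t in truth:
        gid = partition.gene_of(t.chrom, t.pos0)
        if gid is None or gid not in body_counts:
            continue
        feature = partition.feature_of(t.chrom, t.pos0)
        if feature in body:
            body_counts[gid] += 1
        elif feature == "promoter":
            prom_counts[gid] += 1
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "body_density": 1000.0 * body_counts[g.gene_id] / g.body_length,
                "promoter_density": 1000.0 * prom_counts[g.gene_id] / promoter_bp,
            }
        )
    return pd.DataFrame(rows)


def simulate_expression(
    gene_profiles: pd.DataFrame, config: SimulationConfig
) -> List[ExpressionRecord]:
    """TPM values coupled to planted per-gene methylation densities.

    log2(TPM + 1) = alpha + beta_body * z(body_density)
    + beta_promoter * z(promoter_density) + Normal(0, sd); TPM floored at 0.
    ``gene_profiles`` needs columns gene_id, body_density, promoter_density.
    """
    rng = _rng(config.seed, _STAGE_EXPRESSION)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    body = z(gene_profiles["body_density"].to_numpy(float))
    prom = z(gene_profiles["promoter_density"].to_numpy(float))
    noise = rng.normal(0.0, config.expression_noise_sd, size=len(gene_profiles))
    log2_tpm = (
        config.expression_alpha
        + config.beta_body * body
        + config.beta_promoter * prom
        + noise
    )
    tpm = np.maximum(np.exp2(log2_tpm) - 1.0, 0.0)
    return [
        ExpressionRecord(gene_id=str(gid), tpm=float(t))
        for gid, t in zip(gene_profiles["gene_id"], tpm)
    ]


def simulate_term_map(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    n_terms: int = 40,
    mean_terms_per_gene: float = 2.0,
) -> Dict[str, List[str]]:
    """Random gene -> term annotation for exercising term enrichment."""
    rng = _rng(config.seed, _STAGE_TERMS)
    terms = [f"TERM:{i:04d}" for i in range(n_terms)]
    mapping: Dict[str, List[str]] = {}
    for g in genes:
        k = min(rng.poisson(mean_terms_per_gene), n_terms)
        mapping[g.gene_id] = sorted(
            rng.choice(terms, size=k, replace=False).tolist()
        )
    return mapping


def sites_from_truth(
    truth: Sequence[TruthSite],
    genome: GenomeSequence,
    coverage: int = 40,
    ident_qv: float = 40.0,
    ipd_ratio: float = 3.0,
) -> List[MethylationSite]:
    """Promote truth sites to called-site records, bypassing the caller.

    Useful for testing downstream stages in isolation; the kinetic fields are
    filled with values that pass the default high-confidence filter and the
    fraction is the true planted fraction.
    """
    sites = []
    for t in truth:
        sites.append(
            MethylationSite(
                chrom=t.chrom,
                pos0=t.pos0,
                strand=t.strand,
                coverage=coverage,
                ipd_ratio=ipd_ratio,
                ident_qv=ident_qv,
                fraction=t.true_fraction,
            )
        )
    return sites
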