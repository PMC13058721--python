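"""Gene metrics, quartiles, group tests, correlations, metagene, terms."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sixma.expression_integration import (
    ClassifierConfig,
    classify_genes,
    compare_expression,
    gene_region_metrics,
    metagene_profile,
    occupancy_expression_correlation,
    quartile_bins,
    term_enrichment,
    welch_test,
)
from sixma.feature_annotation import assign_sites, build_partition
from sixma.synthetic_data import sites_from_truth
from sixma.types import (
    ExpressionRecord,
    GeneModel,
    GenomeSequence,
    MethylationSite,
    SiteAnnotation,
)


def _simple_gene(gene_id="gA", start=2000, body=1000, chrom="c1", strand="+"):
    end = start + body
    tss, tes = (start, end) if strand == "+" else (end - 1, start - 1)
    return GeneModel(gene_id, chrom, strand, tss, tes, exons=[(start, end)])


def _site(pos, chrom="c1", strand="+", fraction=0.5):
    return MethylationSite(chrom, pos, strand, 40, 2.0, 30.0, fraction=fraction)


@pytest.fixture()
def simple_setup():
    genome = GenomeSequence({"c1": "ACGT" * 2500})
    gene = _simple_gene()
    partition = build_partition(genome, [gene])
    return genome, gene, partition


def test_gene_region_metrics_density(simple_setup):
    genome, gene, partition = simple_setup
    annotations = assign_sites([_site(2100), _site(2900)], partition)
    df = gene_region_metrics(
        annotations, partition, [gene], [ExpressionRecord("gA", 5.0)], genome
    )
    row = df.iloc[0]
    assert row["site_count_gene_body"] == 2
    assert row["density_gene_body"] == pytest.approx(2.0)  # 2 sites / 1 kb
    assert row["tpm"] == 5.0


def test_gene_region_metrics_empty_gene(simple_setup):
    genome, gene, partition = simple_setup
    df = gene_region_metrics([], partition, [gene], [], genome)
    row = df.iloc[0]
    assert row["site_count_gene_body"] == 0
    assert math.isnan(row["mean_fraction_gene_body"])
    assert row["tpm"] == 0.0  # missing expression defaults to zero


def test_gene_region_metrics_recovers_planted_counts(small_study):
    """Per-gene body counts equal the planted truth table exactly."""
    genome = small_study["genome"]
    partition = small_study["partition"]
    genes = small_study["genes"]
    truth = small_study["truth"]
    sites = sites_from_truth(truth, genome)
    annotations = assign_sites(sites, partition)
    df = gene_region_metrics(annotations, partition, genes, [], genome)
    body_features = {"5'UTR", "exon", "intron", "3'UTR"}
    expected = {g.gene_id: 0 for g in genes}
    for t in truth:
        if t.feature_label in body_features:
            gid = partition.gene_of(t.chrom, t.pos0)
            if gid in expected:
                expected[gid] += 1
    got = dict(zip(df["gene_id"], df["site_count_gene_body"]))
    assert got == expected


# ---------------------------------------------------------------------------
# quartiles
# ---------------------------------------------------------------------------


def _profiles_with_density(values):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(values))],
            "density_gene_body": values,
            "log2_tpm": np.zeros(len(values)),
            "tpm": np.zeros(len(values)),
        }
    )


def test_quartiles_of_eight_distinct_values():
    labels = quartile_bins(_profiles_with_density([1, 2, 3, 4, 5, 6, 7, 8]), "gene_body")
    grouped = {q: sorted(labels[labels == q].index) for q in set(labels)}
    assert grouped == {
        "Q1": ["g0", "g1"], "Q2": ["g2", "g3"],
        "Q3": ["g4", "g5"], "Q4": ["g6", "g7"],
    }


def test_quartiles_degenerate_all_equal():
    labels = quartile_bins(_profiles_with_density([2.0] * 8), "gene_body")
    assert set(labels) == {"Q1"}


def test_quartiles_balanced_sizes_without_ties():
    rng = np.random.default_rng(0)
    labels = quartile_bins(_profiles_with_density(rng.normal(size=101)), "gene_body")
    sizes = labels.value_counts()
    assert sizes.max() - sizes.min() <= 1


def test_quartiles_need_four_genes():
    with pytest.raises(ValueError):
        quartile_bins(_profiles_with_density([1, 2, 3]), "gene_body")


# ---------------------------------------------------------------------------
# Welch tests
# ---------------------------------------------------------------------------


def test_welch_identical_groups():
    t, _, p = welch_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert (t, p) == (0.0, 1.0)


def test_welch_large_shift_significant():
    rng = np.random.default_rng(1)
    t, _, p = welch_test(rng.normal(0, 1, 50), rng.normal(3, 1, 50))
    assert p < 0.001


def test_welch_small_group_errors():
    with pytest.raises(ValueError):
        welch_test([1.0], [1.0, 2.0])


def test_compare_expression_pairs():
    profiles = _profiles_with_density([1] * 8)
    profiles["log2_tpm"] = [0, 0, 0, 0, 5, 5, 5, 5.0]
    grouping = {f"g{i}": ("lo" if i < 4 else "hi") for i in range(8)}
    (res,) = compare_expression(profiles, grouping)
    assert {res.group_a, res.group_b} == {"lo", "hi"}
    assert res.p < 0.01


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def test_correlation_perfect_when_metric_is_expression():
    df = _profiles_with_density(np.arange(20, dtype=float))
    df["log2_tpm"] = df["density_gene_body"]
    res = occupancy_expression_correlation(df, "gene_body")
    assert res.pearson_r == pytest.approx(1.0)


def test_correlation_near_zero_when_permuted():
    rng = np.random.default_rng(2)
    df = _profiles_with_density(rng.normal(size=500))
    df["log2_tpm"] = rng.permutation(df["density_gene_body"].to_numpy())
    res = occupancy_expression_correlation(df, "gene_body")
    assert abs(res.pearson_r) < 0.15


def test_correlation_needs_ten_genes():
    with pytest.raises(ValueError):
        occupancy_expression_correlation(_profiles_with_density([1.0] * 5), "gene_body")


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------


def _annotations_at(positions, chrom="c1"):
    return [
        SiteAnnotation(site=_site(p, chrom=chrom), feature="exon") for p in positions
    ]


def test_metagene_midpoint_sites_fill_central_bin():
    genes = [_simple_gene("gA", start=2000, body=1000)]
    anns = _annotations_at([2500] * 7)
    prof = metagene_profile(anns, genes, n_bins_body=20, n_bins_flank=10)
    assert prof.counts.sum() == 7
    assert prof.counts[10 + 10] == 7  # central body bin


def test_metagene_frequencies_sum_to_one(small_study):
    sites = sites_from_truth(small_study["truth"], small_study["genome"])
    anns = assign_sites(sites, small_study["partition"])
    prof = metagene_profile(anns, small_study["genes"])
    assert prof.frequencies.sum() == pytest.approx(1.0)


def test_metagene_invariant_under_gene_order(small_study):
    sites = sites_from_truth(small_study["truth"], small_study["genome"])
    anns = assign_sites(sites, small_study["partition"])
    genes = small_study["genes"]
    a = metagene_profile(anns, genes)
    b = metagene_profile(anns, genes[::-1])
    assert np.array_equal(a.counts, b.counts)


def test_metagene_minus_strand_orientation():
    """An upstream-of-TSS site on a - strand gene lands in the upstream flank."""
    gene = _simple_gene("gA", start=2000, body=1000, strand="-")
    # TSS of a - strand gene is at the right end; upstream means larger coords
    anns = _annotations_at([3100])
    prof = metagene_profile(anns, [gene], n_bins_flank=10, flank_bp=1000)
    assert prof.counts[:10].sum() == 1  # upstream flank
    anns2 = _annotations_at([1900])  # past the TES -> downstream flank
    prof2 = metagene_profile(anns2, [gene], n_bins_flank=10, flank_bp=1000)
    assert prof2.counts[-10:].sum() == 1


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _class_profiles(levels, tpms):
    n = len(levels)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "mean_fraction_gene_body": levels,
            "tpm": tpms,
        }
    )


def test_classify_clear_top_gene():
    levels = [0.1, 0.2, 0.2, 0.3, 0.3, 0.4, 0.4, 0.5, 0.5, 0.95]
    tpms = [1.0] * 9 + [50.0]
    classes = classify_genes(_class_profiles(levels, tpms))
    assert classes["hyper_high"] == {"g9"}


def test_classify_median_methylation_is_neither():
    levels = np.linspace(0, 1, 21)
    tpms = [100.0] * 21
    classes = classify_genes(_class_profiles(levels, tpms))
    assert "g10" not in classes["hyper_high"] | classes["hypo_high"]


def test_classify_sets_disjoint_and_gated(small_study):
    rng = np.random.default_rng(3)
    levels = rng.uniform(0, 1, 200)
    tpms = rng.gamma(2, 10, 200)
    classes = classify_genes(_class_profiles(levels, tpms))
    assert not (classes["hyper_high"] & classes["hypo_high"])
    df = _class_profiles(levels, tpms)
    gated = set(df.loc[df["tpm"] > df["tpm"].mean(), "gene_id"])
    assert classes["hyper_high"] <= gated
    assert classes["hypo_high"] <= gated


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------


def test_term_enrichment_complete_overlap_closed_form():
    """k=n=K=5 in N=20: p = 1/C(20,5)."""
    background = [f"g{i}" for i in range(20)]
    gene_set = background[:5]
    term_map = {g: ["T1"] for g in gene_set}
    df = term_enrichment(gene_set, background, term_map)
    assert df.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)


def test_term_enrichment_zero_hits_p_is_one():
    background = [f"g{i}" for i in range(20)]
    term_map = {"g19": ["T1"]}
    df = term_enrichment(background[:5], background, term_map)
    assert df.loc[0, "p"] == pytest.approx(1.0)


def test_term_enrichment_universal_term_p_is_one():
    background = [f"g{i}" for i in range(20)]
    term_map = {g: ["T1"] for g in background}
    df = term_enrichment(background[:5], background, term_map)
    assert df.loc[0, "p"] == pytest.approx(1.0)


def test_term_enrichment_requires_subset():
    with pytest.raises(ValueError):
        term_enrichment(["gX"], ["g1", "g2"], {})


def test_term_enrichment_null_type_one_control():
    """Uniform random gene sets: few terms reach q < 0.05."""
    rng = np.random.default_rng(4)
    background = [f"g{i}" for i in range(200)]
    terms = [f"T{j}" for j in range(30)]
    term_map = {
        g: list(rng.choice(terms, size=3, replace=False)) for g in background
    }
    n_sig = n_tests = 0
    for _ in range(30):
        gene_set = list(rng.choice(background, size=20, replace=False))
        df = term_enrichment(gene_set, background, term_map)
        n_sig += int(df["significant"].sum())
        n_tests += len(df)
    assert n_sig / n_tests <= 0.05
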