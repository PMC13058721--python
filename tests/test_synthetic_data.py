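"""Generator determinism, planted-truth self-consistency, coupling oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sixma.feature_annotation import build_partition
from sixma.synthetic_data import (
    SimulationConfig,
    largest_remainder,
    plant_6mA,
    simulate_annotation,
    simulate_expression,
    simulate_genome,
    simulate_kinetics,
    simulate_term_map,
)
import pandas as pd


def test_genome_deterministic_given_seed():
    cfg = SimulationConfig(seed=1, n_chrom=1, chrom_len_bp=50_000)
    assert simulate_genome(cfg).sequences == simulate_genome(cfg).sequences


def test_genome_base_composition_matches_gc():
    """A-fraction at GC 0.5 within 5 binomial sd of 0.25 on 1 Mb."""
    cfg = SimulationConfig(seed=2, n_chrom=1, chrom_len_bp=1_000_000, gc=0.5)
    g = simulate_genome(cfg)
    n = len(g)
    a_frac = g.sequences["chr1"].count("A") / n
    sd = math.sqrt(0.25 * 0.75 / n)
    assert abs(a_frac - 0.25) < 5 * sd


def test_genome_short_chromosome_errors():
    with pytest.raises(ValueError, match="1 kb"):
        simulate_genome(SimulationConfig(seed=0, chrom_len_bp=500))


def test_all_gc_genome_has_no_adenines_and_planting_errors():
    cfg = SimulationConfig(seed=3, n_chrom=1, chrom_len_bp=10_000, gc=1.0)
    g = simulate_genome(cfg)
    assert g.strand_adenine_count() == 0
    with pytest.raises(ValueError, match="adenine"):
        plant_6mA(g, [], [], cfg)


def test_annotation_genes_disjoint_with_flanks(small_study):
    genes = small_study["genes"]
    by_chrom = {}
    for g in genes:
        assert len(g.exons) >= 1
        s, e = g.span
        by_chrom.setdefault(g.chrom, []).append((s - 2000, e + 2000))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            assert s1 >= e0, "gene 2 kb flanks overlap"


def test_annotation_intron_exon_length_ratio():
    """Sample mean intron/exon length ratio ~ 15 over many genes."""
    cfg = SimulationConfig(
        seed=5, n_chrom=2, chrom_len_bp=2_000_000, n_genes=200
    )
    genes, _ = simulate_annotation(simulate_genome(cfg), cfg)
    exon_lens, intron_lens = [], []
    for g in genes:
        exon_lens.extend(e - s for s, e in g.exons)
        prev = None
        for s, e in g.exons:
            if prev is not None:
                intron_lens.append(s - prev)
            prev = e
    ratio = np.mean(intron_lens) / np.mean(exon_lens)
    assert 11 < ratio < 19


def test_annotation_zero_te_fraction_gives_no_repeats():
    cfg = SimulationConfig(
        seed=6,
        n_chrom=1,
        chrom_len_bp=100_000,
        n_genes=4,
        te_fraction={c: 0.0 for c in ("LINE", "SINE", "LTR", "SimpleRepeat", "Other")},
    )
    _, repeats = simulate_annotation(simulate_genome(cfg), cfg)
    assert repeats == []


def test_annotation_too_many_genes_errors():
    cfg = SimulationConfig(seed=7, n_chrom=1, chrom_len_bp=20_000, n_genes=50)
    with pytest.raises(ValueError, match="does not fit"):
        simulate_annotation(simulate_genome(cfg), cfg)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def test_planted_count_follows_density(small_study):
    cfg = SimulationConfig(seed=8, planted_density=0.002)
    genome, genes, repeats = (
        small_study["genome"],
        small_study["genes"],
        small_study["repeats"],
    )
    truth = plant_6mA(genome, genes, repeats, cfg, partition=small_study["partition"])
    assert len(truth) == round(0.002 * genome.strand_adenine_count())


def test_planted_sites_sit_on_strand_adenines(small_study):
    genome = small_study["genome"]
    for t in small_study["truth"]:
        base = genome.base(t.chrom, t.pos0)
        assert base == ("A" if t.strand == "+" else "T")


def test_planted_composition_exact(small_study):
    cfg = SimulationConfig(
        seed=9, feature_composition={"exon": 0.42, "intron": 0.58}
    )
    truth = plant_6mA(
        small_study["genome"],
        small_study["genes"],
        small_study["repeats"],
        cfg,
        n_sites=100,
        partition=small_study["partition"],
    )
    labels = [t.feature_label for t in truth]
    assert labels.count("exon") == 42
    assert labels.count("intron") == 58


def test_planting_single_class(small_study):
    cfg = SimulationConfig(seed=10, feature_composition={"intron": 1.0})
    truth = plant_6mA(
        small_study["genome"],
        small_study["genes"],
        small_study["repeats"],
        cfg,
        n_sites=50,
        partition=small_study["partition"],
    )
    assert all(t.feature_label == "intron" for t in truth)


def test_planting_overfull_class_names_it(small_study):
    cfg = SimulationConfig(seed=11, feature_composition={"5'UTR": 1.0})
    with pytest.raises(ValueError, match="5'UTR"):
        plant_6mA(
            small_study["genome"],
            small_study["genes"],
            small_study["repeats"],
            cfg,
            n_sites=10**6,
            partition=small_study["partition"],
        )


@settings(derandomize=True, max_examples=50)
@given(
    n=st.integers(0, 10_000),
    weights=st.lists(st.floats(0.01, 10), min_size=1, max_size=8),
)
def test_largest_remainder_properties(n, weights):
    total = sum(weights)
    props = {f"k{i}": w / total for i, w in enumerate(weights)}
    counts = largest_remainder(n, props)
    assert sum(counts.values()) == n
    for k, p in props.items():
        assert math.floor(n * p) <= counts[k] <= math.ceil(n * p)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def _one_chrom_genome(seq):
    from sixma.types import GenomeSequence

    return GenomeSequence({"c1": seq})


def test_kinetics_background_matches_baseline():
    """Without planted sites the log-IPDs follow Normal(mu0, sigma0)."""
    cfg = SimulationConfig(
        seed=12, coverage_model="fixed", coverage_mean=30, chrom_len_bp=1000
    )
    g = _one_chrom_genome("A" * 2000)
    (table,) = simulate_kinetics(g, [], cfg)
    logs = np.log(table.ipds.astype(float))
    assert abs(logs.mean() - cfg.ipd_baseline_logmean) < 0.01
    assert abs(logs.std() - cfg.ipd_baseline_logsd) < 0.01


def test_kinetics_fully_modified_ratio_matches_multiplier():
    """f=1, m=3, tiny sigma: geometric-mean IPD ratio ~ 3 (lognormal oracle)."""
    from sixma.types import TruthSite

    cfg = SimulationConfig(
        seed=13,
        coverage_model="fixed",
        coverage_mean=50,
        ipd_baseline_logsd=0.01,
        ipd_modified_multiplier=3.0,
    )
    g = _one_chrom_genome("A" * 2000)
    truth = [TruthSite("c1", 100, "+", 1.0, "intergenic")]
    (table,) = simulate_kinetics(g, truth, cfg)
    i = int(np.where((table.pos == 100) & (~table.strand))[0][0])
    site = table.site(i)
    ratio = math.exp(np.log(site.ipds).mean() - cfg.ipd_baseline_logmean)
    assert ratio == pytest.approx(3.0, rel=0.02)


def test_kinetics_fixed_coverage_is_exact():
    cfg = SimulationConfig(seed=14, coverage_model="fixed", coverage_mean=30)
    g = _one_chrom_genome("ACGT" * 500)
    (table,) = simulate_kinetics(g, [], cfg)
    assert (table.coverage == 30).all()


def test_kinetics_multiplier_must_increase_ipd():
    cfg = SimulationConfig(seed=15, ipd_modified_multiplier=0.9)
    with pytest.raises(ValueError, match="exceed 1"):
        simulate_kinetics(_one_chrom_genome("A" * 2000), [], cfg)


def test_kinetics_deterministic(small_study):
    cfg = SimulationConfig(seed=16, n_chrom=1, chrom_len_bp=1000)
    g = _one_chrom_genome("ACGT" * 300)
    t1 = simulate_kinetics(g, [], cfg)
    t2 = simulate_kinetics(g, [], cfg)
    assert np.array_equal(t1[0].ipds, t2[0].ipds)


# ---------------------------------------------------------------------------
# expression coupling
# ---------------------------------------------------------------------------


def _profiles(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "body_density": rng.gamma(2.0, 1.0, n),
            "promoter_density": rng.gamma(2.0, 1.0, n),
        }
    )


def test_expression_uncoupled_when_betas_zero():
    cfg = SimulationConfig(seed=17, beta_body=0.0, beta_promoter=0.0)
    prof = _profiles(1000, 0)
    tpm = np.array([r.tpm for r in simulate_expression(prof, cfg)])
    r, _ = stats.spearmanr(prof["body_density"], tpm)
    assert abs(r) < 0.1


def test_expression_body_coupling_positive():
    cfg = SimulationConfig(
        seed=18, beta_body=1.0, beta_promoter=0.0, expression_noise_sd=0.1
    )
    prof = _profiles(1000, 1)
    tpm = np.array([r.tpm for r in simulate_expression(prof, cfg)])
    r, _ = stats.spearmanr(prof["body_density"], tpm)
    assert r > 0.8


def test_expression_promoter_coupling_negative():
    cfg = SimulationConfig(
        seed=19, beta_body=0.0, beta_promoter=-1.0, expression_noise_sd=0.1
    )
    prof = _profiles(1000, 2)
    tpm = np.array([r.tpm for r in simulate_expression(prof, cfg)])
    r, _ = stats.spearmanr(prof["promoter_density"], tpm)
    assert r < -0.8


def test_term_map_covers_genes(small_study):
    mapping = simulate_term_map(small_study["genes"], small_study["config"])
    assert set(mapping) == {g.gene_id for g in small_study["genes"]}
    assert any(mapping.values())
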