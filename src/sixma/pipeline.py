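"""End-to-end orchestration: simulate -> call -> annotate -> enrich ->
integrate -> motif, with a JSON run report.

Every stage is a pure function of its inputs plus the config; a fixed
config + seed therefore yields a byte-identical report. Output tables are
plain TSV; sites go out in the modifications-GFF dialect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import (
    enrichment_stats,
    expression_integration,
    feature_annotation,
    io_formats,
    kinetics_caller,
    motif_context,
    synthetic_data,
)
from .enrichment_stats import LevelCategories
from .expression_integration import ClassifierConfig
from .feature_annotation import PartitionConfig
from .kinetics_caller import CallerThresholds
from .motif_context import MotifConfig
from .synthetic_data import SimulationConfig
from .types import TE_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: CallerThresholds = field(default_factory=CallerThresholds)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    levels: LevelCategories = field(default_factory=LevelCategories)
    quartile_metric: str = "density"
    window_bp: int = 100_000

    def __post_init__(self) -> None:
        # one global seed drives every stage
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for fld, sub_cls in (
            ("simulation", SimulationConfig),
            ("thresholds", CallerThresholds),
            ("partition", PartitionConfig),
            ("classifier", ClassifierConfig),
            ("motif", MotifConfig),
            ("levels", LevelCategories),
        ):
            if fld in raw:
                sub = raw.pop(fld)
                if "te_fraction" in sub:
                    sub["te_fraction"] = dict(sub["te_fraction"])
                if "fraction_distribution" in sub:
                    sub["fraction_distribution"] = tuple(
                        sub["fraction_distribution"]
                    )
                kwargs[fld] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Dict:
    """Run every stage on synthetic data and write all outputs to out_dir.

    Returns the run report (also written as report.json). Any stage failure
    is re-raised with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"seed": config.seed, "parameters": config.to_dict()}
    stage = "simulate"
    try:
        sim = config.simulation
        genome = synthetic_data.simulate_genome(sim)
        genes, repeats = synthetic_data.simulate_annotation(genome, sim)
        partition = feature_annotation.build_partition(
            genome, genes, config.partition
        )
        truth = synthetic_data.plant_6mA(
            genome, genes, repeats, sim, partition=partition
        )
        occupancy = synthetic_data.truth_gene_occupancy(truth, genes, partition)
        expression = synthetic_data.simulate_expression(occupancy, sim)
        term_map = synthetic_data.simulate_term_map(genes, sim)
        io_formats.write_fasta(genome, out / "genome.fa")
        io_formats.write_gff3_genes(genes, out / "genes.gff3")
        io_formats.write_repeat_bed(repeats, out / "repeats.bed")
        io_formats.write_truth_tsv(truth, out / "truth.tsv")
        io_formats.write_expression_tsv(expression, out / "expression.tsv")
        io_formats.write_term_map(term_map, out / "term_map.tsv")
        report["simulate"] = {
            "genome_bp": len(genome),
            "n_genes": len(genes),
            "n_repeats": len(repeats),
            "n_truth_sites": len(truth),
        }

        stage = "call"
        kinetics = synthetic_data.simulate_kinetics(genome, truth, sim)
        sites = kinetics_caller.call_sites(
            kinetics,
            genome,
            config.thresholds,
            fraction_multiplier=sim.ipd_modified_multiplier,
        )
        del kinetics
        io_formats.write_sites_gff(sites, out / "sites.gff")
        report["call"] = {
            "n_sites": len(sites),
            "density_pct": (
                kinetics_caller.genome_density(sites, genome)
            ),
        }

        stage = "annotate"
        annotations = feature_annotation.assign_sites(sites, partition)
        comp = feature_annotation.composition(annotations)
        te_comp = feature_annotation.assign_te(annotations, repeats)
        gene_summary = feature_annotation.genes_with_sites(annotations, genes)
        pd.DataFrame(
            {
                "chrom": [a.site.chrom for a in annotations],
                "pos0": [a.site.pos0 for a in annotations],
                "strand": [a.site.strand for a in annotations],
                "feature": [a.feature for a in annotations],
                "gene_id": [a.gene_id or "" for a in annotations],
                "te_class": [a.te_class or "" for a in annotations],
            }
        ).to_csv(out / "annotations.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(comp.items()), columns=["feature", "proportion"]
        ).to_csv(out / "composition.tsv", sep="\t", index=False)
        report["annotate"] = {
            "composition": comp,
            "te_composition": te_comp,
            "methylated_genes": gene_summary.counts,
            "methylated_gene_pct": gene_summary.percentages,
        }

        stage = "enrich"
        adenines = feature_annotation.count_adenines(genome, partition)
        observed = {
            f: sum(1 for a in annotations if a.feature == f) for f in adenines
        }
        feat_table = enrichment_stats.enrichment_table(observed, adenines)
        feat_table.to_csv(out / "enrichment_features.tsv", sep="\t", index=False)
        te_adenines = _te_adenine_counts(genome, repeats)
        te_observed = {cls: 0 for cls in TE_CLASSES}
        n_te = 0
        for a in annotations:
            if a.te_class is not None:
                te_observed[a.te_class] += 1
                n_te += 1
        te_observed["none"] = len(annotations) - n_te
        te_table = enrichment_stats.enrichment_table(te_observed, te_adenines)
        te_table.to_csv(out / "enrichment_te.tsv", sep="\t", index=False)
        levels_df, cat_counts = enrichment_stats.level_distribution(
            annotations, config.levels
        )
        levels_df.to_csv(out / "levels.tsv", sep="\t", index=False)
        enrichment_stats.density_tracks(
            sites, genome, config.window_bp, config.levels
        ).to_csv(out / "density_track.tsv", sep="\t", index=False)
        report["enrich"] = {
            "features": feat_table.drop(columns=["stars"]).to_dict("records"),
            "te": te_table.drop(columns=["stars"]).to_dict("records"),
            "level_counts": cat_counts,
        }

        stage = "integrate"
        profiles = expression_integration.gene_region_metrics(
            annotations, partition, genes, expression, genome
        )
        profiles.to_csv(out / "gene_profiles.tsv", sep="\t", index=False)
        quartiles = {}
        tests = []
        correlations = []
        for region in ("gene_body", "promoter"):
            try:
                labels = expression_integration.quartile_bins(
                    profiles, region, config.quartile_metric
                )
            except ValueError:
                continue
            quartiles[region] = labels
            try:
                for res in expression_integration.compare_expression(
                    profiles, labels.to_dict()
                ):
                    tests.append({"region": region, **dataclasses.asdict(res)})
            except ValueError as exc:  # tiny runs: near-empty quartiles
                logger.info("skipping %s quartile tests: %s", region, exc)
        for region in expression_integration.REGIONS:
            try:
                correlations.append(
                    dataclasses.asdict(
                        expression_integration.occupancy_expression_correlation(
                            profiles, region, config.quartile_metric
                        )
                    )
                )
            except ValueError:
                continue
        if quartiles:
            pd.DataFrame(quartiles).to_csv(out / "quartiles.tsv", sep="\t")
        pd.DataFrame(tests).to_csv(out / "expression_tests.tsv", sep="\t", index=False)
        pd.DataFrame(correlations).to_csv(
            out / "correlations.tsv", sep="\t", index=False
        )
        profile = expression_integration.metagene_profile(annotations, genes)
        profile.to_frame().to_csv(out / "metagene.tsv", sep="\t", index=False)
        classes = expression_integration.classify_genes(profiles, config.classifier)
        with open(out / "gene_classes.tsv", "w") as fh:
            fh.write("gene_id\tclass\n")
            for name in ("hyper_high", "hypo_high"):
                for gid in sorted(classes[name]):
                    fh.write(f"{gid}\t{name}\n")
        background = [g.gene_id for g in genes]
        terms = expression_integration.term_enrichment(
            classes["hyper_high"] & set(background), background, term_map
        )
        terms.to_csv(out / "term_enrichment.tsv", sep="\t", index=False)
        report["integrate"] = {
            "n_tests": len(tests),
            "correlations": correlations,
            "class_sizes": {k: len(v) for k, v in classes.items()},
            "n_terms_tested": len(terms),
            "n_terms_significant": int(terms["significant"].sum())
            if len(terms)
            else 0,
        }

        stage = "motif"
        flanks = motif_context.extract_flanks(sites, genome, config.motif)
        if flanks:
            pwm = motif_context.build_pwm(flanks)
            pwm.to_frame().to_csv(out / "pwm.tsv", sep="\t", index=False)
            report["motif"] = {
                "n_flanks": len(flanks),
                "consensus": pwm.consensus(),
            }
        else:
            pd.DataFrame(columns=["position", "A", "C", "G", "T"]).to_csv(
                out / "pwm.tsv", sep="\t", index=False
            )
            report["motif"] = {"n_flanks": 0, "consensus": ""}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["input_hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.name != "report.json"
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _te_adenine_counts(genome, repeats) -> Dict[str, int]:
    """Strand-adenines inside each TE class plus the non-TE remainder."""
    import numpy as np

    counts = {cls: 0 for cls in TE_CLASSES}
    covered = 0
    for r in repeats:
        arr = genome.array(r.chrom)[r.start : r.end]
        n = int(np.count_nonzero((arr == ord("A")) | (arr == ord("T"))))
        counts[r.te_class] += n
        covered += n
    counts["none"] = genome.strand_adenine_count() - covered
    return counts
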