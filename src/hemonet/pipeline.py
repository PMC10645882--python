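"""End-to-end orchestration of the comparative co-expression study.

The study design pairs each cancer cohort with the shared control group:
the pair is normalized jointly, a co-expression network is inferred per
condition, topology statistics compare the cancer network against its
control counterpart, communities and enrichment run on the cancer
network, and a cross-phenotype stage intersects the cancer networks and
builds the shared-process trend matrix.

``run_demo`` wires the synthetic generator through the whole pipeline at
desk scale with a single seed, writing every artifact plus a
deterministic manifest; two runs with one seed produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import communities as comm_mod
from . import coexpression as coex
from . import de_enrichment as de_mod
from . import preprocess as prep
from . import synthetic as synth
from . import topology as topo
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RankedEdgeList,
    read_expression_matrix,
    read_gene_annotation,
    read_gmt,
    write_edge_list,
    write_gene_annotation,
    write_gmt,
)

SCHEMA_VERSION = "1"

__all__ = [
    "PipelineConfig",
    "PhenotypeBundle",
    "run_phenotype",
    "run_comparison",
    "run_demo",
    "demo_inputs",
]


@dataclass
class PipelineConfig:
    """All stage parameters plus input paths for a real run."""

    annotation_path: str = ""
    gene_sets_path: str | None = None
    cohorts: dict = field(default_factory=dict)  # phenotype -> counts TSV
    control_cohort: str = ""
    out_dir: str = "hemonet_out"
    # stage parameters
    quantile_cut: float = 0.25
    zero_majority_fraction: float = 0.5
    mean_cut: float = 10.0
    n_bins_gc: int = 10
    mi_bins: int | None = None
    n_permutations: int = 10
    pairs_per_permutation: int = 1000
    top_k: int = 100_000
    community_top_k: int | None = None  # edges used for community graphs; default top_k
    cutoffs: list[int] | None = None
    resolutions: list[float] | None = None
    jaccard_threshold: float = 0.75
    min_persistence: int = 5
    enrich_padj_threshold: float = 1e-10
    de_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PhenotypeBundle:
    phenotype: str
    normalized: ExpressionMatrix
    cancer_edges: dict  # method -> RankedEdgeList (cancer samples)
    control_edges: dict  # method -> RankedEdgeList (control samples)
    cis_cancer: topo.CisProfile
    cis_control: topo.CisProfile
    ks: tuple[float, float]
    biotype_table: pd.DataFrame
    components: pd.DataFrame
    hierarchy: comm_mod.CommunityHierarchy
    community_tab: pd.DataFrame
    de_table: pd.DataFrame
    enrichment: pd.DataFrame | None
    trend_table: pd.DataFrame | None
    method_agreement: float
    report: dict


def _network(
    matrix: ExpressionMatrix,
    method: str,
    config: PipelineConfig,
    seed: int,
    top_k: int,
) -> RankedEdgeList:
    if method == "mi":
        scores = coex.mutual_information_matrix(matrix, n_bins=config.mi_bins)
    else:
        scores = coex.spearman_matrix(matrix)
    null = coex.permutation_null(
        matrix,
        method,
        n_permutations=config.n_permutations,
        pairs_per_permutation=config.pairs_per_permutation,
        seed=seed,
        n_bins=config.mi_bins,
    )
    return coex.rank_edges(
        scores, null, top_k=top_k, method=method, n_samples=matrix.shape[1]
    )


def run_phenotype(
    cancer_counts: ExpressionMatrix,
    control_counts: ExpressionMatrix,
    annotation: pd.DataFrame,
    config: PipelineConfig,
    phenotype: str,
    gene_sets: GeneSetCollection | None = None,
    out_dir: str | Path | None = None,
) -> PhenotypeBundle:
    """One phenotype's full analysis against the control group.

    Joint filtering/normalization of the paired matrices, MI and Spearman
    networks per condition, cis-profile KS, biotype fractions, component
    spectrum, persistent communities on the cancer MI network, NB Wald
    DE, optional enrichment and community trends.  All artifacts are
    written under ``out_dir/phenotype`` when given.
    """
    joint = ExpressionMatrix(
        pd.concat([cancer_counts.data, control_counts.data], axis=1),
        pd.concat(
            [
                pd.Series(phenotype, index=cancer_counts.sample_ids),
                pd.Series("control", index=control_counts.sample_ids),
            ]
        ),
    )
    normalized, report = prep.normalize(
        joint,
        annotation,
        quantile_cut=config.quantile_cut,
        zero_majority_fraction=config.zero_majority_fraction,
        mean_cut=config.mean_cut,
        n_bins=config.n_bins_gc,
    )
    cancer_norm = normalized.subset_samples(cancer_counts.sample_ids)
    control_norm = normalized.subset_samples(control_counts.sample_ids)

    n_genes = normalized.shape[0]
    max_edges = n_genes * (n_genes - 1) // 2
    top_k = min(config.top_k, max_edges)

    cancer_edges = {
        m: _network(cancer_norm, m, config, config.seed + hash_stage(phenotype, m), top_k)
        for m in ("mi", "spearman")
    }
    control_edges = {
        m: _network(
            control_norm, m, config, config.seed + hash_stage(phenotype, m, "ctl"), top_k
        )
        for m in ("mi", "spearman")
    }

    cutoffs = config.cutoffs or topo.default_cutoff_grid(top_k, lo=max(10, top_k // 100))
    cis_cancer = topo.cis_fraction_curve(
        cancer_edges["mi"], annotation, cutoffs, network_id=phenotype
    )
    cis_control = topo.cis_fraction_curve(
        control_edges["mi"], annotation, cutoffs, network_id=f"{phenotype}_control"
    )
    ks = topo.ks_compare(cis_cancer, cis_control)
    biotype_table = topo.biotype_pair_fractions(cancer_edges["mi"], annotation, top_k)
    components = topo.component_spectrum(
        cancer_edges["mi"], top_k=min(top_k, 2000), annotation=annotation
    )

    community_k = min(config.community_top_k or top_k, top_k)
    graph_edges = sorted(cancer_edges["mi"].edge_set(community_k))
    hierarchy = comm_mod.detect_communities(
        graph_edges,
        resolutions=config.resolutions,
        jaccard_threshold=config.jaccard_threshold,
        min_persistence=config.min_persistence,
        seed=config.seed,
    )
    community_tab = comm_mod.community_table(hierarchy) if len(hierarchy) else pd.DataFrame()

    # DE on raw counts restricted to the filtered gene universe
    kept = normalized.gene_ids
    de_table = de_mod.nb_wald_de(
        cancer_counts.subset_genes(kept),
        control_counts.subset_genes(kept),
        alpha=config.de_alpha,
    )

    enrichment = None
    trend_table = None
    if gene_sets is not None and len(community_tab):
        members_in_universe = {
            row.community_id: set(row.members.split(";")) & set(kept)
            for row in community_tab.itertuples(index=False)
        }
        members_in_universe = {k: v for k, v in members_in_universe.items() if v}
        enrichment = de_mod.hypergeom_enrich(
            members_in_universe, gene_sets, kept, config.enrich_padj_threshold
        )
        rows = []
        for cid, members in members_in_universe.items():
            rows.append({"community_id": cid, **de_mod.de_trend(members, de_table)})
        trend_table = pd.DataFrame(rows)

    overlap = cancer_edges["mi"].edge_set(top_k) & cancer_edges["spearman"].edge_set(top_k)
    union = cancer_edges["mi"].edge_set(top_k) | cancer_edges["spearman"].edge_set(top_k)
    agreement = len(overlap) / len(union) if union else float("nan")

    bundle_report = {
        "schema_version": SCHEMA_VERSION,
        "phenotype": phenotype,
        "n_genes_in": joint.shape[0],
        "n_genes_kept": n_genes,
        "genes_removed_by_rule": report.genes_removed_by_rule,
        "top_k": int(top_k),
        "ks_D": ks[0],
        "ks_p": ks[1],
        "n_communities": len(hierarchy),
        "mi_spearman_topk_jaccard": agreement,
        "cis_profile_caveat": cis_cancer.caveat,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("cohorts", "annotation_path", "gene_sets_path")
        },
    }

    bundle = PhenotypeBundle(
        phenotype, normalized, cancer_edges, control_edges, cis_cancer, cis_control,
        ks, biotype_table, components, hierarchy, community_tab, de_table,
        enrichment, trend_table, agreement, bundle_report,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir) / phenotype)
    return bundle


def hash_stage(*parts: str) -> int:
    """Small deterministic offset for per-stage RNG seeds."""
    digest = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(digest[:2], "big")


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_bundle(bundle: PhenotypeBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for method, el in bundle.cancer_edges.items():
        write_edge_list(el, out / f"edges_cancer_{method}.tsv")
    for method, el in bundle.control_edges.items():
        write_edge_list(el, out / f"edges_control_{method}.tsv")
    _write_frame(bundle.cis_cancer.to_frame(), out / "cis_profile_cancer.tsv")
    _write_frame(bundle.cis_control.to_frame(), out / "cis_profile_control.tsv")
    _write_frame(bundle.biotype_table, out / "biotype_pairs.tsv")
    _write_frame(bundle.components, out / "components.tsv")
    if len(bundle.community_tab):
        _write_frame(bundle.community_tab, out / "communities.tsv")
        links = pd.DataFrame(bundle.hierarchy.containment_links, columns=["parent", "child"])
        _write_frame(links, out / "containment.tsv")
    _write_frame(bundle.de_table.reset_index(drop=True), out / "de_table.tsv")
    if bundle.enrichment is not None:
        _write_frame(bundle.enrichment, out / "enrichment.tsv")
    if bundle.trend_table is not None:
        _write_frame(bundle.trend_table, out / "trends.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.report, fh, indent=2, sort_keys=True, default=str)


def run_comparison(
    bundles: Mapping[str, PhenotypeBundle],
    annotation: pd.DataFrame,
    config: PipelineConfig,
    gene_sets: GeneSetCollection | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Cross-phenotype stage: intersection network, its communities and
    enrichment, per-phenotype KS table, shared-process trend matrix."""
    if len(bundles) < 2:
        raise ValueError("comparison needs >= 2 phenotype bundles")
    universes = {ph: set(b.normalized.gene_ids) for ph, b in bundles.items()}
    ref = next(iter(universes.values()))
    # gene universes may legitimately differ after per-pair filtering; the
    # intersection network is computed on edges, which handles that, but the
    # shared-universe check guards the trend matrix inputs
    edge_lists = [b.cancer_edges["mi"] for b in bundles.values()]
    common_edges, nodes = topo.intersect_networks(edge_lists, top_k=config.top_k)

    inter_hier = None
    inter_table = pd.DataFrame()
    if common_edges:
        inter_hier = comm_mod.detect_communities(
            sorted(common_edges),
            resolutions=config.resolutions,
            jaccard_threshold=config.jaccard_threshold,
            min_persistence=config.min_persistence,
            seed=config.seed,
        )
        if len(inter_hier):
            inter_table = comm_mod.community_table(inter_hier)

    ks_rows = [
        {"phenotype": ph, "ks_D": b.ks[0], "ks_p": b.ks[1]}
        for ph, b in bundles.items()
    ]
    ks_table = pd.DataFrame(ks_rows)

    shared = None
    if all(b.enrichment is not None for b in bundles.values()):
        members = {
            ph: {
                row.community_id: set(row.members.split(";"))
                for row in b.community_tab.itertuples(index=False)
            }
            for ph, b in bundles.items()
        }
        shared = de_mod.shared_bp_matrix(
            {ph: b.enrichment for ph, b in bundles.items()},
            members,
            {ph: b.de_table for ph, b in bundles.items()},
        )

    result = {
        "intersection_edges": sorted(common_edges),
        "intersection_nodes": sorted(nodes),
        "intersection_n_edges": len(common_edges),
        "intersection_n_nodes": len(nodes),
        "intersection_communities": inter_table,
        "ks_table": ks_table,
        "shared_bp_matrix": shared,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(result["intersection_edges"], columns=["gene_a", "gene_b"]).to_csv(
            out / "intersection_edges.tsv", sep="\t", index=False
        )
        _write_frame(ks_table, out / "ks_table.tsv")
        if len(inter_table):
            _write_frame(inter_table, out / "intersection_communities.tsv")
        if shared is not None and shared.shape[1] > 0:
            shared.to_csv(out / "shared_bp_trends.tsv", sep="\t", float_format="%.10g")
    return result


# ---------------------------------------------------------------------------
# synthetic demo

def demo_inputs(
    seed: int,
    n_genes: int = 300,
    n_chromosomes: int = 6,
    n_samples: int = 60,
    n_modules: int = 4,
    module_size: int = 12,
    pseudogene_module_size: int = 10,
    latent_correlation: float = 0.8,
    phenotypes: tuple[str, ...] = ("AML", "MM"),
):
    """Generate annotation, control counts, per-phenotype cancer counts,
    truths, and a gene-set collection derived from the planted modules."""
    per = n_genes // n_chromosomes
    chrom_lengths = {str(i + 1): per for i in range(n_chromosomes)}
    chrom_lengths[str(n_chromosomes)] += n_genes - per * n_chromosomes
    annotation = generate_demo_annotation(n_genes, chrom_lengths, seed)

    cancers = {}
    truths = {}
    rng = np.random.default_rng(seed)
    control_modules = synth.plant_modules(
        annotation, "control", n_modules, module_size,
        latent_correlation, seed=seed + 1,
    )
    control, control_truth = synth.generate_cohort(
        annotation, control_modules, "control", n_samples,
        seed=seed + 2, param_seed=seed,
    )
    for i, ph in enumerate(phenotypes):
        modules = synth.plant_modules(
            annotation, "cancer", n_modules, module_size, latent_correlation,
            pseudogene_module_size=pseudogene_module_size, seed=seed + 10 + i,
        )
        de_genes = rng.choice(annotation["gene_id"], size=n_genes // 10, replace=False)
        de_spec = {
            g: float(fc)
            for g, fc in zip(de_genes, rng.choice([-2.0, -1.0, 1.0, 2.0], len(de_genes)))
        }
        cancer, truth = synth.generate_cohort(
            annotation, modules, "cancer", n_samples,
            de_spec=de_spec, seed=seed + 20 + i, param_seed=seed,
        )
        cancer.data.columns = [f"{ph}_{j + 1:03d}" for j in range(n_samples)]
        cancer.phenotype = pd.Series(ph, index=cancer.data.columns)
        cancers[ph] = cancer
        truths[ph] = truth

    sets = []
    for ph, truth in truths.items():
        mods: dict[str, list[str]] = {}
        for g, mid in truth.module_assignment.items():
            mods.setdefault(mid, []).append(g)
        for mid, genes in sorted(mods.items()):
            sets.append(GeneSet(f"{ph}_{mid}", f"planted module {mid} of {ph}", sorted(genes)))
    # a few random decoy sets
    decoy_rng = np.random.default_rng(seed + 99)
    for i in range(5):
        genes = sorted(decoy_rng.choice(annotation["gene_id"], size=15, replace=False))
        sets.append(GeneSet(f"decoy_{i + 1}", "random decoy set", list(genes)))
    gene_sets = GeneSetCollection(sets)
    return annotation, control, cancers, truths, control_truth, gene_sets


def generate_demo_annotation(n_genes: int, chrom_lengths: dict, seed: int):
    return synth.generate_annotation(
        n_genes,
        chromosome_lengths=chrom_lengths,
        pseudogene_fraction=0.15,
        seed=seed,
    )


def run_demo(seed: int, out_dir: str | Path, **scale_kwargs) -> dict:
    """Synthetic end-to-end run: generate cohorts, analyse every
    phenotype, run the comparison, and write a consolidated report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, control, cancers, truths, control_truth, gene_sets = demo_inputs(
        seed, **scale_kwargs
    )
    write_gene_annotation(annotation, out / "annotation.tsv")
    write_gmt(gene_sets, out / "gene_sets.gmt")

    config = PipelineConfig(
        seed=seed,
        top_k=3000,
        community_top_k=1000,
        n_permutations=5,
        pairs_per_permutation=400,
        min_persistence=5,
    )
    bundles = {}
    for ph, cancer in cancers.items():
        bundles[ph] = run_phenotype(
            cancer, control, annotation, config, ph,
            gene_sets=gene_sets, out_dir=out,
        )
    comparison = run_comparison(bundles, annotation, config, gene_sets, out_dir=out)

    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": int(seed),
        "phenotypes": sorted(bundles),
        "per_phenotype": {ph: b.report for ph, b in bundles.items()},
        "intersection_n_edges": comparison["intersection_n_edges"],
        "intersection_n_nodes": comparison["intersection_n_nodes"],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return {"bundles": bundles, "comparison": comparison, "report": report,
            "truths": truths, "annotation": annotation}


def run_from_config(config: PipelineConfig) -> dict:
    """Real-data entry point: load every input from the config paths and
    run all phenotypes plus the comparison stage."""
    annotation = read_gene_annotation(config.annotation_path)
    gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
    control = read_expression_matrix(config.control_cohort)
    bundles = {}
    for ph, path in config.cohorts.items():
        cancer = read_expression_matrix(path)
        bundles[ph] = run_phenotype(
            cancer, control, annotation, config, ph,
            gene_sets=gene_sets, out_dir=config.out_dir,
        )
    comparison = None
    if len(bundles) >= 2:
        comparison = run_comparison(
            bundles, annotation, config, gene_sets, out_dir=config.out_dir
        )
    return {"bundles": bundles, "comparison": comparison}
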