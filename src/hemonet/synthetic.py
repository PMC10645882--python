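"""Synthetic paired cancer/control cohorts with planted co-expression structure.

The generator emulates the contrast the pipeline is built to detect: a
control condition whose latent co-expression modules mix chromosomes
(mostly trans edges among the strongest interactions) versus a cancer
condition whose strongest modules are restricted to single chromosomes,
plus one dense pseudogene module.  Counts are negative binomial with a
Gaussian copula imposing block-exchangeable rank correlation within each
module, so NB marginals are exact while within-module dependence is a
single tunable parameter.  Known per-gene fold changes between conditions
provide ground truth for the differential-expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .io_formats import ExpressionMatrix, validate_annotation

__all__ = [
    "ModuleSpec",
    "SyntheticTruth",
    "generate_annotation",
    "largest_remainder_counts",
    "plant_modules",
    "generate_cohort",
]


@dataclass
class ModuleSpec:
    """A planted co-expression module: a clique of genes sharing one latent
    factor with exchangeable correlation ``latent_correlation``."""

    module_id: str
    member_genes: list[str]
    latent_correlation: float
    chromosome_restricted: bool = False
    biotype_restricted: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.latent_correlation < 1.0:
            raise ValueError(
                f"latent_correlation must be in [0, 1), got {self.latent_correlation}"
                " (>= 1 gives a non-positive-semidefinite block)"
            )


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated cohort."""

    planted_edges: set[tuple[str, str]]
    log2fc_true: dict[str, float]
    module_assignment: dict[str, str]
    generator_config: dict = field(default_factory=dict)


def largest_remainder_counts(proportions: Mapping[str, float], total: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of ``total`` items.

    Ties on the remainder break by label order so the result is exactly
    reproducible.
    """
    labels = sorted(proportions)
    fracs = np.array([proportions[k] for k in labels], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {fracs.sum()}")
    raw = fracs * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    remainder = raw - base
    # stable ordering: largest remainder first, label order on ties
    order = sorted(range(len(labels)), key=lambda i: (-remainder[i], labels[i]))
    for i in order[:short]:
        base[i] += 1
    return dict(zip(labels, base.tolist()))


def generate_annotation(
    n_genes: int,
    chromosome_lengths: Mapping[str, int] | None = None,
    biotype_proportions: Mapping[str, float] | None = None,
    pseudogene_fraction: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a BioMart-style annotation table.

    ``chromosome_lengths`` maps chromosome label -> number of genes (must
    sum to ``n_genes``); if omitted, genes are spread evenly over 10
    autosome labels.  Biotype counts come from deterministic
    largest-remainder rounding of ``biotype_proportions``; when
    ``pseudogene_fraction`` is given it overrides the total pseudogene
    mass.  Pseudogenes are assigned a protein-coding parent gene.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if chromosome_lengths is None:
        n_chrom = 10
        per = n_genes // n_chrom
        chromosome_lengths = {str(i + 1): per for i in range(n_chrom)}
        chromosome_lengths[str(n_chrom)] += n_genes - per * n_chrom
    if n_genes < len(chromosome_lengths):
        raise ValueError("n_genes smaller than the number of chromosomes")
    if sum(chromosome_lengths.values()) != n_genes:
        raise ValueError("chromosome_lengths must sum to n_genes")

    if biotype_proportions is None:
        pf = 0.15 if pseudogene_fraction is None else pseudogene_fraction
        biotype_proportions = {
            "protein_coding": 1.0 - pf - 0.05,
            "processed_pseudogene": pf,
            "lncRNA": 0.05,
        }
    elif pseudogene_fraction is not None:
        props = dict(biotype_proportions)
        pg_labels = [b for b in props if "pseudogene" in b] or ["processed_pseudogene"]
        other_mass = sum(v for k, v in props.items() if "pseudogene" not in k)
        scale = (1.0 - pseudogene_fraction) / other_mass if other_mass > 0 else 0.0
        props = {k: v * scale for k, v in props.items() if "pseudogene" not in k}
        for lab in pg_labels:
            props[lab] = pseudogene_fraction / len(pg_labels)
        biotype_proportions = props

    counts = largest_remainder_counts(biotype_proportions, n_genes)
    biotypes = np.array(
        [lab for lab, c in sorted(counts.items()) for _ in range(c)], dtype=object
    )
    rng.shuffle(biotypes)

    width = len(str(n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    chroms = np.array(
        [lab for lab, c in chromosome_lengths.items() for _ in range(c)], dtype=object
    )

    starts = rng.integers(1, 200_000_000, size=n_genes)
    lengths = np.maximum(200, rng.lognormal(mean=9.0, sigma=1.0, size=n_genes).astype(int))
    gc = np.clip(rng.normal(47.0, 8.0, size=n_genes), 20.0, 80.0)

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chroms,
            "biotype": biotypes,
            "gc_percent": np.round(gc, 2),
            "start_position": starts,
            "end_position": starts + lengths,
        }
    )
    coding = table.loc[table["biotype"] == "protein_coding", "gene_id"].to_numpy()
    is_pg = table["biotype"].str.contains("pseudogene")
    parents = np.full(n_genes, pd.NA, dtype=object)
    if is_pg.any() and len(coding):
        parents[is_pg.to_numpy()] = rng.choice(coding, size=int(is_pg.sum()))
    table["parent_gene_id"] = parents
    return validate_annotation(table)


def plant_modules(
    annotation: pd.DataFrame,
    mode: str,
    n_modules: int = 8,
    module_size: int = 30,
    latent_correlation: float = 0.8,
    pseudogene_module_size: int = 0,
    seed: int = 0,
) -> list[ModuleSpec]:
    """Build the default module layout for one condition.

    Control mode draws each module's members across chromosomes
    (round-robin over chromosome groups, so modules are maximally
    trans-mixed).  Cancer mode restricts each module to a single
    chromosome and optionally adds one dense pseudogene module drawn from
    pseudogene-biotype genes across chromosomes.
    """
    if mode not in ("control", "cancer"):
        raise ValueError(f"mode must be 'control' or 'cancer', got {mode!r}")
    rng = np.random.default_rng(seed)
    modules: list[ModuleSpec] = []
    used: set[str] = set()

    pg_mask = annotation["biotype"].str.contains("pseudogene")
    pg_genes = annotation.loc[pg_mask, "gene_id"].tolist()

    if mode == "cancer" and pseudogene_module_size > 0:
        if len(pg_genes) < pseudogene_module_size:
            raise ValueError("not enough pseudogenes for the requested module")
        members = sorted(rng.choice(pg_genes, size=pseudogene_module_size, replace=False))
        modules.append(
            ModuleSpec(
                "M_pseudogene",
                list(members),
                latent_correlation,
                chromosome_restricted=False,
                biotype_restricted="pseudogene",
            )
        )
        used.update(members)

    by_chrom = {
        c: [g for g in grp["gene_id"] if g not in used]
        for c, grp in annotation.groupby("chromosome", sort=True)
    }
    chrom_labels = sorted(by_chrom)
    for lab in chrom_labels:
        by_chrom[lab] = list(rng.permutation(by_chrom[lab]))

    for m in range(n_modules):
        if mode == "cancer":
            lab = chrom_labels[m % len(chrom_labels)]
            pool = by_chrom[lab]
            if len(pool) < module_size:
                raise ValueError(f"chromosome {lab} has too few free genes")
            members = [pool.pop() for _ in range(module_size)]
            restricted = True
        else:
            # round-robin across chromosomes: guarantees trans-mixing
            members = []
            k = 0
            while len(members) < module_size:
                lab = chrom_labels[(m + k) % len(chrom_labels)]
                if by_chrom[lab]:
                    members.append(by_chrom[lab].pop())
                k += 1
                if k > 100 * module_size:
                    raise ValueError("not enough free genes for control modules")
            restricted = False
        modules.append(
            ModuleSpec(f"M{m + 1}", sorted(members), latent_correlation, restricted)
        )
        used.update(members)

    _check_disjoint(modules)
    if mode == "cancer":
        _check_restriction(modules, annotation)
    return modules


def _check_disjoint(modules: Sequence[ModuleSpec]) -> None:
    seen: set[str] = set()
    for m in modules:
        overlap = seen.intersection(m.member_genes)
        if overlap:
            raise ValueError(f"module members not disjoint: {sorted(overlap)[:5]}")
        seen.update(m.member_genes)


def _check_restriction(modules: Sequence[ModuleSpec], annotation: pd.DataFrame) -> None:
    chrom = annotation["chromosome"]
    for m in modules:
        if m.chromosome_restricted:
            labs = set(chrom.loc[m.member_genes])
            if len(labs) != 1:
                raise ValueError(f"module {m.module_id} spans chromosomes {labs}")


def _gene_baselines(
    gene_ids: Sequence[str],
    nb_mean_range: tuple[float, float],
    nb_dispersion: float,
    param_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene baseline NB means (log-uniform over the range) and
    dispersions.  Seeded independently of the sampling seed so that the
    control and cancer draws share identical baselines."""
    rng = np.random.default_rng(param_seed)
    lo, hi = nb_mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gene_ids)))
    disps = np.full(len(gene_ids), float(nb_dispersion))
    return means, disps


def generate_cohort(
    annotation: pd.DataFrame,
    modules: Sequence[ModuleSpec],
    mode: str,
    n_samples: int,
    nb_mean_range: tuple[float, float] = (20.0, 500.0),
    nb_dispersion: float = 0.15,
    de_spec: Mapping[str, float] | None = None,
    seed: int = 0,
    param_seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw an NB count matrix with planted within-module correlation.

    Counts come from a Gaussian copula: a latent multivariate normal with
    block-exchangeable correlation per module (``z = sqrt(rho) f +
    sqrt(1-rho) e`` for a shared module factor ``f``), pushed through the
    NB quantile function at each gene's mean and dispersion (NB2:
    ``var = mu + alpha mu^2``).  Cancer mode multiplies each gene's mean
    by ``2**log2FC`` from ``de_spec``.  Deterministic given seeds.

    Returns the matrix plus a :class:`SyntheticTruth` with all
    within-module pairs as planted edges, the applied log2 fold changes,
    and a full config echo.
    """
    if mode not in ("control", "cancer"):
        raise ValueError(f"mode must be 'control' or 'cancer', got {mode!r}")
    _check_disjoint(modules)
    gene_ids = list(annotation["gene_id"])
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for m in modules:
        missing = [g for g in m.member_genes if g not in gene_pos]
        if missing:
            raise ValueError(f"module {m.module_id} genes not annotated: {missing[:5]}")

    n_genes = len(gene_ids)
    means, disps = _gene_baselines(gene_ids, nb_mean_range, nb_dispersion, param_seed)

    log2fc = {g: 0.0 for g in gene_ids}
    if de_spec:
        for g, fc in de_spec.items():
            if g not in gene_pos:
                raise ValueError(f"de_spec gene {g} not annotated")
            log2fc[g] = float(fc)
    mu = means.copy()
    if mode == "cancer" and de_spec:
        for g, fc in de_spec.items():
            mu[gene_pos[g]] *= 2.0 ** float(fc)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_genes))
    for m in modules:
        rho = m.latent_correlation
        if rho > 0:
            idx = [gene_pos[g] for g in m.member_genes]
            f = rng.standard_normal((n_samples, 1))
            z[:, idx] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * z[:, idx]

    u = ndtr(z)
    r = 1.0 / disps  # NB2: var = mu + alpha mu^2 -> size r = 1/alpha
    p = r / (r + mu)
    counts = stats.nbinom.ppf(u, r[None, :], p[None, :]).astype(np.int64)

    data = pd.DataFrame(
        counts.T,
        index=gene_ids,
        columns=[f"{mode[:3].upper()}_{j + 1:03d}" for j in range(n_samples)],
    )
    pheno = pd.Series(mode, index=data.columns)
    matrix = ExpressionMatrix(data, pheno)

    planted: set[tuple[str, str]] = set()
    assignment: dict[str, str] = {}
    for m in modules:
        mem = sorted(m.member_genes)
        for g in mem:
            assignment[g] = m.module_id
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                planted.add((mem[i], mem[j]))

    config = {
        "mode": mode,
        "n_samples": int(n_samples),
        "n_genes": int(n_genes),
        "nb_mean_range": [float(nb_mean_range[0]), float(nb_mean_range[1])],
        "nb_dispersion": float(nb_dispersion),
        "seed": int(seed),
        "param_seed": int(param_seed),
        "modules": [
            {
                "module_id": m.module_id,
                "size": len(m.member_genes),
                "latent_correlation": m.latent_correlation,
                "chromosome_restricted": m.chromosome_restricted,
                "biotype_restricted": m.biotype_restricted,
            }
            for m in modules
        ],
    }
    truth = SyntheticTruth(planted, log2fc, assignment, config)
    return matrix, truth
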