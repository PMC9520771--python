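"""Synthetic pharmacogenomic cohorts with plantable cancer-specific signals.

The generator emulates the structure of a cell-line screening cohort: a small
number of cancer types with 6-64 samples each, TPM-like log-normal expression,
curated pathway gene sets, drugs with known target genes, per-cancer driver
genes, a directed regulatory network, an undirected functional network, and a
per-sample per-drug AUC response table.

A *planted* (drug, pathway, cancer) triplet receives three coordinated
signals: (i) the upstream genes of the pathway are upshifted in the planted
cancer by a chosen number of within-cancer standard deviations, (ii) the
functional network gains links between the cancer's drivers, the drug's
targets, and the pathway genes above the background density (so the three
connectivity weights exceed 0.5), and (iii) the drug's AUC in that cancer is
coupled linearly (negative slope: higher activation, stronger response) to the
true upstream activation, plus Gaussian noise.  Everything else is pure
background, so a configuration with no planted triplets and zero slope is an
exact null cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data import Cohort, DriverSet, DrugTargetMap, PathwayDB
from .errors import ValidationError

__all__ = ["PlantedTriplet", "SimConfig", "SimulatedData", "simulate_cohort"]


@dataclass(frozen=True)
class PlantedTriplet:
    """A (drug, pathway, cancer) signal with an effect size in within-cancer
    standard-deviation units of each upstream gene."""

    drug: str
    pathway: str
    cancer: str
    effect_size: float = 3.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a small screening cohort: 6 cancers x 12 cell lines
    (inside the 6-64 per-cancer range of real screens), 4 drugs x 5 pathways
    (20 drug-pathway candidate pairs), pathways of 10 genes carved from a
    300-gene expression space.  Expression is log-normal per gene
    (log-mean ~ N(1, 0.5), log-sd 0.4, a TPM-like positive skew).  The
    functional network is Erdos-Renyi at density ``background_edge_prob``
    with planted links added at ``planted_edge_prob``.  AUC is
    ``auc_baseline`` plus N(0, noise_sd) noise, with the planted coupling
    ``-response_slope * standardized activation`` added for planted triplets.
    """

    n_cancers: int = 6
    samples_per_cancer: int | Sequence[int] = 12
    n_genes: int = 300
    n_pathways: int = 5
    pathway_size: int = 10
    n_drugs: int = 4
    targets_per_drug: int = 1
    planted: Sequence[PlantedTriplet] = field(default_factory=tuple)
    response_slope: float = 0.1
    noise_sd: float = 0.1
    auc_baseline: float = 0.5
    drivers_per_cancer: int = 5
    background_edge_prob: float = 0.01
    planted_edge_prob: float = 0.5
    log_mean_loc: float = 1.0
    log_mean_scale: float = 0.5
    log_sd: float = 0.4
    seed: int = 0

    def sample_counts(self) -> list[int]:
        if isinstance(self.samples_per_cancer, int):
            return [self.samples_per_cancer] * self.n_cancers
        counts = list(self.samples_per_cancer)
        if len(counts) != self.n_cancers:
            raise ValidationError("samples_per_cancer list must have n_cancers entries")
        return counts

    def validate(self) -> None:
        if self.n_cancers < 3:
            raise ValidationError("need at least 3 cancers")
        if self.pathway_size < 3:
            raise ValidationError("pathway_size must be >= 3")
        if any(n < 2 for n in self.sample_counts()):
            raise ValidationError("every cancer needs >= 2 samples")
        if self.n_pathways * self.pathway_size + self.drivers_per_cancer > self.n_genes:
            raise ValidationError("n_genes too small for the pathways plus drivers")
        if self.targets_per_drug < 1:
            raise ValidationError("targets_per_drug must be >= 1")
        cancers = {f"C{z + 1}" for z in range(self.n_cancers)}
        drugs = {f"D{i + 1}" for i in range(self.n_drugs)}
        pathways = {f"PW{j + 1}" for j in range(self.n_pathways)}
        for pt in self.planted:
            if pt.drug not in drugs or pt.pathway not in pathways or pt.cancer not in cancers:
                raise ValidationError(f"planted triplet {pt} names unknown entities")
            if not np.isfinite(pt.effect_size):
                raise ValidationError("planted effect sizes must be finite")


@dataclass
class SimulatedData:
    """All artifacts of one simulation plus the ground-truth table."""

    cohort: Cohort
    pathways: PathwayDB
    drug_targets: DrugTargetMap
    drivers: DriverSet
    directed: nx.DiGraph
    functional: nx.Graph
    response: pd.DataFrame
    truth: pd.DataFrame


def simulate_cohort(config: SimConfig) -> SimulatedData:
    """Generate a full synthetic cohort; byte-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    counts = config.sample_counts()
    cancers = [f"C{z + 1}" for z in range(config.n_cancers)]
    samples = [f"{c}_S{i + 1:02d}" for c, n in zip(cancers, counts) for i in range(n)]
    labels = pd.Series([c for c, n in zip(cancers, counts) for _ in range(n)],
                       index=samples, name="cancer")
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    drugs = [f"D{i + 1}" for i in range(config.n_drugs)]
    pathway_names = [f"PW{j + 1}" for j in range(config.n_pathways)]

    # pathway gene blocks (disjoint), ordered as regulatory chains
    pathway_genes = {
        name: genes[j * config.pathway_size:(j + 1) * config.pathway_size]
        for j, name in enumerate(pathway_names)
    }
    pathways = PathwayDB({n: frozenset(g) for n, g in pathway_genes.items()})

    # dedicated target genes, outside the expression matrix
    targets = {d: frozenset(f"T_{d}_{k + 1}" for k in range(config.targets_per_drug))
               for d in drugs}

    # baseline log-normal expression, gene-specific log-mean shared across cancers
    log_mu = rng.normal(config.log_mean_loc, config.log_mean_scale, size=config.n_genes)
    expr = np.exp(rng.normal(log_mu[:, None], config.log_sd,
                             size=(config.n_genes, len(samples))))
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    # drivers: a pan-cancer pool of genes outside any pathway, shared by all
    # cancers.  Sharing keeps the connectivity weights — and therefore the PAS
    # scale — identical across cancers, so a configuration without planted
    # triplets is an exact null for the specificity screen; cancer-specific
    # random driver sets would make the weights themselves a source of
    # between-cancer heterogeneity.
    background_genes = genes[config.n_pathways * config.pathway_size:]
    driver_pool = frozenset(rng.choice(background_genes,
                                       size=config.drivers_per_cancer, replace=False))
    drivers = {c: driver_pool for c in cancers}

    # directed network: each pathway is a chain of regulatory edges; a drug's
    # targets are spliced into the chain so every (drug, pathway) pair has
    # nonempty G_u and G_d.  Planted pairs act mid-chain (half the pathway
    # upstream of the target); background drugs act at the top of the chain
    # (one upstream gene), so a planted expression shift is specific to the
    # planted (drug, pathway) pair rather than shared by every drug.
    mid = config.pathway_size // 2
    planted_pairs = {(pt.drug, pt.pathway) for pt in config.planted}
    directed = nx.DiGraph()
    for name in pathway_names:
        chain = pathway_genes[name]
        directed.add_edges_from(zip(chain[:-1], chain[1:]))
        for d in drugs:
            pos = mid if (d, name) in planted_pairs else 1
            for t in sorted(targets[d]):
                directed.add_edge(chain[pos - 1], t)
                directed.add_edge(t, chain[pos])

    # functional network: Erdos-Renyi background over genes + targets
    all_nodes = genes + sorted(t for d in drugs for t in targets[d])
    functional = nx.fast_gnp_random_graph(len(all_nodes), config.background_edge_prob,
                                          seed=int(rng.integers(2**31)))
    functional = nx.relabel_nodes(functional, dict(enumerate(all_nodes)))
    functional.add_nodes_from(all_nodes)

    # theoretical within-cancer sd of each gene's (log-normal) expression
    gene_sd = pd.Series(
        np.sqrt(np.exp(config.log_sd**2) - 1) * np.exp(log_mu + config.log_sd**2 / 2),
        index=genes)

    truth_rows = []
    upstream = {name: pathway_genes[name][:mid] for name in pathway_names}
    for pt in config.planted:
        g_u = upstream[pt.pathway]
        cancer_samples = labels.index[labels == pt.cancer]
        # (i) expression upshift of the upstream genes in the planted cancer
        shift = pt.effect_size * gene_sd[g_u].to_numpy()
        expression.loc[g_u, cancer_samples] = (
            expression.loc[g_u, cancer_samples].to_numpy() + shift[:, None])
        # (ii) enriched functional links among drivers, targets, pathway genes
        pw = pathway_genes[pt.pathway]
        drv = sorted(drivers[pt.cancer])
        tgt = sorted(targets[pt.drug])
        for group_a, group_b in ((drv, tgt), (drv, pw), (tgt, pw)):
            for a in group_a:
                for b in group_b:
                    if a != b and rng.random() < config.planted_edge_prob:
                        functional.add_edge(a, b)
        truth_rows.append({
            "drug": pt.drug, "pathway": pt.pathway, "cancer": pt.cancer,
            "effect_size": pt.effect_size, "response_slope": config.response_slope,
            "targets": ";".join(tgt), "g_u": ";".join(g_u),
            "g_d": ";".join(pathway_genes[pt.pathway][mid:]),
        })

    cohort = Cohort(expression=expression, labels=labels, name=f"sim_seed{config.seed}")

    # (iii) drug response: baseline + noise, with the planted coupling
    auc = {d: config.auc_baseline + rng.normal(0.0, config.noise_sd, size=len(samples))
           for d in drugs}
    for pt in config.planted:
        idx = [samples.index(s) for s in labels.index[labels == pt.cancer]]
        s_u = expression.loc[upstream[pt.pathway], labels.index[labels == pt.cancer]].sum(axis=0)
        z = (s_u - s_u.mean()) / (s_u.std(ddof=1) if s_u.std(ddof=1) > 0 else 1.0)
        auc[pt.drug][idx] = auc[pt.drug][idx] - config.response_slope * z.to_numpy()
    response = pd.DataFrame(
        [(s, d, max(0.0, auc[d][i])) for d in drugs for i, s in enumerate(samples)],
        columns=["sample", "drug", "auc"])

    truth = pd.DataFrame(truth_rows, columns=["drug", "pathway", "cancer", "effect_size",
                                              "response_slope", "targets", "g_u", "g_d"])
    return SimulatedData(cohort=cohort, pathways=pathways, drug_targets=targets,
                         drivers=drivers, directed=directed, functional=functional,
                         response=response, truth=truth)
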