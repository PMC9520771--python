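"""Pathway activation scores (PAS).

For a drug-pathway pair the pathway genes are split, relative to the drug's
target genes and a directed regulatory network, into an upstream set ``G_u``
(the targets plus every pathway gene with a directed path into a target) and a
downstream set ``G_d`` (pathway genes reachable from a target).  Per sample,

    PAS_u = S(G_u) * (1 + w1 + w2 + w3)
    PAS_d = S(G_d) * (1 + w1 + w2 + w3)
    PAS   = PAS_u - PAS_d

where ``S(G)`` is the sum of expression of the genes of ``G`` and the weights
are the NEA connectivity weights between the cancer's driver genes, the drug
targets, and the pathway.  The downstream-activation variant of the score is
simply ``-PAS``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .data import Cohort, DriverSet, DrugTargetMap, PathwayDB
from .errors import DisconnectedPathwayError, NetworkSupportError, ValidationError
from .nea import NEUTRAL_WEIGHTS, ConnectivityWeights, nea_z, weights_from_z

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayPartition",
    "PASConfig",
    "partition_pathway",
    "expression_sum",
    "compute_pas",
    "pas_matrix",
]

PAS_COLUMNS = ["sample", "cancer", "drug", "pathway", "S_u", "S_d", "PAS_u", "PAS_d", "PAS"]


@dataclass(frozen=True)
class PathwayPartition:
    """Upstream/downstream split of a pathway relative to a drug's targets."""

    drug: str
    pathway: str
    g_u: frozenset
    g_d: frozenset
    disconnected: bool = False


@dataclass
class PASConfig:
    """Knobs for the PAS computation.

    nea_mode
        ``"analytic"`` (configuration-model null, deterministic) or
        ``"permute_network"`` (double-edge-swap permutation null).
    n_perm, swap_factor, seed
        Permutation-null parameters; ignored in analytic mode.
    unreached_policy
        Where pathway genes reachable in neither direction go:
        ``"downstream"`` (default, conservative — they cannot be argued to feed
        the target) or ``"exclude"``.
    """

    nea_mode: str = "analytic"
    n_perm: int = 1000
    swap_factor: int = 10
    seed: int = 0
    unreached_policy: str = "downstream"


def partition_pathway(pathway_genes: Iterable[str], targets: Iterable[str],
                      directed: nx.DiGraph, unreached_policy: str = "downstream",
                      drug: str = "", pathway: str = "") -> PathwayPartition:
    """Split pathway genes into upstream (``G_u``) and downstream (``G_d``) sets.

    ``G_u`` contains every drug target that is a pathway member plus every
    pathway gene from which some target is reachable along directed edges
    (unbounded-depth transitive reachability).  ``G_d`` contains pathway genes
    reachable *from* a target, minus ``G_u`` — genes on cycles through a target
    are kept upstream (target-side precedence).  Genes reachable in neither
    direction follow ``unreached_policy``.
    """
    pw = frozenset(pathway_genes)
    tg = frozenset(targets)
    if not pw:
        raise ValidationError("pathway gene set is empty")
    if not tg:
        raise ValidationError("target gene set is empty")
    if unreached_policy not in ("downstream", "exclude"):
        raise ValidationError(f"unknown unreached_policy {unreached_policy!r}")

    present = tg & set(directed.nodes)
    upstream_of_targets: set[str] = set()
    downstream_of_targets: set[str] = set()
    for t in present:
        upstream_of_targets |= nx.ancestors(directed, t)
        downstream_of_targets |= nx.descendants(directed, t)

    g_u = (tg & pw) | (pw & upstream_of_targets)
    disconnected = not g_u
    g_d = (pw & downstream_of_targets) - g_u
    if unreached_policy == "downstream":
        g_d |= pw - g_u - g_d
    if not g_u:
        raise DisconnectedPathwayError(
            f"drug {drug or tuple(sorted(tg))!r} has no upstream support in pathway "
            f"{pathway or '<unnamed>'!r}"
        )
    return PathwayPartition(drug=drug, pathway=pathway, g_u=frozenset(g_u),
                            g_d=frozenset(g_d), disconnected=disconnected)


def expression_sum(cohort: Cohort, sample: str, genes: Iterable[str]) -> float:
    """Sum of expression of ``genes`` in ``sample``; missing genes are dropped."""
    if sample not in cohort.expression.columns:
        raise ValidationError(f"unknown sample {sample!r}")
    present = [g for g in genes if g in cohort.expression.index]
    if not present:
        return 0.0
    return float(cohort.expression.loc[present, sample].sum())


def compute_pas(cohort: Cohort, partition: PathwayPartition,
                weights: ConnectivityWeights,
                samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-sample PAS records for one drug-pathway pair and one weight triple."""
    if not partition.g_u and not partition.g_d:
        raise ValidationError("both G_u and G_d are empty")
    cols = list(samples) if samples is not None else cohort.samples
    idx = cohort.expression.index
    g_u = [g for g in partition.g_u if g in idx]
    g_d = [g for g in partition.g_d if g in idx]
    expr = cohort.expression[cols]
    s_u = expr.loc[g_u].sum(axis=0).to_numpy(float) if g_u else np.zeros(len(cols))
    s_d = expr.loc[g_d].sum(axis=0).to_numpy(float) if g_d else np.zeros(len(cols))
    factor = weights.factor
    pas_u = s_u * factor
    pas_d = s_d * factor
    return pd.DataFrame({
        "sample": cols,
        "cancer": cohort.labels.reindex(cols).values,
        "drug": partition.drug,
        "pathway": partition.pathway,
        "S_u": s_u,
        "S_d": s_d,
        "PAS_u": pas_u,
        "PAS_d": pas_d,
        "PAS": pas_u - pas_d,
    })


def pas_matrix(cohort: Cohort, pathway_db: PathwayDB, drug_targets: DrugTargetMap,
               driver_set: DriverSet, directed: nx.DiGraph, functional: nx.Graph,
               config: PASConfig | None = None) -> pd.DataFrame:
    """PAS for every (sample, drug, pathway) combination.

    For each drug-pathway pair the pathway is partitioned once; connectivity
    weights are computed per cancer (driver sets differ by cancer) with the
    AGS/FGS roles of the published analysis: the drug targets act as the FGS
    against drivers (z1) and against the pathway (z3), the drivers act as the
    FGS against the pathway (z2).  z1/z2/z3 are cached across pairs sharing a
    (drug, cancer), (pathway, cancer) or (drug, pathway) key.  Pairs or
    cancers that fail (disconnected partitions, no network support) are
    skipped and recorded in ``result.attrs["skipped"]``.
    """
    cfg = config or PASConfig()
    cancers = cohort.cancers
    skipped: list[dict] = []
    frames: list[pd.DataFrame] = []
    z1_cache: dict = {}
    z2_cache: dict = {}
    z3_cache: dict = {}

    def _z(cache, key, ags, fgs):
        if key not in cache:
            if not ags or not fgs:
                cache[key] = 0.0  # no driver/target support: neutral weight
            else:
                # derive a stable per-key seed so results do not depend on
                # evaluation order (crc32: stable across processes)
                key_hash = zlib.crc32(repr(key).encode())
                sub_seed = int(np.random.SeedSequence(
                    (cfg.seed, key_hash)).generate_state(1)[0] % (2**31))
                try:
                    cache[key] = nea_z(functional, ags, fgs, mode=cfg.nea_mode,
                                       n_perm=cfg.n_perm, seed=sub_seed,
                                       swap_factor=cfg.swap_factor).z
                except NetworkSupportError:
                    cache[key] = None
        return cache[key]

    for drug in sorted(drug_targets):
        targets = drug_targets[drug]
        for pathway in sorted(pathway_db):
            genes = pathway_db[pathway]
            try:
                part = partition_pathway(genes, targets, directed,
                                         unreached_policy=cfg.unreached_policy,
                                         drug=drug, pathway=pathway)
            except DisconnectedPathwayError as exc:
                skipped.append({"drug": drug, "pathway": pathway, "cancer": "*",
                                "reason": str(exc)})
                continue
            for cancer in cancers:
                drivers = driver_set.get(cancer, frozenset())
                z1 = _z(z1_cache, (drug, cancer), drivers, targets)
                z2 = _z(z2_cache, (pathway, cancer), genes, drivers)
                z3 = _z(z3_cache, (drug, pathway), genes, targets)
                if z1 is None or z2 is None or z3 is None:
                    skipped.append({"drug": drug, "pathway": pathway,
                                    "cancer": cancer, "reason": "no network support"})
                    continue
                weights = weights_from_z(z1, z2, z3)
                frames.append(compute_pas(cohort, part, weights,
                                          samples=cohort.samples_of(cancer)))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=PAS_COLUMNS)
    if skipped:
        logger.info("pas_matrix: skipped %d (drug, pathway, cancer) combinations", len(skipped))
    out.attrs["skipped"] = skipped
    return out
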