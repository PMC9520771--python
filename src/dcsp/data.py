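"""Domain types, readers/writers for the standard formats, and dataset-level filters.

Expression matrices, sample labels, drug targets, driver calls, edge lists and
drug-response tables are all plain TSV (tab-separated, header row, UTF-8);
pathway collections use the MSigDB GMT dialect.  Gene identifiers are opaque,
case-sensitive symbols: no alias resolution is attempted, and expression values
are assumed to arrive already normalized (TPM or array intensity) — the package
only filters, it never renormalizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "PathwayDB",
    "read_gmt",
    "write_gmt",
    "read_cohort",
    "write_cohort",
    "read_drug_targets",
    "write_drug_targets",
    "read_drivers",
    "write_drivers",
    "read_directed_network",
    "read_functional_network",
    "write_edge_list",
    "read_drug_response",
    "write_drug_response",
    "filter_unexpressed_genes",
    "filter_driver_mutations",
    "filter_driver_fusions",
    "dedupe_monotherapy",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A gene x sample expression matrix plus a sample -> cancer-type labelling.

    Parameters
    ----------
    expression
        Nonnegative expression values, genes as rows, sample identifiers as
        columns.
    labels
        Mapping from sample identifier to cancer-type code; must cover exactly
        the samples of the expression matrix.
    name
        Free-form cohort identifier used in logs and manifests.
    """

    expression: pd.DataFrame
    labels: pd.Series
    name: str = "cohort"

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValidationError(f"{self.name}: duplicate gene symbols in expression")
        if self.expression.columns.has_duplicates:
            raise ValidationError(f"{self.name}: duplicate sample identifiers")
        self.labels = pd.Series(self.labels)
        if self.labels.index.has_duplicates:
            raise ValidationError(f"{self.name}: duplicate sample in labels")
        missing = set(self.expression.columns) - set(self.labels.index)
        if missing:
            raise ValidationError(
                f"{self.name}: samples without a cancer label: {sorted(missing)[:5]}"
            )
        # restrict labels to samples actually present, in matrix order
        self.labels = self.labels.reindex(self.expression.columns)
        values = self.expression.to_numpy()
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise ValidationError(f"{self.name}: expression must be finite and >= 0")

    # -- convenience accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def cancers(self) -> list[str]:
        return sorted(self.labels.unique())

    def samples_of(self, cancer: str) -> list[str]:
        return list(self.labels.index[self.labels == cancer])

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class PathwayDB:
    """A named collection of gene sets (pathway name -> member genes)."""

    pathways: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.pathways.items():
            genes = frozenset(genes)
            if not genes:
                raise ValidationError(f"pathway {name!r} has an empty gene set")
            clean[name] = genes
        self.pathways = clean

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def items(self):
        return self.pathways.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, PathwayDB) and self.pathways == other.pathways


# Drug -> target genes and cancer -> driver genes are plain dicts of frozensets;
# the reader/writer pairs below validate the invariants (nonempty sets, unique keys).
DrugTargetMap = dict[str, frozenset]
DriverSet = dict[str, frozenset]


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> PathwayDB:
    """Parse an MSigDB-dialect GMT file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; the
    description field is discarded and duplicate genes within a line are
    deduplicated.  Raises :class:`ParseError` naming the offending line for
    malformed (<3 field) lines or duplicate pathway names.
    """
    pathways: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 tab-separated fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: pathway {name!r} lists no genes")
            if name in pathways:
                raise ParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = frozenset(genes)
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in db.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_cohort(expression_path: str | Path, labels_path: str | Path,
                name: str = "cohort") -> Cohort:
    """Load an expression TSV (first column = gene) and a labels TSV."""
    expr = pd.read_csv(expression_path, sep="\t", index_col=0).rename_axis(None)
    if expr.isna().any().any():
        raise ParseError(f"{expression_path}: missing expression values are forbidden")
    lab = _read_tsv(labels_path, ["sample", "cancer"])
    labels = pd.Series(lab["cancer"].values, index=lab["sample"].values, name="cancer")
    return Cohort(expression=expr, labels=labels, name=name)


def write_cohort(cohort: Cohort, expression_path: str | Path,
                 labels_path: str | Path) -> None:
    cohort.expression.rename_axis("gene").to_csv(expression_path, sep="\t")
    pd.DataFrame({"sample": cohort.labels.index, "cancer": cohort.labels.values}
                 ).to_csv(labels_path, sep="\t", index=False)


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Long-format TSV with columns ``drug`` and ``target`` (one row per target)."""
    df = _read_tsv(path, ["drug", "target"])
    out: DrugTargetMap = {}
    for drug, grp in df.groupby("drug", sort=True):
        targets = frozenset(grp["target"].dropna())
        if not targets:
            raise ParseError(f"{path}: drug {drug!r} has no targets")
        out[str(drug)] = targets
    return out


def write_drug_targets(targets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(d, t) for d in sorted(targets) for t in sorted(targets[d])]
    pd.DataFrame(rows, columns=["drug", "target"]).to_csv(path, sep="\t", index=False)


def read_drivers(path: str | Path) -> DriverSet:
    """TSV with columns ``cancer`` and ``gene`` (one row per driver gene)."""
    df = _read_tsv(path, ["cancer", "gene"])
    return {str(c): frozenset(g["gene"]) for c, g in df.groupby("cancer", sort=True)}


def write_drivers(drivers: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(c, g) for c in sorted(drivers) for g in sorted(drivers[c])]
    pd.DataFrame(rows, columns=["cancer", "gene"]).to_csv(path, sep="\t", index=False)


def _read_edges(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: edge list needs two gene columns")
    a, b = df.columns[:2]
    return list(zip(df[a], df[b]))


def read_directed_network(path: str | Path) -> nx.DiGraph:
    """Edge-list TSV (regulator, regulated); self-loops are dropped with a warning."""
    edges = _read_edges(path)
    n_self = sum(1 for u, v in edges if u == v)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    g = nx.DiGraph()
    g.add_edges_from((u, v) for u, v in edges if u != v)
    return g


def read_functional_network(path: str | Path) -> nx.Graph:
    """Undirected edge-list TSV; an optional third (weight) column is ignored."""
    g = nx.Graph()
    g.add_edges_from((u, v) for u, v in _read_edges(path) if u != v)
    return g


def write_edge_list(graph: nx.Graph | nx.DiGraph, path: str | Path) -> None:
    cols = ("regulator", "regulated") if graph.is_directed() else ("gene1", "gene2")
    pd.DataFrame(sorted(graph.edges()), columns=cols).to_csv(path, sep="\t", index=False)


def read_drug_response(path: str | Path) -> pd.DataFrame:
    """TSV with columns ``sample``, ``drug``, ``auc``."""
    df = _read_tsv(path, ["sample", "drug", "auc"])
    df["auc"] = df["auc"].astype(float)
    if not np.isfinite(df["auc"]).all():
        raise ParseError(f"{path}: AUC values must be finite")
    return df[["sample", "drug", "auc"]]


def write_drug_response(table: pd.DataFrame, path: str | Path) -> None:
    table[["sample", "drug", "auc"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dataset-level filters
# ---------------------------------------------------------------------------

def filter_unexpressed_genes(cohort: Cohort, threshold: float = 1e-2,
                             fraction: float = 0.90) -> Cohort:
    """Drop genes expressed at or below ``threshold`` in more than ``fraction``
    of samples.

    A gene is retained iff the proportion of samples with expression <=
    ``threshold`` is <= ``fraction``.  With the defaults this removes genes with
    TPM <= 1e-2 in more than 90% of samples.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    low = (cohort.expression <= threshold).mean(axis=1)
    keep = low <= fraction
    if not keep.any():
        raise ValidationError(f"{cohort.name}: unexpressed-gene filter removed all genes")
    return Cohort(expression=cohort.expression.loc[keep].copy(),
                  labels=cohort.labels.copy(), name=cohort.name)


def filter_driver_mutations(occurrences: pd.DataFrame, cohort: Cohort,
                            min_fraction: float = 0.02) -> DriverSet:
    """Recurrent-mutation filter: keep genes mutated in at least ``min_fraction``
    of the cohort's *total* samples (across cancers), then assign each kept gene
    to every cancer in which it is mutated.

    ``occurrences`` lists (gene, sample) mutation events; repeated events for
    the same gene/sample pair count once.
    """
    if not (0 < min_fraction < 1):
        raise ValidationError("min_fraction must be in (0, 1)")
    occ = occurrences[["gene", "sample"]].drop_duplicates()
    unknown = set(occ["sample"]) - set(cohort.samples)
    if unknown:
        raise ValidationError(f"mutation table refers to unknown samples: {sorted(unknown)[:5]}")
    total = cohort.n_samples
    counts = occ.groupby("gene")["sample"].nunique()
    kept_genes = set(counts.index[counts / total >= min_fraction])
    occ = occ[occ["gene"].isin(kept_genes)]
    occ = occ.assign(cancer=cohort.labels.reindex(occ["sample"]).values)
    return {str(c): frozenset(g["gene"]) for c, g in occ.groupby("cancer", sort=True)}


def filter_driver_fusions(fusions: pd.DataFrame, cohort: Cohort, min_count: int = 2,
                          whitelist: Iterable[str] | None = None) -> DriverSet:
    """Recurrent-fusion filter.

    ``fusions`` has columns ``fusion`` (identifier), ``genes`` (comma-separated
    partner genes) and ``sample``.  A fusion is kept iff it occurs in at least
    ``min_count`` distinct samples and — when a whitelist of known fusions is
    supplied — it is a member of the whitelist.  Partner genes of kept fusions
    become driver genes of the cancers in which the fusion occurs.
    """
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    unknown = set(fusions["sample"]) - set(cohort.samples)
    if unknown:
        raise ValidationError(f"fusion table refers to unknown samples: {sorted(unknown)[:5]}")
    wl = set(whitelist) if whitelist else None
    tab = fusions[["fusion", "genes", "sample"]].drop_duplicates(["fusion", "sample"])
    counts = tab.groupby("fusion")["sample"].nunique()
    kept = set(counts.index[counts >= min_count])
    if wl is not None:
        kept &= wl
    tab = tab[tab["fusion"].isin(kept)]
    out: dict[str, set[str]] = {}
    for _, row in tab.iterrows():
        cancer = str(cohort.labels[row["sample"]])
        partners = {g for g in str(row["genes"]).split(",") if g}
        out.setdefault(cancer, set()).update(partners)
    return {c: frozenset(g) for c, g in out.items()}


def dedupe_monotherapy(raw: pd.DataFrame) -> pd.DataFrame:
    """Keep only (sample, drug) profiles measured exactly once.

    Pairs with more than one record are dropped entirely, mirroring the removal
    of replicated monotherapy profiles from screening data.
    """
    sizes = raw.groupby(["sample", "drug"])["auc"].transform("size")
    return raw[sizes == 1].reset_index(drop=True)
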