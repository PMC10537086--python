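"""Alpha- and beta-diversity on unrarefied ASV tables.

Alpha metrics are ASV richness, Pielou's evenness (natural-log Shannon over
log richness) and Faith's phylogenetic diversity.  Beta diversity is either
Bray–Curtis dissimilarity on proportions (after removing dataset-wide
singleton/doubleton ASVs) or Aitchison distance (Euclidean distance between
centered-log-ratio rows).  No rarefaction is performed anywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .datasets import AsvTable, CohortDataset, DistanceMatrix

METRICS = ("bray_curtis", "aitchison")


def filter_rare_asvs(table: AsvTable, max_total: int = 2) -> AsvTable:
    """Remove ASVs whose total count across the whole dataset is <= ``max_total``.

    Singleton and doubleton removal (the default) requires a count table;
    a proportion-mode table has no meaningful dataset totals.
    """
    if table.is_proportions:
        raise ValueError(
            "singleton/doubleton removal needs counts; skip this step for "
            "a relative-abundance table"
        )
    keep = table.asv_totals() > max_total
    return AsvTable(table.data.loc[:, keep[keep].index], is_proportions=False)


def to_proportions(table: AsvTable) -> pd.DataFrame:
    """Row-normalize to proportions; every row sums to 1."""
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValueError(f"zero-sum samples cannot be normalized: {zero}")
    return table.data.div(totals, axis=0)


def clr_transform(table: AsvTable | pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform with an additive pseudocount.

    Rows are closed to proportions; then ``pseudocount`` times the row's
    smallest non-zero proportion (the detection-limit convention from
    compositional zero replacement) is added to every cell before a final
    closure.  Zeros become finite, ratios between observed taxa are barely
    perturbed, and the transform is exactly invariant to rescaling rows or
    the whole table.  Each output row has mean zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    data = table.data if isinstance(table, AsvTable) else table
    x = data.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("zero-sum samples cannot be CLR-transformed")
    p = x / totals
    min_pos = np.where(p > 0, p, np.inf).min(axis=1, keepdims=True)
    x = p + pseudocount * min_pos
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=data.index, columns=data.columns)


def _pielou(row: np.ndarray) -> float:
    present = row[row > 0]
    if present.size <= 1:
        return np.nan
    p = present / present.sum()
    shannon = -(p * np.log(p)).sum()
    return float(shannon / np.log(present.size))


def faith_pd(table: AsvTable, tree: TreeNode, *, include_stem: bool = True) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    Total branch length of the minimal subtree connecting the root and the
    leaves present in the sample.  ``include_stem`` keeps the path from the
    subtree's crown to the tree root (on by default).
    """
    # stable integer index per node so edge sums are order-deterministic
    nodes = list(tree.traverse(include_self=True))
    index_of = {id(n): i for i, n in enumerate(nodes)}
    lengths = np.array([n.length or 0.0 for n in nodes])
    leaf_paths: dict[str, np.ndarray] = {}
    for tip in tree.tips():
        path = []
        node = tip
        while node.parent is not None:
            path.append(index_of[id(node)])
            node = node.parent
        leaf_paths[tip.name] = np.array(path, dtype=int)

    out = {}
    for sid in table.sample_ids:
        row = table.data.loc[sid]
        present = row.index[row.to_numpy() > 0]
        edge_mask = np.zeros(len(nodes), dtype=bool)
        shared: set[int] | None = None
        for asv in present:
            if asv not in leaf_paths:
                raise KeyError(f"ASV {asv!r} is not a leaf of the tree")
            edge_mask[leaf_paths[asv]] = True
            if not include_stem:
                path_set = set(leaf_paths[asv].tolist())
                shared = path_set if shared is None else (shared & path_set)
        total = float(lengths[edge_mask].sum())
        if not include_stem and shared:
            total -= float(lengths[sorted(shared)].sum())
        out[sid] = total
    return pd.Series(out, name="faith_pd")


def alpha_diversity(cohort: CohortDataset, *, include_faith: bool | None = None,
                    rare_filter: bool = False) -> pd.DataFrame:
    """Richness, Pielou's evenness and (tree permitting) Faith PD per sample.

    Computed on unrarefied counts.  ``rare_filter`` optionally applies the
    singleton/doubleton filter first (off by default; the filter is part of
    the beta-diversity configuration).  Pielou is undefined (NaN) for
    single-ASV samples.
    """
    table = cohort.table
    if rare_filter:
        table = filter_rare_asvs(table)
    if include_faith is None:
        include_faith = cohort.tree is not None
    if include_faith and cohort.tree is None:
        raise ValueError("Faith PD requested but the cohort has no tree")

    mat = table.data.to_numpy(dtype=float)
    richness = (mat > 0).sum(axis=1)
    pielou = np.array([_pielou(r) for r in mat])
    out = pd.DataFrame(
        {"richness": richness, "pielou": pielou}, index=table.sample_ids)
    out.index.name = "sample_id"
    if include_faith:
        out["faith_pd"] = faith_pd(table, cohort.tree)
    return out


def beta_diversity(table: AsvTable, metric: str, *, pseudocount: float = 0.5,
                   rare_filter: bool = True) -> DistanceMatrix:
    """Pairwise Bray–Curtis or Aitchison distances between samples.

    Bray–Curtis runs on proportions after singleton/doubleton removal
    (``rare_filter`` applies only to count tables); Aitchison is the
    Euclidean distance between CLR-transformed rows.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    work = table
    if rare_filter and not table.is_proportions:
        work = filter_rare_asvs(work)
    if metric == "bray_curtis":
        prop = to_proportions(work)
        condensed = pdist(prop.to_numpy(), metric="braycurtis")
    else:
        clr = clr_transform(work, pseudocount=pseudocount)
        condensed = pdist(clr.to_numpy(), metric="euclidean")
    return DistanceMatrix(work.sample_ids, squareform(condensed), metric)
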