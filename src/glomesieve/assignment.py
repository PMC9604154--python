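"""Taxonomic assignment by accumulating placement mass up the reference tree.

Per query, edge LWRs are summed over clades (an edge's mass counts toward
the clade below it); the assignment is the lineage common to the smallest
clade whose cumulative mass reaches the threshold (default 0.9). Queries
resolvable only at the root are labelled ``Glomeromycota_unclassified``.
Clusters sharing a species-level lineage are merged into taxonomic units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROOT_LABEL = "Glomeromycota_unclassified"
SPECIES_DEPTH = 6  # phylum;class;order;family;genus;species


@dataclass
class TaxonAssignment:
    query: str
    lineage: str
    mass: float        # accumulated LWR at the assignment clade
    rank_depth: int    # number of lineage ranks (6 = species, 0 = root)

    @property
    def is_species(self) -> bool:
        return self.rank_depth >= SPECIES_DEPTH


def _common_lineage(lineages: list[str]) -> tuple[str, int]:
    split = [l.split(";") for l in lineages]
    prefix = []
    for ranks in zip(*split):
        if len(set(ranks)) == 1:
            prefix.append(ranks[0])
        else:
            break
    if not prefix:
        return ROOT_LABEL, 0
    return ";".join(prefix), len(prefix)


def accumulate_and_assign(placements, bundle, threshold: float = 0.9
                          ) -> dict[str, TaxonAssignment]:
    """Assign every query to the smallest clade holding >= threshold mass."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    tree = bundle.tree
    n_nodes = tree.n_nodes
    post = tree.postorder()
    n_leaves_below = np.zeros(n_nodes, dtype=int)
    for v in post:
        if tree.is_leaf(v):
            n_leaves_below[v] = 1
        else:
            n_leaves_below[v] = sum(n_leaves_below[c] for c in tree.children[v])
    leaf_lineages = {v: bundle.taxonomy[tree.name[v]] for v in tree.leaves}
    out = {}
    for query, plist in placements.items():
        edge_mass = np.zeros(tree.n_edges)
        for p in plist:
            if p.edge_num >= tree.n_edges:
                raise ValueError(f"placement edge {p.edge_num} not in tree")
            edge_mass[p.edge_num] += p.like_weight_ratio
        clade_mass = np.zeros(n_nodes)
        for v in post:
            m = sum(clade_mass[c] for c in tree.children[v])
            if v != tree.root:
                m += edge_mass[tree.edge_num[v]]
            clade_mass[v] = m
        # smallest clade with mass >= threshold; ties by fewer leaves then
        # by deeper (higher) node id for determinism
        best = None
        for v in range(n_nodes):
            if v == tree.root or clade_mass[v] < threshold:
                continue
            key = (n_leaves_below[v], -v)
            if best is None or key < best[0]:
                best = (key, v)
        if best is None:
            out[query] = TaxonAssignment(query, ROOT_LABEL,
                                         float(clade_mass[tree.root]), 0)
            continue
        v = best[1]
        lineage, depth = _common_lineage(
            [leaf_lineages[u] for u in tree.subtree_leaves(v)])
        out[query] = TaxonAssignment(query, lineage, float(clade_mass[v]),
                                     depth)
    return out


def merge_species_units(assignments: dict[str, TaxonAssignment],
                        cluster_counts: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Merge clusters sharing a species-level lineage into taxonomic units.

    Returns (samples x units count table, unit -> rank depth). Units
    assigned above species level stay distinct, keyed by their lineage.
    """
    if len(cluster_counts.columns) == 0:
        return (pd.DataFrame(index=cluster_counts.index, dtype=int),
                pd.Series(dtype=int))
    missing = set(cluster_counts.columns) - set(assignments)
    if missing:
        raise ValueError(f"clusters without an assignment: {sorted(missing)}")
    unit_of = {}
    ranks = {}
    for cluster in cluster_counts.columns:
        a = assignments[cluster]
        lineage = a.lineage
        depth = a.rank_depth
        if depth > SPECIES_DEPTH:   # sub-species resolution collapses
            lineage = ";".join(lineage.split(";")[:SPECIES_DEPTH])
            depth = SPECIES_DEPTH
        unit_of[cluster] = lineage
        ranks[lineage] = depth
    table = cluster_counts.T.groupby(
        cluster_counts.columns.map(unit_of)).sum().T
    table.index.name = "sample"
    rank_series = pd.Series({u: ranks[u] for u in table.columns},
                            name="rank_depth")
    return table.astype(int), rank_series


def filter_rare_units(table: pd.DataFrame, ranks: pd.Series,
                      min_assigned: int = 10, min_unassigned: int = 100,
                      min_sample_total: int = 100
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Drop rare units and under-sequenced samples.

    Species-level units with total < ``min_assigned`` and non-species units
    with total < ``min_unassigned`` are removed (strict thresholds: "less
    than ten", "less than 100"); samples left with fewer than
    ``min_sample_total`` sequences are excluded.
    """
    if table.empty:
        return table, ranks
    totals = table.sum(axis=0)
    keep = []
    for unit in table.columns:
        limit = min_assigned if ranks[unit] >= SPECIES_DEPTH else min_unassigned
        if totals[unit] >= limit:
            keep.append(unit)
    out = table[keep]
    sample_tot = out.sum(axis=1)
    out = out.loc[sample_tot >= min_sample_total]
    return out, ranks[keep]
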