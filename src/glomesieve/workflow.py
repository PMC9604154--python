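"""End-to-end synthetic study: fixtures -> reads -> clusters -> placements
-> taxonomic units -> count table and mass trees.

This is the wiring used by the command line, the integration tests and the
acceptance analysis. Simulated reads are substitution-only copies of
reference rows, so they are already in reference column space and placement
consumes them directly (with real data an external aligner produces the
combined alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import fixtures as fx
from .analytics import MassTreeSet, mass_trees_from_counts
from .assignment import accumulate_and_assign, filter_rare_units, \
    merge_species_units
from .placement import PlacementSet, place_queries
from .read_pipeline import SeqRecord, run_pipeline


@dataclass
class StudyResult:
    bundle: fx.ReferenceBundle
    design: fx.StudyDesign
    reads: fx.ReadSet
    metadata: pd.DataFrame
    clusters: object
    pipeline_stats: dict
    placements: PlacementSet
    assignments: dict
    unit_table: pd.DataFrame        # after rare-unit / sample filtering
    unit_ranks: pd.Series
    mass_trees: MassTreeSet

    def groups(self, *parts: str) -> pd.Series:
        """Group labels from sample-id fields: parts from
        {'site','plant','matrix'}."""
        idx = {"site": 0, "plant": 1, "matrix": 2}
        cols = [idx[p] for p in parts]

        def label(sample):
            f = sample.split("_")
            return "_".join(f[c] for c in cols)

        return pd.Series({s: label(s) for s in self.unit_table.index},
                         name="group")


def run_synthetic_study(n_taxa: int = 16, seed: int = 1, depth: int = 300,
                        error_rate: float = 0.005,
                        design: fx.StudyDesign | None = None,
                        threshold: float = 0.9,
                        min_divergence: float = 0.06) -> StudyResult:
    """Simulate the study and run the full analysis pipeline on it."""
    if design is None:
        design = fx.StudyDesign()
    bundle = fx.simulate_reference(n_taxa, seed,
                                   min_divergence=min_divergence)
    meta_model = fx.plant_metacommunities(bundle, design)
    reads = fx.simulate_reads(bundle, design, depth, error_rate, seed + 1,
                              metacommunities=meta_model)
    metadata = fx.simulate_metadata(design, seed + 2)
    records = [SeqRecord(rid, sample, seq, quals)
               for rid, sample, seq, quals in reads.reads]
    clusters, stats = run_pipeline(records)
    queries = {rep.id: rep.sequence for rep in clusters.representatives}
    placements = place_queries(queries, bundle, bundle.model)
    assignments = accumulate_and_assign(placements, bundle, threshold)
    table, ranks = merge_species_units(assignments, clusters.counts)
    table, ranks = filter_rare_units(table, ranks)
    mts = mass_trees_from_counts(placements, bundle.tree,
                                 clusters.counts.loc[table.index])
    return StudyResult(bundle, design, reads, metadata, clusters, stats,
                       placements, assignments, table, ranks, mts)
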