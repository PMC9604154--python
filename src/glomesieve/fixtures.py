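"""Synthetic study generator.

Emulates the field design the analyses assume: two sites (a phenol/PAH
contaminated pond shore and an uncontaminated control), two host plants
(*Poa trivialis* ``Pt`` and *Phragmites australis* ``Pa``), root and soil
sample matrices, and twelve replicates per site x plant x matrix. Community
structure is planted as a Dirichlet-multinomial metacommunity model: every
group maps to one Dirichlet component, the contaminated component
concentrates its mass inside one clade of the reference tree (the planted
"contamination clade"), and the two control components split the remaining
taxa by host plant.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every artefact is reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import io as gio
from .phylo import GTRModel, Tree, random_bifurcating_tree, simulate_alignment

SITES = ("K", "C")        # contaminated (Kalina) / control (Kokotek)
PLANTS = ("Pt", "Pa")
MATRICES = ("R", "S")     # root / soil

#: per-site covariate means: (contaminated, control)
DEFAULT_METADATA_MODEL = {
    "pH_water": ((7.13, 0.30), (6.15, 0.30)),
    "pH_KCl": ((7.31, 0.30), (5.63, 0.30)),
    "moisture": ((6.88, 1.50), (4.96, 1.50)),
    "SOM": ((4.85, 1.00), (3.96, 1.00)),
    "Ntot": ((0.61, 0.10), (0.68, 0.10)),
}

#: contaminated-site contaminant ranges, mg per kg soil
PHENOL_RANGE = (98.0, 2814.0)
PAH_RANGE = (40.0, 538.0)

#: physical truncation ranges for the covariates
COVARIATE_RANGES = {
    "pH_water": (3.0, 10.0),
    "pH_KCl": (3.0, 10.0),
    "moisture": (0.0, 100.0),
    "SOM": (0.0, 100.0),
    "Ntot": (0.0, 100.0),
}


def default_metacommunity_map() -> dict[tuple[str, str, str], int]:
    """Group -> Dirichlet component: contaminated groups share component 0,
    control groups split by host plant (components 1 and 2)."""
    out = {}
    for plant in PLANTS:
        for matrix in MATRICES:
            out[("K", plant, matrix)] = 0
            out[("C", plant, matrix)] = 1 if plant == "Pa" else 2
    return out


@dataclass
class StudyDesign:
    """The sampling design and planted statistical structure."""

    n_sites: int = 2
    n_plants: int = 2
    n_matrices: int = 2
    replicates: int = 12
    metacommunity_map: dict = field(default_factory=default_metacommunity_map)
    metadata_model: dict = field(default_factory=lambda: dict(DEFAULT_METADATA_MODEL))
    #: Dirichlet concentration of each component (within-group tightness)
    concentration: float = 50.0
    #: within-site covariate correlation (the source study does not report
    #: one, so it is a parameter; 0 draws covariates independently)
    covariate_correlation: float = 0.0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        groups = {g for g in self.groups()}
        mapped = set(self.metacommunity_map)
        if groups - mapped:
            raise ValueError(f"groups without a component: {groups - mapped}")

    def groups(self):
        for site in SITES[: self.n_sites]:
            for plant in PLANTS[: self.n_plants]:
                for matrix in MATRICES[: self.n_matrices]:
                    yield site, plant, matrix

    def samples(self):
        """Yield (sample_id, site, plant, matrix) for the whole design."""
        for site, plant, matrix in self.groups():
            for rep in range(1, self.replicates + 1):
                yield f"{site}_{plant}_{matrix}_{rep:02d}", site, plant, matrix

    @property
    def n_components(self) -> int:
        return len(set(self.metacommunity_map.values()))


@dataclass
class ReferenceBundle:
    """Reference tree + aligned sequences + model + taxonomy."""

    tree: Tree
    alignment: dict[str, str]
    model: GTRModel
    taxonomy: dict[str, str]

    def write(self, outdir):
        import os
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "ref.nwk"), "w") as fh:
            fh.write(self.tree.to_newick() + "\n")
        gio.write_fasta(self.alignment, os.path.join(outdir, "ref.fasta"))
        gio.write_taxonomy(self.taxonomy, os.path.join(outdir, "taxonomy.tsv"))
        import json
        with open(os.path.join(outdir, "model.json"), "w") as fh:
            json.dump(self.model.to_dict(), fh, indent=1)


def _lineages(tree: Tree) -> dict[str, str]:
    """Six-rank lineages derived from tree ancestry.

    Genus = parent node, family = grandparent, order = great-grandparent
    (clamped at the root), so sister leaves are congeneric and lineage
    prefixes are hierarchically consistent.
    """
    out = {}
    for v in tree.leaves:
        anc = []
        u = tree.parent[v]
        while u != tree.root and len(anc) < 3:
            anc.append(u)
            u = tree.parent[u]
        # ranks missing above a shallow leaf fall back to labels derived
        # from the rank below, keeping lineages hierarchically consistent
        genus = f"Gen{anc[0]}" if len(anc) > 0 else f"Gen_leaf{v}"
        family = f"Fam{anc[1]}" if len(anc) > 1 else f"Fam_{genus}"
        order = f"Ord{anc[2]}" if len(anc) > 2 else f"Ord_{family}"
        name = tree.name[v]
        out[name] = (f"Glomeromycota;Glomeromycetes;{order};"
                     f"{family};{genus};{name}")
    return out


def simulate_reference(n_taxa: int, seed: int, n_cols: int = 400,
                       model: GTRModel | None = None,
                       mean_blen: float = 0.08,
                       min_divergence: float | None = None) -> ReferenceBundle:
    """Random bifurcating reference tree with GTR+Gamma evolved sequences.

    Parameters
    ----------
    min_divergence : if given, branch lengths are rescaled (deterministically,
        in bounded steps) until every leaf pair differs at more than this
        fraction of columns -- used when downstream clustering or placement
        recovery requires distinguishable taxa.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    ss = np.random.SeedSequence(seed)
    rng_tree, rng_seq = [np.random.default_rng(s) for s in ss.spawn(2)]
    if model is None:
        # mildly asymmetric GTR defaults: transition-rich, slight GC skew
        model = GTRModel(np.array([1.0, 3.0, 1.0, 1.0, 3.0, 1.0]),
                         np.array([0.28, 0.22, 0.24, 0.26]),
                         gamma_shape=0.8, p_inv=0.1)
    tree = random_bifurcating_tree(n_taxa, rng_tree, mean_blen=mean_blen)
    if min_divergence is not None:
        # a floor on branch lengths keeps even sister leaves apart; the
        # resampling loop below is a backstop against unlucky draws
        floor = np.maximum(tree.blen, 1.5 * min_divergence)
        floor[tree.root] = 0.0
        tree.blen = floor
    for attempt in range(20):
        rng = np.random.default_rng(ss.spawn(1)[0]) if attempt else rng_seq
        aln = simulate_alignment(tree, model, n_cols, rng)
        if min_divergence is None or _min_pairwise_divergence(aln) > min_divergence:
            break
        tree.blen *= 1.3
        tree.blen[tree.root] = 0.0
    else:
        raise RuntimeError("could not reach requested minimum divergence")
    return ReferenceBundle(tree, aln, model, _lineages(tree))


def _min_pairwise_divergence(aln: dict[str, str]) -> float:
    seqs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in aln.values()]
    best = 1.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            best = min(best, float(np.mean(seqs[i] != seqs[j])))
    return best


# ---------------------------------------------------------------------------
# planted metacommunity structure


@dataclass
class MetacommunityModel:
    """Dirichlet components over reference taxa, tied to a planted clade."""

    component_alphas: np.ndarray          # (k, n_taxa)
    taxa: list[str]
    planted_edge: int                     # contamination clade edge number

    @property
    def k(self) -> int:
        return self.component_alphas.shape[0]


def plant_metacommunities(bundle: ReferenceBundle, design: StudyDesign,
                          inside_mass: float = 0.85) -> MetacommunityModel:
    """Construct component Dirichlet parameters on the reference taxa.

    Component 0 (contaminated) puts ``inside_mass`` of its expected
    composition inside one clade whose size is closest to a third of the
    taxa; the remaining components divide the outside taxa evenly.
    """
    tree = bundle.tree
    taxa = tree.leaf_names()
    n = len(taxa)
    # deterministic clade choice: subtree leaf count closest to n/3,
    # ties broken by the lower edge number
    best, best_score = None, None
    for e in range(tree.n_edges):
        v = tree.node_of_edge[e]
        size = len(tree.subtree_leaves(v))
        if size < 2 or size > n - 2:
            continue
        score = (abs(size - n / 3), e)
        if best_score is None or score < best_score:
            best, best_score = e, score
    if best is None:
        raise ValueError("tree too small to plant a clade")
    inside = {tree.name[u] for u in
              tree.subtree_leaves(tree.node_of_edge[best])}
    outside = [t for t in taxa if t not in inside]
    k = design.n_components
    means = np.zeros((k, n))
    idx = {t: i for i, t in enumerate(taxa)}
    for t in inside:
        means[0, idx[t]] = inside_mass / len(inside)
    for t in outside:
        means[0, idx[t]] = (1 - inside_mass) / len(outside)
    # control components: split outside taxa into k-1 contiguous blocks
    blocks = np.array_split(outside, max(k - 1, 1))
    for c in range(1, k):
        block = list(blocks[c - 1])
        rest = [t for t in taxa if t not in block]
        for t in block:
            means[c, idx[t]] = inside_mass / len(block)
        for t in rest:
            means[c, idx[t]] = (1 - inside_mass) / len(rest)
    alphas = means * design.concentration
    return MetacommunityModel(alphas, taxa, int(best))


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSet:
    """Simulated amplicon reads plus the truth needed for recovery tests."""

    reads: list          # (read_id, sample, sequence, qualities)
    truth: pd.DataFrame  # read_id, sample, origin leaf
    proportions: pd.DataFrame  # per-sample drawn multinomial proportions
    components: pd.Series      # per-sample true component index
    metacommunities: MetacommunityModel

    def counts_by_origin(self) -> pd.DataFrame:
        """Samples x origin-taxon integer counts (the true count table)."""
        tab = (self.truth.groupby(["sample", "origin"]).size()
               .unstack(fill_value=0))
        return tab.reindex(columns=self.metacommunities.taxa, fill_value=0)

    def write_fastq(self, path):
        gio.write_fastq(((rid, seq, quals) for rid, _, seq, quals in self.reads),
                        path)

    def pairs(self, read_len: int = 250):
        """Split each read into a (R1, R2) pair, R2 reverse-complemented."""
        from .read_pipeline import reverse_complement
        for rid, sample, seq, quals in self.reads:
            r1 = (rid + "/1", seq[:read_len], quals[:read_len])
            tail = seq[-read_len:]
            r2 = (rid + "/2", reverse_complement(tail),
                  quals[-read_len:][::-1])
            yield r1, r2


#: constant per-base quality assigned to simulated merged reads. This models
#: the consensus quality of overlap-merged pairs and is deliberately not tied
#: to the injected substitution rate.
FIXTURE_QUALITY = 35


def simulate_reads(bundle: ReferenceBundle, design: StudyDesign, depth: int,
                   error_rate: float, seed: int,
                   metacommunities: MetacommunityModel | None = None) -> ReadSet:
    """Draw per-sample reads from the planted metacommunity model.

    Each sample draws composition p ~ Dirichlet(alpha_component), read
    origins ~ Multinomial(depth, p), and per-base substitution errors at
    ``error_rate``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if metacommunities is None:
        metacommunities = plant_metacommunities(bundle, design)
    taxa = metacommunities.taxa
    seqs = {t: bundle.alignment[t] for t in taxa}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads, truth_rows, props, comps = [], [], {}, {}
    for sample, site, plant, matrix in design.samples():
        comp = design.metacommunity_map[(site, plant, matrix)]
        comps[sample] = comp
        p = rng.dirichlet(metacommunities.component_alphas[comp])
        props[sample] = p
        counts = rng.multinomial(depth, p)
        r = 0
        for t, c in zip(taxa, counts):
            template = np.frombuffer(seqs[t].encode(), dtype=np.uint8)
            for _ in range(c):
                seq = template.copy()
                if error_rate > 0:
                    hit = rng.random(len(seq)) < error_rate
                    if hit.any():
                        # substitute with a uniformly chosen different base
                        cur = seq[hit]
                        shift = rng.integers(1, 4, size=hit.sum())
                        pos = (np.searchsorted(bases, cur) + shift) % 4
                        seq[hit] = bases[pos]
                rid = f"{sample}|r{r:05d}"
                r += 1
                reads.append((rid, sample, seq.tobytes().decode(),
                              [FIXTURE_QUALITY] * len(seq)))
                truth_rows.append((rid, sample, t))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample", "origin"])
    proportions = pd.DataFrame(props, index=taxa).T
    proportions.index.name = "sample"
    return ReadSet(reads, truth, proportions, pd.Series(comps),
                   metacommunities)


# ---------------------------------------------------------------------------
# metadata


def simulate_metadata(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Per-sample covariates from per-site truncated normals.

    Contaminated-site samples draw phenol and PAHs uniformly within the
    observed field ranges; at the control site both are 0 (below detection).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = {}
    for sample, site, plant, matrix in design.samples():
        contaminated = site == "K"
        row = {}
        if contaminated:
            row["phenol"] = rng.uniform(*PHENOL_RANGE)
            row["PAHs"] = rng.uniform(*PAH_RANGE)
        else:
            row["phenol"] = 0.0
            row["PAHs"] = 0.0
        for var, (k_ms, c_ms) in design.metadata_model.items():
            mean, sd = k_ms if contaminated else c_ms
            lo, hi = COVARIATE_RANGES.get(var, (-np.inf, np.inf))
            a, b = (lo - mean) / sd, (hi - mean) / sd
            row[var] = float(truncnorm.rvs(a, b, loc=mean, scale=sd,
                                           random_state=rng))
        rows[sample] = row
    meta = pd.DataFrame(rows).T
    meta.index.name = "sample"
    return meta
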