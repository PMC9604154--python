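"""Evolutionary placement of aligned queries on a fixed reference tree.

Each query is attached to every candidate edge by a pendant branch (fast
pass at the edge midpoint), the best-scoring edges are refined by bounded
scalar optimization of the attachment position and pendant length, and
per-edge likelihood weight ratios (LWR) are the softmax of edge
log-likelihoods. Results round-trip through jplace (v3).

The query must already be aligned to the reference column space; the engine
verifies the column count but never computes an alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .fixtures import ReferenceBundle
from .phylo import GTRModel, PruningEngine, Tree, tip_partial

JPLACE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio",
                 "distal_length", "pendant_length"]


@dataclass
class Placement:
    edge_num: int
    log_likelihood: float
    like_weight_ratio: float
    distal_length: float
    pendant_length: float


class PlacementSet(dict):
    """query id -> list of Placement, best (highest LWR) first."""

    def best_edge(self, query: str) -> int:
        return self[query][0].edge_num

    def total_lwr(self, query: str) -> float:
        return sum(p.like_weight_ratio for p in self[query])


# ---------------------------------------------------------------------------
# model fitting


def _check_alignment(alignment: dict[str, str]):
    if len(alignment) < 4:
        raise ValueError("need at least 4 reference sequences")
    cols = np.array([list(s.upper()) for s in alignment.values()])
    informative = np.isin(cols, list("ACGT")).any(axis=0)
    if not informative.all():
        bad = np.flatnonzero(~informative)
        raise ValueError(f"degenerate alignment columns (no unambiguous "
                         f"base): {bad[:10].tolist()}")


def fit_or_load_model(bundle: ReferenceBundle,
                      config: dict | None = None,
                      fit_rate_variation: bool = True) -> GTRModel:
    """Return model parameters, from a config dict or by ML estimation.

    Estimation maximizes the reference-tree likelihood with fixed topology
    and branch lengths over exchangeabilities (GT fixed at 1), base
    frequencies, and -- when ``fit_rate_variation`` -- the gamma shape and
    invariant-sites proportion.
    """
    if config is not None:
        return GTRModel.from_dict(config)
    _check_alignment(bundle.alignment)
    tree = bundle.tree

    def unpack(x):
        exch = np.concatenate([np.exp(x[:5]), [1.0]])
        w = np.concatenate([np.exp(x[5:8]), [1.0]])
        freqs = w / w.sum()
        if fit_rate_variation:
            shape = float(np.exp(x[8]))
            p_inv = float(1.0 / (1.0 + np.exp(-x[9])) * 0.5)
        else:
            shape, p_inv = 1.0, 0.0
        return GTRModel(exch, freqs, shape, p_inv)

    def nll(x):
        try:
            model = unpack(x)
            return -PruningEngine(tree, model, bundle.alignment).log_likelihood()
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    n = 10 if fit_rate_variation else 8
    x0 = np.zeros(n)
    x0[5:8] = 0.0
    if fit_rate_variation:
        x0[8] = 0.0      # shape = 1
        x0[9] = -2.0     # p_inv ~ 0.06
    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": 500, "eps": 1e-6, "ftol": 1e-12,
                            "gtol": 1e-8})
    return unpack(res.x)


# ---------------------------------------------------------------------------
# placement


def place_query(query: str, bundle: ReferenceBundle, model: GTRModel,
                engine: PruningEngine | None = None,
                keep_mass: float = 0.99, optimize: bool = True,
                query_id: str = "query") -> list[Placement]:
    """Place one aligned query; returns placements sorted by LWR.

    Edges are retained (best first) until their cumulative LWR reaches
    ``keep_mass``; LWRs are normalised over *all* edges, so the retained
    total lies in [keep_mass, 1].
    """
    if engine is None:
        engine = PruningEngine(bundle.tree, model, bundle.alignment)
    if len(query) != engine.n_cols:
        raise ValueError(f"query has {len(query)} columns, reference "
                         f"alignment has {engine.n_cols}")
    tree = bundle.tree
    qtip = tip_partial(query)
    pend0 = float(np.mean(tree.blen[tree.blen > 0])) if \
        np.any(tree.blen > 0) else 0.05
    n_edges = tree.n_edges
    logliks = np.empty(n_edges)
    pos = np.empty((n_edges, 2))  # distal, pendant
    for e in range(n_edges):
        t = tree.blen[tree.node_of_edge[e]]
        logliks[e] = engine.grafted_log_likelihood(qtip, e, t / 2.0, pend0)
        pos[e] = (t / 2.0, pend0)
    if optimize:
        for e in _edges_to_refine(logliks, keep_mass):
            logliks[e], pos[e] = _refine(engine, qtip, e, pend0)
    lwr = np.exp(logliks - logliks.max())
    lwr /= lwr.sum()
    order = np.argsort(-lwr, kind="stable")
    out, cum = [], 0.0
    for e in order:
        v = tree.node_of_edge[e]
        out.append(Placement(int(e), float(logliks[e]), float(lwr[e]),
                             float(pos[e][0]), float(pos[e][1])))
        cum += lwr[e]
        if cum >= keep_mass:
            break
    return out


def _edges_to_refine(logliks: np.ndarray, keep_mass: float,
                     minimum: int = 3) -> np.ndarray:
    lwr = np.exp(logliks - logliks.max())
    lwr /= lwr.sum()
    order = np.argsort(-lwr, kind="stable")
    cum = np.cumsum(lwr[order])
    k = int(np.searchsorted(cum, keep_mass) + 1)
    return order[:max(k, min(minimum, len(order)))]


def _refine(engine: PruningEngine, qtip, edge: int, pend0: float,
            rounds: int = 2, tol: float = 1e-6):
    tree = engine.tree
    t = float(tree.blen[tree.node_of_edge[edge]])
    distal, pendant = t / 2.0, pend0
    for _ in range(rounds):
        if t > 0:
            res = minimize_scalar(
                lambda d: -engine.grafted_log_likelihood(qtip, edge, d, pendant),
                bounds=(0.0, t), method="bounded",
                options={"xatol": tol})
            distal = float(res.x)
        res = minimize_scalar(
            lambda p: -engine.grafted_log_likelihood(qtip, edge, distal, p),
            bounds=(1e-9, 3.0), method="bounded", options={"xatol": tol})
        pendant = float(res.x)
    ll = engine.grafted_log_likelihood(qtip, edge, distal, pendant)
    return ll, (distal, pendant)


def place_queries(queries: dict[str, str], bundle: ReferenceBundle,
                  model: GTRModel, keep_mass: float = 0.99,
                  optimize: bool = True) -> PlacementSet:
    engine = PruningEngine(bundle.tree, model, bundle.alignment)
    out = PlacementSet()
    for name, seq in queries.items():
        out[name] = place_query(seq, bundle, model, engine=engine,
                                keep_mass=keep_mass, optimize=optimize,
                                query_id=name)
    return out


# ---------------------------------------------------------------------------
# jplace


def write_jplace(placements: PlacementSet, bundle: ReferenceBundle, path):
    doc = {
        "version": 3,
        "tree": bundle.tree.to_newick(edge_tags=True),
        "fields": JPLACE_FIELDS,
        "placements": [
            {"p": [[p.edge_num, p.log_likelihood, p.like_weight_ratio,
                    p.distal_length, p.pendant_length] for p in plist],
             "n": [name]}
            for name, plist in placements.items()
        ],
        "metadata": {"invocation": "glomesieve placement"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_jplace(path) -> tuple[PlacementSet, Tree]:
    with open(path) as fh:
        doc = json.load(fh)
    fields = doc["fields"]
    idx = {f: fields.index(f) for f in JPLACE_FIELDS}
    tree = Tree.from_newick(doc["tree"])
    out = PlacementSet()
    for entry in doc["placements"]:
        names = entry.get("n") or [nm[0] for nm in entry["nm"]]
        plist = [Placement(int(row[idx["edge_num"]]),
                           float(row[idx["likelihood"]]),
                           float(row[idx["like_weight_ratio"]]),
                           float(row[idx["distal_length"]]),
                           float(row[idx["pendant_length"]]))
                 for row in entry["p"]]
        plist.sort(key=lambda p: -p.like_weight_ratio)
        for name in names:
            out[name] = plist
    return out, tree
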