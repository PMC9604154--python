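"""Phylogeny-aware beta diversity on per-sample placement mass trees.

A mass tree assigns each tree edge the summed likelihood weight of the
sample's query placements (optionally weighted by read multiplicity).
Downstream: edge-imbalance PCA, k-means of imbalance vectors, per-edge
Spearman correlation with soil covariates, and placement-factorization
(phylofactorization of balances under a Gaussian GLM).

Sign conventions: the imbalance of an edge is (mass distal to the edge,
including the edge's own mass) minus (mass proximal), with the jplace root
as the proximal reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .phylo import Tree
from .placement import PlacementSet, read_jplace


@dataclass
class MassTreeSet:
    """Per-sample edge-mass vectors over one shared reference tree."""

    tree: Tree
    masses: pd.DataFrame  # samples x edges (columns are edge numbers)

    def normalized(self) -> "MassTreeSet":
        totals = self.masses.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("sample with zero total mass")
        return MassTreeSet(self.tree, self.masses.div(totals, axis=0))

    def total_mass(self) -> pd.Series:
        return self.masses.sum(axis=1)


def build_mass_trees(jplace_by_sample: dict, tree: Tree | None = None,
                     normalize: bool = False) -> MassTreeSet:
    """Accumulate per-edge LWR mass per sample.

    ``jplace_by_sample`` maps sample -> jplace path or PlacementSet (a dict,
    or an iterable of (sample, source) pairs). All files must share one tree
    (verified by the tagged newick string). Masses from repeated samples are
    added.
    """
    rows: dict[str, np.ndarray] = {}
    ref_newick = tree.to_newick(edge_tags=True) if tree is not None else None
    items = (jplace_by_sample.items() if isinstance(jplace_by_sample, dict)
             else jplace_by_sample)
    for sample, src in items:
        if isinstance(src, PlacementSet):
            pset, t = src, tree
            if t is None:
                raise ValueError("tree required with PlacementSet input")
        else:
            pset, t = read_jplace(src)
            nwk = t.to_newick(edge_tags=True)
            if ref_newick is None:
                ref_newick, tree = nwk, t
            elif nwk != ref_newick:
                raise ValueError(f"jplace tree mismatch for sample {sample}")
        vec = rows.get(sample)
        if vec is None:
            vec = rows[sample] = np.zeros(tree.n_edges)
        for plist in pset.values():
            for p in plist:
                vec[p.edge_num] += p.like_weight_ratio
    masses = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=range(tree.n_edges))
    masses.index.name = "sample"
    out = MassTreeSet(tree, masses)
    return out.normalized() if normalize else out


def mass_trees_from_counts(placements: PlacementSet, tree: Tree,
                           counts: pd.DataFrame,
                           normalize: bool = False) -> MassTreeSet:
    """Multiplicity-weighted mass trees: each placed unit contributes its
    LWR vector times its per-sample count (samples x units table)."""
    lwr = np.zeros((len(counts.columns), tree.n_edges))
    for j, unit in enumerate(counts.columns):
        for p in placements[unit]:
            lwr[j, p.edge_num] += p.like_weight_ratio
    masses = pd.DataFrame(counts.to_numpy(dtype=float) @ lwr,
                          index=counts.index, columns=range(tree.n_edges))
    masses.index.name = "sample"
    out = MassTreeSet(tree, masses)
    return out.normalized() if normalize else out


# ---------------------------------------------------------------------------
# imbalance


def edge_imbalance(mts: MassTreeSet) -> pd.DataFrame:
    """Per-edge imbalance of unit-normalised samples: distal minus proximal
    mass, the edge's own mass counting as distal."""
    norm = mts.normalized()
    x = norm.masses.to_numpy(dtype=float)
    tree = mts.tree
    out = np.empty_like(x)
    for e in range(tree.n_edges):
        distal = tree.subtree_edges(e)
        m = x[:, distal].sum(axis=1)
        out[:, e] = m - (1.0 - m)
    return pd.DataFrame(out, index=mts.masses.index,
                        columns=mts.masses.columns)


@dataclass
class EdgePCAResult:
    coordinates: pd.DataFrame       # samples x components
    loadings: pd.DataFrame          # edges x components
    explained_variance_ratio: np.ndarray


def edge_pca(mts: MassTreeSet, components: int = 2) -> EdgePCAResult:
    """PCA (via SVD) of the centered edge-imbalance matrix."""
    imb = edge_imbalance(mts)
    n = len(imb)
    if n < components + 1:
        raise ValueError("need more samples than components")
    x = imb.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    evr = (s[:components] ** 2) / total if total > 0 else \
        np.zeros(components)
    coords = u[:, :components] * s[:components]
    cols = [f"PC{i + 1}" for i in range(components)]
    return EdgePCAResult(
        pd.DataFrame(coords, index=imb.index, columns=cols),
        pd.DataFrame(vt[:components].T, index=imb.columns, columns=cols),
        evr)


def imbalance_kmeans(mts: MassTreeSet, k: int = 8, seed: int = 0,
                     restarts: int = 50,
                     groups: pd.Series | None = None):
    """k-means++ clustering of edge-imbalance vectors.

    Returns (assignments, inertia, contingency) -- contingency is the
    group-by-cluster table when ``groups`` is given, else None.
    """
    from sklearn.cluster import KMeans
    imb = edge_imbalance(mts)
    if k > len(imb):
        raise ValueError("k exceeds the number of samples")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(imb.to_numpy(dtype=float))
    assignments = pd.Series(labels, index=imb.index, name="cluster")
    contingency = None
    if groups is not None:
        contingency = pd.crosstab(groups.loc[imb.index], assignments)
    return assignments, float(km.inertia_), contingency


# ---------------------------------------------------------------------------
# per-edge metadata correlation


def edge_correlation(mts: MassTreeSet, metadata: pd.DataFrame,
                     permutations: int = 999, seed: int = 0) -> dict:
    """Spearman rho of normalised edge mass vs each covariate, with a
    label-permutation p per edge and BH correction across edges.

    Constant edges or covariates give missing (NaN) correlations.
    """
    common = mts.masses.index.intersection(metadata.index)
    if len(common) < 4:
        raise ValueError("need >= 4 samples with metadata")
    norm = mts.normalized().masses.loc[common]
    meta = metadata.loc[common]
    x = norm.to_numpy(dtype=float)
    n, n_edges = x.shape
    edge_const = np.ptp(x, axis=0) == 0
    rx = rankdata(x, axis=0)
    rx_c = rx - rx.mean(axis=0)
    rx_norm = np.sqrt((rx_c ** 2).sum(axis=0))
    rng = np.random.default_rng(seed)
    out = {}
    for var in meta.columns:
        v = meta[var].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            out[var] = pd.DataFrame(
                {"rho": np.nan, "p": np.nan, "q": np.nan},
                index=norm.columns)
            continue
        rv = rankdata(v)
        rv_c = rv - rv.mean()
        rv_norm = np.sqrt((rv_c ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rx_c.T @ rv_c) / (rx_norm * rv_norm)
        rho[edge_const] = np.nan
        perm_hits = np.zeros(n_edges)
        for _ in range(permutations):
            pv = rv_c[rng.permutation(n)]
            with np.errstate(invalid="ignore", divide="ignore"):
                rho_p = (rx_c.T @ pv) / (rx_norm * rv_norm)
            perm_hits += np.abs(rho_p) >= np.abs(rho) - 1e-12
        p = (perm_hits + 1) / (permutations + 1)
        p[edge_const | np.isnan(rho)] = np.nan
        q = np.full(n_edges, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out[var] = pd.DataFrame({"rho": rho, "p": p, "q": q},
                                index=norm.columns)
    return out


# ---------------------------------------------------------------------------
# placement-factorization


@dataclass
class Factor:
    edge: int
    balances: pd.Series          # per sample
    deviance_fraction: float     # (null - fitted deviance) / null deviance
    coefficients: pd.Series
    p_values: pd.Series


@dataclass
class PhyloFactorResult:
    factors: list
    pseudocount: float

    @property
    def winning_edges(self) -> list[int]:
        return [f.edge for f in self.factors]

    def balance_matrix(self) -> pd.DataFrame:
        return pd.DataFrame({f"F{i + 1}": f.balances
                             for i, f in enumerate(self.factors)})


def _balance(x: np.ndarray, distal_idx, proximal_idx,
             pseudocount: float) -> np.ndarray:
    """Isometric log-ratio of geometric-mean masses across an edge split."""
    nd, npx = len(distal_idx), len(proximal_idx)
    logm = np.log(x + pseudocount)
    gd = logm[:, distal_idx].mean(axis=1)
    gp = logm[:, proximal_idx].mean(axis=1)
    return np.sqrt(nd * npx / (nd + npx)) * (gd - gp)


def placement_factorization(mts: MassTreeSet, metadata: pd.DataFrame,
                            n_factors: int = 3,
                            pseudocount: float | None = None
                            ) -> PhyloFactorResult:
    """Iteratively select the edges whose balances the covariates explain
    best under an ordinary (Gaussian, identity link) GLM.

    Each factor's winning edge splits its tree region in two; later factors
    search only within regions not yet separated. The objective is the
    fraction of null deviance explained by the fitted model.
    """
    import statsmodels.api as sm
    common = mts.masses.index.intersection(metadata.index)
    norm = mts.normalized().masses.loc[common]
    meta = metadata.loc[common].astype(float)
    design = sm.add_constant(meta)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = meta.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if not corr.empty else ("?", "?")
        raise ValueError(f"rank-deficient design matrix; check collinear "
                         f"columns {worst}")
    x = norm.to_numpy(dtype=float)
    if pseudocount is None:
        nz = x[x > 0]
        if nz.size == 0:
            raise ValueError("all masses are zero")
        pseudocount = 0.65 * float(nz.min())
    tree = mts.tree
    all_edges = list(range(tree.n_edges))
    subtree = {e: set(tree.subtree_edges(e)) for e in all_edges}
    blocks = [set(all_edges)]
    factors = []
    for _ in range(n_factors):
        best = None
        for bi, block in enumerate(blocks):
            if len(block) < 2:
                continue
            for e in sorted(block):
                distal = sorted(subtree[e] & block)
                proximal = sorted(block - subtree[e])
                if not distal or not proximal:
                    continue
                y = _balance(x, distal, proximal, pseudocount)
                tss = float(((y - y.mean()) ** 2).sum())
                if tss == 0:
                    continue
                fit = sm.OLS(y, design).fit()
                objective = 1.0 - float(fit.ssr) / tss
                if best is None or objective > best[0]:
                    best = (objective, e, bi, distal, proximal, y, fit)
        if best is None:
            break
        objective, e, bi, distal, proximal, y, fit = best
        factors.append(Factor(
            e, pd.Series(y, index=norm.index),
            objective,
            pd.Series(fit.params.to_numpy(), index=design.columns),
            pd.Series(fit.pvalues.to_numpy(), index=design.columns)))
        block = blocks.pop(bi)
        blocks.append(set(distal) - {e})
        blocks.append(set(proximal))
    return PhyloFactorResult(factors, pseudocount)
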