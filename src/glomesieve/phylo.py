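"""Phylogenetic core: trees with jplace edge numbering, GTR+Gamma+I likelihoods.

The tree is stored in flat arrays indexed by node id. Every non-root node
``v`` owns the edge between ``v`` and its parent; edges are therefore
identified by their child node. jplace edge numbers are assigned in the
order the edge tags appear in the emitted newick string (children before
their parent, left to right), which makes the numbering reproducible and
bijective over edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincinv, gammainc

DNA_STATES = "ACGT"
# IUPAC nucleotide codes as bit masks over (A, C, G, T)
IUPAC_MASKS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b1111, ".": 0b1111,
}


def tip_partial(sequence: str) -> np.ndarray:
    """(ncols, 4) indicator partials for a tip sequence; gaps/N are all-ones."""
    out = np.zeros((len(sequence), 4))
    for i, ch in enumerate(sequence.upper()):
        mask = IUPAC_MASKS.get(ch)
        if mask is None:
            raise ValueError(f"non-IUPAC character {ch!r} at column {i}")
        for s in range(4):
            if mask >> s & 1:
                out[i, s] = 1.0
    return out


class Tree:
    """Rooted tree in array form; the root may be multifurcating.

    Attributes
    ----------
    parent : parent node id per node (-1 for root)
    children : list of child ids per node
    blen : branch length of the edge above each node (0 for root)
    name : leaf label per node ('' for internals unless named)
    edge_num : jplace edge number of the edge above each node (-1 for root)
    """

    def __init__(self, parent, blen, names):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for v, p in enumerate(self.parent):
            if p < 0:
                root = v
            else:
                self.children[p].append(v)
        if root < 0:
            raise ValueError("tree has no root")
        self.root = root
        self.name = list(names)
        self._assign_edge_numbers()

    # -- structure ---------------------------------------------------------

    def _assign_edge_numbers(self):
        self.edge_num = np.full(len(self.parent), -1, dtype=int)
        counter = [0]

        def visit(v):
            for c in self.children[v]:
                visit(c)
                self.edge_num[c] = counter[0]
                counter[0] += 1

        visit(self.root)
        self.node_of_edge = np.full(counter[0], -1, dtype=int)
        for v, e in enumerate(self.edge_num):
            if e >= 0:
                self.node_of_edge[e] = v

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_edges(self) -> int:
        return len(self.node_of_edge)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_leaf(v)]

    def leaf_names(self) -> list[str]:
        return [self.name[v] for v in self.leaves]

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def subtree_nodes(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def subtree_leaves(self, v: int) -> list[int]:
        return [u for u in self.subtree_nodes(v) if self.is_leaf(u)]

    def subtree_edges(self, edge: int) -> list[int]:
        """Edges in the clade distal to ``edge``, including ``edge`` itself."""
        v = self.node_of_edge[edge]
        return [int(self.edge_num[u]) for u in self.subtree_nodes(v)
                if self.edge_num[u] >= 0]

    # -- newick ------------------------------------------------------------

    def to_newick(self, edge_tags: bool = False) -> str:
        def fmt(v):
            if self.is_leaf(v):
                s = self.name[v]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
                if self.name[v]:
                    s += self.name[v]
            if v != self.root:
                s += f":{self.blen[v]:.10g}"
                if edge_tags:
                    s += "{%d}" % self.edge_num[v]
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse newick, optionally carrying jplace {edge_num} tags.

        Edge numbers present in the string are validated against the
        numbering this class would assign (they must agree, since numbering
        follows the order of appearance in the string).
        """
        text = text.strip().rstrip(";")
        parent, blen, names, tags = [], [], [], []

        def new_node(p):
            parent.append(p)
            blen.append(0.0)
            names.append("")
            tags.append(-1)
            return len(parent) - 1

        root = new_node(-1)
        cur = root
        i = 0
        n = len(text)
        while i < n:
            ch = text[i]
            if ch == "(":
                cur = new_node(cur)
                i += 1
            elif ch == ",":
                cur = new_node(parent[cur])
                i += 1
            elif ch == ")":
                cur = parent[cur]
                i += 1
            else:
                j = i
                while j < n and text[j] not in "(),":
                    j += 1
                token = text[i:j]
                label = token
                if "{" in token:
                    label, tag = token.split("{", 1)
                    tags[cur] = int(tag.rstrip("}"))
                if ":" in label:
                    label, bl = label.rsplit(":", 1)
                    blen[cur] = float(bl)
                if label:
                    names[cur] = label
                i = j
        order = _reindex_preorder(parent)
        remap = {old: new for new, old in enumerate(order)}
        n_nodes = len(parent)
        par2 = [0] * n_nodes
        bl2 = [0.0] * n_nodes
        nm2 = [""] * n_nodes
        for old, new in remap.items():
            par2[new] = remap[parent[old]] if parent[old] >= 0 else -1
            bl2[new] = blen[old]
            nm2[new] = names[old]
        tree = cls(par2, bl2, nm2)
        for old, tag in enumerate(tags):
            if tag >= 0 and tree.edge_num[remap[old]] != tag:
                raise ValueError("edge numbering in newick tags is not the "
                                 "order-of-appearance numbering")
        return tree


def _reindex_preorder(parent):
    children = {}
    root = 0
    for v, p in enumerate(parent):
        if p < 0:
            root = v
        else:
            children.setdefault(p, []).append(v)
    order, stack = [], [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children.get(v, [])))
    return order


def random_bifurcating_tree(n_taxa: int, rng: np.random.Generator,
                            mean_blen: float = 0.1) -> Tree:
    """Random unrooted-style binary tree (trifurcating root), 2n-3 edges.

    Built by sequential random attachment; branch lengths are Exp(mean_blen).
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    # start from a 3-leaf star, then split random edges
    parent = [-1, 0, 0, 0]
    leaves = [1, 2, 3]
    for _ in range(n_taxa - 3):
        # pick a random non-root node, break its parent edge with a new node
        v = int(rng.integers(1, len(parent)))
        u = parent[v]
        mid = len(parent)
        parent.append(u)          # mid
        parent[v] = mid
        leaf = len(parent)
        parent.append(mid)        # new leaf
        leaves.append(leaf)
    n_nodes = len(parent)
    blen = rng.exponential(mean_blen, size=n_nodes)
    blen[0] = 0.0
    names = [""] * n_nodes
    leafset = set(range(n_nodes)) - set(parent)
    for k, v in enumerate(sorted(leafset)):
        names[v] = f"t{k + 1}"
    order = _reindex_preorder(parent)
    remap = {old: new for new, old in enumerate(order)}
    par2 = [0] * n_nodes
    bl2 = [0.0] * n_nodes
    nm2 = [""] * n_nodes
    for old, new in remap.items():
        par2[new] = remap[parent[old]] if parent[old] >= 0 else -1
        bl2[new] = float(blen[old])
        nm2[new] = names[old]
    return Tree(par2, bl2, nm2)


# ---------------------------------------------------------------------------
# substitution model


@dataclass
class GTRModel:
    """GTR+Gamma(+I) nucleotide model.

    ``exchangeabilities`` are the six symmetric rates in the order
    AC, AG, AT, CG, CT, GT; ``freqs`` the stationary base frequencies
    (A, C, G, T). ``gamma_shape`` controls among-site rate variation with
    ``n_categories`` equal-probability discrete categories (category rate =
    mean of its quantile slice); ``p_inv`` adds a zero-rate invariant class.
    Rates are normalised so the expected substitution rate over the full
    mixture is 1 per unit branch length.
    """

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    gamma_shape: float = 1.0
    p_inv: float = 0.0
    n_categories: int = 4

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        self.freqs = np.asarray(self.freqs, float)
        if self.exchangeabilities.shape != (6,):
            raise ValueError("expected 6 exchangeabilities")
        if np.any(self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("frequencies must be 4 positive values")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")
        self.freqs = self.freqs / self.freqs.sum()
        self._decompose()

    @classmethod
    def jukes_cantor(cls, gamma_shape: float = 1.0, p_inv: float = 0.0):
        return cls(np.ones(6), np.full(4, 0.25), gamma_shape, p_inv)

    def _q_matrix(self) -> np.ndarray:
        s = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.exchangeabilities, idx):
            s[i, j] = s[j, i] = r
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise: mean instantaneous rate of the variable class is scaled
        # so the whole mixture (including the invariant class) has rate 1
        mu = -np.sum(self.freqs * np.diag(q))
        q /= mu * (1.0 - self.p_inv)
        return q

    def _decompose(self):
        q = self._q_matrix()
        pi_sqrt = np.sqrt(self.freqs)
        b = (q * pi_sqrt[:, None]) / pi_sqrt[None, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        self._eval = w
        self._evec = u / pi_sqrt[:, None]
        self._ivec = u.T * pi_sqrt[None, :]

    def category_rates(self) -> np.ndarray:
        """Rates of the discrete classes: gamma categories then (optionally) 0."""
        a = self.gamma_shape
        k = self.n_categories
        qs = gammaincinv(a, np.arange(k + 1) / k) / a
        # mean of X ~ Gamma(a, scale=1/a) over each quantile slice
        upper = gammainc(a + 1, a * qs[1:])
        lower = gammainc(a + 1, a * qs[:-1])
        rates = (upper - lower) * k
        rates = rates / rates.mean()
        if self.p_inv > 0:
            return np.concatenate([rates, [0.0]])
        return rates

    def category_weights(self) -> np.ndarray:
        k = self.n_categories
        if self.p_inv > 0:
            return np.concatenate([np.full(k, (1 - self.p_inv) / k),
                                   [self.p_inv]])
        return np.full(k, 1.0 / k)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        if rate == 0.0 or t == 0.0:
            return np.eye(4)
        p = (self._evec * np.exp(self._eval * rate * t)) @ self._ivec
        return np.clip(p, 0.0, None)

    def to_dict(self) -> dict:
        return {
            "exchangeabilities": self.exchangeabilities.tolist(),
            "freqs": self.freqs.tolist(),
            "gamma_shape": float(self.gamma_shape),
            "p_inv": float(self.p_inv),
            "n_categories": int(self.n_categories),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GTRModel":
        return cls(np.asarray(d["exchangeabilities"], float),
                   np.asarray(d["freqs"], float),
                   float(d.get("gamma_shape", 1.0)),
                   float(d.get("p_inv", 0.0)),
                   int(d.get("n_categories", 4)))


# ---------------------------------------------------------------------------
# likelihood machinery


class PruningEngine:
    """Felsenstein pruning over a Tree with per-node log rescaling.

    Down-partials (conditional likelihood of the clade below each node,
    given the node state) are cached per rate category so grafted queries
    only recompute the attachment-to-root path.
    """

    def __init__(self, tree: Tree, model: GTRModel,
                 alignment: dict[str, str]):
        self.tree = tree
        self.model = model
        leaves = tree.leaves
        lengths = {len(s) for s in alignment.values()}
        if len(lengths) != 1:
            raise ValueError("reference alignment rows differ in length")
        self.n_cols = lengths.pop()
        missing = [tree.name[v] for v in leaves if tree.name[v] not in alignment]
        if missing:
            raise ValueError(f"alignment missing leaves: {missing}")
        self.tips = {v: tip_partial(alignment[tree.name[v]]) for v in leaves}
        self.rates = model.category_rates()
        self.weights = model.category_weights()
        self._down()

    def _p(self, t: float, c: int) -> np.ndarray:
        return self.model.transition_matrix(t, self.rates[c])

    def _down(self):
        """Cache down partials D[c][v] (ncols,4) and log-scales S[c][v]."""
        tree, ncat = self.tree, len(self.rates)
        self.D = [dict() for _ in range(ncat)]
        self.S = [dict() for _ in range(ncat)]
        for c in range(ncat):
            for v in tree.postorder():
                if tree.is_leaf(v):
                    self.D[c][v] = self.tips[v]
                    self.S[c][v] = np.zeros(self.n_cols)
                    continue
                part = np.ones((self.n_cols, 4))
                scale = np.zeros(self.n_cols)
                for ch in tree.children[v]:
                    part = part * (self.D[c][ch] @ self._p(tree.blen[ch], c).T)
                    scale += self.S[c][ch]
                colmax = part.max(axis=1)
                colmax[colmax == 0] = 1.0
                self.D[c][v] = part / colmax[:, None]
                self.S[c][v] = scale + np.log(colmax)

    def _site_logliks(self, root_parts, root_scales) -> np.ndarray:
        """Combine per-category root partials into per-site log-likelihoods."""
        logs = []
        for c, (part, scale) in enumerate(zip(root_parts, root_scales)):
            lc = part @ self.model.freqs
            with np.errstate(divide="ignore"):
                logs.append(np.log(self.weights[c]) + np.log(lc) + scale)
        m = np.max(logs, axis=0)
        out = m + np.log(np.sum(np.exp(np.array(logs) - m), axis=0))
        return out

    def log_likelihood(self) -> float:
        parts = [self.D[c][self.tree.root] for c in range(len(self.rates))]
        scales = [self.S[c][self.tree.root] for c in range(len(self.rates))]
        return float(self._site_logliks(parts, scales).sum())

    def grafted_log_likelihood(self, query_tip: np.ndarray, edge: int,
                               distal: float, pendant: float) -> float:
        """Log-likelihood with a query grafted onto ``edge``.

        ``distal`` is the distance from the attachment point to the edge's
        child (distal) node; the pendant branch carries the query tip.
        """
        tree = self.tree
        v = tree.node_of_edge[edge]
        t = tree.blen[v]
        distal = min(max(distal, 0.0), t)
        path = []
        u = v
        while u != tree.root:
            u = tree.parent[u]
            path.append(u)
        parts, scales = [], []
        for c in range(len(self.rates)):
            # attachment node: children are v (length `distal`) and the query
            a = (self.D[c][v] @ self._p(distal, c).T) * \
                (query_tip @ self._p(pendant, c).T)
            s = self.S[c][v].copy()
            colmax = a.max(axis=1)
            colmax[colmax == 0] = 1.0
            a /= colmax[:, None]
            s += np.log(colmax)
            # replace edge (u,v) by (u,a) with remaining length t - distal
            child, child_part, child_scale, child_len = v, a, s, t - distal
            for u in path:
                part = np.ones((self.n_cols, 4))
                scale = np.zeros(self.n_cols)
                for ch in tree.children[u]:
                    if ch == child:
                        part = part * (child_part @ self._p(child_len, c).T)
                        scale += child_scale
                    else:
                        part = part * (self.D[c][ch] @
                                       self._p(tree.blen[ch], c).T)
                        scale += self.S[c][ch]
                colmax = part.max(axis=1)
                colmax[colmax == 0] = 1.0
                part /= colmax[:, None]
                scale += np.log(colmax)
                child, child_part, child_scale = u, part, scale
                child_len = tree.blen[u]
            parts.append(child_part)
            scales.append(child_scale)
        return float(self._site_logliks(parts, scales).sum())


# ---------------------------------------------------------------------------
# sequence simulation


def simulate_alignment(tree: Tree, model: GTRModel, n_cols: int,
                       rng: np.random.Generator) -> dict[str, str]:
    """Evolve a root sequence down the tree; substitutions only, no indels.

    Each column draws one rate class (gamma category or invariant) shared
    across the whole tree, matching the likelihood model.
    """
    rates = model.category_rates()
    weights = model.category_weights()
    cat = rng.choice(len(rates), size=n_cols, p=weights)
    states = {tree.root: rng.choice(4, size=n_cols, p=model.freqs)}
    order = tree.postorder()[::-1]  # preorder
    for v in order:
        if v == tree.root:
            continue
        pstate = states[tree.parent[v]]
        child = np.empty(n_cols, dtype=int)
        for c in range(len(rates)):
            sel = cat == c
            if not sel.any():
                continue
            p = model.transition_matrix(tree.blen[v], rates[c])
            cum = p.cumsum(axis=1)
            u = rng.random(sel.sum())
            child[sel] = (u[:, None] > cum[pstate[sel]]).sum(axis=1)
        states[v] = child
    base = np.array(list(DNA_STATES))
    return {tree.name[v]: "".join(base[states[v]]) for v in tree.leaves}
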