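"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: primer sites by a
position-by-position Hamming/IUPAC scan, tree likelihoods by naive pruning
over nested tuples with expm transition matrices and no rescaling.
"""

import numpy as np
from scipy.linalg import expm

from glomesieve.phylo import IUPAC_MASKS, tip_partial
from glomesieve.primer_scan import reverse_complement

IUPAC_SETS = {c: {b for b in "ACGT" if IUPAC_MASKS[c] & IUPAC_MASKS[b]}
              for c in IUPAC_MASKS if c not in "-."}


def oracle_sites(template, primer, strand="plus"):
    """Exhaustive binding-site scan honouring the 3'-protected zone."""
    pat = primer.sequence if strand == "plus" else \
        reverse_complement(primer.sequence)
    if strand == "plus":
        protected = set(range(len(pat) - primer.protected_3prime, len(pat)))
    else:
        protected = set(range(primer.protected_3prime))
    out = []
    for start in range(len(template) - len(pat) + 1):
        mism = 0
        ok = True
        for i, pc in enumerate(pat):
            if template[start + i] not in IUPAC_SETS[pc]:
                if i in protected:
                    ok = False
                    break
                mism += 1
                if mism > primer.max_mismatches:
                    ok = False
                    break
        if ok:
            out.append((start, mism))
    return out


def oracle_q(model):
    s = np.zeros((4, 4))
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for r, (i, j) in zip(model.exchangeabilities, idx):
        s[i, j] = s[j, i] = r
    q = s * model.freqs[None, :]
    np.fill_diagonal(q, -q.sum(axis=1) + np.diag(q))
    mu = -np.sum(model.freqs * np.diag(q))
    return q / (mu * (1.0 - model.p_inv))


def naive_loglik(nested, model, seqs):
    """Naive pruning log-likelihood; nested = leaf name or
    [(child, branch_length), ...]."""
    q = oracle_q(model)
    rates = model.category_rates()
    weights = model.category_weights()
    ncols = len(next(iter(seqs.values())))
    tips = {name: tip_partial(s) for name, s in seqs.items()}

    def partial(node, rate, col):
        if isinstance(node, str):
            return tips[node][col]
        vec = np.ones(4)
        for child, bl in node:
            p = np.eye(4) if rate == 0 else expm(q * rate * bl)
            vec = vec * (p @ partial(child, rate, col))
        return vec

    total = 0.0
    for col in range(ncols):
        site = sum(w * float(model.freqs @ partial(nested, r, col))
                   for r, w in zip(rates, weights))
        total += np.log(site)
    return total


def tree_to_nested(tree, graft_edge=None, distal=None, pendant=None,
                   query_name=None):
    """Nested-tuple view of a Tree, optionally with a grafted query."""
    gv = tree.node_of_edge[graft_edge] if graft_edge is not None else -1

    def conv(v):
        if tree.is_leaf(v):
            return tree.name[v]
        return [branch(c) for c in tree.children[v]]

    def branch(v):
        sub = conv(v)
        bl = float(tree.blen[v])
        if v == gv:
            attach = [(sub, distal), (query_name, pendant)]
            return (attach, bl - distal)
        return (sub, bl)

    return conv(tree.root)
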