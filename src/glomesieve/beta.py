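"""Beta diversity on species composition.

Yue-Clayton dissimilarity drives NMDS ordination, AMOVA (permutation
pseudo-F on squared distances) and HOMOVA (Bartlett-style homogeneity of
within-group dispersion). Metastats tests per-unit differential abundance
between two groups (permutation t-test, Fisher's exact for sparse units,
Benjamini-Hochberg q-values). A Dirichlet-multinomial mixture (DMM)
partitions samples into metacommunities, with the number of components
selected by Laplace-approximated model evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi, logsumexp
from scipy.stats import spearmanr, fisher_exact
from statsmodels.stats.multitest import multipletests


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=1)
    if (totals == 0).any():
        bad = list(table.index[totals == 0])
        raise ValueError(f"all-zero samples: {bad}")
    return table.div(totals, axis=0)


def yue_clayton(table: pd.DataFrame) -> pd.DataFrame:
    """1 - theta_YC: theta = sum(a b) / (sum a^2 + sum b^2 - sum a b)."""
    x = relative_abundance(table).to_numpy(dtype=float)
    cross = x @ x.T
    sq = np.sum(x ** 2, axis=1)
    denom = sq[:, None] + sq[None, :] - cross
    with np.errstate(invalid="ignore"):
        theta = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 1.0)
    d = 1.0 - theta
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# AMOVA / HOMOVA


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Within-group sums of squared distances per group (mothur convention:
    sum over pairs divided by group size)."""
    groups = np.unique(labels)
    ss = np.empty(len(groups))
    sizes = np.empty(len(groups), dtype=int)
    for k, g in enumerate(groups):
        idx = np.flatnonzero(labels == g)
        sizes[k] = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss[k] = sub.sum() / (2.0 * len(idx))
    return float(ss.sum()), ss, sizes


def _validate_groups(dist: pd.DataFrame, groups: pd.Series):
    groups = groups.loc[dist.index]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"groups with a single sample: {small}")
    return groups


def amova(dist: pd.DataFrame, groups: pd.Series, permutations: int = 1000,
          seed: int = 0) -> tuple[float, float]:
    """Non-parametric AMOVA: permutation pseudo-F from squared distances."""
    groups = _validate_groups(dist, groups)
    d2 = dist.to_numpy(dtype=float) ** 2
    labels = groups.to_numpy()
    n = len(labels)
    k = len(np.unique(labels))
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(lab):
        ss_within, _, _ = _group_ss(d2, lab)
        ss_among = ss_total - ss_within
        return (ss_among / (k - 1)) / (ss_within / (n - k))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if pseudo_f(rng.permutation(labels)) >= f_obs:
            hits += 1
    return float(f_obs), (hits + 1) / (permutations + 1)


def homova(dist: pd.DataFrame, groups: pd.Series, permutations: int = 1000,
           seed: int = 0) -> tuple[float, float]:
    """Bartlett-style test of homogeneity of within-group dispersion."""
    groups = _validate_groups(dist, groups)
    d2 = dist.to_numpy(dtype=float) ** 2
    labels = groups.to_numpy()
    n = len(labels)
    k = len(np.unique(labels))

    def b_stat(lab):
        _, ss, sizes = _group_ss(d2, lab)
        within = ss / (sizes - 1)
        pooled = ss.sum() / (n - k)
        if pooled <= 0 or np.any(within <= 0):
            return 0.0
        return (n - k) * np.log(pooled) - np.sum((sizes - 1) * np.log(within))

    b_obs = b_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if b_stat(rng.permutation(labels)) >= b_obs:
            hits += 1
    return float(b_obs), (hits + 1) / (permutations + 1)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame   # samples x axes, centered, principal-rotated
    stress: float               # Kruskal stress-1
    vectors: pd.DataFrame | None = None  # variable x (rho_axis*, p_axis*)


def kruskal_stress(dist: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with monotone (isotonic) regression of the
    configuration distances on the input dissimilarities."""
    from sklearn.isotonic import IsotonicRegression
    iu = np.triu_indices(len(dist), 1)
    diss = dist[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    conf = np.sqrt((diff ** 2).sum(axis=2))[iu]
    order = np.argsort(diss, kind="stable")
    fitted = np.empty_like(conf)
    fitted[order] = IsotonicRegression().fit_transform(
        np.arange(len(order)), conf[order])
    denom = float((conf ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((conf - fitted) ** 2).sum() / denom))


def nmds(dist: pd.DataFrame, ndim: int = 2, restarts: int = 20,
         seed: int = 0, max_iter: int = 500, tol: float = 1e-7,
         vector_variables: pd.DataFrame | None = None) -> NMDSResult:
    """Non-metric MDS of a distance matrix.

    The best-stress configuration over ``restarts`` random starts is
    centered and rotated to its principal axes. If ``vector_variables`` is
    given (samples x variables: species relative abundances and/or
    metadata), per-axis Spearman rho and p are reported for each variable.
    """
    from sklearn.manifold import MDS
    d = dist.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    if len(dist) < ndim + 1:
        raise ValueError("need at least ndim+1 samples")
    mds = MDS(n_components=ndim, metric=False, dissimilarity="precomputed",
              n_init=restarts, max_iter=max_iter, eps=tol,
              random_state=np.random.RandomState(seed),
              normalized_stress=True)
    coords = mds.fit_transform(d)
    coords = coords - coords.mean(axis=0)
    # rotate to principal axes
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    stress = kruskal_stress(d, coords)
    axes = [f"NMDS{i + 1}" for i in range(ndim)]
    cdf = pd.DataFrame(coords, index=dist.index, columns=axes)
    vectors = None
    if vector_variables is not None:
        rows = {}
        vv = vector_variables.loc[dist.index]
        for var in vv.columns:
            row = {}
            for ax in axes:
                if np.ptp(vv[var].to_numpy(dtype=float)) == 0:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = spearmanr(vv[var], cdf[ax])
                row[f"rho_{ax}"] = rho
                row[f"p_{ax}"] = p
            rows[var] = row
        vectors = pd.DataFrame(rows).T
    return NMDSResult(cdf, stress, vectors)


# ---------------------------------------------------------------------------
# Metastats


def metastats(table: pd.DataFrame, groups: pd.Series,
              permutations: int = 1000, seed: int = 0,
              sparse_threshold: int = 8) -> pd.DataFrame:
    """Differential abundance between two groups.

    Units with pooled counts below ``sparse_threshold`` are tested by
    Fisher's exact test on pooled counts; the rest by a Welch t statistic on
    relative abundances with a label-permutation p-value. q-values are
    Benjamini-Hochberg.
    """
    groups = groups.loc[table.index]
    names = list(pd.unique(groups))
    if len(names) != 2:
        raise ValueError("metastats compares exactly 2 groups")
    if (groups.value_counts() < 2).any():
        raise ValueError("each group needs >= 2 samples")
    present = table.columns[table.sum(axis=0) > 0]
    table = table[present]
    rel = relative_abundance(table)
    mask1 = (groups == names[0]).to_numpy()
    mask2 = ~mask1
    x = rel.to_numpy(dtype=float)
    counts = table.to_numpy(dtype=int)
    rng = np.random.default_rng(seed)

    def welch_t(a, b):
        va = a.var(ddof=1) / len(a)
        vb = b.var(ddof=1) / len(b)
        denom = np.sqrt(va + vb)
        if denom == 0:
            return 0.0
        return (a.mean() - b.mean()) / denom

    rows = []
    perm_masks = [rng.permutation(mask1) for _ in range(permutations)]
    for j, unit in enumerate(table.columns):
        col = x[:, j]
        mean1 = float(col[mask1].mean())
        mean2 = float(col[mask2].mean())
        pooled = int(counts[:, j].sum())
        if pooled < sparse_threshold:
            unit_g = (int(counts[mask1, j].sum()), int(counts[mask2, j].sum()))
            other_g = (int(counts[mask1].sum() - unit_g[0]),
                       int(counts[mask2].sum() - unit_g[1]))
            _, p = fisher_exact([[unit_g[0], unit_g[1]],
                                 [other_g[0], other_g[1]]])
            t = np.nan
            method = "fisher"
        else:
            t = welch_t(col[mask1], col[mask2])
            hits = sum(abs(welch_t(col[m], col[~m])) >= abs(t)
                       for m in perm_masks)
            p = (hits + 1) / (permutations + 1)
            method = "permutation_t"
        rows.append({"unit": unit, f"mean_{names[0]}": mean1,
                     f"mean_{names[1]}": mean2, "t": t, "p": float(p),
                     "method": method})
    out = pd.DataFrame(rows).set_index("unit")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Dirichlet-multinomial mixtures


def dirichlet_multinomial_logpmf(counts: np.ndarray, alpha: np.ndarray
                                 ) -> np.ndarray:
    """Row-wise log pmf of counts (n x S) under DirMult(alpha)."""
    n = counts.sum(axis=1)
    a0 = alpha.sum()
    coef = gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
    return (coef + gammaln(a0) - gammaln(n + a0) +
            (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=1))


def dirichlet_mle(counts: np.ndarray, weights: np.ndarray | None = None,
                  max_iter: int = 1000, tol: float = 1e-10,
                  alpha0: np.ndarray | None = None) -> np.ndarray:
    """Weighted Dirichlet-multinomial MLE via the fixed-point update."""
    n, s = counts.shape
    if weights is None:
        weights = np.ones(n)
    if alpha0 is not None:
        alpha = np.maximum(np.asarray(alpha0, float), 1e-10)
    else:
        rel = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
        wsum = weights.sum()
        mean = (weights[:, None] * rel).sum(axis=0) / wsum
        alpha = np.maximum(mean, 1e-6)
    totals = counts.sum(axis=1)
    for _ in range(max_iter):
        a0 = alpha.sum()
        num = (weights[:, None] * (psi(counts + alpha) - psi(alpha))).sum(axis=0)
        den = (weights * (psi(totals + a0) - psi(a0))).sum()
        if den <= 0:
            break
        new = alpha * num / den
        new = np.maximum(new, 1e-10)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


@dataclass
class DMMFit:
    k: int
    weights: np.ndarray
    alphas: np.ndarray            # k x S
    posterior: pd.DataFrame       # samples x components
    neg_log_evidence: float
    log_likelihood: float
    evidence_by_k: dict | None = None
    top_units: pd.DataFrame | None = None

    @property
    def assignments(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)


def _dmm_em(counts: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int = 200, tol: float = 1e-6):
    n, s = counts.shape
    rel = counts / counts.sum(axis=1, keepdims=True)
    if k == 1:
        resp = np.ones((n, 1))
    else:
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=k, n_init=5,
                    random_state=int(rng.integers(2 ** 31)))
        lab = km.fit_predict(rel)
        resp = np.zeros((n, k))
        resp[np.arange(n), lab] = 1.0
        resp = resp * 0.9 + 0.1 / k
    weights = resp.mean(axis=0)
    alphas = np.stack([dirichlet_mle(counts, resp[:, c], max_iter=200)
                       for c in range(k)])
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = np.stack([dirichlet_multinomial_logpmf(counts, alphas[c])
                         for c in range(k)], axis=1)
        logp = logp + np.log(np.maximum(weights, 1e-300))
        ll = float(logsumexp(logp, axis=1).sum())
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        weights = resp.mean(axis=0)
        # warm-start each M-step fixed point from the current parameters
        alphas = np.stack([dirichlet_mle(counts, resp[:, c], max_iter=100,
                                         alpha0=alphas[c])
                           for c in range(k)])
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    # polish the component parameters at the converged posteriors
    alphas = np.stack([dirichlet_mle(counts, resp[:, c], max_iter=5000,
                                     tol=1e-12, alpha0=alphas[c])
                       for c in range(k)])
    logp = np.stack([dirichlet_multinomial_logpmf(counts, alphas[c])
                     for c in range(k)], axis=1)
    logp = logp + np.log(np.maximum(weights, 1e-300))
    prev_ll = float(logsumexp(logp, axis=1).sum())
    resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    return weights, alphas, resp, prev_ll


#: prior scale for the Laplace evidence: theta = log(alpha) ~ Normal(0, s^2)
LAPLACE_PRIOR_SD = 10.0


def _laplace_neg_log_evidence(counts: np.ndarray, weights: np.ndarray,
                              alphas: np.ndarray, ll: float) -> float:
    """Laplace approximation of -log evidence in log-alpha space.

    Uses a vague independent normal prior on theta = log(alpha) (scale
    ``LAPLACE_PRIOR_SD``), a numeric diagonal Hessian of the log-likelihood,
    and posterior curvature H + 1/s^2 so directions the data leave flat
    (e.g. from an emptied component) fall back to the prior:

        log Ev ~ logL + log prior + d/2 log(2 pi) - 1/2 log det(H + I/s^2)
    """
    k, s = alphas.shape
    theta = np.log(np.maximum(alphas.reshape(-1), 1e-300))
    d = len(theta)
    sd2 = LAPLACE_PRIOR_SD ** 2

    def loglik(th):
        a = np.exp(th).reshape(k, s)
        logp = np.stack([dirichlet_multinomial_logpmf(counts, a[c])
                         for c in range(k)], axis=1)
        logp = logp + np.log(np.maximum(weights, 1e-300))
        return float(logsumexp(logp, axis=1).sum())

    h = 1e-4
    base = loglik(theta)
    diag = np.empty(d)
    for i in range(d):
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        diag[i] = (loglik(tp) - 2 * base + loglik(tm)) / h ** 2
    curv = np.maximum(-diag, 0.0) + 1.0 / sd2
    log_prior = (-0.5 * d * np.log(2 * np.pi * sd2)
                 - float((theta ** 2).sum()) / (2 * sd2))
    log_ev = (ll + log_prior + 0.5 * d * np.log(2 * np.pi)
              - 0.5 * float(np.log(curv).sum()))
    return -log_ev


def dmm_fit(table: pd.DataFrame, k_range=range(1, 7), seed: int = 0,
            max_iter: int = 200) -> DMMFit:
    """Fit DMM for each k and return the best fit by Laplace evidence.

    ``top_units`` ranks units by the absolute difference between each
    component's mean composition and the single-component fit.
    """
    if table.empty:
        raise ValueError("empty count table")
    counts = table.to_numpy(dtype=float)
    n = len(table)
    rng_master = np.random.default_rng(seed)
    fits, evidence = {}, {}
    for k in k_range:
        if k > n:
            continue
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        weights, alphas, resp, ll = _dmm_em(counts, k, rng, max_iter=max_iter)
        nle = _laplace_neg_log_evidence(counts, weights, alphas, ll)
        fits[k] = (weights, alphas, resp, ll)
        evidence[k] = nle
    best_k = min(evidence, key=evidence.get)
    weights, alphas, resp, ll = fits[best_k]
    posterior = pd.DataFrame(resp, index=table.index,
                             columns=[f"component_{c}" for c in
                                      range(best_k)])
    single = fits[1][1][0] if 1 in fits else dirichlet_mle(counts)
    single_mean = single / single.sum()
    rows = {}
    for c in range(best_k):
        mean = alphas[c] / alphas[c].sum()
        contrib = pd.Series(np.abs(mean - single_mean), index=table.columns)
        rows[f"component_{c}"] = contrib
    top = pd.DataFrame(rows)
    return DMMFit(best_k, weights, alphas, posterior, evidence[best_k], ll,
                  evidence_by_k=evidence, top_units=top)
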