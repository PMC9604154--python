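"""Alpha diversity: subsample-standardised estimators and group comparisons.

Sequencing depth varies by orders of magnitude between samples, so every
estimator is computed on repeated subsamples of fixed size (default 100
reads, 1000 iterations) drawn without replacement; the result is the mean
and SD over iterations. Estimators: observed species, bias-corrected Chao1,
ACE (rare cutoff 10), Boneh's prediction of new species in an equal-sized
follow-up sample, Shannon H (natural log), Shannon evenness H/ln(S), and
Good's coverage 1 - singletons/reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kruskal, mannwhitneyu

ESTIMATORS = ["sobs", "chao1", "ace", "boneh", "shannon", "evenness",
              "coverage"]


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1: S + n1(n1-1) / (2(n2+1))."""
    c = counts[counts > 0]
    n1 = int(np.sum(c == 1))
    n2 = int(np.sum(c == 2))
    return len(c) + n1 * (n1 - 1) / (2.0 * (n2 + 1))


def ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    c = counts[counts > 0]
    rare = c[c <= rare_cutoff]
    s_abund = int(np.sum(c > rare_cutoff))
    s_rare = len(rare)
    n_rare = int(rare.sum())
    if s_rare == 0:
        return float(s_abund)
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare if n_rare else 0.0
    if c_ace <= 0:
        return chao1(counts)  # all rare reads are singletons
    i = np.arange(1, rare_cutoff + 1)
    fi = np.array([np.sum(rare == k) for k in i])
    gamma2 = (s_rare / c_ace) * np.sum(i * (i - 1) * fi) / \
        (n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def evenness(counts: np.ndarray) -> float:
    s = int(np.sum(counts > 0))
    if s <= 1:
        return 1.0
    return shannon(counts) / np.log(s)


def goods_coverage(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    return 1.0 - float(np.sum(counts == 1)) / float(n)


def boneh(counts: np.ndarray, m: int) -> float:
    """Predicted number of new species in a follow-up sample of size m.

    Plug-in form of the Boneh-Boneh-Caron prediction function: each observed
    species with count n_i contributes e^{-n_i} (1 - e^{-n_i m / n}).
    """
    c = counts[counts > 0].astype(float)
    n = c.sum()
    if n == 0:
        return 0.0
    return float(np.sum(np.exp(-c) * (1.0 - np.exp(-c * m / n))))


def _all_estimators(counts: np.ndarray, m: int) -> list[float]:
    return [float(np.sum(counts > 0)), chao1(counts), ace(counts),
            boneh(counts, m), shannon(counts), evenness(counts),
            goods_coverage(counts)]


@dataclass
class AlphaResult:
    """Per-sample estimator means and SDs over subsampling iterations."""

    mean: pd.DataFrame   # samples x estimators
    sd: pd.DataFrame
    skipped: list[str]
    subsample: int
    iterations: int


def subsample_estimates(table: pd.DataFrame, subsample: int = 100,
                        iterations: int = 1000, seed: int = 0) -> AlphaResult:
    """Mean +/- SD of each estimator over subsamples without replacement.

    Samples with fewer than ``subsample`` total reads are skipped with a
    warning.
    """
    rng = np.random.default_rng(seed)
    means, sds, skipped = {}, {}, []
    for sample, row in table.iterrows():
        counts = row.to_numpy(dtype=int)
        total = counts.sum()
        if total < subsample:
            warnings.warn(f"sample {sample} has {total} < {subsample} reads; "
                          f"skipped")
            skipped.append(sample)
            continue
        vals = np.empty((iterations, len(ESTIMATORS)))
        if total == subsample:
            vals[:] = _all_estimators(counts, subsample)
        else:
            for it in range(iterations):
                sub = rng.multivariate_hypergeometric(counts, subsample)
                vals[it] = _all_estimators(sub, subsample)
        means[sample] = vals.mean(axis=0)
        sds[sample] = vals.std(axis=0, ddof=0)
    mean = pd.DataFrame(means, index=ESTIMATORS).T
    sd = pd.DataFrame(sds, index=ESTIMATORS).T
    mean.index.name = sd.index.name = "sample"
    return AlphaResult(mean, sd, skipped, subsample, iterations)


def rarefaction_curve(counts: np.ndarray, step: int = 10) -> pd.DataFrame:
    """Analytic rarefaction: E[S(n)] = sum_i 1 - C(N-N_i, n)/C(N, n)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    depths = np.arange(1, n_total + 1, step)
    if depths[-1] != n_total:
        depths = np.append(depths, n_total)
    # log C(N - N_i, n) - log C(N, n), guarded where n > N - N_i
    expected = []
    for n in depths:
        keep = n_total - counts >= n
        log_ratio = np.full(len(counts), -np.inf)
        if keep.any():
            a = n_total - counts[keep]
            log_ratio[keep] = (gammaln(a + 1) - gammaln(n + 1) -
                               gammaln(a - n + 1) - (gammaln(n_total + 1) -
                               gammaln(n + 1) - gammaln(n_total - n + 1)))
        expected.append(float(np.sum(1.0 - np.exp(log_ratio))))
    return pd.DataFrame({"depth": depths, "expected_species": expected})


# ---------------------------------------------------------------------------
# group comparisons


def group_tests(alpha_means: pd.DataFrame, groups: pd.Series,
                permutations: int = 9999, seed: int = 0,
                alpha_level: float = 0.05) -> dict:
    """PERMANOVA over all estimators plus per-estimator rank tests.

    PERMANOVA uses Euclidean distances between the per-sample estimator
    vectors; each estimator also gets a Kruskal-Wallis test and pairwise
    Mann-Whitney comparisons with Bonferroni correction, summarised as a
    compact letter display.
    """
    from .beta import amova  # permutation pseudo-F on a distance matrix
    groups = groups.loc[alpha_means.index]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    x = alpha_means.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    dist = pd.DataFrame(np.sqrt((diff ** 2).sum(axis=2)),
                        index=alpha_means.index, columns=alpha_means.index)
    f, p = amova(dist, groups, permutations=permutations, seed=seed)
    result = {"permanova_F": f, "permanova_p": p, "estimators": {}}
    for est in alpha_means.columns:
        vals = alpha_means[est]
        by_group = [vals[groups == g].to_numpy() for g in groups.unique()]
        if np.ptp(np.concatenate(by_group)) == 0:
            kw_p = 1.0  # scipy rejects all-identical input
        else:
            kw_p = float(kruskal(*by_group).pvalue)
        pair_p = {}
        names = list(groups.unique())
        n_pairs = len(names) * (len(names) - 1) // 2
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = vals[groups == names[i]].to_numpy()
                b = vals[groups == names[j]].to_numpy()
                if np.ptp(np.concatenate([a, b])) == 0:
                    praw = 1.0
                else:
                    praw = float(mannwhitneyu(a, b,
                                              alternative="two-sided").pvalue)
                pair_p[(names[i], names[j])] = min(praw * n_pairs, 1.0)
        letters = compact_letter_display(
            {g: float(vals[groups == g].mean()) for g in names},
            {pair: pp < alpha_level for pair, pp in pair_p.items()})
        result["estimators"][est] = {"kruskal_p": kw_p,
                                     "pairwise_p": pair_p,
                                     "letters": letters}
    return result


def compact_letter_display(means: dict, significant: dict) -> dict:
    """Greedy letter assignment: groups not significantly different share a
    letter; significantly different pairs never do."""
    order = sorted(means, key=lambda g: -means[g])

    def differ(a, b):
        return significant.get((a, b), significant.get((b, a), False))

    letter_groups: list[list] = []
    for g in order:
        placed = False
        for bucket in letter_groups:
            if g not in bucket and \
                    all(not differ(g, member) for member in bucket):
                bucket.append(g)
                placed = True
        if not placed:
            bucket = [g]
            # absorb earlier groups compatible with the new bucket
            for h in order:
                if h not in bucket and \
                        all(not differ(h, m) for m in bucket):
                    bucket.append(h)
            letter_groups.append(bucket)
    out = {g: "" for g in order}
    for k, bucket in enumerate(letter_groups):
        ch = chr(ord("a") + k)
        for g in bucket:
            out[g] += ch
    return out
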