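"""Alpha diversity, analytic rarefaction curves, dissimilarity CV, and the
group-comparison tests used on them.

Estimator conventions (all switchable where noted):

* Chao1 is bias-corrected: ``S_obs + F1(F1-1) / (2(F2+1))`` with F1/F2 the
  singleton/doubleton counts.
* ACE uses the standard rare/abundant split at 10 reads; the gamma^2
  coefficient-of-variation correction is floored at 0.
* Shannon H' uses natural log; Pielou J = H'/ln S_obs.
* Simpson is reported both as concentration D = sum p^2 (smaller = more
  diverse) and as Gini-Simpson 1 - D.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data_model import DistanceMatrix, OTUTable, TableError


def _chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(s_obs)
    return s_obs + f1 * f1 / (2.0 * max(f2, 1))


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= rare_threshold]
    s_abund = int((counts > rare_threshold).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if f1 == n_rare:
        # no coverage information (all rare reads are singletons)
        return float("nan")
    c_ace = 1.0 - f1 / n_rare
    ss = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_threshold + 1))
    gamma2 = max(s_rare / c_ace * ss / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def alpha_diversity(
    table: OTUTable, ace_rare_threshold: int = 10, chao1_bias_corrected: bool = True
) -> pd.DataFrame:
    """Per-sample richness and evenness indices.

    Returns a DataFrame with columns ``s_obs, chao1, ace, shannon, simpson,
    gini_simpson, pielou``.  Pielou is NaN for single-OTU samples.
    """
    rows = {}
    for sid, row in zip(table.sample_ids, table.counts):
        counts = row[row > 0].astype(float)
        if counts.sum() == 0:
            raise TableError(f"sample {sid!r} is empty")
        p = counts / counts.sum()
        s_obs = len(counts)
        h = float(-(p * np.log(p)).sum())
        d = float((p**2).sum())
        rows[sid] = {
            "s_obs": s_obs,
            "chao1": _chao1(row, chao1_bias_corrected),
            "ace": _ace(row, ace_rare_threshold),
            "shannon": h,
            "simpson": d,
            "gini_simpson": 1.0 - d,
            "pielou": h / np.log(s_obs) if s_obs > 1 else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]
    out.attrs["ace_rare_threshold"] = ace_rare_threshold
    out.attrs["chao1_bias_corrected"] = chao1_bias_corrected
    return out


def rarefaction_curve(counts: np.ndarray, depths) -> np.ndarray:
    """Expected richness at each subsampling depth, computed analytically.

    ``E[S(d)] = sum_i 1 - C(N - N_i, d) / C(N, d)`` evaluated in log-gamma
    space, no resampling involved.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths > n).any():
        raise TableError(f"depth exceeds sample total {n}")
    if (depths < 1).any():
        raise TableError("depths must be >= 1")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths), dtype=float)
    for k, d in enumerate(depths):
        rest = n - counts  # reads not belonging to OTU i
        with np.errstate(invalid="ignore"):
            log_absent = np.where(
                rest >= d, log_choose(rest, d) - log_choose(n, d), -np.inf
            )
        out[k] = float((1.0 - np.exp(log_absent)).sum())
    return out


@dataclass
class DissimilarityCV:
    group: str
    n_pairs: int
    mean: float
    sd: float
    cv: float  # sd / mean, NaN when mean == 0


def dissimilarity_cv(dm: DistanceMatrix, grouping: pd.Series) -> pd.DataFrame:
    """Coefficient of variation of within-group pairwise dissimilarities.

    SD uses the n-1 denominator.  Groups need at least two members.
    """
    grouping = pd.Series(grouping).reindex(dm.ids)
    if grouping.isna().any():
        raise TableError("grouping must cover every item in the distance matrix")
    records = []
    for g, members in grouping.groupby(grouping).groups.items():
        idx = [dm.ids.index(x) for x in members]
        if len(idx) < 2:
            raise TableError(f"group {g!r} has fewer than 2 members")
        pairs = [dm.values[i, j] for i, j in combinations(idx, 2)]
        mean = float(np.mean(pairs))
        sd = float(np.std(pairs, ddof=1)) if len(pairs) > 1 else 0.0
        cv = sd / mean if mean > 0 else np.nan
        records.append(
            {"group": g, "n_pairs": len(pairs), "mean": mean, "sd": sd, "cv": cv}
        )
    return pd.DataFrame(records).set_index("group")


# ---------------------------------------------------------------------------
# group-comparison tests


def _letters_display(groups: list, nonsig_pairs: set) -> dict:
    """Compact significance letters: connected components of the graph whose
    edges are non-significant pairs share a letter."""
    parent = {g: g for g in groups}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in nonsig_pairs:
        parent[find(a)] = find(b)
    roots = {}
    letters = {}
    for g in groups:
        r = find(g)
        if r not in roots:
            roots[r] = chr(ord("a") + len(roots))
        letters[g] = roots[r]
    return letters


def group_tests(
    values: pd.Series, grouping: pd.Series, method: str = "anova", alpha: float = 0.05
) -> dict:
    """One-way ANOVA, all-pairs Bonferroni t-tests, or Mann-Whitney U.

    ``values`` and ``grouping`` are aligned by index.  Pairwise methods
    return a per-pair table plus a compact letters display (groups sharing a
    letter are not significantly different).
    """
    values = pd.Series(values).astype(float)
    grouping = pd.Series(grouping).reindex(values.index)
    if grouping.isna().any():
        raise TableError("grouping must cover every value")
    groups = list(dict.fromkeys(grouping))
    if len(groups) < 2:
        raise TableError("need at least 2 groups")
    by_group = {g: values[grouping == g].to_numpy() for g in groups}

    if method == "anova":
        arrays = list(by_group.values())
        if any(len(a) < 2 for a in arrays):
            raise TableError("ANOVA needs >= 2 values per group")
        if np.ptp(np.concatenate(arrays)) == 0:
            # identical values everywhere: no variance between or within
            return {"method": "anova", "statistic": 0.0, "p": 1.0}
        zero_var = [g for g, a in by_group.items() if np.ptp(a) == 0]
        if len(zero_var) == len(groups):
            raise TableError(f"zero within-group variance in groups: {zero_var}")
        f, p = stats.f_oneway(*arrays)
        return {"method": "anova", "statistic": float(f), "p": float(p)}

    if method == "t_bonferroni":
        pairs = list(combinations(groups, 2))
        records = []
        nonsig = set()
        for a, b in pairs:
            xa, xb = by_group[a], by_group[b]
            if len(xa) < 2 or len(xb) < 2:
                raise TableError("t-test needs >= 2 values per group")
            if np.ptp(xa) == 0 and np.ptp(xb) == 0:
                if xa.mean() == xb.mean():
                    t, p = 0.0, 1.0
                else:
                    raise TableError(f"zero within-group variance in groups: {[a, b]}")
            else:
                t, p = stats.ttest_ind(xa, xb)
            p_adj = min(float(p) * len(pairs), 1.0)
            records.append(
                {"group_a": a, "group_b": b, "t": float(t), "p": float(p), "p_adj": p_adj}
            )
            if p_adj >= alpha:
                nonsig.add((a, b))
        return {
            "method": "t_bonferroni",
            "pairs": pd.DataFrame(records),
            "letters": _letters_display(groups, nonsig),
        }

    if method == "mannwhitney":
        pairs = list(combinations(groups, 2))
        records = []
        nonsig = set()
        for a, b in pairs:
            xa, xb = by_group[a], by_group[b]
            ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
            exact = len(xa) <= 8 and len(xb) <= 8 and not ties
            res = stats.mannwhitneyu(
                xa, xb, alternative="two-sided", method="exact" if exact else "asymptotic"
            )
            records.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "U": float(res.statistic),
                    "p": float(res.pvalue),
                    "exact": exact,
                }
            )
            if res.pvalue >= alpha:
                nonsig.add((a, b))
        return {
            "method": "mannwhitney",
            "pairs": pd.DataFrame(records),
            "letters": _letters_display(groups, nonsig),
        }

    raise ValueError(f"unknown method {method!r}")
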