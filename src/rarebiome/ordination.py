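"""Unconstrained and constrained ordination with permutation inference.

Covers NMDS (Kruskal stress-1), ANOSIM, Mantel-style distance-matrix
correlation, redundancy analysis (RDA) with VIF filtering and forward
selection, three-block variation partitioning (VPA), and distance-based RDA
along taxonomic ranks.

Predictor handling is shared across RDA, VPA and dbRDA: quantitative
variables are log(x+1)-transformed (pH exempt) and standardized; categorical
variables are dummy-coded with one reference level dropped.  Permutation
p-values use the add-one convention; label permutations switch to exhaustive
enumeration when few distinct labelings exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _itperm
from math import factorial

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata, spearmanr
from sklearn.manifold import MDS

from ._permutation import EXHAUSTIVE_LIMIT, iter_labelings
from .data_model import (
    AGG_RANKS,
    DistanceMatrix,
    OTUTable,
    RelativeAbundanceTable,
    TableError,
    TaxonomyTable,
    aggregate_by_rank,
    bray_curtis,
    env_transform,
    to_relative,
)

# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NMDSResult:
    scores: pd.DataFrame  # samples x axes
    stress: float  # Kruskal stress-1
    restarts: int
    stresses: list
    converged: bool  # best two restarts agreed within 0.01 stress


def nmds(dm: DistanceMatrix, k: int = 2, restarts: int = 20, seed: int | None = None) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1 by iterative majorization
    (SMACOF) with monotone regression on dissimilarity ranks.

    Runs ``restarts`` random initializations plus one metric (classical
    scaling) initialization and keeps the lowest-stress embedding.
    """
    if dm.n < 3:
        raise TableError("NMDS needs at least 3 samples")
    rng = np.random.default_rng(seed)
    d = dm.values
    best_stress, best_coords = np.inf, None
    stresses = []

    def run(init, rs=None):
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init=init,
            max_iter=500,
            eps=1e-9,
            normalized_stress=True,
            random_state=rs,
        )
        coords = model.fit_transform(d)
        return float(model.stress_), coords

    for _ in range(restarts):
        s, c = run("random", rs=int(rng.integers(0, 2**31 - 1)))
        stresses.append(s)
        if s < best_stress:
            best_stress, best_coords = s, c
    # one metric (classical scaling) initialization on top of the random ones
    s, c = run("classical_mds")
    stresses.append(s)
    if s < best_stress:
        best_stress, best_coords = s, c

    ranked = sorted(stresses)
    converged = len(ranked) < 2 or (ranked[1] - ranked[0]) <= 0.01
    scores = pd.DataFrame(
        best_coords, index=dm.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NMDSResult(scores, best_stress, len(stresses), stresses, converged)


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int
    exhaustive: bool
    grouping: str = "group"


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    dm: DistanceMatrix,
    grouping: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> AnosimResult:
    """Clarke's ANOSIM: R = (mean between-group rank - mean within-group
    rank) / (n(n-1)/4), computed on mid-ranked dissimilarities; R = 1 means
    complete separation, 0 none."""
    grouping = pd.Series(grouping).reindex(dm.ids)
    if grouping.isna().any():
        raise TableError("grouping must cover every sample")
    sizes = grouping.value_counts()
    if len(sizes) < 2:
        raise TableError("need at least 2 groups")
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise TableError(f"groups with fewer than 2 members: {small}")

    n = dm.n
    ranks = rankdata(dm.condensed())  # mid-ranks for ties
    labels = list(grouping)

    def within_mask(lab):
        arr = np.asarray(lab, dtype=object)
        iu, ju = np.triu_indices(n, k=1)
        return arr[iu] == arr[ju]

    r_obs = _anosim_r(ranks, within_mask(labels), n)
    perms, m, exhaustive = iter_labelings(labels, n_perm, seed, exhaustive_limit)
    n_ge, skipped = 0, False
    for lab in perms:
        if exhaustive and not skipped and lab == labels:
            skipped = True
            continue
        n_ge += _anosim_r(ranks, within_mask(lab), n) >= r_obs - 1e-12
    p = (n_ge + 1) / (m + 1)
    return AnosimResult(r_obs, p, m, exhaustive)


# ---------------------------------------------------------------------------
# Mantel-style matrix correlation


@dataclass
class MatrixCorrelation:
    rho: float
    p: float
    method: str
    n_perm: int
    exhaustive: bool


def matrix_correlation(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> MatrixCorrelation:
    """Correlation between corresponding lower-triangle entries of two
    distance matrices, with a Mantel permutation test (simultaneous
    row/column permutation of the second matrix; two-sided on |rho|)."""
    if dm1.ids != dm2.ids:
        raise TableError("distance matrices must share item ids and order")
    corr = {"spearman": spearmanr, "pearson": pearsonr}.get(method)
    if corr is None:
        raise ValueError(f"unknown method {method!r}")
    x = dm1.condensed()
    n = dm1.n
    rho = float(corr(x, dm2.condensed()).statistic)

    total = factorial(n)
    exhaustive = total <= exhaustive_limit
    n_ge = 0
    if exhaustive:
        m = total
        skipped = False
        for perm in _itperm(range(n)):
            if not skipped and perm == tuple(range(n)):
                skipped = True
                continue
            y = squareform(dm2.values[np.ix_(perm, perm)], checks=False)
            n_ge += abs(float(corr(x, y).statistic)) >= abs(rho) - 1e-12
    else:
        m = n_perm
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            y = squareform(dm2.values[np.ix_(perm, perm)], checks=False)
            n_ge += abs(float(corr(x, y).statistic)) >= abs(rho) - 1e-12
    return MatrixCorrelation(rho, (n_ge + 1) / (m + 1), method, m, exhaustive)


# ---------------------------------------------------------------------------
# design matrices, VIF, least-squares core


def build_design(predictors: pd.DataFrame, log_exempt=("pH",)) -> pd.DataFrame:
    """Numeric columns log(x+1)-transformed (pH exempt) and standardized;
    categorical columns dummy-coded, one reference level dropped."""
    num_cols = [c for c in predictors.columns if pd.api.types.is_numeric_dtype(predictors[c])]
    cat_cols = [c for c in predictors.columns if c not in num_cols]
    parts = []
    if num_cols:
        parts.append(env_transform(predictors[num_cols], log_exempt=log_exempt))
    if cat_cols:
        dummies = pd.get_dummies(
            predictors[cat_cols].astype(str), drop_first=True, prefix_sep="="
        ).astype(float)
        parts.append(dummies)
    if not parts:
        raise TableError("no predictors")
    return pd.concat(parts, axis=1)


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R^2) of column j regressed on the others."""
    vals = X.to_numpy(float)
    n, p = vals.shape
    out = {}
    for j, col in enumerate(X.columns):
        y = vals[:, j]
        others = np.delete(vals, j, axis=1)
        others = np.column_stack([np.ones(n), others]) if p > 1 else np.ones((n, 1))
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 0.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def prune_vif(X: pd.DataFrame, cut: float = 20.0) -> tuple[pd.DataFrame, list]:
    """Iteratively drop the worst-VIF column until all VIFs <= cut."""
    dropped = []
    X = X.copy()
    while X.shape[1] > 1:
        vif = variance_inflation(X)
        worst = vif.idxmax()
        if vif[worst] <= cut:
            break
        X = X.drop(columns=[worst])
        dropped.append(worst)
    return X, dropped


def _center(Y: np.ndarray) -> np.ndarray:
    return Y - Y.mean(axis=0, keepdims=True)


def _ls_fit(Y: np.ndarray, X: np.ndarray) -> dict:
    """Least-squares fit of centered Y on centered X; explained variance is
    SS(fitted)/SS(total) summed over response columns."""
    n = Y.shape[0]
    Xc = _center(X)
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fitted = Xc @ beta
    ss_tot = float((Y**2).sum())
    ss_fit = float((fitted**2).sum())
    ss_res = ss_tot - ss_fit
    rank = int(np.linalg.matrix_rank(Xc)) if X.shape[1] else 0
    r2 = ss_fit / ss_tot if ss_tot > 0 else np.nan
    adj = (
        1.0 - (1.0 - r2) * (n - 1) / (n - 1 - rank)
        if n - 1 - rank > 0
        else np.nan
    )
    return {
        "fitted": fitted,
        "r2": r2,
        "adj_r2": adj,
        "ss_tot": ss_tot,
        "ss_fit": ss_fit,
        "ss_res": ss_res,
        "rank": rank,
    }


def _pseudo_f(fit: dict, n: int) -> float:
    p = fit["rank"]
    if p == 0 or n - p - 1 <= 0 or fit["ss_res"] <= 0:
        return np.inf
    return (fit["ss_fit"] / p) / (fit["ss_res"] / (n - p - 1))


# ---------------------------------------------------------------------------
# RDA


@dataclass
class RDAResult:
    """Constrained-ordination summary.

    ``explained`` is the fraction of total response variance captured by the
    fitted values (sum over axes); ``adj_r2`` is the Ezekiel adjustment.
    """

    explained: float
    adj_r2: float
    eigenvalues: np.ndarray
    axis_proportions: np.ndarray  # per canonical axis, of total variance
    scores: pd.DataFrame
    selected: list
    dropped_vif: list
    pseudo_f: float
    p: float
    n_perm: int
    selection_path: list = field(default_factory=list)
    method: str = "rda"


def _response_matrix(response, hellinger: bool = False) -> tuple[np.ndarray, list]:
    if isinstance(response, OTUTable):
        rel = to_relative(response)
        Y, ids = rel.values, rel.sample_ids
    elif isinstance(response, RelativeAbundanceTable):
        Y, ids = response.values, response.sample_ids
    elif isinstance(response, pd.DataFrame):
        Y, ids = response.to_numpy(float), list(response.index)
    else:
        Y, ids = np.asarray(response, dtype=float), list(range(len(response)))
    if hellinger:
        Y = np.sqrt(Y / Y.sum(axis=1, keepdims=True))
    return _center(Y), ids


def _forward_select(
    Y: np.ndarray,
    X: pd.DataFrame,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[list, list]:
    """Greedy forward selection: at each step the candidate adding the most
    explained variance is admitted if its partial permutation p < alpha
    (residuals of the reduced model are permuted, Freedman-Lane style);
    selection stops at the first non-significant best candidate."""
    n = Y.shape[0]
    selected: list = []
    path = []
    remaining = list(X.columns)
    while remaining:
        base = X[selected].to_numpy(float) if selected else np.zeros((n, 0))
        fit_red = _ls_fit(Y, base) if selected else {
            "fitted": np.zeros_like(Y),
            "ss_res": float((Y**2).sum()),
            "rank": 0,
        }
        best, best_fit, best_gain = None, None, -np.inf
        for c in remaining:
            trial = X[selected + [c]].to_numpy(float)
            fit = _ls_fit(Y, trial)
            gain = fit_red["ss_res"] - fit["ss_res"]
            if gain > best_gain + 1e-15:
                best, best_fit, best_gain = c, fit, gain
        if best is None or best_gain <= 1e-12:
            break
        df_res = n - best_fit["rank"] - 1
        if df_res <= 0 or best_fit["ss_res"] <= 0:
            break
        f_obs = best_gain / (best_fit["ss_res"] / df_res)
        resid = Y - fit_red["fitted"]
        trial = X[selected + [best]].to_numpy(float)
        n_ge = 0
        for _ in range(n_perm):
            Yp = fit_red["fitted"] + resid[rng.permutation(n)]
            fit_p = _ls_fit(Yp, trial)
            fit_red_p = _ls_fit(Yp, base) if selected else {"ss_res": float((_center(Yp) ** 2).sum())}
            gain_p = fit_red_p["ss_res"] - fit_p["ss_res"]
            f_p = gain_p / (fit_p["ss_res"] / df_res) if fit_p["ss_res"] > 0 else np.inf
            n_ge += f_p >= f_obs - 1e-12
        p = (n_ge + 1) / (n_perm + 1)
        path.append({"candidate": best, "gain": best_gain, "p": p})
        if p >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
    return selected, path


def rda(
    response,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    vif_cut: float = 20.0,
    forward_select: bool = True,
    forward_alpha: float = 0.05,
    hellinger: bool = False,
    log_exempt=("pH",),
) -> RDAResult:
    """Redundancy analysis of a (relative-abundance) community table on
    environmental predictors.

    Pipeline: transform/dummy-code predictors, prune collinear ones
    (VIF > ``vif_cut``), optional forward selection (permutation p <
    ``forward_alpha``), then eigen-decompose the fitted-value covariance.
    The global significance is a pseudo-F permutation test.
    """
    Y, ids = _response_matrix(response, hellinger)
    n = Y.shape[0]
    X = build_design(predictors.loc[ids] if set(ids) <= set(predictors.index) else predictors,
                     log_exempt=log_exempt)
    X, dropped = prune_vif(X, vif_cut)
    rng = np.random.default_rng(seed)

    path: list = []
    if forward_select:
        selected, path = _forward_select(Y, X, forward_alpha, n_perm, rng)
        if not selected:  # keep the best single predictor for a reportable model
            selected = list(X.columns[:1])
        X = X[selected]
    selected = list(X.columns)
    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(_center(Xv)) < Xv.shape[1]:
        raise TableError(f"rank-deficient design; aliased among: {selected}")
    if n <= Xv.shape[1] + 1:
        raise TableError("more predictors than samples allow")

    fit = _ls_fit(Y, Xv)
    u, s, _ = np.linalg.svd(fit["fitted"], full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(eig.max(), 1e-300) * 1e-12 if eig.size else np.array([], bool)
    eig = eig[keep]
    total_var = fit["ss_tot"] / (n - 1)
    proportions = eig / total_var if total_var > 0 else eig * np.nan
    scores = pd.DataFrame(
        (u[:, keep] * s[keep]),
        index=ids,
        columns=[f"RDA{i + 1}" for i in range(int(keep.sum()))],
    )

    f_obs = _pseudo_f(fit, n)
    n_ge = 0
    for _ in range(n_perm):
        fp = _ls_fit(_center(Y[rng.permutation(n)]), Xv)
        n_ge += _pseudo_f(fp, n) >= f_obs - 1e-12
    p = (n_ge + 1) / (n_perm + 1)
    return RDAResult(
        fit["r2"], fit["adj_r2"], eig, proportions, scores, selected, dropped,
        f_obs, p, n_perm, path,
    )


# ---------------------------------------------------------------------------
# variation partitioning


@dataclass
class VpaResult:
    """Pure/shared adjusted-R^2 fractions of three predictor blocks.

    Individual fractions may be negative (adjusted R^2 arithmetic); they sum
    with the residual to 1 exactly by construction.
    """

    block_names: tuple
    adj_r2: dict  # frozenset of block names -> adjusted R^2 of the union
    fractions: dict  # e.g. "pure_E", "shared_E&V", "shared_E&V&S"
    residual: float


def vpa(
    response,
    blocks: dict,
    hellinger: bool = False,
    log_exempt=("pH",),
) -> VpaResult:
    """Variation partitioning over three blocks via adjusted R^2 of the
    seven block unions and inclusion-exclusion."""
    if len(blocks) != 3:
        raise TableError("vpa expects exactly 3 blocks")
    for name, df in blocks.items():
        if df is None or df.shape[1] == 0:
            raise TableError(f"block {name!r} is empty")
    Y, ids = _response_matrix(response, hellinger)
    n = Y.shape[0]
    names = tuple(blocks)
    designs = {
        name: build_design(df.loc[ids] if set(ids) <= set(df.index) else df, log_exempt=log_exempt)
        for name, df in blocks.items()
    }

    combos = []
    for mask in range(1, 8):
        combo = frozenset(names[i] for i in range(3) if mask >> i & 1)
        combos.append(combo)
    adj = {}
    for combo in combos:
        X = pd.concat([designs[name] for name in names if name in combo], axis=1)
        fit = _ls_fit(Y, X.to_numpy(float))
        if not np.isfinite(fit["adj_r2"]):
            raise TableError(f"saturated model for blocks {sorted(combo)}; adjusted R^2 undefined")
        adj[combo] = fit["adj_r2"]

    # solve for the 7 disjoint fractions a..g from the 7 union equations
    a_, b_, c_ = names
    parts = [
        frozenset([a_]), frozenset([b_]), frozenset([c_]),
        frozenset([a_, b_]), frozenset([a_, c_]), frozenset([b_, c_]),
        frozenset([a_, b_, c_]),
    ]
    M = np.zeros((7, 7))
    rhs = np.zeros(7)
    for r, combo in enumerate(combos):
        for c, part in enumerate(parts):
            # fraction `part` contributes to union `combo` iff they intersect
            M[r, c] = 1.0 if part & combo else 0.0
        rhs[r] = adj[combo]
    frac = np.linalg.solve(M, rhs)
    full = adj[frozenset(names)]
    labels = [
        f"pure_{a_}", f"pure_{b_}", f"pure_{c_}",
        f"shared_{a_}&{b_}", f"shared_{a_}&{c_}", f"shared_{b_}&{c_}",
        f"shared_{a_}&{b_}&{c_}",
    ]
    fractions = dict(zip(labels, frac))
    # force the exact identity: fractions sum to the full-model adjusted R^2
    fractions[labels[-1]] += full - sum(fractions.values())
    return VpaResult(names, adj, fractions, 1.0 - full)


# ---------------------------------------------------------------------------
# PCoA + distance-based RDA


def _pcoa_coords(d: np.ndarray, lingoes: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix: Gower-center -0.5*J*D^2*J,
    eigendecompose, keep positive-eigenvalue axes scaled by sqrt(eigenvalue).
    ``lingoes`` adds the Lingoes constant to off-diagonal squared distances
    to remove negative eigenvalues."""
    n = d.shape[0]
    d2 = d.astype(float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eig, vec = np.linalg.eigh(B)
    if lingoes and eig.min() < -1e-12:
        c = -eig.min()
        d2 = d2 + 2 * c * (1 - np.eye(n))
        B = -0.5 * J @ d2 @ J
        eig, vec = np.linalg.eigh(B)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    keep = eig > max(eig.max(), 0) * 1e-10 if eig.size else np.array([], bool)
    eig = eig[keep]
    coords = vec[:, keep] * np.sqrt(eig)
    return coords, eig


def dbrda(
    dm: DistanceMatrix,
    predictors: pd.DataFrame,
    vif_cut: float = 20.0,
    lingoes: bool = False,
    log_exempt=("pH",),
) -> dict:
    """Distance-based RDA: RDA of (eigenvalue-weighted) principal
    coordinates on the transformed/VIF-pruned predictor set.  Returns the
    explained fraction of the retained-axis inertia."""
    coords, eig = _pcoa_coords(dm.values, lingoes)
    if coords.shape[1] == 0:
        return {"explained": np.nan, "adj_r2": np.nan, "n_axes": 0, "selected": []}
    Y = _center(coords)
    X = build_design(
        predictors.loc[dm.ids] if set(dm.ids) <= set(predictors.index) else predictors,
        log_exempt=log_exempt,
    )
    X, dropped = prune_vif(X, vif_cut)
    fit = _ls_fit(Y, X.to_numpy(float))
    return {
        "explained": fit["r2"],
        "adj_r2": fit["adj_r2"],
        "n_axes": coords.shape[1],
        "selected": list(X.columns),
        "dropped_vif": dropped,
    }


def dbrda_by_rank(
    table: OTUTable,
    taxonomy: TaxonomyTable,
    predictors: pd.DataFrame,
    ranks=AGG_RANKS,
    vif_cut: float = 20.0,
    lingoes: bool = False,
) -> pd.DataFrame:
    """Explained variation (Bray-Curtis dbRDA) at each taxonomic rank, same
    predictor pipeline throughout.  Ranks aggregating to a single taxon get
    NaN (no compositional variation left)."""
    rows = []
    for rank in ranks:
        agg = aggregate_by_rank(table, taxonomy, rank)
        if agg.data.shape[1] < 2:
            rows.append({"rank": rank, "n_taxa": agg.data.shape[1], "explained": np.nan,
                         "adj_r2": np.nan})
            continue
        dm = bray_curtis(agg)
        res = dbrda(dm, predictors, vif_cut=vif_cut, lingoes=lingoes)
        rows.append({"rank": rank, "n_taxa": agg.data.shape[1],
                     "explained": res["explained"], "adj_r2": res["adj_r2"]})
    return pd.DataFrame(rows).set_index("rank")
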