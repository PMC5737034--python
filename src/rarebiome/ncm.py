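"""Sloan neutral community model fit.

The model predicts a taxon's detection frequency across local communities
from its mean regional relative abundance p: under neutral drift with
migration, local relative abundance follows Beta(N*m*p, N*m*(1-p)) where N
is the local community size (reads per sample) and m the migration
probability.  The expected frequency of detection above a limit d is
``1 - BetaCDF(d; N m p, N m (1 - p))``.  m is the single free parameter,
estimated by bounded nonlinear least squares of observed occurrence
frequencies on predicted ones; fit quality is R^2 = 1 - SSE/SST.  A 95%
Wilson score envelope around the prediction partitions taxa into those
above, within, and below neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist

from .data_model import (
    AGG_RANKS,
    OTUTable,
    TableError,
    TaxonomyTable,
    aggregate_by_rank,
)

Z_95 = 1.959964


def predict_frequency(p, N: float, m: float, d: float) -> np.ndarray:
    """Expected detection frequency of taxa with regional abundance ``p``.

    ``p`` in {0, 1} are handled as limits (0 and 1 respectively).
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 < d < 1:
        raise ValueError("d must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p must be in [0, 1]")
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[p == 0] = 0.0
    out[p == 1] = 1.0
    Nm = N * m
    out[interior] = beta_dist.sf(d, Nm * p[interior], Nm * (1.0 - p[interior]))
    return float(out[0]) if scalar else out


def wilson_interval(phat, n: int, z: float = Z_95) -> tuple:
    """Wilson score confidence bounds for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    phat = np.asarray(phat, dtype=float)
    if ((phat < 0) | (phat > 1)).any():
        raise ValueError("phat must be in [0, 1]")
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (phat + z2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z2 / (4 * n * n)) / denom
    lower = np.clip(center - half, 0.0, 1.0)
    upper = np.clip(center + half, 0.0, 1.0)
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


@dataclass
class NCMFit:
    """Fitted migration rate with per-OTU frequencies and envelope flags."""

    m: float
    N: int
    d: float
    r2: float
    table: pd.DataFrame  # p, frequency, predicted, lower, upper, position
    n_samples: int

    @property
    def Nm(self) -> float:
        return self.N * self.m

    def position_counts(self) -> pd.Series:
        return (
            self.table["position"]
            .value_counts()
            .reindex(["above", "within", "below"], fill_value=0)
        )


def _sse(m: float, p: np.ndarray, f: np.ndarray, N: float, d: float, w: np.ndarray) -> float:
    pred = predict_frequency(p, N, m, d)
    return float((w * (f - pred) ** 2).sum())


M_BOUNDS = (1e-6, 1.0)


def fit_ncm(
    table: OTUTable,
    detection_limit: float | None = None,
    log_weight: bool = False,
) -> NCMFit:
    """Fit the neutral model to a rarefied OTU table.

    N is the per-sample depth, p_i is the mean relative abundance and f_i
    the occupancy of OTU i.  m is found by bounded least squares over
    (1e-6, 1] from several log-spaced starts; ``log_weight`` optionally
    weights squared errors by 1/p (down-weighting abundant taxa) instead of
    equal weights.

    The default detection limit is ``d = 1 - 2**(-1/N)`` (~= ln2/N), the
    local relative abundance at which a taxon has a 50% chance of yielding
    at least one read among N: occupancy is scored from counts, so the
    model's sharp threshold is matched to the half-point of the count
    detection curve ``1 - (1 - x)^N``.  The one-read convention ``d = 1/N``
    sits above that half-point and systematically overestimates m; it
    remains available via ``detection_limit=1/N``.
    """
    if not table.rarefied:
        raise TableError("fit_ncm requires a rarefied table (uniform depth)")
    n_samples = len(table.sample_ids)
    if n_samples < 8:
        warn(f"only {n_samples} samples; the occupancy fit will be coarse", stacklevel=2)
    N = int(table.sample_sums.iloc[0])
    d = 1.0 - 2.0 ** (-1.0 / N) if detection_limit is None else float(detection_limit)
    counts = table.counts
    present = counts.sum(axis=0) > 0
    otu_ids = [o for o, keep in zip(table.otu_ids, present) if keep]
    counts = counts[:, present]
    p = counts.mean(axis=0) / N
    f = (counts > 0).mean(axis=0)
    if (f >= 1.0).all():
        raise TableError("all OTUs occur in every sample; no signal to fit m")
    best_m = fit_occupancy(p, f, N, d, log_weight=log_weight)
    pred = predict_frequency(p, N, best_m, d)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float(((f - pred) ** 2).sum()) / sst
    lower, upper = wilson_interval(pred, n_samples)
    position = np.where(f > upper, "above", np.where(f < lower, "below", "within"))
    out = pd.DataFrame(
        {
            "p": p,
            "frequency": f,
            "predicted": pred,
            "lower": lower,
            "upper": upper,
            "position": position,
        },
        index=otu_ids,
    )
    return NCMFit(best_m, N, d, r2, out, n_samples)


def fit_occupancy(
    p: np.ndarray, f: np.ndarray, N: float, d: float, log_weight: bool = False
) -> float:
    """Least-squares estimate of m from (abundance, occupancy) pairs."""
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    w = 1.0 / p if log_weight else np.ones_like(p)
    best_m, best_sse = M_BOUNDS[0], np.inf
    for lo, hi in _bracket_pairs():
        res = minimize_scalar(
            _sse,
            bounds=(lo, hi),
            args=(p, f, N, d, w),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best_sse:
            best_sse, best_m = float(res.fun), float(res.x)
    return best_m


def _bracket_pairs():
    """Sub-intervals of (1e-6, 1] from 5 log-spaced breakpoints, guarding the
    bounded optimizer against local minima."""
    edges = np.concatenate([[M_BOUNDS[0]], np.logspace(-5, 0, 5)])
    return list(zip(edges[:-1], edges[1:])) + [M_BOUNDS]


def ncm_by_rank(
    table: OTUTable,
    taxonomy: TaxonomyTable,
    ranks=AGG_RANKS,
    low_confidence_taxa: int = 10,
) -> pd.DataFrame:
    """Aggregate to each rank (depth conserved), refit, and report R^2.

    Ranks with fewer taxa than ``low_confidence_taxa`` are flagged.
    """
    rows = []
    for rank in ranks:
        agg = aggregate_by_rank(table, taxonomy, rank)
        n_taxa = agg.data.shape[1]
        try:
            fit = fit_ncm(agg)
            rows.append(
                {"rank": rank, "n_taxa": n_taxa, "m": fit.m, "r2": fit.r2,
                 "low_confidence": n_taxa < low_confidence_taxa}
            )
        except TableError:
            rows.append(
                {"rank": rank, "n_taxa": n_taxa, "m": np.nan, "r2": np.nan,
                 "low_confidence": True}
            )
    return pd.DataFrame(rows).set_index("rank")
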