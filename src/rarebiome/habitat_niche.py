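"""Habitat specialization: Levins niche breadth and indicator species
analysis (IndVal, Dufrene-Legendre).

Niche breadth of taxon j is ``B_j = 1 / sum_i P_ij^2`` where P_ij is the
proportion of j's habitat-mean relative abundance found in habitat i.  B
ranges from 1 (single habitat) to the number of habitats (perfectly even
use).  Taxa with B above a generalist threshold (default 3) are habitat
generalists, below a specialist threshold (default 1.5) specialists.

IndVal combines specificity A (concentration of mean abundance in one
group) and fidelity B (occurrence frequency within that group); a *strict
habitat specialist* has a significant permutation p and both components
>= 0.8 at its best group.  Both analyses consider only taxa above a mean
relative-abundance floor (default 2e-5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._permutation import EXHAUSTIVE_LIMIT, iter_labelings
from .data_model import OTUTable, RelativeAbundanceTable, TableError

NICHE_CLASSES = ("generalist", "specialist", "neither", "excluded")


def _habitat_means(
    values: np.ndarray, grouping: pd.Series, sample_ids: list, pooled: bool = False
) -> tuple[pd.DataFrame, list]:
    grouping = pd.Series(grouping).reindex(sample_ids)
    if grouping.isna().any():
        raise TableError("grouping must cover every sample")
    groups = list(dict.fromkeys(grouping))
    rows = []
    for g in groups:
        mask = (grouping == g).to_numpy()
        if mask.sum() < 1:
            raise TableError(f"habitat {g!r} has no samples")
        rows.append(values[mask].sum(axis=0) if pooled else values[mask].mean(axis=0))
    return np.asarray(rows), groups


def niche_breadth(
    rel: RelativeAbundanceTable,
    grouping: pd.Series,
    min_mean_abund: float = 2e-5,
    generalist_cut: float = 3.0,
    specialist_cut: float = 1.5,
    pooled: bool = False,
) -> pd.DataFrame:
    """Levins B per OTU with generalist/specialist classification.

    Returns a DataFrame indexed by OTU with ``mean_abundance``, ``B``,
    ``niche_class``, and one ``P_<habitat>`` column per habitat.  OTUs below
    the abundance floor are ``excluded`` (B and P are NaN).  ``pooled``
    switches habitat means to habitat-pooled sums before normalization.
    """
    values = rel.values
    hab_means, groups = _habitat_means(values, grouping, rel.sample_ids, pooled)
    mean_abund = values.mean(axis=0)
    included = mean_abund >= min_mean_abund

    col_tot = hab_means.sum(axis=0)
    if (col_tot[included] == 0).any():
        raise TableError("included OTU with all-zero habitat means")  # defensive
    with np.errstate(invalid="ignore", divide="ignore"):
        P = hab_means / col_tot
        B = 1.0 / (P**2).sum(axis=0)
    n_hab = len(groups)
    B = np.clip(B, 1.0, n_hab)

    klass = np.where(
        B > generalist_cut, "generalist", np.where(B < specialist_cut, "specialist", "neither")
    )
    klass = np.where(included, klass, "excluded")
    out = pd.DataFrame(
        {"mean_abundance": mean_abund, "B": np.where(included, B, np.nan), "niche_class": klass},
        index=rel.otu_ids,
    )
    for i, g in enumerate(groups):
        out[f"P_{g}"] = np.where(included, P[i], np.nan)
    out.attrs.update(
        min_mean_abund=min_mean_abund,
        generalist_cut=generalist_cut,
        specialist_cut=specialist_cut,
        habitats=groups,
    )
    return out


@dataclass
class IndvalResult:
    """Per-OTU indicator values with permutation significance."""

    table: pd.DataFrame  # best_group, specificity, fidelity, indval, p, strict, tied
    groups: list
    n_perm: int
    exhaustive: bool
    alpha: float
    min_component: float

    def strict_specialists(self) -> pd.DataFrame:
        return self.table[self.table["strict"]]


def _indval_components(
    rel: np.ndarray, membership: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Specificity A and fidelity B matrices (groups x OTUs) from a
    normalized group-membership matrix (rows sum to 1 within each group)."""
    means = membership @ rel
    tot = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(tot > 0, means / tot, 0.0)
    B = membership @ (rel > 0)
    return A, B


def indval(
    table: OTUTable,
    grouping: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    min_component: float = 0.8,
    abundance_filter: float = 2e-5,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> IndvalResult:
    """Dufrene-Legendre indicator species analysis on a rarefied table.

    Specificity uses unweighted group means of relative abundance, so the
    table must be rarefied (uniform depth) first; this is asserted.  The
    best group per OTU is the argmax of A*B, ties broken toward the
    earliest group (recorded in the ``tied`` column).  Significance is by
    permutation of sample-group labels, exhaustive when the number of
    distinct labelings is small.
    """
    if not table.rarefied:
        raise TableError("indval requires a rarefied table (uniform depth)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grouping = pd.Series(grouping).reindex(table.sample_ids)
    if grouping.isna().any():
        raise TableError("grouping must cover every sample")
    groups = list(dict.fromkeys(grouping))
    if len(groups) < 2:
        raise TableError("need at least 2 groups")
    sizes = grouping.value_counts()
    if (sizes < 1).any():
        raise TableError("every group needs at least 1 sample")

    depth = float(table.sample_sums.iloc[0])
    rel = table.counts / depth
    keep = rel.mean(axis=0) >= abundance_filter
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    rel = rel[:, keep]

    labels = list(grouping)

    def membership_of(lab: list) -> np.ndarray:
        M = np.zeros((len(groups), len(lab)))
        for gi, g in enumerate(groups):
            mask = np.asarray([x == g for x in lab])
            M[gi, mask] = 1.0 / mask.sum()
        return M

    A, B = _indval_components(rel, membership_of(labels))
    iv = A * B
    best = iv.argmax(axis=0)  # first max -> earliest group wins ties
    obs = iv[best, np.arange(iv.shape[1])]
    tied = (iv >= obs - 1e-12).sum(axis=0) > 1

    perms, m, exhaustive = iter_labelings(labels, n_perm, seed, exhaustive_limit)
    n_ge = np.zeros(iv.shape[1], dtype=int)
    skipped = False  # exhaustive mode: observed labeling enters via the +1
    for lab in perms:
        if exhaustive and not skipped and lab == labels:
            skipped = True
            continue
        Ap, Bp = _indval_components(rel, membership_of(lab))
        perm_max = (Ap * Bp).max(axis=0)
        n_ge += perm_max >= obs - 1e-12
    p = (n_ge + 1) / (m + 1)

    a_best = A[best, np.arange(A.shape[1])]
    b_best = B[best, np.arange(B.shape[1])]
    strict = (p < alpha) & (a_best >= min_component) & (b_best >= min_component)
    out = pd.DataFrame(
        {
            "best_group": [groups[i] for i in best],
            "specificity": a_best,
            "fidelity": b_best,
            "indval": obs,
            "p": p,
            "strict": strict,
            "tied": tied,
        },
        index=otu_ids,
    )
    return IndvalResult(out, groups, m, exhaustive, alpha, min_component)


def strict_specialist_summary(result: IndvalResult) -> pd.Series:
    """Strict-specialist counts per habitat plus their total."""
    strict = result.strict_specialists()
    counts = strict["best_group"].value_counts().reindex(result.groups, fill_value=0)
    counts.loc["total"] = counts.sum()
    return counts.astype(int)
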