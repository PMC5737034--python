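"""Rare-biosphere partitioning and cutoff-sensitivity analysis.

Taxa are split by relative-abundance thresholds: *rare* taxa stay below
``rare_cut`` (default 0.01%) in every sample; *conditionally rare* taxa are
rare in at least one sample but never reach ``abundant_cut`` (default 1%);
*abundant* taxa are the literal complement.  The complement bucket also
captures OTUs that are always moderate (never < 0.01%, never >= 1%); their
count is surfaced so users can see how many "abundant" OTUs never actually
reach the abundant threshold.

MultiCoLA (multivariate cutoff level analysis) quantifies how sensitive
community structure is to discarding low-abundance taxa: OTUs below an
overall relative-abundance cutoff are dropped and the truncated Bray-Curtis
matrix is compared to the full one by Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data_model import OTUTable, RelativeAbundanceTable, TableError, bray_curtis

CATEGORIES = ("abundant", "conditionally_rare", "rare")

DEFAULT_MULTICOLA_CUTOFFS = (0.0, 1e-5, 2e-5, 5e-5, 1e-4, 5e-4, 1e-3, 1e-2)


@dataclass
class RarityPartition:
    """Per-OTU category plus the thresholds that produced it."""

    categories: pd.Series  # otu_id -> category
    rare_cut: float
    abundant_cut: float
    #: "abundant" OTUs whose maximum never reaches abundant_cut (the
    #: always-moderate complement bucket)
    never_abundant_count: int = 0

    def __post_init__(self) -> None:
        bad = set(self.categories.unique()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {bad}")

    def counts(self) -> pd.Series:
        return self.categories.value_counts().reindex(CATEGORIES, fill_value=0)

    def otus(self, category: str) -> list:
        return list(self.categories.index[self.categories == category])


def classify_rarity(
    rel: RelativeAbundanceTable, rare_cut: float = 1e-4, abundant_cut: float = 1e-2
) -> RarityPartition:
    """Assign every OTU to abundant / conditionally_rare / rare.

    rare: relative abundance < rare_cut in *all* samples.
    conditionally_rare: < rare_cut in some sample, never >= abundant_cut.
    abundant: everything else (literal complement of the two rules).
    """
    if not 0 < rare_cut < abundant_cut <= 1:
        raise ValueError("need 0 < rare_cut < abundant_cut <= 1")
    vals = rel.values
    vmax = vals.max(axis=0)
    vmin = vals.min(axis=0)
    if (vmax == 0).any():
        n_absent = int((vmax == 0).sum())
        warnings.warn(
            f"{n_absent} OTU(s) absent from all samples classified as rare",
            stacklevel=2,
        )
    is_rare = vmax < rare_cut
    is_crt = ~is_rare & (vmin < rare_cut) & (vmax < abundant_cut)
    cats = np.where(is_rare, "rare", np.where(is_crt, "conditionally_rare", "abundant"))
    categories = pd.Series(cats, index=rel.otu_ids)
    never_abundant = int(((cats == "abundant") & (vmax < abundant_cut)).sum())
    return RarityPartition(categories, rare_cut, abundant_cut, never_abundant)


def category_percentages(
    otu_counts: pd.Series | dict, read_counts: pd.Series | dict
) -> pd.DataFrame:
    """Percentage arithmetic of a partition summary.

    Takes per-category OTU and read counts (e.g. a published summary table)
    and returns counts plus percentages of the respective totals.  Full
    precision is retained; display rounding is up to the caller.
    """
    oc = pd.Series(otu_counts, dtype=float).reindex(CATEGORIES, fill_value=0)
    rc = pd.Series(read_counts, dtype=float).reindex(CATEGORIES, fill_value=0)
    out = pd.DataFrame(
        {
            "n_otus": oc.astype(int),
            "pct_otus": 100.0 * oc / oc.sum(),
            "n_reads": rc.astype(int),
            "pct_reads": 100.0 * rc / rc.sum(),
        }
    )
    out.index.name = "category"
    return out


def rarity_summary(partition: RarityPartition, table: OTUTable) -> pd.DataFrame:
    """Per-category OTU and read counts with percentages of both totals."""
    if set(partition.categories.index) != set(table.otu_ids):
        raise TableError("partition and table cover different OTU sets")
    cats = partition.categories.reindex(table.otu_ids)
    otu_counts = cats.value_counts().reindex(CATEGORIES, fill_value=0)
    reads_per_otu = table.data.sum(axis=0)
    read_counts = reads_per_otu.groupby(cats.to_numpy()).sum().reindex(
        CATEGORIES, fill_value=0
    )
    out = category_percentages(otu_counts, read_counts)
    # exhaustiveness: per-category sums must reproduce the table totals
    assert int(out["n_otus"].sum()) == len(table.otu_ids)
    assert int(out["n_reads"].sum()) == table.total_reads
    out.attrs["never_abundant_count"] = partition.never_abundant_count
    return out


@dataclass
class MulticolaProfile:
    """Structure-sensitivity of the dataset to low-abundance truncation."""

    table: pd.DataFrame  # index cutoff; columns n_otus, reads_fraction, spearman_rho

    def __post_init__(self) -> None:
        n = self.table["n_otus"].to_numpy()
        if (np.diff(n) > 0).any():
            raise ValueError("retained OTU counts must be non-increasing in cutoff")


def multicola_profile(
    table: OTUTable, cutoffs=DEFAULT_MULTICOLA_CUTOFFS
) -> MulticolaProfile:
    """Truncate at each overall-relative-abundance cutoff and correlate the
    truncated Bray-Curtis matrix with the full one (Spearman on the lower
    triangles).  A cutoff that removes everything records an undefined
    correlation rather than raising."""
    cutoffs = list(cutoffs)
    if any(c < 0 or c >= 1 for c in cutoffs) or sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be ascending values in [0, 1)")
    total = table.total_reads
    overall = table.data.sum(axis=0) / total
    full = bray_curtis(table).condensed()
    rows = []
    for c in cutoffs:
        keep = overall >= c if c > 0 else overall >= 0
        sub = table.data.loc[:, keep]
        n_otus = int(keep.sum())
        reads_fraction = float(sub.to_numpy().sum()) / total if total else np.nan
        if n_otus == 0 or (sub.sum(axis=1) == 0).any():
            rho = np.nan
        elif c == 0:
            rho = 1.0
        else:
            trunc = bray_curtis(OTUTable(sub)).condensed()
            rho = float(spearmanr(full, trunc).statistic)
        rows.append({"cutoff": c, "n_otus": n_otus, "reads_fraction": reads_fraction, "spearman_rho": rho})
    df = pd.DataFrame(rows).set_index("cutoff")
    return MulticolaProfile(df)
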