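"""Pedigree-guided correction of length-based cohort assignments.

Mixture-model cohorts are merged whenever a family cluster (or, optionally,
a full-sib family) spans them — related individuals cannot belong to
different spawning years in a semelparous species.  The same rule links
cohorts across collection years, and external length bands plus constraint
events (barrier installation, lampricide treatment) map final cohorts to
spawn years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


REQUIRED_COLS = ["id", "mixture_label", "cluster_id"]


def crosstab_clusters_cohorts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Contingency matrix of family clusters x mixture cohorts.

    Returns a long-format frame with one row per cluster: member count per
    mixture label, median / IQR of lengths when present, and a ``spanning``
    flag for clusters touching more than one mixture cohort.
    """
    for c in REQUIRED_COLS:
        if c not in assignments.columns:
            raise ValueError(f"assignments missing column {c!r}")
    if assignments.empty:
        return pd.DataFrame(columns=["cluster_id", "counts", "n", "spanning",
                                     "median_length", "iqr_length"])
    rows = []
    for cid, sub in assignments.groupby("cluster_id"):
        counts = sub["mixture_label"].value_counts().to_dict()
        med = iqr = np.nan
        if "length_mm" in sub.columns:
            med = float(sub["length_mm"].median())
            q3, q1 = sub["length_mm"].quantile([0.75, 0.25])
            iqr = float(q3 - q1)
        rows.append({"cluster_id": cid, "counts": counts, "n": len(sub),
                     "spanning": len(counts) > 1,
                     "median_length": med, "iqr_length": iqr})
    return pd.DataFrame(rows)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            lo, hi = sorted((ra, rb), key=str)
            self.parent[hi] = lo


def reconcile_cohorts(assignments: pd.DataFrame,
                      group_col: str = "cluster_id",
                      span_fraction: float = 0.3) -> pd.DataFrame:
    """Force related individuals into a single cohort.

    Each family group in ``group_col`` must end up in one final cohort.  A
    group whose minority-cohort share is below ``span_fraction`` is treated
    as containing stray length misassignments: its members are relabelled to
    the group's majority cohort.  A group spanning cohorts more
    substantially signals genuine oversplitting, and the involved cohorts
    are merged outright (union-find; ``span_fraction=0`` recovers pure
    merge-on-any-overlap semantics).  Deterministic; adds ``final_cohort``.
    """
    df = assignments.copy()
    labels = df["mixture_label"].unique().tolist()
    uf = _UnionFind(labels)
    work = df["mixture_label"].copy()
    for _, sub in df.groupby(group_col):
        counts = sub["mixture_label"].value_counts()
        if len(counts) < 2:
            continue
        minority = 1.0 - counts.iloc[0] / counts.sum()
        if minority < span_fraction:
            work.loc[sub.index] = counts.index[0]
        else:
            present = counts.index.tolist()
            for other in present[1:]:
                uf.union(present[0], other)
    roots = {lab: uf.find(lab) for lab in labels}
    # stable final ids ordered by root label
    ordered = sorted(set(roots.values()), key=str)
    final_id = {r: f"cohort_{k}" for k, r in enumerate(ordered)}
    df["final_cohort"] = work.map(lambda l: final_id[roots[l]])
    # related individuals can never span final cohorts
    assert (df.groupby(group_col)["final_cohort"].nunique() == 1).all()
    return df


def link_across_collections(assignments: pd.DataFrame,
                            group_col: str = "cluster_id") -> pd.DataFrame:
    """Unify final cohorts across collection years via spanning families.

    ``assignments`` must carry ``collection_year`` and ``final_cohort``.
    Cohorts from different collections merge when a family group spans them;
    cohorts with no cross-collection relatives stay collection-local.  Adds
    ``unified_cohort`` and returns a per-cohort growth summary in
    ``df.attrs['growth']`` (median length per collection year).
    """
    df = assignments.copy()
    if "collection_year" not in df.columns:
        raise ValueError("assignments must carry collection_year")
    df["_key"] = list(zip(df["collection_year"], df["final_cohort"]))
    uf = _UnionFind(df["_key"].unique().tolist())
    for _, sub in df.groupby(group_col):
        keys = sub["_key"].unique()
        for other in keys[1:]:
            uf.union(keys[0], other)
    roots = {k: uf.find(k) for k in df["_key"].unique()}
    ordered = sorted(set(roots.values()), key=str)
    final_id = {r: f"unified_{k}" for k, r in enumerate(ordered)}
    df["unified_cohort"] = df["_key"].map(lambda k: final_id[roots[k]])
    df = df.drop(columns="_key")

    if "length_mm" in df.columns:
        growth = (df.groupby(["unified_cohort", "collection_year"])["length_mm"]
                  .median().rename("median_length").reset_index())
        df.attrs["growth"] = growth
    return df


@dataclass
class ConstraintEvent:
    """A management event bounding feasible spawn years.

    ``treatment`` (lampricide) and ``barrier`` events both imply no surviving
    cohort can have spawned before ``year``.
    """
    type: str
    year: int


def assign_spawn_years(assignments: pd.DataFrame,
                       length_bands: dict[int, tuple[float, float]],
                       events: list[ConstraintEvent] | None = None,
                       cohort_col: str = "final_cohort") -> pd.DataFrame:
    """Map each final cohort to a spawn year using length-at-age bands.

    For every (cohort, collection year), candidate ages are those whose band
    contains the cohort's median length in that collection; candidate spawn
    years are intersected across collections and filtered by constraint
    events.  A unique survivor labels the cohort; several give
    ``ambiguous``; none gives ``infeasible``.
    """
    events = events or []
    min_year = max((e.year for e in events), default=None)
    out_rows = []
    for cid, sub in assignments.groupby(cohort_col):
        candidates: set[int] | None = None
        for cyear, csub in sub.groupby("collection_year"):
            med = float(csub["length_mm"].median())
            years = {int(cyear) - age for age, (lo, hi) in length_bands.items()
                     if lo <= med <= hi}
            candidates = years if candidates is None else candidates & years
        candidates = candidates or set()
        if min_year is not None:
            candidates = {y for y in candidates if y >= min_year}
        if len(candidates) == 1:
            label, cands = str(candidates.pop()), []
        elif len(candidates) > 1:
            label, cands = "ambiguous", sorted(candidates)
        else:
            label, cands = "infeasible", []
        out_rows.append({cohort_col: cid, "spawn_year": label,
                         "candidates": cands})
    return pd.DataFrame(out_rows)
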