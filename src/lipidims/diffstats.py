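"""Zone-wise univariate differential testing and cross-zone set logic.

Each growth-plate zone (resting, proliferating, hypertrophic) is tested
independently: per-ion unpaired two-sided Welch t-tests between genotypes
on log2 ROI intensities, Benjamini-Hochberg correction across ions within
the zone, and fold changes derived from the mean log2 differences
(fold_change = 2^|mean_diff|, the ratio of geometric means). ROIs are the
replication unit; note these are pseudo-replicates within animals — pass
``aggregate_by`` to collapse to animal-level means first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .roi import FeatureMatrix

ZONES = ("resting", "proliferating", "hypertrophic")


@dataclass
class ZoneTestResult:
    """Per-ion Welch test results for one zone's genotype contrast."""

    zone: str
    group_a: str        # e.g. KO; mean_diff = mean_a - mean_b
    group_b: str        # e.g. WT
    table: pd.DataFrame  # index bin_id: mean_diff, t_stat, p, q, fold_change, direction
    n_a: int
    n_b: int
    fdr_method: str = "fdr_bh"

    def to_csv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, index=False)


def zone_ttest(
    fm: FeatureMatrix,
    zone: str,
    group_column: str = "genotype",
    group_a: str = "KO",
    group_b: str = "WT",
    zone_column: str = "zone",
    aggregate_by: str | None = None,
    fdr_method: str = "fdr_bh",
) -> ZoneTestResult:
    """Unpaired two-sided Welch t-test per ion within one zone.

    Requires a log2-scale matrix and >= 2 ROIs per genotype in the zone.
    p-values are FDR-adjusted across ions within the zone (BH by default;
    the variant is recorded). Ions with zero variance in both groups get
    p = q = 1 and are flagged. ``aggregate_by`` (e.g. ``"replicate"``)
    averages ROIs within that metadata column per group before testing.
    """
    if fm.scale != "log2":
        raise ValueError("zone_ttest expects a log2-scale feature matrix")
    in_zone = fm.meta[zone_column] == zone
    meta = fm.meta[in_zone]
    values = fm.values[in_zone.to_numpy()]
    if aggregate_by:
        keys = meta[[group_column, aggregate_by]].astype(str)
        grouping = keys[group_column] + "|" + keys[aggregate_by]
        values = values.groupby(grouping.to_numpy()).mean()
        meta = pd.DataFrame({
            group_column: [g.split("|")[0] for g in values.index]
        })
        values = values.reset_index(drop=True)
    a = values[(meta[group_column] == group_a).to_numpy()].to_numpy(dtype=float)
    b = values[(meta[group_column] == group_b).to_numpy()].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"zone {zone!r}: need >=2 observations per group, got "
            f"{len(a)} {group_a} / {len(b)} {group_b}"
        )
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # zero-variance ion columns are handled explicitly below
        _warnings.simplefilter("ignore")
        t_stat, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method=fdr_method)[1]
    table = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t_stat": t_stat,
            "p": p,
            "q": q,
            "fold_change": 2.0 ** np.abs(mean_diff),
            "direction": np.where(mean_diff > 0, f"up_in_{group_a}",
                                  np.where(mean_diff < 0, f"down_in_{group_a}", "none")),
            "degenerate": degenerate,
        },
        index=pd.Index(fm.bin_ids, name="bin_id"),
    )
    return ZoneTestResult(zone, group_a, group_b, table, len(a), len(b), fdr_method)


def significant_sets(
    res: ZoneTestResult, q_cut: float = 0.05, fc_cut: float | None = None
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated ion sets: ``q < q_cut`` split by the sign of
    the mean difference, with an optional fold-change gate on top."""
    if not 0 < q_cut < 1:
        raise ValueError("q_cut must be in (0, 1)")
    t = res.table
    sig = t["q"] < q_cut
    if fc_cut is not None:
        sig = sig & (t["fold_change"] > fc_cut)
    up = set(t.index[sig & (t["mean_diff"] > 0)])
    down = set(t.index[sig & (t["mean_diff"] < 0)])
    return up, down


@dataclass
class CrossZoneSummary:
    """Venn-style overlap of per-zone significant ion sets."""

    up_sets: dict[str, set[str]]
    down_sets: dict[str, set[str]]
    up_intersections: dict[tuple[str, ...], int] = field(default_factory=dict)
    down_intersections: dict[tuple[str, ...], int] = field(default_factory=dict)
    membership: pd.DataFrame | None = None

    @property
    def common_up(self) -> set[str]:
        return set.intersection(*self.up_sets.values()) if self.up_sets else set()

    @property
    def common_down(self) -> set[str]:
        return set.intersection(*self.down_sets.values()) if self.down_sets else set()

    def to_csv(self, path: str | Path) -> None:
        self.membership.to_csv(path, index=False)


def cross_zone_overlap(
    up_sets: dict[str, set[str]], down_sets: dict[str, set[str]]
) -> CrossZoneSummary:
    """All pairwise and higher-order intersections of the per-zone sets,
    plus a per-ion zone-membership bit-pattern table."""
    if len(up_sets) < 2:
        raise ValueError("need sets from at least 2 zones")

    def _intersections(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
        out = {}
        zones = list(sets)
        for r in range(2, len(zones) + 1):
            for combo in combinations(zones, r):
                out[combo] = len(set.intersection(*(sets[z] for z in combo)))
        return out

    zones = list(up_sets)
    all_ions = sorted(set().union(*up_sets.values(), *down_sets.values()))
    rows = []
    for ion in all_ions:
        row = {"bin_id": ion}
        for z in zones:
            row[f"up_{z}"] = ion in up_sets[z]
            row[f"down_{z}"] = ion in down_sets.get(z, set())
        rows.append(row)
    membership = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["bin_id"])
    return CrossZoneSummary(
        up_sets, down_sets,
        _intersections(up_sets), _intersections(down_sets), membership,
    )


def volcano_table(res: ZoneTestResult, q_floor: float = 1e-300) -> pd.DataFrame:
    """One row per ion: signed log2 fold change and -log10 q.

    q-values of 0 are floored at ``q_floor`` so the ordinate stays finite
    (documented cap of 300).
    """
    t = res.table
    return pd.DataFrame({
        "bin_id": t.index,
        "log2_fold_change": t["mean_diff"].to_numpy(),
        "neg_log10_q": -np.log10(np.maximum(t["q"].to_numpy(), q_floor)),
        "q": t["q"].to_numpy(),
        "fold_change": t["fold_change"].to_numpy(),
        "direction": t["direction"].to_numpy(),
    }).reset_index(drop=True)
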