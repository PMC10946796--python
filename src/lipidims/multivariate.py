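"""Multivariate modeling: PCA, OPLS-DA with S-plot statistics, panels.

OPLS-DA separates class-predictive variation from class-orthogonal
variation: the orthogonal-signal-correction PLS formulation with a NIPALS
inner loop fits ``n_orth`` orthogonal components followed by a single
predictive component. With ``n_orth = 0`` the predictive component is
exactly a one-component PLS1 fit.

The S-plot statistics describe each ion's association with the predictive
score t: ``splot_cov`` is cov(t, x_j) (ddof 1) and ``splot_corr`` is the
Pearson correlation, both computed against the Pareto-scaled, centered
matrix that entered the fit. Extreme ions on both axes are the candidate
discriminators; panels are cut at an absolute threshold on either axis.

All scaling here is Pareto: center, then divide by the square root of the
population SD — intermediate between no scaling and unit variance, the
convention of the commercial S-plot workflow this module reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SkPCA

from .roi import FeatureMatrix, zscore_columns


@dataclass
class ScalingRecord:
    mean: np.ndarray
    divisor: np.ndarray          # sqrt(population SD); 1 for flagged columns
    zero_variance: np.ndarray    # bool per column

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.divisor


def pareto_scale(X: np.ndarray) -> tuple[np.ndarray, ScalingRecord]:
    """Center each column and divide by the square root of its SD.

    Zero-variance columns are centered only and flagged. Population SD
    (ddof 0).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Pareto scaling needs at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = sd == 0
    divisor = np.where(zero, 1.0, np.sqrt(np.where(zero, 1.0, sd)))
    record = ScalingRecord(mean, divisor, zero)
    return record.apply(X), record


@dataclass
class PcaModel:
    scores: pd.DataFrame            # rows x components
    loadings: pd.DataFrame          # ions x components (orthonormal columns)
    explained_variance_pct: np.ndarray
    scaling: ScalingRecord


def fit_pca(fm: FeatureMatrix, n_components: int = 3) -> PcaModel:
    """PCA of the Pareto-scaled feature matrix."""
    X = fm.values.to_numpy(dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if n_components > limit:
        raise ValueError(f"n_components={n_components} exceeds limit {limit}")
    Xs, record = pareto_scale(X)
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    return PcaModel(
        scores=pd.DataFrame(scores, columns=comps),
        loadings=pd.DataFrame(pca.components_.T, index=fm.bin_ids, columns=comps),
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        scaling=record,
    )


@dataclass
class OplsModel:
    """Fitted OPLS-DA model for one binary contrast."""

    contrast: str
    group_pos: str                  # group coded +1 (positive t_pred mean)
    group_neg: str
    t_pred: np.ndarray
    t_orth: np.ndarray              # rows x n_orth
    w_pred: np.ndarray              # predictive weights per ion
    p_pred: np.ndarray              # predictive loadings per ion
    splot: pd.DataFrame             # index bin_id: splot_cov, splot_corr
    r2y: float
    q2: float
    scaling: ScalingRecord
    bin_ids: list[str]

    def splot_table(self) -> pd.DataFrame:
        return self.splot.copy()


def _center(y: np.ndarray) -> np.ndarray:
    return y - y.mean()


def fit_oplsda(
    fm: FeatureMatrix,
    groups: pd.Series | np.ndarray,
    group_pos: str | None = None,
    n_orth: int = 1,
    contrast: str = "",
    compute_q2: bool = True,
) -> OplsModel:
    """Fit OPLS-DA for a two-group contrast on Pareto-scaled data.

    ``groups`` assigns each row to one of exactly two labels; ``group_pos``
    names the label coded +1 (default: lexicographically last, so e.g. KO
    beats WT). ``n_orth`` orthogonal components are removed before the
    single predictive component is fitted; ``n_orth = 0`` reduces to
    one-component PLS1. The predictive score is oriented so the +1 group
    has positive mean.
    """
    groups = pd.Series(np.asarray(groups), name="group")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    if group_pos is None:
        group_pos = labels[-1]
    if group_pos not in labels:
        raise ValueError(f"group_pos {group_pos!r} not among {labels}")
    group_neg = [g for g in labels if g != group_pos][0]
    y = np.where(groups == group_pos, 1.0, -1.0)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")

    X0, record = pareto_scale(fm.values.to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(X0)
    if n_orth >= rank:
        raise ValueError(f"n_orth={n_orth} >= rank(X)={rank}")
    yc = _center(y)
    if np.allclose(yc, 0):
        raise ValueError("constant group vector")

    t, t_orth, w, p = _opls_core(X0, yc, n_orth)
    # orient: +1 group has positive mean predictive score
    if t[y > 0].mean() < 0:
        t, w, p = -t, -w, -p

    c = float(t @ yc / (t @ t))
    r2y = 1.0 - float(((yc - t * c) ** 2).sum() / (yc ** 2).sum())
    q2 = _q2_loo(X0, yc, n_orth) if compute_q2 else float("nan")

    n = len(t)
    xc = X0 - X0.mean(axis=0)
    tc = t - t.mean()
    cov = xc.T @ tc / (n - 1)
    sd_x = X0.std(axis=0, ddof=1)
    sd_t = tc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sd_x > 0, cov / (sd_x * sd_t), 0.0)
    splot = pd.DataFrame(
        {"splot_cov": cov, "splot_corr": corr}, index=pd.Index(fm.bin_ids, name="bin_id")
    )
    return OplsModel(
        contrast=contrast or f"{group_pos}_vs_{group_neg}",
        group_pos=group_pos, group_neg=group_neg,
        t_pred=t, t_orth=t_orth, w_pred=w, p_pred=p,
        splot=splot, r2y=r2y, q2=q2, scaling=record, bin_ids=fm.bin_ids,
    )


def _opls_core(X: np.ndarray, yc: np.ndarray, n_orth: int):
    """Orthogonal-signal-correction PLS: strip n_orth y-orthogonal
    components, then one predictive NIPALS component."""
    Xf = X.copy()
    t_orths = []
    w = Xf.T @ yc
    w /= np.linalg.norm(w)
    for _ in range(n_orth):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no y-orthogonal variation left
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        t_orths.append(t_o)
        w = Xf.T @ yc
        w /= np.linalg.norm(w)
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    t_orth = np.column_stack(t_orths) if t_orths else np.empty((len(yc), 0))
    return t, t_orth, w, p


def _q2_loo(X: np.ndarray, yc: np.ndarray, n_orth: int) -> float:
    """Leave-one-out Q2 of the class response."""
    n = len(yc)
    press, ss = 0.0, float((yc ** 2).sum())
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], yc[mask]
        Xtr_c = Xtr - Xtr.mean(axis=0)
        ytr_c = ytr - ytr.mean()
        try:
            t, _, w, _ = _opls_core(Xtr_c, ytr_c, n_orth)
        except (ValueError, FloatingPointError):
            return float("nan")
        c = float(t @ ytr_c / (t @ t))
        # project the held-out row through the same orthogonal filter
        xi = X[i] - Xtr.mean(axis=0)
        Xf, wk = Xtr_c.copy(), Xtr_c.T @ ytr_c
        wk /= np.linalg.norm(wk)
        for _ in range(n_orth):
            tk = Xf @ wk
            pk = Xf.T @ tk / (tk @ tk)
            w_o = pk - (wk @ pk) * wk
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                break
            w_o /= norm
            t_o = Xf @ w_o
            p_o = Xf.T @ t_o / (t_o @ t_o)
            Xf = Xf - np.outer(t_o, p_o)
            xi = xi - (xi @ w_o) * p_o
            wk = Xf.T @ ytr_c
            wk /= np.linalg.norm(wk)
        pred = (xi @ w) * c + ytr.mean()
        press += (yc[i] - pred) ** 2
    return 1.0 - press / ss


@dataclass
class DiffPanel:
    """Selected differential ions for one contrast."""

    contrast: str
    table: pd.DataFrame     # bin_id, direction, splot_cov, splot_corr, source
    stat: str = "cov"
    threshold: float = 0.0
    excluded: list = field(default_factory=list)
    overlap: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def bin_ids(self) -> set[str]:
        return set(self.table["bin_id"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


_STAT_COLUMN = {"cov": "splot_cov", "corr": "splot_corr", "loading": "splot_cov"}


def select_panel(
    model: OplsModel,
    stat: str = "cov",
    threshold: float = 0.04,
    exclude: list[str] | None = None,
) -> DiffPanel:
    """Select ions whose absolute S-plot statistic meets the threshold.

    ``stat`` chooses the axis: ``cov`` (the w*/p1 covariance axis, the
    primary convention here, with ``loading`` accepted as an alias) or
    ``corr`` (the p(corr) axis). Direction is the sign of the statistic:
    positive means enriched in the model's +1 group. ``exclude`` is an
    explicit post-hoc exclusion list (the audited replacement for manual
    visual inspection); excluded ions are logged, never silently dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if stat not in _STAT_COLUMN:
        raise ValueError(f"stat must be one of {sorted(_STAT_COLUMN)}")
    col = _STAT_COLUMN[stat]
    s = model.splot[col]
    selected = model.splot[s.abs() >= threshold].copy()
    selected["direction"] = np.where(
        selected[col] > 0, model.group_pos, model.group_neg
    )
    selected = selected.reset_index()
    excluded = []
    if exclude:
        hit = selected["bin_id"].isin(exclude)
        excluded = [
            {"bin_id": b, "reason": "post_hoc_exclusion"}
            for b in selected.loc[hit, "bin_id"]
        ]
        selected = selected[~hit]
    if selected.empty:
        warnings.warn(f"empty panel for contrast {model.contrast!r}")
    selected["source"] = model.contrast
    table = selected[["bin_id", "direction", "splot_cov", "splot_corr", "source"]]
    return DiffPanel(model.contrast, table.reset_index(drop=True),
                     stat, threshold, excluded)


def merge_panels(panels: list[DiffPanel], contrast: str = "merged") -> DiffPanel:
    """Union of panels keyed by bin_id, with per-ion source provenance.

    Ions selected with conflicting directions across panels are kept and
    flagged. Pairwise overlap counts are reported.
    """
    if not panels:
        raise ValueError("no panels to merge")
    frames = [p.table for p in panels]
    combined = pd.concat(frames, ignore_index=True)
    rows = []
    for bin_id, grp in combined.groupby("bin_id", sort=False):
        directions = grp["direction"].unique()
        rows.append({
            "bin_id": bin_id,
            "direction": directions[0] if len(directions) == 1 else "conflict",
            "splot_cov": grp["splot_cov"].iloc[np.argmax(grp["splot_cov"].abs().to_numpy())],
            "splot_corr": grp["splot_corr"].iloc[np.argmax(grp["splot_corr"].abs().to_numpy())],
            "source": "+".join(grp["source"].unique()),
        })
    table = pd.DataFrame(rows)
    overlap = {}
    for i, a in enumerate(panels):
        for b in panels[i + 1:]:
            overlap[(a.contrast, b.contrast)] = len(a.bin_ids & b.bin_ids)
    return DiffPanel(contrast, table, panels[0].stat,
                     min(p.threshold for p in panels), overlap=overlap)


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    ordered: pd.DataFrame   # z-scored, leaf-ordered heat-map table
    metric: str
    method: str

    def cut_rows(self, k: int) -> np.ndarray:
        """Flat row-cluster labels at k clusters."""
        return hierarchy.fcluster(self.row_linkage, k, criterion="maxclust")


def hierarchical_cluster(
    fm: FeatureMatrix,
    panel: DiffPanel | list[str] | None = None,
    metric: str = "correlation",
    method: str = "average",
) -> ClusterResult:
    """Cluster ROIs (rows) and ions (columns) on z-scored intensities.

    Defaults — correlation distance, average linkage — are the
    conventional choices for z-scored omics heat maps; both are
    configurable and recorded in the result.
    """
    sub = fm
    if panel is not None:
        keep = sorted(panel.bin_ids if isinstance(panel, DiffPanel) else set(panel))
        keep = [b for b in fm.bin_ids if b in set(keep)]
        sub = FeatureMatrix(fm.meta.copy(), fm.values[keep].copy(), fm.scale)
    if len(sub.values) < 2 or sub.values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 ions")
    z = zscore_columns(sub).values.to_numpy(dtype=float)

    def _link(data: np.ndarray) -> np.ndarray:
        d = pdist(data, metric=metric)
        return hierarchy.linkage(np.nan_to_num(d, nan=1.0), method=method)

    row_l = _link(z)
    col_l = _link(z.T)
    row_order = hierarchy.leaves_list(row_l)
    col_order = hierarchy.leaves_list(col_l)
    ordered = pd.DataFrame(
        z[np.ix_(row_order, col_order)],
        index=sub.meta["roi_id"].to_numpy()[row_order],
        columns=np.asarray(sub.bin_ids)[col_order],
    )
    return ClusterResult(row_l, col_l, row_order, col_order,
                         sub.meta["roi_id"].tolist(), sub.bin_ids,
                         ordered, metric, method)
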