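"""Statistical pipeline for two-group pre/post brain-measure and drum-score tables.

Implements the analysis run on a drum-training cohort: total-cerebellar-volume
(TCV) residualization of lobular volumes, baseline group comparisons
(Mann-Whitney U, chi-squared for sex), Mann-Whitney tests on post-minus-pre
delta scores, per-measure ANCOVAs of the delta on group with covariates, and
rank correlations between regional volume and drumming precision change.

Input tables are tidy: one row per subject x timepoint with columns
``subject_id, group, sex, age, timepoint`` plus measure columns named by
prefix — ``vol_`` (cerebellar lobular volumes), ``fa_`` / ``md_`` (peduncle
diffusion), ``thick_`` (cortical thickness, mm) and ``score_`` (drum
performance measures).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PipelineConfig",
    "TCVCorrector",
    "tcv_correct",
    "mann_whitney_u",
    "chi_squared_independence",
    "ancova_group",
    "rank_correlation",
    "shapiro_wilk",
    "run_table2_pipeline",
]

SEX_CODES = {"male": 0, "female": 1}  # documented coding for covariates

ID_COLUMNS = ["subject_id", "group", "sex", "age", "timepoint"]
MEASURE_PREFIXES = ("vol_", "fa_", "md_", "thick_", "score_")


@dataclass(frozen=True)
class StatResult:
    """Named test output: statistic, optional degrees of freedom, p-value."""

    test_name: str
    statistic: float
    p_value: float
    df: Optional[tuple] = None
    two_sided: bool = True
    extra: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "df": list(self.df) if self.df is not None else None,
            "two_sided": self.two_sided,
        }
        d.update({k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                  for k, v in self.extra.items()})
        return d


# --------------------------------------------------------------------------
# TCV residualization
# --------------------------------------------------------------------------

class TCVCorrector:
    """Regress total cerebellar volume out of each lobular volume.

    TCV is the row-wise sum of all lobular volume columns.  For each lobule a
    pooled ordinary least squares fit of volume on TCV (both groups, both
    timepoints together) is removed; the returned value is the residual plus
    the lobule's grand mean, so corrected volumes keep their original units
    and scale.  If TCV has zero variance the slope is unidentifiable and
    volumes are passed through unchanged (with a warning).

    fit/transform style: ``fit`` learns per-lobule slope and mean,
    ``transform`` residualizes (new) rows against the fitted line.
    """

    def __init__(self, volume_cols: Optional[Sequence[str]] = None):
        self.volume_cols = volume_cols

    def fit(self, table: pd.DataFrame, tcv: Optional[np.ndarray] = None) -> "TCVCorrector":
        cols = list(self.volume_cols) if self.volume_cols is not None else [
            c for c in table.columns if c.startswith("vol_")
        ]
        if not cols:
            raise ValueError("no lobular volume columns to correct")
        if len(table) < 3:
            raise ValueError("need at least 3 rows to fit the TCV regression")
        V = table[cols].to_numpy(float)
        if not np.isfinite(V).all():
            raise ValueError("non-finite lobular volumes")
        tcv = V.sum(axis=1) if tcv is None else np.asarray(tcv, float)
        self.columns_ = cols
        self.tcv_ = tcv
        self.tcv_mean_ = tcv.mean()
        self.means_ = V.mean(axis=0)
        var = np.var(tcv)
        if var <= 1e-12 * max(1.0, self.tcv_mean_ ** 2):
            warnings.warn("TCV has (near-)zero variance; volumes returned uncorrected")
            self.slopes_ = np.zeros(len(cols))
            self.degenerate_ = True
        else:
            centered_tcv = tcv - self.tcv_mean_
            self.slopes_ = centered_tcv @ (V - self.means_) / (centered_tcv @ centered_tcv)
            self.degenerate_ = False
        return self

    def transform(self, table: pd.DataFrame, tcv: Optional[np.ndarray] = None) -> pd.DataFrame:
        V = table[self.columns_].to_numpy(float)
        tcv = V.sum(axis=1) if tcv is None else np.asarray(tcv, float)
        corrected = V - np.outer(tcv - self.tcv_mean_, self.slopes_)
        out = table.copy()
        out[self.columns_] = corrected
        out["tcv"] = tcv
        return out

    def fit_transform(self, table: pd.DataFrame, tcv: Optional[np.ndarray] = None) -> pd.DataFrame:
        return self.fit(table, tcv).transform(table, tcv)


def tcv_correct(table: pd.DataFrame, volume_cols: Optional[Sequence[str]] = None,
                tcv: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Pooled TCV residualization of a volume table (see :class:`TCVCorrector`)."""
    return TCVCorrector(volume_cols).fit_transform(table, tcv)


# --------------------------------------------------------------------------
# Hypothesis tests
# --------------------------------------------------------------------------

def mann_whitney_u(x, y, two_sided: bool = True) -> StatResult:
    """Mann-Whitney U test; exact by enumeration for small tie-free samples.

    Exact null distribution (scipy's recurrence enumeration) is used when
    n_x + n_y <= 20 and the pooled sample has no ties; otherwise the normal
    approximation with tie and continuity corrections.  Identical samples
    (zero spread pooled) return U = n_x*n_y/2 and p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return StatResult("mann_whitney_u", x.size * y.size / 2.0, 1.0,
                          two_sided=two_sided, extra={"method": "degenerate"})
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    alternative = "two-sided" if two_sided else "greater"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return StatResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      two_sided=two_sided, extra={"method": method})


def chi_squared_independence(counts, yates: bool = False) -> StatResult:
    """Pearson chi-squared test of independence on a 2x2 group x sex table."""
    table = np.asarray(counts, float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(table, correction=yates)
    return StatResult("chi_squared", float(res.statistic), float(res.pvalue),
                      df=(int(res.dof),), extra={"yates": yates})


def _design_matrix(group, covariates) -> tuple[np.ndarray, list[str]]:
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    cols = [np.ones(len(group)), (group == levels[1]).astype(float)]
    names = ["intercept", f"group[{levels[1]}]"]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            covariates = {c: covariates[c].to_numpy() for c in covariates.columns}
        for name, values in covariates.items():
            cols.append(np.asarray(values, float))
            names.append(str(name))
    return np.column_stack(cols), names


def ancova_group(response, group, covariates=None) -> tuple[StatResult, StatResult]:
    """OLS ANCOVA of a response on group plus numeric covariates.

    Returns (corrected-model F, group-effect F).  The corrected-model F tests
    all predictors jointly against the intercept-only model; the group F is
    the Wald F on the group indicator (identical to the type-III F for a
    binary factor).  The response is typically the post-minus-pre delta; the
    post-adjusting-for-pre design is obtained by passing the baseline value
    as one of the covariates.

    A constant response yields F = 0, p = 1 (nothing to explain); a
    rank-deficient design raises an error naming the aliased columns.
    """
    y = np.asarray(response, float)
    X, names = _design_matrix(group, covariates)
    if min(np.bincount(X[:, 1].astype(int))) < 2:
        raise ValueError("need at least 2 subjects per group")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased term(s): {aliased or names}")
    df_model = X.shape[1] - 1
    df_resid = len(y) - X.shape[1]
    if df_resid <= 0:
        raise ValueError("not enough observations for the requested model")
    if np.ptp(y) == 0:
        return (
            StatResult("ancova_model", 0.0, 1.0, df=(df_model, df_resid)),
            StatResult("ancova_group", 0.0, 1.0, df=(1, df_resid)),
        )
    fit = sm.OLS(y, X).fit()
    model = StatResult("ancova_model", float(fit.fvalue), float(fit.f_pvalue),
                       df=(int(fit.df_model), int(fit.df_resid)))
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    ft = fit.f_test(contrast)
    group_res = StatResult(
        "ancova_group", float(np.squeeze(ft.fvalue)), float(ft.pvalue),
        df=(1, int(fit.df_resid)),
        extra={"group_coef": float(fit.params[1]), "term": names[1]},
    )
    return model, group_res


def _spearman_coef(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def rank_correlation(x, y, method: str = "spearman_rho",
                     exact_max_n: int = 7) -> StatResult:
    """Spearman's rho or Kendall's tau-b with a two-sided p-value.

    For n <= ``exact_max_n`` the p-value is exact: the coefficient is
    recomputed under every permutation of one sample and the two-sided tail
    is the fraction of permutations at least as extreme in |coefficient|.
    Larger samples use the asymptotic p from scipy.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a zero-variance sample")
    if method == "spearman_rho":
        coef = float(sps.spearmanr(x, y).statistic)
        asym_p = float(sps.spearmanr(x, y).pvalue)
    elif method == "kendall_tau_b":
        res = sps.kendalltau(x, y)
        coef, asym_p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    if x.size <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        n_extreme = 0
        n_total = 0
        for perm in itertools.permutations(range(x.size)):
            if method == "spearman_rho":
                c = _spearman_coef(rx, ry[list(perm)])
            else:
                c = float(sps.kendalltau(x, y[list(perm)]).statistic)
            n_extreme += abs(c) >= abs(coef) - 1e-12
            n_total += 1
        return StatResult(method, coef, n_extreme / n_total, extra={"method": "exact_permutation"})
    return StatResult(method, coef, asym_p, extra={"method": "asymptotic"})


def shapiro_wilk(x) -> StatResult:
    """Shapiro-Wilk normality test (W statistic)."""
    res = sps.shapiro(np.asarray(x, float))
    return StatResult("shapiro_wilk", float(res.statistic), float(res.pvalue))


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.05
    covariates: tuple = ("sex",)          # subset of {"sex", "age"}
    design: str = "on_delta"              # or "on_post_adjusting_pre"
    hrs_delta: str = "ms"                 # "ms" or "precision_pct" for the MW delta
    yates: bool = False
    bh_adjust: bool = False               # add a labelled BH column, never silently
    viiia_column: str = "vol_left_viiia"  # region correlated with precision change
    hrs_score_column: str = "score_hrs_ms"


def _wide_by_timepoint(df: pd.DataFrame, measure_cols: list[str]):
    """Pivot tidy rows into per-subject T1/T2 columns; drop incomplete subjects."""
    counts = df.groupby("subject_id")["timepoint"].nunique()
    incomplete = sorted(counts.index[counts < 2].tolist())
    if incomplete:
        warnings.warn(f"excluding subject(s) without both timepoints: {incomplete}")
        df = df[~df["subject_id"].isin(incomplete)]
    t1 = df[df.timepoint == "T1"].set_index("subject_id").sort_index()
    t2 = df[df.timepoint == "T2"].set_index("subject_id").sort_index()
    meta = t1[["group", "sex", "age"]]
    return t1[measure_cols], t2[measure_cols], meta, incomplete


def _bh(pvals: list[float]) -> list[float]:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1].tolist()


def run_table2_pipeline(measures: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Run the full measure-table analysis and return a machine-readable report.

    Steps: TCV-correct lobular volumes (pooled across groups and timepoints);
    baseline group tests (sex chi-squared, age and baseline drum scores by
    Mann-Whitney); per-measure ANCOVA of the group effect on volumes,
    diffusion and thickness; drum-score deltas tested by Mann-Whitney (or t
    test when Shapiro-Wilk finds both groups' deltas normal); and the rank
    correlation of corrected left-VIIIa volume at T2 with the HRS precision
    change, within the drum group.  Rows of ``report["table"]`` mirror a
    before/after x group summary with the group F, p and a significance flag
    at ``alpha``.
    """
    cfg = config or PipelineConfig()
    df = measures.copy()
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measure table lacks required column(s) {missing}")
    if df["sex"].dtype == object:
        df["sex"] = df["sex"].map(SEX_CODES)
    if df["sex"].isna().any():
        raise ValueError(f"sex must be coded male/female or 0/1 ({SEX_CODES})")

    vol_cols = [c for c in df.columns if c.startswith("vol_")]
    brain_cols = [c for c in df.columns if c.startswith(("fa_", "md_", "thick_"))]
    score_cols = [c for c in df.columns if c.startswith("score_")]

    if vol_cols:
        df = TCVCorrector(vol_cols).fit_transform(df)

    measure_cols = vol_cols + brain_cols
    t1, t2, meta, excluded = _wide_by_timepoint(df, measure_cols + score_cols)
    group = meta["group"].to_numpy()
    is_drum = group == "drum"

    # Baseline comparisons
    sex_table = pd.crosstab(meta["group"], meta["sex"]).to_numpy()
    baseline = {
        "sex_chi_squared": chi_squared_independence(sex_table, yates=cfg.yates).to_dict(),
        "age_mann_whitney": mann_whitney_u(meta.loc[is_drum, "age"],
                                           meta.loc[~is_drum, "age"]).to_dict(),
    }
    for col in score_cols:
        baseline[f"{col}_mann_whitney"] = mann_whitney_u(
            t1.loc[is_drum, col].dropna(), t1.loc[~is_drum, col].dropna()
        ).to_dict()

    covariates = {}
    if "sex" in cfg.covariates:
        covariates["sex"] = meta["sex"].to_numpy(float)
    if "age" in cfg.covariates:
        covariates["age"] = meta["age"].to_numpy(float)

    # Per-measure ANCOVAs
    table_rows = []
    for col in measure_cols:
        pre = t1[col].to_numpy(float)
        post = t2[col].to_numpy(float)
        covs = dict(covariates)
        if cfg.design == "on_delta":
            response = post - pre
        elif cfg.design == "on_post_adjusting_pre":
            response = post
            covs["pre"] = pre
        else:
            raise ValueError(f"unknown design {cfg.design!r}")
        model_res, group_res = ancova_group(response, group, covs)
        table_rows.append({
            "measure": col,
            "before_control": float(pre[~is_drum].mean()),
            "before_drum": float(pre[is_drum].mean()),
            "after_control": float(post[~is_drum].mean()),
            "after_drum": float(post[is_drum].mean()),
            "F_model": model_res.statistic,
            "df_model": list(model_res.df),
            "F_group": group_res.statistic,
            "p": group_res.p_value,
            "significant": bool(group_res.p_value <= cfg.alpha),
            "direction_drum": float((post[is_drum] - pre[is_drum]).mean()
                                    - (post[~is_drum] - pre[~is_drum]).mean()),
        })
    if cfg.bh_adjust and table_rows:
        for row, q in zip(table_rows, _bh([r["p"] for r in table_rows])):
            row["p_bh_adjusted"] = q

    # Drum-score deltas: Shapiro-Wilk gates parametric vs nonparametric
    drum_scores = {}
    for col in score_cols:
        if col == cfg.hrs_score_column and cfg.hrs_delta == "precision_pct":
            pre, post = t1[col], t2[col]
            delta = (100.0 * (pre - post) / pre).to_numpy(float)
        else:
            delta = (t2[col] - t1[col]).to_numpy(float)
        d_drum = delta[is_drum & np.isfinite(delta)]
        d_ctrl = delta[~is_drum & np.isfinite(delta)]
        normal = (shapiro_wilk(d_drum).p_value > cfg.alpha
                  and shapiro_wilk(d_ctrl).p_value > cfg.alpha)
        if normal:
            t_res = sps.ttest_ind(d_drum, d_ctrl)
            res = StatResult("t_test", float(t_res.statistic), float(t_res.pvalue),
                             df=(int(round(t_res.df)),))
        else:
            res = mann_whitney_u(d_drum, d_ctrl)
        drum_scores[col] = {
            "delta_kind": ("precision_pct" if col == cfg.hrs_score_column
                           and cfg.hrs_delta == "precision_pct" else "post_minus_pre"),
            "median_delta_drum": float(np.median(d_drum)),
            "median_delta_control": float(np.median(d_ctrl)),
            "test": res.to_dict(),
            "significant": bool(res.p_value <= cfg.alpha),
        }

    # Precision-volume correlation at T2, drum group
    correlation = {}
    if cfg.viiia_column in t2.columns and cfg.hrs_score_column in t1.columns:
        pre_hrs = t1.loc[is_drum, cfg.hrs_score_column].to_numpy(float)
        post_hrs = t2.loc[is_drum, cfg.hrs_score_column].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            precision_change = 100.0 * (pre_hrs - post_hrs) / pre_hrs
        vol_t2 = t2.loc[is_drum, cfg.viiia_column].to_numpy(float)
        ok = np.isfinite(precision_change) & np.isfinite(vol_t2)
        if ok.sum() >= 3 and np.ptp(precision_change[ok]) > 0 and np.ptp(vol_t2[ok]) > 0:
            for method in ("spearman_rho", "kendall_tau_b"):
                correlation[method] = rank_correlation(
                    vol_t2[ok], precision_change[ok], method=method
                ).to_dict()

    return {
        "config": {
            "alpha": cfg.alpha, "covariates": list(cfg.covariates),
            "design": cfg.design, "hrs_delta": cfg.hrs_delta, "yates": cfg.yates,
        },
        "n_subjects": {"drum": int(is_drum.sum()), "control": int((~is_drum).sum())},
        "excluded_subjects": excluded,
        "baseline": baseline,
        "table": table_rows,
        "drum_scores": drum_scores,
        "correlation": correlation,
    }
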