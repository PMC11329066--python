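"""Cohort statistics layer and report assembly.

Group comparisons use Mann-Whitney U tests (exact enumeration for small
samples, tie-corrected normal approximation otherwise, reporting
min(U1, U2)); diagnostic performance uses ROC curves with the cutoff
maximizing sensitivity + specificity (Youden); correlations use Spearman's
rank test; the regression layer screens univariate predictors at P < 0.1
before a single multivariate fit, ln-transforming the response when the
multivariate residuals fail Shapiro-Wilk normality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "roc_with_cutoff",
    "spearman",
    "regression_screen",
    "cohort_report",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    medians: tuple[tuple[float, float, float], ...] = ()  # (median, Q1, Q3) per group
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    rho: float | None = None
    extra: dict = field(default_factory=dict)


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(x)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test; reports min(U1, U2).

    Exact p by enumeration when n1*n2 <= 200 and the data are tie-free;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 200 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = a.size * b.size - u1
    return TestResult(
        statistic=min(u1, u2),
        p_value=float(res.pvalue),
        medians=(_median_iqr(a), _median_iqr(b)),
        extra={"U1": u1, "U2": u2, "method": method},
    )


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """Sensitivity/specificity at every candidate cutoff (classify score > c)."""
    cuts = np.unique(scores)
    # candidate cutoffs: just below each observed score plus one above all
    cand = np.concatenate([[-np.inf], (cuts[:-1] + cuts[1:]) / 2, [cuts[-1]]]) \
        if cuts.size > 1 else np.array([-np.inf, cuts[0]])
    pos = labels == 1
    sens = np.array([(scores[pos] > c).mean() for c in cand])
    spec = np.array([(scores[~pos] <= c).mean() for c in cand])
    return cand, sens, spec


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the concordance probability (ties count half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # rank-sum formulation, equivalent to trapezoid over all thresholds
    n1, n0 = pos.size, neg.size
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u1 / (n1 * n0))


def roc_with_cutoff(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> TestResult:
    """ROC analysis with the sensitivity+specificity-maximizing cutoff.

    Cutoff ties resolve to the lower cutoff. The AUC confidence interval is
    a stratified bootstrap percentile interval (seeded, 2,000 resamples).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    auc = _auc(scores, labels)
    cand, sens, spec = _roc_points(scores, labels)
    youden = sens + spec
    best = int(np.argmax(youden))  # argmax takes the first (lowest) cutoff on ties
    cutoff = float(cand[best])
    pred = scores > cutoff
    acc = float((pred == (labels == 1)).mean())

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        s = np.concatenate([scores[pi], scores[ni]])
        l = np.concatenate([np.ones(pi.size, int), np.zeros(ni.size, int)])
        boots[i] = _auc(s, l)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return TestResult(
        statistic=auc,
        p_value=float("nan"),
        auc=auc,
        auc_ci=ci,
        cutoff=cutoff,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        accuracy=acc,
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with tie correction; p via t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need paired samples with n >= 3")
    res = sps.spearmanr(x, y)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      rho=float(res.statistic))


def regression_screen(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    screen_alpha: float = 0.1,
    normality_alpha: float = 0.05,
) -> dict:
    """Univariate screen at P < 0.1, then one multivariate linear fit.

    If the multivariate residuals fail Shapiro-Wilk normality, the response
    is natural-log transformed (requires positivity; otherwise flagged) and
    the model refit once. Returns a trace of every step.
    """
    import statsmodels.api as sm

    trace: dict = {"univariate": {}, "selected": [], "response": response}
    y = table[response].to_numpy(dtype=float)
    for p in predictors:
        x = sm.add_constant(table[p].to_numpy(dtype=float))
        fit = sm.OLS(y, x).fit()
        pval = float(fit.pvalues[1])
        trace["univariate"][p] = {"coef": float(fit.params[1]), "p": pval}
        if pval < screen_alpha:
            trace["selected"].append(p)

    if not trace["selected"]:
        trace["multivariate"] = None
        trace["note"] = "no predictor passed the univariate screen"
        return trace

    # drop collinear predictors in selection (pivoting) order
    kept: list[str] = []
    for p in trace["selected"]:
        cand = np.column_stack(
            [np.ones(len(table))] + [table[q].to_numpy(dtype=float) for q in kept + [p]]
        )
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept.append(p)
        else:
            import warnings

            warnings.warn(f"dropping collinear predictor {p!r}", stacklevel=2)
    trace["selected"] = kept

    X = sm.add_constant(table[trace["selected"]].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    sw_p = float(sps.shapiro(fit.resid).pvalue)
    trace["shapiro_p"] = sw_p
    trace["log_transformed"] = False
    if sw_p < normality_alpha:
        if np.all(y > 0):
            fit = sm.OLS(np.log(y), X).fit()
            trace["log_transformed"] = True
            trace["shapiro_p_after"] = float(sps.shapiro(fit.resid).pvalue)
        else:
            trace["log_transform_flag"] = "response not positive; transform skipped"
    trace["multivariate"] = {
        "coef": dict(zip(["const"] + trace["selected"], map(float, fit.params))),
        "p": dict(zip(["const"] + trace["selected"], map(float, fit.pvalues))),
        "r2": float(fit.rsquared),
    }
    return trace


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

REQUIRED_LOCATION_COLUMNS = [
    "location_id", "type", "iat", "fd", "fe",
]


def cohort_report(
    table: pd.DataFrame,
    out_dir=None,
    seed: int = 0,
    alpha: float = 0.05,
    make_figures: bool = True,
) -> dict:
    """Assemble the cohort analysis report from a per-location table.

    Expected columns: ``location_id``, ``type`` (LIR/LCR), ``iat`` (bool),
    ``fd``, ``fe``; optional ``voltage_max``, ``voltage_mean``, ``icl_pct``,
    ``burden`` and ``n_rotors`` (per-substrate columns for correlations).
    Emits group comparisons (LIR vs LCR, iAT vs iAT-free), ROC cutoffs, and
    Spearman correlations; writes CSV (and figures) when ``out_dir`` given.
    """
    missing = [c for c in REQUIRED_LOCATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")

    report: dict = {"comparisons": {}, "roc": {}, "correlations": {}, "notices": []}
    metric_cols = [c for c in ("fd", "fe", "voltage_max", "voltage_mean", "icl_pct")
                   if c in table.columns]

    def _compare(mask_a, mask_b, tag):
        for col in metric_cols:
            a = table.loc[mask_a, col].dropna().to_numpy()
            b = table.loc[mask_b, col].dropna().to_numpy()
            if a.size and b.size:
                r = mann_whitney(a, b)
                report["comparisons"][f"{tag}:{col}"] = {
                    "U": r.statistic,
                    "p": r.p_value,
                    "significant": bool(r.p_value < alpha),
                    "median_a": r.medians[0][0],
                    "median_b": r.medians[1][0],
                }

    is_lir = table["type"] == "LIR"
    is_lcr = table["type"] == "LCR"
    if is_lir.any() and is_lcr.any():
        _compare(is_lir, is_lcr, "LIR_vs_LCR")
        for col in metric_cols:
            sub = table.loc[is_lir | is_lcr, [col, "type"]].dropna()
            if sub["type"].nunique() == 2:
                r = roc_with_cutoff(
                    sub[col].to_numpy(), (sub["type"] == "LIR").to_numpy().astype(int),
                    seed=seed,
                )
                report["roc"][f"LIR:{col}"] = {
                    "auc": r.auc, "cutoff": r.cutoff,
                    "sensitivity": r.sensitivity, "specificity": r.specificity,
                    "accuracy": r.accuracy, "auc_ci": r.auc_ci,
                }
    iat = table["iat"].astype(bool)
    if iat.any() and (~iat).any():
        _compare(iat, ~iat, "iAT_vs_free")
        for col in metric_cols:
            sub = table[[col, "iat"]].dropna()
            if sub["iat"].astype(bool).nunique() == 2:
                r = roc_with_cutoff(
                    sub[col].to_numpy(), sub["iat"].to_numpy().astype(int), seed=seed
                )
                report["roc"][f"iAT:{col}"] = {
                    "auc": r.auc, "cutoff": r.cutoff,
                    "sensitivity": r.sensitivity, "specificity": r.specificity,
                    "accuracy": r.accuracy, "auc_ci": r.auc_ci,
                }

    if {"burden", "n_rotors"} <= set(table.columns):
        sub = table[["burden", "n_rotors"]].dropna().drop_duplicates()
        if len(sub) >= 3:
            r = spearman(sub["burden"], sub["n_rotors"])
            report["correlations"]["burden_vs_n_rotors"] = {"rho": r.rho, "p": r.p_value}
        else:
            report["notices"].append("fewer than 3 substrates: correlations skipped")

    if out_dir is not None:
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.sort_values("location_id").to_csv(out / "cohort_table.csv", index=False)
        flat = []
        for section in ("comparisons", "roc", "correlations"):
            for key, vals in report[section].items():
                row = {"section": section, "key": key}
                row.update({k: v for k, v in vals.items() if not isinstance(v, tuple)})
                flat.append(row)
        pd.DataFrame(flat).to_csv(out / "report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        if make_figures and is_lir.any() and is_lcr.any():
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, len(metric_cols) or 1, figsize=(3 * max(len(metric_cols), 1), 3))
            axes = np.atleast_1d(axes)
            for ax, col in zip(axes, metric_cols):
                data = [table.loc[is_lir, col].dropna(), table.loc[is_lcr, col].dropna()]
                ax.boxplot(data, tick_labels=["LIR", "LCR"])
                ax.set_title(col)
            fig.tight_layout()
            fig.savefig(out / "lir_vs_lcr.png", dpi=100)
            plt.close(fig)
    return report
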