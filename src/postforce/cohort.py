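"""Subject-level cohort statistics: the assay's statistical battery and the
transfusion-prediction analysis.

Endpoint forces per subject are compared with classical parametric tests
(paired / unpaired two-sided t, one-way ANOVA with Tukey's post-hoc, gated
by Shapiro-Wilk normality; Pearson correlation; chi-square for categorical
contrasts).  The clinical question — does a low platelet force on arrival
predict blood-product transfusion within 24 h? — is answered with nominal
logistic regression: an ROC curve with its rank-based AUC, the unit odds
ratio per +1 nN of force, and a multivariate model with likelihood-ratio
tests for hematocrit and prehospital-fluid confounding.

:class:`CohortModel` wraps the whole battery in a Model -> fit() ->
Results object with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RocResult",
    "paired_t",
    "unpaired_t",
    "anova_tukey",
    "pearson_r",
    "chi_square",
    "shapiro_wilk",
    "rank_auc",
    "logistic_roc",
    "multivariate_logistic_lr",
    "CohortModel",
    "CohortResults",
]


# ---------------------------------------------------------------------------
# Classical tests (scipy/statsmodels behind a stable surface)
# ---------------------------------------------------------------------------

def paired_t(control, treated, pairing=None) -> dict:
    """Two-sided paired t-test of control vs treated.

    ``pairing`` may give per-observation keys for both samples; unmatched
    keys raise with the offending keys listed.  Zero-variance differences
    are flagged and reported with a p-value at the machine floor.
    """
    control = np.asarray(control, float)
    treated = np.asarray(treated, float)
    if pairing is not None:
        ck, tk = (list(pairing[0]), list(pairing[1]))
        missing = sorted(set(ck) ^ set(tk))
        if missing:
            raise ValueError(f"broken pairing, unmatched keys: {missing}")
        order_c = np.argsort(ck)
        order_t = np.argsort(tk)
        control, treated = control[order_c], treated[order_t]
    if control.shape != treated.shape:
        raise ValueError("paired samples must have equal length")
    if len(control) < 2:
        raise ValueError("need n >= 2 pairs")
    diff = control - treated
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return {"t": 0.0, "df": len(diff) - 1, "p": 1.0, "degenerate": True}
        return {"t": np.inf * np.sign(diff.mean()), "df": len(diff) - 1,
                "p": np.finfo(float).tiny, "degenerate": True}
    res = stats.ttest_rel(control, treated)
    return {"t": float(res.statistic), "df": int(res.df), "p": float(res.pvalue),
            "degenerate": False}


def unpaired_t(a, b) -> dict:
    """Two-sided unpaired (independent-sample) t-test."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def anova_tukey(groups: dict | list) -> dict:
    """One-way ANOVA across >=3 groups plus all pairwise Tukey HSD contrasts.

    Unequal group sizes use the Tukey-Kramer adjustment (via statsmodels).
    Returns F, df pair, p and a {(label_a, label_b): p_adj} mapping.  Zero
    within-group variance is flagged rather than dividing by zero.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        values = [np.asarray(groups[k], float) for k in labels]
    else:
        labels = [f"group{i}" for i in range(len(groups))]
        values = [np.asarray(g, float) for g in groups]
    if len(values) < 3:
        raise ValueError("one-way ANOVA with Tukey requires >= 3 groups")
    for lab, v in zip(labels, values):
        if len(v) < 2:
            raise ValueError(f"group '{lab}' has n < 2")
    if all(np.allclose(v.std(ddof=1), 0) for v in values):
        same = np.allclose([v.mean() for v in values],
                           values[0].mean())
        return {"F": 0.0 if same else np.inf, "df": (len(values) - 1,
                sum(map(len, values)) - len(values)),
                "p": 1.0 if same else np.finfo(float).tiny,
                "tukey": {}, "degenerate": True}
    F, p = stats.f_oneway(*values)
    flat = np.concatenate(values)
    memb = np.concatenate([[lab] * len(v) for lab, v in zip(labels, values)])
    tk = pairwise_tukeyhsd(flat, memb)
    tukey = {}
    for row in zip(tk.summary().data[1:], tk.pvalues):
        (g1, g2, *_), padj = row
        tukey[(str(g1), str(g2))] = float(padj)
    return {"F": float(F), "df": (len(values) - 1, len(flat) - len(values)),
            "p": float(p), "tukey": tukey, "degenerate": False}


def pearson_r(x, y) -> dict:
    """Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


def chi_square(table) -> dict:
    """Chi-square test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table, float), correction=False)
    return {"chi2": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue)}


def shapiro_wilk(values) -> dict:
    """Shapiro-Wilk normality test — the gate that justifies parametric tests
    (p > 0.05 treated as consistent with normality)."""
    v = np.asarray(values, float)
    if np.allclose(v.std(), 0):
        raise ValueError("Shapiro-Wilk undefined for constant input")
    W, p = stats.shapiro(v)
    return {"W": float(W), "p": float(p), "normal": bool(p > 0.05)}


# ---------------------------------------------------------------------------
# Logistic ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Logistic-regression ROC summary for one continuous predictor."""

    auc: float
    curve: np.ndarray                  # (n+1, 2): (1-specificity, sensitivity)
    slope: float                       # logit slope per predictor unit
    intercept: float
    unit_odds_ratio: float             # exp(slope): odds multiplier per +1 unit
    percent_odds_change: float         # 100*(1-exp(slope)); >0 = odds decrease
    odds_ratio_ci: tuple[float, float]
    model_p: float                     # LR test vs intercept-only
    separation_warning: bool = False
    n_cases: int = 0
    n_controls: int = 0

    def plot(self, ax=None):
        """ROC polyline with the chance diagonal and the AUC in the legend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve[:, 0], self.curve[:, 1],
                label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax


def rank_auc(scores, outcomes) -> float:
    """ROC area by the rank (Mann-Whitney) estimator with midrank ties.

    AUC = (R1 - n1(n1+1)/2) / (n1 n0) with R1 the positive-class rank sum of
    the scores.  Exactly the probability that a random case outranks a
    random control (ties count 1/2).
    """
    scores = np.asarray(scores, float)
    y = np.asarray(outcomes).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve_points(scores, outcomes) -> np.ndarray:
    """Empirical ROC polyline: (1-specificity, sensitivity) at every
    distinct score threshold, from (0,0) to (1,1)."""
    scores = np.asarray(scores, float)
    y = np.asarray(outcomes).astype(int)
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last point of each tied-score run
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tps, fps = tps[distinct], fps[distinct]
    sens = tps / max(y.sum(), 1)
    fpr = fps / max(len(y) - y.sum(), 1)
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, sens]])


def _fit_logit(y, X):
    """Binomial GLM (IRLS) fit; returns the results object."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-10)


def logistic_roc(records: pd.DataFrame, predictor: str = "force_nN",
                 outcome: str = "transfused") -> RocResult:
    """Univariate nominal logistic regression of ``outcome`` on ``predictor``
    with ROC characterisation.

    The AUC comes from the rank estimator on the fitted scores — identical
    to ranking the raw predictor up to the monotone logistic link, so it is
    invariant to any increasing transform of the predictor.  The unit odds
    ratio exp(beta) gives the multiplicative odds change per +1 unit (+1 nN);
    ``percent_odds_change`` is the percent *decrease*, positive when higher
    force lowers transfusion odds.  Complete separation yields AUC 1.0 and a
    warning flag instead of a crash.
    """
    df = records.dropna(subset=[predictor, outcome])
    y = df[outcome].astype(int).to_numpy()
    x = df[predictor].astype(float).to_numpy()
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("outcome has a single class; ROC undefined")

    separated = x[y == 1].max() < x[y == 0].min() or x[y == 0].max() < x[y == 1].min()
    X = sm.add_constant(x)
    res = _fit_logit(y, X)
    null = _fit_logit(y, np.ones((len(y), 1)))
    lr = 2.0 * (res.llf - null.llf)
    model_p = float(stats.chi2.sf(max(lr, 0.0), df=1))

    slope = float(res.params[1])
    score = X @ res.params
    auc = rank_auc(score, y)
    if separated:
        warnings.warn("predictor completely separates the outcome classes",
                      UserWarning, stacklevel=2)
        auc = 1.0
    # clamp before exponentiating: separated fits have huge Wald intervals
    ci_lo, ci_hi = np.clip(res.conf_int()[1], -700.0, 700.0)
    return RocResult(
        auc=auc,
        curve=roc_curve_points(score, y),
        slope=slope,
        intercept=float(res.params[0]),
        unit_odds_ratio=float(np.exp(slope)),
        percent_odds_change=float(100.0 * (1.0 - np.exp(slope))),
        odds_ratio_ci=(float(np.exp(ci_lo)), float(np.exp(ci_hi))),
        model_p=model_p,
        separation_warning=bool(separated),
        n_cases=n1,
        n_controls=n0,
    )


def multivariate_logistic_lr(records: pd.DataFrame,
                             covariates: list[str] | None = None,
                             outcome: str = "transfused") -> dict:
    """Multivariate logistic model with per-effect likelihood-ratio tests.

    Each effect's LR p-value comes from refitting the model without that
    term: LR = 2(llf_full - llf_reduced) ~ chi2(1).  Listwise deletion of
    incomplete records is applied and the dropped count reported.  A
    duplicated (rank-deficient) design raises.
    """
    if covariates is None:
        covariates = ["force_nN", "hematocrit", "prehospital_fluids"]
    n_before = len(records)
    df = records.dropna(subset=[outcome, *covariates])
    n_dropped = n_before - len(df)
    y = df[outcome].astype(int).to_numpy()
    X = df[covariates].astype(float).to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    Xc = sm.add_constant(X)
    full = _fit_logit(y, Xc)
    if not full.converged:
        raise RuntimeError(
            f"logistic fit did not converge in {full.fit_history['iteration']} iterations")
    null = _fit_logit(y, np.ones((len(y), 1)))
    lr_model = 2.0 * (full.llf - null.llf)
    effects = {}
    for j, name in enumerate(covariates):
        keep = [0] + [1 + i for i in range(len(covariates)) if i != j]
        red = _fit_logit(y, Xc[:, keep])
        lr = 2.0 * (full.llf - red.llf)
        effects[name] = {
            "coef": float(full.params[1 + j]),
            "lr": float(lr),
            "p": float(stats.chi2.sf(max(lr, 0.0), df=1)),
        }
    return {
        "effects": effects,
        "model_lr": float(lr_model),
        "model_p": float(stats.chi2.sf(max(lr_model, 0.0), df=len(covariates))),
        "deviance": float(full.deviance),
        "n": int(len(df)),
        "n_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

@dataclass
class CohortResults:
    """Fitted cohort analysis: group summaries, omnibus tests, ROC model."""

    group_summary: pd.DataFrame
    anova: dict | None
    roc: RocResult | None
    multivariate: dict | None
    normality: dict[str, dict] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Cohort analysis", "=" * 60, "",
                 "Group endpoint forces (nN):"]
        lines.append(self.group_summary.to_string(
            float_format=lambda v: f"{v:.1f}"))
        if self.anova is not None:
            a = self.anova
            lines += ["", f"One-way ANOVA: F = {a['F']:.2f}, "
                          f"df = {a['df'][0]},{a['df'][1]}, p = {a['p']:.4g}"]
            for (g1, g2), p in a["tukey"].items():
                lines.append(f"  Tukey {g1} vs {g2}: p = {p:.4g}")
        if self.roc is not None:
            r = self.roc
            lines += ["", f"Logistic ROC (force -> transfusion):",
                      f"  AUC = {r.auc:.3f}  (model p = {r.model_p:.4g})",
                      f"  unit odds ratio per +1 nN = {r.unit_odds_ratio:.4f} "
                      f"({r.percent_odds_change:+.2f}% odds change)"]
        if self.multivariate is not None:
            m = self.multivariate
            lines += ["", f"Multivariate logistic (whole-model p = "
                          f"{m['model_p']:.4g}, n = {m['n']}):"]
            for name, e in m["effects"].items():
                lines.append(f"  {name}: coef = {e['coef']:+.4f}, LR p = {e['p']:.4g}")
        return "\n".join(lines)


class CohortModel:
    """Cohort analysis as a statsmodels-style model object.

    Parameters
    ----------
    data : DataFrame with at least ``force_nN``, ``group`` and the outcome
        column; optional hematocrit / prehospital_fluids covariates.
    """

    def __init__(self, data: pd.DataFrame, outcome: str = "transfused",
                 predictor: str = "force_nN"):
        required = {predictor, "group"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        self.data = data.copy()
        self.outcome = outcome
        self.predictor = predictor

    @classmethod
    def from_csv(cls, path, **kw) -> "CohortModel":
        return cls(pd.read_csv(path, sep=None, engine="python"), **kw)

    def fit(self, covariates: list[str] | None = None) -> CohortResults:
        df = self.data
        gs = df.groupby("group")[self.predictor].agg(["count", "mean", "std"])
        gs.columns = ["n", "mean_nN", "sd_nN"]

        normality = {}
        for g, vals in df.groupby("group")[self.predictor]:
            if len(vals) >= 3 and vals.std() > 0:
                normality[g] = shapiro_wilk(vals)

        anova = None
        if df["group"].nunique() >= 3:
            anova = anova_tukey({g: v.to_numpy()
                                 for g, v in df.groupby("group")[self.predictor]})

        roc = None
        if self.outcome in df.columns and df[self.outcome].nunique() == 2:
            roc = logistic_roc(df, predictor=self.predictor, outcome=self.outcome)

        multivariate = None
        if covariates is None:
            covariates = [c for c in (self.predictor, "hematocrit",
                                      "prehospital_fluids") if c in df.columns]
        if roc is not None and len(covariates) > 1:
            multivariate = multivariate_logistic_lr(df, covariates,
                                                    outcome=self.outcome)
        return CohortResults(group_summary=gs, anova=anova, roc=roc,
                             multivariate=multivariate, normality=normality)
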