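"""Prognostic statistical layer.

Cox proportional hazards and Kaplan-Meier/log-rank analyses (overall and per
scan-delay window), 2-year dichotomized logistic/ROC modelling with Youden
thresholds, stratified train/test splitting with training-set feature
normalization, mRMR + AIC-stepwise selection, and Benjamini-Hochberg
adjustment.

Conventions fixed here: Efron tie handling in Cox fits; DeLong variance for
AUC confidence intervals; tercile discretization for mutual-information
estimates; dichotomization at 2 years of overall survival with
censored-before-endpoint records excluded from logistic analyses only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import mutual_info_score

from .phantom import SCAN_DELAY_GROUPS

__all__ = [
    "CoxResult",
    "RocResult",
    "KmResult",
    "SelectionResult",
    "dichotomize_os",
    "split_cohort",
    "normalize_features",
    "mrmr_select",
    "stepwise_logistic",
    "cox_fit",
    "km_logrank",
    "roc_youden",
    "bh_adjust",
    "subgroup_analysis",
    "combined_model",
    "TWO_YEARS_DAYS",
]

TWO_YEARS_DAYS = 730.0


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    covariate: str = ""
    log_hr: float = 0.0
    log_hr_se: float = 0.0

    def as_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "hr": self.hazard_ratio,
            "ci95": [self.ci_low, self.ci_high],
            "p": self.p_value,
            "n": self.n,
            "n_events": self.n_events,
        }


@dataclass
class KmResult:
    times: dict[str, np.ndarray]
    survival: dict[str, np.ndarray]
    logrank_statistic: float
    p_value: float


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    n: int


@dataclass
class SelectionResult:
    selected: list[str]
    coefficients: dict[str, float]
    aic: float
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def dichotomize_os(records: pd.DataFrame, endpoint_days: float = TWO_YEARS_DAYS) -> pd.DataFrame:
    """Long (OS >= endpoint) vs short (OS < endpoint with event) outcome.

    Patients censored before the endpoint are flagged excluded — they are
    dropped from logistic/ROC analyses but retained in Cox/KM.
    """
    out = records.copy()
    long_surv = out["os_days"] >= endpoint_days
    excluded = (out["os_days"] < endpoint_days) & (out["os_event"] == 0)
    out["long_survivor"] = long_surv.astype(int)
    out["endpoint_excluded"] = excluded.astype(int)
    return out


def split_cohort(records: pd.DataFrame, train_frac: float = 0.7, seed: int = 0,
                 outcome_col: str = "long_survivor"):
    """Stratified train/test split on the dichotomized outcome.

    Class proportions in the two sets agree within one patient.
    """
    if outcome_col not in records:
        records = dichotomize_os(records)
    eligible = records.loc[records.get("endpoint_excluded", 0) == 0]
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for _, grp in eligible.groupby(outcome_col):
        if len(grp) < 2:
            raise ValueError(f"outcome class with fewer than 2 members ({len(grp)})")
        order = grp.index.to_numpy()[rng.permutation(len(grp))]
        n_train = int(round(train_frac * len(grp)))
        n_train = min(max(n_train, 1), len(grp) - 1)
        train_idx.extend(order[:n_train])
        test_idx.extend(order[n_train:])
    return eligible.loc[sorted(train_idx)].copy(), eligible.loc[sorted(test_idx)].copy()


def normalize_features(train: pd.DataFrame, test: pd.DataFrame, feature_cols):
    """Z-score both sets with the training mean/s.d.; drop zero-variance
    features with a warning. Returns (train, test, scaler dict)."""
    scaler = {}
    kept = []
    train = train.copy()
    test = test.copy()
    for col in feature_cols:
        mu = float(train[col].mean())
        sd = float(train[col].std(ddof=0))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance feature {col!r}")
            train = train.drop(columns=col)
            test = test.drop(columns=col, errors="ignore")
            continue
        train[col] = (train[col] - mu) / sd
        test[col] = (test[col] - mu) / sd
        scaler[col] = (mu, sd)
        kept.append(col)
    return train, test, {"features": kept, "stats": scaler}


def _discretize_quantile(x: np.ndarray, bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(x, qs)


def mrmr_select(features: pd.DataFrame, outcome: np.ndarray, k: int, bins: int = 3) -> list[str]:
    """Greedy minimum-redundancy-maximum-relevance feature ordering.

    Relevance and redundancy are mutual information on quantile-discretized
    features (``bins`` levels, terciles by default). The first pick maximizes
    MI(feature; outcome); each next maximizes relevance minus the mean MI with
    the already-selected set. Ties break lexicographically on feature name.
    """
    cols = list(features.columns)
    if k > len(cols):
        raise ValueError(f"k={k} exceeds number of features ({len(cols)})")
    y = np.asarray(outcome)
    disc = {c: _discretize_quantile(features[c].to_numpy(dtype=float), bins) for c in cols}
    relevance = {c: mutual_info_score(disc[c], y) for c in cols}
    selected: list[str] = []
    remaining = sorted(cols)  # lexicographic tie-break baked into stable max
    pair_mi: dict[tuple[str, str], float] = {}

    def redundancy(c: str) -> float:
        if not selected:
            return 0.0
        vals = []
        for s in selected:
            key = (min(c, s), max(c, s))
            if key not in pair_mi:
                pair_mi[key] = mutual_info_score(disc[c], disc[s])
            vals.append(pair_mi[key])
        return float(np.mean(vals))

    while len(selected) < k:
        scores = [(relevance[c] - redundancy(c), c) for c in remaining]
        best_score = max(s for s, _ in scores)
        best = min(c for s, c in scores if s >= best_score - 1e-12)
        selected.append(best)
        remaining.remove(best)
    return selected


def _fit_logit(x: pd.DataFrame, y: np.ndarray):
    import statsmodels.api as sm

    design = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(model.params)) or np.any(np.abs(model.params) > 50):
                raise np.linalg.LinAlgError("separation")
            return model, None
        except Exception:
            # separation or non-convergence: ridge-penalized refit caps coefficients
            model = sm.Logit(y, design).fit_regularized(
                disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
            )
            return model, "separation detected: coefficients capped via L2 penalty"


def _logit_aic(model, n_params: int) -> float:
    return float(2 * n_params - 2 * model.llf)


def stepwise_logistic(train: pd.DataFrame, candidates, outcome_col: str = "long_survivor",
                      max_steps: int = 50) -> SelectionResult:
    """Bidirectional AIC-stepwise logistic regression on the dichotomized
    outcome, starting from the intercept-only model."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    y = train[outcome_col].to_numpy(dtype=int)
    notes: list[str] = []

    def fit_aic(cols: list[str]) -> float:
        if cols:
            model, note = _fit_logit(train[cols], y)
        else:
            model, note = _fit_logit(pd.DataFrame(index=train.index), y)
        if note:
            notes.append(note)
        return _logit_aic(model, len(cols) + 1)

    current: list[str] = []
    current_aic = fit_aic(current)
    for _ in range(max_steps):
        moves: list[tuple[float, str, str]] = []
        for c in candidates:
            if c not in current:
                moves.append((fit_aic(current + [c]), "add", c))
        for c in current:
            moves.append((fit_aic([x for x in current if x != c]), "drop", c))
        if not moves:
            break
        best_aic, action, col = min(moves, key=lambda m: (m[0], m[2]))
        if best_aic >= current_aic - 1e-9:
            break
        current_aic = best_aic
        if action == "add":
            current.append(col)
        else:
            current.remove(col)

    if current:
        final, note = _fit_logit(train[current], y)
    else:
        final, note = _fit_logit(pd.DataFrame(index=train.index), y)
    if note:
        notes.append(note)
    coefs = {name: float(val) for name, val in final.params.items()}
    return SelectionResult(
        selected=list(current),
        coefficients=coefs,
        aic=current_aic,
        warnings=sorted(set(notes)),
    )


def cox_fit(records: pd.DataFrame, covariates, endpoint: str = "OS") -> CoxResult | list[CoxResult]:
    """Cox proportional-hazards fit (Efron ties) for one or more covariates.

    A single covariate name returns one :class:`CoxResult` (univariate fit);
    a list returns one result per covariate from a joint multivariate fit.
    """
    single = isinstance(covariates, str)
    covs = [covariates] if single else list(covariates)
    time_col, event_col = ("os_days", "os_event") if endpoint.upper() == "OS" else (
        "pfs_days", "pfs_event")
    data = records[[time_col, event_col] + covs].dropna()
    n_events = int(data[event_col].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col=time_col, event_col=event_col)
    out = []
    for cov in covs:
        row = cph.summary.loc[cov]
        out.append(
            CoxResult(
                hazard_ratio=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
                n=int(len(data)),
                n_events=n_events,
                covariate=cov,
                log_hr=float(row["coef"]),
                log_hr_se=float(row["se(coef)"]),
            )
        )
    return out[0] if single else out


def km_logrank(records: pd.DataFrame, covariate: str, threshold: float,
               endpoint: str = "OS") -> KmResult:
    """Kaplan-Meier curves for covariate <= / > threshold plus log-rank test."""
    time_col, event_col = ("os_days", "os_event") if endpoint.upper() == "OS" else (
        "pfs_days", "pfs_event")
    data = records[[time_col, event_col, covariate]].dropna()
    high = data[covariate] > threshold
    if high.all() or (~high).all():
        raise ValueError("empty stratum at this threshold")
    curves_t, curves_s = {}, {}
    for name, sel in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(data.loc[sel, time_col], data.loc[sel, event_col])
        curves_t[name] = kmf.survival_function_.index.to_numpy(dtype=float)
        curves_s[name] = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    lr = logrank_test(
        data.loc[~high, time_col], data.loc[high, time_col],
        event_observed_A=data.loc[~high, event_col],
        event_observed_B=data.loc[high, event_col],
    )
    return KmResult(
        times=curves_t,
        survival=curves_s,
        logrank_statistic=float(lr.test_statistic),
        p_value=float(lr.p_value),
    )


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values via midrank comparison
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc_youden(scores: np.ndarray, outcomes: np.ndarray) -> RocResult:
    """Empirical ROC with trapezoidal AUC (= Mann-Whitney U / (n1*n0)),
    DeLong 95% CI and p vs 0.5, and the Youden-index threshold
    (argmax of sensitivity + specificity - 1; ties take the lowest)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    auc, var = _delong_variance(scores, y)
    se = float(np.sqrt(var))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * stats.norm.sf(abs(z)))
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
        ci = (auc, auc)

    best = (-np.inf, np.inf, 0.0, 0.0)  # (youden, threshold, sens, spec)
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = float(np.mean(pred[y == 1]))
        spec = float(np.mean(~pred[y == 0]))
        j = sens + spec - 1.0
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and thr < best[1]):
            best = (j, float(thr), sens, spec)
    return RocResult(
        auc=auc, ci_low=ci[0], ci_high=ci[1], p_value=p,
        youden_threshold=best[1], sensitivity=best[2], specificity=best[3],
        n=len(y),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment: adj p_(i) = min_{j>=i} m p_(j)/j,
    capped at 1. Monotone, idempotent, never below the raw p."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def subgroup_analysis(
    records: pd.DataFrame,
    covariates,
    endpoint: str = "OS",
    adjust_within: str = "covariate",
    min_events: int = 10,
) -> pd.DataFrame:
    """Per-scan-delay-window univariate Cox fits with BH-adjusted p-values.

    ``adjust_within="covariate"`` (default) adjusts across windows separately
    for each covariate; ``"all"`` adjusts over every row jointly. Windows with
    fewer than ``min_events`` events are flagged unstable; empty windows are
    skipped.
    """
    covs = [covariates] if isinstance(covariates, str) else list(covariates)
    rows = []
    for cov in covs:
        for window in ("all",) + SCAN_DELAY_GROUPS:
            sub = records if window == "all" else records[records["scan_delay_group"] == window]
            if len(sub) == 0:
                continue
            try:
                res = cox_fit(sub, cov, endpoint=endpoint)
            except ValueError:
                continue
            rows.append(
                {
                    "covariate": cov,
                    "window": window,
                    "n": res.n,
                    "n_events": res.n_events,
                    "mean": float(sub[cov].mean()),
                    "sd": float(sub[cov].std(ddof=1)),
                    "hr": res.hazard_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_raw": res.p_value,
                    "unstable": res.n_events < min_events,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = np.nan
    window_rows = table["window"] != "all"
    if adjust_within == "covariate":
        for cov in covs:
            sel = (table["covariate"] == cov) & window_rows
            if sel.any():
                table.loc[sel, "p_adj"] = bh_adjust(table.loc[sel, "p_raw"].to_numpy())
    else:
        if window_rows.any():
            table.loc[window_rows, "p_adj"] = bh_adjust(
                table.loc[window_rows, "p_raw"].to_numpy()
            )
    table.loc[~window_rows, "p_adj"] = table.loc[~window_rows, "p_raw"]
    table["significant"] = table["p_adj"] < 0.05
    return table


#: Nested model families evaluated by :func:`combined_model`.
MODEL_FAMILIES: dict[str, tuple[str, ...]] = {
    "clinical": ("age_years", "kps_ge90"),
    "perfusion": ("rcbv99", "psr_max_percent"),
    "thickness": ("mean_thickness_mm",),
    "radiomics": ("radiomics_score",),
    "combined": (
        "mean_thickness_mm", "rcbv99", "psr_max_percent", "radiomics_score",
        "age_years", "kps_ge90",
    ),
}


def combined_model(
    train: pd.DataFrame,
    test: pd.DataFrame,
    outcome_col: str = "long_survivor",
    families: dict[str, tuple[str, ...]] | None = None,
    min_rows: int = 10,
) -> dict[str, RocResult]:
    """Fit the nested prognostic model family on training data and evaluate
    each model's ROC on the held-out test set. Models whose complete-case
    training rows fall below ``min_rows`` are skipped (count logged)."""
    families = families or MODEL_FAMILIES
    out: dict[str, RocResult] = {}
    for name, cols in families.items():
        cols = [c for c in cols if c in train.columns]
        if not cols:
            continue
        tr = train[list(cols) + [outcome_col]].dropna()
        te = test[list(cols) + [outcome_col]].dropna()
        n_dropped = len(train) - len(tr)
        if len(tr) < min_rows or te.empty or te[outcome_col].nunique() < 2:
            warnings.warn(
                f"model {name!r}: skipped ({len(tr)} complete training rows, "
                f"{n_dropped} dropped)"
            )
            continue
        model, _ = _fit_logit(tr[cols], tr[outcome_col].to_numpy(dtype=int))
        import statsmodels.api as sm

        design = sm.add_constant(te[cols], has_constant="add")
        scores = np.asarray(model.predict(design), dtype=float)
        out[name] = roc_youden(scores, te[outcome_col].to_numpy(dtype=int))
    return out
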