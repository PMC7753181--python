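"""Global-radiomics signature modeling chain.

Stages, mirroring a standard peritumoral-radiomics workflow:

1. robustness filter — two-way random-effects, absolute-agreement,
   single-rater ICC (ICC(2,1)) across repeated delineations; features with
   ICC > 0.9 are considered stable;
2. feature reduction — PCA on z-scored training features keeping the
   smallest number of components reaching 95% explained variance, each
   component replaced by its surrogate: the feature with the largest
   absolute Pearson correlation to the component scores;
3. univariate logistic screen at alpha = 0.05 (Wald p, likelihood-ratio
   fallback under separation), no multiple-testing correction;
4. multivariate logistic regression with backward elimination by AIC;
5. evaluation — AUC of the linear predictor with a DeLong 95% CI (a model
   whose validation CI covers 0.5 fails validation), plus 5-fold
   cross-validation re-running the screen + backward selection per fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "ICCResult",
    "ModelSpec",
    "icc_filter",
    "icc_2_1",
    "pca_surrogates",
    "univariate_screen",
    "backward_aic",
    "auc_mann_whitney",
    "delong_ci",
    "evaluate",
    "cross_validate",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ICC robustness filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    feature_name: str
    icc: float
    stable: bool


def icc_2_1(table: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``table`` is (n targets/patients) x (k raters/observers).  Computed from
    the classical ANOVA mean squares:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    Returns NaN when the denominator vanishes (e.g. a constant table).
    """
    x = np.asarray(table, dtype=np.float64)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 targets and 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom):
        return np.nan
    return float((msr - mse) / denom)


def icc_filter(
    observer_tables: list[pd.DataFrame],
    features: list[str] | None = None,
    cutoff: float = 0.9,
) -> list[ICCResult]:
    """Per-feature ICC(2,1) across observers; stable iff ICC > cutoff.

    Each table is patients x features, identically indexed across observers.
    Features that are constant across both patients and observers have an
    undefined ICC and are flagged unstable.
    """
    if len(observer_tables) < 2:
        raise ValueError("need at least two observers")
    first = observer_tables[0]
    for t in observer_tables[1:]:
        if not t.index.equals(first.index) or not t.columns.equals(first.columns):
            raise ValueError("observer tables are misaligned (patients/features differ)")
    if features is None:
        features = list(first.columns)
    out = []
    for f in features:
        table = np.column_stack([t[f].to_numpy(dtype=np.float64) for t in observer_tables])
        icc = np.nan if not np.isfinite(table).all() else icc_2_1(table)
        out.append(ICCResult(feature_name=f, icc=icc, stable=bool(np.isfinite(icc) and icc > cutoff)))
    return out


# ---------------------------------------------------------------------------
# PCA surrogate reduction
# ---------------------------------------------------------------------------

def pca_surrogates(
    train: pd.DataFrame,
    features: list[str],
    variance_kept: float = 0.95,
) -> list[str]:
    """Surrogate features for the principal components carrying 95% variance.

    Features are z-scored with training statistics before PCA.  For each of
    the smallest set of leading components whose cumulative explained
    variance reaches ``variance_kept``, the surrogate is the feature with the
    largest |Pearson r| against the component scores (ties break toward the
    earlier feature in panel order); duplicates collapse.
    """
    X = train[features].to_numpy(dtype=np.float64)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [f for f, k in zip(features, keep) if not k]
    if dropped:
        log.warning("dropping %d zero-variance features before PCA: %s",
                    len(dropped), dropped[:5])
    feats = [f for f, k in zip(features, keep) if k]
    if len(feats) < 1:
        raise ValueError("no non-constant features for PCA")
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Xz)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, scores.shape[1])
    surrogates: list[str] = []
    for c in range(k):
        s = scores[:, c]
        if s.std() == 0:
            continue
        r = np.array([abs(np.corrcoef(Xz[:, j], s)[0, 1]) for j in range(Xz.shape[1])])
        best = feats[int(np.argmax(r))]
        if best not in surrogates:
            surrogates.append(best)
    return surrogates


# ---------------------------------------------------------------------------
# logistic regression helpers
# ---------------------------------------------------------------------------

def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Binomial GLM fit (IRLS); returns the fitted results or None."""
    try:
        with np.errstate(all="ignore"):
            model = sm.GLM(y, X, family=sm.families.Binomial())
            return model.fit(maxiter=200)
    except Exception:  # noqa: BLE001 — any numerical failure means "no fit"
        return None


def univariate_screen(
    train: pd.DataFrame,
    features: list[str],
    label_col: str = "label",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One logistic fit per feature: Wald p for the slope, training AUC, keep flag.

    Under (quasi-)separation the Wald statistic degenerates; the p-value then
    falls back to the likelihood-ratio test against the intercept-only model.
    Constant features are dropped with a warning.
    """
    y = train[label_col].to_numpy(dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training cohort")
    rows = []
    for f in features:
        x = train[f].to_numpy(dtype=np.float64)
        if not np.isfinite(x).all():
            log.warning("feature %s has missing values; dropped from screen", f)
            continue
        if x.std() == 0:
            log.warning("constant feature %s has undefined slope; dropped", f)
            continue
        X = sm.add_constant((x - x.mean()) / x.std(), prepend=True)
        res = _fit_logit(y, X)
        if res is None:
            log.warning("logistic fit failed for %s; dropped", f)
            continue
        p_wald = float(res.pvalues[1])
        separated = (not np.isfinite(p_wald)) or float(res.bse[1]) > 50.0
        if separated:
            llf = float(res.llf)
            if not np.isfinite(llf):
                llf = 0.0  # perfect separation: the likelihood supremum
            ll0 = float(_fit_logit(y, np.ones((len(y), 1))).llf)
            p_val = float(stats.chi2.sf(2.0 * (llf - ll0), df=1))
            method = "likelihood_ratio"
        else:
            p_val, method = p_wald, "wald"
        score = X @ res.params
        rows.append(
            {
                "feature": f,
                "auc": auc_mann_whitney(y, np.asarray(score)),
                "p_value": p_val,
                "method": method,
                "keep": p_val < alpha,
            }
        )
    return pd.DataFrame(rows, columns=["feature", "auc", "p_value", "method", "keep"])


@dataclass
class ModelSpec:
    """A fitted logistic signature: intercept, coefficients, selection trace."""

    intercept: float
    coefficients: dict[str, float]
    trace: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def features(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(cohort), self.intercept, dtype=np.float64)
        for f, b in self.coefficients.items():
            lp += b * cohort[f].to_numpy(dtype=np.float64)
        return lp

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "trace": self.trace,
            "seed": self.seed,
        }


def _aic_for(y: np.ndarray, cohort: pd.DataFrame, feats: list[str]):
    X = np.column_stack([np.ones(len(y))] + [cohort[f].to_numpy(dtype=np.float64) for f in feats])
    res = _fit_logit(y, X)
    return (None, np.inf) if res is None else (res, float(res.aic))


def backward_aic(
    train: pd.DataFrame,
    candidate_features: list[str],
    label_col: str = "label",
) -> ModelSpec:
    """Backward elimination by AIC from the full multivariate logistic model.

    At each step the removal that most decreases AIC is applied (ties: drop
    the earlier-listed feature); elimination stops when no removal lowers
    AIC.  The intercept-only model is a legal endpoint.
    """
    if not candidate_features:
        raise ValueError("no candidate features")
    y = train[label_col].to_numpy(dtype=np.float64)
    feats = list(candidate_features)
    res, aic = _aic_for(y, train, feats)
    trace = [{"step": 0, "features": list(feats), "aic": aic, "removed": None}]
    step = 0
    while feats:
        options = []
        for f in feats:
            reduced = [g for g in feats if g != f]
            _, aic_r = _aic_for(y, train, reduced)
            options.append((aic_r, f))
        best_aic, best_f = min(options, key=lambda t: (t[0], feats.index(t[1])))
        if best_aic < aic - 1e-12:
            feats.remove(best_f)
            aic = best_aic
            step += 1
            trace.append({"step": step, "features": list(feats), "aic": aic, "removed": best_f})
        else:
            break
    res, aic = _aic_for(y, train, feats)
    if res is None:
        raise RuntimeError("final logistic fit failed")
    params = np.asarray(res.params, dtype=np.float64)
    return ModelSpec(
        intercept=float(params[0]),
        coefficients={f: float(b) for f, b in zip(feats, params[1:])},
        trace=trace,
    )


# ---------------------------------------------------------------------------
# AUC and DeLong confidence interval
# ---------------------------------------------------------------------------

def auc_mann_whitney(y: np.ndarray, score: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance of scores (ties count 1/2)."""
    y = np.asarray(y)
    score = np.asarray(score, dtype=np.float64)
    pos = score[y == 1]
    neg = score[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_ci(y: np.ndarray, score: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong analytic confidence interval (clipped to [0, 1])."""
    y = np.asarray(y)
    score = np.asarray(score, dtype=np.float64)
    pos = score[y == 1]
    neg = score[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("DeLong CI needs both classes")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n          # structural components over positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # over negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), float(lo), float(hi)


def evaluate(model: ModelSpec, cohort: pd.DataFrame, label_col: str = "label") -> dict:
    """AUC (Mann-Whitney) with DeLong 95% CI for a model on a cohort.

    ``validated`` is False when the CI covers 0.5 (random-predictor band).
    """
    y = cohort[label_col].to_numpy(dtype=np.float64)
    score = model.linear_predictor(cohort)
    auc, lo, hi = delong_ci(y, score)
    return {
        "auc": auc,
        "ci_low": lo,
        "ci_high": hi,
        "n": int(len(y)),
        "validated": not (lo <= 0.5 <= hi),
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(idx, k)]


def cross_validate(
    train: pd.DataFrame,
    feature_pool: list[str],
    label_col: str = "label",
    k: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    max_refolds: int = 100,
) -> dict:
    """k-fold CV re-running the full selection chain (screen + backward AIC) per fold.

    Folds are a random partition without repetition.  If any fold lacks a
    class (held-out or training side), the cohort is re-partitioned with an
    incremented seed, which is logged.
    """
    n = len(train)
    if n < k:
        raise ValueError(f"need at least {k} patients for {k}-fold CV")
    y_all = train[label_col].to_numpy()
    attempt = 0
    while True:
        rng = np.random.default_rng(seed + attempt)
        folds = _partition(n, k, rng)
        ok = all(
            len(np.unique(y_all[f])) == 2 and len(np.unique(np.delete(y_all, f))) == 2
            for f in folds
        )
        if ok:
            break
        attempt += 1
        if attempt > max_refolds:
            raise ValueError("could not form class-balanced folds")
        log.warning("fold with a single class; re-partitioning with seed %d", seed + attempt)
    fold_aucs = []
    for f in folds:
        tr = train.iloc[np.delete(np.arange(n), f)].reset_index(drop=True)
        te = train.iloc[f].reset_index(drop=True)
        screen = univariate_screen(tr, feature_pool, label_col=label_col, alpha=alpha)
        kept = screen[screen["keep"]]["feature"].tolist()
        if kept:
            model = backward_aic(tr, kept, label_col=label_col)
        else:  # nothing passes the screen in this fold: intercept-only model
            model = ModelSpec(intercept=0.0, coefficients={})
        if model.coefficients:
            score = model.linear_predictor(te)
        else:
            score = np.zeros(len(te))
        fold_aucs.append(auc_mann_whitney(te[label_col].to_numpy(), score))
    return {
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "range": (float(np.min(fold_aucs)), float(np.max(fold_aucs))),
        "k": k,
        "seed": seed + attempt,
    }
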