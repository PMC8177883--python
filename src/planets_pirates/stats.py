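"""Cohort-level statistics: one-sample ratio tests, single-df orthogonal
contrast ANOVA for mixed (between x within) designs, correlation-matrix PCA
with varimax rotation and a communality-based retention rule, and stepwise
linear/logistic regression with Nagelkerke pseudo-r².

The contrast ANOVA follows the classic single-degree-of-freedom reduction:
each within-subject contrast ``c`` is collapsed to a per-subject score
``L_i = sum_j c_j x_ij``; the within effect tests the (unweighted) grand
mean of ``L`` against zero on the pooled within-group error, F(1, n - g);
the contrast-by-group interaction is a one-way ANOVA on ``L``; the
between-groups effect is a one-way ANOVA on subject cell means.  This
reproduces the F(1, .) pattern conventional for contrast-coded repeated
measures output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

COLLINEARITY_TOL = 1e-8


# ---- one-sample ratio test --------------------------------------------


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    infinite: bool = False   # zero variance with mean != null


def one_sample_ratio_test(values, null: float = 0.5) -> TTestResult:
    """Two-sided one-sample Student t of a ratio against a null value."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite values")
    if np.ptp(x) == 0:
        if x[0] == null:
            return TTestResult(t=0.0, df=x.size - 1, p=1.0, mean=float(x[0]))
        sign = 1.0 if x[0] > null else -1.0
        return TTestResult(t=sign * np.inf, df=x.size - 1, p=0.0,
                           mean=float(x[0]), infinite=True)
    res = sps.ttest_1samp(x, popmean=null)
    return TTestResult(t=float(res.statistic), df=int(x.size - 1),
                       p=float(res.pvalue), mean=float(x.mean()))


# ---- orthogonal-contrast mixed ANOVA ----------------------------------


def _one_way_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, int, int, float]:
    levels = np.unique(groups)
    n, g = values.size, levels.size
    grand = values.mean()
    ss_between = sum(np.sum(groups == lv) * (values[groups == lv].mean() - grand) ** 2
                     for lv in levels)
    ss_within = sum(np.sum((values[groups == lv] - values[groups == lv].mean()) ** 2)
                    for lv in levels)
    df1, df2 = g - 1, n - g
    if df2 <= 0 or ss_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
        return f, df1, max(df2, 0), (0.0 if ss_between > 0 else 1.0)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def contrast_anova(cells: pd.DataFrame, contrasts: dict,
                   groups: pd.Series | np.ndarray | None = None) -> pd.DataFrame:
    """Single-df contrast tests on a participants x condition-cells matrix.

    ``contrasts`` maps effect names to coefficient vectors over the cell
    columns; each must sum to zero and the family must be mutually
    orthogonal.  Returns a tidy frame with one row per within effect, per
    within x group interaction (if groups given), and the between-groups
    effect on subject cell means.  Rows with missing cells are dropped
    (pairwise complete-case per analysis is the caller's responsibility).
    """
    X = cells.to_numpy(dtype=float)
    keep = ~np.isnan(X).any(axis=1)
    X = X[keep]
    n, m = X.shape
    names = list(contrasts)
    C = {k: np.asarray(v, dtype=float) for k, v in contrasts.items()}
    for k, c in C.items():
        if c.size != m:
            raise ValueError(f"contrast {k!r} has {c.size} coefficients for {m} cells")
        if abs(c.sum()) > 1e-10:
            raise ValueError(f"contrast {k!r} does not sum to zero")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if abs(np.dot(C[a], C[b])) > 1e-10:
                raise ValueError(f"contrasts {a!r} and {b!r} are not orthogonal")

    if groups is None:
        grp = np.zeros(n, dtype=int)
    else:
        grp = np.asarray(pd.Series(groups))[keep] if len(groups) == len(keep) \
            else np.asarray(pd.Series(groups))
        if grp.shape[0] != n:
            raise ValueError("groups length does not match cells rows")
    levels = np.unique(grp)
    g = levels.size

    rows = []
    for name, c in C.items():
        L = X @ c
        group_means = np.array([L[grp == lv].mean() for lv in levels])
        counts = np.array([np.sum(grp == lv) for lv in levels])
        ss_within = sum(np.sum((L[grp == lv] - L[grp == lv].mean()) ** 2)
                        for lv in levels)
        df2 = n - g
        mse = ss_within / df2 if df2 > 0 else np.nan
        # within effect: unweighted grand mean of L vs 0
        mu = group_means.mean()
        var_mu = mse * np.sum(1.0 / counts) / g**2
        if var_mu > 0:
            f = mu**2 / var_mu
            p = float(sps.f.sf(f, 1, df2))
        else:
            f, p = (np.inf, 0.0) if mu != 0 else (0.0, 1.0)
        rows.append({"effect": name, "F": float(f), "df1": 1, "df2": df2, "p": p})
        if g > 1:
            fi, d1, d2, pi = _one_way_anova(L, grp)
            rows.append({"effect": f"{name} x group", "F": fi, "df1": d1,
                         "df2": d2, "p": pi})
    if g > 1:
        M = X.mean(axis=1)
        fb, d1, d2, pb = _one_way_anova(M, grp)
        rows.append({"effect": "group", "F": fb, "df1": d1, "df2": d2, "p": pb})
    return pd.DataFrame(rows)


# ---- PCA with varimax rotation ----------------------------------------


@dataclass
class PCAResult:
    n_components: int
    loadings: pd.DataFrame           # items x components, varimax-rotated
    communalities: pd.Series
    variance_explained: np.ndarray   # per rotated component, fraction of total
    total_variance_explained: float
    annotations: pd.DataFrame        # '++' > 0.707, '+' > 0.5, '' otherwise
    dropped_items: list = field(default_factory=list)


def _varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Classic varimax rotation (SVD form); returns the rotated loadings."""
    p, k = L.shape
    if k < 2:
        return L.copy()
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p))
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return L @ R


def pca_varimax(items: pd.DataFrame, min_communality: float = 0.5) -> PCAResult:
    """Correlation-matrix PCA retaining the smallest number of components
    that extracts at least ``min_communality`` of every item's variance,
    then varimax-rotated with Kaiser normalisation.

    Constant items are dropped with a warning; rows with any missing value
    are dropped listwise.
    """
    df = items.dropna()
    dropped = [c for c in df.columns if np.ptp(df[c].to_numpy(float)) == 0]
    if dropped:
        warnings.warn(f"dropping constant items: {dropped}", stacklevel=2)
        df = df.drop(columns=dropped)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 non-constant items")
    X = df.to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    full = eigvecs * np.sqrt(eigvals)
    p = df.shape[1]
    m = p
    for k in range(1, p + 1):
        comm = (full[:, :k] ** 2).sum(axis=1)
        if np.all(comm >= min_communality - 1e-12):
            m = k
            break
    L = full[:, :m]
    comm = (L**2).sum(axis=1)
    # Kaiser normalisation: rotate rows scaled to unit communality
    h = np.sqrt(np.maximum(comm, 1e-12))
    Lr = _varimax(L / h[:, None]) * h[:, None]
    # orient each component so its largest-magnitude loading is positive
    for j in range(m):
        if Lr[np.abs(Lr[:, j]).argmax(), j] < 0:
            Lr[:, j] = -Lr[:, j]
    var_expl = (Lr**2).sum(axis=0) / p
    order2 = np.argsort(var_expl)[::-1]
    Lr, var_expl = Lr[:, order2], var_expl[order2]
    comp_names = [f"PC{j + 1}" for j in range(m)]
    loadings = pd.DataFrame(Lr, index=df.columns, columns=comp_names)
    ann = loadings.abs().map(lambda v: "++" if v > 0.707 else ("+" if v > 0.5 else ""))
    return PCAResult(
        n_components=m,
        loadings=loadings,
        communalities=pd.Series(comm, index=df.columns, name="communality"),
        variance_explained=var_expl,
        total_variance_explained=float(var_expl.sum()),
        annotations=ann,
        dropped_items=dropped,
    )


# ---- stepwise linear regression ---------------------------------------


@dataclass
class StepwiseStep:
    action: str       # "enter" | "remove"
    variable: str
    F: float
    p: float
    r2: float         # model r² after this step
    delta_r2: float


@dataclass
class StepwiseLinearResult:
    included: list
    steps: list
    r2: float
    params: pd.Series | None      # final coefficients (const first)
    skipped_collinear: list = field(default_factory=list)

    @property
    def path_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def stepwise_linear(y, X: pd.DataFrame, p_enter: float = 0.05,
                    p_remove: float = 0.10) -> StepwiseLinearResult:
    """SPSS-style stepwise OLS: forward entry of the smallest partial-F
    p-value <= ``p_enter``, backward removal of any retained predictor whose
    partial p >= ``p_remove``.  Deterministic; ties broken by larger r²
    increment, then column order.  Near-collinear candidates (tolerance
    below 1e-8 given the current model) are skipped with a warning.
    """
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if n <= X.shape[1] + 2:
        raise ValueError("need n > number of predictors + 2")
    cols = list(X.columns)
    Xv = {c: np.asarray(X[c], dtype=float) for c in cols}
    const = np.ones(n)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    included: list[str] = []
    steps: list[StepwiseStep] = []
    skipped: list[str] = []

    def design(names):
        return np.column_stack([const] + [Xv[c] for c in names])

    while True:
        base = design(included)
        rss_base = _rss(yv, base)
        df_base = n - base.shape[1]
        if rss_base <= max(tss, 1.0) * 1e-12:
            break  # perfect fit: nothing left to explain
        # forward step
        best = None
        for c in cols:
            if c in included:
                continue
            xc = Xv[c]
            # tolerance: share of xc's variance not explained by current model
            rss_x = _rss(xc, base)
            ss_x = float(np.sum((xc - xc.mean()) ** 2))
            if ss_x <= 0 or rss_x / ss_x < COLLINEARITY_TOL:
                if c not in skipped:
                    warnings.warn(f"skipping collinear predictor {c!r}", stacklevel=2)
                    skipped.append(c)
                continue
            rss_new = _rss(yv, design(included + [c]))
            df_new = df_base - 1
            if df_new <= 0:
                continue
            f = (rss_base - rss_new) / (rss_new / df_new) if rss_new > 0 else np.inf
            p = float(sps.f.sf(f, 1, df_new)) if np.isfinite(f) else 0.0
            delta_r2 = (rss_base - rss_new) / tss if tss > 0 else 0.0
            key = (p, -delta_r2, cols.index(c))
            if best is None or key < best[0]:
                best = (key, c, f, p, rss_new, delta_r2)
        if best is None or best[3] > p_enter:
            break
        _, c, f, p, rss_new, delta_r2 = best
        included.append(c)
        steps.append(StepwiseStep("enter", c, float(f), float(p),
                                  1 - rss_new / tss if tss > 0 else np.nan,
                                  float(delta_r2)))
        # backward sweep
        changed = True
        while changed and len(included) > 1:
            changed = False
            full = design(included)
            rss_full = _rss(yv, full)
            df_full = n - full.shape[1]
            worst = None
            for c in included:
                others = [v for v in included if v != c]
                rss_red = _rss(yv, design(others))
                f_c = ((rss_red - rss_full) / (rss_full / df_full)
                       if rss_full > 0 else np.inf)
                p_c = float(sps.f.sf(f_c, 1, df_full)) if np.isfinite(f_c) else 0.0
                if worst is None or p_c > worst[1]:
                    worst = (c, p_c, f_c, rss_red)
            if worst is not None and worst[1] >= p_remove:
                c, p_c, f_c, rss_red = worst
                included.remove(c)
                steps.append(StepwiseStep("remove", c, float(f_c), float(p_c),
                                          1 - rss_red / tss if tss > 0 else np.nan,
                                          float(-(rss_red - rss_full) / tss)))
                changed = True

    final = design(included)
    rss_final = _rss(yv, final)
    r2 = 1 - rss_final / tss if tss > 0 else np.nan
    beta, *_ = np.linalg.lstsq(final, yv, rcond=None)
    params = pd.Series(beta, index=["const"] + included)
    return StepwiseLinearResult(included=included, steps=steps, r2=float(r2),
                                params=params, skipped_collinear=skipped)


# ---- stepwise logistic regression -------------------------------------


@dataclass
class StepwiseLogisticResult:
    included: list
    steps: list                    # (action, variable, LR_chi2, p)
    nagelkerke_r2: float
    accuracy: float                # in-sample, 0.5 threshold
    params: pd.Series | None
    separation_flag: bool = False


def nagelkerke_r2(ll_null: float, ll_model: float, n: int) -> float:
    """Nagelkerke pseudo-r²: Cox-Snell normalised to a [0, 1] maximum."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(cox_snell / max_cs)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200, method="newton")
        except Exception:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
    return res


def stepwise_logistic(labels, X: pd.DataFrame, p_enter: float = 0.05,
                      p_remove: float = 0.10) -> StepwiseLogisticResult:
    """Likelihood-ratio stepwise logistic regression.

    Entry requires the smallest LR-test p-value <= ``p_enter``; retained
    predictors with LR p >= ``p_remove`` are removed.  Perfect separation is
    flagged (coefficients then reported as non-converged estimates).
    """
    yv = np.asarray(labels, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if yv.min() == yv.max():
        raise ValueError("both classes must be present")
    n = yv.size
    cols = list(X.columns)
    const = np.ones((n, 1))

    def design(names):
        if not names:
            return const
        return np.column_stack([const] + [np.asarray(X[c], dtype=float) for c in names])

    included: list[str] = []
    steps = []
    res_cur = _fit_logit(yv, design(included))
    ll_null = float(res_cur.llf)
    separation = False
    while True:
        ll_cur = float(res_cur.llf)
        best = None
        for c in cols:
            if c in included:
                continue
            try:
                res_new = _fit_logit(yv, design(included + [c]))
            except Exception:
                continue
            lr = 2.0 * (float(res_new.llf) - ll_cur)
            p = float(sps.chi2.sf(max(lr, 0.0), 1))
            key = (p, -lr, cols.index(c))
            if best is None or key < best[0]:
                best = (key, c, lr, p, res_new)
        if best is None or best[3] > p_enter:
            break
        _, c, lr, p, res_new = best
        included.append(c)
        res_cur = res_new
        steps.append(("enter", c, float(lr), float(p)))
        # backward sweep
        changed = True
        while changed and len(included) > 1:
            changed = False
            ll_full = float(res_cur.llf)
            worst = None
            for c2 in included:
                others = [v for v in included if v != c2]
                res_red = _fit_logit(yv, design(others))
                lr2 = 2.0 * (ll_full - float(res_red.llf))
                p2 = float(sps.chi2.sf(max(lr2, 0.0), 1))
                if worst is None or p2 > worst[1]:
                    worst = (c2, p2, lr2, res_red)
            if worst is not None and worst[1] >= p_remove:
                c2, p2, lr2, res_red = worst
                included.remove(c2)
                res_cur = res_red
                steps.append(("remove", c2, float(lr2), float(p2)))
                changed = True

    fitted = np.asarray(res_cur.predict(design(included)), dtype=float)
    accuracy = float(np.mean((fitted >= 0.5) == (yv == 1)))
    # a perfectly classifying fit with all probabilities pinned at 0/1
    # indicates (quasi-)separation: the MLE does not exist
    if included and accuracy == 1.0 and np.all(np.abs(fitted - yv) < 0.01):
        separation = True
    r2 = nagelkerke_r2(ll_null, float(res_cur.llf), n)
    names = ["const"] + included
    params = pd.Series(np.asarray(res_cur.params, dtype=float), index=names)
    return StepwiseLogisticResult(included=included, steps=steps,
                                  nagelkerke_r2=r2, accuracy=accuracy,
                                  params=params, separation_flag=separation)
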