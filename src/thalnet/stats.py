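"""Group-level statistical battery.

Mixed (between x within) repeated-measures ANOVA with partial eta squared,
planned one-sample / paired / independent t-tests with Cohen d and
Bonferroni correction, Pearson correlations, and edgewise group t-maps.

Within-subject effects are tested with the multivariate approach: the
within-cell responses are projected onto difference contrasts and the
resulting multivariate linear hypothesis is evaluated with Pillai's trace
(reported default; when the hypothesis has a single degree of freedom the F
is exact and identical to Wilks') and Wilks' lambda with Rao's F
approximation, side by side.  Between-subject effects use the univariate
ANOVA on subject means.  Partial eta squared is reported through the
conversion ``F * df1 / (F * df1 + df2)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

# ---------------------------------------------------------------------------
# effect sizes & corrections


def partial_eta_from_F(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic and its degrees of freedom."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# t-tests


@dataclass
class TTestResult:
    mean: float
    sd: float
    n: int
    t: float
    df: float
    p_uncorrected: float
    p_bonferroni: float
    cohen_d: float
    mean_diff: float | None = None  # paired / independent contrasts


def one_sample_t(
    values: np.ndarray | None = None,
    *,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    mu: float = 0.0,
    m: int = 1,
) -> TTestResult:
    """One-sample t-test against ``mu`` from raw values or summary statistics.

    Cohen d is reported as a magnitude (|mean - mu| / sd); the sign of the
    deviation is carried by ``mean``.
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        n = len(values)
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
    if n is None or mean is None or sd is None:
        raise ValueError("provide raw values or (mean, sd, n)")
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        if mean == mu:
            # degenerate null sample (e.g. all zeros against mu=0)
            return TTestResult(mean, 0.0, n, 0.0, n - 1, 1.0, 1.0, 0.0)
        raise ValueError("sd must be positive")
    t = (mean - mu) / (sd / np.sqrt(n))
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    d = abs(mean - mu) / sd
    return TTestResult(mean, sd, n, t, df, p, bonferroni(p, m), d)


def paired_t(a: np.ndarray, b: np.ndarray, m: int = 1) -> TTestResult:
    """Paired t-test (a - b); d = |mean diff| / sd(diff)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    res = one_sample_t(diff, m=m)
    res.mean_diff = res.mean
    return res


def independent_t(
    a: np.ndarray, b: np.ndarray, m: int = 1, equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test (pooled-variance by default; Welch behind a switch)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        # degenerate but well-defined null case
        t, df, p = 0.0, len(a) + len(b) - 2, 1.0
        sp = 0.0
    else:
        if va == 0 and vb == 0:
            raise ValueError("zero variance in both groups with unequal means")
        if equal_var:
            t, p = sps.ttest_ind(a, b, equal_var=True)
            df = len(a) + len(b) - 2
            sp = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / df)
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
            df = sps.ttest_ind(a, b, equal_var=False).df
            sp = np.sqrt((va + vb) / 2)
    diff = a.mean() - b.mean()
    d = abs(diff) / sp if sp > 0 else 0.0
    return TTestResult(
        float(a.mean()), float(np.sqrt(va)), len(a), float(t), float(df),
        float(p), bonferroni(float(p), m), float(d), mean_diff=float(diff),
    )


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA (multivariate approach)


@dataclass
class MixedAnovaResult:
    effect: str
    statistic: str  # 'pillai', 'wilks', or 'F' (univariate between)
    value: float    # Pillai's V / Wilks' lambda / nan for univariate
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float


def _difference_contrast(k: int) -> np.ndarray:
    """k x (k-1) contrast matrix whose columns span deviations from level 1."""
    c = np.zeros((k, k - 1))
    c[0, :] = 1.0
    for j in range(k - 1):
        c[j + 1, j] = -1.0
    return c


def _pillai(H: np.ndarray, E: np.ndarray, p: int, h: int, e: float):
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p, h)
    m_ = (abs(p - h) - 1) / 2.0
    n_ = (e - p - 1) / 2.0
    df1 = s * (2 * m_ + s + 1)
    df2 = s * (2 * n_ + s + 1)
    F = (df2 / df1) * V / (s - V)
    return V, F, df1, df2


def _wilks(H: np.ndarray, E: np.ndarray, p: int, h: int, e: float):
    lam = float(np.linalg.det(E) / np.linalg.det(H + E))
    pq = p * h
    if p**2 + h**2 - 5 > 0:
        t = np.sqrt((p**2 * h**2 - 4) / (p**2 + h**2 - 5))
    else:
        t = 1.0
    df1 = pq
    df2 = t * (e - (p - h + 1) / 2.0) - (pq - 2) / 2.0
    F = ((1 - lam ** (1 / t)) / lam ** (1 / t)) * df2 / df1
    return lam, F, df1, df2


def _mlm_hypothesis(Yc, X, L):
    """H and E SSCP matrices for the hypothesis L @ B = 0 in Yc = X B + E."""
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ X.T @ Yc
    E = Yc.T @ Yc - B.T @ XtX @ B
    LB = L @ B
    M = L @ XtX_inv @ L.T
    H = LB.T @ np.linalg.solve(M, LB)
    return H, E


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str,
) -> list[MixedAnovaResult]:
    """Mixed ANOVA with one between factor and one or two within factors.

    ``data`` is long-format with one row per subject x within-cell.  Every
    subject must have a value for every within-cell (complete crossed
    design).  Returns results for each within effect, its interaction with
    the between factor, and the between-subject main effect, with Pillai
    (default-reported) and Wilks forms for the within effects.
    """
    within_levels = {w: sorted(data[w].unique()) for w in within}
    cells = list(itertools.product(*[within_levels[w] for w in within]))
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="first", observed=True
    )
    if len(within) == 1:
        wide = wide.reindex(columns=[c[0] for c in cells])
    else:
        wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells))
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"incomplete within-subject design for subjects {bad}")

    grp = (
        data[[subject, between]].drop_duplicates().set_index(subject)[between]
    ).reindex(wide.index)
    if grp.isna().any():
        raise ValueError("missing between-group label for some subjects")
    glevels = sorted(grp.unique())
    g = len(glevels)
    ncell = grp.value_counts()
    if (ncell < 2).any():
        raise ValueError("need >= 2 subjects per between-group cell")
    N = len(wide)
    Y = wide.to_numpy(float)

    # effect-coded between design: intercept = unweighted mean of group means
    X = np.ones((N, g))
    for j, lev in enumerate(glevels[:-1]):
        col = np.where(grp == lev, 1.0, 0.0) - np.where(grp == glevels[-1], 1.0, 0.0)
        X[:, j + 1] = col
    e_df = N - g

    results: list[MixedAnovaResult] = []

    # within effects: all non-empty subsets of within factors
    contrasts = {w: _difference_contrast(len(within_levels[w])) for w in within}
    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(within, r):
            M = np.ones((1, 1))
            for w in within:
                Cw = contrasts[w] if w in subset else np.ones((len(within_levels[w]), 1))
                M = np.kron(M, Cw)
            Yc = Y @ M
            p = Yc.shape[1]
            name = " x ".join(subset)
            for L, h, suffix in (
                (np.eye(g)[:1], 1, ""),                      # grand-mean test
                (np.eye(g)[1:], g - 1, f" x {between}"),     # interaction
            ):
                H, E = _mlm_hypothesis(Yc, X, L)
                V, Fp, d1p, d2p = _pillai(H, E, p, h, e_df)
                results.append(MixedAnovaResult(
                    name + suffix, "pillai", V, Fp, d1p, d2p,
                    float(sps.f.sf(Fp, d1p, d2p)),
                    partial_eta_from_F(Fp, d1p, d2p),
                ))
                lam, Fw, d1w, d2w = _wilks(H, E, p, h, e_df)
                results.append(MixedAnovaResult(
                    name + suffix, "wilks", lam, Fw, d1w, d2w,
                    float(sps.f.sf(Fw, d1w, d2w)),
                    partial_eta_from_F(Fw, d1w, d2w),
                ))

    # between-subject main effect: univariate ANOVA on subject means
    means = Y.mean(axis=1)
    groups = [means[(grp == lev).to_numpy()] for lev in glevels]
    Fb, pb = sps.f_oneway(*groups)
    results.append(MixedAnovaResult(
        between, "F", np.nan, float(Fb), g - 1, N - g, float(pb),
        partial_eta_from_F(float(Fb), g - 1, N - g),
    ))
    return results


def anova_table(results: list[MixedAnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "statistic": r.statistic,
                "value": r.value,
                "F": r.F,
                "df1": r.df1,
                "df2": r.df2,
                "p": r.p,
                "partial_eta_sq": r.partial_eta_sq,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_uncorrected: float
    p_corrected: float


def pearson_corr(x: np.ndarray, y: np.ndarray, m: int = 1) -> CorrelationResult:
    """Pearson correlation with two-sided p and Bonferroni-corrected p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), len(x), float(p), bonferroni(float(p), m))


# ---------------------------------------------------------------------------
# edgewise maps & control profiles


def edgewise_map(
    matrices_a: dict[str, np.ndarray],
    matrices_b: dict[str, np.ndarray],
    atlas,
    subdivision: str,
    side: str,
) -> pd.DataFrame:
    """Independent t per edge from one thalamic subdivision to all regions.

    Group A vs group B (positive t = stronger connectivity in A).  P-values
    are uncorrected by design: these maps are exploratory.
    """
    from .network import extract_thalamic_edges

    if not matrices_a or not matrices_b:
        raise ValueError("both matrix sets must be non-empty")
    ea = pd.DataFrame(
        {s: extract_thalamic_edges(m, atlas, subdivision, side)
         for s, m in matrices_a.items()}
    ).T
    eb = pd.DataFrame(
        {s: extract_thalamic_edges(m, atlas, subdivision, side)
         for s, m in matrices_b.items()}
    ).T
    if list(ea.columns) != list(eb.columns):
        raise ValueError("edge target labels do not match between groups")
    rows = []
    for target in ea.columns:
        res = independent_t(ea[target].to_numpy(), eb[target].to_numpy())
        rows.append(
            {"subdivision": subdivision, "side": side, "target": target,
             "t": res.t, "p_uncorrected": res.p_uncorrected}
        )
    return pd.DataFrame(rows)


def control_profile(
    matrices: dict[str, np.ndarray],
    atlas,
    subdivision: str,
    covariates: pd.DataFrame | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Mean hemisphere-averaged edge profile of a subdivision in controls.

    Edge values are optionally adjusted for covariates (age, sex) by
    removing the fitted covariate component, then averaged across the two
    hemispheres per homologous target, averaged over subjects, and ranked
    in descending order of connectivity.
    """
    from .network import extract_thalamic_edges

    if len(matrices) < 2:
        raise ValueError("need at least 2 control subjects")
    per_side = {}
    for side in ("L", "R"):
        tab = pd.DataFrame(
            {s: extract_thalamic_edges(m, atlas, subdivision, side)
             for s, m in matrices.items()}
        ).T
        if covariates is not None:
            C = covariates.reindex(tab.index).to_numpy(float)
            Xd = np.hstack([np.ones((len(tab), 1)), C - C.mean(axis=0)])
            B, *_ = np.linalg.lstsq(Xd, tab.to_numpy(), rcond=None)
            tab = pd.DataFrame(
                tab.to_numpy() - (Xd[:, 1:] @ B[1:]),
                index=tab.index, columns=tab.columns,
            )
        # collapse targets to hemisphere-neutral base labels
        base = {}
        for col in tab.columns:
            key = col[2:] if col[:2] in ("L_", "R_") else col
            base.setdefault(key, []).append(col)
        collapsed = pd.DataFrame(
            {key: tab[cols].mean(axis=1) for key, cols in base.items()}
        )
        per_side[side] = collapsed.mean(axis=0)
    profile = (per_side["L"] + per_side["R"]) / 2
    # drop the seed subdivision's own homologue (self-pair across hemispheres)
    profile = profile.drop(index=f"thal_{subdivision}", errors="ignore")
    out = profile.sort_values(ascending=False).reset_index()
    out.columns = ["target", "mean_connectivity"]
    out.insert(0, "subdivision", subdivision)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out
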