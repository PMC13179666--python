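"""Empirical-Bayes location/scale batch harmonization (ComBat).

Removes additive and multiplicative scanner/batch effects from feature
tables (thalamic volumes, vectorized connectivity edges) while preserving
designated biological covariates (age, sex, group).  Model per feature f and
subject i in batch b::

    y_ifb = alpha_f + x_i' beta_f + gamma_bf + delta_bf * eps_ifb

Batch locations gamma and scales delta are shrunk toward parametric
empirical-Bayes priors (normal on locations, inverse-gamma on scales,
hyperparameters by method of moments), then removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ComBatModel:
    batch_levels: list[str]
    feature_names: list[str]
    covariate_names: list[str]
    alpha: np.ndarray          # (F,) grand mean per feature
    beta: np.ndarray           # (C, F) covariate coefficients
    sigma: np.ndarray          # (F,) pooled residual SD
    gamma_star: np.ndarray     # (B, F) EB-shrunk batch locations (standardized)
    delta_star: np.ndarray     # (B, F) EB-shrunk batch variance ratios (> 0)
    batch_fractions: np.ndarray  # (B,) n_b / n used for the grand mean
    constant_features: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "batch_levels": self.batch_levels,
            "feature_names": self.feature_names,
            "covariate_names": self.covariate_names,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "batch_fractions": self.batch_fractions.tolist(),
            "constant_features": self.constant_features,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ComBatModel":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("alpha", "beta", "sigma", "gamma_star", "delta_star",
                    "batch_fractions"):
            d[key] = np.asarray(d[key])
        d["beta"] = d["beta"].reshape(-1, len(d["feature_names"]))
        return cls(**d)


def _postmean(g_hat, g_bar, n, d_star, tau2):
    return (n * tau2 * g_hat + d_star * g_bar) / (n * tau2 + d_star)


def _it_solve(z, g_hat, d_hat, g_bar, tau2, a_prior, b_prior, tol=1e-8,
              max_iter=500):
    """Iterative EB solution for one batch (neuroCombat-style)."""
    n = z.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_prev, d_prev = g_new, d_new
        g_new = _postmean(g_hat, g_bar, n, d_prev, tau2)
        ssq = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * ssq + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_prev) / np.maximum(np.abs(g_prev), 1e-12)),
            np.max(np.abs(d_new - d_prev) / np.maximum(np.abs(d_prev), 1e-12)),
        )
        if change < tol:
            break
    return g_new, d_new


def _aprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1) if d_hat.size > 1 else 0.0
    if s2 <= 0:
        return 2.0  # diffuse but proper
    return (2.0 * s2 + m**2) / s2


def _bprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1) if d_hat.size > 1 else 0.0
    if s2 <= 0:
        return m
    return (m * s2 + m**3) / s2


def combat_fit(
    features: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ComBatModel:
    """Fit the harmonization model.

    Parameters
    ----------
    features
        subjects x features, numeric.
    batch
        batch label per subject (aligned index).
    covariates
        numeric-coded biological covariates to preserve (may be None).
    """
    features = features.astype(float)
    batch = batch.reindex(features.index)
    if batch.isna().any():
        raise ValueError("batch labels missing for some subjects")
    levels = sorted(batch.unique())
    counts = batch.value_counts()
    small = [lev for lev in levels if counts[lev] < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 subjects: {small}")

    Y = features.to_numpy()
    n, F = Y.shape
    const_mask = np.nanstd(Y, axis=0) == 0
    constant_features = [f for f, c in zip(features.columns, const_mask) if c]
    if constant_features:
        warnings.warn(
            f"{len(constant_features)} zero-variance feature(s) passed through "
            "unharmonized", stacklevel=2,
        )
    if not np.isfinite(Y).all():
        raise ValueError("features contain non-finite values")

    B = np.stack([(batch == lev).to_numpy(float) for lev in levels], axis=1)
    if covariates is not None:
        covariates = covariates.reindex(features.index).astype(float)
        C = covariates.to_numpy()
        cov_names = list(covariates.columns)
    else:
        C = np.empty((n, 0))
        cov_names = []
    X = np.hstack([B, C])

    theta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_effects = theta[: len(levels)]      # (B, F) per-batch intercepts
    beta = theta[len(levels):]                # (C, F)
    frac = counts.reindex(levels).to_numpy(float) / n
    alpha = frac @ batch_effects

    resid = Y - X @ theta
    sigma = np.sqrt((resid**2).mean(axis=0))
    sigma_safe = np.where(sigma > 0, sigma, 1.0)

    # standardized data retain the batch shifts; per-batch moments of Z
    # estimate gamma/delta
    stand_mean = alpha[None, :] + C @ beta
    Z = (Y - stand_mean) / sigma_safe

    gamma_star = np.zeros((len(levels), F))
    delta_star = np.ones((len(levels), F))
    for bi, lev in enumerate(levels):
        zb = Z[(batch == lev).to_numpy()]
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1)
        d_hat = np.where(d_hat > 0, d_hat, 1.0)
        g_bar, tau2 = g_hat.mean(), g_hat.var(ddof=1) if F > 1 else 1.0
        if tau2 <= 0:
            tau2 = 1.0
        a_p, b_p = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_solve(zb, g_hat, d_hat, g_bar, tau2, a_p, b_p)
        gamma_star[bi], delta_star[bi] = g_star, d_star

    # constant features: identity transform
    gamma_star[:, const_mask] = 0.0
    delta_star[:, const_mask] = 1.0

    return ComBatModel(
        batch_levels=[str(lev) for lev in levels],
        feature_names=list(features.columns),
        covariate_names=cov_names,
        alpha=alpha,
        beta=beta,
        sigma=sigma_safe,
        gamma_star=gamma_star,
        delta_star=delta_star,
        batch_fractions=frac,
        constant_features=constant_features,
    )


def combat_apply(
    features: pd.DataFrame,
    model: ComBatModel,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Remove the fitted batch effects; covariate structure is restored."""
    if list(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    batch = batch.reindex(features.index)
    unseen = set(batch.astype(str)) - set(model.batch_levels)
    if unseen:
        raise ValueError(f"unseen batch label(s): {sorted(unseen)}")
    Y = features.to_numpy(float)
    if model.covariate_names:
        if covariates is None:
            raise ValueError("model was fitted with covariates; none given")
        C = covariates.reindex(features.index)[model.covariate_names].to_numpy(float)
    else:
        C = np.empty((len(features), 0))
    stand_mean = model.alpha[None, :] + C @ model.beta
    Z = (Y - stand_mean) / model.sigma
    bi = np.array([model.batch_levels.index(str(b)) for b in batch])
    Z_adj = (Z - model.gamma_star[bi]) / np.sqrt(model.delta_star[bi])
    out = Z_adj * model.sigma + stand_mean
    const = [model.feature_names.index(f) for f in model.constant_features]
    out[:, const] = Y[:, const]
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def harmonize(
    features: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ComBatModel]:
    """Fit and apply in one step."""
    model = combat_fit(features, batch, covariates)
    return combat_apply(features, model, batch, covariates), model


def between_batch_variance_fraction(
    features: pd.DataFrame, batch: pd.Series
) -> pd.Series:
    """Per-feature eta-squared of batch: SS_between / SS_total."""
    Y = features.to_numpy(float)
    grand = Y.mean(axis=0)
    ss_total = ((Y - grand) ** 2).sum(axis=0)
    ss_between = np.zeros(Y.shape[1])
    for lev in batch.unique():
        sel = (batch == lev).to_numpy()
        ss_between += sel.sum() * (Y[sel].mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return pd.Series(frac, index=features.columns)


@dataclass
class HarmonizationReport:
    pre_fraction: pd.Series
    post_fraction: pd.Series
    still_batch_associated: pd.Series  # bool per feature

    @property
    def reduced_fraction(self) -> float:
        """Share of features whose between-batch variance fraction decreased."""
        return float((self.post_fraction < self.pre_fraction).mean())


def _residualize(table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    C = covariates.reindex(table.index).to_numpy(float)
    C = C - C.mean(axis=0)
    Y = table.to_numpy(float)
    B, *_ = np.linalg.lstsq(C, Y - Y.mean(axis=0), rcond=None)
    return pd.DataFrame(Y - C @ B, index=table.index, columns=table.columns)


def harmonization_report(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    threshold: float = 0.05,
) -> HarmonizationReport:
    """Diagnostic: between-batch variance fraction before vs after.

    If ``covariates`` are given they are partialled out of both tables
    first, so preserved biology (e.g. an age effect whose batch balance is
    imperfect) is not counted as batch-associated variance.
    """
    if pre.shape != post.shape or list(pre.columns) != list(post.columns):
        raise ValueError("pre and post tables must have matching shape/columns")
    if covariates is not None:
        pre = _residualize(pre, covariates)
        post = _residualize(post, covariates)
    pre_frac = between_batch_variance_fraction(pre, batch)
    post_frac = between_batch_variance_fraction(post, batch)
    return HarmonizationReport(
        pre_fraction=pre_frac,
        post_fraction=post_frac,
        still_batch_associated=post_frac > threshold,
    )


def harmonize_matrices(
    matrices: dict[str, np.ndarray],
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[dict[str, np.ndarray], ComBatModel]:
    """Harmonize a set of symmetric matrices on their upper-triangle edges.

    Output matrices are re-symmetrized; entries outside (-1, 1) are reported
    (warning) but not clipped.
    """
    sids = list(matrices)
    n = next(iter(matrices.values())).shape[0]
    iu, ju = np.triu_indices(n, k=1)
    table = pd.DataFrame(
        {sid: matrices[sid][iu, ju] for sid in sids}
    ).T
    table.columns = [f"e{i}_{j}" for i, j in zip(iu, ju)]
    table.index.name = "subject_id"
    harmonized, model = harmonize(table, batch.reindex(table.index), covariates)
    out = {}
    n_outside = 0
    for sid in sids:
        m = np.zeros((n, n))
        vals = harmonized.loc[sid].to_numpy()
        m[iu, ju] = vals
        m += m.T
        n_outside += int((np.abs(vals) >= 1).sum())
        out[sid] = m
    if n_outside:
        warnings.warn(
            f"{n_outside} harmonized edge value(s) fell outside (-1, 1)",
            stacklevel=2,
        )
    return out, model
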