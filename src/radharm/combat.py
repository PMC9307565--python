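"""Feature-level batch harmonisation: per-centre quantile Gaussianisation
followed by parametric empirical-Bayes ComBat aligned to a virtual
reference.

The location/scale model assumes that, after standardisation against the
pooled grand mean and variance, each feature ``g`` in batch ``i`` carries an
additive batch shift ``gamma_ig`` and a multiplicative batch scale
``delta_ig``.  Naive per-batch estimates are shrunk towards cross-feature
priors — normal for ``gamma`` and inverse-gamma for ``delta^2``, with
hyperparameters estimated by method of moments — via the standard iterative
conditional update.  The adjusted value is

    y*_ijg = sigma_g * (z_ijg - gamma*_ig) / delta*_ig + alpha_g

where ``z`` is the standardised feature, so no single batch is privileged
(a "virtual reference frame").  No covariates are modelled.

Because the model assumes per-batch normality, the table is first passed
through a per-batch quantile transform onto a standard normal (K = 20
quantile grid by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import QuantileTransformer

from .io import FeatureTable


def quantile_gaussianise(table: FeatureTable, n_quantiles: int = 20,
                         batch_col: str = "centre") -> FeatureTable:
    """Map each feature, within each batch, onto a standard normal via an
    empirical quantile transform on a ``n_quantiles``-point grid.

    Rank-preserving within batch; batches of size 1 are rejected.
    """
    batches = table.row_meta[batch_col]
    out = table.data.copy()
    for b in sorted(batches.unique()):
        sel = (batches == b).values
        n = int(sel.sum())
        if n < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 subjects")
        qt = QuantileTransformer(
            n_quantiles=min(n_quantiles, n),
            output_distribution="normal",
            subsample=None,
            random_state=0,
        )
        out.iloc[sel, :] = qt.fit_transform(table.data.iloc[sel, :].to_numpy())
    return table.with_data(out.to_numpy())


@dataclass
class ComBatModel:
    """Fitted ComBat parameters.

    Arrays are (n_batches, n_features) for per-batch terms and
    (n_features,) for the virtual-reference terms.
    """

    batches: list
    features: list
    alpha: np.ndarray  # grand mean per feature
    sigma: np.ndarray  # pooled SD per feature
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    gamma_bar: np.ndarray  # (n_batches,) prior means
    tau2: np.ndarray
    lamb: np.ndarray  # inverse-gamma shape per batch
    theta: np.ndarray  # inverse-gamma scale per batch
    n_quantiles: int = 20
    constant_features: list = field(default_factory=list)


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_batch, g_hat, d2_hat, g_bar, t2, a, b,
            conv: float = 1e-4, max_iter: int = 500):
    """Iterative conditional update for the EB-shrunk batch effects of one
    batch (rows: subjects in batch, cols: features)."""
    n = z_batch.shape[0]
    g_old, d2_old = g_hat.copy(), d2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d2_old * g_bar) / (n * t2 + d2_old)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d2_new - d2_old) / np.maximum(np.abs(d2_old), 1e-12)),
        )
        g_old, d2_old = g_new, d2_new
        if change < conv:
            break
    return g_old, d2_old


def fit_combat(table: FeatureTable, batch_col: str = "centre",
               conv: float = 1e-4, max_iter: int = 500) -> ComBatModel:
    """Estimate per-batch location/scale effects with parametric EB shrinkage.

    Zero-variance features are flagged and excluded from estimation (they are
    passed through unchanged by :func:`apply_combat`).
    """
    batches = sorted(table.row_meta[batch_col].unique())
    if len(batches) < 2:
        raise ValueError("ComBat requires at least 2 batches")
    y = table.data.to_numpy(dtype=float)
    features = list(table.data.columns)

    spread = np.ptp(y, axis=0)  # exact constancy check, robust to roundoff
    constant = [f for f, s in zip(features, spread) if s == 0]
    if constant:
        warnings.warn(
            f"{len(constant)} zero-variance feature(s) passed through "
            "unharmonised", stacklevel=2)
    keep = spread > 0
    yk = y[:, keep]
    n_total, n_feat = yk.shape

    batch_idx = [np.flatnonzero((table.row_meta[batch_col] == b).values)
                 for b in batches]
    batch_n = np.array([len(ix) for ix in batch_idx])
    if (batch_n < 2).any():
        small = [b for b, n in zip(batches, batch_n) if n < 2]
        raise ValueError(f"batch(es) with fewer than 2 subjects: {small}")

    # virtual reference: grand mean, and SD pooled from within-batch
    # residuals (so batch shifts do not inflate the reference scale)
    alpha = yk.mean(axis=0)
    resid = yk.copy()
    for ix in batch_idx:
        resid[ix] -= yk[ix].mean(axis=0)
    sigma = np.sqrt((resid**2).mean(axis=0))
    if (sigma == 0).any():
        sigma = np.where(sigma == 0, 1.0, sigma)
    z = (yk - alpha) / sigma

    gamma_hat = np.vstack([z[ix].mean(axis=0) for ix in batch_idx])
    delta2_hat = np.vstack([z[ix].var(axis=0, ddof=1) for ix in batch_idx])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    lamb = np.array([_aprior(d2) for d2 in delta2_hat])
    theta = np.array([_bprior(d2) for d2 in delta2_hat])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i, ix in enumerate(batch_idx):
        g, d2 = _it_sol(z[ix], gamma_hat[i], delta2_hat[i],
                        gamma_bar[i], tau2[i], lamb[i], theta[i],
                        conv=conv, max_iter=max_iter)
        gamma_star[i] = g
        delta2_star[i] = d2

    kept_features = [f for f, k in zip(features, keep) if k]
    return ComBatModel(
        batches=list(batches), features=kept_features,
        alpha=alpha, sigma=sigma,
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_star, delta2_star=delta2_star,
        gamma_bar=gamma_bar, tau2=tau2, lamb=lamb, theta=theta,
        constant_features=constant,
    )


def apply_combat(table: FeatureTable, model: ComBatModel,
                 batch_col: str = "centre") -> FeatureTable:
    """Remove the fitted batch effects:
    ``y* = sigma * (z - gamma*) / delta* + alpha``."""
    seen = set(table.row_meta[batch_col].unique())
    unseen = seen - set(model.batches)
    if unseen:
        raise ValueError(f"batch(es) not in model: {sorted(unseen)}")
    out = table.data.to_numpy(dtype=float).copy()
    cols = [table.data.columns.get_loc(f) for f in model.features]
    cols = np.asarray(cols, dtype=int)
    y = out[:, cols]
    z = (y - model.alpha) / model.sigma
    for i, b in enumerate(model.batches):
        sel = (table.row_meta[batch_col] == b).values
        if not sel.any():
            continue
        z[sel] = (z[sel] - model.gamma_star[i]) / np.sqrt(model.delta2_star[i])
    out[:, cols] = z * model.sigma + model.alpha
    return table.with_data(out)


def harmonise(table: FeatureTable, batch_col: str = "centre",
              n_quantiles: int = 20) -> tuple[FeatureTable, ComBatModel]:
    """Quantile-Gaussianise per batch, then fit and apply ComBat."""
    gauss = quantile_gaussianise(table, n_quantiles=n_quantiles,
                                 batch_col=batch_col)
    model = fit_combat(gauss, batch_col=batch_col)
    model.n_quantiles = n_quantiles
    return apply_combat(gauss, model, batch_col=batch_col), model
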