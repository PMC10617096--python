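"""Identify and remove unperturbed (editing-escape) cells.

A guide in a cell does not guarantee loss of function of its target.  To
separate perturbed from escaped cells, an elastic-net linear model regresses
standardized expression of the most variable genes on guide-indicator
covariates; each cell's perturbation probability is the equal-prior Gaussian
posterior that its expression is better explained with its guide's fitted
signature than without it.  Non-targeting cells have no signature and centre
at 0.5; truly targeting guides produce a bimodal probability distribution.
A per-guide two-component Gaussian mixture then labels the lower mode; cells
whose posterior for the higher-mean (perturbed) component falls below a
threshold (default 0.05) are removed from expression analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .screen_data import ScreenMatrix

__all__ = [
    "build_guide_design",
    "PerturbationProbabilityModel",
    "fit_perturbation_model",
    "GmmFit",
    "fit_gmm2",
    "classify_unperturbed",
    "filter_unperturbed_cells",
]


#: covariate columns in the design matrix carry this prefix and are kept in
#: both the full and the guide-zeroed model when computing probabilities
COVARIATE_PREFIX = "cov_"


def build_guide_design(
    m: ScreenMatrix, covariates: Sequence[str] = ()
) -> pd.DataFrame:
    """Cell x guide 0/1 indicator matrix from the unique-sgRNA annotation.

    ``covariates`` may name ``"total_umi"`` (log-scaled, standardized) and/or
    ``"condition"`` (dummy-coded); they are appended as ``cov_``-prefixed
    columns.
    """
    if "sgrna_id" not in m.obs:
        raise ValueError("run select_unique_sgrna_cells first")
    design = pd.get_dummies(m.obs["sgrna_id"]).astype(float)
    for cov in covariates:
        if cov == "total_umi":
            v = np.log1p(m.obs["total_umi"].to_numpy(dtype=float))
            design[f"{COVARIATE_PREFIX}log_umi"] = (v - v.mean()) / (v.std() or 1.0)
        elif cov == "condition":
            for level, col in pd.get_dummies(m.obs["condition"], drop_first=True).items():
                design[f"{COVARIATE_PREFIX}condition_{level}"] = col.astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return design


class PerturbationProbabilityModel(BaseEstimator):
    """Elastic-net guide-signature model with Gaussian posterior probabilities.

    Parameters
    ----------
    l1_ratio
        Elastic-net mixing parameter (0 = ridge, 1 = lasso).
    alpha
        Penalty strength; ``None`` selects it by 5-fold cross-validation over
        a small log-spaced grid on the multi-output problem.
    n_top_genes
        Number of highest-variance genes (of the log-normalized matrix) used
        as responses.
    random_state
        Seed for the cross-validation folds.

    Attributes
    ----------
    coef_ : pd.DataFrame, guide x gene fitted coefficients
    alpha_ : float, the penalty actually used
    sigma2_ : float, pooled residual variance
    """

    def __init__(
        self,
        l1_ratio: float = 0.5,
        alpha: float | None = None,
        n_top_genes: int = 2000,
        random_state: int = 0,
    ):
        self.l1_ratio = l1_ratio
        self.alpha = alpha
        self.n_top_genes = n_top_genes
        self.random_state = random_state

    # -- internal -----------------------------------------------------------
    def _responses(self, m: ScreenMatrix) -> pd.DataFrame:
        if m.normalized is None:
            raise ValueError("run normalize_log first")
        X = np.asarray(m.normalized.todense())
        var = X.var(axis=0)
        n = min(self.n_top_genes, X.shape[1])
        top = np.argsort(-var, kind="stable")[:n]
        Y = X[:, top]
        mu, sd = Y.mean(axis=0), Y.std(axis=0)
        sd[sd == 0] = 1.0
        return pd.DataFrame((Y - mu) / sd, index=m.barcodes, columns=m.genes[top])

    def _cv_alpha(self, X: np.ndarray, Y: np.ndarray) -> float:
        grid = np.array([1e-3, 3e-3, 1e-2, 3e-2, 1e-1])
        kf = KFold(n_splits=5, shuffle=True, random_state=self.random_state)
        losses = np.zeros(len(grid))
        for tr, te in kf.split(X):
            for i, a in enumerate(grid):
                en = ElasticNet(alpha=a, l1_ratio=self.l1_ratio, fit_intercept=True, max_iter=2000)
                en.fit(X[tr], Y[tr])
                losses[i] += ((Y[te] - en.predict(X[te])) ** 2).mean()
        return float(grid[int(np.argmin(losses))])

    # -- sklearn surface ----------------------------------------------------
    def fit(self, m: ScreenMatrix, design: pd.DataFrame | None = None) -> "PerturbationProbabilityModel":
        design = build_guide_design(m) if design is None else design
        if not design.index.equals(m.barcodes):
            design = design.reindex(m.barcodes)
        guide_cols = [c for c in design.columns if not c.startswith(COVARIATE_PREFIX)]
        row_sums = design[guide_cols].to_numpy().sum(axis=1)
        if not np.all(row_sums == 1):
            raise ValueError("each cell must carry exactly one guide indicator")
        self._guide_cols = guide_cols
        Y = self._responses(m)
        X = design.to_numpy(dtype=float)
        alpha = self._cv_alpha(X, Y.to_numpy()) if self.alpha is None else float(self.alpha)
        if alpha <= 0:
            raise ValueError("degenerate unpenalized design; supply a positive penalty")
        en = ElasticNet(alpha=alpha, l1_ratio=self.l1_ratio, fit_intercept=True, max_iter=5000)
        en.fit(X, Y.to_numpy())
        self.alpha_ = alpha
        self.design_ = design
        self.genes_ = Y.columns
        self.coef_ = pd.DataFrame(en.coef_.T, index=design.columns, columns=Y.columns)
        self.intercept_ = np.asarray(en.intercept_, dtype=float)
        resid = Y.to_numpy() - X @ self.coef_.to_numpy() - self.intercept_
        self._resid = resid
        self.sigma2_ = float((resid**2).mean())
        return self

    def predict_proba(self, m: ScreenMatrix | None = None) -> pd.Series:
        """Per-cell perturbation probability in [0, 1].

        For cell c carrying guide g, with r1 the residual sum of squares under
        the full model and r0 with g's coefficient row zeroed, the equal-prior
        Gaussian posterior is sigmoid((r0 - r1) / (2 sigma^2)).
        """
        resid = self._resid
        X = self.design_[self._guide_cols].to_numpy(dtype=float)
        beta = self.coef_.loc[self._guide_cols].to_numpy()
        r1 = (resid**2).sum(axis=1)
        # zeroing the cell's own guide row adds X[c] @ beta back to its residual
        resid0 = resid + X @ beta
        r0 = (resid0**2).sum(axis=1)
        prob = expit((r0 - r1) / (2.0 * self.sigma2_))
        return pd.Series(prob, index=self.design_.index, name="perturbation_probability")


def fit_perturbation_model(
    m: ScreenMatrix,
    design: pd.DataFrame | None = None,
    l1_ratio: float = 0.5,
    alpha: float | None = None,
    n_top_genes: int = 2000,
    random_state: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fit the guide-signature model; returns (guide x gene coefficients,
    per-cell perturbation probability)."""
    model = PerturbationProbabilityModel(
        l1_ratio=l1_ratio, alpha=alpha, n_top_genes=n_top_genes, random_state=random_state
    ).fit(m, design)
    return model.coef_, model.predict_proba()


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture
# ---------------------------------------------------------------------------


@dataclass
class GmmFit:
    """A 1-D two-component Gaussian mixture fit, components ordered by mean.

    ``posterior`` is the per-observation responsibility of the higher-mean
    ("perturbed") component.  Non-converged or degenerate fits are flagged and
    treated as unfiltered downstream.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    posterior: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.converged:
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            if (self.sds <= 0).any():
                raise ValueError("mixture sds must be positive")


_MIN_SD = 1e-4


def _em_once(x: np.ndarray, mu: np.ndarray, tol: float, max_iter: int) -> GmmFit:
    n = len(x)
    sd = np.array([x.std() or 1.0] * 2)
    w = np.array([0.5, 0.5])
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * sd[None, :] ** 2)
            - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
        )
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(logp - norm[:, None])
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        nk = resp.sum(axis=0)
        if (nk < 1e-8).any():
            break  # a component died: degenerate
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk)
        if (sd < _MIN_SD).any():
            break  # variance collapse: degenerate
    order = np.argsort(mu)
    logp = (
        np.log(np.maximum(w, 1e-300))[None, :]
        - 0.5 * np.log(2 * np.pi * np.maximum(sd, _MIN_SD)[None, :] ** 2)
        - 0.5 * ((x[:, None] - mu[None, :]) / np.maximum(sd, _MIN_SD)[None, :]) ** 2
    )
    resp = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    return GmmFit(
        means=mu[order],
        sds=sd[order],
        weights=w[order] / w.sum(),
        posterior=resp[:, order][:, 1],
        converged=converged,
        n_iter=it,
        log_likelihood=trace[-1] if trace else -np.inf,
        log_likelihood_trace=np.array(trace),
    )


def fit_gmm2(
    values: Sequence[float],
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_init: int = 10,
) -> GmmFit:
    """EM fit of a two-component 1-D Gaussian mixture.

    ``n_init`` restarts with k-means++-style initial means (a random point,
    then a far point weighted by squared distance); the best log-likelihood
    fit is kept.  Requires >= 10 observations.  All-identical input (or any
    variance-collapsed fit) is flagged non-converged so the caller can pass
    the group through unfiltered.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations per group")
    if np.ptp(x) == 0:
        warnings.warn("all values identical; mixture fit is degenerate")
        return GmmFit(
            means=np.array([x[0], x[0]]),
            sds=np.array([_MIN_SD, _MIN_SD]),
            weights=np.array([0.5, 0.5]),
            posterior=np.ones(len(x)),
            converged=False,
            n_iter=0,
            log_likelihood=-np.inf,
        )
    rng = np.random.default_rng(seed)
    best: GmmFit | None = None
    for _ in range(n_init):
        m1 = x[rng.integers(len(x))]
        d2 = (x - m1) ** 2
        if d2.sum() == 0:
            m2 = m1
        else:
            m2 = x[rng.choice(len(x), p=d2 / d2.sum())]
        fit = _em_once(x, np.array([m1, m2], dtype=float), tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    if not best.converged:
        warnings.warn("GMM did not converge; group will pass through unfiltered")
    return best


def classify_unperturbed(f: GmmFit, threshold: float = 0.05) -> np.ndarray:
    """Label each observation: 'unperturbed' iff the posterior of the
    higher-mean component is strictly below ``threshold``.

    Non-converged fits label everything perturbed (pass-through).
    """
    if not f.converged:
        return np.array(["perturbed"] * len(f.posterior))
    return np.where(f.posterior < threshold, "unperturbed", "perturbed")


def _logit_clipped(p: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p) - np.log1p(-p)


def filter_unperturbed_cells(
    m: ScreenMatrix,
    prob: pd.Series,
    grouping: str = "sgrna",
    threshold: float = 0.05,
    seed: int = 0,
    min_group_size: int = 10,
) -> tuple[ScreenMatrix, pd.DataFrame]:
    """Per-guide (or per-gene) mixture filtering of the probability values.

    The two-component mixture is fitted on the logit of the probabilities
    (clipped away from 0 and 1): posterior probabilities saturate for strong
    guide signatures, and on the logit scale the perturbed and escaped modes
    are both approximately Gaussian instead of piling up at the boundaries.
    NT cells are never filtered (they define the reference distribution).
    Groups smaller than ``min_group_size`` pass through unfiltered.  Returns
    the filtered matrix and a per-cell table (barcode, group, prob, posterior,
    label).
    """
    if grouping not in {"sgrna", "gene"}:
        raise ValueError("grouping must be 'sgrna' or 'gene'")
    key = "sgrna_id" if grouping == "sgrna" else "target_gene"
    if key not in m.obs:
        raise ValueError("run select_unique_sgrna_cells first")
    prob = prob.reindex(m.barcodes)
    records = []
    keep_mask = pd.Series(True, index=m.barcodes)
    for name, sub in m.obs.groupby(key, sort=True):
        cells = sub.index
        vals = prob.loc[cells].to_numpy()
        if bool(sub["is_nt"].iloc[0]) or len(cells) < min_group_size:
            labels = np.array(["perturbed"] * len(cells))
            post = np.full(len(cells), np.nan)
        else:
            z = _logit_clipped(vals)
            fit = fit_gmm2(z, seed=seed)
            labels = classify_unperturbed(fit, threshold=threshold)
            post = fit.posterior
        for bc, v, q, lab in zip(cells, vals, post, labels):
            records.append({"barcode": bc, "group": name, "prob": v, "posterior": q, "label": lab})
        keep_mask.loc[cells] = labels == "perturbed"
    table = pd.DataFrame(records).set_index("barcode").loc[m.barcodes]
    return m.subset_cells(keep_mask.to_numpy()), table
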