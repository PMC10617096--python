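"""Method-evaluation layer: consistency, co-directionality and robustness.

Compares perturbation-effect readouts (regulon activities versus single-gene
expression, or any two effect estimators) with three instruments:

* **consistency profile** — per target, the Spearman correlation of its
  effect vector with a reference target's over the method's most variable
  features; two methods are compared by correlating their per-target
  profiles.
* **co-directionality matrix D** — the full-data coefficient signs are
  compared against re-estimates on repeated per-group downsamples; entry
  R_ij is the fraction of downsamples whose sign at (feature i, target j)
  agrees with the full data.
* **robustness score** — RS_j = ||D_.j − 1||₂ per target; 0 means every
  feature's sign is perfectly stable under downsampling.
* **cell-number sweep** — the smallest per-group cell count at which the
  median subsample-versus-full Spearman of feature means crosses a
  threshold, the quantity by which regulon activities beat single genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .effects import EffectMatrix

__all__ = [
    "MeanDifferenceEstimator",
    "consistency_profile",
    "codirectionality",
    "robustness_score",
    "cell_number_sweep",
    "select_feature_universe",
]


@dataclass(frozen=True)
class MeanDifferenceEstimator:
    """The shipped effect estimator: per feature, group mean minus the mean of
    the reference-labelled cells.  Signature: (M0, P0) -> features x targets."""

    reference_label: str = "NT"
    standardize: bool = True

    def __call__(self, M0: pd.DataFrame, P0: pd.Series) -> pd.DataFrame:
        P0 = P0.reindex(M0.index)
        if self.reference_label not in set(P0):
            raise ValueError(f"reference label {self.reference_label!r} absent from P0")
        X = M0.to_numpy(dtype=float)
        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        ref_mean = X[(P0 == self.reference_label).to_numpy()].mean(axis=0)
        cols = {}
        for target in sorted(set(P0) - {self.reference_label}):
            cols[target] = X[(P0 == target).to_numpy()].mean(axis=0) - ref_mean
        return pd.DataFrame(cols, index=M0.columns)


def _top_variable(effect: pd.DataFrame, n: int) -> list[str]:
    var = effect.var(axis=0, ddof=1)
    return sorted(var.index, key=lambda f: (-var[f], f))[: min(n, len(var))]


def consistency_profile(
    eA: EffectMatrix,
    eB: EffectMatrix,
    reference_target: str,
    n_features: int = 200,
) -> tuple[pd.DataFrame, float]:
    """Per-target relative-effect profiles of two methods and their agreement.

    For each method, each target's relative effect is the Spearman correlation
    between its effect vector and the reference target's, restricted to that
    method's ``n_features`` most variable features.  The cross-method
    consistency is the Spearman correlation of the two per-target profiles.
    """
    shared = [t for t in eA.targets if t in set(eB.targets)]
    if reference_target not in shared:
        raise ValueError(f"reference target {reference_target!r} missing from a method")
    profiles = {}
    for name, e in (("A", eA), ("B", eB)):
        feats = _top_variable(e.effect, n_features)
        sub = e.effect[feats]
        ref_vec = sub.loc[reference_target].to_numpy()
        profiles[name] = pd.Series(
            {t: float(spearmanr(sub.loc[t].to_numpy(), ref_vec).statistic) for t in shared}
        )
    table = pd.DataFrame(profiles)
    cross = float(spearmanr(table["A"], table["B"]).statistic)
    return table, cross


def codirectionality(
    estimator: Callable[[pd.DataFrame, pd.Series], pd.DataFrame],
    M0: pd.DataFrame,
    P0: pd.Series,
    cells_per_group: int,
    n_downsample: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sign stability of estimated coefficients under per-group downsampling.

    Returns (C0*, D): the full-data coefficient signs and the feature x target
    co-directionality matrix, D_ij = fraction of the ``n_downsample``
    re-estimates whose sign agrees with the full data at (i, j).
    """
    P0 = P0.reindex(M0.index)
    group_cells = {g: np.flatnonzero((P0 == g).to_numpy()) for g in sorted(set(P0))}
    too_small = [g for g, idx in group_cells.items() if len(idx) < cells_per_group]
    if too_small:
        raise ValueError(f"groups smaller than cells_per_group={cells_per_group}: {too_small}")
    C0_star = np.sign(estimator(M0, P0))
    rng = np.random.default_rng(seed)
    agree = np.zeros(C0_star.shape)
    for _ in range(n_downsample):
        rows = np.concatenate(
            [rng.choice(idx, size=cells_per_group, replace=False) for idx in group_cells.values()]
        )
        Mt = M0.iloc[rows]
        Ct_star = np.sign(estimator(Mt, P0.iloc[rows]))
        agree += (Ct_star.to_numpy() == C0_star.to_numpy())
    D = pd.DataFrame(agree / n_downsample, index=C0_star.index, columns=C0_star.columns)
    return C0_star, D


def robustness_score(D: pd.DataFrame) -> pd.Series:
    """RS_j = Euclidean distance of D's column j from the all-ones vector.

    0 for perfect sign agreement; sqrt(n features) for total disagreement.
    Lower is more robust.
    """
    return pd.Series(
        np.linalg.norm(1.0 - D.to_numpy(), axis=0), index=D.columns, name="robustness_score"
    )


def cell_number_sweep(
    feature_matrix: pd.DataFrame,
    n_grid: Sequence[int],
    n_iter: int = 1000,
    threshold: float = 0.9,
    seed: int = 0,
) -> tuple[pd.Series, int | None]:
    """How many cells are needed before subsample feature means track the
    full-group means.

    For each n in ``n_grid``: draw ``n_iter`` random subsamples of n cells
    (without replacement), compute the Spearman correlation between the
    subsample's per-feature means and the whole group's, and report the
    median.  Also returns the smallest n whose median reaches ``threshold``
    (None if none does).
    """
    n_cells = feature_matrix.shape[0]
    if max(n_grid) > n_cells:
        raise ValueError("n_grid exceeds the group size")
    X = feature_matrix.to_numpy(dtype=float)
    full_mean = X.mean(axis=0)
    rng = np.random.default_rng(seed)
    medians = {}
    for n in sorted(n_grid):
        if n == n_cells:
            medians[n] = 1.0
            continue
        corrs = np.empty(n_iter)
        for t in range(n_iter):
            rows = rng.choice(n_cells, size=n, replace=False)
            corrs[t] = spearmanr(X[rows].mean(axis=0), full_mean).statistic
        medians[n] = float(np.median(corrs))
    curve = pd.Series(medians, name="median_spearman")
    reaching = curve[curve >= threshold]
    min_cells = int(reaching.index.min()) if len(reaching) else None
    return curve, min_cells


def select_feature_universe(
    m, regulons, n_top_hvg: int = 4000, proxy: str = "tf_or_first_member"
) -> dict[str, str]:
    """Feature universe for the cell-feature matrix M0: regulon TFs that are
    also among the top highly-variable genes.

    Returns TF -> gene mapping (the TF symbol itself when it is in the
    matrix, otherwise the regulon's first member as its proxy single gene).
    Variable genes are ranked with the standard dispersion-based selection.
    """
    import scanpy as sc

    adata = m.to_anndata()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    n_top = min(n_top_hvg, adata.n_vars - 1)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    hvg = set(adata.var_names[adata.var["highly_variable"]])
    universe = {}
    for r in regulons:
        gene = r.tf if r.tf in m.genes else next((g for g in r.members if g in m.genes), None)
        if gene is not None and gene in hvg:
            universe[r.tf] = gene
    return universe
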