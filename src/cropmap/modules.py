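"""Perturbation/regulon modules and the hypergeometric module-to-module map.

Targets (and regulons) are clustered by k-means on the rows of their Spearman
correlation matrix over effect profiles.  Directed edges from perturbation
module Pi to regulon module Rj are then scored, separately for activating and
repressive regulations, with a hypergeometric test on the contingency of
significant regulation pairs, followed by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .effects import EffectMatrix, RegulationPair

__all__ = [
    "ModuleAssignment",
    "ModuleEdge",
    "correlate_spearman",
    "kmeans_modules",
    "hypergeom_pvalue",
    "build_module_map",
    "export_edges",
    "read_edges",
]


@dataclass
class ModuleAssignment:
    """label -> module id (1..k) with the k-means fit diagnostics."""

    assignment: dict[str, int]
    k: int
    seed: int
    inertia: float

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if not ids <= set(range(1, self.k + 1)):
            raise ValueError("module ids must lie in 1..k")

    def members(self, module_id: int) -> list[str]:
        return [l for l, m in self.assignment.items() if m == module_id]


@dataclass(frozen=True)
class ModuleEdge:
    from_module: int
    to_module: int
    sign_class: str  # "activating" | "repressive"
    pvalue: float
    adj_pvalue: float

    @property
    def weight(self) -> float:
        return float(-np.log10(self.adj_pvalue))


def correlate_spearman(e: EffectMatrix, axis: str) -> pd.DataFrame:
    """Pairwise Spearman correlation of effect profiles.

    ``axis="targets"`` correlates target rows (perturbation pairs),
    ``axis="features"`` correlates feature columns (regulon pairs).  Constant
    vectors have undefined ranks; their correlations are set to 0 with a
    warning, and the diagonal to 1.
    """
    if axis not in {"targets", "features"}:
        raise ValueError("axis must be 'targets' or 'features'")
    mat = e.effect if axis == "targets" else e.effect.T
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 labels to correlate")
    X = mat.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    ranks = rankdata(X, axis=1, method="average")
    ranks = (ranks - ranks.mean(axis=1, keepdims=True))
    denom = np.sqrt((ranks**2).sum(axis=1))
    denom[denom == 0] = 1.0
    R = (ranks / denom[:, None]) @ (ranks / denom[:, None]).T
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profiles; their correlations set to 0")
        R[constant, :] = 0.0
        R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(R, index=mat.index, columns=mat.index)


def kmeans_modules(
    c: pd.DataFrame, k: int, seed: int = 0, n_init: int = 50
) -> ModuleAssignment:
    """k-means on the rows of the correlation matrix (each label's correlation
    profile is its feature vector); best of ``n_init`` restarts.

    Module ids are renumbered deterministically in order of first appearance
    along the label order, so identical partitions always get identical ids.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > c.shape[0]:
        raise ValueError(f"k={k} exceeds the {c.shape[0]} labels")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(c.to_numpy(dtype=float))
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    assignment = {label: relabel[lab] for label, lab in zip(c.index, raw)}
    return ModuleAssignment(assignment=assignment, k=k, seed=seed, inertia=float(km.inertia_))


def _log_pmf(N: int, K_P: int, K_R: int, k: int) -> float:
    return (
        gammaln(K_P + 1) - gammaln(k + 1) - gammaln(K_P - k + 1)
        + gammaln(N - K_P + 1) - gammaln(K_R - k + 1) - gammaln(N - K_P - (K_R - k) + 1)
        - (gammaln(N + 1) - gammaln(K_R + 1) - gammaln(N - K_R + 1))
    )


def hypergeom_pvalue(N: int, K_P: int, K_R: int, k: int, tail: str = "upper") -> float:
    """Hypergeometric probability for a module-map cell, in log space.

    With N total regulations, K_P from module Pi, K_R into module Rj and k in
    their intersection: ``tail="pmf"`` returns P(X = k) =
    C(K_P, k) C(N-K_P, K_R-k) / C(N, K_R); ``tail="upper"`` returns
    P(X >= k), the enrichment p-value.
    """
    if not (0 <= K_P <= N and 0 <= K_R <= N):
        raise ValueError("need 0 <= K_P, K_R <= N")
    if not (max(0, K_P + K_R - N) <= k <= min(K_P, K_R)):
        raise ValueError(f"k={k} outside the hypergeometric support")
    if tail == "pmf":
        return float(np.exp(_log_pmf(N, K_P, K_R, k)))
    if tail == "upper":
        ks = np.arange(k, min(K_P, K_R) + 1)
        if len(ks) == 0:
            return 0.0
        return float(min(1.0, np.exp(logsumexp([_log_pmf(N, K_P, K_R, x) for x in ks]))))
    raise ValueError("tail must be 'pmf' or 'upper'")


def build_module_map(
    pairs: Sequence[RegulationPair],
    pm: ModuleAssignment,
    rm: ModuleAssignment,
    alpha: float = 0.05,
    tail: str = "upper",
    bh_pool: str = "joint",
) -> list[ModuleEdge]:
    """Hypergeometric module-to-module map from significant regulation pairs.

    Regulations are split by sign class; within each class, each (Pi, Rj)
    cell is tested against the class total.  BH adjustment is applied jointly
    over all (Pi, Rj, sign) tests by default (``bh_pool="per_class"`` adjusts
    each class separately); edges with adjusted p < alpha are retained.
    """
    if bh_pool not in {"joint", "per_class"}:
        raise ValueError("bh_pool must be 'joint' or 'per_class'")
    for p in pairs:
        if p.target not in pm.assignment:
            raise ValueError(f"target {p.target!r} missing from the perturbation modules")
        if p.feature not in rm.assignment:
            raise ValueError(f"feature {p.feature!r} missing from the regulon modules")
    records = []  # (sign_class, Pi, Rj, pvalue)
    for sign_class in ("activating", "repressive"):
        cls = [p for p in pairs if p.sign == sign_class]
        N = len(cls)
        if N == 0:
            continue
        from_p = np.array([pm.assignment[p.target] for p in cls])
        to_r = np.array([rm.assignment[p.feature] for p in cls])
        for pi in range(1, pm.k + 1):
            in_pi = from_p == pi
            K_P = int(in_pi.sum())
            for rj in range(1, rm.k + 1):
                in_rj = to_r == rj
                K_R = int(in_rj.sum())
                k = int((in_pi & in_rj).sum())
                if K_P == 0 or K_R == 0:
                    continue
                records.append((sign_class, pi, rj, hypergeom_pvalue(N, K_P, K_R, k, tail=tail)))
    if not records:
        return []
    edges: list[ModuleEdge] = []
    if bh_pool == "joint":
        pools = {"all": records}
    else:
        pools = {}
        for rec in records:
            pools.setdefault(rec[0], []).append(rec)
    for recs in pools.values():
        raw = [r[3] for r in recs]
        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        for (sign_class, pi, rj, p), q in zip(recs, adj):
            if q < alpha:
                edges.append(ModuleEdge(pi, rj, sign_class, float(p), float(q)))
    edges.sort(key=lambda e: (e.adj_pvalue, e.from_module, e.to_module, e.sign_class))
    return edges


def export_edges(edges: Sequence[ModuleEdge], path: str | Path, format: str = "tsv") -> None:
    """Write edges as TSV (from, to, sign, p, p_adj, weight) or SIF."""
    path = Path(path)
    ordered = sorted(
        edges, key=lambda e: (e.from_module, e.to_module, e.sign_class, e.adj_pvalue, e.pvalue)
    )
    if format == "tsv":
        pd.DataFrame(
            {
                "from": [f"P{e.from_module}" for e in ordered],
                "to": [f"R{e.to_module}" for e in ordered],
                "sign": [e.sign_class for e in ordered],
                "p": [e.pvalue for e in ordered],
                "p_adj": [e.adj_pvalue for e in ordered],
                "weight": [e.weight for e in ordered],
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "sif":
        with open(path, "w") as fh:
            for e in ordered:
                fh.write(f"P{e.from_module}\t{e.sign_class}\tR{e.to_module}\n")
    else:
        raise ValueError("format must be 'tsv' or 'sif'")


def read_edges(path: str | Path) -> list[ModuleEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        ModuleEdge(
            int(str(r["from"]).lstrip("P")),
            int(str(r["to"]).lstrip("R")),
            str(r["sign"]),
            float(r["p"]),
            float(r["p_adj"]),
        )
        for _, r in df.iterrows()
    ]
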