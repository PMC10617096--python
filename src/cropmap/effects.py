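"""Perturbation effect sizes on regulon activities (or genes) and their tests.

The effect of a perturbation on a feature is the mean feature value in the
target-gene group minus the mean in the reference cells (non-targeting
controls by default), tested with a two-sided Wilcoxon rank-sum test.
Significant pairs are classified as activating (effect > 0) or repressive
(effect < 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .screen_data import NT_TARGET, ScreenMatrix

__all__ = [
    "TargetGroup",
    "EffectMatrix",
    "RegulationPair",
    "build_target_groups",
    "filter_min_cells",
    "compute_effect_matrix",
    "test_regulations",
]

#: switch to the exact Wilcoxon null when both sides are at most this large
EXACT_WILCOXON_MAX_N = 25


@dataclass
class TargetGroup:
    """Cells assigned to guides against one target gene."""

    target_gene: str
    cells: list[str]
    sgrna_cells: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class EffectMatrix:
    """Target x feature effect sizes with Wilcoxon p-values."""

    effect: pd.DataFrame
    pvalue: pd.DataFrame
    feature_kind: str = "regulon"
    reference: str = NT_TARGET

    def __post_init__(self) -> None:
        if self.effect.shape != self.pvalue.shape:
            raise ValueError("effect and pvalue shapes differ")

    @property
    def targets(self) -> pd.Index:
        return self.effect.index

    @property
    def features(self) -> pd.Index:
        return self.effect.columns


@dataclass(frozen=True)
class RegulationPair:
    target: str
    feature: str
    sign: str  # "activating" | "repressive"
    effect: float
    pvalue: float

    def __post_init__(self) -> None:
        expected = "activating" if self.effect > 0 else "repressive"
        if self.sign != expected:
            raise ValueError(f"sign {self.sign!r} inconsistent with effect {self.effect}")


def build_target_groups(
    m: ScreenMatrix, condition: str | None = None
) -> tuple[list[TargetGroup], list[str]]:
    """Group annotated cells by target gene; returns (groups, NT reference cells).

    Requires unique-sgRNA annotation (``sgrna_id`` / ``target_gene`` in obs).
    When ``condition`` is given, only cells of that condition are used.
    """
    if "target_gene" not in m.obs:
        raise ValueError("run select_unique_sgrna_cells first")
    obs = m.obs
    if condition is not None:
        if "condition" not in obs:
            raise ValueError("matrix carries no condition labels")
        obs = obs[obs["condition"] == condition]
    nt_cells = list(obs.index[obs["is_nt"]])
    groups = []
    for target, sub in obs[~obs["is_nt"]].groupby("target_gene", sort=True):
        sgrna_cells = {g: list(s.index) for g, s in sub.groupby("sgrna_id", sort=True)}
        groups.append(TargetGroup(target_gene=str(target), cells=list(sub.index), sgrna_cells=sgrna_cells))
    return groups, nt_cells


def filter_min_cells(
    groups: Sequence[TargetGroup], min_cells: int = 40, level: str = "sgRNA"
) -> tuple[list[TargetGroup], pd.DataFrame]:
    """Drop sgRNAs supported by fewer than ``min_cells`` cells.

    A target group survives if at least one of its sgRNAs survives; its cell
    list shrinks to the cells of surviving guides.  Returns the retained
    groups and a removal report (one row per dropped guide or group).
    """
    if level != "sgRNA":
        raise ValueError("only sgRNA-level filtering is defined")
    retained, report = [], []
    for g in groups:
        kept = {sg: cells for sg, cells in g.sgrna_cells.items() if len(cells) >= min_cells}
        for sg, cells in g.sgrna_cells.items():
            if sg not in kept:
                report.append({"level": "sgRNA", "name": sg, "target": g.target_gene, "n_cells": len(cells)})
        if kept:
            cells = [c for sg in kept for c in kept[sg]]
            retained.append(TargetGroup(g.target_gene, cells, kept))
        else:
            report.append({"level": "target", "name": g.target_gene, "target": g.target_gene, "n_cells": len(g)})
    return retained, pd.DataFrame(report, columns=["level", "name", "target", "n_cells"])


def _wilcoxon_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values, feature-wise (columns of a and b)."""
    method = "exact" if max(len(a), len(b)) <= EXACT_WILCOXON_MAX_N else "asymptotic"
    res = mannwhitneyu(a, b, axis=0, alternative="two-sided", method=method, use_continuity=True)
    return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)


def compute_effect_matrix(
    activity: pd.DataFrame,
    groups: Sequence[TargetGroup],
    reference_cells: Sequence[str],
    feature_kind: str = "regulon",
    reference_label: str = NT_TARGET,
) -> EffectMatrix:
    """Mean-difference effect of each target group on each feature.

    effect[t, f] = mean(feature f over group t cells) - mean(over reference
    cells); p-value from the two-sided Wilcoxon rank-sum test (exact null for
    both sides <= 25 cells, normal approximation with continuity correction
    otherwise).
    """
    if not groups or len(reference_cells) == 0:
        raise ValueError("groups and reference cells must be non-empty")
    ref = activity.loc[list(reference_cells)].to_numpy()
    ref_mean = ref.mean(axis=0)
    eff_rows, p_rows, index = [], [], []
    for g in groups:
        if len(g) < 2:
            raise ValueError(f"group {g.target_gene!r} has <2 cells; apply filter_min_cells first")
        a = activity.loc[g.cells].to_numpy()
        eff_rows.append(a.mean(axis=0) - ref_mean)
        p_rows.append(_wilcoxon_pvalues(a, ref))
        index.append(g.target_gene)
    effect = pd.DataFrame(eff_rows, index=index, columns=activity.columns)
    pvalue = pd.DataFrame(p_rows, index=index, columns=activity.columns)
    return EffectMatrix(effect=effect, pvalue=pvalue, feature_kind=feature_kind, reference=reference_label)


def test_regulations(e: EffectMatrix, alpha: float = 0.05) -> list[RegulationPair]:
    """Retain target-feature pairs with p < alpha; sign by the effect's sign.

    Pairs that are nominally significant but have exactly zero effect carry
    no direction and are discarded with a warning.
    """
    pairs = []
    n_zero = 0
    for t in e.targets:
        for f in e.features:
            p = float(e.pvalue.at[t, f])
            if p < alpha:
                eff = float(e.effect.at[t, f])
                if eff == 0.0:
                    n_zero += 1
                    continue
                sign = "activating" if eff > 0 else "repressive"
                pairs.append(RegulationPair(t, f, sign, eff, p))
    if n_zero:
        warnings.warn(f"{n_zero} significant pairs with zero effect discarded")
    return pairs
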