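"""Composite marker-based ranking of perturbations.

Each perturbation i is scored by the mean log2 fold change of a hepatocyte
marker panel against unperturbed reference cells:

    Score_i = sum_j log2(FC_ij) / k

where FC_ij is the fold change of depth-normalized expression of marker j in
cells carrying perturbation i, and k the panel size.  A positive score means
the knockout raises marker expression — the perturbed gene is a candidate
negative regulator of the differentiated fate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_data import ScreenMatrix, cp_scale_matrix

__all__ = ["MarkerPanel", "DEFAULT_MARKERS", "compute_fold_changes", "regulator_score"]

DEFAULT_MARKERS = ("Alb", "Ttr", "Mup20", "Sult1a1", "Cyp3a13", "Abcc3", "Tff3", "Trf", "Fga")


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker panel must be non-empty")

    def __len__(self) -> int:
        return len(self.markers)

    def intersect(self, genes: pd.Index) -> "MarkerPanel":
        present = tuple(g for g in self.markers if g in genes)
        if not present:
            raise ValueError("no panel marker present in the matrix")
        if len(present) < len(self.markers):
            import warnings

            missing = sorted(set(self.markers) - set(present))
            warnings.warn(f"markers absent from the matrix dropped from the panel: {missing}")
        return MarkerPanel(present)


def compute_fold_changes(
    m: ScreenMatrix,
    perturbed_cells: Mapping[str, Sequence[str]],
    reference_cells: Sequence[str],
    panel: MarkerPanel | None = None,
    pseudocount: float = 1e-2,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Marker fold changes of each perturbation group against the reference.

    FC_ij = (mean CP-scaled expression of marker j in group i + pseudocount) /
    (mean in reference + pseudocount).  Expression is depth-normalized to
    ``scale`` counts per cell on the linear scale; the pseudocount acts on the
    group means, stabilizing markers with zero expression.  Unperturbed cells
    are assumed to have been removed from the groups upstream.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    panel = (panel or MarkerPanel()).intersect(m.genes)
    if len(reference_cells) == 0:
        raise ValueError("reference cell set is empty")
    norm = cp_scale_matrix(m, scale=scale)
    cols = m.genes.get_indexer(pd.Index(panel.markers))
    marker_expr = pd.DataFrame(
        np.asarray(norm[:, cols].todense()), index=m.barcodes, columns=panel.markers
    )
    ref_mean = marker_expr.loc[list(reference_cells)].mean(axis=0)
    rows = {}
    for name, cells in perturbed_cells.items():
        if len(cells) == 0:
            raise ValueError(f"perturbation group {name!r} is empty")
        group_mean = marker_expr.loc[list(cells)].mean(axis=0)
        rows[name] = (group_mean + pseudocount) / (ref_mean + pseudocount)
    return pd.DataFrame.from_dict(rows, orient="index")


def regulator_score(fc: pd.DataFrame, panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Mean log2 fold change over the panel, one score per perturbation.

    Returns a table with per-marker log2 fold changes, the composite score and
    the descending rank (1 = strongest increase in marker expression).
    """
    if panel is not None:
        missing = [g for g in panel.markers if g not in fc.columns]
        if missing:
            raise ValueError(f"panel markers missing from the fold-change matrix: {missing}")
        fc = fc[list(panel.markers)]
    if (fc.to_numpy() <= 0).any():
        raise ValueError("fold changes must be positive")
    log2fc = np.log2(fc)
    out = log2fc.add_prefix("log2fc_")
    out["score"] = log2fc.mean(axis=1)
    out = out.sort_values("score", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
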