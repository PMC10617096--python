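"""Per-cell regulon activity from ranked expression (AUCell-style recovery AUC).

A regulon is a transcription factor together with its inferred member genes.
Its activity in a cell is the area under the recovery curve of the member
genes within the cell's top-ranked genes, normalized to the maximum
achievable area — a rank statistic in [0, 1] that is invariant to any
monotone per-cell rescaling of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .screen_data import FormatError, ScreenMatrix

__all__ = [
    "Regulon",
    "read_regulons_gmt",
    "write_regulons_gmt",
    "filter_genes_for_activity",
    "AUCellScorer",
    "score_aucell",
    "select_variable_regulons",
]


@dataclass(frozen=True)
class Regulon:
    """A TF-centred gene set; ``weights``, when given, parallel ``members``."""

    tf: str
    members: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("regulon TF name must be non-empty")
        if not self.members:
            raise ValueError(f"regulon {self.tf!r} has no member genes")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"regulon {self.tf!r} has duplicate members")
        if self.weights is not None and len(self.weights) != len(self.members):
            raise ValueError(f"regulon {self.tf!r}: weights/members length mismatch")

    def __len__(self) -> int:
        return len(self.members)


def read_regulons_gmt(path: str | Path) -> list[Regulon]:
    """Read regulons from GMT (one per line: name, description, genes...).

    Genes absent from a later expression matrix are retained here and dropped
    at scoring time.  Duplicate genes within a line are deduplicated with a
    warning.
    """
    regulons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, genes = fields[0], fields[2:]
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                warnings.warn(f"{path}:{lineno}: duplicate genes in regulon {name!r} deduplicated")
            regulons.append(Regulon(tf=name, members=tuple(deduped)))
    return regulons


def write_regulons_gmt(regulons: Iterable[Regulon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regulons:
            fh.write("\t".join([r.tf, "na", *r.members]) + "\n")


def filter_genes_for_activity(
    m: ScreenMatrix, min_total_umi: int = 6, min_cell_frac: float = 0.01
) -> ScreenMatrix:
    """Keep genes with >= ``min_total_umi`` UMIs in total and detected in at
    least ``min_cell_frac`` of cells (both inclusive)."""
    total = np.asarray(m.counts.sum(axis=0)).ravel()
    detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    keep = (total >= min_total_umi) & (detected / m.n_cells >= min_cell_frac)
    return m.subset_genes(keep)


class AUCellScorer(BaseEstimator, TransformerMixin):
    """Rank-based recovery-curve AUC scorer for regulon activity.

    Per cell, all G genes are ranked by decreasing raw count (ties resolved
    per ``tie_rule``); with T = floor(top_frac * G), the recovery curve counts
    regulon members among the top x ranks for x = 1..T and the activity is its
    area divided by the maximal area (all members ranked first).

    Parameters
    ----------
    regulons
        Gene sets to score.  Members absent from the fitted gene universe are
        dropped at ``fit`` with a logged count; a regulon whose intersection
        is empty scores 0 everywhere (with a warning).
    top_frac
        Fraction of the ranking that defines the recovery window, in (0, 1].
    tie_rule
        ``"average"`` (deterministic, default) or ``"random"`` (seeded shuffle
        for cross-checking against random-tie implementations).
    random_state
        Seed for the random tie rule.
    """

    def __init__(
        self,
        regulons: Sequence[Regulon] = (),
        top_frac: float = 0.05,
        tie_rule: str = "average",
        random_state: int | None = None,
    ):
        self.regulons = regulons
        self.top_frac = top_frac
        self.tie_rule = tie_rule
        self.random_state = random_state

    def fit(self, m: ScreenMatrix, y=None) -> "AUCellScorer":
        if not 0.0 < self.top_frac <= 1.0:
            raise ValueError("top_frac must be in (0, 1]")
        if self.tie_rule not in {"average", "random"}:
            raise ValueError("tie_rule must be 'average' or 'random'")
        if not self.regulons:
            raise ValueError("no regulons supplied")
        genes = m.genes
        pos = {g: i for i, g in enumerate(genes)}
        self.genes_ = genes
        self.member_idx_ = []
        self.regulon_names_ = []
        n_dropped = 0
        for r in self.regulons:
            idx = np.array([pos[g] for g in r.members if g in pos], dtype=int)
            n_dropped += len(r.members) - len(idx)
            if len(idx) == 0:
                warnings.warn(f"regulon {r.tf!r} shares no genes with the matrix; activity will be 0")
            self.member_idx_.append(idx)
            self.regulon_names_.append(r.tf)
        if n_dropped:
            warnings.warn(f"{n_dropped} regulon member genes absent from the matrix were dropped")
        self.n_top_ = int(np.floor(self.top_frac * len(genes)))
        if self.n_top_ < 1:
            raise ValueError("top_frac window is empty for this gene universe")
        return self

    def transform(self, m: ScreenMatrix) -> pd.DataFrame:
        """Score each cell; returns a cells x regulons DataFrame in [0, 1]."""
        if not m.genes.equals(self.genes_):
            raise ValueError("gene universe differs from the fitted one")
        X = m.counts.toarray().astype(np.float64)
        rng = np.random.default_rng(self.random_state)
        if self.tie_rule == "random":
            X = X + rng.uniform(0, 1e-9, size=X.shape)
        ranks = rankdata(-X, axis=1, method="average")
        T = self.n_top_
        out = np.zeros((m.n_cells, len(self.member_idx_)))
        # a member at (ceiled) rank r contributes (T - r + 1) recovery-curve steps
        start = np.ceil(ranks).astype(np.int64)
        for j, idx in enumerate(self.member_idx_):
            n_members = len(idx)
            if n_members == 0:
                continue
            contrib = np.clip(T - start[:, idx] + 1, 0, None).sum(axis=1)
            x = np.arange(1, T + 1)
            max_area = np.minimum(x, n_members).sum()
            out[:, j] = contrib / max_area
        return pd.DataFrame(out, index=m.barcodes, columns=self.regulon_names_)

    def fit_transform(self, m: ScreenMatrix, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(m).transform(m)


def score_aucell(
    m: ScreenMatrix,
    regulons: Sequence[Regulon],
    top_frac: float = 0.05,
    tie_rule: str = "average",
    random_state: int | None = None,
) -> pd.DataFrame:
    """Functional wrapper around :class:`AUCellScorer` (fit + transform)."""
    return AUCellScorer(
        regulons=regulons, top_frac=top_frac, tie_rule=tie_rule, random_state=random_state
    ).fit_transform(m)


def select_variable_regulons(
    source: pd.DataFrame, n: int = 20, criterion: str = "variance"
) -> list[str]:
    """Order columns by decreasing variance (activity across cells, or effect
    across targets) and return the top ``n``; ties broken by name."""
    if criterion != "variance":
        raise ValueError(f"unknown criterion {criterion!r}")
    if n > source.shape[1]:
        raise ValueError(f"requested {n} regulons but only {source.shape[1]} available")
    var = source.var(axis=0, ddof=1)
    order = sorted(var.index, key=lambda name: (-var[name], name))
    return order[:n]
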