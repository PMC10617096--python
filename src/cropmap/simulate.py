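"""Synthetic CROP-seq screen generator with full ground truth.

Emulates the structure of a low-MOI in-organoid CRISPR screen read out by
scRNA-seq: a guide library of targeting sgRNAs plus non-targeting (NT)
controls, negative-binomial UMI counts with logistic dropout, TF-centred
regulons whose member genes shift coherently when the cell is truly
perturbed, and an editing-escape fraction of guide-carrying cells that remain
transcriptionally indistinguishable from NT cells.  Every stochastic choice
is recorded in a :class:`GroundTruth` object so downstream stages can be
validated against known labels and effect sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .activity import Regulon, write_regulons_gmt
from .screen_data import (
    GuideEntry,
    GuideLibrary,
    ScreenMatrix,
    compute_qc_metrics,
    write_counts_mtx,
    write_guide_assignments,
)

__all__ = ["SimConfig", "GroundTruth", "simulate_regulons", "simulate_screen", "write_screen"]

#: Hepatocyte marker panel; the first members of the designated
#: differentiation regulon are given these names so the marker-scoring stage
#: works on simulated screens out of the box.
MARKER_NAMES = ("Alb", "Ttr", "Mup20", "Sult1a1", "Cyp3a13", "Abcc3", "Tff3", "Trf", "Fga")


@dataclass
class SimConfig:
    """Configuration of the synthetic screen.

    ``targets`` maps each target-gene name to its effect vector: a mapping
    from TF name (``TF1`` .. ``TF{n_tfs}``) to the log2-scale shift applied to
    every member gene of that TF's regulon in truly perturbed cells.  ``TF1``
    is the designated differentiation regulon carrying the marker panel.
    """

    n_cells_per_guide: int = 100
    n_genes: int = 2000
    n_tfs: int = 20
    regulon_size: tuple[int, int] = (10, 30)
    targets: dict[str, dict[str, float]] = field(default_factory=dict)
    n_guides_per_target: int = 3
    n_nt: int = 4
    escape_rate: float = 0.3
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    gene_mean_sigma: float = 1.0
    tf_expression_factor: float = 0.25
    tf_mean_sigma: float = 0.5
    dropout_midpoint: float = -2.0
    marker_panel: tuple[str, ...] = MARKER_NAMES
    moi: float | None = None  # Poisson rate for multi-guide mode; None = unique
    condition: str = "DM"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_rate <= 1.0:
            raise ValueError("escape_rate must be in [0, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        lo, hi = self.regulon_size
        if lo < 1 or hi < lo:
            raise ValueError("regulon_size must be a (lo, hi) range with 1 <= lo <= hi")
        if self.n_tfs * (hi + 1) > self.n_genes:
            raise ValueError(
                f"{self.n_tfs} TF genes plus regulons of up to {hi} genes cannot "
                f"be drawn disjointly from {self.n_genes} genes"
            )

    @classmethod
    def with_random_targets(
        cls,
        n_targets: int,
        effect_size: float = 1.0,
        n_regulons_hit: int = 2,
        seed: int = 0,
        **kwargs,
    ) -> "SimConfig":
        """Convenience constructor: each target hits ``n_regulons_hit`` random
        regulons with +/- ``effect_size`` log2 shifts."""
        cfg = cls(seed=seed, **kwargs)
        rng = np.random.default_rng(seed + 101)
        tf_names = [f"TF{i + 1}" for i in range(cfg.n_tfs)]
        targets = {}
        for i in range(n_targets):
            hit = rng.choice(cfg.n_tfs, size=min(n_regulons_hit, cfg.n_tfs), replace=False)
            signs = rng.choice([-1.0, 1.0], size=len(hit))
            targets[f"Tgt{i + 1:02d}"] = {tf_names[j]: float(s * effect_size) for j, s in zip(hit, signs)}
        cfg.targets = targets
        return cfg


@dataclass
class GroundTruth:
    """Simulator record: true regulons, per-cell perturbation status, true
    per-target effect sizes (log2 scale) and the guide carried by each cell."""

    regulons: list[Regulon]
    cell_status: pd.Series  # barcode -> bool, True = truly perturbed
    true_effects: pd.DataFrame  # target x TF, log2 shifts
    guide_of_cell: pd.Series  # barcode -> sgrna_id

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regulons": {r.tf: list(r.members) for r in self.regulons},
            "cell_status": {b: bool(v) for b, v in self.cell_status.items()},
            "true_effects": self.true_effects.to_dict(orient="index"),
            "guide_of_cell": self.guide_of_cell.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        regulons = [Regulon(tf, tuple(genes)) for tf, genes in payload["regulons"].items()]
        te = pd.DataFrame.from_dict(payload["true_effects"], orient="index")
        return cls(
            regulons=regulons,
            cell_status=pd.Series(payload["cell_status"]),
            true_effects=te,
            guide_of_cell=pd.Series(payload["guide_of_cell"]),
        )


def _gene_universe(cfg: SimConfig) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(cfg.n_genes)]


def _draw_regulons(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[Regulon], dict[str, str]]:
    genes = np.array(_gene_universe(cfg), dtype=object)
    lo, hi = cfg.regulon_size
    sizes = rng.integers(lo, hi + 1, size=cfg.n_tfs)
    # the designated differentiation regulon must be able to carry the panel
    if cfg.marker_panel:
        sizes[0] = max(sizes[0], min(len(cfg.marker_panel), hi))
    # the first n_tfs universe slots become the TF transcripts themselves;
    # regulon members are drawn from the remaining genes so sets stay disjoint
    pool = cfg.n_tfs + rng.permutation(cfg.n_genes - cfg.n_tfs)
    regulons, offset = [], 0
    for i, size in enumerate(sizes):
        members = genes[np.sort(pool[offset : offset + size])]
        regulons.append(Regulon(tf=f"TF{i + 1}", members=tuple(members)))
        offset += size
    universe = _gene_universe(cfg)
    renames: dict[str, str] = {g: f"TF{i + 1}" for i, g in enumerate(universe[: cfg.n_tfs])}
    if cfg.marker_panel:
        first = regulons[0]
        n_markers = min(len(cfg.marker_panel), len(first.members))
        renames.update(zip(first.members[:n_markers], cfg.marker_panel[:n_markers]))
        regulons[0] = Regulon(tf=first.tf, members=tuple(renames.get(g, g) for g in first.members))
    return regulons, renames


def simulate_regulons(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[Regulon]:
    """Draw disjoint TF-centred regulons from the gene universe.

    The first regulon (``TF1``) is the designated differentiation regulon:
    its leading member genes are renamed to the marker panel.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return _draw_regulons(cfg, rng)[0]


def _guide_library(cfg: SimConfig) -> GuideLibrary:
    entries = []
    for target in cfg.targets:
        for j in range(cfg.n_guides_per_target):
            entries.append(GuideEntry(f"{target}-{j + 1}", target, False))
    for j in range(cfg.n_nt):
        entries.append(GuideEntry(f"NT-{j + 1}", None, True))
    return GuideLibrary(entries)


def simulate_screen(
    cfg: SimConfig,
) -> tuple[ScreenMatrix, GuideLibrary, dict[str, list[str]], GroundTruth]:
    """Generate one synthetic screen.

    Per cell: a guide (one per cell by default; zero-truncated Poisson
    multiplicity in MOI mode), a true perturbation status (non-NT cells escape
    editing with probability ``escape_rate``), NB(mean, dispersion) counts with
    per-gene lognormal baseline means, regulon-member means scaled by
    ``2**effect`` in truly perturbed cells, and per-entry logistic dropout in
    the log-mean.  Byte-deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    regulons, renames = _draw_regulons(cfg, rng)
    genes = pd.Index([renames.get(g, g) for g in _gene_universe(cfg)])
    gene_pos = {g: i for i, g in enumerate(genes)}
    member_idx = {r.tf: np.array([gene_pos[g] for g in r.members]) for r in regulons}

    library = _guide_library(cfg)
    tf_names = [r.tf for r in regulons]
    true_effects = pd.DataFrame(0.0, index=list(cfg.targets), columns=tf_names)
    for t, eff in cfg.targets.items():
        unknown = set(eff) - set(tf_names)
        if unknown:
            raise ValueError(f"target {t!r} references unknown regulons {sorted(unknown)}")
        for tf, v in eff.items():
            true_effects.loc[t, tf] = v

    # per-gene baseline means: lognormal with median nb_mean; TF transcripts
    # are low-abundance (scaled down), the sparsity that motivates regulon
    # readouts in the first place
    base_mean = rng.lognormal(np.log(cfg.nb_mean), cfg.gene_mean_sigma, cfg.n_genes)
    # TF transcripts sit in a compressed low-abundance band
    base_mean[: cfg.n_tfs] = rng.lognormal(
        np.log(cfg.nb_mean * cfg.tf_expression_factor), cfg.tf_mean_sigma, cfg.n_tfs
    )

    guides = [e.sgrna_id for e in library.entries]
    barcodes, guide_of_cell, status, extra_guides = [], [], [], {}
    for g in guides:
        target = library.target_of(g)
        for i in range(cfg.n_cells_per_guide):
            bc = f"{g}_c{i + 1:04d}"
            barcodes.append(bc)
            guide_of_cell.append(g)
            if target is None:
                status.append(False)
            else:
                status.append(bool(rng.random() >= cfg.escape_rate))
    status = np.array(status)
    guide_of_cell = pd.Series(guide_of_cell, index=barcodes, name="sgrna_id")

    # group cells by expression arm (baseline vs perturbed-by-target)
    arm_of_cell = np.array(
        [
            library.target_of(g) if perturbed else "__baseline__"
            for g, perturbed in zip(guide_of_cell, status)
        ],
        dtype=object,
    )
    counts = np.zeros((len(barcodes), cfg.n_genes), dtype=np.int64)
    disp = cfg.nb_dispersion
    for arm in pd.unique(arm_of_cell):
        rows = np.flatnonzero(arm_of_cell == arm)
        mean = base_mean.copy()
        if arm != "__baseline__":
            for tf, shift in cfg.targets[arm].items():
                mean[member_idx[tf]] *= 2.0 ** shift
                # the TF transcript moves with its regulon
                mean[gene_pos[tf]] *= 2.0 ** shift
        p = disp / (disp + mean)
        block = rng.negative_binomial(disp, p, size=(len(rows), cfg.n_genes))
        with np.errstate(divide="ignore"):
            p_drop = expit(cfg.dropout_midpoint - np.log(mean))
        block[rng.random(block.shape) < p_drop] = 0
        counts[rows] = block

    assignments: dict[str, list[str]] = {}
    if cfg.moi is None:
        for bc, g in guide_of_cell.items():
            assignments[bc] = [g]
    else:
        # zero-truncated Poisson multiplicity; extra guides drawn uniformly
        for bc, g in guide_of_cell.items():
            k = 0
            while k == 0:
                k = rng.poisson(cfg.moi)
            extras = list(rng.choice(guides, size=k - 1)) if k > 1 else []
            assignments[bc] = [g] + [e for e in extras if e != g]

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["condition"] = cfg.condition
    m = ScreenMatrix(counts=sp.csr_matrix(counts), genes=genes, obs=obs)
    m = compute_qc_metrics(m)
    gt = GroundTruth(
        regulons=regulons,
        cell_status=pd.Series(status, index=barcodes, name="perturbed"),
        true_effects=true_effects,
        guide_of_cell=guide_of_cell,
    )
    return m, library, assignments, gt


def write_screen(
    out_dir: str | Path,
    m: ScreenMatrix,
    library: GuideLibrary,
    assignments: Mapping[str, Sequence[str]],
    gt: GroundTruth,
) -> None:
    """Serialize a simulated screen in the same dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(m, out)
    library.to_table(out / "guides.tsv")
    write_guide_assignments(assignments, out / "assignments.tsv")
    write_regulons_gmt(gt.regulons, out / "regulons.gmt")
    gt.to_json(out / "ground_truth.json")
    if "condition" in m.obs:
        m.obs[["condition"]].to_csv(out / "conditions.tsv", sep="\t")
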