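"""End-to-end run: QC -> unique-sgRNA -> activity -> effects -> modules ->
map -> unperturbed-cell filtering -> marker scores, with every stage artifact
written to disk, checksummed, and the resolved configuration dumped verbatim
so each run is self-describing and byte-reproducible under a fixed seed."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import activity as act
from . import effects as eff
from . import filtering as flt
from . import modules as mod
from . import scoring as sco
from . import screen_data as sd

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cropmap")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Numeric defaults follow the screen-analysis conventions used throughout
    the package: QC bounds 200/6000 genes and 10% mitochondrial reads, gene
    filter 6 UMIs and 1% of cells, a 40-cell minimum per sgRNA, Wilcoxon
    alpha 0.05, k=4 perturbation and k=5 regulon modules, AUCell window 5%,
    elastic-net l1_ratio 0.5 and GMM posterior threshold 0.05.
    """

    screen_dir: str
    out_dir: str
    seed: int = 0
    condition: str | None = None
    min_genes: int = 200
    max_genes: int = 6000
    max_mito: float = 0.10
    mito_prefix: str = "mt-"
    min_total_umi: int = 6
    min_cell_frac: float = 0.01
    top_frac: float = 0.05
    n_variable_regulons: int = 20
    min_cells: int = 40
    alpha: float = 0.05
    k_perturbation: int = 4
    k_regulon: int = 5
    kmeans_n_init: int = 50
    map_tail: str = "upper"
    l1_ratio: float = 0.5
    en_alpha: float | None = 0.05
    n_top_genes: int = 2000
    gmm_threshold: float = 0.05
    gmm_grouping: str = "sgrna"
    pseudocount: float = 1e-2
    scale: float = 1e4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage on a screen directory; returns the output directory.

    The screen directory must contain matrix.mtx / features.tsv /
    barcodes.tsv, guides.tsv, assignments.tsv and regulons.gmt (the layout
    the simulator writes and the readers consume).
    """
    src = Path(cfg.screen_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    artifacts: list[Path] = [out / "config.yaml"]

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("read")
        library = sd.GuideLibrary.from_table(src / "guides.tsv")
        m = sd.read_counts_mtx(
            src / "matrix.mtx", src / "features.tsv", src / "barcodes.tsv", mito_prefix=cfg.mito_prefix
        )
        cond_path = src / "conditions.tsv"
        if cond_path.exists():
            cond = pd.read_csv(cond_path, sep="\t", index_col=0)["condition"]
            m.obs["condition"] = cond.reindex(m.barcodes)
        assignments = sd.read_guide_assignments(src / "assignments.tsv", library)
        regulons = act.read_regulons_gmt(src / "regulons.gmt")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"read: {e}") from e

    try:
        stage("qc")
        m = sd.qc_filter_cells(
            m, min_genes=cfg.min_genes, max_genes=cfg.max_genes,
            max_mito=cfg.max_mito, mito_prefix=cfg.mito_prefix,
        )
        m = sd.select_unique_sgrna_cells(m, assignments, library)
        if cfg.condition is not None:
            m = m.subset_cells((m.obs["condition"] == cfg.condition).to_numpy())
        if m.n_cells == 0:
            raise PipelineError("qc: no cells survive")
        m = sd.normalize_log(m, scale=cfg.scale)
        m.obs.to_csv(out / "cells_qc.tsv", sep="\t")
        artifacts.append(out / "cells_qc.tsv")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"qc: {e}") from e

    try:
        stage("activity")
        mf = act.filter_genes_for_activity(
            m, min_total_umi=cfg.min_total_umi, min_cell_frac=cfg.min_cell_frac
        )
        activity = act.score_aucell(mf, regulons, top_frac=cfg.top_frac)
        activity.to_csv(out / "activity.tsv", sep="\t", float_format="%.10g")
        artifacts.append(out / "activity.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"activity: {e}") from e

    try:
        stage("effects")
        groups, nt_cells = eff.build_target_groups(m)
        groups, removal = eff.filter_min_cells(groups, min_cells=cfg.min_cells)
        if not groups:
            raise PipelineError("effects: no groups survive the min-cell filter")
        if not nt_cells:
            raise PipelineError("effects: no NT reference cells")
        removal.to_csv(out / "min_cell_removals.tsv", sep="\t", index=False)
        e = eff.compute_effect_matrix(activity, groups, nt_cells)
        e.effect.to_csv(out / "effects.tsv", sep="\t", float_format="%.10g")
        e.pvalue.to_csv(out / "effect_pvalues.tsv", sep="\t", float_format="%.10g")
        (out / "effects_meta.json").write_text(
            json.dumps(
                {"reference": e.reference, "condition": cfg.condition,
                 "min_cells": cfg.min_cells, "feature_kind": e.feature_kind},
                sort_keys=True, indent=1,
            )
        )
        artifacts += [out / "min_cell_removals.tsv", out / "effects.tsv",
                      out / "effect_pvalues.tsv", out / "effects_meta.json"]
        pairs = eff.test_regulations(e, alpha=cfg.alpha)
        pd.DataFrame(
            [{"target": p.target, "feature": p.feature, "sign": p.sign,
              "effect": p.effect, "pvalue": p.pvalue} for p in pairs]
        ).to_csv(out / "regulations.tsv", sep="\t", index=False, float_format="%.10g")
        artifacts.append(out / "regulations.tsv")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"effects: {e}") from e

    try:
        stage("modules")
        kp = min(cfg.k_perturbation, len(e.targets))
        kr = min(cfg.k_regulon, len(e.features))
        corr_t = mod.correlate_spearman(e, axis="targets")
        corr_f = mod.correlate_spearman(e, axis="features")
        pm = mod.kmeans_modules(corr_t, k=kp, seed=cfg.seed, n_init=cfg.kmeans_n_init)
        rm = mod.kmeans_modules(corr_f, k=kr, seed=cfg.seed, n_init=cfg.kmeans_n_init)
        pd.Series(pm.assignment, name="module").to_csv(out / "perturbation_modules.tsv", sep="\t")
        pd.Series(rm.assignment, name="module").to_csv(out / "regulon_modules.tsv", sep="\t")
        edges = mod.build_module_map(pairs, pm, rm, alpha=cfg.alpha, tail=cfg.map_tail)
        mod.export_edges(edges, out / "module_map.tsv", format="tsv")
        mod.export_edges(edges, out / "module_map.sif", format="sif")
        artifacts += [out / "perturbation_modules.tsv", out / "regulon_modules.tsv",
                      out / "module_map.tsv", out / "module_map.sif"]
    except Exception as e2:  # noqa: BLE001
        raise PipelineError(f"modules: {e2}") from e2

    try:
        stage("filter-cells")
        _, prob = flt.fit_perturbation_model(
            m, l1_ratio=cfg.l1_ratio, alpha=cfg.en_alpha,
            n_top_genes=cfg.n_top_genes, random_state=cfg.seed,
        )
        m_filt, cell_table = flt.filter_unperturbed_cells(
            m, prob, grouping=cfg.gmm_grouping, threshold=cfg.gmm_threshold, seed=cfg.seed
        )
        cell_table.to_csv(out / "perturbation_probability.tsv", sep="\t", float_format="%.10g")
        artifacts.append(out / "perturbation_probability.tsv")
    except Exception as e2:  # noqa: BLE001
        raise PipelineError(f"filter-cells: {e2}") from e2

    try:
        stage("score")
        obs = m_filt.obs
        groups_cells = {
            t: list(s.index) for t, s in obs[~obs["is_nt"]].groupby("target_gene", sort=True)
        }
        nt = list(obs.index[obs["is_nt"]])
        panel = sco.MarkerPanel().intersect(m_filt.genes)
        fc = sco.compute_fold_changes(
            m_filt, groups_cells, nt, panel=panel,
            pseudocount=cfg.pseudocount, scale=cfg.scale,
        )
        scores = sco.regulator_score(fc)
        scores.to_csv(out / "regulator_scores.tsv", sep="\t", float_format="%.10g")
        artifacts.append(out / "regulator_scores.tsv")
    except Exception as e2:  # noqa: BLE001
        raise PipelineError(f"score: {e2}") from e2

    checks = {p.name: _sha256(p) for p in artifacts}
    (out / "checksums.json").write_text(json.dumps(checks, sort_keys=True, indent=1))
    return out
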