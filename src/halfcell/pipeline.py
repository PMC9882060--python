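"""End-to-end orchestration of the half-cell regionalization analysis.

One :class:`RunConfig` drives the whole sequence — load or simulate paired
half-cell TPM, adjust and filter, compute skews, fit control PCA and project
knockdowns, detect flipped/lost/retained genes, and (optionally) intersect
with reference enrichment calls — writing every stage's tables plus a run
manifest. Two runs with identical config and seed produce identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from . import axis as haxis
from . import flips as hflips
from . import io as hio
from . import skew as hskew
from . import synthetic as hsyn

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("halfcell")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one input source must be given: either file paths
    (``abundance_files`` + ``sample_sheet_path`` or ``matrix_path`` +
    ``sample_sheet_path``) or a simulation block (``sim``).
    """

    out_dir: str = "results"
    # file inputs
    abundance_files: dict[str, str] | None = None
    matrix_path: str | None = None
    sample_sheet_path: str | None = None
    intersect_genes: bool = False
    # simulation input
    sim: hsyn.SimConfig | None = None
    # stage settings
    min_mean_tpm: float = 1.0
    max_dispersion: float = 2.0
    n_components: int | None = None
    control_label: str = "control"
    k_candidates: int = 500
    alpha: float = 0.05
    significance_mode: str = "bh"
    min_effect: float = hflips.DEFAULT_MIN_EFFECT
    reference_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.matrix_path is not None or self.abundance_files is not None
        has_sim = self.sim is not None
        if has_files == has_sim:
            raise ValueError(
                "exactly one of file inputs (matrix/abundance + sample sheet) "
                "or a simulation block must be configured"
            )
        if has_files and self.sample_sheet_path is None:
            raise ValueError("file inputs require a sample sheet path")


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        matrix, sheet, truth = hsyn.generate_experiment(sim)
        return matrix, sheet, truth
    sheet = hio.read_sample_sheet(config.sample_sheet_path)
    if config.matrix_path is not None:
        matrix = hio.read_tpm_matrix(config.matrix_path)
        matrix = matrix[list(sheet["sample_id"])]
    else:
        matrix = hio.assemble_matrix(
            config.abundance_files, sheet, intersect=config.intersect_genes
        )
    return matrix, sheet, None


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the result tables under ``config.out_dir``.

    Returns a bundle with the in-memory results of each stage
    (matrix, sheet, filter report, skew, PCA scores, separation, flip
    results per knockdown condition, and the manifest). Stage failures are
    re-raised with the stage name prepended.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    bundle: dict = {}

    def stage(name: str):
        log.info("[%s] starting", name)
        return name

    name = stage("input")
    try:
        matrix, sheet, truth = _load_inputs(config)
    except Exception as err:  # pragma: no cover - error path
        raise type(err)(f"[{name}] {err}") from err
    bundle.update(matrix=matrix, sheet=sheet, truth=truth)
    problems = hio.validate_pairing(sheet)
    if problems:
        raise hio.ValidationError(f"[input] invalid pairing: {problems[:5]}")

    name = stage("skew")
    adjusted = hskew.log1_adjust(matrix)
    report = hskew.filter_genes(matrix, adjusted, config.min_mean_tpm,
                                config.max_dispersion)
    retained = report.index[report["retained"]]
    adj_retained = hskew.AdjustedMatrix(
        values=adjusted.values.loc[retained], offsets=adjusted.offsets
    )
    skew = hskew.compute_skew(adj_retained, sheet)
    per_gene, per_condition = hskew.summarize_skew(skew)
    bundle.update(adjusted=adjusted, filter_report=report, skew=skew,
                  skew_per_gene=per_gene, skew_per_condition=per_condition)
    hio.write_table(report, os.path.join(config.out_dir, "gene_filter_report.tsv"))
    hio.write_table(skew.values, os.path.join(config.out_dir, "skew_matrix.tsv"))
    hio.write_table(per_gene, os.path.join(config.out_dir, "skew_per_gene.tsv"),
                    index=False)
    hio.write_table(per_condition,
                    os.path.join(config.out_dir, "skew_per_condition.tsv"))

    name = stage("pca")
    control_ids = sheet.loc[sheet["condition"] == config.control_label, "sample_id"]
    model = haxis.fit_control_pca(adj_retained.values[list(control_ids)],
                                  n_components=config.n_components)
    scores = haxis.project(model, adj_retained.values)
    halves = sheet.set_index("sample_id")["half"]
    conditions = sheet.set_index("sample_id")["condition"]
    control_report = haxis.identify_ap_axis(scores.loc[control_ids],
                                            halves.loc[control_ids])
    separation = {}
    for cond in conditions[conditions != config.control_label].unique():
        ids = conditions.index[conditions == cond]
        cond_report = haxis.identify_ap_axis(scores.loc[ids], halves.loc[ids])
        separation[cond] = haxis.separation_loss(control_report, cond_report)
    bundle.update(pca_model=model, scores=scores, control_report=control_report,
                  separation=separation)
    hio.write_table(scores, os.path.join(config.out_dir, "pca_scores.tsv"))
    hio.write_table(control_report,
                    os.path.join(config.out_dir, "ap_separation_control.tsv"))
    if separation:
        hio.write_table(pd.DataFrame(separation).T,
                        os.path.join(config.out_dir, "ap_separation_loss.tsv"))

    name = stage("flips")
    flip_results = {}
    for cond in conditions[conditions != config.control_label].unique():
        mask = skew.pair_condition.isin([config.control_label, cond])
        sub = hskew.SkewMatrix(values=skew.values.loc[mask.to_numpy()],
                               pair_condition=skew.pair_condition[mask.to_numpy()])
        candidates = hflips.select_candidates(sub, k=config.k_candidates,
                                              control_label=config.control_label)
        results = hflips.test_candidates(
            candidates, sub, control_label=config.control_label,
            alpha=config.alpha, significance_mode=config.significance_mode,
            min_effect=config.min_effect,
        )
        flip_results[cond] = results
        hio.write_table(results,
                        os.path.join(config.out_dir, f"flip_results_{cond}.tsv"))
    bundle["flip_results"] = flip_results

    if config.reference_path is not None:
        name = stage("overlap")
        reference = pd.read_csv(config.reference_path, sep="\t", dtype=str)
        for cond, results in flip_results.items():
            overlap = hflips.overlap_with_reference(results, reference, skew=skew)
            hio.write_table(overlap["table"],
                            os.path.join(config.out_dir, f"overlap_{cond}.tsv"))
            if "heatmap" in overlap:
                hio.write_table(
                    overlap["heatmap"],
                    os.path.join(config.out_dir, f"overlap_heatmap_{cond}.tsv"),
                )
            bundle.setdefault("overlap", {})[cond] = overlap

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _manifest_config(config),
        "stages": ["input", "skew", "pca", "flips"]
        + (["overlap"] if config.reference_path else []),
        "n_genes": int(matrix.shape[0]),
        "n_half_samples": int(matrix.shape[1]),
        "n_retained_genes": int(len(retained)),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def _manifest_config(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    return out
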