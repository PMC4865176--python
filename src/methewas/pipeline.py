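"""End-to-end orchestration: simulate -> QC -> normalize -> deconvolve ->
regress -> report, as one reproducible, seeded run.

Stages execute in the fixed order: QC filters, colour-bias correction,
background subtraction, beta computation, BMIQ, cross-reactive removal,
M-value transform, cell deconvolution, control-probe PCA, design
construction and per-CpG regression.  Identical config + seed yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .cohort import characteristics_table
from .datatypes import MethylationMatrix
from .deconv import project_cell_fractions, select_reference_sites
from .ewas import build_design, control_probe_pcs, ewas_regression, plot_series
from .preprocess import (
    apply_qc_filters, background_subtract, beta_to_m, betas_from_intensities,
    bmiq_normalize, color_bias_correct, detection_pvalues, remove_crossreactive,
)
from .simulate import SimulationConfig, default_effects, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run (defaults as published)."""

    sim: SimulationConfig = None
    out_dir: str = "methewas_run"
    detection_p: float = 0.01
    min_beads: int = 3
    sample_call_rate: float = 0.8
    max_probe_missing: float = 0.05
    k_sites: int = 500
    k_pcs: int = 30
    fdr: float = 0.05
    skip_bmiq: bool = False
    blacklist: tuple = ()
    lambda_ladder: bool = True
    write_outputs: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)
        if not (0 < self.detection_p < 1 and 0 < self.sample_call_rate <= 1
                and 0 <= self.max_probe_missing <= 1 and 0 < self.fdr < 1
                and self.min_beads >= 0 and self.k_pcs >= 0
                and self.k_sites > 0):
            raise ValueError("pipeline parameter out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("sim", None)
        cfg = cls(**data)
        if sim:
            if "cell_dirichlet_alpha" in sim:
                sim["cell_dirichlet_alpha"] = tuple(sim["cell_dirichlet_alpha"])
            cfg.sim = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["sim"]["cell_dirichlet_alpha"] = list(
            self.sim.cell_dirichlet_alpha)
        data["blacklist"] = list(self.blacklist)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    ewas: object
    fractions: object
    lambdas: dict
    qc_log: dict
    run_log: dict
    out_dir: Path = None
    cohort_table: object = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in order; see the module docstring for the order.

    Writes per-stage TSVs, the top-table and cohort reports and a
    machine-readable ``run.json`` (QC counts, lambda per adjustment model,
    discoveries at the FDR threshold) unless ``write_outputs`` is False.
    """
    run_log: dict = {"seed": config.seed, "stages": []}

    def stage(name):
        run_log["stages"].append(name)
        log.info("stage: %s", name)

    stage("simulate")
    cohort = simulate_cohort(config.sim, keep_truth=False)
    sheet, manifest, raw = cohort.sheet, cohort.manifest, cohort.raw

    stage("detection_p")
    detp = detection_pvalues(raw)
    stage("qc_filters")
    qc = apply_qc_filters(raw, detp, detection_p=config.detection_p,
                          min_beads=config.min_beads,
                          sample_call_rate=config.sample_call_rate,
                          max_probe_missing=config.max_probe_missing)
    stage("color_bias_correct")
    raw_cc = color_bias_correct(raw, manifest)
    stage("background_subtract")
    raw_bg = background_subtract(raw_cc, manifest)
    stage("beta_values")
    betas = betas_from_intensities(raw_bg, qc.mask)

    if config.skip_bmiq:
        run_log["bmiq"] = "skipped"
        bmiq_fits = {}
    else:
        stage("bmiq")
        betas, bmiq_fits = bmiq_normalize(betas, manifest)
        run_log["bmiq"] = {
            "n_fallback": sum(1 for f in bmiq_fits.values() if f.fallback)}

    stage("crossreactive_removal")
    betas = remove_crossreactive(betas, config.blacklist)
    run_log["n_probes_final"] = int(len(betas.probe_ids))

    stage("mvalues")
    mvals = MethylationMatrix(
        values=pd.DataFrame(beta_to_m(betas.values.values),
                            index=betas.probe_ids, columns=betas.samples),
        scale="mvalue", mask=betas.mask, stage="mvalue")

    stage("cell_deconvolution")
    ref = select_reference_sites(cohort.reference,
                                 k=min(config.k_sites,
                                       len(cohort.reference)))
    fractions = project_cell_fractions(betas, ref)

    stage("control_probe_pca")
    controls = pd.concat([
        raw.controls_red.loc[:, qc.retained_samples].set_axis(
            [f"{i}_red" for i in raw.controls_red.index], axis=0),
        raw.controls_green.loc[:, qc.retained_samples].set_axis(
            [f"{i}_grn" for i in raw.controls_green.index], axis=0),
    ])
    pcs = control_probe_pcs(controls, k=config.k_pcs)

    stage("design_and_regression")
    analysed = sheet.analysed()
    keep = [s for s in analysed.samples if s in set(qc.retained_samples)]
    analysed_sheet = type(sheet)(analysed.frame.loc[keep])
    design = build_design(analysed_sheet, fractions, pcs)
    result = ewas_regression(mvals, betas, design, manifest=manifest)

    lambdas = {"full": result.lambda_}
    if config.lambda_ladder:
        stage("lambda_ladder")
        cell_cols = ["intercept", "exposure"] + \
            [c for c in design.matrix.columns if c.startswith("cell_")]
        cell_design = dataclasses.replace(
            design, matrix=design.matrix[cell_cols])
        r_cell = ewas_regression(mvals, None, cell_design)
        lambdas["cell_only"] = r_cell.lambda_
        cellpc_cols = cell_cols + [c for c in design.matrix.columns
                                   if c.startswith("PC")]
        cellpc_design = dataclasses.replace(
            design, matrix=design.matrix[cellpc_cols])
        r_cellpc = ewas_regression(mvals, None, cellpc_design)
        lambdas["cell_and_pcs"] = r_cellpc.lambda_
    run_log["lambda"] = lambdas
    n_hits = int((result.table["q_value"] < config.fdr).sum())
    run_log["n_discoveries"] = n_hits
    run_log["qc"] = qc.log
    run_log["n_samples_analysed"] = int(design.matrix.shape[0])
    run_log["design_columns"] = int(design.matrix.shape[1])

    table2 = characteristics_table(sheet)
    out_dir = None
    if config.write_outputs:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mio.write_sample_sheet(sheet, out_dir / "sample_sheet.tsv")
        mio.write_cell_fractions(fractions, out_dir / "cell_fractions.tsv")
        mio.write_ewas_results(result, out_dir / "ewas_top_table.tsv")
        volcano, qq = plot_series(result)
        volcano.to_csv(out_dir / "volcano.tsv", sep="\t", index=False,
                       float_format="%.6f")
        qq.to_csv(out_dir / "qq.tsv", sep="\t", index=False,
                  float_format="%.6f")
        table2.drop(columns=["p_value"]).to_csv(
            out_dir / "cohort_characteristics.tsv", sep="\t", index=False)
        with open(out_dir / "run.json", "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
        config.to_yaml(out_dir / "config.yaml")
    return PipelineResult(ewas=result, fractions=fractions, lambdas=lambdas,
                          qc_log=qc.log, run_log=run_log, out_dir=out_dir,
                          cohort_table=table2)


def planted_effect_replicates(seeds, lambda_ladder: bool = True) -> pd.DataFrame:
    """Run the full pipeline once per seed; tabulate the planted probes.

    Returns one row per (seed, planted probe) with the adjusted beta-scale
    exposure effect, its SE, p and q, plus the run's genomic-inflation
    values — the Monte-Carlo replication study used to check that the
    pipeline recovers the planted effect sizes.
    """
    rows = []
    for seed in seeds:
        cfg = RunConfig(seed=int(seed), write_outputs=False,
                        lambda_ladder=lambda_ladder)
        result = run_pipeline(cfg)
        t = result.ewas.table.set_index("probe_id")
        for rank, (pid, delta) in enumerate(default_effects(), start=1):
            r = t.loc[pid]
            rows.append({
                "seed": int(seed), "rank": rank, "probe_id": pid,
                "planted": delta, "beta_diff": float(r["beta_diff"]),
                "se_beta": float(r["se_beta"]), "p_value": float(r["p_value"]),
                "q_value": float(r["q_value"]),
                "n_samples": result.run_log["n_samples_analysed"],
                "lambda_full": result.lambdas.get("full"),
                "lambda_cell_only": result.lambdas.get("cell_only"),
            })
    return pd.DataFrame(rows)
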