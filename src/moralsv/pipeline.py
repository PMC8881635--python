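"""End-to-end synthetic reproduction pipeline.

simulate → fit → match → group → GLM, writing every stage's inputs and
outputs to disk together with a manifest of content hashes.  With a fixed
configuration the run is fully deterministic, down to the bytes of every
output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, glm, group, matching, synthetic
from .data import FINANCIAL, MORAL, write_choice_tsv
from .errors import PipelineError, ValidationError

log = logging.getLogger("moralsv")

__all__ = ["PipelineConfig", "run_pipeline"]

#: Stable float format for all TSV output.
_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything a reproduction run needs; JSON round-trippable."""

    seed: int = 0
    n_subjects: int = 25
    repeats: int = 3  # 180 trials/task: repeated types make cell proportions informative
    population: synthetic.PopulationConfig = field(default_factory=synthetic.PopulationConfig)
    matching_mode: str = "paper"
    matching_n_types: int = 2
    alpha: float = 0.05
    fit_n_starts: int = 10
    glm_n_subjects: int = 1
    glm_shape: tuple[int, int, int] = (12, 12, 12)
    glm_tr: float = 2.0
    glm_noise_sd: float = 1.0
    glm_amplitude: float = 1.0
    glm_threshold: float = 3.0
    glm_drift_order: int = 2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        pop = raw.pop("population", {})
        pop = {k: tuple(v) if isinstance(v, list) else v for k, v in pop.items()}
        cfg = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(population=synthetic.PopulationConfig(**pop), **cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _default_truth(config: PipelineConfig) -> synthetic.BoldTruthConfig:
    """Two disjoint clusters: a financial-SV cluster and a negative moral-SV one."""
    return synthetic.BoldTruthConfig(
        clusters=[
            synthetic.TruthCluster(
                name="vmpfc_like",
                center=(3, 3, 3),
                radius_vox=1.8,
                regressor="financial_sv",
                amplitude=config.glm_amplitude,
            ),
            synthetic.TruthCluster(
                name="rtpj_like",
                center=(8, 8, 8),
                radius_vox=1.8,
                regressor="-moral_sv",
                amplitude=config.glm_amplitude,
            ),
        ],
        noise_sd=config.glm_noise_sd,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages, write outputs under ``out_dir``, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t_start = time.time()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t_start)

    try:
        config.to_json(out / "config.json")
        written.append(out / "config.json")

        # --- simulate -----------------------------------------------------
        stage("simulate")
        rng = np.random.default_rng(config.seed)
        agents = synthetic.sample_cohort(config.population, config.n_subjects, config.seed)
        designs = {
            FINANCIAL: synthetic.build_design(FINANCIAL, repeats=config.repeats),
            MORAL: synthetic.build_design(MORAL, repeats=config.repeats),
        }
        datasets: dict[str, list] = {FINANCIAL: [], MORAL: []}
        for agent in agents:
            for task in (FINANCIAL, MORAL):
                datasets[task].append(
                    synthetic.simulate_choices(
                        agent, designs[task], seed=int(rng.integers(2**31))
                    )
                )
        for task in (FINANCIAL, MORAL):
            write_choice_tsv(datasets[task], out / f"choices_{task}.tsv")
            written.append(out / f"choices_{task}.tsv")
        perception = pd.concat(
            [a.perception.to_frame(a.subject_id) for a in agents], ignore_index=True
        )
        _write_tsv(perception, out / "perception.tsv")
        _write_tsv(pd.DataFrame([a.to_record() for a in agents]), out / "agents_true.tsv")
        written += [out / "perception.tsv", out / "agents_true.tsv"]

        # --- fit ----------------------------------------------------------
        stage("fit")
        fit_rows = []
        fits: dict[str, list] = {FINANCIAL: [], MORAL: []}
        for task in (FINANCIAL, MORAL):
            for ds in datasets[task]:
                fit = behavior.fit_subject(ds, n_starts=config.fit_n_starts, seed=config.seed)
                fits[task].append(fit)
                fit_rows.append(
                    {
                        "subject_id": ds.subject_id,
                        "task": task,
                        "k_hat": fit.k_hat,
                        "beta_hat": fit.beta_hat,
                        "loglik": fit.loglik,
                        "converged": fit.converged,
                        "identifiable": fit.identifiable,
                        "n_trials": fit.n_trials,
                        "discount_r2": fit.discount_r2,
                        "mean_rt": float(ds.trials["rt_ms"].mean()),
                    }
                )
        fit_table = pd.DataFrame(fit_rows)
        for task in (FINANCIAL, MORAL):
            _write_tsv(fit_table[fit_table["task"] == task], out / f"fits_{task}.tsv")
            written.append(out / f"fits_{task}.tsv")

        # --- match --------------------------------------------------------
        stage("match")
        filtered, excluded = matching.exclude_extreme_certainty(
            datasets[FINANCIAL], n_types=config.matching_n_types, mode=config.matching_mode
        )
        slopes_f = matching.cohort_slopes(filtered)
        slopes_m = matching.cohort_slopes(datasets[MORAL])
        report = matching.compare_task_slopes(
            slopes_f,
            slopes_m,
            alpha=config.alpha,
            excluded_trial_types=excluded,
            mode=config.matching_mode,
        )
        (out / "match_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        written.append(out / "match_report.json")

        # --- group --------------------------------------------------------
        stage("group")
        wide = fit_table.pivot(index="subject_id", columns="task")
        summary_table = pd.DataFrame(
            {
                "subject_id": wide.index,
                "k_f": wide[("k_hat", FINANCIAL)],
                "k_m": wide[("k_hat", MORAL)],
                "r2_f": wide[("discount_r2", FINANCIAL)],
                "r2_m": wide[("discount_r2", MORAL)],
                "mean_rt_f": wide[("mean_rt", FINANCIAL)],
                "mean_rt_m": wide[("mean_rt", MORAL)],
            }
        ).reset_index(drop=True)
        summary = group.summarize_cohort(summary_table)
        (out / "cohort_summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True)
        )
        written.append(out / "cohort_summary.json")

        # --- glm ----------------------------------------------------------
        stage("glm")
        import nibabel as nib

        truth = _default_truth(config)
        truth.to_json(out / "glm_truth.json")
        written.append(out / "glm_truth.json")
        glm_summaries = []
        for i in range(min(config.glm_n_subjects, config.n_subjects)):
            subject_datasets = [datasets[FINANCIAL][i], datasets[MORAL][i]]
            bold = synthetic.simulate_bold(
                subject_datasets,
                truth,
                seed=int(rng.integers(2**31)),
                shape=config.glm_shape,
                tr=config.glm_tr,
            )
            design = glm.build_design(
                bold.events,
                tr=config.glm_tr,
                n_scans=bold.n_scans,
                drift_order=config.glm_drift_order,
            )
            result = glm.fit_glm(bold, design)
            fin_t = result.t_map({"financial_sv": 1.0})
            mor_neg_t = result.t_map({"moral_sv": -1.0})
            conj = glm.conjunction(fin_t, mor_neg_t, config.glm_threshold)
            domain_t = glm.contrast_sv_domains(result, pair=("-moral_sv", "financial_sv"))
            sid = subject_datasets[0].subject_id
            if i == 0:
                _write_tsv(bold.events, out / "events.tsv")
                _write_tsv(design.frame, out / "design_matrix.tsv")
                written += [out / "events.tsv", out / "design_matrix.tsv"]
                for name, vol in (
                    ("tmap_financial_sv", fin_t),
                    ("tmap_neg_moral_sv", mor_neg_t),
                    ("tmap_domain_contrast", domain_t),
                ):
                    img = nib.Nifti1Image(vol.astype(np.float32), bold.affine)
                    nib.save(img, out / f"{name}.nii")
                    written.append(out / f"{name}.nii")
            cluster_means = {}
            for cluster in truth.clusters:
                beta = result.beta_map(
                    cluster.regressor.lstrip("-")
                )
                sign = -1.0 if cluster.regressor.startswith("-") else 1.0
                vox = cluster.voxels(config.glm_shape)
                cluster_means[cluster.name] = float(
                    np.mean([sign * beta[v] for v in vox])
                )
            glm_summaries.append(
                {
                    "subject_id": sid,
                    "conjunction_voxels": int(conj.sum()),
                    "cluster_mean_betas": cluster_means,
                    "residual_df": result.residual_df,
                }
            )
        (out / "glm_summary.json").write_text(
            json.dumps(glm_summaries, indent=2, sort_keys=True)
        )
        written.append(out / "glm_summary.json")

        # --- manifest -----------------------------------------------------
        stage("manifest")
        manifest = {
            "config_sha256": _sha256(out / "config.json"),
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except ValidationError:
        raise
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise PipelineError(f"pipeline failed during stage execution: {exc}") from exc
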