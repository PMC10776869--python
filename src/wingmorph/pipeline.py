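"""One-command reproduction of the full wing-morphometrics analysis.

Stage order: Procrustes superimposition → centroid-size ANOVA →
allometry permutation test → LDA ordination with convex hulls →
mean-shape comparison → Mahalanobis/CVA distance permutation tests →
jackknife leave-one-out classification.  Every stage writes a CSV (or
JSON) artifact and the run closes with a JSON manifest capturing every
setting, seed and output, sufficient to re-execute the identical
analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cva import mahalanobis_matrix
from .discriminant import ProcrustesLDA, convex_hulls, loocv
from .procrustes import gpa, mean_shapes
from .size_allometry import allometry_test, size_anova
from .synthetic import GeneratorSpec, default_spec, generate
from .tps import LandmarkDataset, read_labels, read_tps

log = logging.getLogger("wingmorph.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Closure of every setting of one analysis run."""

    tps_path: str | None = None
    labels_path: str | None = None
    generator_spec_path: str | None = None
    use_default_spec: bool = False
    out_dir: str = "wingmorph_out"
    subset: list[str] | None = None
    flip_y: bool = False
    seed: int = 0
    n_perm_allometry: int = 1000
    n_perm_cva: int = 10_000
    priors: str = "proportional"
    project: bool = True
    scale_mode: str = "unit"
    use_log_cs: bool = True
    refit_gpa_loocv: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


STAGES = [
    "load",
    "gpa",
    "size_anova",
    "allometry",
    "lda",
    "mean_shapes",
    "cva",
    "loocv",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load(config: PipelineConfig, out: Path) -> tuple[LandmarkDataset, dict]:
    meta: dict = {}
    if config.use_default_spec or config.generator_spec_path:
        if config.generator_spec_path:
            spec = GeneratorSpec.from_json(Path(config.generator_spec_path).read_text())
            meta["generator_spec"] = str(config.generator_spec_path)
            meta["input_hash"] = _sha256(Path(config.generator_spec_path))
        else:
            spec = default_spec(seed=config.seed)
            meta["generator_spec"] = "default"
        spec = dataclasses.replace(spec, seed=config.seed)
        dataset = generate(spec)
        meta["seed"] = config.seed
    elif config.tps_path:
        labels = read_labels(config.labels_path) if config.labels_path else None
        dataset = read_tps(config.tps_path, labels=labels)
        meta["input_hash"] = _sha256(Path(config.tps_path))
    else:
        raise ValueError("config must name a TPS input or a generator spec")
    if config.flip_y:
        dataset = dataset.flip_y()
    if config.subset:
        dataset = dataset.subset(config.subset)
    if not dataset.group_names:
        raise ValueError("no taxon labels present; supply a label table")
    return dataset, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": {},
        "warnings": [],
        "group_order": None,
    }

    def finish_stage(stage: str, t0: float, outputs: list[str], caught: list):
        manifest["stages"][stage] = {
            "outputs": outputs,
            "seconds": round(time.time() - t0, 4),
        }
        for w in caught:
            manifest["warnings"].append(f"{stage}: {w.message}")
        log.info("stage=%s outputs=%s seconds=%.3f", stage, outputs, time.time() - t0)

    def run_stage(stage: str, fn):
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs = fn()
            except Exception as exc:  # annotate with the stage name
                manifest["stages"][stage] = {"failed": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise PipelineError(stage, exc) from exc
        finish_stage(stage, t0, outputs, caught)

    state: dict = {}

    def stage_load():
        dataset, meta = _load(config, out)
        state["dataset"] = dataset
        manifest["input"] = meta
        manifest["group_order"] = dataset.group_names
        manifest["counts"] = dataset.counts
        raw_path = out / "raw_coordinates.csv"
        dataset.to_frame().to_csv(raw_path, index=False)
        return [raw_path.name]

    def stage_gpa():
        dataset = state["dataset"]
        res = gpa(dataset, project=config.project, scale=config.scale_mode)
        state["gpa"] = res
        state["labels"] = dataset.labels()
        frame = dataset.to_frame()
        frame.iloc[:, 2:] = res.flat()
        aligned_path = out / "aligned_coordinates.csv"
        frame.to_csv(aligned_path, index=False)
        import pandas as pd

        cs_path = out / "centroid_sizes.csv"
        pd.DataFrame(
            {
                "specimen_id": [c.specimen_id for c in dataset],
                "taxon": [c.taxon for c in dataset],
                "centroid_size": res.centroid_sizes,
            }
        ).to_csv(cs_path, index=False)
        meta_path = out / "gpa_meta.json"
        meta_path.write_text(
            json.dumps(
                {
                    "consensus": res.consensus.tolist(),
                    "iterations": res.iterations,
                    "converged": res.converged,
                    "projection": res.projection,
                    "scale": res.scale,
                },
                indent=2,
            )
        )
        if not res.converged:
            warnings.warn("GPA did not converge; downstream results may be unstable")
        return [aligned_path.name, cs_path.name, meta_path.name]

    def stage_size_anova():
        res = size_anova(state["gpa"].centroid_sizes, state["labels"])
        state["anova"] = res
        path = out / "size_anova.json"
        path.write_text(
            json.dumps(
                {
                    "F": res.F,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p": res.p,
                    "group_means": res.group_means,
                },
                indent=2,
            )
        )
        pw_path = out / "size_pairwise.csv"
        res.to_frame().to_csv(pw_path, index=False)
        return [path.name, pw_path.name]

    def stage_allometry():
        res = allometry_test(
            state["gpa"],
            n_permutations=config.n_perm_allometry,
            seed=config.seed,
            use_log=config.use_log_cs,
        )
        state["allometry"] = res
        path = out / "allometry.json"
        path.write_text(json.dumps(dataclasses.asdict(res), indent=2))
        return [path.name]

    def stage_lda():
        model = ProcrustesLDA(priors=config.priors).fit(state["gpa"], state["labels"])
        state["lda"] = model
        scores = model.transform(state["gpa"])
        import pandas as pd

        g = scores.shape[1]
        frame = pd.DataFrame(scores, columns=[f"LD{i + 1}" for i in range(g)])
        frame.insert(0, "taxon", state["labels"])
        frame.insert(
            0, "specimen_id", [c.specimen_id for c in state["dataset"]]
        )
        scores_path = out / "ld_scores.csv"
        frame.to_csv(scores_path, index=False)
        ev_path = out / "lda_axes.json"
        ev_path.write_text(
            json.dumps(
                {
                    "explained_variance_ratio": model.explained_variance_ratio_.tolist(),
                    "eigenvalues": model.eigenvalues_.tolist(),
                    "priors": model.priors_.tolist(),
                    "classes": list(model.classes_),
                },
                indent=2,
            )
        )
        outputs = [scores_path.name, ev_path.name]
        if scores.shape[1] >= 2:
            hulls = convex_hulls(scores[:, :2], state["labels"])
            hull_path = out / "hulls.csv"
            hulls.to_frame().to_csv(hull_path, index=False)
            outputs.append(hull_path.name)
        return outputs

    def stage_mean_shapes():
        comp = mean_shapes(state["gpa"], state["labels"])
        path = out / "mean_shape_displacements.csv"
        comp.to_frame().to_csv(path, index=False)
        return [path.name]

    def stage_cva():
        dm = mahalanobis_matrix(
            state["gpa"],
            state["labels"],
            n_permutations=config.n_perm_cva,
            seed=config.seed,
        )
        state["cva"] = dm
        path = out / "mahalanobis.csv"
        dm.to_frame().to_csv(path)
        return [path.name]

    def stage_loocv():
        cm = loocv(
            state["gpa"],
            state["labels"],
            priors=config.priors,
            refit_gpa=config.refit_gpa_loocv,
            raw_dataset=state["dataset"] if config.refit_gpa_loocv else None,
        )
        state["confusion"] = cm
        counts_path = out / "confusion_counts.csv"
        cm.to_frame(percentages=False).to_csv(counts_path)
        table_path = out / "confusion_table.csv"
        cm.to_frame(percentages=True).to_csv(table_path)
        manifest["loocv_overall_accuracy"] = cm.overall_accuracy
        return [counts_path.name, table_path.name]

    for stage, fn in zip(
        STAGES,
        [
            stage_load,
            stage_gpa,
            stage_size_anova,
            stage_allometry,
            stage_lda,
            stage_mean_shapes,
            stage_cva,
            stage_loocv,
        ],
    ):
        run_stage(stage, fn)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["_state"] = state  # in-memory results for library callers
    return manifest
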