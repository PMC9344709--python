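"""End-to-end pipeline: simulate -> ADC -> features -> normalize ->
select -> train -> threshold -> evaluate, with config and provenance.

All randomness flows from one master seed via named SeedSequence
substreams, so a run's config plus seed reproduces its outputs exactly.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
import yaml

from . import classify, features, selection, synthetic
from .errors import AdcTextureError, PipelineStageError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "substream_seeds"]

_STREAMS = ("simulate", "selection", "split", "cv", "search", "model")


def substream_seeds(master_seed: int) -> dict:
    """Named child seeds derived from one master seed (all < 2**31)."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STREAMS, children)
    }


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run."""

    n_slices: int = 400
    malignant_fraction: float = 0.6222
    class_preset: str = "default"  # default | well_separated | null
    noise_sd: float = 0.02
    levels: int = 16
    distance: int = 1
    normalization: str = "minmax"  # minmax | zscore
    repeats: int = 5
    resample_fraction: float = 0.8
    drop_k: int = 2
    test_fraction: float = 0.30
    cv_folds: int = 10
    run_cv_comparison: bool = True
    search_iters: int = 100
    search_cv_folds: int = 5
    scoring: str = "precision"
    threshold_mode: str = "fixed"  # fixed | max_f1
    fixed_threshold: float = 0.45
    seed: int = 0
    write_images: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise AdcTextureError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def class_params(self) -> dict:
        presets = {
            "default": synthetic._default_class_params,
            "well_separated": synthetic.well_separated_class_params,
            "null": synthetic.null_class_params,
        }
        if self.class_preset not in presets:
            raise AdcTextureError(f"unknown class_preset '{self.class_preset}'")
        return presets[self.class_preset]()


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute every stage in order, writing artifacts to ``out_dir``.

    Returns the final evaluation report (also written as report.json).
    """
    os.makedirs(out_dir, exist_ok=True)
    seeds = substream_seeds(config.seed)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("adctexture")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("substream seeds: %s", seeds)
        with open(os.path.join(out_dir, "resolved_config.yaml"), "w") as fh:
            yaml.safe_dump({**asdict(config), "substream_seeds": seeds}, fh)

        sim_cfg = synthetic.SimConfig(
            n_slices=config.n_slices,
            malignant_fraction=config.malignant_fraction,
            class_params=config.class_params(),
            noise_sd=config.noise_sd,
            seed=seeds["simulate"],
        )
        cases = _stage("simulate", synthetic.generate_cohort, sim_cfg)
        if config.write_images:
            _stage(
                "simulate",
                synthetic.write_cohort,
                cases,
                os.path.join(out_dir, "cohort"),
                True,
            )

        table = _stage(
            "extract",
            features.extract_feature_table,
            cases,
            levels=config.levels,
            distance=config.distance,
        )
        features.write_table(table, os.path.join(out_dir, "features.csv"))

        train, test = _stage(
            "split",
            classify.stratified_split,
            table,
            classify.SplitSpec(test_fraction=config.test_fraction, seed=seeds["split"]),
        )

        params = _stage(
            "normalize",
            features.minmax_fit,
            table,
            train.index,
            method=config.normalization,
        )
        train_n = features.minmax_apply(train, params)
        test_n = features.minmax_apply(test, params)

        scores = _stage(
            "select",
            selection.repeated_anova,
            train_n,
            repeats=config.repeats,
            resample_fraction=config.resample_fraction,
            seed=seeds["selection"],
        )
        retained = _stage("select", selection.select_features, scores, config.drop_k)
        with open(os.path.join(out_dir, "selection.json"), "w") as fh:
            json.dump(
                {
                    "mean_scores": scores.mean_scores.to_dict(),
                    "retained": retained,
                    "repeats": scores.repeats,
                    "resample_fraction": scores.resample_fraction,
                },
                fh,
                indent=2,
            )

        if config.run_cv_comparison:
            cv = _stage(
                "crossvalidate",
                classify.crossvalidate_algorithms,
                train_n,
                retained,
                folds=config.cv_folds,
                seed=seeds["cv"],
            )
            cv.table.to_csv(os.path.join(out_dir, "cv_results.csv"), index=False)
            logger.info("cross-validation winner: %s", cv.winner)

        grid = classify.RFGrid(
            n_sampled_candidates=config.search_iters,
            scoring=config.scoring,
            cv_folds=config.search_cv_folds,
        )
        search = _stage(
            "search", classify.random_search_rf, train_n, grid, retained, seeds["search"]
        )
        with open(os.path.join(out_dir, "search.json"), "w") as fh:
            json.dump(
                {"best_params": search.best_params, "best_score": search.best_score},
                fh,
                indent=2,
            )

        model = _stage(
            "train", classify.fit_rf, train_n, search.best_params, retained, seeds["model"]
        )
        train_scores = classify.predict_scores(model, train_n, retained)
        threshold = _stage(
            "threshold",
            classify.pr_threshold,
            train_scores,
            classify._encode(train_n["label"]),
            mode=config.threshold_mode,
            fixed_value=config.fixed_threshold,
        )

        report = _stage("evaluate", classify.evaluate, model, threshold, test_n, retained)
        test_scores = classify.predict_scores(model, test_n, retained)
        pr, roc = classify.curve_points(test_scores, classify._encode(test_n["label"]))
        pr.to_csv(os.path.join(out_dir, "pr_curve.csv"), index=False)
        roc.to_csv(os.path.join(out_dir, "roc_curve.csv"), index=False)
        joblib.dump(
            {"model": model, "retained": retained, "normalization": params,
             "threshold": threshold},
            os.path.join(out_dir, "model.joblib"),
        )
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("final accuracy: %.4f", report["accuracy"])
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
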