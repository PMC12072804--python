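"""End-to-end experiment orchestration.

``run_experiment`` wires the full screening study together: simulate a cohort
and its photographs (or ingest user-supplied ones), white-balance against the
in-frame reference, convert to YCbCr, extract pixel sets and feature vectors,
cross-validate every configured model on both the scleral and urine pathways,
and summarise each with a regression report, a bilirubin-threshold sweep, a
confusion matrix at the best threshold, and a McNemar comparison of the two
headline models.

Reproducibility contract: one global seed fans out to per-stage seeds through
a fixed hash-based splitting rule, every artifact embeds the seed and a hash
of the resolved configuration, and reruns with the same (config, seed) pair
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, SubjectRecord, simulate_cohort
from .color import (
    RGBImage,
    apply_von_kries,
    clipped_fraction,
    fit_von_kries,
    measure_reference,
    read_image,
    rgb_to_ycbcr,
)
from .errors import ConfigurationError
from .evaluation import (
    DEFAULT_GRID,
    classification_report,
    cross_validate,
    mcnemar_exact,
    regression_report,
    stratified_folds,
    threshold_sweep,
)
from .features import RoIMask, extract_features, extract_pixel_set
from .models import ModelKind, ModelSpec
from .render import read_geometry, read_mask, render_sclera_image, render_urine_image, SceneConfig

logger = logging.getLogger("icterus")

REPORT_SCHEMA_VERSION = "1"

PATHWAYS = ("sclera", "urine")


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    models: tuple[str, ...] = (
        "decision_tree",
        "random_forest",
        "xgboost",
        "deepsets",
    )
    model_hyperparams: dict = field(default_factory=dict)  # kind -> overrides
    k_folds: int = 5
    strat_threshold: float = 3.0  # mg/dL, fold stratification cutoff
    grid: tuple[float, ...] = DEFAULT_GRID
    compare_pair: tuple[str, str] = ("deepsets", "random_forest")
    seed: int = 0
    outdir: str | None = None

    def resolved(self) -> "RunConfig":
        """Copy with all stage seeds fanned out from the global seed."""
        cohort = dataclasses.replace(self.cohort, seed=derive_seed(self.seed, "cohort"))
        scene = dataclasses.replace(self.scene, seed=derive_seed(self.seed, "scene"))
        return dataclasses.replace(self, cohort=cohort, scene=scene)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class SubjectData:
    """Everything extracted for one subject on one pathway."""

    record: SubjectRecord
    pixel_set: object
    features: object


def _process_image(
    image: RGBImage, mask: RoIMask, box, subject_id: str
) -> tuple[object, object]:
    patch = measure_reference(image, box)
    wb = fit_von_kries(patch)
    frac = clipped_fraction(image, wb)
    if frac > 0.01:
        logger.warning("[correct] subject %s: %.1f%% of values clip", subject_id, 100 * frac)
    corrected = apply_von_kries(image, wb)
    ycbcr = rgb_to_ycbcr(corrected)
    pixel_set = extract_pixel_set(ycbcr, mask, subject_id=subject_id)
    return pixel_set, extract_features(pixel_set)


def prepare_synthetic_dataset(
    config: RunConfig,
) -> tuple[list[SubjectRecord], dict[str, dict[str, SubjectData]]]:
    """Simulate the cohort and run both render+correct+extract pathways."""
    cohort = simulate_cohort(config.cohort)
    data: dict[str, dict[str, SubjectData]] = {p: {} for p in PATHWAYS}
    for record in cohort:
        for pathway, renderer in (
            ("sclera", render_sclera_image),
            ("urine", render_urine_image),
        ):
            image, mask, patch = renderer(record, config.scene)
            pixel_set, feats = _process_image(image, mask, patch.region, record.subject_id)
            data[pathway][record.subject_id] = SubjectData(record, pixel_set, feats)
    return cohort, data


def _model_inputs(kind: ModelKind, pathway_data: dict[str, SubjectData]) -> dict:
    use_sets = kind is ModelKind.DEEPSETS
    return {
        sid: (d.pixel_set if use_sets else d.features) for sid, d in pathway_data.items()
    }


def run_experiment(config: RunConfig) -> dict:
    """Execute the full study and return (and optionally write) the report."""
    config = config.resolved()
    logger.info("[simulate] cohort of %d cases + %d controls",
                config.cohort.n_cases, config.cohort.n_controls)
    cohort, data = prepare_synthetic_dataset(config)
    truth = {r.subject_id: r.total_bilirubin for r in cohort}
    order = [r.subject_id for r in cohort]

    folds = stratified_folds(
        cohort,
        k=config.k_folds,
        strat_threshold=config.strat_threshold,
        seed=derive_seed(config.seed, "folds"),
    )

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": len(cohort),
        "models": {},
    }
    predictions: dict[tuple[str, str], dict[str, float]] = {}

    for kind_name in config.models:
        kind = ModelKind(kind_name)
        spec = ModelSpec(
            kind=kind,
            hyperparams=config.model_hyperparams.get(kind_name, {}),
            seed=derive_seed(config.seed, f"model:{kind_name}"),
        )
        block: dict = {}
        for pathway in PATHWAYS:
            logger.info("[cv] %s on %s pathway", kind_name, pathway)
            preds = cross_validate(spec, cohort, _model_inputs(kind, data[pathway]), folds)
            pred_vec = [preds[sid] for sid in order]
            truth_vec = [truth[sid] for sid in order]
            sweep = threshold_sweep(pred_vec, truth_vec, config.grid)
            block[pathway] = {
                "regression": regression_report(pred_vec, truth_vec).as_dict(),
                "threshold_sweep": sweep.as_dict(),
                "classification_at_best": classification_report(
                    pred_vec, truth_vec, sweep.best_threshold
                ).as_dict(),
            }
            predictions[(kind_name, pathway)] = preds
        report["models"][kind_name] = block

    # paired comparison of the two headline models on the scleral pathway
    a, b = config.compare_pair
    if a in config.models and b in config.models:
        report["mcnemar"] = {}
        truth_vec = np.array([truth[sid] for sid in order])
        pa = np.array([predictions[(a, "sclera")][sid] for sid in order])
        pb = np.array([predictions[(b, "sclera")][sid] for sid in order])
        for label, t in (
            (a, report["models"][a]["sclera"]["threshold_sweep"]["best_threshold"]),
            (b, report["models"][b]["sclera"]["threshold_sweep"]["best_threshold"]),
        ):
            correct_a = (pa > t) == (truth_vec > t)
            correct_b = (pb > t) == (truth_vec > t)
            res = mcnemar_exact(correct_a, correct_b)
            report["mcnemar"][f"at_{label}_threshold"] = {
                "threshold": float(t),
                "model_a": a,
                "model_b": b,
                **res.as_dict(),
            }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        rows = []
        for (kind_name, pathway), preds in predictions.items():
            for sid in order:
                rows.append(
                    {
                        "subject_id": sid,
                        "model": kind_name,
                        "pathway": pathway,
                        "prediction": preds[sid],
                        "truth": truth[sid],
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "predictions.csv", index=False)
    return report


# --------------------------------------------------------------------------
# real-data ingestion
# --------------------------------------------------------------------------


@dataclass
class IngestedSubject:
    record: SubjectRecord
    image: RGBImage
    mask: RoIMask
    reference_box: tuple[int, int, int, int]


def ingest_real(
    images_dir: str | Path,
    masks_dir: str | Path,
    cohort: list[SubjectRecord],
) -> list[IngestedSubject]:
    """Match user-supplied images/masks/geometry to cohort records.

    Expects ``<subject_id>.png`` in both directories plus
    ``<subject_id>.json`` (reference box) beside each mask.  Subjects missing
    any piece are excluded with a logged warning; duplicate cohort ids are an
    error.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    seen: set[str] = set()
    for r in cohort:
        if r.subject_id in seen:
            raise ConfigurationError(f"duplicate subject id {r.subject_id}")
        seen.add(r.subject_id)

    out: list[IngestedSubject] = []
    excluded: list[str] = []
    for record in cohort:
        sid = record.subject_id
        img_path = images_dir / f"{sid}.png"
        mask_path = masks_dir / f"{sid}.png"
        geom_path = masks_dir / f"{sid}.json"
        if not (img_path.exists() and mask_path.exists() and geom_path.exists()):
            excluded.append(sid)
            continue
        image = read_image(img_path)
        mask = read_mask(mask_path)
        if mask.mask.shape != image.shape:
            raise ConfigurationError(
                f"subject {sid}: mask shape {mask.mask.shape} != image {image.shape}"
            )
        out.append(
            IngestedSubject(
                record=record,
                image=image,
                mask=mask,
                reference_box=read_geometry(geom_path),
            )
        )
    if excluded:
        logger.warning("[ingest] excluded %d incomplete subjects: %s",
                       len(excluded), excluded[:10])
    logger.info("[ingest] %d subjects ready", len(out))
    return out
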