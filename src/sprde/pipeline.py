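"""End-to-end orchestration: simulate -> preprocess -> extract -> train -> evaluate.

A single :class:`PipelineConfig` collects every tunable constant of the
pipeline (region layout, eigen-feature retention, band splits, classifier
hyperparameters, validation schemes, simulation protocol) together with
one global seed, so a run is fully reproducible from the config alone.
Unknown config keys are rejected rather than ignored.

Feature extraction is per-sample and stateless: each frame's trunk matrix
is preprocessed, rank-decomposed and projected on its own loadings, then
banded into the SBWH / LMR / SE feature sets.  The one knob that couples
stages is the retention floor ``k_min = 7``: the salient matrix is kept
at a fixed 7-column width for every sample, so the banded feature slots
are comparable across the cohort and the three-way longitudinal split is
always well-posed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import band_features, evaluation, preprocessing, smr
from .band_features import BandDefinition
from .data_model import PressureFrame, RegionLayout, extract_region, save_cohort
from .ensemble import BoostConfig, TrainingSet, predict, train
from .simulate import SimulationConfig, simulate_cohort

REPRESENTATIONS = ("raw", "salient", "sbwh", "lmr", "se")


@dataclass(frozen=True)
class SmrConfig:
    """Eigen-feature retention: cumulative contribution threshold and caps.

    ``theta`` retains the smallest eigenvalue prefix reaching that
    cumulative contribution; ``k_min``/``k_max`` clip the result.  The
    pipeline default pins ``k_min = k_max = 7`` so every sample's salient
    matrix has the same 7-column width: feature slots then mean the same
    thing in every SE vector, which matters more for the downstream
    classifier than shaving components off individual frames.
    """

    theta: float = 0.95
    k_max: int = 7
    k_min: int = 7


def _from_mapping(cls, data: dict[str, Any]):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline constants plus the single global seed."""

    seed: int = 0
    out_dir: str = "sprde_run"
    schemes: tuple[str, ...] = ("tenfold", "loocv")
    smr: SmrConfig = field(default_factory=SmrConfig)
    classifier: BoostConfig = field(default_factory=BoostConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        parts: dict[str, Any] = {}
        if "smr" in data:
            parts["smr"] = _from_mapping(SmrConfig, data.pop("smr"))
        if "classifier" in data:
            parts["classifier"] = _from_mapping(BoostConfig, data.pop("classifier"))
        if "simulation" in data:
            sim = dict(data.pop("simulation"))
            if "weight_range" in sim:
                sim["weight_range"] = tuple(sim["weight_range"])
            parts["simulation"] = _from_mapping(SimulationConfig, sim)
        if "schemes" in data:
            data["schemes"] = tuple(data.pop("schemes"))
        known = {f.name for f in fields(cls)} - {"smr", "classifier", "simulation"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data, **parts)
        for scheme in cfg.schemes:
            if scheme not in evaluation.SCHEMES:
                raise ValueError(f"unknown validation scheme {scheme!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def seeded(self, seed: int) -> "PipelineConfig":
        """Copy of the config with every stage seed derived from ``seed``."""
        return PipelineConfig(
            seed=seed,
            out_dir=self.out_dir,
            schemes=self.schemes,
            smr=self.smr,
            classifier=BoostConfig(**{**asdict(self.classifier), "seed": seed}),
            simulation=SimulationConfig(**{
                **{f.name: getattr(self.simulation, f.name)
                   for f in fields(SimulationConfig) if f.name != "layout"},
                "seed": seed,
                "layout": self.simulation.layout,
            }),
        )


@dataclass
class SampleFeatures:
    """Every intermediate representation of one frame."""

    trunk: np.ndarray
    trunk_filtered: np.ndarray
    salient: np.ndarray
    horizontal: band_features.HorizontalFeatures
    longitudinal: band_features.LongitudinalFeatures
    se: np.ndarray
    k_retained: int
    thre: float
    nthre: float


def extract_features(frame: PressureFrame, layout: RegionLayout | None = None,
                     smr_config: SmrConfig | None = None,
                     bands: BandDefinition | None = None) -> SampleFeatures:
    """Run one frame through preprocessing, SMR and band construction."""
    layout = layout or RegionLayout()
    smr_config = smr_config or SmrConfig()
    Z = extract_region(frame, layout, "trunk")
    pre = preprocessing.preprocess(Z)
    views = smr.build_rank_views(pre.Z_filtered)
    decomp = smr.mrr_decompose(views, theta=smr_config.theta,
                               k_max=smr_config.k_max, k_min=smr_config.k_min)
    T = smr.salient_matrix(pre.Z_filtered, decomp)
    band_def = bands or BandDefinition.default(n_rows=T.shape[0], n_cols=T.shape[1])
    h = band_features.horizontal_features(T, band_def)
    l = band_features.longitudinal_features(T, band_def)
    se = band_features.fuse_se(h, l)
    return SampleFeatures(trunk=Z, trunk_filtered=pre.Z_filtered, salient=T,
                          horizontal=h, longitudinal=l, se=se,
                          k_retained=decomp.k_retained, thre=pre.thre, nthre=pre.nthre)


def build_feature_table(frames: Sequence[PressureFrame],
                        layout: RegionLayout | None = None,
                        smr_config: SmrConfig | None = None,
                        bands: BandDefinition | None = None) -> pd.DataFrame:
    """SE feature table: one row per frame, 76 feature columns + metadata."""
    rows = []
    for idx, frame in enumerate(frames):
        try:
            feats = extract_features(frame, layout=layout, smr_config=smr_config, bands=bands)
        except Exception as exc:
            raise type(exc)(
                f"feature extraction failed at sample {idx} "
                f"(subject {frame.subject_id}): {exc}") from exc
        row = {f"se_{i:02d}": v for i, v in enumerate(feats.se)}
        row["label"] = frame.label
        row["subject_id"] = frame.subject_id
        rows.append(row)
    return pd.DataFrame(rows)


def build_representations(frames: Sequence[PressureFrame],
                          layout: RegionLayout | None = None,
                          smr_config: SmrConfig | None = None,
                          bands: BandDefinition | None = None
                          ) -> dict[str, np.ndarray]:
    """Feature matrices for the ablation study, over identical samples.

    raw: the 121 trunk readings, flattened, no preprocessing;
    salient: T flattened, zero-padded to 11 x k_max columns;
    sbwh: boundary + ratio horizontal features (40);
    lmr: boundary + ratio longitudinal features (36);
    se: the fused 76-feature vector.
    """
    smr_config = smr_config or SmrConfig()
    raw, salient, sbwh, lmr, se = [], [], [], [], []
    width = 11 * smr_config.k_max
    for frame in frames:
        feats = extract_features(frame, layout=layout, smr_config=smr_config, bands=bands)
        raw.append(feats.trunk.ravel())
        flat_T = np.zeros(width)
        flat_T[: feats.salient.size] = feats.salient.ravel()
        salient.append(flat_T)
        sbwh.append(np.concatenate([feats.horizontal.A.ravel(), feats.horizontal.B.ravel()]))
        lmr.append(np.concatenate([feats.longitudinal.C.ravel(), feats.longitudinal.D.ravel()]))
        se.append(feats.se)
    return {
        "raw": np.asarray(raw),
        "salient": np.asarray(salient),
        "sbwh": np.asarray(sbwh),
        "lmr": np.asarray(lmr),
        "se": np.asarray(se),
    }


def run_pipeline(config: PipelineConfig | None = None,
                 write_frames: bool = False) -> dict[str, Any]:
    """Execute the full study: simulate, extract, train, cross-validate.

    Writes the feature table, the trained model, per-scheme CV reports and
    a learning-curve series under ``config.out_dir`` and returns a summary
    record.  Identical (config, seed) pairs produce identical outputs.
    """
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames, manifest = simulate_cohort(config.simulation)
    if write_frames:
        save_cohort(frames, out / "frames")
    manifest.to_csv(out / "cohort_manifest.csv", index=False)

    table = build_feature_table(frames, smr_config=config.smr)
    table.to_csv(out / "features.csv", index=False)
    feature_cols = [c for c in table.columns if c.startswith("se_")]
    X = table[feature_cols].to_numpy()
    y = table["label"].to_numpy(dtype=int)

    summary: dict[str, Any] = {"n_samples": int(len(y)), "seed": config.seed,
                               "schemes": {}}
    fit_predict = evaluation.boost_fit_predict(config.classifier)
    for scheme in config.schemes:
        result = evaluation.cross_validate(X, y, fit_predict, scheme=scheme,
                                           seed=config.seed)
        result.per_fold.to_csv(out / f"cv_{scheme}_folds.csv", index=False)
        summary["schemes"][scheme] = result.summary

    model = train(TrainingSet(X, y), config.classifier)
    model.to_json(out / "model.json")
    summary["ensemble_rounds"] = len(model.learners)
    summary["train_error"] = model.trace[-1]["train_error"]

    holdout = evaluation.make_splits(len(y), y, "tenfold", seed=config.seed) == 0
    curve = evaluation.learning_curve(X[~holdout], y[~holdout], X[holdout], y[holdout],
                                      config.classifier)
    curve.to_csv(out / "learning_curve.csv", index=False)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
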