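"""End-to-end orchestration: WAV directory -> segments -> LPC features ->
optimized ensemble + fixed-kernel baselines -> comparison table.

The training flow mirrors how the system is meant to be used: every labeled
recording contributes one 24-coefficient LPC feature vector (extracted from
the enclosing span of its detected tone segments, so split-tone pairs stay in
one analysis window); the Modified Cuckoo Search picks the feature subset and
per-classifier kernels/penalties by leave-one-out balanced accuracy; the
fixed-kernel baselines (SVM-poly, SVM-rbf, SVM-quad) are trained on all 24
coefficients with documented default parameters for comparison.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .evaluation import EvaluationReport, loo_evaluate
from .genome import Genome, fixed_kernel_genome
from .lpc import DEFAULT_ORDER, extract_features
from .mcs import MCSConfig, evolve
from .signals import (
    PCGRecording,
    SegmentationConfig,
    load_recording,
    resample,
    segment_heart_tones,
)
from .svm import OvREnsemble, load_model, save_model, train_ovr_ensemble

log = logging.getLogger("pcgclassify")

#: fixed-kernel baseline parameters (all 24 coefficients, documented defaults)
BASELINE_GENES = {
    "svm-poly": dict(kind="polynomial", u=3, C=1.0),
    "svm-rbf": dict(kind="rbf", sigma=1.0, C=1.0),
    "svm-quad": dict(kind="quadratic", C=1.0),
}


@dataclass
class RunConfig:
    """Everything one experiment needs; seeds propagate to every stage."""

    sample_rate: float = 4000.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    lpc_order: int = DEFAULT_ORDER
    mcs: MCSConfig = field(default_factory=MCSConfig)
    baselines: tuple[str, ...] = ("svm-poly", "svm-rbf", "svm-quad")
    evaluation_mode: str = "leave-one-out"  # or "half-split"
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.evaluation_mode not in ("leave-one-out", "half-split"):
            raise ConfigurationError(f"unknown evaluation mode {self.evaluation_mode!r}")
        for b in self.baselines:
            if b not in BASELINE_GENES:
                raise ConfigurationError(f"unknown baseline {b!r}")
        self.mcs.seed = self.seed


@dataclass
class ComparisonTable:
    """Per-class balanced accuracy of each trained system, plus summary rows."""

    frame: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, float_format="%.4f")


def load_labeled_dir(data_dir: str | Path, sample_rate: float) -> list[tuple[PCGRecording, str]]:
    """Read WAVs listed in ``manifest.csv`` (filename,class_label,...) and resample."""
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.csv"
    if not manifest.exists():
        raise InputError(f"ingestion stage: no manifest.csv in {data_dir}")
    samples = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = load_recording(data_dir / row["filename"])
            rec = resample(rec, sample_rate)
            rec.label = row["class_label"]
            samples.append((rec, row["class_label"]))
    if not samples:
        raise InputError(f"ingestion stage: manifest in {data_dir} lists no recordings")
    return samples


def recording_features(
    rec: PCGRecording, seg_cfg: SegmentationConfig, order: int = DEFAULT_ORDER
) -> np.ndarray:
    """One LPC feature vector for a recording holding a single tone (or pair).

    The analysis window is the enclosing span of all detected segments, so a
    split tone's two bursts are modelled together.
    """
    segments = segment_heart_tones(rec, seg_cfg)
    if not segments:
        raise InputError(f"segmentation stage: no heart tone found in {rec.source_id!r}")
    i0 = int(segments[0].start_time * rec.sample_rate)
    i1 = int(np.ceil(segments[-1].end_time * rec.sample_rate))
    return extract_features(rec.samples[i0:i1], order)


def build_feature_matrix(
    samples: Sequence[tuple[PCGRecording, str]],
    seg_cfg: SegmentationConfig,
    order: int = DEFAULT_ORDER,
) -> tuple[np.ndarray, list[str], list[str]]:
    """(X, labels, source_ids) for a labeled recording collection."""
    X, labels, ids = [], [], []
    for rec, label in samples:
        X.append(recording_features(rec, seg_cfg, order))
        labels.append(label)
        ids.append(rec.source_id)
    return np.asarray(X), labels, ids


def write_feature_table(path: str | Path, X: np.ndarray, y: Sequence[str], ids: Sequence[str]) -> None:
    cols = [f"a{i}" for i in range(1, X.shape[1] + 1)]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "class_label", list(y))
    frame.insert(0, "source_id", list(ids))
    frame.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    frame = pd.read_csv(path)
    cols = [c for c in frame.columns if c.startswith("a")]
    return frame[cols].to_numpy(float), list(frame["class_label"]), list(frame["source_id"])


def stratified_half_split(
    y: Sequence[str], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class half split (train indices, test indices)."""
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(set(y)):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        half = len(idx) // 2
        train.extend(idx[:half])
        test.extend(idx[half:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def _split_report(
    Xtr: np.ndarray, ytr: list[str], Xte: np.ndarray, yte: list[str], genome: Genome
) -> EvaluationReport:
    classes = sorted(set(ytr) | set(yte))
    ens = train_ovr_ensemble(Xtr, ytr, genome, class_order=classes)
    return EvaluationReport.from_predictions(ens.predict(Xte), yte, classes)


def run_experiment(
    config: RunConfig, data_dir: str | Path, out_dir: str | Path | None = None
) -> tuple[ComparisonTable, dict[str, OvREnsemble]]:
    """Execute segment -> features -> train (MCS + baselines) -> evaluate.

    Returns the comparison table (per-class balanced accuracy per system) and
    the final per-system ensembles trained on all available training data.
    Every stage logs its duration and input counts; any stage failure names
    the stage and the offending input.
    """
    t0 = time.time()
    samples = load_labeled_dir(data_dir, config.sample_rate)
    log.info("ingested %d recordings in %.1f s", len(samples), time.time() - t0)

    t0 = time.time()
    X, y, ids = build_feature_matrix(samples, config.segmentation, config.lpc_order)
    log.info("extracted %s features in %.1f s", X.shape, time.time() - t0)

    classes = sorted(set(y))
    m = len(classes)
    genomes: dict[str, Genome] = {
        name: fixed_kernel_genome(m, n_features=X.shape[1], **BASELINE_GENES[name])
        for name in config.baselines
    }

    if config.evaluation_mode == "half-split":
        tr, te = stratified_half_split(y, config.seed)
        Xtr, ytr = X[tr], [y[i] for i in tr]
        Xte, yte = X[te], [y[i] for i in te]
    else:
        Xtr, ytr, Xte, yte = X, y, None, None

    t0 = time.time()
    best_genome, best_fitness, trace = evolve(Xtr, ytr, config.mcs)
    genomes["SVM-MCS"] = best_genome
    log.info("MCS search fitness %.2f in %.1f s", best_fitness, time.time() - t0)

    reports: dict[str, EvaluationReport] = {}
    models: dict[str, OvREnsemble] = {}
    for name, genome in genomes.items():
        if config.evaluation_mode == "leave-one-out":
            reports[name] = loo_evaluate(X, y, genome)
        else:
            reports[name] = _split_report(Xtr, ytr, Xte, yte, genome)
        models[name] = train_ovr_ensemble(Xtr, ytr, genome, class_order=classes)

    columns = ["SVM-MCS"] + [n for n in genomes if n != "SVM-MCS"]
    frame = pd.DataFrame(
        {
            name: [reports[name].per_class[c].balanced_accuracy for c in classes]
            for name in columns
        },
        index=classes,
    )
    frame.loc["Average"] = [reports[name].average for name in columns]
    frame.loc["Average var."] = [reports[name].variance for name in columns]
    table = ComparisonTable(frame=frame)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "comparison.csv")
        write_feature_table(out_dir / "features.csv", X, y, ids)
        metadata = {
            "sample_rate": config.sample_rate,
            "lpc_order": config.lpc_order,
            "segmentation": asdict(config.segmentation),
            "seed": config.seed,
        }
        for name, model in models.items():
            save_model(model, out_dir / f"model_{name}.json", metadata=metadata)
        with open(out_dir / "mcs_trace.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["generation", "best_fitness", "mean_fitness", "levy_scale"])
            for rec in trace:
                writer.writerow([rec.generation, rec.best_fitness, rec.mean_fitness, rec.levy_scale])
        import yaml

        (out_dir / "run_config.yaml").write_text(
            yaml.safe_dump(
                {
                    "sample_rate": config.sample_rate,
                    "lpc_order": config.lpc_order,
                    "evaluation_mode": config.evaluation_mode,
                    "seed": config.seed,
                    "baselines": list(config.baselines),
                    "segmentation": asdict(config.segmentation),
                    "mcs": asdict(config.mcs),
                    "genome_dimension": X.shape[1] + 3 * m,
                }
            )
        )
    return table, models


def classify(model_path: str | Path, wav_path: str | Path) -> list[dict]:
    """Segment a recording and classify each heart tone with a saved model.

    Returns one entry per detected segment: boundary times, the predicted
    class, and the per-class decision values.  Applies the preprocessing
    stored with the model, so predictions match the in-memory model exactly.
    """
    ensemble, metadata = load_model(model_path)
    rec = load_recording(wav_path)
    rec = resample(rec, float(metadata.get("sample_rate", rec.sample_rate)))
    seg_cfg = SegmentationConfig(**metadata["segmentation"]) if "segmentation" in metadata else SegmentationConfig()
    order = int(metadata.get("lpc_order", DEFAULT_ORDER))
    results = []
    for seg in segment_heart_tones(rec, seg_cfg):
        feats = extract_features(seg, order)
        decisions = ensemble.decision_values(feats)[0]
        results.append(
            {
                "start_s": seg.start_time,
                "end_s": seg.end_time,
                "label": ensemble.class_order[int(np.argmax(decisions))],
                "decision_values": dict(zip(ensemble.class_order, decisions.tolist())),
            }
        )
    return results
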