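"""File formats, model serialization, and the configurable pipeline runner.

On-disk conventions:

* FuzzyDataset — CSV with one ``attr:term`` column per membership degree,
  plus a JSON side-car (same path + ``.meta.json``) holding attribute
  roles, term labels and provenance; round-trips bit-exactly (degrees are
  written with full repr precision).
* Signals — one CSV per record: a ``rate_hz=<r>,label=<l>`` header line,
  then one sample per line.
* Models (FDT, FNB, FCM, PCA) — versioned JSON.
* Pipeline configuration — YAML.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, fuzzify, preprocess, synth
from .classify import FDTModel, FDTNode, FNBModel
from .fuzzy import FuzzyAttribute, FuzzyDataset
from .fuzzify import FCMAttribute, FCMModel
from .preprocess import FeatureMatrix, PCAModel, SignalRecord

__all__ = [
    "PipelineConfig",
    "save_fuzzy_dataset",
    "load_fuzzy_dataset",
    "save_signal_record",
    "load_signal_record",
    "save_feature_matrix",
    "load_feature_matrix",
    "save_model",
    "load_model",
    "load_crisp_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Stage chains per data type: which pre-processing steps run before
#: fuzzy-classifier induction.
STAGES_BY_DATA_TYPE = {
    "signal": ("segment", "fft", "pca", "fuzzify"),
    "large_dimensional": ("pca", "fuzzify"),
    "numeric": ("fuzzify",),
    "expert": (),
}


# ---------------------------------------------------------------------------
# FuzzyDataset CSV + sidecar


def save_fuzzy_dataset(ds: FuzzyDataset, path: str | Path) -> None:
    path = Path(path)
    cols = {}
    for attr, block in zip(ds.attributes, ds.memberships):
        for j, term in enumerate(attr.term_labels):
            cols[f"{attr.name}:{term}"] = block[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "provenance": ds.provenance,
        "attributes": [
            {"name": a.name, "terms": list(a.term_labels), "role": a.role}
            for a in ds.attributes
        ],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_fuzzy_dataset(path: str | Path) -> FuzzyDataset:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported fuzzy-dataset schema version {meta.get('schema_version')}")
    df = pd.read_csv(path, float_precision="round_trip")
    attributes, blocks = [], []
    for a in meta["attributes"]:
        attributes.append(FuzzyAttribute(a["name"], tuple(a["terms"]), a["role"]))
        blocks.append(df[[f"{a['name']}:{t}" for t in a["terms"]]].to_numpy(float))
    return FuzzyDataset(attributes=attributes, memberships=blocks, provenance=meta["provenance"])


# ---------------------------------------------------------------------------
# Signals and feature matrices


def save_signal_record(rec: SignalRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"rate_hz={float(rec.sampling_rate)!r},label={rec.label},id={rec.record_id}\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")


def load_signal_record(path: str | Path) -> SignalRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(kv.split("=", 1) for kv in header.split(","))
        samples = np.array([float(line) for line in fh if line.strip()])
    return SignalRecord(
        samples=samples,
        sampling_rate=float(fields["rate_hz"]),
        label=fields.get("label", ""),
        record_id=fields.get("id", ""),
    )


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "label", fm.labels)
    df.to_csv(path, index=False, float_format="%.17g")


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    return FeatureMatrix(
        values=df.drop(columns=["label"]).to_numpy(float),
        feature_names=[c for c in df.columns if c != "label"],
        labels=[str(v) for v in df["label"]],
    )


# ---------------------------------------------------------------------------
# Model JSON round-trips


def _attr_to_json(a: FuzzyAttribute) -> dict:
    return {"name": a.name, "terms": list(a.term_labels), "role": a.role}


def _attr_from_json(d: dict) -> FuzzyAttribute:
    return FuzzyAttribute(d["name"], tuple(d["terms"]), d["role"])


def _node_to_json(n: FDTNode) -> dict:
    if n.is_leaf:
        return {"leaf": True, "confidence": n.confidence.tolist(), "mass": n.mass}
    return {
        "leaf": False,
        "attribute_index": n.attribute_index,
        "mass": n.mass,
        "children": [_node_to_json(c) for c in n.children],
    }


def _node_from_json(d: dict) -> FDTNode:
    if d["leaf"]:
        return FDTNode(confidence=np.asarray(d["confidence"], float), mass=d["mass"])
    return FDTNode(
        attribute_index=d["attribute_index"],
        children=[_node_from_json(c) for c in d["children"]],
        mass=d["mass"],
    )


def save_model(model: FDTModel | FNBModel | FCMModel | PCAModel, path: str | Path) -> None:
    if isinstance(model, FDTModel):
        payload: dict[str, Any] = {
            "kind": "fdt",
            "alpha": model.alpha,
            "beta": model.beta,
            "tnorm": model.tnorm,
            "output_index": model.output_index,
            "attributes": [_attr_to_json(a) for a in model.attributes],
            "root": _node_to_json(model.root),
            "induction_log": model.induction_log,
        }
    elif isinstance(model, FNBModel):
        payload = {
            "kind": "fnb",
            "smoothing": model.smoothing,
            "output_index": model.output_index,
            "attributes": [_attr_to_json(a) for a in model.attributes],
            "priors": model.priors.tolist(),
            "conditionals": {str(i): c.tolist() for i, c in model.conditionals.items()},
        }
    elif isinstance(model, FCMModel):
        payload = {
            "kind": "fcm",
            "attributes": {
                name: {"column": fa.column, "centers": fa.centers.tolist(), "q": fa.q}
                for name, fa in model.attributes.items()
            },
        }
    elif isinstance(model, PCAModel):
        payload = {
            "kind": "pca",
            "means": model.means.tolist(),
            "scales": model.scales.tolist(),
            "kept_columns": model.kept_columns.tolist(),
            "loadings": model.loadings.tolist(),
            "component_variances": model.component_variances.tolist(),
            "feature_names": model.feature_names,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    payload["schema_version"] = SCHEMA_VERSION
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FDTModel | FNBModel | FCMModel | PCAModel:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {d.get('schema_version')}")
    kind = d["kind"]
    if kind == "fdt":
        return FDTModel(
            root=_node_from_json(d["root"]),
            alpha=d["alpha"],
            beta=d["beta"],
            tnorm=d["tnorm"],
            attributes=[_attr_from_json(a) for a in d["attributes"]],
            output_index=d["output_index"],
            induction_log=d["induction_log"],
        )
    if kind == "fnb":
        return FNBModel(
            attributes=[_attr_from_json(a) for a in d["attributes"]],
            output_index=d["output_index"],
            priors=np.asarray(d["priors"], float),
            conditionals={int(i): np.asarray(c, float) for i, c in d["conditionals"].items()},
            smoothing=d["smoothing"],
        )
    if kind == "fcm":
        return FCMModel(
            attributes={
                name: FCMAttribute(column=fa["column"], centers=np.asarray(fa["centers"]), q=fa["q"])
                for name, fa in d["attributes"].items()
            }
        )
    if kind == "pca":
        return PCAModel(
            means=np.asarray(d["means"], float),
            scales=np.asarray(d["scales"], float),
            kept_columns=np.asarray(d["kept_columns"], int),
            loadings=np.asarray(d["loadings"], float),
            component_variances=np.asarray(d["component_variances"], float),
            feature_names=d["feature_names"],
        )
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Crisp tables


def load_crisp_table(
    path: str | Path,
    class_column: str,
    categorical_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Load a crisp CSV table; numeric columns are parsed, missing cells kept.

    Raises if the class column is absent or a numeric cell fails to parse
    (the error names the row and column).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    if class_column not in df.columns:
        raise ValueError(f"{path}: missing class column {class_column!r}")
    categorical = set(categorical_columns or [])
    for col in df.columns:
        if col == class_column or col in categorical:
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad.index[0]) if len(bad) else -1
            raise ValueError(f"{path}: unparseable numeric value at row {row}, column {col!r}") from exc
    return df


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Full pipeline configuration for one data type.

    The stage chain is fixed by ``data_type``: signal data runs
    segment -> FFT -> PCA -> FCM; large-dimensional data runs PCA -> FCM;
    numeric/categorical data runs FCM only; expert data is already fuzzy
    and goes straight to classifier induction.
    """

    data_type: str = "signal"
    segment_seconds: float = 2.95
    n_components: int = 8
    term_counts: int | dict[str, int] = 3
    categorical_columns: list[str] = field(default_factory=list)
    class_column: str = "label"
    positive_class: str = ""
    classifier: str = "fdt"  # fdt | fnb
    alpha: float = 0.01
    beta: float = 0.95
    q: float = 2.0
    train_fraction: float = 0.7
    reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.data_type not in STAGES_BY_DATA_TYPE:
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if self.classifier not in ("fdt", "fnb"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d))


def _feature_matrix_from_signals(cfg: PipelineConfig, signals: list[SignalRecord]) -> FeatureMatrix:
    segments = []
    for rec in signals:
        segments.extend(preprocess.segment_signal(rec, cfg.segment_seconds))
    return preprocess.fft_features(segments)


def _fuzzify_features(cfg: PipelineConfig, fm: FeatureMatrix) -> tuple[FCMModel, FuzzyDataset]:
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df[cfg.class_column] = fm.labels
    tc = cfg.term_counts
    term_counts = {c: tc for c in fm.feature_names} if isinstance(tc, int) else dict(tc)
    return fuzzify.fuzzify_dataset(
        df, term_counts, cfg.class_column, q=cfg.q, seed=cfg.seed, provenance="pipeline"
    )


def _crisp_labels(ds: FuzzyDataset) -> list[str]:
    out = ds.output_attribute
    idx = np.argmax(ds.memberships[ds.output_index], axis=1)
    return [out.term_labels[j] for j in idx]


def _fit_predict_factory(cfg: PipelineConfig):
    def fit_predict(train: FuzzyDataset, test: FuzzyDataset) -> list[str]:
        rows = [
            [test.memberships[i][r] for i in test.input_indices]
            for r in range(test.n_samples)
        ]
        if cfg.classifier == "fdt":
            model = classify.induct_fdt(train, alpha=cfg.alpha, beta=cfg.beta)
            return [classify.fdt_predict_class(model, row) for row in rows]
        model = classify.fnb_fit(train)
        return [classify.fnb_predict_class(model, row) for row in rows]

    return fit_predict


def run_pipeline(
    cfg: PipelineConfig,
    *,
    signals: list[SignalRecord] | None = None,
    table: pd.DataFrame | None = None,
    fuzzy_dataset: FuzzyDataset | None = None,
    artifact_dir: str | Path | None = None,
) -> dict:
    """Execute the stage chain for the configured data type and evaluate.

    Input is one of ``signals`` (data_type=signal), ``table``
    (large_dimensional / numeric) or ``fuzzy_dataset`` (expert).  Returns a
    dict with the fuzzy dataset, fitted artifacts, and the evaluation
    summary; optionally persists intermediate artifacts.
    """
    stages = STAGES_BY_DATA_TYPE[cfg.data_type]
    artifacts: dict[str, Any] = {}
    timings: dict[str, float] = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        out = fn(*args)
        timings[name] = time.perf_counter() - t0
        log.info("stage %s: %.3f s", name, timings[name])
        return out

    if cfg.data_type == "signal":
        if signals is None:
            raise ValueError("signal pipeline needs `signals`")
        fm = timed("segment+fft", _feature_matrix_from_signals, cfg, signals)
    elif cfg.data_type in ("large_dimensional", "numeric"):
        if table is None:
            raise ValueError(f"{cfg.data_type} pipeline needs `table`")
        if cfg.class_column not in table.columns:
            raise ValueError(f"class column {cfg.class_column!r} missing from table")
        numeric = table.drop(columns=[cfg.class_column] + cfg.categorical_columns)
        fm = FeatureMatrix(
            values=numeric.to_numpy(float),
            feature_names=list(numeric.columns),
            labels=[str(v) for v in table[cfg.class_column]],
        )
    else:  # expert
        if fuzzy_dataset is None:
            raise ValueError("expert pipeline needs `fuzzy_dataset`")
        ds = timed("validate", fuzzify.validate_expert_dataset, fuzzy_dataset)

    if "pca" in stages:
        pca_model, fm = timed("pca", preprocess.pca_fit_transform, fm, cfg.n_components)
        artifacts["pca"] = pca_model

    if "fuzzify" in stages:
        if cfg.data_type == "numeric" and table is not None:
            tc = cfg.term_counts
            numeric_cols = [
                c for c in table.columns
                if c != cfg.class_column and c not in cfg.categorical_columns
            ]
            term_counts = {c: tc for c in numeric_cols} if isinstance(tc, int) else dict(tc)
            fcm_model, ds = timed(
                "fuzzify",
                lambda: fuzzify.fuzzify_dataset(
                    table,
                    term_counts,
                    cfg.class_column,
                    categorical_columns=cfg.categorical_columns,
                    q=cfg.q,
                    seed=cfg.seed,
                    provenance="pipeline",
                ),
            )
        else:
            fcm_model, ds = timed("fuzzify", _fuzzify_features, cfg, fm)
        artifacts["fcm"] = fcm_model

    labels = _crisp_labels(ds)
    positive = cfg.positive_class or sorted(set(labels))[-1]
    fit_predict = _fit_predict_factory(cfg)
    result = timed(
        "evaluate",
        lambda: evaluate.random_subsampling_eval(
            ds,
            fit_predict,
            positive,
            reps=cfg.reps,
            train_fraction=cfg.train_fraction,
            seed=cfg.seed,
        ),
    )

    # Fit a final model on all data for the artifact set.
    if cfg.classifier == "fdt":
        final = classify.induct_fdt(ds, alpha=cfg.alpha, beta=cfg.beta)
    else:
        final = classify.fnb_fit(ds)
    artifacts["model"] = final
    out = {
        "fuzzy_dataset": ds,
        "artifacts": artifacts,
        "evaluation": result,
        "positive_class": positive,
        "timings": timings,
    }
    if artifact_dir is not None:
        adir = Path(artifact_dir)
        adir.mkdir(parents=True, exist_ok=True)
        save_fuzzy_dataset(ds, adir / "fuzzy_dataset.csv")
        save_model(final, adir / f"model_{cfg.classifier}.json")
        if "pca" in artifacts:
            save_model(artifacts["pca"], adir / "pca.json")
        if "fcm" in artifacts:
            save_model(artifacts["fcm"], adir / "fcm.json")
        summary = {
            "positive_class": positive,
            "summary": result["summary"],
            "timings": timings,
        }
        (adir / "metrics.json").write_text(json.dumps(summary, indent=1))
    return out
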