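"""Vote-stacked ensemble of per-encoding SVMs.

The pipeline trains one RBF-SVM per feature encoding — by default ten g-gap
dipeptide models (g = 0..9, with ANOVA-F + IFS feature selection) and five
reduced amino-acid composition models (Op5 tripeptides; Op8/Op9/Op11/Op13
dipeptides) — evaluates each on the held-out test split, drops models whose
test sensitivity falls below a threshold (default 20%), and re-encodes every
sequence as the ordered +/-1 predictions of the retained models.  A final
RBF-SVM trained on those vote vectors is the stacked classifier; with the
published protocol and data nine models survive the filter, hence the name
"Vote9", but any retained count k >= 1 is supported.

Vote vectors for final-classifier *training* are produced out-of-fold by
default (cross-fitted clones of each base model predict the folds they were
not fitted on), which keeps the stacking features leakage-free; a
``resubstitution`` policy lets the frozen base models predict their own
training data instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import RunConfig
from .encoders import (
    PROFILES,
    EncoderSpec,
    FeatureMatrix,
    FeatureVector,
    GGapSpec,
    encode_dataset,
    encode_record,
    encoder_name,
)
from .io_fasta import DatasetSplit, LabeledDataset, ProteinRecord
from .modeling import (
    MetricsReport,
    SVMConfig,
    confusion,
    grid_search,
    kfold_accuracy,
    metrics,
    predict_labels,
    train,
)
from .selection import IFSResult, anova_f_scores, ifs_select

logger = logging.getLogger(__name__)

ARTIFACT_FORMAT_VERSION = 1


@dataclass
class BaseModelSpec:
    """One per-encoding SVM: encoder, selected features, config, fitted model."""

    name: str
    encoder_spec: EncoderSpec
    selected_features: list[str]
    svm_config: SVMConfig
    model: SVC
    test_metrics: MetricsReport
    ifs: IFSResult | None = None

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise ValueError(f"model {self.name}: empty feature selection")

    def encode(self, record: ProteinRecord) -> np.ndarray:
        vec = encode_record(record, self.encoder_spec)
        index = {f: j for j, f in enumerate(vec.names)}
        return vec.values[[index[f] for f in self.selected_features]]

    def predict_record(self, record: ProteinRecord) -> int:
        return int(predict_labels(self.model, self.encode(record))[0])


@dataclass
class VoteEnsemble:
    """Retained base models plus the final SVM over +/-1 vote vectors."""

    base_models: list[BaseModelSpec]
    final_config: SVMConfig
    final_model: SVC
    sensitivity_threshold: float
    stacking_policy: str
    test_metrics: MetricsReport | None = None

    @property
    def vote_dimension(self) -> int:
        return len(self.base_models)


def _encoder_specs(cfg: RunConfig) -> list[EncoderSpec]:
    specs: list[EncoderSpec] = [GGapSpec(g) for g in cfg.gaps]
    for pname in cfg.profiles:
        profile = PROFILES[pname]
        specs.append((profile, profile.optimal_n))
    return specs


def _fit_one(
    spec: EncoderSpec,
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    cfg: RunConfig,
    use_ifs: bool,
) -> BaseModelSpec:
    name = encoder_name(spec)
    svm_cfg = grid_search(
        train_fm, cfg.c_grid, cfg.gamma_grid,
        folds=cfg.cv_folds, seed=cfg.seed, class_weight=cfg.class_weight,
    )
    ifs_result: IFSResult | None = None
    if use_ifs:
        ranking = anova_f_scores(train_fm)

        if cfg.ifs_nested_grid:
            def evaluator(sub: FeatureMatrix) -> float:
                inner = grid_search(sub, cfg.c_grid, cfg.gamma_grid,
                                    folds=cfg.cv_folds, seed=cfg.seed,
                                    class_weight=cfg.class_weight)
                return kfold_accuracy(sub, inner, folds=cfg.cv_folds, seed=cfg.seed)
        else:
            def evaluator(sub: FeatureMatrix) -> float:
                return kfold_accuracy(sub, svm_cfg, folds=cfg.cv_folds, seed=cfg.seed)

        ifs_result = ifs_select(train_fm, ranking, evaluator, max_k=cfg.ifs_max_k)
        selected = ifs_result.optimal_features
    else:
        selected = list(train_fm.feature_names)

    fit_fm = train_fm.select_features(selected)
    model = train(fit_fm, svm_cfg)
    test_sub = test_fm.select_features(selected)
    pred = predict_labels(model, test_sub.X)
    report = metrics(confusion(pred, test_sub.labels))
    logger.info("base model %s: k=%d features, test Sn=%.3f Acc=%.3f",
                name, len(selected), report.Sn, report.Acc)
    return BaseModelSpec(
        name=name,
        encoder_spec=spec,
        selected_features=selected,
        svm_config=svm_cfg,
        model=model,
        test_metrics=report,
        ifs=ifs_result,
    )


def train_base_models(split: DatasetSplit, cfg: RunConfig) -> list[BaseModelSpec]:
    """Train all per-encoding base models on the train split; score on test.

    Default configuration yields 15 models: g-gap for g = 0..9 (each with
    ANOVA-F + IFS selection) and the five cluster profiles at their default
    peptide orders (full feature set).
    """
    models: list[BaseModelSpec] = []
    for spec in _encoder_specs(cfg):
        train_fm = encode_dataset(split.train, spec)
        test_fm = encode_dataset(split.test, spec)
        use_ifs = cfg.ifs_ggap if isinstance(spec, GGapSpec) else cfg.ifs_raac
        models.append(_fit_one(spec, train_fm, test_fm, cfg, use_ifs))
    return models


def filter_models(models: list[BaseModelSpec], threshold: float = 0.2) -> list[BaseModelSpec]:
    """Keep models whose test sensitivity is >= threshold, preserving order."""
    kept = [m for m in models if m.test_metrics.Sn >= threshold]
    removed = [m for m in models if m.test_metrics.Sn < threshold]
    for m in removed:
        logger.info("removed %s (test Sn %.3f < %.2f)", m.name, m.test_metrics.Sn, threshold)
    if not kept:
        raise ValueError(
            f"all {len(models)} base models fall below the sensitivity threshold "
            f"{threshold}; no ensemble possible"
        )
    return kept


def vote_encode(record: ProteinRecord, models: list[BaseModelSpec]) -> FeatureVector:
    """Re-encode one sequence as the ordered +/-1 predictions of the models."""
    if not models:
        raise ValueError("no base models to vote")
    votes = np.empty(len(models), dtype=float)
    for j, m in enumerate(models):
        try:
            votes[j] = m.predict_record(record)
        except ValueError as exc:
            raise ValueError(f"model {m.name}: {exc}") from exc
    return FeatureVector(names=[m.name for m in models], values=votes)


def _vote_matrix(data: LabeledDataset, models: list[BaseModelSpec]) -> FeatureMatrix:
    X = np.empty((len(data), len(models)), dtype=float)
    for i, record in enumerate(data.records):
        X[i] = vote_encode(record, models).values
    return FeatureMatrix(ids=data.ids, labels=data.label_array,
                         X=X, feature_names=[m.name for m in models])


def _out_of_fold_votes(
    data: LabeledDataset, models: list[BaseModelSpec], cfg: RunConfig
) -> FeatureMatrix:
    """Cross-fitted vote vectors: clones of each base model predict only the
    fold they were not trained on.  The frozen base models are untouched."""
    n = len(data)
    X = np.empty((n, len(models)), dtype=float)
    labels = data.label_array
    skf = StratifiedKFold(n_splits=cfg.stacking_folds, shuffle=True, random_state=cfg.seed)
    for j, m in enumerate(models):
        fm = encode_dataset(data, m.encoder_spec).select_features(m.selected_features)
        for tr, te in skf.split(fm.X, labels):
            clone = train(fm.subset_rows(tr), m.svm_config)
            X[te, j] = predict_labels(clone, fm.X[te])
    return FeatureMatrix(ids=data.ids, labels=labels,
                         X=X, feature_names=[m.name for m in models])


def train_vote_ensemble(
    split: DatasetSplit,
    models: list[BaseModelSpec],
    cfg: RunConfig,
) -> VoteEnsemble:
    """Grid-search and fit the final SVM on training vote vectors.

    ``cfg.stacking_policy`` chooses how the training vote matrix is built:
    ``out_of_fold`` (cross-fitted, leakage-free; default) or
    ``resubstitution`` (frozen base models predict their own training data).
    The fitted ensemble is scored on the test split.
    """
    if cfg.stacking_policy == "out_of_fold":
        vote_train = _out_of_fold_votes(split.train, models, cfg)
    else:
        vote_train = _vote_matrix(split.train, models)

    row0 = vote_train.X[0]
    if np.all(vote_train.X == row0):
        raise ValueError(
            "degenerate vote matrix: every training sequence received the "
            f"identical vote vector {row0.tolist()} across both classes"
        )

    final_cfg = grid_search(
        vote_train, cfg.c_grid, cfg.gamma_grid,
        folds=cfg.cv_folds, seed=cfg.seed, class_weight=cfg.class_weight,
    )
    final_model = train(vote_train, final_cfg)

    vote_test = _vote_matrix(split.test, models)
    pred = predict_labels(final_model, vote_test.X)
    report = metrics(confusion(pred, vote_test.labels))
    logger.info("stacked ensemble (%d votes): test Sn=%.3f Sp=%.3f Acc=%.3f MCC=%.3f",
                len(models), report.Sn, report.Sp, report.Acc, report.MCC)
    return VoteEnsemble(
        base_models=list(models),
        final_config=final_cfg,
        final_model=final_model,
        sensitivity_threshold=cfg.sensitivity_threshold,
        stacking_policy=cfg.stacking_policy,
        test_metrics=report,
    )


def train_pipeline(split: DatasetSplit, cfg: RunConfig) -> tuple[VoteEnsemble, list[BaseModelSpec]]:
    """Full protocol: base models -> sensitivity filter -> vote stacking."""
    models = train_base_models(split, cfg)
    kept = filter_models(models, cfg.sensitivity_threshold)
    ensemble = train_vote_ensemble(split, kept, cfg)
    return ensemble, models


def predict(
    ensemble: VoteEnsemble,
    records: list[ProteinRecord],
    strict: bool = False,
) -> list[int | None]:
    """Predict +/-1 for each sequence via vote encoding + the final classifier.

    In batch-tolerant mode (default) a record violating some base encoder's
    length precondition yields ``None`` and the rest are still predicted;
    ``strict`` aborts on the first failure.
    """
    out: list[int | None] = []
    for record in records:
        try:
            votes = vote_encode(record, ensemble.base_models)
            out.append(int(predict_labels(ensemble.final_model, votes.values)[0]))
        except ValueError as exc:
            if strict:
                raise
            logger.warning("record %s skipped: %s", record.id, exc)
            out.append(None)
    return out


def evaluate(ensemble: VoteEnsemble, data: LabeledDataset) -> MetricsReport:
    """Metrics of the stacked classifier on a labeled dataset."""
    preds = predict(ensemble, data.records, strict=True)
    return metrics(confusion(np.asarray(preds, dtype=int), data.label_array))


# --------------------------------------------------------------------------
# persistence

def _spec_to_json(spec: EncoderSpec) -> dict:
    if isinstance(spec, GGapSpec):
        return {"kind": "ggap", "g": spec.g}
    profile, n = spec
    return {"kind": "raac", "profile": profile.name, "groups": list(profile.groups),
            "optimal_n": profile.optimal_n, "n": n}


def _spec_from_json(d: dict) -> EncoderSpec:
    if d["kind"] == "ggap":
        return GGapSpec(d["g"])
    from .encoders import ClusterProfile

    profile = ClusterProfile(name=d["profile"], groups=tuple(d["groups"]),
                             optimal_n=d["optimal_n"])
    return (profile, d["n"])


def save_ensemble(ensemble: VoteEnsemble, directory: str | Path) -> None:
    """Persist the ensemble: JSON metadata + joblib model artifacts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": ARTIFACT_FORMAT_VERSION,
        "sensitivity_threshold": ensemble.sensitivity_threshold,
        "stacking_policy": ensemble.stacking_policy,
        "final_config": {"C": ensemble.final_config.C, "gamma": ensemble.final_config.gamma,
                         "class_weight": ensemble.final_config.class_weight},
        "test_metrics": ensemble.test_metrics.as_dict() if ensemble.test_metrics else None,
        "base_models": [
            {
                "name": m.name,
                "encoder": _spec_to_json(m.encoder_spec),
                "selected_features": m.selected_features,
                "svm_config": {"C": m.svm_config.C, "gamma": m.svm_config.gamma,
                               "class_weight": m.svm_config.class_weight},
                "test_metrics": m.test_metrics.as_dict(),
            }
            for m in ensemble.base_models
        ],
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2) + "\n")
    joblib.dump(ensemble.final_model, directory / "final_model.joblib")
    for i, m in enumerate(ensemble.base_models):
        joblib.dump(m.model, directory / f"base_{i:02d}_{m.name}.joblib")


def load_ensemble(directory: str | Path) -> VoteEnsemble:
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    if meta["format_version"] != ARTIFACT_FORMAT_VERSION:
        raise ValueError(f"unsupported artifact format {meta['format_version']}")
    base_models = []
    for i, md in enumerate(meta["base_models"]):
        model = joblib.load(directory / f"base_{i:02d}_{md['name']}.joblib")
        base_models.append(BaseModelSpec(
            name=md["name"],
            encoder_spec=_spec_from_json(md["encoder"]),
            selected_features=md["selected_features"],
            svm_config=SVMConfig(**md["svm_config"]),
            model=model,
            test_metrics=MetricsReport(**{k: v for k, v in md["test_metrics"].items()
                                          if k != "flags"},
                                       flags=tuple(md["test_metrics"]["flags"])),
        ))
    final_model = joblib.load(directory / "final_model.joblib")
    tm = meta.get("test_metrics")
    return VoteEnsemble(
        base_models=base_models,
        final_config=SVMConfig(**meta["final_config"]),
        final_model=final_model,
        sensitivity_threshold=meta["sensitivity_threshold"],
        stacking_policy=meta["stacking_policy"],
        test_metrics=MetricsReport(**{k: v for k, v in tm.items() if k != "flags"},
                                   flags=tuple(tm["flags"])) if tm else None,
    )
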