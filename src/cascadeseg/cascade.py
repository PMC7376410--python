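"""Three-stage CNN → bagged-SVM cascade with ROI-restricted iterative refinement.

Stage 1 trains the convolutional pixel classifier on the labeled cases.
Stage 2 trains the SVM ensemble to map (intensity features + the CNN's
presegmentation label) to the ground truth, pooled over the training cases —
so the ensemble learns to *correct* the CNN, not to imitate it.  Stage 3, at
segmentation time, iterates: dilate the current foreground into a region of
interest (ROI), let the ensemble re-classify the ROI pixels, then let the
CNN re-score the ROI and overwrite where its maximum class probability
clears a confidence threshold (default 0.9).  Pixels outside the ROI are
never touched.  The loop stops when the fraction of changed pixels drops
below ``convergence_tol`` or after ``max_iterations`` passes.

3-D volumes are processed slice-wise along the last axis and restacked.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, disk

from . import cnn_classifier as _cnn
from . import features as _feat
from . import metrics as _metrics
from . import svm_ensemble as _svm
from .cnn_classifier import CNNConfig, CNNModel
from .features import FeatureConfig, PixelFeatureTable
from .io_formats import CaseRecord, ImageVolume, LabelMap, LabelScheme, binarize_whole_tumor
from .svm_ensemble import SVMEnsembleConfig, SVMEnsembleModel

__all__ = ["CascadeConfig", "CascadeResult", "make_roi", "fit_pipeline", "run_case",
           "crossvalidate", "save_models", "load_models"]

logger = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """All tunables of the three-stage pipeline."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    svm: SVMEnsembleConfig = field(default_factory=SVMEnsembleConfig)
    roi_dilation: int = 3
    max_iterations: int = 2
    convergence_tol: float = 0.001
    cnn_veto_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_dilation < 0:
            raise ValueError("roi_dilation must be >= 0")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if not (0 <= self.convergence_tol <= 1):
            raise ValueError("convergence_tol must be in [0, 1]")

    def seeded(self) -> "CascadeConfig":
        """Copy with stage seeds derived from the cascade seed (kept < 2^31)."""
        return replace(
            self,
            cnn=replace(self.cnn, seed=int(self.seed) % (2**31 - 1)),
            svm=replace(self.svm, seed=int(self.seed + 1) % (2**31 - 1)),
        )


@dataclass
class CascadeResult:
    """Presegmentation, every refinement pass, and bookkeeping of one case."""

    presegmentation: LabelMap
    refined: List[LabelMap]
    final: LabelMap
    iterations_run: int
    per_iteration_change: List[float]


def make_roi(preseg: LabelMap, radius: int) -> np.ndarray:
    """Dilate the binary foreground by a disc (2-D) or ball (3-D) of ``radius``.

    Radius 0 returns the foreground itself.  The returned boolean mask is the
    only territory the refinement stage may rewrite.
    """
    if preseg.scheme is not LabelScheme.BINARY:
        raise ValueError("presegmentation must be a BINARY label map")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    fg = preseg.data.astype(bool)
    if radius == 0 or not fg.any():
        return fg
    footprint = disk(radius) if fg.ndim == 2 else ball(radius)
    return ndimage.binary_dilation(fg, structure=footprint)


def _case_feature_table(case: CaseRecord, config: FeatureConfig,
                        slice_index: Optional[int] = None) -> PixelFeatureTable:
    """Concatenate per-modality (gray, mean, median) triplets into one table.

    Modalities follow the CNN's fixed channel order; intensities are
    standardized first when the feature config asks for it.
    """
    vols = [case.volumes[m] for m in _cnn.MODALITY_ORDER if m in case.volumes]
    if not vols:
        vols = list(case.volumes.values())
    blocks, columns = [], []
    coords = shape = None
    for vol in vols:
        if config.normalize:
            vol = _feat.normalize_intensity(vol)
        if slice_index is not None:
            vol = ImageVolume(data=vol.data[..., slice_index], modality=vol.modality)
        t = _feat.pixel_features(vol, config)
        blocks.append(t.features)
        columns += [f"{vol.modality.value.lower()}_{c}" for c in t.columns]
        coords, shape = t.coords, t.shape
    return PixelFeatureTable(coords=coords, features=np.hstack(blocks),
                             columns=columns, shape=shape)


def fit_pipeline(train_cases: Sequence[CaseRecord],
                 config: Optional[CascadeConfig] = None) -> Tuple[CNNModel, SVMEnsembleModel]:
    """Stages 1–2: train the CNN, then the ensemble on CNN-labeled features.

    The ensemble's training rows carry the CNN *presegmentation* as their
    label column while their targets are the ground truth, pooled over all
    training cases.  Everything is driven by ``config.seed``.
    """
    config = (config or CascadeConfig()).seeded()
    if not train_cases:
        raise ValueError("at least one training case required")
    cnn_model = _cnn.train_cnn(list(train_cases), config.cnn)

    tables, targets = [], []
    for case in train_cases:
        preseg = _cnn.predict_labels(cnn_model, case)
        truth = binarize_whole_tumor(case.truth)
        ndim = len(case.shape)
        slice_indices = [None] if ndim == 2 else list(range(case.shape[-1]))
        for si in slice_indices:
            pdata = preseg.data if si is None else preseg.data[..., si]
            tdata = truth.data if si is None else truth.data[..., si]
            table = _case_feature_table(case, config.feature, slice_index=si)
            table = _feat.augment_with_labels(
                table, LabelMap(data=pdata, scheme=LabelScheme.BINARY))
            tables.append(table.features)
            targets.append(tdata.ravel())
    pooled = PixelFeatureTable(
        coords=np.zeros((sum(t.shape[0] for t in tables), 1), dtype=np.int64),
        features=np.vstack(tables))
    svm_model = _svm.train_ensemble(pooled, np.concatenate(targets), config.svm)
    return cnn_model, svm_model


def _run_slice(svm_model: SVMEnsembleModel, case: CaseRecord, config: CascadeConfig,
               proba: np.ndarray, slice_index: Optional[int]) -> CascadeResult:
    cnn_argmax = proba.argmax(axis=-1).astype(np.int64)
    cnn_conf = proba.max(axis=-1)
    preseg = LabelMap(data=cnn_argmax, scheme=LabelScheme.BINARY)

    base_table = _case_feature_table(case, config.feature, slice_index=slice_index)
    current = preseg.data.copy()
    refined: List[LabelMap] = []
    changes: List[float] = []
    for _ in range(config.max_iterations):
        roi = make_roi(LabelMap(data=current, scheme=LabelScheme.BINARY),
                       config.roi_dilation)
        candidate = current.copy()
        if roi.any():
            labeled = _feat.augment_with_labels(
                base_table, LabelMap(data=current, scheme=LabelScheme.BINARY))
            roi_rows = roi[tuple(labeled.coords.T)]
            roi_table = PixelFeatureTable(coords=labeled.coords[roi_rows],
                                          features=labeled.features[roi_rows],
                                          columns=labeled.columns, shape=labeled.shape)
            svm_map = _svm.predict_ensemble(svm_model, roi_table, shape=current.shape)
            candidate[roi] = svm_map.data[roi]
            veto = roi & (cnn_conf >= config.cnn_veto_threshold)
            candidate[veto] = cnn_argmax[veto]
        change = float(np.mean(candidate != current))
        refined.append(LabelMap(data=candidate.copy(), scheme=LabelScheme.BINARY))
        changes.append(change)
        logger.info("refinement pass %d: %.4f%% of pixels changed",
                    len(refined), 100 * change)
        current = candidate
        if change < config.convergence_tol:
            break
    final = refined[-1] if refined else preseg
    return CascadeResult(presegmentation=preseg, refined=refined, final=final,
                         iterations_run=len(refined), per_iteration_change=changes)


def run_case(cnn_model: CNNModel, svm_model: SVMEnsembleModel, case: CaseRecord,
             config: Optional[CascadeConfig] = None) -> CascadeResult:
    """Stage 3: presegment with the CNN, then iterate SVM/CNN refinement.

    For 3-D cases each slice along the last axis is refined independently and
    the maps are restacked; ``iterations_run`` is the slice-wise maximum and
    ``per_iteration_change`` the mean change fraction over slices per pass.
    """
    config = config or CascadeConfig()
    if not cnn_model.trained:
        raise RuntimeError("CNN model is not trained")
    proba = _cnn.predict_proba(cnn_model, case)
    ndim = len(case.shape)
    if ndim == 2:
        return _run_slice(svm_model, case, config, proba, None)

    results = [_run_slice(svm_model, case, config, proba[:, :, s, :], s)
               for s in range(case.shape[-1])]
    n_passes = max(r.iterations_run for r in results)

    def _stack(maps: List[np.ndarray]) -> LabelMap:
        return LabelMap(data=np.stack(maps, axis=-1), scheme=LabelScheme.BINARY)

    preseg = _stack([r.presegmentation.data for r in results])
    refined = []
    for i in range(n_passes):
        refined.append(_stack([
            (r.refined[i] if i < len(r.refined) else r.final).data for r in results]))
    changes = [float(np.mean([r.per_iteration_change[i]
                              for r in results if i < len(r.per_iteration_change)]))
               for i in range(n_passes)]
    final = refined[-1] if refined else preseg
    return CascadeResult(presegmentation=preseg, refined=refined, final=final,
                         iterations_run=n_passes, per_iteration_change=changes)


def crossvalidate(cases: Sequence[CaseRecord], config: Optional[CascadeConfig] = None,
                  k: int = 3) -> List[_metrics.MetricReport]:
    """Seeded case-level k-fold cross-validation of the full pipeline.

    Cases are permuted with the cascade seed and split into k folds that
    partition the cohort exactly; each fold's report evaluates the final
    cascade output against the whole-tumor truth of its held-out cases.
    """
    config = config or CascadeConfig()
    cases = list(cases)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(cases):
        raise ValueError(f"k={k} exceeds number of cases ({len(cases)})")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(cases))
    folds = np.array_split(order, k)
    reports = []
    for fi, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train = [cases[i] for i in range(len(cases)) if i not in test_set]
        cnn_model, svm_model = fit_pipeline(train, config)
        rows = []
        for i in test_idx:
            case = cases[i]
            result = run_case(cnn_model, svm_model, case, config)
            rows.append(_metrics.case_metrics(result.final,
                                              binarize_whole_tumor(case.truth),
                                              case.case_id))
        report = _metrics.cohort_report(rows)
        logger.info("fold %d/%d: DSC %.4f over %d case(s)", fi + 1, k,
                    report.dsc, report.n_cases)
        reports.append(report)
    return reports


def save_models(path, cnn_model: CNNModel, svm_model: SVMEnsembleModel) -> None:
    """Persist both trained stages into one pickle container."""
    with open(Path(path), "wb") as fh:
        pickle.dump({"cnn": cnn_model, "svm": svm_model}, fh)


def load_models(path) -> Tuple[CNNModel, SVMEnsembleModel]:
    with open(Path(path), "rb") as fh:
        blob = pickle.load(fh)
    return blob["cnn"], blob["svm"]
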