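"""End-to-end synthetic experiment: simulate → segment → ROIs → features →
train/score the three models → evaluation report.

The protocol mirrors a train/test workflow at cohort sizes where a single
holdout split is unstable: lesions are split by stratified k-fold
cross-validation (never at ROI level, so no lesion's ROIs leak across a
split), each fold's models are fitted on the training lesions only, and the
pooled out-of-fold per-lesion scores feed one ROC per model.

The expensive stages (segmentation + feature extraction) are
content-addressed by a hash of the configuration that determines them;
re-running a completed stage with the same configuration is a no-op that
loads the cached arrays.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import radiomics
from .aicals import SegmentationOptions, segment_lesion
from .evaluate import agreement_regions, confusion_at, operating_point, roc_auc
from .models import (CNNConfig, RFConfig, predict_scores, select_features,
                     train_cnn, train_random_forest)
from .phantom import PhantomParams, SyntheticCase, generate_cohort
from .roipair import extract_rois, pair_rois
from .types import RegionBox, SegmentationMask, dice

#: leaf-size-to-training-size ratios of the reference configurations
#: (13 and 29 leaves of 104 training pairs)
SL_LEAF_RATIO = 13 / 104
ROI_LEAF_RATIO = 29 / 104


@dataclass
class ExperimentConfig:
    """Everything that determines one synthetic experiment."""

    n_cases: int = 60
    response_rate: float = 0.3
    seed: int = 0
    phantom: PhantomParams = field(default_factory=PhantomParams)
    params_ranges: Optional[Dict[str, Tuple[float, float]]] = None
    seg: SegmentationOptions = field(default_factory=SegmentationOptions)
    use_true_masks: bool = False
    roi_stride: int = 8
    roi_coverage: float = 0.75
    max_pairs_per_lesion: int = 24
    selection_method: str = "sfs"
    k_max_sl: int = 5
    k_max_roi: int = 4
    n_trees_sl: int = 6
    n_trees_roi: int = 2
    cnn: CNNConfig = field(default_factory=lambda: CNNConfig(epochs=30))
    n_folds: int = 3
    target_sensitivity: float = 0.65
    shuffle_labels: bool = False
    null_seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not (2 <= self.n_folds <= self.n_cases):
            raise ValueError("n_folds must be between 2 and n_cases")


def _cfg_hash(parts: Dict) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)
    blob = json.dumps(parts, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _scaled_leaf(ratio: float, n_train: int) -> int:
    return max(1, int(round(ratio * n_train)))


# ------------------------------------------------------------------ stages

def _segment_case(case: SyntheticCase, cfg: ExperimentConfig
                  ) -> Tuple[SegmentationMask, SegmentationMask, List[float]]:
    """Segment both time points; returns masks plus Dice values vs truth
    (where truth exists)."""
    dices: List[float] = []
    if cfg.use_true_masks:
        m_pre = case.true_mask_pre
        m_post = case.true_mask_post
        if m_post is None:
            m_post = SegmentationMask(np.zeros(case.box_post.shape, bool), case.box_post)
        return m_pre, m_post, [1.0]
    m_pre = segment_lesion(case.pre, case.box_pre, cfg.seg)
    dices.append(dice(m_pre.data, case.true_mask_pre.data))
    m_post = segment_lesion(case.post, case.box_post, cfg.seg)
    if case.true_mask_post is not None:
        dices.append(dice(m_post.data, case.true_mask_post.data))
    return m_pre, m_post, dices


def _centroid_only_mask(box: RegionBox) -> SegmentationMask:
    """Single-voxel mask at the box centre: forces the centroid-ROI
    fallback when nothing was segmented (complete responders)."""
    data = np.zeros(box.shape, dtype=bool)
    data[tuple(s // 2 for s in box.shape)] = True
    return SegmentationMask(data, box)


def _lesion_features(case: SyntheticCase, m_pre: SegmentationMask,
                     m_post: SegmentationMask, cfg: ExperimentConfig,
                     pair_seed: int):
    """SL percent-change vector, per-lesion ROI vector, paired patches."""
    fv_pre = radiomics.extract_sl_features(case.pre, m_pre)
    if m_post.is_empty:
        fv_post = radiomics.sl_zero_vector()
    else:
        fv_post = radiomics.extract_sl_features(case.post, m_post)
    pct = radiomics.percent_change(fv_pre, fv_post)

    rois_pre = extract_rois(case.pre, m_pre, stride=cfg.roi_stride,
                            coverage=cfg.roi_coverage,
                            lesion_id=case.case_id, timepoint="pre")
    m_post_roi = m_post if not m_post.is_empty else _centroid_only_mask(case.box_post)
    rois_post = extract_rois(case.post, m_post_roi, stride=cfg.roi_stride,
                             coverage=cfg.roi_coverage,
                             lesion_id=case.case_id, timepoint="post")
    pairs = pair_rois(rois_pre, rois_post, case.label,
                      max_pairs=cfg.max_pairs_per_lesion, seed=pair_seed)
    patches = np.stack([p.patch for p in pairs], axis=0)
    roi_vecs = [radiomics.extract_roi_features(p.patch) for p in pairs]
    per_lesion = radiomics.aggregate_per_lesion(roi_vecs)
    return pct.values, per_lesion.values, patches


def _feature_stage(cfg: ExperimentConfig) -> Dict:
    """Simulation + segmentation + feature extraction, with caching."""
    key = _cfg_hash({
        "n_cases": cfg.n_cases, "response_rate": cfg.response_rate,
        "seed": cfg.seed, "phantom": cfg.phantom, "ranges": cfg.params_ranges,
        "seg": cfg.seg, "true_masks": cfg.use_true_masks,
        "stride": cfg.roi_stride, "coverage": cfg.roi_coverage,
        "max_pairs": cfg.max_pairs_per_lesion,
    })
    cache_path = None
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        cache_path = os.path.join(cfg.out_dir, f"features_{key}.npz")
        if os.path.exists(cache_path):
            npz = np.load(cache_path, allow_pickle=True)
            return {k: npz[k] for k in npz.files} | {"cache_hit": True, "key": key}

    cohort = generate_cohort(cfg.n_cases, cfg.response_rate,
                             cfg.params_ranges, seed=cfg.seed,
                             base_params=cfg.phantom)
    labels, pct_rows, roi_rows, patch_sets, dice_all = [], [], [], [], []
    for i, case in enumerate(cohort):
        m_pre, m_post, dices = _segment_case(case, cfg)
        dice_all.extend(dices)
        pct, roi_vec, patches = _lesion_features(
            case, m_pre, m_post, cfg, pair_seed=cfg.seed * 100003 + i)
        labels.append(1 if case.label.is_complete else 0)
        pct_rows.append(pct)
        roi_rows.append(roi_vec)
        patch_sets.append(patches)

    counts = np.array([p.shape[0] for p in patch_sets])
    out = {
        "labels": np.array(labels, dtype=int),
        "X_sl": np.array(pct_rows, dtype=float),
        "X_roi": np.array(roi_rows, dtype=float),
        "patches": np.concatenate(patch_sets, axis=0),
        "patch_counts": counts,
        "dice": np.array(dice_all, dtype=float),
        "key": key,
    }
    if cache_path:
        np.savez_compressed(cache_path, **{k: v for k, v in out.items()
                                           if k != "key"})
    out["cache_hit"] = False
    return out


def _lesion_patch_slices(counts: np.ndarray) -> List[slice]:
    ends = np.cumsum(counts)
    starts = ends - counts
    return [slice(int(a), int(b)) for a, b in zip(starts, ends)]


def _cv_scores(cfg: ExperimentConfig, feats: Dict, y: np.ndarray) -> Dict[str, np.ndarray]:
    """Out-of-fold per-lesion scores for the three models."""
    n = len(y)
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                          random_state=cfg.seed + 7)
    sl_scores = np.zeros(n)
    roi_scores = np.zeros(n)
    cnn_scores = np.zeros(n)
    patch_slices = _lesion_patch_slices(feats["patch_counts"])
    patches = feats["patches"]

    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
        # RF-SL on percent-change features
        cfg_sl = RFConfig(cfg.n_trees_sl, _scaled_leaf(SL_LEAF_RATIO, len(tr)),
                          seed=cfg.seed + fold)
        cols = select_features(feats["X_sl"][tr], y[tr], method=cfg.selection_method,
                               k_max=cfg.k_max_sl, seed=cfg.seed + fold,
                               rf_config=cfg_sl)
        model = train_random_forest(cfg_sl, feats["X_sl"][np.ix_(tr, cols)], y[tr],
                                    kind="rf_sl")
        sl_scores[te] = predict_scores(model, feats["X_sl"][np.ix_(te, cols)])

        # RF-ROI on per-lesion averaged ROI features
        cfg_roi = RFConfig(cfg.n_trees_roi, _scaled_leaf(ROI_LEAF_RATIO, len(tr)),
                           seed=cfg.seed + fold)
        cols = select_features(feats["X_roi"][tr], y[tr], method=cfg.selection_method,
                               k_max=cfg.k_max_roi, seed=cfg.seed + fold,
                               rf_config=cfg_roi)
        model = train_random_forest(cfg_roi, feats["X_roi"][np.ix_(tr, cols)], y[tr],
                                    kind="rf_roi")
        roi_scores[te] = predict_scores(model, feats["X_roi"][np.ix_(te, cols)])

        # DL-CNN on paired ROIs (trained on training lesions' ROIs only)
        tr_patches = np.concatenate([patches[patch_slices[i]] for i in tr], axis=0)
        tr_labels = np.concatenate([np.full(patch_slices[i].stop - patch_slices[i].start,
                                            y[i]) for i in tr])
        cnn_cfg = dataclasses.replace(cfg.cnn, seed=cfg.seed + fold)
        net = train_cnn(cnn_cfg, tr_patches, tr_labels)
        for i in te:
            probs = net.predict_proba(patches[patch_slices[i]])[:, 1]
            cnn_scores[i] = float(probs.mean())

    return {"rf_sl": sl_scores, "rf_roi": roi_scores, "dl_cnn": cnn_scores}


def run_experiment(cfg: ExperimentConfig) -> Dict:
    """Run the full synthetic experiment; returns a JSON-serializable report."""
    feats = _feature_stage(cfg)
    y = np.asarray(feats["labels"], dtype=int)
    if cfg.shuffle_labels:
        # null cohort: labels replaced by an independent seeded draw at the
        # configured response rate, so the images carry no label information.
        # (A fixed permutation would couple train- and test-fold label/class
        # correlations through its fixed class counts, biasing cross-validated
        # null AUCs below 0.5.)
        rng = np.random.default_rng(cfg.seed * 31 + 13 + cfg.null_seed)
        while True:
            y_new = (rng.random(len(y)) < cfg.response_rate).astype(int)
            if min(np.bincount(y_new, minlength=2)) >= cfg.n_folds:
                break
        y = y_new

    scores = _cv_scores(cfg, feats, y)

    report: Dict = {
        "n_cases": int(len(y)),
        "n_responders": int(y.sum()),
        "labels_shuffled": bool(cfg.shuffle_labels),
        "feature_stage_cache_hit": bool(feats.get("cache_hit", False)),
        "median_dice": float(np.median(np.asarray(feats["dice"], dtype=float))),
        "models": {},
    }
    correctness = []
    for name in ("dl_cnn", "rf_sl", "rf_roi"):
        s = scores[name]
        roc = roc_auc(s, y)
        op = operating_point(s, y, cfg.target_sensitivity)
        conf = confusion_at(s, y, op.threshold)
        pred = s >= op.threshold
        correctness.append(pred == (y == 1))
        report["models"][name] = {
            "auc": round(roc.auc, 6), "auc_se": round(roc.se, 6),
            "operating_threshold": round(op.threshold, 6),
            "confusion": conf,
            "scores": [round(float(v), 6) for v in s],
        }
    table = agreement_regions(np.array(correctness).T.tolist())
    report["agreement"] = {
        "all_correct": table.all_correct,
        "none_correct": table.none_correct,
        "all_correct_pct": table.all_correct_fraction_pct,
        "counts": {"".join("1" if b else "0" for b in k): v
                   for k, v in sorted(table.counts.items())},
    }
    report["labels"] = [int(v) for v in y]

    if cfg.out_dir:
        suffix = f"_null{cfg.null_seed}" if cfg.shuffle_labels else ""
        path = os.path.join(cfg.out_dir, f"report_{feats['key']}{suffix}.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
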