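"""Patient-based leave-one-out evaluation protocol.

Each patient's windows in turn form the test set; training (and any
hyperparameter selection) uses only the remaining patients, so no information
leaks between training and test.  Training pools are class-balanced by
undersampling the majority class *within each patient*; test sets are never
rebalanced — every window of the held-out patient is scored.  Hyperparameters
are selected by nested, patient-grouped k-fold cross-validation over a grid
(skipped for singleton grids); ties prefer the smaller kernel, then fewer
channels.  Optionally the whole procedure is repeated with different seeds and
per-patient scores averaged.

Reported per patient: AuROC, the ROC curve, TPR/precision at fixed FPR levels
(default 10/20/30%), the confusion matrix at 20% FPR, the chosen
hyperparameters and seeds, and (optionally) a within-patient permutation test
of better-than-chance performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GroupKFold

from .features import featurize_matrix
from .models import BlackboxFCNClassifier, NAMClassifier, NAMExplanation, fit_baseline
from .preprocess import MODALITIES, stack_inputs, prepare_window
from .stats import TestResult, permutation_test_auroc
from .windowing import WindowingConfig, extract_windows

logger = logging.getLogger(__name__)


@dataclass
class WindowDataset:
    """Stacked, preprocessed windows for a cohort."""

    X: np.ndarray  # (n, n_features) flat model inputs
    y: np.ndarray  # (n,) 1 = target
    groups: np.ndarray  # (n,) patient ids
    start_s: np.ndarray  # (n,) window start times
    horizon_s: float = 15.0
    window_len_s: float = 30.0

    def __len__(self) -> int:
        return len(self.y)


def build_dataset(recordings, ann_lists, cfg: WindowingConfig = WindowingConfig()
                  ) -> WindowDataset:
    """Extract, preprocess and stack all windows of a cohort."""
    inputs = []
    for rec, anns in zip(recordings, ann_lists):
        for w in extract_windows(rec, anns, cfg):
            inputs.append(prepare_window(w))
    X, y, groups = stack_inputs(inputs)
    start_s = np.array([m.start_s for m in inputs])
    return WindowDataset(X, y, groups, start_s, cfg.horizon_s, cfg.window_len_s)


def undersample(y: np.ndarray, groups: np.ndarray,
                seed: int | None = 0) -> np.ndarray:
    """Indices of a per-patient class-balanced subset.

    Within each patient the majority class is subsampled without replacement
    down to the minority count (symmetric: works whichever class dominates).
    Patients exhibiting a single class are excluded with a warning.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        classes, counts = np.unique(y[idx], return_counts=True)
        if len(classes) < 2:
            logger.warning("patient %s has a single class; excluded from training", g)
            continue
        k = counts.min()
        for c in classes:
            ic = idx[y[idx] == c]
            keep.append(ic if len(ic) == k else rng.choice(ic, k, replace=False))
    if not keep:
        raise ValueError("no patient contributes both classes")
    return np.sort(np.concatenate(keep))


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def metrics_at_fpr(scores, labels, fpr_target: float
                   ) -> tuple[float, float, np.ndarray]:
    """TPR, precision and confusion matrix at the loosest threshold whose
    empirical FPR does not exceed ``fpr_target``.

    Returns ``(tpr, precision, [[tn, fp], [fn, tp]])``; precision is 0 when
    nothing is predicted positive.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pos = labels == labels.max()
    fpr, tpr, thresholds = roc_curve(pos, scores, drop_intermediate=False)
    ok = np.flatnonzero(fpr <= fpr_target + 1e-12)
    i = ok[-1]
    pred = scores >= thresholds[i] if np.isfinite(thresholds[i]) else np.zeros_like(pos)
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    tpr_v = tp / max(tp + fn, 1)
    prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    return float(tpr_v), float(prec), np.array([[tn, fp], [fn, tp]])


@dataclass(frozen=True)
class EvalConfig:
    """Settings of the leave-one-patient-out protocol."""

    inner_folds: int = 5
    n_repeats: int = 1
    seed: int = 0
    fpr_levels: tuple[float, ...] = (0.1, 0.2, 0.3)
    permutation_test: bool = False
    n_perm: int = 999
    collect_explanations: bool = False
    model_params: dict = field(default_factory=dict)


@dataclass
class PatientResult:
    patient: str
    auroc: float
    auroc_per_repeat: list[float]
    roc: tuple[np.ndarray, np.ndarray]
    metrics: dict[float, tuple[float, float]]  # fpr -> (tpr, precision)
    confusion_at_02: np.ndarray
    chosen_params: dict
    seeds: list[int]
    n_test: int
    train_patients: tuple[str, ...]
    permutation: TestResult | None = None
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None


@dataclass
class CVReport:
    patients: list[PatientResult]
    explanations: dict[str, NAMExplanation] = field(default_factory=dict)

    @property
    def patient_aurocs(self) -> np.ndarray:
        return np.array([p.auroc for p in self.patients])

    @property
    def mean_auroc(self) -> float:
        return float(np.nanmean(self.patient_aurocs))

    @property
    def sd_auroc(self) -> float:
        return float(np.nanstd(self.patient_aurocs))

    def aggregate(self) -> dict:
        """Aggregate statistics, recomputed purely from per-patient entries."""
        out = {
            "mean_auroc": self.mean_auroc,
            "sd_auroc": self.sd_auroc,
            "n_patients": len(self.patients),
        }
        if self.patients:
            for f in self.patients[0].metrics:
                tprs = np.array([p.metrics[f][0] for p in self.patients])
                precs = np.array([p.metrics[f][1] for p in self.patients])
                out[f"tpr_at_fpr_{f}"] = {
                    "median": float(np.median(tprs)),
                    "q25": float(np.percentile(tprs, 25)),
                    "q75": float(np.percentile(tprs, 75)),
                }
                out[f"precision_at_fpr_{f}"] = {
                    "median": float(np.median(precs)),
                    "q25": float(np.percentile(precs, 25)),
                    "q75": float(np.percentile(precs, 75)),
                }
        return out


def _derive_seed(base: int, *parts: int) -> int:
    return int(np.random.SeedSequence([base, *parts]).generate_state(1)[0] % (2**31))


def _make_estimator(model_kind: str, params: dict, seed: int,
                    window_len_s: float):
    params = dict(params)
    if model_kind == "nam":
        return NAMClassifier(random_state=seed, window_len_s=window_len_s, **params)
    if model_kind == "blackbox":
        return BlackboxFCNClassifier(random_state=seed, window_len_s=window_len_s,
                                     **params)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _fit_and_score(model_kind, params, seed, Xtr, ytr, gtr, Xte, window_len_s):
    """Undersample the training pool, fit one model, score the test windows."""
    idx = undersample(ytr, gtr, seed)
    if model_kind in ("logreg", "mlp"):
        clf = fit_baseline(model_kind, Xtr[idx], ytr[idx], seed)
        return clf.predict_proba(Xte)[:, 1], clf
    est = _make_estimator(model_kind, params, seed, window_len_s)
    est.fit(Xtr[idx], ytr[idx])
    return est.predict_proba(Xte)[:, 1], est


def _select_params(model_kind, grid, Xtr, ytr, gtr, cfg, window_len_s) -> dict:
    """Nested, patient-grouped k-fold selection of the best grid point."""
    if len(grid) == 1:
        return dict(grid[0])
    n_groups = len(np.unique(gtr))
    k = max(2, min(cfg.inner_folds, n_groups))
    splits = list(GroupKFold(n_splits=k).split(Xtr, ytr, gtr))
    results = []
    for gi, params in enumerate(grid):
        scores = []
        for fi, (itr, iva) in enumerate(splits):
            if len(np.unique(ytr[iva])) < 2:
                continue
            seed = _derive_seed(cfg.seed, 7, gi, fi)
            s, _ = _fit_and_score(model_kind, params, seed, Xtr[itr], ytr[itr],
                                  gtr[itr], Xtr[iva], window_len_s)
            scores.append(auroc(s, ytr[iva]))
        mean_score = float(np.mean(scores)) if scores else -np.inf
        results.append((-mean_score, params.get("kernel_size", 0),
                        params.get("hidden_channels", 0), gi, params))
    results.sort(key=lambda r: r[:4])
    return dict(results[0][4])


def loocv(dataset: WindowDataset, model_kind: str = "nam",
          grid: list[dict] | None = None, cfg: EvalConfig = EvalConfig()
          ) -> CVReport:
    """Leave-one-patient-out cross-validation with nested model selection."""
    patients = list(np.unique(dataset.groups))
    if len(patients) < 3:
        raise ValueError("need at least 3 patients")
    if grid is not None and len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    grid = grid or [{}]
    X = (featurize_matrix(dataset.X, dataset.window_len_s)
         if model_kind in ("logreg", "mlp") else dataset.X)
    y, groups = dataset.y, dataset.groups

    report = CVReport(patients=[])
    for pi, pat in enumerate(patients):
        te = groups == pat
        Xtr, ytr, gtr = X[~te], y[~te], groups[~te]
        Xte, yte = X[te], y[te]
        base_params = dict(cfg.model_params)
        sel = _select_params(model_kind, [dict(base_params, **g) for g in grid],
                             Xtr, ytr, gtr, cfg, dataset.window_len_s)
        aurocs, seeds = [], []
        scores = est = None
        for r in range(cfg.n_repeats):
            seed = _derive_seed(cfg.seed, pi, r)
            seeds.append(seed)
            scores, est = _fit_and_score(model_kind, sel, seed, Xtr, ytr, gtr,
                                         Xte, dataset.window_len_s)
            if len(np.unique(yte)) < 2:
                logger.warning("patient %s has a single test class; AuROC undefined",
                               pat)
                aurocs.append(np.nan)
            else:
                aurocs.append(auroc(scores, yte))

        if len(np.unique(yte)) < 2:
            metrics = {f: (np.nan, np.nan) for f in cfg.fpr_levels}
            conf = np.zeros((2, 2), dtype=int)
            fpr = tpr = np.array([])
            perm = None
        else:
            metrics = {f: metrics_at_fpr(scores, yte, f)[:2] for f in cfg.fpr_levels}
            _, _, conf = metrics_at_fpr(scores, yte, 0.2)
            fpr, tpr, _ = roc_curve(yte, scores, drop_intermediate=False)
            perm = (permutation_test_auroc(scores, yte, cfg.n_perm, seeds[-1])
                    if cfg.permutation_test else None)

        if cfg.collect_explanations and hasattr(est, "explain"):
            report.explanations[pat] = est.explain(Xte)
            report.explanations[pat].patient_ids = np.repeat(pat, len(Xte))

        report.patients.append(PatientResult(
            patient=pat, auroc=float(np.nanmean(aurocs)), auroc_per_repeat=aurocs,
            roc=(fpr, tpr), metrics=metrics, confusion_at_02=conf,
            chosen_params=sel, seeds=seeds, n_test=int(te.sum()),
            train_patients=tuple(p for p in patients if p != pat),
            permutation=perm, scores=scores, labels=yte,
        ))
    return report


def horizon_curve(recordings, ann_lists, horizons, wcfg: WindowingConfig,
                  model_kind: str = "nam", grid: list[dict] | None = None,
                  cfg: EvalConfig = EvalConfig()) -> dict[float, CVReport]:
    """Full LOOCV per prediction horizon on re-extracted windows."""
    out = {}
    for h in horizons:
        ds = build_dataset(recordings, ann_lists, replace(wcfg, horizon_s=h))
        out[h] = loocv(ds, model_kind, grid, cfg)
    return out


@dataclass
class ImportanceReport:
    """Modality importance from the spread of additive contributions."""

    pooled_sd: dict[str, float]
    per_patient_sd: pd.DataFrame  # rows: patients, columns: modalities
    ranking: tuple[str, ...]  # modalities, most important first


def modality_importance(explanations: dict[str, NAMExplanation]
                        ) -> ImportanceReport:
    """Rank modalities by the spread of their additive contributions."""
    if not explanations:
        raise ValueError("no explanations")
    mods = next(iter(explanations.values())).modalities
    pooled = np.concatenate([e.contributions for e in explanations.values()])
    pooled_sd = {m: float(pooled[:, j].std()) for j, m in enumerate(mods)}
    rows = {
        pat: {m: float(e.contributions[:, j].std()) for j, m in enumerate(mods)}
        for pat, e in explanations.items()
    }
    per_patient = pd.DataFrame.from_dict(rows, orient="index")[list(mods)]
    ranking = tuple(sorted(mods, key=lambda m: -pooled_sd[m]))
    return ImportanceReport(pooled_sd, per_patient, ranking)


def single_modality_suite(dataset: WindowDataset, modality_sets,
                          grid: list[dict] | None = None,
                          cfg: EvalConfig = EvalConfig()) -> dict:
    """LOOCV of single-modality (or reduced-subset) additive models."""
    out = {}
    for entry in modality_sets:
        mods = (entry,) if isinstance(entry, str) else tuple(entry)
        sub_cfg = replace(cfg, model_params=dict(cfg.model_params,
                                                 modalities=mods))
        key = mods[0] if len(mods) == 1 else mods
        out[key] = loocv(dataset, "nam", grid, sub_cfg)
    return out


def average_roc(report: CVReport, n_grid: int = 101
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertically averaged ROC over patients on a fixed FPR grid."""
    grid = np.linspace(0, 1, n_grid)
    tprs = []
    for p in report.patients:
        fpr, tpr = p.roc
        if len(fpr) == 0:
            continue
        tprs.append(np.interp(grid, fpr, tpr))
    tprs = np.array(tprs)
    return grid, tprs.mean(axis=0), tprs.std(axis=0)
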