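"""Cohort balancing, grouped 80/20 splitting, end-to-end orchestration and
held-out performance reporting.

The pediatric phenotype is the positive class throughout: sensitivity is
the fraction of true pediatric spectra called pediatric, specificity the
fraction of adult spectra called adult.  Splits operate on whole physical
cells, so no spectra of one cell ever straddle the train/test boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .classify import (
    MLPConfig,
    PCAModel,
    ScalerParams,
    apply_pca,
    apply_scaler,
    fit_pca,
    fit_scaler,
    grid_search_mlp,
    predict,
    train_mlp,
)
from .core import SpectralDataset
from .preprocess import PreprocessConfig, PreprocessResult, preprocess_dataset
from .simulate import SyntheticConfig, generate_cohort

POSITIVE = "pediatric"
NEGATIVE = "adult"


def _cells_by_class(ds: SpectralDataset, label: str) -> list:
    """Ordered (cell key, [spectrum ids]) lists for one class."""
    cells: dict = {}
    for s in ds:
        if s.meta.class_label == label:
            cells.setdefault(f"{s.meta.cell_line}|{s.meta.cell_id}", []).append(
                s.meta.spectrum_id
            )
    return sorted(cells.items())


def balance_classes(ds: SpectralDataset, seed: int = 0) -> SpectralDataset:
    """Subsample the majority class to the minority count, by whole cells.

    The minority class is kept complete; majority cells are drawn without
    replacement in seeded random order, the last drawn cell contributing
    only as many spectra as needed to match the minority count exactly.
    """
    counts = ds.class_counts
    if counts[POSITIVE] == 0 or counts[NEGATIVE] == 0:
        raise ValueError("both classes must be non-empty to balance")
    if counts[POSITIVE] == counts[NEGATIVE]:
        return ds
    minority = min(counts, key=counts.get)
    majority = POSITIVE if minority == NEGATIVE else NEGATIVE
    target = counts[minority]
    rng = np.random.default_rng(seed)
    cells = _cells_by_class(ds, majority)
    order = rng.permutation(len(cells))
    keep_ids = {s.meta.spectrum_id for s in ds if s.meta.class_label == minority}
    taken = 0
    for i in order:
        if taken >= target:
            break
        _, ids = cells[i]
        ids = list(ids)
        if taken + len(ids) > target:
            ids = ids[: target - taken]  # partial last cell
        keep_ids.update(ids)
        taken += len(ids)
    return ds.subset(keep_ids)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test spectrum ids; whole cells on one side only."""

    train_ids: tuple
    test_ids: tuple
    seed: int


def make_split(ds: SpectralDataset, test_frac: float = 0.2, seed: int = 0) -> SplitPlan:
    """Stratified, cell-grouped random split of a balanced dataset.

    Within each class, whole cells are assigned to the test side until the
    test count is as close to ``test_frac`` of the class as whole cells
    allow.  Deterministic given ``seed``.
    """
    if not 0 <= test_frac < 1:
        raise ValueError("test_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    test_ids: list = []
    train_ids: list = []
    for label in (POSITIVE, NEGATIVE):
        cells = _cells_by_class(ds, label)
        if len(cells) < 2:
            raise ValueError(f"need at least 2 cell groups in class {label!r} to split")
        n_class = sum(len(ids) for _, ids in cells)
        target = test_frac * n_class
        order = rng.permutation(len(cells))
        count = 0
        for i in order:
            _, ids = cells[i]
            if abs(count + len(ids) - target) <= abs(count - target):
                test_ids.extend(ids)
                count += len(ids)
            else:
                train_ids.extend(ids)
        # note: cells are never split; per-class test size is within one
        # whole cell of the target
    return SplitPlan(train_ids=tuple(sorted(train_ids)), test_ids=tuple(sorted(test_ids)), seed=seed)


# ---------------------------------------------------------------------------
# reporting


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and summary metrics, pediatric as positive class."""

    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1_pediatric: float
    f1_adult: float
    auc: Optional[float]
    n_test_pediatric: int
    n_test_adult: int

    @property
    def confusion_percent(self) -> np.ndarray:
        """Row-normalized confusion matrix, rows actual ped/adult, in %."""
        counts = np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)
        return 100.0 * counts / counts.sum(axis=1, keepdims=True)

    def rounded(self, decimals: int = 1) -> dict:
        """Presentation metrics in percent, half-up rounded."""
        out = {
            "accuracy": round_half_up(100 * self.accuracy, decimals),
            "sensitivity": round_half_up(100 * self.sensitivity, decimals),
            "specificity": round_half_up(100 * self.specificity, decimals),
            "precision": round_half_up(100 * self.precision, decimals),
            "f1_pediatric": round_half_up(100 * self.f1_pediatric, decimals),
            "f1_adult": round_half_up(100 * self.f1_adult, decimals),
        }
        if self.auc is not None:
            out["auc"] = round_half_up(self.auc, 3)
        return out

    def to_text(self) -> str:
        pct = self.confusion_percent
        lines = [
            f"{'':>16}{'Predicted pediatric':>22}{'Predicted adult':>18}",
            f"{'Actual pediatric':>16}{round_half_up(pct[0, 0]):>21.1f}%{round_half_up(pct[0, 1]):>17.1f}%",
            f"{'Actual adult':>16}{round_half_up(pct[1, 0]):>21.1f}%{round_half_up(pct[1, 1]):>17.1f}%",
            "",
        ]
        for k, v in self.rounded().items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def compute_report(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    pediatric_scores: Sequence[float],
) -> ClassificationReport:
    """Confusion counts, rates, per-class F1 and trapezoidal ROC AUC."""
    y = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    s = np.asarray(pediatric_scores, dtype=float)
    if not (y.size == p.size == s.size):
        raise ValueError("inputs must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite scores")
    tp = int(np.sum((y == POSITIVE) & (p == POSITIVE)))
    fn = int(np.sum((y == POSITIVE) & (p == NEGATIVE)))
    fp = int(np.sum((y == NEGATIVE) & (p == POSITIVE)))
    tn = int(np.sum((y == NEGATIVE) & (p == NEGATIVE)))
    n = tp + fn + fp + tn
    n_pos, n_neg = tp + fn, fp + tn
    accuracy = (tp + tn) / n if n else float("nan")
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    f1_ped = 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) else float("nan")
    f1_adu = 2 * tn / (2 * tn + fn + fp) if (2 * tn + fn + fp) else float("nan")
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class truth: ROC AUC undefined", RuntimeWarning)
        auc = None
    else:
        # rank-based (trapezoidal over all thresholds, midrank tie handling)
        auc = float(roc_auc_score(y == POSITIVE, s))
    return ClassificationReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        precision=precision, f1_pediatric=f1_ped, f1_adult=f1_adu, auc=auc,
        n_test_pediatric=n_pos, n_test_adult=n_neg,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    report: ClassificationReport
    split: SplitPlan
    scaler: ScalerParams
    pca: PCAModel
    mlp_config: MLPConfig
    preprocess: PreprocessResult
    cv_result: object = None
    pca_cumulative_variance: float = float("nan")

    @property
    def explained_variance_pct(self) -> float:
        return 100.0 * self.pca_cumulative_variance


def fit_transforms(train_matrix: np.ndarray, n_components: int = 20) -> tuple:
    """Fit scaler then PCA on the training matrix only."""
    scaler = fit_scaler(train_matrix)
    Xs = apply_scaler(scaler, train_matrix)
    pca = fit_pca(Xs, n_components=n_components)
    return scaler, pca


def run_pipeline(
    synth_cfg: Optional[SyntheticConfig] = None,
    dataset: Optional[SpectralDataset] = None,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    mlp_cfg: Optional[MLPConfig] = None,
    seed: int = 0,
    test_frac: float = 0.2,
    n_components: int = 20,
    do_grid_search: bool = False,
    search_kwargs: Optional[dict] = None,
) -> PipelineResult:
    """simulate/load -> preprocess -> balance -> grouped split -> train-only
    scaler + PCA -> (optional architecture search) -> MLP -> held-out report.

    ``seed`` drives every random stage through independent substreams;
    identical inputs and seed reproduce the result exactly.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s) % (2**31) for s in ss.generate_state(4)]
    seed_gen, seed_bal, seed_split, seed_mlp = sub

    if dataset is None:
        if synth_cfg is None:
            raise ValueError("provide either synth_cfg or dataset")
        from dataclasses import replace as _replace
        dataset, _ = generate_cohort(_replace(synth_cfg, seed=seed_gen))

    try:
        pre = preprocess_dataset(dataset, pre_cfg)
    except ValueError as exc:
        raise ValueError(f"preprocess stage failed: {exc}") from exc

    balanced = balance_classes(pre.dataset, seed=seed_bal)
    split = make_split(balanced, test_frac=test_frac, seed=seed_split)

    train = balanced.subset(split.train_ids)
    test = balanced.subset(split.test_ids)
    X_train = train.intensity_matrix()
    y_train = train.labels()

    scaler, pca = fit_transforms(X_train, n_components=n_components)
    Z_train = apply_pca(pca, apply_scaler(scaler, X_train))
    cum_var = float(pca.explained_variance_ratio.sum())

    cv_result = None
    if mlp_cfg is None:
        mlp_cfg = MLPConfig(seed=seed_mlp)
    else:
        from dataclasses import replace as _replace
        mlp_cfg = _replace(mlp_cfg, seed=seed_mlp)
    if do_grid_search:
        kwargs = dict(search_kwargs or {})
        cv_result = grid_search_mlp(
            Z_train, y_train, train.groups(), seed=seed_mlp,
            mlp_cfg=mlp_cfg, **kwargs,
        )
        from dataclasses import replace as _replace
        mlp_cfg = _replace(mlp_cfg, hidden_layout=cv_result.chosen)

    clf = train_mlp(Z_train, y_train, mlp_cfg)

    X_test = test.intensity_matrix()
    Z_test = apply_pca(pca, apply_scaler(scaler, X_test))
    pred, p_ped = predict(clf, Z_test)
    report = compute_report(test.labels(), pred, p_ped)

    return PipelineResult(
        report=report, split=split, scaler=scaler, pca=pca,
        mlp_config=mlp_cfg, preprocess=pre, cv_result=cv_result,
        pca_cumulative_variance=cum_var,
    )
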