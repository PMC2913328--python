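"""Validation statistics for BCF models.

SDEP (standard deviation error in prediction), R², external Q², 3x3
nB/B/vB confusion matrices with the "percent(count)" rendering used in
regulatory model reports, accuracy, false-negative / false-positive
rates, and the experimental-variability summary (mean per-compound range
of replicate measurements).

Percentages are always 100*count/n of the evaluated (in-domain) set;
counts are the authoritative quantity, display rounding is 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemdata import Dataset, DataError, mean_exp_logbcf
from .classify import BcfClass, ClassificationScheme, REACH, classify, classify_with_offset

CLASS_LABELS = ("nB", "B", "vB")


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise DataError("observed and predicted must be 1-D vectors of equal length")
    if o.size == 0:
        raise DataError("empty vectors")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise DataError("observed and predicted must be finite")
    return o, p


def sdep(observed, predicted) -> float:
    """Standard deviation error in prediction: sqrt(Σ(oᵢ−pᵢ)²/n)."""
    o, p = _pair(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted."""
    o, p = _pair(observed, predicted)
    if o.size < 3:
        raise DataError("need at least 3 pairs for r²")
    if np.ptp(o) == 0 or np.ptp(p) == 0:
        raise DataError("constant vector: correlation undefined")
    r = np.corrcoef(o, p)[0, 1]
    return float(r * r)


def q_squared_ext(observed, predicted, training_mean: float) -> float:
    """External predictive Q²: 1 − PRESS / Σ(oᵢ − ȳ_train)².

    The reference mean is the *training-set* mean of the observed
    response, so Q² measures improvement over the null model that
    predicts the training average for every external compound.
    """
    o, p = _pair(observed, predicted)
    ss = float(np.sum((o - training_mean) ** 2))
    if ss == 0:
        raise DataError("zero total sum of squares about the training mean")
    press = float(np.sum((o - p) ** 2))
    return 1.0 - press / ss


@dataclass
class ConfusionMatrix3:
    """3x3 confusion matrix; rows = predicted class, columns = observed.

    Row/column order is nB, B, vB.  For two-class schemes the vB row and
    column simply stay zero.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3), dtype=int)
    )

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise DataError("confusion matrix must be 3x3")
        if (self.counts < 0).any():
            raise DataError("negative count in confusion matrix")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key) -> int:
        pred, obs = key
        if isinstance(pred, str):
            pred = BcfClass.from_label(pred)
        if isinstance(obs, str):
            obs = BcfClass.from_label(obs)
        return int(self.counts[int(pred), int(obs)])

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)

    def render(self, title: str = "") -> str:
        """Aligned text table in the "percent(count)" report style."""
        n = self.n
        lines = []
        if title:
            lines.append(f"{title}  ({n} comp.)")
        corner = "Pred / Obs"
        lines.append(f"{corner:>12}" + "".join(f"{c:>16}" for c in CLASS_LABELS))
        for i, row_label in enumerate(CLASS_LABELS):
            cells = []
            for j in range(3):
                c = int(self.counts[i, j])
                pct = 100.0 * c / n if n else 0.0
                cells.append(f"{pct:.2f}({c})")
            lines.append(f"{row_label:>12}" + "".join(f"{cell:>16}" for cell in cells))
        return "\n".join(lines)


def confusion_matrix(observed_classes, predicted_classes) -> ConfusionMatrix3:
    """Build counts[predicted][observed] from paired class labels."""
    if len(observed_classes) != len(predicted_classes):
        raise DataError("observed and predicted class lists differ in length")
    counts = np.zeros((3, 3), dtype=int)
    for obs, pred in zip(observed_classes, predicted_classes):
        if isinstance(obs, str):
            obs = BcfClass.from_label(obs)
        if isinstance(pred, str):
            pred = BcfClass.from_label(pred)
        counts[int(pred), int(obs)] += 1
    return ConfusionMatrix3(counts)


def _require_n(matrix: ConfusionMatrix3) -> int:
    if matrix.n == 0:
        raise DataError("empty confusion matrix")
    return matrix.n


def accuracy_pct(matrix: ConfusionMatrix3) -> float:
    """100 x trace / n."""
    n = _require_n(matrix)
    return 100.0 * float(np.trace(matrix.counts)) / n


def fn_pct(matrix: ConfusionMatrix3) -> float:
    """False negatives: observed B or vB but predicted nB — the compound
    is declared safe while it bioaccumulates, the error regulators most
    want to avoid.  Returned as 100 x count / n."""
    n = _require_n(matrix)
    fn = int(matrix.counts[0, 1] + matrix.counts[0, 2])
    return 100.0 * fn / n


def fp_pct(matrix: ConfusionMatrix3) -> float:
    """False positives: observed nB but predicted B or vB (over-
    conservative calls).  Returned as 100 x count / n."""
    n = _require_n(matrix)
    fp = int(matrix.counts[1, 0] + matrix.counts[2, 0])
    return 100.0 * fp / n


def experimental_variability(dataset: Dataset) -> float:
    """Mean, over compounds with >= 2 experimental values, of the range
    (max − min) of their logBCF measurements.

    Quantifies the irreducible experimental noise a model is judged
    against; singletons carry no range information and are excluded.
    """
    ranges = [
        max(r.exp_logbcf) - min(r.exp_logbcf)
        for r in dataset
        if len(r.exp_logbcf) >= 2
    ]
    if not ranges:
        raise DataError(
            "no compound has two or more experimental values; variability undefined"
        )
    return float(np.mean(ranges))


@dataclass
class ValidationReport:
    """Everything reported per evaluation split."""

    n: int
    r2: float
    q2: float
    sdep: float
    matrix: ConfusionMatrix3
    accuracy_pct: float
    fn_pct: float
    fp_pct: float
    excluded: int = 0
    split_label: str = "unlabelled"

    def to_dict(self) -> dict:
        return {
            "split": self.split_label,
            "n": self.n,
            "excluded": self.excluded,
            "r2": self.r2,
            "q2": self.q2,
            "sdep": self.sdep,
            "accuracy_pct": self.accuracy_pct,
            "fn_pct": self.fn_pct,
            "fp_pct": self.fp_pct,
            "confusion_counts": self.matrix.counts.tolist(),
        }


def evaluate_split(
    dataset: Dataset,
    predictions: dict[str, float] | None = None,
    scheme: ClassificationScheme = REACH,
    offset: bool = True,
    training_mean: float | None = None,
    domain_reports: dict[str, object] | None = None,
) -> ValidationReport:
    """Full evaluation of one split against experimental values.

    ``predictions`` maps record id -> raw predicted logBCF; when omitted
    each record's own ``predicted_logbcf`` is used.  Records whose
    domain report (if given) says ``out_of_domain`` are excluded and
    counted.  ``training_mean`` defaults to the mean observed value of
    this split (adequate for a training split; pass the training mean
    explicitly when evaluating an external set).
    """
    observed, raw_pred = [], []
    excluded = 0
    for rec in dataset:
        if domain_reports is not None:
            rep = domain_reports.get(rec.id)
            if rep is not None and getattr(rep, "verdict", rep) == "out_of_domain":
                excluded += 1
                continue
        if predictions is not None:
            if rec.id not in predictions:
                raise DataError(f"no prediction for in-domain record {rec.id}")
            p = predictions[rec.id]
        else:
            if rec.predicted_logbcf is None:
                raise DataError(f"record {rec.id} has no predicted logBCF")
            p = rec.predicted_logbcf
        observed.append(mean_exp_logbcf(rec))
        raw_pred.append(p)

    if not observed:
        raise DataError("no in-domain records to evaluate")
    o = np.asarray(observed)
    p = np.asarray(raw_pred)
    if training_mean is None:
        training_mean = float(o.mean())

    obs_classes = [classify(v, scheme) for v in o]
    if offset:
        pred_classes = [classify_with_offset(v, scheme)[1] for v in p]
    else:
        pred_classes = [classify(v, scheme) for v in p]
    matrix = confusion_matrix(obs_classes, pred_classes)

    return ValidationReport(
        n=len(o),
        r2=r_squared(o, p),
        q2=q_squared_ext(o, p, training_mean),
        sdep=sdep(o, p),
        matrix=matrix,
        accuracy_pct=accuracy_pct(matrix),
        fn_pct=fn_pct(matrix),
        fp_pct=fp_pct(matrix),
        excluded=excluded,
        split_label=dataset.split_label,
    )


def accuracy_comparison_report(
    reports: dict[str, dict[str, ValidationReport]]
) -> str:
    """Text comparison of classification accuracy across models and
    splits (the bar-chart comparison rendered as an aligned table).

    ``reports[model_name][split_name]`` is a :class:`ValidationReport`.
    """
    models = list(reports)
    splits: list[str] = []
    for per_split in reports.values():
        for s in per_split:
            if s not in splits:
                splits.append(s)
    lines = [f"{'split':<22}" + "".join(f"{m:>18}" for m in models)]
    for s in splits:
        cells = []
        for m in models:
            rep = reports[m].get(s)
            cells.append(f"{rep.accuracy_pct:.1f}%" if rep else "-")
        lines.append(f"{s:<22}" + "".join(f"{c:>18}" for c in cells))
    return "\n".join(lines)
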