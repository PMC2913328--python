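"""Regulatory three-class BCF classification with a conservative offset.

REACH labels a substance bioaccumulative (B) when its fish BCF exceeds
2000 L/kg (log10 ≈ 3.3) and very bioaccumulative (vB) above log10 3.7;
CLP uses a single 500 L/kg threshold.  Because both experimental and
predicted logBCF carry roughly half a log unit of uncertainty, a
conservative offset raises predictions that land just below a threshold
up past it before classifying: raw values in [2.8, 3.3] become 3.31 and
values in (3.3, 3.7] become 3.71.  The offset only ever upgrades the
class — the regulatorily safe direction.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


class BcfClass(enum.IntEnum):
    """Ordered regulatory bioaccumulation classes: nB < B < vB."""

    nB = 0
    B = 1
    vB = 2

    def __str__(self) -> str:  # "nB"/"B"/"vB" labels in reports and CSVs
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "BcfClass":
        try:
            return cls[label]
        except KeyError:
            raise ValueError(
                f"unknown BCF class {label!r}; expected one of nB, B, vB"
            ) from None


# How far above a threshold an offset lands a borderline prediction.
# 3.3 -> 3.31 and 3.7 -> 3.71 under the REACH scheme.
OFFSET_EPSILON = 0.01


@dataclass(frozen=True)
class ClassificationScheme:
    """Thresholds (log10 BCF) and offset band for one regulation.

    ``vb_threshold`` may be None for two-class regulations (CLP): then
    only nB/B are assigned and the offset has a single band below the B
    threshold.
    """

    name: str
    b_threshold: float = 3.3
    vb_threshold: float | None = 3.7
    offset_band_low: float = 2.8
    offset_active: bool = True

    def __post_init__(self):
        if not self.offset_band_low < self.b_threshold:
            raise ValueError("offset_band_low must be below b_threshold")
        if self.vb_threshold is not None and not self.b_threshold < self.vb_threshold:
            raise ValueError("b_threshold must be below vb_threshold")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "ClassificationScheme":
        return cls(**json.loads(payload))


def bcf_to_log(bcf_linear: float) -> float:
    """log10 of a linear BCF (L/kg), so linear regulatory thresholds
    (2000 for REACH B, 500 for CLP) can parameterise schemes."""
    if not bcf_linear > 0:
        raise ValueError(f"BCF must be positive, got {bcf_linear!r}")
    return math.log10(bcf_linear)


REACH = ClassificationScheme(name="reach")
CLP = ClassificationScheme(
    name="clp",
    b_threshold=bcf_to_log(500.0),
    vb_threshold=None,
    offset_band_low=bcf_to_log(500.0) - 0.5,
)

SCHEMES = {"reach": REACH, "clp": CLP}


def apply_offset(raw_logbcf: float, scheme: ClassificationScheme = REACH) -> float:
    """Conservative adjustment of a raw logBCF prediction near thresholds.

    Values in [offset_band_low, b_threshold] map to just above the B
    threshold; values in (b_threshold, vb_threshold] map to just above
    the vB threshold.  Everything else is unchanged.  The result is
    always >= the input, and the map is idempotent.
    """
    if not math.isfinite(raw_logbcf):
        raise ValueError(f"raw logBCF must be finite, got {raw_logbcf!r}")
    if not scheme.offset_active:
        return raw_logbcf
    b_target = round(scheme.b_threshold + OFFSET_EPSILON, 12)
    if scheme.offset_band_low <= raw_logbcf <= scheme.b_threshold:
        return b_target
    # The upper band starts just above the B threshold but excludes the
    # B offset target itself (3.31 stays 3.31 and classifies B): the map
    # is idempotent, already-offset values are fixed points.
    if scheme.vb_threshold is not None and (
        scheme.b_threshold < raw_logbcf <= scheme.vb_threshold
        and raw_logbcf != b_target
    ):
        return round(scheme.vb_threshold + OFFSET_EPSILON, 12)
    return raw_logbcf


def classify(logbcf: float, scheme: ClassificationScheme = REACH) -> BcfClass:
    """Map a logBCF value to nB/B/vB; thresholds are strict-above
    ("greater than 2000"), so a value exactly at a threshold takes the
    lower class."""
    if not math.isfinite(logbcf):
        raise ValueError(f"logBCF must be finite, got {logbcf!r}")
    if scheme.vb_threshold is not None and logbcf > scheme.vb_threshold:
        return BcfClass.vB
    if logbcf > scheme.b_threshold:
        return BcfClass.B
    return BcfClass.nB


def classify_with_offset(
    raw_logbcf: float, scheme: ClassificationScheme = REACH
) -> tuple[float, BcfClass, bool]:
    """Offset then classify; returns (adjusted, class, offset_applied)."""
    adjusted = apply_offset(raw_logbcf, scheme)
    return adjusted, classify(adjusted, scheme), adjusted != raw_logbcf


class LogPScreen(enum.Enum):
    screened_nB = "screened_nB"
    potential_B = "potential_B"


def logp_screen(logp: float, cutoff: float = 4.5) -> LogPScreen:
    """ECHA screening rule: logP strictly below 4.5 screens a substance
    as non-bioaccumulative; at or above the cutoff it stays a potential
    B/vB candidate needing a real BCF assessment."""
    if not math.isfinite(logp):
        raise ValueError(f"logp must be finite, got {logp!r}")
    return LogPScreen.screened_nB if logp < cutoff else LogPScreen.potential_B


@dataclass
class PredictionResult:
    """One compound's classification outcome, ready for reporting."""

    raw_logbcf: float
    adjusted_logbcf: float
    bcf_class: BcfClass
    offset_applied: bool
    domain_verdict: str = "not_assessed"
    warnings: list[str] = field(default_factory=list)

    @property
    def reliable(self) -> bool:
        return self.domain_verdict in ("in_domain", "not_assessed")


def make_result(
    raw_logbcf: float,
    scheme: ClassificationScheme = REACH,
    domain_verdict: str = "not_assessed",
    warnings: list[str] | None = None,
) -> PredictionResult:
    adjusted, cls, applied = classify_with_offset(raw_logbcf, scheme)
    return PredictionResult(
        raw_logbcf=raw_logbcf,
        adjusted_logbcf=adjusted,
        bcf_class=cls,
        offset_applied=applied,
        domain_verdict=domain_verdict,
        warnings=list(warnings or []),
    )


class ThresholdBcfClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn classifier mapping continuous logBCF to nB/B/vB.

    Stateless by design — the thresholds come from the regulation, not
    from data — so :meth:`fit` only records the class labels.  ``X`` is
    a column of raw predicted logBCF values.

    Parameters
    ----------
    scheme : str or ClassificationScheme, default="reach"
    offset : bool, default=True
        Apply the conservative near-threshold offset before classifying.
    """

    def __init__(self, scheme="reach", offset: bool = True):
        self.scheme = scheme
        self.offset = offset

    def _resolved_scheme(self) -> ClassificationScheme:
        s = SCHEMES[self.scheme] if isinstance(self.scheme, str) else self.scheme
        if s.offset_active != self.offset:
            s = ClassificationScheme(
                name=s.name,
                b_threshold=s.b_threshold,
                vb_threshold=s.vb_threshold,
                offset_band_low=s.offset_band_low,
                offset_active=self.offset,
            )
        return s

    def fit(self, X=None, y=None):
        scheme = self._resolved_scheme()
        self.scheme_ = scheme
        labels = ["nB", "B"] + ([] if scheme.vb_threshold is None else ["vB"])
        self.classes_ = np.asarray(labels, dtype=object)
        return self

    def predict(self, X):
        if not hasattr(self, "scheme_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return np.asarray(
            [str(classify_with_offset(v, self.scheme_)[1]) for v in X], dtype=object
        )

    def transform(self, X):
        """Offset-adjusted logBCF values (no classification)."""
        if not hasattr(self, "scheme_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return np.asarray([apply_offset(v, self.scheme_) for v in X])
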