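"""Rule-based assignment of neurons to the nine electrophysiological groups.

The decision tree splits first on the falling-phase dV/dt shape class — the
only feature that cleanly separates the broad-AP S-family (double dV/dt
peaks), the deflection M1/M2 pair, and the narrow linear-repolarization
groups — then on mechanical responsiveness, train firing, AP width at base
(dB) and AHP kinetics:

1. double_peak  -> S3 if MA-responsive, else S2 if it fires trains, else S1
2. deflection   -> M2 if MA-responsive, else M1
3. linear, dB > 4 ms                    -> S4 (must be MA-negative, no train)
4. linear, dB <= 4 ms, MA-responsive   -> M3 if the AHP is negligible
   (AHP80 < 5 ms and |AHP peak| < 5 mV), else M4 if AHP80 > 20 ms, else M5
5. anything else -> UNCLASSIFIED (an explicit output, never an error)

All cutoffs are estimator parameters with the defaults above.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .ap import APFeatures
from .ma import MAFeatures
from .waveforms import DEFLECTION, DOUBLE_PEAK, LINEAR

GROUP_LABELS = ("S1", "S2", "S3", "S4", "M1", "M2", "M3", "M4", "M5")
UNCLASSIFIED = "UNCLASSIFIED"

_REQUIRED = ("shape_class", "dB_ms", "AHP80_ms", "AHPpeak_mV", "fires_train",
             "MA_responsive")


class GroupRuleClassifier(BaseEstimator, ClassifierMixin):
    """Deterministic rule classifier over extracted feature tables.

    Stateless: ``fit`` only records the label set.  ``predict`` accepts a
    DataFrame carrying the merged AP + MA feature columns.
    """

    def __init__(
        self,
        db_cut_ms: float = 4.0,
        ahp80_slow_ms: float = 20.0,
        ahp80_fast_ms: float = 5.0,
        ahp_small_mv: float = 5.0,
    ):
        self.db_cut_ms = db_cut_ms
        self.ahp80_slow_ms = ahp80_slow_ms
        self.ahp80_fast_ms = ahp80_fast_ms
        self.ahp_small_mv = ahp_small_mv

    def fit(self, X=None, y=None):
        self.classes_ = np.array(GROUP_LABELS + (UNCLASSIFIED,))
        return self

    # -- single neuron ------------------------------------------------------

    def classify_one(
        self,
        shape_class: Optional[str],
        db_ms: Optional[float],
        ahp80_ms: float,
        ahp_peak_mv: float,
        fires_train: bool,
        ma_responsive: bool,
    ) -> str:
        for name, value in (("shape_class", shape_class), ("db_ms", db_ms)):
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError(f"classification requires feature {name!r}")
        if shape_class == DOUBLE_PEAK:
            if ma_responsive:
                return "S3"
            return "S2" if fires_train else "S1"
        if shape_class == DEFLECTION:
            return "M2" if ma_responsive else "M1"
        if shape_class == LINEAR:
            if db_ms > self.db_cut_ms:
                if not ma_responsive and not fires_train:
                    return "S4"
                return UNCLASSIFIED
            if ma_responsive:
                if (
                    ahp80_ms < self.ahp80_fast_ms
                    and abs(ahp_peak_mv) < self.ahp_small_mv
                ):
                    return "M3"
                if ahp80_ms > self.ahp80_slow_ms:
                    return "M4"
                return "M5"
        return UNCLASSIFIED

    # -- table --------------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in _REQUIRED if c not in X.columns]
        if missing:
            raise ValueError(f"feature table lacks columns: {missing}")
        labels = [
            self.classify_one(
                row.shape_class,
                row.dB_ms,
                row.AHP80_ms,
                row.AHPpeak_mV,
                bool(row.fires_train),
                bool(row.MA_responsive),
            )
            for row in X.itertuples()
        ]
        return np.asarray(labels, dtype=object)


def classify_neuron(ap: APFeatures, ma: MAFeatures, **cutoffs) -> str:
    """Label one neuron from its AP and MA feature records."""
    clf = GroupRuleClassifier(**cutoffs)
    return clf.classify_one(
        ap.shape_class,
        ap.db_ms,
        ap.ahp80_ms,
        ap.ahp_peak,
        ap.fires_train,
        ma.responsive,
    )


def classify_cohort(
    features: pd.DataFrame,
    truth: Optional[pd.Series] = None,
    **cutoffs,
) -> tuple[pd.DataFrame, Optional[dict]]:
    """Label a feature table; score against truth labels when provided.

    Returns the table with a ``label`` column appended and, if truth labels
    are given, a summary dict with the concordance fraction, a confusion
    matrix (truth rows x assigned columns) and the responder count.  The
    responder tally is reported because the source data's text and table
    disagree on it (72 vs 82 of 185); the table logic is what this
    implements.
    """
    out = features.copy()
    if len(out) == 0:
        out["label"] = pd.Series(dtype=object)
        return out, None
    clf = GroupRuleClassifier(**cutoffs).fit()
    out["label"] = clf.predict(out)
    summary = None
    if truth is not None:
        t = truth.reindex(out["neuron_id"]).to_numpy()
        agree = (out["label"].to_numpy() == t).mean()
        confusion = pd.crosstab(
            pd.Series(t, name="truth"), pd.Series(out["label"].to_numpy(), name="assigned")
        )
        summary = dict(
            concordance=float(agree),
            confusion=confusion,
            n=int(len(out)),
            n_responders=int(out["MA_responsive"].sum()),
        )
    return out, summary


def export_rules(clf: Optional[GroupRuleClassifier] = None) -> dict:
    """The rule set as a JSON-serializable document for audit."""
    clf = clf or GroupRuleClassifier()
    return {
        "order": [
            "double_peak -> S3 (MA+) | S2 (train) | S1",
            "deflection -> M2 (MA+) | M1",
            f"linear & dB > {clf.db_cut_ms} ms -> S4 (MA-, no train) else UNCLASSIFIED",
            f"linear & dB <= {clf.db_cut_ms} ms & MA+ -> "
            f"M3 (AHP80 < {clf.ahp80_fast_ms} ms and |AHP| < {clf.ahp_small_mv} mV) | "
            f"M4 (AHP80 > {clf.ahp80_slow_ms} ms) | M5",
            "else -> UNCLASSIFIED",
        ],
        "cutoffs": clf.get_params(),
        "labels": list(GROUP_LABELS) + [UNCLASSIFIED],
    }
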