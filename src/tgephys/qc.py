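"""Recording-quality filters applied before any analysis.

A recording is discarded when the measured resting potential is more
depolarized than -35 mV, when access resistance drifted by more than 20%
during the recording, when leak current exceeds 100 pA, or when input
resistance falls below 100 MOhm.  "RMP less than -35 mV" is read as *less
hyperpolarized* (the standard electrophysiological convention: depolarized
cells are unhealthy); the literal numeric reading would discard every
healthy neuron.  All boundary comparisons are strict: a recording exactly
at a threshold passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .sweeps import RecordingMeta

RMP_DEPOLARIZED = "RMP_DEPOLARIZED"
RS_DRIFT = "RS_DRIFT"
LEAK = "LEAK"
LOW_INPUT_RESISTANCE = "LOW_INPUT_RESISTANCE"


@dataclass
class QCResult:
    passed: bool
    reasons: list

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


def apply_qc(
    meta: RecordingMeta,
    measured_rmp: float,
    rmp_cut_mv: float = -35.0,
    rs_drift_frac: float = 0.20,
    leak_max_pa: float = 100.0,
    rin_min_mohm: float = 100.0,
) -> QCResult:
    """Evaluate all four discard rules; reasons accumulate."""
    missing = [
        name
        for name in (
            "rs_start_mohm",
            "rs_end_mohm",
            "leak_pa",
            "input_resistance_mohm",
        )
        if getattr(meta, name) is None
    ]
    if measured_rmp is None:
        missing.append("measured_rmp")
    if missing:
        raise ValueError(f"QC requires fields: {', '.join(missing)}")
    reasons = []
    if measured_rmp > rmp_cut_mv:
        reasons.append(RMP_DEPOLARIZED)
    if abs(meta.rs_end_mohm - meta.rs_start_mohm) / meta.rs_start_mohm > rs_drift_frac:
        reasons.append(RS_DRIFT)
    if meta.leak_pa > leak_max_pa:
        reasons.append(LEAK)
    if meta.input_resistance_mohm < rin_min_mohm:
        reasons.append(LOW_INPUT_RESISTANCE)
    return QCResult(passed=not reasons, reasons=reasons)


class QCFilter(BaseEstimator):
    """Estimator applying the four discard rules to a cohort.

    ``transform`` keeps passing records; ``report`` tabulates per-neuron
    outcomes with reasons.
    """

    def __init__(
        self,
        rmp_cut_mv: float = -35.0,
        rs_drift_frac: float = 0.20,
        leak_max_pa: float = 100.0,
        rin_min_mohm: float = 100.0,
    ):
        self.rmp_cut_mv = rmp_cut_mv
        self.rs_drift_frac = rs_drift_frac
        self.leak_max_pa = leak_max_pa
        self.rin_min_mohm = rin_min_mohm

    def fit(self, X=None, y=None):
        return self

    def _qc(self, rec, measured_rmp=None):
        rmp = measured_rmp if measured_rmp is not None else rec.meta.rmp_reported_mv
        return apply_qc(
            rec.meta,
            rmp,
            self.rmp_cut_mv,
            self.rs_drift_frac,
            self.leak_max_pa,
            self.rin_min_mohm,
        )

    def report(self, X, measured_rmp: dict | None = None) -> pd.DataFrame:
        records = getattr(X, "records", X)
        measured_rmp = measured_rmp or {}
        rows = []
        for rec in records:
            res = self._qc(rec, measured_rmp.get(rec.neuron_id))
            rows.append(
                dict(
                    neuron_id=rec.neuron_id,
                    passed=res.passed,
                    reasons=";".join(res.reasons),
                )
            )
        return pd.DataFrame(rows)

    def transform(self, X, measured_rmp: dict | None = None) -> list:
        records = getattr(X, "records", X)
        measured_rmp = measured_rmp or {}
        return [
            rec
            for rec in records
            if self._qc(rec, measured_rmp.get(rec.neuron_id)).passed
        ]
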