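"""End-to-end composition of the analysis stages.

Convenience functions tying generation, QC, feature extraction,
classification and summary statistics together; the command-line interface
is a thin shell over these.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .ap import APFeatureExtractor
from .classify import classify_cohort
from .ma import MAFeatureExtractor
from .qc import QCFilter
from .stats import anova_posthoc, group_summary
from .synth import CohortBundle

AP_REPORT_COLUMNS = [
    "neuron_id", "Cap_pF", "RMP_mV", "dB_ms", "shape_class",
    "dVdt_mV_per_ms", "AHP80_ms", "AHPpeak_mV", "APThresh_pA",
    "fires_train", "APTrain_Hz",
]
MA_REPORT_COLUMNS = [
    "MA_responsive", "MA_threshold_um", "MA_max_current_pA",
    "MA_current_density_pA_per_pF", "MA_tau_ms",
]


def extract_features(
    cohort,
    ap_extractor: Optional[APFeatureExtractor] = None,
    ma_extractor: Optional[MAFeatureExtractor] = None,
) -> pd.DataFrame:
    """Merged per-neuron AP + MA feature table."""
    ap_extractor = ap_extractor or APFeatureExtractor()
    ma_extractor = ma_extractor or MAFeatureExtractor()
    ap = ap_extractor.transform(cohort)
    ma = ma_extractor.transform(cohort)
    return ap.merge(ma, on="neuron_id", validate="one_to_one")


def run_cohort(
    cohort: CohortBundle,
    qc: Optional[QCFilter] = None,
    posthoc: str = "tukey",
    **classifier_cutoffs,
) -> dict:
    """QC, extract, classify and summarize one cohort.

    Returns a dict with the QC report, the labeled feature table, the
    truth-concordance summary, per-group parameter summaries, and ANOVA
    results for the headline parameters.
    """
    qc = qc or QCFilter()
    qc_report = qc.report(cohort)
    kept = qc.transform(cohort)
    features = extract_features(kept)
    truth = cohort.truth_labels if cohort.truth_table is not None else None
    labeled, concordance = classify_cohort(features, truth, **classifier_cutoffs)
    summaries = group_summary(
        labeled,
        labeled["label"],
        columns=[
            "Cap_pF", "RMP_mV", "dB_ms", "dVdt_mV_per_ms", "AHP80_ms",
            "AHPpeak_mV", "APThresh_pA", "APTrain_Hz", "MA_threshold_um",
            "MA_max_current_pA", "MA_current_density_pA_per_pF", "MA_tau_ms",
        ],
    )
    anovas = {}
    for col in ("dB_ms", "MA_max_current_pA", "MA_threshold_um", "MA_tau_ms"):
        sub = labeled[["label", col]].dropna()
        counts = sub.groupby("label").size()
        ok = counts[counts >= 2]
        if len(ok) >= 2:
            keep = sub["label"].isin(ok.index)
            anovas[col] = anova_posthoc(
                sub.loc[keep, col], sub.loc[keep, "label"], method=posthoc
            )
    return dict(
        qc=qc_report,
        features=labeled,
        concordance=concordance,
        summaries=summaries,
        anovas=anovas,
    )
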