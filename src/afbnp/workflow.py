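"""End-to-end glue: annotations -> cleaned windows -> features -> tensors.

This is the stage pipeline the evaluation harness and the CLI drive:
noise-peak removal, RR computation, plausibility filtering, the usability
gate, fixed-grid windowing, HRV feature extraction and the long-term
summaries, bundled per patient for fold-scoped standardization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SyntheticPatient, generate_cohort
from .errors import DataQualityError
from .features import ClinicalRecord, FeatureStandardizer, OutcomePair
from .hrv import (
    HRV_SEQUENCE_FEATURES,
    HRVWindowFeatures,
    LongTermSummary,
    SpectralConfig,
    long_term_summary,
    window_features,
)
from .preprocessing import (
    DEFAULT_RR_BOUNDS_MS,
    QualityReport,
    RPeakAnnotation,
    compute_rr,
    filter_implausible_rr,
    quality_gate,
    remove_noise_peaks,
    segment_windows,
)

__all__ = ["PatientData", "extract_patient_data", "extract_cohort", "window_table"]


@dataclass(frozen=True)
class PatientData:
    """One patient's raw (pre-standardization) pipeline products."""

    clinical: ClinicalRecord
    windows: list[HRVWindowFeatures]
    summary: LongTermSummary
    outcome: OutcomePair
    quality: QualityReport

    @property
    def patient_id(self) -> str:
        return self.clinical.patient_id

    def fingerprint(self) -> str:
        """Stable content hash of everything the model could see for this
        patient (features + outcome); used for fold-hygiene proofs."""
        h = hashlib.sha256()
        for w in self.windows:
            h.update(np.asarray(
                [w.window_index, *[w.as_dict()[k] for k in HRV_SEQUENCE_FEATURES]],
                dtype=np.float64,
            ).tobytes())
        h.update(np.asarray(
            [self.summary.minRR, self.summary.maxRR, self.summary.avgRR,
             self.summary.meanRMSSD], dtype=np.float64).tobytes())
        h.update(str(sorted(self.clinical.as_dict().items())).encode())
        h.update(np.asarray(
            [self.outcome.baseline_ntprobnp, self.outcome.followup_ntprobnp],
            dtype=np.float64).tobytes())
        return h.hexdigest()


def extract_patient_data(
    annotation: RPeakAnnotation,
    clinical: ClinicalRecord,
    outcome: OutcomePair,
    window_min: float = 30.0,
    rr_bounds_ms: tuple[float, float] = DEFAULT_RR_BOUNDS_MS,
    spectral: SpectralConfig = SpectralConfig(),
    max_noise_fraction: float = 0.20,
    min_analyzable_hours: float = 48.0,
    enforce_quality: bool = True,
) -> PatientData:
    """Run the preprocessing + feature chain for one recording.

    Raises :class:`DataQualityError` when the recording fails the
    usability gate (unless ``enforce_quality`` is off, for scaled-down
    synthetic studies whose recordings are deliberately short).
    """
    quality = quality_gate(annotation, max_noise_fraction, min_analyzable_hours)
    if enforce_quality and not quality.usable:
        raise DataQualityError(
            f"{annotation.recording_id}: failed gates {quality.reasons}"
        )
    cleaned = remove_noise_peaks(annotation)
    rr = compute_rr(cleaned)
    rr = filter_implausible_rr(rr, *rr_bounds_ms)
    windows = segment_windows(rr, window_min, span_ms=annotation.recording_span_ms)
    feats = [window_features(w, spectral) for w in windows]
    summary = long_term_summary(rr, feats)
    return PatientData(
        clinical=clinical,
        windows=feats,
        summary=summary,
        outcome=outcome,
        quality=quality,
    )


def extract_cohort(
    patients: list[SyntheticPatient] | None = None,
    config: CohortConfig | None = None,
    **extract_kwargs,
) -> list[PatientData]:
    """Feature-extract a synthetic cohort (generating it if needed)."""
    if patients is None:
        if config is None:
            raise ValueError("either patients or config is required")
        patients = generate_cohort(config)
    return [
        extract_patient_data(p.annotation, p.clinical, p.outcome, **extract_kwargs)
        for p in patients
    ]


def window_table(data: PatientData) -> pd.DataFrame:
    """Per-window feature table (raw values, -1 sentinels preserved)."""
    rows = []
    for w in data.windows:
        rows.append({"window_index": w.window_index, "start_ms": w.start_ms,
                     "valid": w.valid, **w.as_dict()})
    return pd.DataFrame(rows)


def fit_fold_standardizer(
    train: list[PatientData], groups=("CM", "RR", "HRV72h", "HRV30min")
) -> FeatureStandardizer:
    """Fit fold-scoped scalers on the training patients only."""
    return FeatureStandardizer(groups=tuple(groups)).fit(train)
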