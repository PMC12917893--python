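"""Feature groups, standardization and per-patient model-input assembly.

Four feature groups feed the predictor:

* ``CM`` — 19 static clinical metrics from the medical record,
* ``RR`` — whole-recording RR summaries (minRR, maxRR, avgRR),
* ``HRV72h`` — whole-recording heart-rate summaries (minHR, maxHR, avgHR),
* ``HRV30min`` — the nine per-window HRV metrics, which form the temporal
  sequence block (plus two declared interaction terms).

All features are Yeo-Johnson transformed (per-feature maximum-likelihood
lambda) and then z-scored, with transform parameters fit on the training
fold only. Static features are replicated across the patient's windows and
concatenated with the sequence block; baseline NT-proBNP and meanRMSSD
form the attention context vector. Invalid windows (sentinel -1) never
enter the transform statistics: they are masked and carry a fill value of
0 after standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, ContractViolationError, InsufficientDataError
from .hrv import HRV_SEQUENCE_FEATURES, SENTINEL, HRVWindowFeatures, LongTermSummary

__all__ = [
    "ClinicalRecord",
    "OutcomePair",
    "ScalerState",
    "PatientTensor",
    "FeatureStandardizer",
    "CM_FEATURES",
    "FEATURE_GROUPS",
    "INTERACTION_FEATURES",
    "DIRECTION_INCREASE",
    "DIRECTION_DECREASE",
    "yeo_johnson",
    "select_groups",
    "interaction_terms",
    "build_patient_tensor",
]

DIRECTION_INCREASE = "increase"
DIRECTION_DECREASE = "decrease_or_stable"

#: Static clinical-metric feature names (group CM).
CM_FEATURES = (
    "age",
    "bmi",
    "hbp",
    "dm",
    "cva",
    "hfpef",
    "aad",
    "noac",
    "antiplatelet",
    "bb",
    "ccb",
    "hb",
    "platelet",
    "creatinine",
    "uric_acid",
    "e_over_eprime",
    "ef_tte",
    "tr_tte",
    "baseline_bnp",
)

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "CM": CM_FEATURES,
    "RR": ("minRR", "maxRR", "avgRR"),
    "HRV72h": ("minHR", "maxHR", "avgHR"),
    "HRV30min": HRV_SEQUENCE_FEATURES,
}

#: Declared per-window interaction terms added to the sequence block:
#: RMSSD scaled by instantaneous heart rate (60000/meanNN), and LF/HF
#: weighted by overall variability (SDNN).
INTERACTION_FEATURES = ("RMSSD_x_HR", "LFHF_x_SDNN")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's static clinical metrics.

    ``male`` and ``arb_acei`` are cohort-description variables (kept for
    calibration and reporting); they are not part of the CM feature group.
    """

    patient_id: str
    age: float
    bmi: float
    hbp: int
    dm: int
    cva: int
    hfpef: int
    aad: int
    noac: int
    antiplatelet: int
    bb: int
    ccb: int
    hb: float
    platelet: float
    creatinine: float
    uric_acid: float
    e_over_eprime: float
    ef_tte: float
    tr_tte: float
    baseline_bnp: float
    male: int = 0
    arb_acei: int = 0

    def __post_init__(self) -> None:
        for name in ("hbp", "dm", "cva", "hfpef", "aad", "noac", "antiplatelet",
                     "bb", "ccb", "male", "arb_acei"):
            if getattr(self, name) not in (0, 1):
                raise ConfigurationError(f"{name} must be a 0/1 flag")
        if self.baseline_bnp <= 0:
            raise ConfigurationError("baseline_bnp must be positive")
        if not 0 < self.ef_tte <= 100:
            raise ConfigurationError("ef_tte must lie in (0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class OutcomePair:
    """Baseline and follow-up NT-proBNP with the derived trend label."""

    baseline_ntprobnp: float
    followup_ntprobnp: float
    followup_months: float

    @property
    def delta(self) -> float:
        return self.followup_ntprobnp - self.baseline_ntprobnp

    @property
    def direction(self) -> str:
        return direction_label(self.delta)


def direction_label(delta: float) -> str:
    """Trend binarization: strictly positive change is an increase; zero
    belongs to decrease_or_stable."""
    return DIRECTION_INCREASE if delta > 0 else DIRECTION_DECREASE


def yeo_johnson(x, lam: float):
    """Yeo-Johnson power transform, defined for all real x.

    Four branches: for x >= 0, ((x+1)^lam - 1)/lam (log1p(x) at lam = 0);
    for x < 0, -(((-x+1)^(2-lam)) - 1)/(2-lam) (-log1p(-x) at lam = 2).
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    if lam != 0.0:
        out[pos] = (np.power(x[pos] + 1.0, lam) - 1.0) / lam
    else:
        out[pos] = np.log1p(x[pos])
    if lam != 2.0:
        out[~pos] = -(np.power(1.0 - x[~pos], 2.0 - lam) - 1.0) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScalerState:
    """Per-feature Yeo-Johnson + z-score parameters fit on one population.

    ``lambdas`` is NaN for passthrough features (all-sentinel columns).
    ``fit_population`` records the training-fold patient ids so fold
    hygiene is assertable downstream.
    """

    feature_names: tuple[str, ...]
    lambdas: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    zero_variance: np.ndarray
    all_sentinel: np.ndarray
    fit_population: tuple[str, ...]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardize rows; sentinel entries become the fill value 0."""
        X = np.asarray(X, dtype=np.float64)
        one_d = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != len(self.feature_names):
            raise ContractViolationError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        out = np.zeros_like(X)
        for j in range(X.shape[1]):
            col = X[:, j]
            ok = col != SENTINEL
            if self.all_sentinel[j]:
                continue  # passthrough: centered fill
            t = yeo_johnson(col[ok], float(self.lambdas[j]))
            out[ok, j] = (t - self.means[j]) / self.sds[j]
        return out[0] if one_d else out


def fit_scaler_state(
    X: np.ndarray,
    feature_names: tuple[str, ...],
    fit_population: tuple[str, ...],
) -> ScalerState:
    """Fit per-feature Yeo-Johnson (ML lambda) + z-score on non-sentinel rows.

    Degenerate columns: all-sentinel -> flagged passthrough; zero variance
    -> lambda 1, centered with unit scale.
    """
    X = np.asarray(X, dtype=np.float64)
    n_feat = X.shape[1]
    if len(feature_names) != n_feat:
        raise ContractViolationError("feature_names length mismatch")
    lambdas = np.full(n_feat, np.nan)
    means = np.zeros(n_feat)
    sds = np.ones(n_feat)
    zero_var = np.zeros(n_feat, dtype=bool)
    all_sent = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        col = X[:, j]
        vals = col[(col != SENTINEL) & np.isfinite(col)]
        if vals.size == 0:
            all_sent[j] = True
            continue
        if np.std(vals) == 0.0:
            zero_var[j] = True
            lambdas[j] = 1.0
            means[j] = float(np.mean(vals))
            continue
        try:
            lam = float(sps.yeojohnson_normmax(vals))
        except Exception:  # optimizer failure on pathological columns
            lam = 1.0
        if not np.isfinite(lam):
            lam = 1.0
        t = yeo_johnson(vals, lam)
        mu, sd = float(np.mean(t)), float(np.std(t))
        if sd == 0.0 or not np.isfinite(sd):
            lam, mu, sd = 1.0, float(np.mean(vals)), 1.0
            zero_var[j] = True
        lambdas[j], means[j], sds[j] = lam, mu, sd
    return ScalerState(
        feature_names=tuple(feature_names),
        lambdas=lambdas,
        means=means,
        sds=sds,
        zero_variance=zero_var,
        all_sentinel=all_sent,
        fit_population=tuple(fit_population),
    )


def select_groups(groups) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Resolve feature-group names to (static_names, sequence_names).

    HRV30min contributes the sequence block (with the declared interaction
    terms); CM, RR and HRV72h contribute static features in that order.
    """
    groups = list(groups)
    if not groups:
        raise ConfigurationError("at least one feature group is required")
    unknown = [g for g in groups if g not in FEATURE_GROUPS]
    if unknown:
        raise ConfigurationError(
            f"unknown feature group(s) {unknown}; valid: {sorted(FEATURE_GROUPS)}"
        )
    static: list[str] = []
    for g in ("CM", "RR", "HRV72h"):
        if g in groups:
            static.extend(FEATURE_GROUPS[g])
    sequence: tuple[str, ...] = ()
    if "HRV30min" in groups:
        sequence = FEATURE_GROUPS["HRV30min"] + INTERACTION_FEATURES
    return tuple(static), sequence


def interaction_terms(w: HRVWindowFeatures) -> dict[str, float]:
    """Per-window interaction features (sentinel-aware products)."""
    if not w.valid or w.meanNN <= 0:
        return {k: SENTINEL for k in INTERACTION_FEATURES}
    lfhf_sdnn = SENTINEL if w.LF_HF == SENTINEL else w.LF_HF * w.SDNN
    return {
        "RMSSD_x_HR": w.RMSSD * (60000.0 / w.meanNN),
        "LFHF_x_SDNN": lfhf_sdnn,
    }


@dataclass(frozen=True)
class PatientTensor:
    """Standardized model input for one patient.

    ``sequence_block`` is (T, F) with the per-window sequence features
    followed by the replicated static block; ``validity_mask`` is False on
    sentinel windows (those rows hold the fill value 0) and on any padding
    appended later by batching. ``context_vector`` is the standardized
    [baseline NT-proBNP, meanRMSSD] pair used by the attention module.
    """

    patient_id: str
    sequence_block: np.ndarray
    validity_mask: np.ndarray
    context_vector: np.ndarray
    sequence_names: tuple[str, ...]
    static_names: tuple[str, ...]
    baseline_ntprobnp: float
    scaler_population: tuple[str, ...]

    @property
    def n_windows(self) -> int:
        return int(self.sequence_block.shape[0])


CONTEXT_FEATURES = ("baseline_bnp", "meanRMSSD")


@dataclass
class FeatureStandardizer:
    """Fold-scoped standardization of sequence, static and context features.

    Fit on the training fold only; ``fit_population`` ids prove the
    held-out patient never contributed to any transform statistic.
    """

    groups: tuple[str, ...] = ("CM", "RR", "HRV72h", "HRV30min")
    sequence_state: ScalerState | None = field(default=None, repr=False)
    static_state: ScalerState | None = field(default=None, repr=False)
    context_state: ScalerState | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.static_names_, self.sequence_names_ = select_groups(self.groups)

    @property
    def is_fitted(self) -> bool:
        return self.context_state is not None

    @property
    def fit_population(self) -> tuple[str, ...]:
        if not self.is_fitted:
            raise ContractViolationError("standardizer is not fitted")
        return self.context_state.fit_population

    def fit(self, patients) -> "FeatureStandardizer":
        """``patients`` is an iterable of PatientData (see workflow module)."""
        patients = list(patients)
        if not patients:
            raise InsufficientDataError("cannot fit scalers on an empty fold")
        ids = tuple(p.clinical.patient_id for p in patients)
        if self.sequence_names_:
            rows = [
                _sequence_row(w, self.sequence_names_)
                for p in patients
                for w in p.windows
                if w.valid
            ]
            if not rows:
                raise InsufficientDataError("no valid windows in training fold")
            self.sequence_state = fit_scaler_state(
                np.asarray(rows), self.sequence_names_, ids
            )
        if self.static_names_:
            stat = np.asarray(
                [_static_row(p, self.static_names_) for p in patients]
            )
            self.static_state = fit_scaler_state(stat, self.static_names_, ids)
        ctx = np.asarray(
            [[p.clinical.baseline_bnp, p.summary.meanRMSSD] for p in patients]
        )
        self.context_state = fit_scaler_state(ctx, CONTEXT_FEATURES, ids)
        return self

    def transform(self, patient) -> PatientTensor:
        if not self.is_fitted:
            raise ContractViolationError("standardizer is not fitted")
        return build_patient_tensor(
            patient.windows,
            patient.summary,
            patient.clinical,
            self,
        )


def _sequence_row(w: HRVWindowFeatures, names: tuple[str, ...]) -> list[float]:
    vals = w.as_dict() | interaction_terms(w)
    return [vals[n] for n in names]


def _static_row(patient, names: tuple[str, ...]) -> list[float]:
    return _static_row_for(patient.clinical, patient.summary, names)


def build_patient_tensor(
    windows: list[HRVWindowFeatures],
    summary: LongTermSummary,
    clinical: ClinicalRecord,
    standardizer: FeatureStandardizer,
) -> PatientTensor:
    """Assemble one patient's standardized (T, F) input.

    Sequence features are standardized per window; static features are
    standardized once and replicated across every row; the mask is False
    on invalid (sentinel) windows, whose rows carry the fill value 0 in
    the sequence columns. A patient with no valid window is rejected.
    """
    if not windows:
        raise InsufficientDataError("patient has no windows")
    mask = np.array([w.valid for w in windows], dtype=bool)
    if not mask.any():
        raise InsufficientDataError(
            f"{clinical.patient_id}: all windows invalid"
        )
    T = len(windows)
    blocks: list[np.ndarray] = []
    if standardizer.sequence_names_:
        raw = np.asarray(
            [_sequence_row(w, standardizer.sequence_names_) for w in windows]
        )
        raw[~mask] = SENTINEL  # invalid windows are all-sentinel rows
        blocks.append(standardizer.sequence_state.transform(raw))
    if standardizer.static_names_:
        srow = standardizer.static_state.transform(
            np.asarray(_static_row_for(clinical, summary, standardizer.static_names_))
        )
        blocks.append(np.tile(srow, (T, 1)))
    if not blocks:
        raise ConfigurationError("no feature groups selected")
    seq = np.hstack(blocks)
    ctx = standardizer.context_state.transform(
        np.asarray([clinical.baseline_bnp, summary.meanRMSSD])
    )
    return PatientTensor(
        patient_id=clinical.patient_id,
        sequence_block=seq,
        validity_mask=mask,
        context_vector=np.asarray(ctx, dtype=np.float64),
        sequence_names=standardizer.sequence_names_,
        static_names=standardizer.static_names_,
        baseline_ntprobnp=float(clinical.baseline_bnp),
        scaler_population=standardizer.fit_population,
    )


def _static_row_for(clinical, summary, names):
    pool = clinical.as_dict() | {
        "minRR": summary.minRR,
        "maxRR": summary.maxRR,
        "avgRR": summary.avgRR,
        "minHR": summary.minHR,
        "maxHR": summary.maxHR,
        "avgHR": summary.avgHR,
    }
    return [pool[n] for n in names]
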