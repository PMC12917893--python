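"""Patient-level leave-one-out evaluation, metrics and reports.

Each LOOCV fold refits the feature scalers *and* the model on the n-1
training patients, predicts the held-out patient's NT-proBNP change and
records a content hash of every training input, so the absence of the
held-out patient from every fold artifact is provable after the fact.
Metrics follow the study: RMSE and MAE on the pg/mL change scale and
directional accuracy of the increase vs decrease/stable trend label
(strictly positive change counts as an increase).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ContractViolationError, InsufficientDataError
from .features import DIRECTION_INCREASE, direction_label
from .model import ContextLSTMRegressor
from .workflow import PatientData, fit_fold_standardizer

__all__ = [
    "FoldResult",
    "CVReport",
    "rmse",
    "mae",
    "directional_accuracy",
    "loocv",
    "trajectory_report",
    "fold_seed",
]


def rmse(pred, true) -> float:
    """Root mean squared error."""
    pred, true = _paired(pred, true)
    return float(np.sqrt(np.mean((pred - true) ** 2)))


def mae(pred, true) -> float:
    """Mean absolute error."""
    pred, true = _paired(pred, true)
    return float(np.mean(np.abs(pred - true)))


def _paired(pred, true):
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape or pred.size == 0:
        raise ContractViolationError("pred/true must be equal-length and non-empty")
    return pred, true


@dataclass(frozen=True)
class FoldResult:
    """One LOOCV fold: held-out prediction plus fold provenance."""

    held_out_patient: str
    predicted_delta: float
    true_delta: float
    baseline_ntprobnp: float
    followup_months: float
    train_epochs: int
    train_fingerprints: tuple[str, ...] = field(default_factory=tuple)
    failed: bool = False

    @property
    def predicted_direction(self) -> str:
        return direction_label(self.predicted_delta)

    @property
    def true_direction(self) -> str:
        return direction_label(self.true_delta)

    @property
    def correct_direction(self) -> bool:
        return self.predicted_direction == self.true_direction


def directional_accuracy(folds: list[FoldResult]) -> float:
    """Fraction of folds whose predicted trend label matches the truth."""
    if not folds:
        raise InsufficientDataError("no folds")
    return float(np.mean([f.correct_direction for f in folds]))


@dataclass
class CVReport:
    """Aggregate LOOCV result."""

    folds: list[FoldResult]
    rmse: float
    mae: float
    directional_accuracy: float
    abs_error_quartiles: tuple[float, float, float]
    seed: int
    incomplete: bool = False
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "rmse": self.rmse,
            "mae": self.mae,
            "directional_accuracy": self.directional_accuracy,
            "abs_error_quartiles": list(self.abs_error_quartiles),
            "incomplete": self.incomplete,
            "config": self.config,
            "folds": [
                asdict(f)
                | {
                    "predicted_direction": f.predicted_direction,
                    "true_direction": f.true_direction,
                }
                for f in self.folds
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "CVReport":
        text = str(text_or_path)
        try:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        except OSError:
            pass
        d = json.loads(text)
        folds = [
            FoldResult(
                held_out_patient=f["held_out_patient"],
                predicted_delta=f["predicted_delta"],
                true_delta=f["true_delta"],
                baseline_ntprobnp=f["baseline_ntprobnp"],
                followup_months=f["followup_months"],
                train_epochs=f["train_epochs"],
                train_fingerprints=tuple(f["train_fingerprints"]),
                failed=f["failed"],
            )
            for f in d["folds"]
        ]
        return cls(
            folds=folds,
            rmse=d["rmse"],
            mae=d["mae"],
            directional_accuracy=d["directional_accuracy"],
            abs_error_quartiles=tuple(d["abs_error_quartiles"]),
            seed=d["seed"],
            incomplete=d["incomplete"],
            config=d["config"],
        )


def fold_seed(global_seed: int, patient_id: str) -> int:
    """Stable per-fold seed; folds are reproducible in any order."""
    return zlib.crc32(f"{global_seed}:{patient_id}".encode()) & 0x7FFFFFFF


def loocv(
    patients: list[PatientData],
    groups=("CM", "RR", "HRV72h", "HRV30min"),
    model_params: dict | None = None,
    seed: int = 0,
    outcome_overrides: dict[str, float] | None = None,
) -> CVReport:
    """Patient-level leave-one-out cross-validation.

    Every fold refits scalers and model on the other n-1 patients; the
    held-out patient contributes nothing to any fold artifact (asserted
    via the scaler fit-population and provable from the recorded content
    hashes). ``outcome_overrides`` maps patient_id -> delta and exists for
    permutation-null experiments.

    A fold whose training raises is marked failed and excluded from the
    aggregate metrics; the report is then flagged incomplete.
    """
    if len(patients) < 3:
        raise InsufficientDataError("LOOCV needs at least 3 patients")
    model_params = dict(model_params or {})
    model_params.pop("random_state", None)  # per-fold seeds are derived below
    deltas = {p.patient_id: p.outcome.delta for p in patients}
    if outcome_overrides:
        deltas.update(outcome_overrides)
    fingerprints = {p.patient_id: p.fingerprint() for p in patients}
    folds: list[FoldResult] = []
    for held in patients:
        train = [p for p in patients if p.patient_id != held.patient_id]
        try:
            std = fit_fold_standardizer(train, groups)
            if held.patient_id in std.fit_population:
                raise ContractViolationError("held-out patient leaked into scalers")
            tensors = [std.transform(p) for p in train]
            y = np.asarray([deltas[p.patient_id] for p in train])
            est = ContextLSTMRegressor(
                **model_params, random_state=fold_seed(seed, held.patient_id)
            )
            est.fit(tensors, y)
            pred = float(est.predict([std.transform(held)])[0])
            folds.append(
                FoldResult(
                    held_out_patient=held.patient_id,
                    predicted_delta=pred,
                    true_delta=float(deltas[held.patient_id]),
                    baseline_ntprobnp=held.outcome.baseline_ntprobnp,
                    followup_months=held.outcome.followup_months,
                    train_epochs=est.n_epochs_trained_,
                    train_fingerprints=tuple(
                        fingerprints[p.patient_id] for p in train
                    ),
                )
            )
        except ContractViolationError:
            raise
        except Exception:
            folds.append(
                FoldResult(
                    held_out_patient=held.patient_id,
                    predicted_delta=float("nan"),
                    true_delta=float(deltas[held.patient_id]),
                    baseline_ntprobnp=held.outcome.baseline_ntprobnp,
                    followup_months=held.outcome.followup_months,
                    train_epochs=0,
                    failed=True,
                )
            )
    ok = [f for f in folds if not f.failed]
    if not ok:
        raise InsufficientDataError("every fold failed")
    pred = [f.predicted_delta for f in ok]
    true = [f.true_delta for f in ok]
    abs_err = np.abs(np.asarray(pred) - np.asarray(true))
    q1, q2, q3 = np.percentile(abs_err, [25, 50, 75])
    return CVReport(
        folds=folds,
        rmse=rmse(pred, true),
        mae=mae(pred, true),
        directional_accuracy=directional_accuracy(ok),
        abs_error_quartiles=(float(q1), float(q2), float(q3)),
        seed=seed,
        incomplete=any(f.failed for f in folds),
        config={"groups": list(groups), "model_params": model_params},
    )


def mean_ci_halfwidth(values, level: float = 0.95) -> float:
    """Normal-approximation CI halfwidth of the mean (1.96 * SEM at 95%)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise InsufficientDataError("CI needs at least 2 values")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return float(z * values.std(ddof=1) / np.sqrt(values.size))


def trajectory_report(report: CVReport, out_dir=None, show_ci: bool = True):
    """Observed vs predicted baseline -> follow-up trajectories.

    Draws per-patient spaghetti lines plus observed and predicted group
    means with 95% CIs, and writes the metrics JSON next to the figure
    when ``out_dir`` is given. Returns (figure, metrics dict).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = [f for f in report.folds if not f.failed]
    base = np.asarray([f.baseline_ntprobnp for f in ok])
    obs = base + np.asarray([f.true_delta for f in ok])
    pred = base + np.asarray([f.predicted_delta for f in ok])
    fig, ax = plt.subplots(figsize=(7, 5))
    for b, o in zip(base, obs):
        ax.plot([0, 1], [b, o], color="0.8", lw=0.8, zorder=1)
    n = base.size
    for values, color, label, style in (
        (obs, "tab:blue", "observed mean", "-"),
        (pred, "tab:red", "predicted mean", "--"),
    ):
        means = np.array([base.mean(), values.mean()])
        hws = np.array([mean_ci_halfwidth(base), mean_ci_halfwidth(values)])
        ax.errorbar(
            [0, 1], means, yerr=hws if show_ci else None,
            color=color, label=label, lw=2, linestyle=style, capsize=4, zorder=3,
        )
    ax.set_xticks([0, 1], ["baseline", "follow-up"])
    ax.set_ylabel("NT-proBNP (pg/mL)")
    ax.set_title("Observed vs predicted NT-proBNP trajectories")
    ax.legend()
    metrics = {
        "rmse": report.rmse,
        "mae": report.mae,
        "directional_accuracy": report.directional_accuracy,
        "abs_error_quartiles": list(report.abs_error_quartiles),
        "n_folds": len(report.folds),
        "n_failed": sum(f.failed for f in report.folds),
        "n_increase_true": sum(
            f.true_direction == DIRECTION_INCREASE for f in ok
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fig.savefig(out / "trajectories.svg")
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        report.to_json(out / "cv_report.json")
    return fig, metrics
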