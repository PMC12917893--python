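"""Synthetic cohort generator: calibration, determinism, planted signal."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from afbnp.cohort import (
    CohortConfig,
    LatentPatientState,
    clinical_frame,
    generate_clinical,
    generate_cohort,
    generate_latents,
    generate_outcome,
    generate_rr_stream,
    write_cohort,
)
from afbnp.errors import ConfigurationError
from afbnp.hrv import time_domain
from afbnp.preprocessing import compute_rr, quality_gate


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 1},
            {"noise_fraction_range": (0.2, 1.0)},
            {"noise_fraction_range": (-0.1, 0.1)},
            {"effect_strength": 1.5},
            {"recording_days_range": (0.1, 2.0)},
            {"recording_days_range": (3.0, 20.0)},
            {"direction_balance": 0.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kwargs).validate()

    def test_defaults_are_study_conditions(self):
        cfg = CohortConfig().validate()
        assert cfg.n_patients == 50
        assert cfg.recording_days_range == (3.0, 7.0)
        assert cfg.followup_months_range == (6.0, 12.0)


@pytest.fixture(scope="module")
def records():
    return generate_clinical(CohortConfig(n_patients=2000, seed=7))


class TestClinicalCalibration:
    def test_continuous_medians(self, records):
        df = pd.DataFrame([r.as_dict() for r in records])
        assert np.median(df.age) == pytest.approx(70.0, abs=2.0)
        assert np.median(df.bmi) == pytest.approx(24.76, abs=0.5)
        assert np.median(df.ef_tte) == pytest.approx(59.8, abs=1.5)
        assert np.median(df.baseline_bnp) == pytest.approx(1344.0, rel=0.15)
        assert np.median(df.creatinine) == pytest.approx(1.0, abs=0.1)
        assert np.median(df.e_over_eprime) == pytest.approx(11.07, abs=1.0)

    def test_binary_prevalences(self, records):
        df = pd.DataFrame([r.as_dict() for r in records])
        expected = {
            "male": 0.56, "hbp": 0.76, "dm": 0.30, "hfpef": 1.00,
            "noac": 0.96, "bb": 0.72, "arb_acei": 0.60, "aad": 0.36,
            "cva": 0.06, "antiplatelet": 0.06, "ccb": 0.04,
        }
        for name, p in expected.items():
            assert df[name].mean() == pytest.approx(p, abs=0.03), name

    def test_seed_determinism(self):
        cfg = CohortConfig(n_patients=20, seed=5)
        a = generate_clinical(cfg)
        b = generate_clinical(cfg)
        assert [r.as_dict() for r in a] == [r.as_dict() for r in b]


class TestRRStream:
    def test_expected_peak_count(self):
        p = LatentPatientState(0.0, 800.0, 60.0, 20.0, 0.0)
        ann = generate_rr_stream(p, duration_hours=1.0, seed=2)
        assert ann.peak_times_ms.size == pytest.approx(4500, rel=0.10)

    def test_strictly_increasing_and_plausible(self):
        p = LatentPatientState(0.5, 700.0, 120.0, 40.0, 50.0)
        ann = generate_rr_stream(p, duration_hours=2.0, seed=3)
        rr = np.diff(ann.peak_times_ms)
        assert np.all(rr > 0)
        assert rr.min() >= 300 - 1 and rr.max() <= 2000 + 1  # integer rounding

    def test_degenerate_dispersion_flat_sdnn(self):
        p = LatentPatientState(0.0, 800.0, 1e-12, 0.0, 0.0)
        ann = generate_rr_stream(p, duration_hours=0.5, seed=4)
        td = time_domain(compute_rr(ann))
        assert td["SDNN"] == pytest.approx(0.0, abs=0.6)  # integer-ms rounding

    def test_heavy_noise_fails_usability_gate(self):
        p = LatentPatientState(0.0, 800.0, 60.0, 20.0, 0.0)
        ann = generate_rr_stream(p, duration_hours=72.0, seed=5, noise_fraction=0.25)
        rep = quality_gate(ann)
        assert not rep.usable and "noise_fraction" in rep.reasons
        assert rep.noise_fraction == pytest.approx(0.25, abs=0.03)

    def test_span_approximates_duration(self):
        p = LatentPatientState(0.0, 750.0, 80.0, 20.0, 30.0)
        ann = generate_rr_stream(p, duration_hours=1.0, seed=6)
        assert ann.peak_times_ms[-1] == pytest.approx(3_600_000, rel=0.01)


class TestOutcome:
    def _patient(self, burden):
        return LatentPatientState(burden, 750.0, 90.0, 25.0, 30.0)

    def test_noiseless_limit_direction_from_burden(self):
        cfg = CohortConfig(effect_strength=1.0, seed=0)
        rec = generate_clinical(CohortConfig(n_patients=2, seed=1))[0]
        for burden in (-1.5, -0.2, 0.3, 2.0):
            o = generate_outcome(self._patient(burden), rec, cfg, seed=9)
            assert (o.delta > 0) == (burden > 0)

    def test_effect_strength_partitions_variance(self):
        # empirical variance decomposition of the log change
        cfg = CohortConfig(effect_strength=0.6, seed=0)
        rec = generate_clinical(CohortConfig(n_patients=2, seed=1))[0]
        rng = np.random.default_rng(0)
        burdens = rng.standard_normal(4000)
        y = np.array([
            np.log(
                generate_outcome(self._patient(b), rec, cfg, seed=s).followup_ntprobnp
                / rec.baseline_bnp
            )
            for s, b in enumerate(burdens)
        ])
        total = y.var()
        signal = (cfg.log_change_sd**2) * cfg.effect_strength
        assert total == pytest.approx(cfg.log_change_sd**2, rel=0.1)
        rho = np.corrcoef(burdens, y)[0, 1]
        assert rho**2 == pytest.approx(cfg.effect_strength, abs=0.05)
        assert signal / total == pytest.approx(0.6, abs=0.06)

    def test_followup_months_within_range(self):
        cfg = CohortConfig(seed=0)
        rec = generate_clinical(CohortConfig(n_patients=2, seed=1))[0]
        months = [
            generate_outcome(self._patient(0.0), rec, cfg, seed=s).followup_months
            for s in range(50)
        ]
        assert all(6.0 <= m <= 12.0 for m in months)


class TestPlantedSignal:
    def _summaries(self, cfg, n):
        latents = generate_latents(cfg)
        recs = generate_clinical(cfg)
        rmssd, logch = [], []
        for i, (lat, rec) in enumerate(zip(latents, recs)):
            ann = generate_rr_stream(lat, duration_hours=1.0, seed=1000 + i)
            rmssd.append(time_domain(compute_rr(ann))["RMSSD"])
            o = generate_outcome(lat, rec, cfg, seed=2000 + i)
            logch.append(np.log(o.followup_ntprobnp / o.baseline_ntprobnp))
        return np.asarray(rmssd), np.asarray(logch)

    def test_null_effect_uncorrelated(self):
        cfg = CohortConfig(n_patients=500, effect_strength=0.0, seed=13)
        rmssd, logch = self._summaries(cfg, 500)
        rho = spearmanr(rmssd, logch).statistic
        assert abs(rho) < 0.1

    def test_signal_monotone_in_effect_strength(self):
        rhos = []
        for effect in (0.0, 0.3, 0.75):
            cfg = CohortConfig(n_patients=300, effect_strength=effect, seed=13)
            rmssd, logch = self._summaries(cfg, 300)
            rhos.append(abs(spearmanr(rmssd, logch).statistic))
        assert rhos[0] < rhos[1] < rhos[2]
        assert rhos[2] > 0.5


class TestCohortAssembly:
    def test_bit_identical_under_fixed_seed(self):
        cfg = CohortConfig(
            n_patients=3, recording_days_range=(0.5, 0.6), seed=21
        )
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.annotation.peak_times_ms, pb.annotation.peak_times_ms)
            assert np.array_equal(pa.annotation.noise_intervals, pb.annotation.noise_intervals)
            assert pa.clinical.as_dict() == pb.clinical.as_dict()
            assert pa.outcome.followup_ntprobnp == pb.outcome.followup_ntprobnp

    def test_write_cohort_round_trip(self, tmp_path):
        cfg = CohortConfig(n_patients=3, recording_days_range=(0.5, 0.6), seed=21)
        patients = generate_cohort(cfg)
        manifest_path = write_cohort(patients, tmp_path, cfg)
        manifest = json.loads(manifest_path.read_text())
        assert manifest["seed"] == 21 and len(manifest["recordings"]) == 3
        df = pd.read_csv(tmp_path / manifest["clinical_csv"])
        assert {"patient_id", "age", "baseline_bnp", "followup_ntprobnp",
                "followup_months"} <= set(df.columns)
        rec = manifest["recordings"][0]
        peaks = pd.read_csv(tmp_path / "recordings" / rec["peaks"])
        assert (peaks.peak_time_ms.diff().dropna() > 0).all()
        noise = json.loads((tmp_path / "recordings" / rec["noise"]).read_text())
        assert "noise_intervals" in noise

    def test_clinical_frame_columns(self):
        cfg = CohortConfig(n_patients=2, seed=3)
        df = clinical_frame(generate_clinical(cfg))
        assert df.columns[0] == "patient_id" and len(df) == 2
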