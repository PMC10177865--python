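"""Diagonal fit, A_R prediction, classification and map export."""

import json

import numpy as np
import pandas as pd
import pytest

from emt_phenotyper.errors import FitError, JoinError, ValidationError
from emt_phenotyper.morphometrics import ShapeSummary
from emt_phenotyper.phenotype import (
    EMTAxisModel,
    PhenotypeRecord,
    PhenotypeThresholds,
    assemble_phenotype_record,
    classify_phenotype,
    export_phenotype_map,
    fit_control_diagonal,
    predict_aspect_ratio,
)

#: C_N/A_R means of the four untreated reference lines
CONTROL_POINTS = [(0.801, 0.654), (0.808, 0.707), (0.877, 0.683), (0.735, 0.240)]


def _two_pass_ols(points):
    """Closed-form OLS oracle, independent of the fitting path."""
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    sx, sy = x - x.mean(), y - y.mean()
    slope = float((sx * sy).sum() / (sx * sx).sum())
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    r2 = float(1.0 - (resid**2).sum() / (sy**2).sum())
    return slope, intercept, r2


class TestDiagonalFit:
    def test_two_points_exact_line(self):
        m = fit_control_diagonal([(0.7, 0.3), (0.9, 0.8)])
        assert m.slope == pytest.approx(2.5)
        assert m.r_squared == pytest.approx(1.0)

    def test_four_reference_means_match_closed_form(self):
        m = fit_control_diagonal(CONTROL_POINTS)
        slope, intercept, r2 = _two_pass_ols(CONTROL_POINTS)
        assert m.slope == pytest.approx(slope, abs=1e-10)
        assert m.intercept == pytest.approx(intercept, abs=1e-10)
        assert m.r_squared == pytest.approx(r2, abs=1e-10)
        # approximate concordance with the published control fit
        assert m.slope == pytest.approx(3.10, abs=0.05)
        assert m.r_squared == pytest.approx(0.66, abs=0.01)

    def test_zero_noise_published_line_recovered_exactly(self):
        xs = np.linspace(0.60, 0.95, 8)
        pts = [(x, 2.935 * x - 1.787) for x in xs]
        m = fit_control_diagonal(pts)
        assert m.slope == pytest.approx(2.935, abs=1e-9)
        assert m.intercept == pytest.approx(-1.787, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_ols_matches_oracle_on_random_sets(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 12))
            x = rng.uniform(0.3, 1.0, n)
            y = rng.uniform(0.0, 1.0, n)
            pts = list(zip(x, y))
            m = fit_control_diagonal(pts)
            slope, intercept, r2 = _two_pass_ols(pts)
            assert m.slope == pytest.approx(slope, rel=1e-10)
            assert m.intercept == pytest.approx(intercept, rel=1e-10)
            assert m.r_squared == pytest.approx(r2, rel=1e-10, abs=1e-12)

    def test_noisy_slope_within_3se(self, rng):
        """200 seeded fits of y = 2.935x - 1.787 + N(0, 0.05)."""
        true_slope = 2.935
        xs = np.linspace(0.6, 0.95, 12)
        hits = 0
        for _ in range(200):
            y = true_slope * xs - 1.787 + rng.normal(0, 0.05, xs.size)
            m = fit_control_diagonal(list(zip(xs, y)))
            resid = y - (m.slope * xs + m.intercept)
            se = np.sqrt(
                (resid**2).sum() / (xs.size - 2) / ((xs - xs.mean()) ** 2).sum()
            )
            hits += abs(m.slope - true_slope) <= 3 * se
        assert hits >= 196  # ~99.7% nominal coverage

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_control_diagonal([(0.8, 0.6)])
        with pytest.raises(FitError):
            fit_control_diagonal([(0.8, 0.6), (0.8, 0.7)])


class TestPrediction:
    MODEL = EMTAxisModel(2.935, -1.787, 0.62, 4)

    @pytest.mark.parametrize(
        "cn,expected,flagged",
        [(0.70, 0.2675, False), (0.877, 0.787, False), (0.5, -0.320, True)],
    )
    def test_linear_prediction(self, cn, expected, flagged):
        value, out_of_range = predict_aspect_ratio(self.MODEL, cn)
        assert value == pytest.approx(expected, abs=1e-3)
        assert out_of_range == flagged

    def test_unfitted_model_rejected(self):
        with pytest.raises(FitError):
            predict_aspect_ratio(EMTAxisModel(0.0, 0.0, 0.0, 0), 0.8)


class TestClassification:
    def _record(self, ar, cn, me, em, flag=None):
        return PhenotypeRecord(
            condition="x", ar_mean=ar, cn_mean=cn, me_ratio=me, em_ratio=em,
            ratio_undefined=flag,
        )

    def test_epithelial_reference(self):
        # HCC1954-like: round shape, vimentin absent
        rec = self._record(0.707, 0.808, me=0.0, em=None, flag="em")
        assert classify_phenotype(rec) == "E"

    def test_mesenchymal_reference(self):
        # MDA-MB-231-like: spindle shape, E-cadherin absent, vimentin high
        rec = self._record(0.240, 0.735, me=None, em=0.0, flag="me")
        assert classify_phenotype(rec) == "M"

    def test_hybrid_reference(self):
        # MDA-MB-468-like: epithelial shape factors but both markers present
        rec = self._record(0.683, 0.877, me=0.5, em=2.0)
        assert classify_phenotype(rec) == "E/M"

    def test_missing_shape_unclassified(self):
        rec = PhenotypeRecord(condition="x", me_ratio=1.0, em_ratio=1.0)
        assert classify_phenotype(rec) == "unclassified"

    def test_classification_is_total(self, rng):
        """Every record with shape+marker inputs maps to exactly one class."""
        classes = set()
        for _ in range(300):
            me = [None, 0.0, float(rng.uniform(0, 30))][int(rng.integers(0, 3))]
            em = (
                0.0 if me is None
                else (None if me == 0 else 1.0 / me if me > 0 else None)
            )
            flag = "me" if me is None else ("em" if em is None else None)
            rec = self._record(
                float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.2, 1.0)), me, em, flag
            )
            cls = classify_phenotype(rec)
            assert cls in ("E", "E/M", "M", "unclassified")
            classes.add(cls)
        assert {"E", "E/M", "M"} <= classes

    def test_thresholds_validated(self):
        with pytest.raises(ValidationError):
            classify_phenotype(
                self._record(0.5, 0.5, 1.0, 1.0),
                PhenotypeThresholds(cn_epithelial_band=(0.9, 0.8)),
            )


class TestAssembly:
    SUMMARY = ShapeSummary("tgf", 30, 0.80, 0.05, 0.65, 0.1)
    MARKER = {"condition": "tgf", "me_ratio": 0.4, "em_ratio": 2.5, "ratio_undefined": ""}

    def test_full_record(self):
        wound = pd.DataFrame(
            [{"t_closure_h": 50.0, "censored": False,
              "nu_a_pct_per_h": 2.0, "estimator_flag": "closure_time"}]
        )
        rec = assemble_phenotype_record(self.SUMMARY, self.MARKER, wound)
        assert rec.nu_a == 2.0 and not rec.no_velocity
        assert rec.phenotype_class in ("E", "E/M", "M")

    def test_missing_migration_flagged(self):
        rec = assemble_phenotype_record(self.SUMMARY, self.MARKER, None)
        assert rec.no_velocity and rec.nu_a is None

    def test_key_mismatch_raises_join_error(self):
        with pytest.raises(JoinError) as err:
            assemble_phenotype_record(self.SUMMARY, {"condition": "egf"}, None)
        assert "tgf" in str(err.value) and "egf" in str(err.value)


class TestExport:
    def _records(self):
        recs = []
        for i, (cn, ar) in enumerate(CONTROL_POINTS):
            recs.append(
                PhenotypeRecord(
                    condition=f"c{i}", cn_mean=cn, ar_mean=ar,
                    me_ratio=1.0 + i, em_ratio=1.0 / (1.0 + i),
                    nu_a=None if i == 3 else 1.0 + i,
                    no_velocity=i == 3,
                )
            )
        return recs

    def test_csv_and_plots_written(self, tmp_path):
        model = fit_control_diagonal(CONTROL_POINTS)
        frame = export_phenotype_map(
            self._records(), model,
            tmp_path / "records.csv", tmp_path / "map.png", tmp_path / "map.svg",
        )
        assert len(frame) == 4
        assert {"model_slope", "model_intercept", "model_r_squared"} <= set(frame.columns)
        assert (tmp_path / "map.png").stat().st_size > 0
        assert (tmp_path / "map.svg").stat().st_size > 0

    def test_rerun_is_byte_identical(self, tmp_path):
        model = fit_control_diagonal(CONTROL_POINTS)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        export_phenotype_map(self._records(), model, p1)
        export_phenotype_map(self._records(), model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            export_phenotype_map([], None, tmp_path / "x.csv")

    def test_model_sidecar_json(self, tmp_path):
        model = fit_control_diagonal(CONTROL_POINTS)
        model.to_json(tmp_path / "model.json")
        payload = json.loads((tmp_path / "model.json").read_text())
        assert set(payload) == {"slope", "intercept", "r_squared", "n_points"}


class TestMETTrajectory:
    def test_predicted_ar_monotone_along_diagonal(self):
        """A 0/48/72 h MET induction (rising C_N and E/M, falling nu_a)
        maps to non-decreasing predicted A_R and a rightward map shift."""
        model = fit_control_diagonal(CONTROL_POINTS)
        cn_series = [0.692, 0.741, 0.758]  # increasing nuclear circularity
        em_series = [0.1, 0.8, 2.0]
        nu_series = [3.0, 2.0, 1.2]
        assert all(a < b for a, b in zip(cn_series, cn_series[1:]))
        assert all(a < b for a, b in zip(em_series, em_series[1:]))
        assert all(a > b for a, b in zip(nu_series, nu_series[1:]))
        preds = [predict_aspect_ratio(model, c)[0] for c in cn_series]
        assert all(b >= a for a, b in zip(preds, preds[1:]))

    def test_exported_map_shifts_right(self, tmp_path):
        model = fit_control_diagonal(CONTROL_POINTS)
        records = [
            PhenotypeRecord(
                condition=f"t{i}", cn_mean=cn,
                ar_mean=predict_aspect_ratio(model, cn)[0],
                me_ratio=1.0 / em, em_ratio=em, nu_a=nu,
            )
            for i, (cn, em, nu) in enumerate(
                zip([0.692, 0.741, 0.758], [0.1, 0.8, 2.0], [3.0, 2.0, 1.2])
            )
        ]
        frame = export_phenotype_map(records, model, tmp_path / "met.csv")
        ordered = frame.sort_values("condition")  # t0, t1, t2
        assert list(ordered.cn_mean) == sorted(ordered.cn_mean)
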