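"""The combined EMT-phenotyping model.

Per-condition inputs — mean nuclear circularity C_N, mean cellular aspect
ratio A_R, the M/E marker ratio and (optionally) the apparent migration
velocity nu_a — are merged into one record per condition.  An ordinary
least-squares line of A_R on C_N fitted to the untreated control conditions
(the "regression diagonal") defines the EMT axis: conditions move along it
from the epithelial corner (C_N, A_R near 1) towards the mesenchymal corner
as EMT progresses, and back during MET.  The fitted line also predicts A_R
from C_N alone for new conditions.

Classification uses interpretive thresholds: the epithelial bands for C_N
(0.8-0.9) and A_R (0.6-0.8) come from reference epithelial lines; the
mesenchymal cutoffs (A_R < 0.45 with M/E >= 1 or E-cadherin absent) are
interpolated between the mesenchymal reference (A_R ~ 0.24) and the
epithelial band floor.  All cutoffs are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, JoinError, ValidationError
from .morphometrics import ShapeSummary

CLASSES = ("E", "E/M", "M", "unclassified")


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Decision boundaries of the phenotype classifier."""

    cn_epithelial_band: tuple[float, float] = (0.8, 0.9)
    ar_epithelial_band: tuple[float, float] = (0.6, 0.8)
    me_mesenchymal_min: float = 1.0
    ar_mesenchymal_max: float = 0.45
    #: M/E below this counts as "mesenchymal marker absent" (interpretive)
    me_epithelial_max: float = 0.05

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("cn_epithelial_band", self.cn_epithelial_band),
            ("ar_epithelial_band", self.ar_epithelial_band),
        ):
            if not 0 < lo <= hi <= 1:
                raise ValidationError(f"{name} must be ordered within (0, 1]")
        if self.ar_mesenchymal_max <= 0 or self.me_mesenchymal_min < 0:
            raise ValidationError("mesenchymal cutoffs must be positive")


@dataclass
class PhenotypeRecord:
    """One condition's bubble on the phenotype map."""

    condition: str
    cell_line: str = ""
    cn_mean: float | None = None
    ar_mean: float | None = None
    me_ratio: float | None = None  # None = undefined (E absent) when em == 0
    em_ratio: float | None = None
    ratio_undefined: str | None = None
    nu_a: float | None = None
    nu_a_method: str | None = None
    phenotype_class: str = "unclassified"
    no_velocity: bool = False


@dataclass
class EMTAxisModel:
    """OLS diagonal A_R = slope * C_N + intercept over control conditions."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    control_points: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def fit_control_diagonal(control_points: Sequence[tuple[float, float]]) -> EMTAxisModel:
    """OLS of A_R on C_N over the untreated-control (C_N, A_R) points."""
    pts = [(float(x), float(y)) for x, y in control_points]
    if len(pts) < 2:
        raise FitError("need at least 2 control points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise FitError("control C_N values are constant; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return EMTAxisModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_points=len(pts),
        control_points=pts,
    )


def predict_aspect_ratio(model: EMTAxisModel, c_n: float) -> tuple[float, bool]:
    """Predicted A_R = slope * C_N + intercept; flags values outside (0, 1].

    The raw prediction is returned unclipped — the diagonal is a diagnostic,
    not a simulator.
    """
    if model is None or model.n_points < 2:
        raise FitError("model is not fitted")
    value = model.slope * c_n + model.intercept
    return float(value), not (0.0 < value <= 1.0)


def classify_phenotype(
    record: PhenotypeRecord, thresholds: PhenotypeThresholds | None = None
) -> str:
    """Assign one of E, E/M, M or unclassified; the mapping is total.

    * M: spindle shape (A_R below the mesenchymal cutoff) together with a
      dominant mesenchymal marker (M/E >= 1, or undefined-high because
      E-cadherin is absent while vimentin is present).
    * E: shape factors inside or above the epithelial bands with the
      mesenchymal marker (essentially) absent.
    * E/M: both markers detected, neither rule above matched.
    * unclassified: missing shape or marker inputs.
    """
    thr = thresholds or PhenotypeThresholds()
    thr.validate()
    if record.cn_mean is None or record.ar_mean is None:
        return "unclassified"
    has_ratio = record.ratio_undefined != "both" and (
        record.me_ratio is not None or record.em_ratio is not None
    )
    if not has_ratio:
        return "unclassified"

    me_undefined_high = record.me_ratio is None and (record.em_ratio or 0) == 0
    me_high = record.me_ratio is not None and record.me_ratio >= thr.me_mesenchymal_min
    if record.ar_mean < thr.ar_mesenchymal_max and (me_undefined_high or me_high):
        return "M"

    m_absent = record.me_ratio is not None and record.me_ratio <= thr.me_epithelial_max
    if (
        record.ar_mean >= thr.ar_epithelial_band[0]
        and record.cn_mean >= thr.cn_epithelial_band[0]
        and m_absent
    ):
        return "E"

    # markers present but neither extreme matched: intermediate/hybrid state
    return "E/M"


def assemble_phenotype_record(
    shape_summary: ShapeSummary,
    marker_row: pd.Series | dict,
    wound_summary: pd.DataFrame | dict | None = None,
    cell_line: str = "",
    thresholds: PhenotypeThresholds | None = None,
) -> PhenotypeRecord:
    """Join one condition's shape, marker and (optional) migration outputs.

    ``marker_row`` is one row of :func:`~emt_phenotyper.markers.quantify_panel`
    output; a missing wound summary yields a record flagged ``no_velocity``
    (rendered grey on the map).  Mismatched condition keys raise
    :class:`JoinError` naming the offending keys.
    """
    marker = dict(marker_row)
    cond = shape_summary.condition
    if marker.get("condition") != cond:
        raise JoinError(
            f"condition keys do not match: shapes={cond!r} "
            f"markers={marker.get('condition')!r}",
            keys=(cond, marker.get("condition")),
        )
    me = marker.get("me_ratio")
    em = marker.get("em_ratio")
    me = None if me is None or (isinstance(me, float) and np.isnan(me)) else float(me)
    em = None if em is None or (isinstance(em, float) and np.isnan(em)) else float(em)
    flag = marker.get("ratio_undefined") or None

    record = PhenotypeRecord(
        condition=cond,
        cell_line=cell_line,
        cn_mean=shape_summary.cn_mean,
        ar_mean=shape_summary.ar_mean,
        me_ratio=me,
        em_ratio=em,
        ratio_undefined=flag,
    )
    if wound_summary is None:
        record.no_velocity = True
    else:
        row = (
            wound_summary.iloc[0].to_dict()
            if isinstance(wound_summary, pd.DataFrame)
            else dict(wound_summary)
        )
        record.nu_a = float(row["nu_a_pct_per_h"])
        record.nu_a_method = str(row.get("estimator_flag", ""))
    record.phenotype_class = classify_phenotype(record, thresholds)
    return record


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def export_phenotype_map(
    records: Sequence[PhenotypeRecord],
    model: EMTAxisModel | None,
    out_csv: str | Path,
    out_png: str | Path | None = None,
    out_svg: str | Path | None = None,
    ratio_direction: str = "me",
) -> pd.DataFrame:
    """Write the tidy record CSV and the bubble map (x=C_N, y=A_R).

    Bubble area scales with the chosen marker ratio (``me`` for EMT
    induction, ``em`` for MET), color encodes nu_a (yellow = fastest);
    records without velocity are grey.  The control diagonal is overlaid
    dashed when a model is given.  Output is deterministic for fixed input.
    """
    if not records:
        raise ValidationError("no records to export")
    if ratio_direction not in ("me", "em"):
        raise ValidationError("ratio_direction must be 'me' or 'em'")
    frame = records_to_frame(records).sort_values("condition").reset_index(drop=True)
    if model is not None:
        frame["model_slope"] = model.slope
        frame["model_intercept"] = model.intercept
        frame["model_r_squared"] = model.r_squared
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_csv, index=False, float_format="%.6g")

    if out_png or out_svg:
        _render_map(records, model, out_png, out_svg, ratio_direction)
    return frame


def _render_map(records, model, out_png, out_svg, ratio_direction):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    velocities = [r.nu_a for r in records if r.nu_a is not None]
    vmax = max(velocities) if velocities else 1.0
    for r in sorted(records, key=lambda r: r.condition):
        ratio = getattr(r, f"{ratio_direction}_ratio")
        size = 80.0 * (0.5 + (ratio if ratio is not None else 2.0))
        if r.nu_a is None:
            color, label_v = "0.6", "n/a"
        else:
            color = plt.cm.viridis(r.nu_a / max(vmax, 1e-9))
            label_v = f"{r.nu_a:.2f}"
        ax.scatter(r.cn_mean, r.ar_mean, s=size, color=color, edgecolor="k", zorder=3)
        ax.annotate(
            f"{r.condition} [{r.phenotype_class}]",
            (r.cn_mean, r.ar_mean),
            textcoords="offset points",
            xytext=(6, 6),
            fontsize=7,
        )
    if model is not None:
        xs = np.linspace(0.5, 1.0, 50)
        ax.plot(xs, model.slope * xs + model.intercept, "k--", lw=1, zorder=2,
                label=f"diagonal: y = {model.slope:.3f}x {model.intercept:+.3f}")
        ax.legend(fontsize=7, loc="lower right")
    ax.set_xlabel("nuclear circularity $C_N$")
    ax.set_ylabel("cellular aspect ratio $A_R$")
    ax.set_xlim(0.5, 1.0)
    ax.set_ylim(0.0, 1.0)
    ax.set_title("EMT phenotype map")
    fig.tight_layout()
    if out_png:
        Path(out_png).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_png, dpi=150)
    if out_svg:
        Path(out_svg).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_svg)
    plt.close(fig)
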