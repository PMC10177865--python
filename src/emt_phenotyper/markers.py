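"""EMT-marker quantification from band intensities and qPCR Ct values.

Western-blot densitometry: CDH1 (E-cadherin, epithelial) and VIM (vimentin,
mesenchymal) band intensities are normalized to the GAPDH housekeeping band,
giving the epithelial level ``E = CDH1/GAPDH`` and mesenchymal level
``M = VIM/GAPDH``.  Fold changes are relative to the untreated control
condition.  The M/E ratio (and its reciprocal E/M) summarizes the marker
balance; absent markers (a zero denominator, e.g. E-cadherin-negative
mesenchymal lines) are flagged as undefined rather than epsilon-substituted.

qPCR: ``delta_ct = Ct_target - Ct_housekeeper`` and relative expression
``2**(-delta_ct)`` (GAPDH housekeeper for mRNA, miR-191 for the miRNA
panel).  Replicates are averaged at the Ct level before delta-Ct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import HousekeepingError, ValidationError


@dataclass
class MERatio:
    """M/E and E/M with explicit undefined flags (never substituted)."""

    me: float | None  # None when E == 0 while M > 0 ("undefined-high")
    em: float | None
    undefined_flag: str | None  # None | "me" | "em" | "both"

    @property
    def defined(self) -> bool:
        return self.undefined_flag is None


@dataclass
class ExpressionRecord:
    target: str
    ct_target: float
    ct_housekeeper: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeper

    @property
    def rel_expr(self) -> float:
        return float(2.0 ** (-self.delta_ct))


def normalize_bands(cdh1: float, vim: float, gapdh: float) -> tuple[float, float]:
    """Housekeeping normalization: ``E = CDH1/GAPDH``, ``M = VIM/GAPDH``."""
    if gapdh <= 0:
        raise HousekeepingError(f"GAPDH intensity must be positive, got {gapdh}")
    if cdh1 < 0 or vim < 0:
        raise ValidationError("band intensities must be >= 0")
    return cdh1 / gapdh, vim / gapdh


def fold_change(level: float, control_level: float) -> float:
    """Level relative to the untreated control; the control maps to 1."""
    if control_level <= 0:
        raise ValidationError(f"control level must be positive, got {control_level}")
    if level < 0:
        raise ValidationError("level must be >= 0")
    return level / control_level


def me_ratio(m: float, e: float) -> MERatio:
    """Mesenchymal/epithelial marker ratio with honest zero handling.

    When one marker is absent the corresponding ratio is undefined (its
    reciprocal is 0); when both are absent, both are undefined.
    """
    if m < 0 or e < 0:
        raise ValidationError("normalized levels must be >= 0")
    if m == 0 and e == 0:
        return MERatio(me=None, em=None, undefined_flag="both")
    if e == 0:
        return MERatio(me=None, em=0.0, undefined_flag="me")
    if m == 0:
        return MERatio(me=0.0, em=None, undefined_flag="em")
    return MERatio(me=m / e, em=e / m, undefined_flag=None)


def relative_expression(
    ct_target: float, ct_housekeeper: float, target: str = ""
) -> ExpressionRecord:
    """delta-Ct and ``2**(-delta_ct)`` for one target/housekeeper pair."""
    if not np.isfinite(ct_target) or not np.isfinite(ct_housekeeper):
        raise ValidationError("Ct values must be finite")
    if ct_target <= 0 or ct_housekeeper <= 0:
        raise HousekeepingError("Ct values must be positive")
    return ExpressionRecord(target=target, ct_target=ct_target, ct_housekeeper=ct_housekeeper)


def quantify_panel(bands: pd.DataFrame, control: str = "control") -> pd.DataFrame:
    """Full marker panel from a (condition, cdh1, vim, gapdh) table.

    Adds normalized levels E and M, fold changes vs the control condition,
    M/E and E/M ratios and their undefined flag.
    """
    required = {"condition", "cdh1", "vim", "gapdh"}
    if not required.issubset(bands.columns):
        raise ValidationError(f"band table must have columns {sorted(required)}")
    if control not in set(bands["condition"]):
        raise ValidationError(f"control condition {control!r} not in table")

    out = bands.copy()
    levels = [normalize_bands(r.cdh1, r.vim, r.gapdh) for r in out.itertuples()]
    out["e_level"] = [e for e, _ in levels]
    out["m_level"] = [m for _, m in levels]
    ctrl = out.loc[out["condition"] == control].iloc[0]
    out["cdh1_fold"] = [
        fold_change(e, ctrl.e_level) if ctrl.e_level > 0 else np.nan for e in out["e_level"]
    ]
    out["vim_fold"] = [
        fold_change(m, ctrl.m_level) if ctrl.m_level > 0 else np.nan for m in out["m_level"]
    ]
    ratios = [me_ratio(m, e) for m, e in zip(out["m_level"], out["e_level"])]
    out["me_ratio"] = [r.me if r.me is not None else np.nan for r in ratios]
    out["em_ratio"] = [r.em if r.em is not None else np.nan for r in ratios]
    out["ratio_undefined"] = [r.undefined_flag or "" for r in ratios]
    return out


def expression_table(cts: pd.DataFrame) -> pd.DataFrame:
    """delta-Ct / relative-expression table from a long Ct table.

    Expects columns (sample, target, ct, housekeeper_ct); technical
    replicates of the same (sample, target) are averaged at the Ct level
    before delta-Ct is computed.
    """
    required = {"sample", "target", "ct", "housekeeper_ct"}
    if not required.issubset(cts.columns):
        raise ValidationError(f"Ct table must have columns {sorted(required)}")
    agg = (
        cts.groupby(["sample", "target"], as_index=False)[["ct", "housekeeper_ct"]].mean()
    )
    records = [
        relative_expression(r.ct, r.housekeeper_ct, target=r.target) for r in agg.itertuples()
    ]
    agg["delta_ct"] = [r.delta_ct for r in records]
    agg["rel_expr"] = [r.rel_expr for r in records]
    return agg
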