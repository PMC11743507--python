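"""Group phenotype deltas, tolerance-test AUC, and offset–phenotype coupling.

ΔBW and ΔFBG are group-mean changes, endpoint week minus reference week
(end − ref): a positive ΔBW is weight gain, a negative ΔFBG is a glucose
drop. The percentage contrast between two group deltas uses the first
group's delta as denominator: 100·(Δa − Δb)/Δa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, ValidationError
from .tables_io import GlucoseCurve, PhenotypeTable, SampleMetadata


@dataclass
class DeltaSummary:
    group: str
    bw_mean_ref: float
    bw_mean_end: float
    delta_bw: float
    fbg_mean_ref: float
    fbg_mean_end: float
    delta_fbg: float
    n_mice: int
    week_ref: int
    week_end: int


@dataclass
class DeltaContrast:
    measure: str
    absolute_excess: float
    percent_excess: float
    undefined: bool = False


@dataclass
class AucResult:
    mouse_id: str
    auc: float  # mmol/L · min
    baseline_subtracted: bool


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str = "pearson"
    undefined: bool = False


def group_delta(pheno: PhenotypeTable, meta: SampleMetadata, group: str,
                week_ref: int = 4, week_end: int = 10) -> DeltaSummary:
    """Group-mean BW/FBG at both weeks and their end−ref deltas."""
    mice = meta.mice_in(group)
    if not mice:
        raise ValidationError(f"group {group!r} has no mice in metadata")
    missing = []
    bw_ref, bw_end, fbg_ref, fbg_end = [], [], [], []
    for m in mice:
        sub = pheno.df[pheno.df["mouse_id"] == m]
        have = set(sub["week"])
        if week_ref not in have or week_end not in have:
            missing.append(m)
            continue
        bw_ref.append(pheno.at(m, week_ref, "bw"))
        bw_end.append(pheno.at(m, week_end, "bw"))
        fbg_ref.append(pheno.at(m, week_ref, "fbg"))
        fbg_end.append(pheno.at(m, week_end, "fbg"))
    if missing:
        raise ValidationError(
            f"mice missing week {week_ref} or {week_end} measurements: {missing}")
    bw_r, bw_e = float(np.mean(bw_ref)), float(np.mean(bw_end))
    fb_r, fb_e = float(np.mean(fbg_ref)), float(np.mean(fbg_end))
    return DeltaSummary(group=group, bw_mean_ref=bw_r, bw_mean_end=bw_e,
                        delta_bw=bw_e - bw_r, fbg_mean_ref=fb_r,
                        fbg_mean_end=fb_e, delta_fbg=fb_e - fb_r,
                        n_mice=len(mice), week_ref=week_ref, week_end=week_end)


def delta_contrast(a: DeltaSummary, b: DeltaSummary, measure: str = "bw"
                   ) -> DeltaContrast:
    """Excess of group a's delta over group b's, absolute and as a percent
    of group a's delta (flagged undefined when Δa = 0)."""
    if measure not in ("bw", "fbg"):
        raise ParameterError("measure must be 'bw' or 'fbg'")
    da = a.delta_bw if measure == "bw" else a.delta_fbg
    db = b.delta_bw if measure == "bw" else b.delta_fbg
    excess = da - db
    if da == 0:
        return DeltaContrast(measure, excess, float("nan"), undefined=True)
    return DeltaContrast(measure, excess, 100.0 * excess / da)


def glucose_auc(curve: GlucoseCurve, baseline_subtract: bool = False) -> AucResult:
    """Trapezoidal area under the glucose–time curve (mmol/L · min).

    With ``baseline_subtract`` the integrand is max(glucose − glucose(0), 0),
    the incremental-AUC convention.
    """
    if curve.minutes.size < 2:
        raise ValidationError("AUC needs at least 2 time points")
    g = curve.glucose
    if baseline_subtract:
        g = np.maximum(g - g[0], 0.0)
    auc = float(np.trapezoid(g, curve.minutes))
    return AucResult(mouse_id=curve.mouse_id, auc=auc,
                     baseline_subtracted=baseline_subtract)


def offset_phenotype_correlation(points: list[tuple[float, float]],
                                 mode: str = "pearson") -> CorrelationResult:
    """Correlation between community-offset magnitudes and phenotype deltas.

    The caller constructs the (offset, delta) points — per group pair or per
    mouse; either granularity is accepted.
    """
    if mode not in ("pearson", "spearman"):
        raise ParameterError("mode must be 'pearson' or 'spearman'")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need at least 3 (offset, delta) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(pts),
                                 method=mode, undefined=True)
    if mode == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), len(pts), method=mode)
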