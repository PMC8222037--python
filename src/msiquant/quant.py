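"""Internal-standard normalization, ROI statistics and calibration modeling.

The quantitative core of the workflow.  Per pixel, the analyte hydrazone
signal is divided by the co-sprayed internal-standard hydrazone
(triamcinolone acetonide), cancelling pixel-to-pixel ionization
variability.  Per calibration spot, the median ratio is regressed on the
deposited amount with the surfactant (lipid) level as a categorical
covariate:

    median_ratio ~ amount_ng * C(lipid_level)

Ordinary least squares; Wald/F tests on the lipid dummies quantify ion
suppression as an intercept effect, and on the interaction terms as a
slope effect.  Inverse prediction turns tissue-section median ratios
back into deposited-amount equivalents with first-order error
propagation from the coefficient covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .images import IonImage
from .segment import RoiLabelMap

__all__ = [
    "RoiSummary",
    "CalibrationFit",
    "PredictionResult",
    "normalize_ratio",
    "summarize_roi",
    "fit_calibration",
    "predict_concentration",
    "spike_arithmetic",
    "build_distribution_map",
]


def normalize_ratio(analyte_img: IonImage, is_img: IonImage) -> IonImage:
    """Pixel-wise analyte / internal-standard ratio on the linear scale.

    Pixels where the internal standard is 0 or missing are masked (NaN):
    with no IS signal the pixel's ionization cannot be referenced.  A
    zero analyte over positive IS is a genuine ratio of 0.  The result is
    invariant to any joint rescaling of the two channels, which is the
    point of the normalization.
    """
    if analyte_img.transform != "linear" or is_img.transform != "linear":
        raise ValueError("normalize_ratio expects linear-scale images")
    if analyte_img.shape != is_img.shape:
        raise ValueError(
            f"shape mismatch: analyte {analyte_img.shape} vs IS {is_img.shape}"
        )
    a = analyte_img.values
    s = is_img.values
    out = np.full(a.shape, np.nan)
    ok = (~np.isnan(a)) & (~np.isnan(s)) & (s > 0)
    out[ok] = a[ok] / s[ok]
    return IonImage(
        out,
        analyte_img.target_mz,
        analyte_img.tolerance,
        "linear",
        provenance=f"{analyte_img.provenance}/{is_img.provenance}",
    )


@dataclass
class RoiSummary:
    """Median/IQR summary of the normalized signal inside one ROI."""

    roi_id: int
    n_pixels_used: int
    median_ratio: float
    iqr_ratio: float
    below_detection_fraction: float
    flagged: bool = False
    annotation: Dict[str, object] = field(default_factory=dict)


def summarize_roi(ratio_img: IonImage, roi_map: RoiLabelMap) -> List[RoiSummary]:
    """Per-ROI median and interquartile range of the ratio image.

    Only pixels with a finite ratio contribute; the fraction of masked
    pixels is reported.  An ROI with zero usable pixels yields a flagged
    summary (NaN statistics) rather than being dropped.
    """
    if ratio_img.shape != roi_map.labels.shape:
        raise ValueError("ratio image and label map shapes differ")
    out = []
    for roi in roi_map.rois:
        vals = ratio_img.values[roi_map.labels == roi.id]
        finite = vals[~np.isnan(vals)]
        frac_masked = 1.0 - finite.size / vals.size if vals.size else 1.0
        if finite.size == 0:
            out.append(
                RoiSummary(roi.id, 0, np.nan, np.nan, frac_masked, flagged=True,
                           annotation=dict(roi.annotation))
            )
            continue
        q1, med, q3 = np.percentile(finite, [25, 50, 75])
        out.append(
            RoiSummary(
                roi.id,
                int(finite.size),
                float(med),
                float(q3 - q1),
                float(frac_masked),
                annotation=dict(roi.annotation),
            )
        )
    return out


@dataclass
class CalibrationFit:
    """Per-lipid-level calibration lines plus suppression-effect tests.

    ``levels`` is the sorted list of lipid levels (mg/g).  Coefficients
    are stored per level together with the 2x2 covariance of
    (intercept, slope) needed for inverse prediction.  ``p_intercept_effect``
    and ``p_slope_effect`` are joint F-test p-values for any lipid effect
    on intercept resp. slope (NaN for single-level fits).
    """

    levels: List[float]
    intercepts: Dict[float, float]
    slopes: Dict[float, float]
    intercept_ses: Dict[float, float]
    slope_ses: Dict[float, float]
    coef_cov: Dict[float, np.ndarray]  # per level, 2x2 for (intercept, slope)
    r_squared: float
    df_resid: int
    p_intercept_effect: float
    p_slope_effect: float
    intercept_shifts: Dict[float, Tuple[float, float, float]]  # level -> (est, se, p)
    slope_shifts: Dict[float, Tuple[float, float, float]]
    formula: str = "median_ratio ~ amount_ng * C(lipid_mg_per_g)"

    def line(self, lipid_level: float) -> Tuple[float, float]:
        lvl = self._level(lipid_level)
        return self.intercepts[lvl], self.slopes[lvl]

    def _level(self, lipid_level: float) -> float:
        for lvl in self.levels:
            if np.isclose(lvl, lipid_level):
                return lvl
        raise KeyError(
            f"lipid level {lipid_level} not in fitted levels {self.levels}"
        )

    def predict_ratio(self, amount_ng, lipid_level: float):
        a, b = self.line(lipid_level)
        return a + b * np.asarray(amount_ng)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "levels": list(map(float, self.levels)),
            "intercepts": {str(k): v for k, v in self.intercepts.items()},
            "slopes": {str(k): v for k, v in self.slopes.items()},
            "intercept_ses": {str(k): v for k, v in self.intercept_ses.items()},
            "slope_ses": {str(k): v for k, v in self.slope_ses.items()},
            "coef_cov": {str(k): np.asarray(v).tolist() for k, v in self.coef_cov.items()},
            "r_squared": self.r_squared,
            "df_resid": self.df_resid,
            "p_intercept_effect": self.p_intercept_effect,
            "p_slope_effect": self.p_slope_effect,
            "intercept_shifts": {str(k): list(v) for k, v in self.intercept_shifts.items()},
            "slope_shifts": {str(k): list(v) for k, v in self.slope_shifts.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def _summaries_frame(summaries: Sequence[RoiSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        if s.flagged or np.isnan(s.median_ratio):
            continue
        ann = s.annotation
        if "amount_ng" not in ann:
            raise ValueError(
                f"summary for ROI {s.roi_id} lacks an amount_ng annotation; "
                "run annotate_rois first"
            )
        rows.append(
            dict(
                roi_id=s.roi_id,
                median_ratio=s.median_ratio,
                iqr_ratio=s.iqr_ratio,
                n_pixels=s.n_pixels_used,
                amount_ng=float(ann["amount_ng"]),
                lipid_mg_per_g=float(ann.get("lipid_mg_per_g", 0.0)),
            )
        )
    if not rows:
        raise ValueError("no usable ROI summaries")
    return pd.DataFrame(rows)


def fit_calibration(summaries: Sequence[RoiSummary]) -> CalibrationFit:
    """OLS calibration of median ratio on deposited amount, by lipid level.

    With one lipid level this is a plain line and the effect tests are
    undefined (NaN).  With several levels the full interaction model is
    fitted and two joint Wald/F tests are reported: lipid main effect
    (intercept suppression) and lipid x amount interaction (slope
    suppression).  Raises ``ValueError`` on rank-deficient designs,
    naming the offending cells.
    """
    df = _summaries_frame(summaries)
    levels = sorted(df["lipid_mg_per_g"].unique())
    bad = [
        f"lipid {lvl:g} mg/g has {df[df.lipid_mg_per_g == lvl].amount_ng.nunique()} distinct amount(s)"
        for lvl in levels
        if df[df.lipid_mg_per_g == lvl]["amount_ng"].nunique() < 2
    ]
    if bad:
        raise ValueError("rank-deficient calibration design: " + "; ".join(bad))

    base = levels[0]
    X = pd.DataFrame({"intercept": np.ones(len(df))})
    for lvl in levels[1:]:
        X[f"lipid[{lvl:g}]"] = (df["lipid_mg_per_g"] == lvl).astype(float)
    X["slope"] = df["amount_ng"]
    for lvl in levels[1:]:
        X[f"slope:lipid[{lvl:g}]"] = df["amount_ng"] * (df["lipid_mg_per_g"] == lvl)

    # point estimates are plain OLS; inference uses HC3 robust covariance
    # because the pixel noise is multiplicative, so summary variance grows
    # with the response and classical F-tests on the slope terms would be
    # anti-conservative
    res = sm.OLS(df["median_ratio"], X).fit(cov_type="HC3")
    cov = res.cov_params()
    # perfect (noise-free) fit: Wald statistics are 0/0, decide by estimates
    perfect = float(res.ssr) <= 1e-20 * max(float((df["median_ratio"] ** 2).sum()), 1e-300)
    coef_scale = max(1e-300, float(np.abs(res.params).max()))

    def _degenerate_p(estimates) -> float:
        return 1.0 if all(abs(e) <= 1e-9 * coef_scale for e in estimates) else 0.0

    intercepts, slopes, i_ses, s_ses, lcov = {}, {}, {}, {}, {}
    i_shift, s_shift = {}, {}
    names = list(X.columns)

    def contrast(name_list):
        v = np.zeros(len(names))
        for n in name_list:
            v[names.index(n)] = 1.0
        return v

    for lvl in levels:
        ci = contrast(["intercept"] + ([f"lipid[{lvl:g}]"] if lvl != base else []))
        cs = contrast(["slope"] + ([f"slope:lipid[{lvl:g}]"] if lvl != base else []))
        intercepts[lvl] = float(ci @ res.params)
        slopes[lvl] = float(cs @ res.params)
        C = np.vstack([ci, cs])
        V = C @ cov.values @ C.T
        lcov[lvl] = V
        i_ses[lvl] = float(np.sqrt(V[0, 0]))
        s_ses[lvl] = float(np.sqrt(V[1, 1]))
        if lvl != base:
            for key, shifts in ((f"lipid[{lvl:g}]", i_shift), (f"slope:lipid[{lvl:g}]", s_shift)):
                est = float(res.params[key])
                se = float(res.bse[key])
                p = _degenerate_p([est]) if perfect else float(res.pvalues[key])
                shifts[lvl] = (est, se, p)

    if len(levels) > 1:
        dummy_names = [f"lipid[{l:g}]" for l in levels[1:]]
        inter_names = [f"slope:lipid[{l:g}]" for l in levels[1:]]
        R_i = np.zeros((len(dummy_names), len(names)))
        for k, n in enumerate(dummy_names):
            R_i[k, names.index(n)] = 1.0
        R_s = np.zeros((len(inter_names), len(names)))
        for k, n in enumerate(inter_names):
            R_s[k, names.index(n)] = 1.0
        if perfect:
            p_int = _degenerate_p([res.params[n] for n in dummy_names])
            p_slp = _degenerate_p([res.params[n] for n in inter_names])
        else:
            p_int = float(res.f_test(R_i).pvalue)
            p_slp = float(res.f_test(R_s).pvalue)
    else:
        p_int = p_slp = float("nan")

    return CalibrationFit(
        levels=levels,
        intercepts=intercepts,
        slopes=slopes,
        intercept_ses=i_ses,
        slope_ses=s_ses,
        coef_cov=lcov,
        r_squared=float(res.rsquared),
        df_resid=int(res.df_resid),
        p_intercept_effect=p_int,
        p_slope_effect=p_slp,
        intercept_shifts=i_shift,
        slope_shifts=s_shift,
    )


@dataclass
class PredictionResult:
    amount_ng: float
    se_ng: float
    interval_ng: Tuple[float, float]
    below_calibration: bool = False


def predict_concentration(
    fit: CalibrationFit,
    summary: RoiSummary,
    lipid_level: float = 0.0,
    z: float = 1.96,
) -> PredictionResult:
    """Inverse prediction: deposited amount from a measured median ratio.

    amount = (median_ratio - intercept) / slope at the given lipid level.
    The standard error propagates, to first order, the coefficient
    covariance plus the ROI's own sampling noise (IQR-based normal-scale
    estimate of the median's variance).  A ratio below the intercept is
    reported as 0 ng with ``below_calibration=True``.
    """
    a, b = fit.line(lipid_level)
    if b <= 0:
        raise ValueError(f"non-positive slope {b:.4g} at lipid level {lipid_level:g}")
    m = summary.median_ratio
    if np.isnan(m):
        raise ValueError(f"ROI {summary.roi_id} has no usable ratio")
    amount = (m - a) / b

    var_m = 0.0
    if summary.n_pixels_used > 0 and np.isfinite(summary.iqr_ratio):
        # var of the sample median ~ (pi/2) * sigma^2 / n with sigma from IQR
        sigma = summary.iqr_ratio / 1.349
        var_m = (np.pi / 2) * sigma**2 / summary.n_pixels_used
    V = fit.coef_cov[fit._level(lipid_level)]
    var = (var_m + V[0, 0] + amount**2 * V[1, 1] + 2 * amount * V[0, 1]) / b**2
    se = float(np.sqrt(max(var, 0.0)))

    below = amount < 0
    est = 0.0 if below else float(amount)
    return PredictionResult(
        amount_ng=est,
        se_ng=se,
        interval_ng=(max(0.0, amount - z * se), amount + z * se),
        below_calibration=bool(below),
    )


def spike_arithmetic(
    volume_a_ul: float,
    conc_a_mg_per_ml: float,
    volume_b_ul: float,
    spike_fraction_ww: float,
) -> float:
    """Tissue concentration (ug/g) from a two-component spiking recipe.

    Component A (drug solution, ``volume_a_ul`` at ``conc_a_mg_per_ml``)
    is mixed into component B (``volume_b_ul``); the formulation is then
    spiked into tissue homogenate at ``spike_fraction_ww`` (w/w).  Unit
    density (1 g/mL) is assumed throughout, which reproduces the study's
    printed 14.2 / 7.1 ug/g from its surfactant-budesonide recipe.
    """
    if volume_a_ul <= 0 or volume_b_ul <= 0:
        raise ValueError("volumes must be > 0")
    if not (0 < spike_fraction_ww <= 1):
        raise ValueError(f"spike fraction must be in (0, 1], got {spike_fraction_ww}")
    mass_ug = volume_a_ul * conc_a_mg_per_ml  # uL * mg/mL == ug
    formulation_ug_per_g = mass_ug / ((volume_a_ul + volume_b_ul) / 1000.0)
    return formulation_ug_per_g * spike_fraction_ww


def build_distribution_map(
    ratio_img: IonImage,
    roi_map: RoiLabelMap,
    fit: CalibrationFit,
    lipid_level: float = 0.0,
) -> Tuple[IonImage, pd.DataFrame]:
    """Per-pixel concentration map inside tissue ROIs + per-section table.

    Each tissue pixel's ratio is inverse-predicted through the
    calibration line for ``lipid_level``; ratios below the intercept clip
    to 0 (below detection).  Background and spots stay masked.  The table
    reports per-section median, IQR and the below-detection fraction.
    """
    a, b = fit.line(lipid_level)
    if b <= 0:
        raise ValueError("calibration slope must be positive")
    conc = np.full(ratio_img.values.shape, np.nan)
    rows = []
    for roi in roi_map.rois:
        if roi.kind != "tissue-section":
            continue
        mask = roi_map.labels == roi.id
        vals = ratio_img.values[mask]
        est = (vals - a) / b
        est = np.where(np.isnan(vals), np.nan, np.clip(est, 0.0, None))
        conc[mask] = est
        finite = est[~np.isnan(est)]
        rows.append(
            dict(
                roi_id=roi.id,
                role=roi.annotation.get("role", ""),
                n_pixels=int(finite.size),
                median_ng=float(np.median(finite)) if finite.size else np.nan,
                iqr_ng=float(np.subtract(*np.percentile(finite, [75, 25]))) if finite.size else np.nan,
                below_detection_fraction=float((finite == 0).mean()) if finite.size else np.nan,
            )
        )
    img = IonImage(
        conc,
        ratio_img.target_mz,
        ratio_img.tolerance,
        "linear",
        provenance=f"{ratio_img.provenance} -> ng via calibration",
    )
    return img, pd.DataFrame(rows)
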