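"""Synthetic centroided MSI slides with full ground truth.

Emulates the structure of the study's slides so every downstream stage
is testable without instrument data:

* rectangular tissue sections — one treated "sample" section and spiked
  control homogenate sections — carrying heme B and internal-standard
  channels;
* calibration sections bearing a dilution-series of circular spots
  (default: 5 amounts x 4 replicates), each spot marked by a high
  tiotropium channel so spot detection at the log10 threshold works as
  in the real workflow;
* a lipid-dependent additive shift of the calibration intercept
  (default +10% of the intercept at 8 mg/g surfactant, +5% at 4 mg/g,
  no slope change) modeling ion suppression;
* multiplicative lognormal pixel noise split into a shared component
  (cancelled by internal-standard normalization — the reason the IS is
  sprayed at all) and an independent per-channel component that
  survives the ratio; ppm-scale m/z jitter; uniform background peaks.

Noise factors have median 1, so per-spot *median* ratios are unbiased
estimates of the configured response — the property the calibration fit
relies on.  All randomness flows from one seed; identical spec + seed
gives identical spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import chem
from .design import CalibrationDesign, SectionRole
from .grid import Pixel, SpectrumGrid

__all__ = [
    "SpotSpec",
    "SectionSpec",
    "NoiseSpec",
    "ResponseSpec",
    "SlideSpec",
    "GroundTruth",
    "generate_slide",
    "generate_calibration_only",
    "default_slide_spec",
    "default_calibration_spec",
]


@dataclass(frozen=True)
class SpotSpec:
    """One deposited calibration drop."""

    center: Tuple[float, float]  # (row, col)
    conc_ng_per_ul: float
    replicate: int
    radius: float = 2.5  # px; ~2 mm drop at a 400 um raster
    drop_volume_ul: float = 0.5

    @property
    def amount_ng(self) -> float:
        return self.conc_ng_per_ul * self.drop_volume_ul


@dataclass(frozen=True)
class SectionSpec:
    """One rectangular tissue section on the slide.

    ``amount_ng`` is the per-pixel deposited-amount equivalent of the
    analyte (None = untreated: no analyte channel at all).
    """

    role: str
    origin: Tuple[int, int]  # (row, col), 0-based
    size: Tuple[int, int]    # (height, width)
    amount_ng: Optional[float] = None
    lipid_mg_per_g: float = 0.0
    spots: Tuple[SpotSpec, ...] = ()


@dataclass(frozen=True)
class NoiseSpec:
    sigma_indep: float = 0.15      # per-channel lognormal sd (log scale)
    sigma_shared: float = 0.30     # shared per-pixel factor, cancelled by IS
    mz_jitter_ppm: float = 2.0
    background_rate: float = 5.0   # Poisson peaks per pixel over the full range
    background_intensity: float = 50.0

    def __post_init__(self) -> None:
        if min(self.sigma_indep, self.sigma_shared, self.mz_jitter_ppm,
               self.background_rate, self.background_intensity) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class ResponseSpec:
    """Calibration response: expected ratio = intercept + slope * amount.

    ``intercept_shift_frac`` / ``slope_shift_frac`` map lipid level to a
    fractional change of the zero-lipid coefficient, modeling ion
    suppression as found in the study (intercept effect only).
    """

    intercept: float = 1.0
    slope_per_ng: float = 0.025
    intercept_shift_frac: Dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 4.0: 0.05, 8.0: 0.10}
    )
    slope_shift_frac: Dict[float, float] = field(default_factory=dict)

    def line(self, lipid: float) -> Tuple[float, float]:
        a = self.intercept * (1.0 + self.intercept_shift_frac.get(lipid, 0.0))
        b = self.slope_per_ng * (1.0 + self.slope_shift_frac.get(lipid, 0.0))
        return a, b

    def expected_ratio(self, amount_ng: float, lipid: float = 0.0) -> float:
        a, b = self.line(lipid)
        return a + b * amount_ng


@dataclass(frozen=True)
class ChannelSpec:
    is_intensity: float = 1e5
    heme_intensity: float = 1e6
    tiotropium_intensity: float = 1e7  # log10 = 7 >> spot threshold 5.6
    analyte_baseline: float = 0.0      # residual analyte floor on analyte-free tissue


@dataclass
class SlideSpec:
    grid_shape: Tuple[int, int] = (64, 80)  # (rows, cols)
    pixel_size_um: float = 400.0
    mz_range: Tuple[float, float] = (185.0, 650.0)
    sections: List[SectionSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    response: ResponseSpec = field(default_factory=ResponseSpec)
    channels: ChannelSpec = field(default_factory=ChannelSpec)
    seed: int = 0

    def validate(self) -> None:
        nr, nc = self.grid_shape
        boxes = []
        for s in self.sections:
            r0, c0 = s.origin
            h, w = s.size
            if r0 < 0 or c0 < 0 or r0 + h > nr or c0 + w > nc:
                raise ValueError(f"section {s.role!r} exceeds the grid")
            for b in boxes:
                if not (r0 + h <= b[0] or b[0] + b[2] <= r0 or c0 + w <= b[1] or b[1] + b[3] <= c0):
                    raise ValueError(f"section {s.role!r} overlaps another section")
            boxes.append((r0, c0, h, w))
            for sp in s.spots:
                rr, cc = sp.center
                if sp.radius < 1:
                    raise ValueError("spot radius must be >= 1 px")
                if not (r0 <= rr - sp.radius and rr + sp.radius < r0 + h
                        and c0 <= cc - sp.radius and cc + sp.radius < c0 + w):
                    raise ValueError(f"spot at {sp.center} outside its section {s.role!r}")
            for i, a in enumerate(s.spots):
                for b in s.spots[i + 1:]:
                    d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                    if d < a.radius + b.radius:
                        raise ValueError(f"spots at {a.center} and {b.center} overlap")


@dataclass
class GroundTruth:
    """Everything the generator knows: per-pixel labels, true response."""

    section_labels: np.ndarray           # 0 = background, else index+1 into sections
    spot_labels: np.ndarray              # 0 = background, else index+1 into design rows
    true_ratio: np.ndarray               # NaN where no analyte channel
    design: CalibrationDesign
    sections: List[SectionSpec]
    response: ResponseSpec
    target_mz: Dict[str, float]

    def tissue_mask(self) -> np.ndarray:
        return self.section_labels > 0

    def section_mask(self, index: int) -> np.ndarray:
        return self.section_labels == index + 1


def _spot_design(sections: List[SectionSpec]) -> CalibrationDesign:
    rows = []
    roles = []
    for s in sections:
        r0, c0 = s.origin
        h, w = s.size
        roles.append(SectionRole(s.role, r0 + h / 2.0, c0 + w / 2.0))
        for sp in s.spots:
            rows.append(
                dict(
                    spot_id=f"L{s.lipid_mg_per_g:g}-R{sp.replicate}-C{sp.conc_ng_per_ul:g}",
                    row_hint=sp.center[0],
                    col_hint=sp.center[1],
                    conc_ng_per_ul=sp.conc_ng_per_ul,
                    drop_volume_ul=sp.drop_volume_ul,
                    lipid_mg_per_g=s.lipid_mg_per_g,
                    replicate=sp.replicate,
                )
            )
    import pandas as pd

    df = pd.DataFrame(rows) if rows else _empty_design_frame()
    return CalibrationDesign(spots=df, sections=roles)


def _empty_design_frame():
    import pandas as pd
    from .design import SPOT_COLUMNS

    return pd.DataFrame({c: [] for c in SPOT_COLUMNS})


def generate_slide(spec: SlideSpec) -> Tuple[SpectrumGrid, GroundTruth]:
    """Render a slide spec into centroided spectra plus ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    targets = {k: t.mz for k, t in chem.builtin_targets().items()}
    nr, nc = spec.grid_shape
    lo, hi = spec.mz_range

    section_labels = np.zeros((nr, nc), dtype=int)
    spot_labels = np.zeros((nr, nc), dtype=int)
    pixel_amount = np.full((nr, nc), np.nan)
    pixel_lipid = np.zeros((nr, nc))
    true_ratio = np.full((nr, nc), np.nan)

    design = _spot_design(spec.sections)
    spot_index = 0
    for si, s in enumerate(spec.sections):
        r0, c0 = s.origin
        h, w = s.size
        section_labels[r0:r0 + h, c0:c0 + w] = si + 1
        pixel_lipid[r0:r0 + h, c0:c0 + w] = s.lipid_mg_per_g
        if s.amount_ng is not None:
            pixel_amount[r0:r0 + h, c0:c0 + w] = s.amount_ng
        for sp in s.spots:
            spot_index += 1
            rr, cc = np.ogrid[:nr, :nc]
            disc = (rr - sp.center[0]) ** 2 + (cc - sp.center[1]) ** 2 <= sp.radius**2
            spot_labels[disc] = spot_index
            pixel_amount[disc] = sp.amount_ng

    resp = spec.response
    ch = spec.channels
    nz = spec.noise
    pixels: List[Pixel] = []

    def lognoise() -> float:
        return math.exp(nz.sigma_indep * rng.standard_normal()) if nz.sigma_indep else 1.0

    def jitter(mz: float) -> float:
        if not nz.mz_jitter_ppm:
            return mz
        return mz * (1.0 + nz.mz_jitter_ppm * 1e-6 * rng.standard_normal())

    for r in range(nr):
        for c in range(nc):
            peaks: List[Tuple[float, float]] = []
            n_bg = rng.poisson(nz.background_rate) if nz.background_rate else 0
            for _ in range(n_bg):
                peaks.append(
                    (rng.uniform(lo, hi),
                     nz.background_intensity * math.exp(rng.standard_normal())))
            on_tissue = section_labels[r, c] > 0
            on_spot = spot_labels[r, c] > 0
            if on_tissue or on_spot:
                shared = (
                    math.exp(nz.sigma_shared * rng.standard_normal())
                    if nz.sigma_shared else 1.0
                )
                peaks.append((jitter(targets["TA-GirP"]), ch.is_intensity * shared * lognoise()))
                if on_tissue:
                    peaks.append((jitter(targets["hemeB"]), ch.heme_intensity * shared * lognoise()))
                if on_spot:
                    peaks.append(
                        (jitter(targets["tiotropium"]), ch.tiotropium_intensity * shared * lognoise()))
                amount = pixel_amount[r, c]
                if not np.isnan(amount):
                    ratio = resp.expected_ratio(float(amount), float(pixel_lipid[r, c]))
                    true_ratio[r, c] = ratio
                    peaks.append(
                        (jitter(targets["BUD-GirP"]), ratio * ch.is_intensity * shared * lognoise()))
                elif ch.analyte_baseline > 0 and on_tissue:
                    peaks.append((jitter(targets["BUD-GirP"]), ch.analyte_baseline * lognoise()))
            if not peaks:
                # electronic noise floor: a centroided scan never comes back
                # truly empty, and the imzML backend cannot encode one either
                peaks.append((rng.uniform(lo, hi), max(nz.background_intensity, 1.0)))
            peaks.sort()
            mzs = np.array([p[0] for p in peaks])
            ints = np.array([p[1] for p in peaks])
            # merge coincident m/z (background collisions) to keep arrays strictly ascending
            keep = np.concatenate(([True], np.diff(mzs) > 0))
            if not keep.all():
                for i in np.nonzero(~keep)[0]:
                    ints[i - 1] += ints[i]
                mzs, ints = mzs[keep], ints[keep]
            np.clip(mzs, lo, hi, out=mzs)
            if np.any(np.diff(mzs) <= 0):  # clipping collision at range edge
                keep = np.concatenate(([True], np.diff(mzs) > 0))
                mzs, ints = mzs[keep], ints[keep]
            pixels.append(Pixel(c + 1, r + 1, mzs, ints))

    grid = SpectrumGrid(
        pixels=pixels,
        pixel_size=(spec.pixel_size_um, spec.pixel_size_um),
        mz_range=spec.mz_range,
        polarity="positive",
        metadata={"generator": "msiquant.simulate", "seed": str(spec.seed)},
    )
    truth = GroundTruth(
        section_labels=section_labels,
        spot_labels=spot_labels,
        true_ratio=true_ratio,
        design=design,
        sections=list(spec.sections),
        response=resp,
        target_mz=targets,
    )
    return grid, truth


def generate_calibration_only(spec: SlideSpec) -> Tuple[SpectrumGrid, GroundTruth]:
    """As :func:`generate_slide`, keeping only spot-bearing sections."""
    reduced = replace(spec, sections=[s for s in spec.sections if s.spots])
    return generate_slide(reduced)


# ---------------------------------------------------------------------------
# Default layouts mirroring the study

def _calibration_section(
    role: str,
    origin: Tuple[int, int],
    lipid: float,
    concentrations: Optional[List[float]] = None,
    n_replicates: int = 4,
    radius: float = 2.5,
    pitch: int = 7,
) -> SectionSpec:
    concs = concentrations or [0.2, 2.0, 5.0, 20.0, 40.0]
    r0, c0 = origin
    spots = []
    for j in range(n_replicates):
        for k, conc in enumerate(concs):
            spots.append(
                SpotSpec(
                    center=(r0 + 4 + j * pitch, c0 + 4 + k * pitch),
                    conc_ng_per_ul=conc,
                    replicate=j + 1,
                    radius=radius,
                )
            )
    h = 4 + (n_replicates - 1) * pitch + 4 + 1
    w = 4 + (len(concs) - 1) * pitch + 4 + 1
    return SectionSpec(role, origin, (h, w), amount_ng=None,
                       lipid_mg_per_g=lipid, spots=tuple(spots))


def default_calibration_spec(seed: int = 0) -> SlideSpec:
    """Three homogenate sections (lipid 0 / 4 / 8 mg/g), 20 spots each.

    This is the study's quantification design: dilution series 0.2-40
    ng/uL x 500 nL (0.1-20 ng deposited), four replicates, three
    surfactant levels.
    """
    sections = [
        _calibration_section("calibration-L0", (2, 2), 0.0),
        _calibration_section("calibration-L4", (2, 42), 4.0),
        _calibration_section("calibration-L8", (2, 82), 8.0),
    ]
    return SlideSpec(grid_shape=(34, 122), sections=sections, seed=seed)


def default_slide_spec(seed: int = 0, treated_amount_ng: float = 5.0) -> SlideSpec:
    """Full slide: treated sample, two spiked controls, one spot section.

    Mirrors the study's slide layout of one sample section plus control
    homogenate sections spiked with 2.5 and 10 ng, alongside an
    on-tissue dilution series for calibration.
    """
    sections = [
        SectionSpec("sample", (2, 2), (24, 24), amount_ng=treated_amount_ng),
        SectionSpec("control-2.5ng", (2, 30), (24, 24), amount_ng=2.5),
        SectionSpec("control-10ng", (2, 58), (24, 24), amount_ng=10.0),
        _calibration_section("calibration-L0", (30, 2), 0.0),
    ]
    return SlideSpec(grid_shape=(64, 84), sections=sections, seed=seed)
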