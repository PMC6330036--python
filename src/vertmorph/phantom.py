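"""Synthetic longitudinal vertebral CT studies with known ground truth.

Each subject carries three lumbar vertebral bodies (L2-L4), each rendered
as a stack of elliptical cross-sections: a high-density cortical shell
around a lower-density cancellous interior with smooth stochastic texture,
optionally blurred (partial-volume) and corrupted by additive noise.  Two
cohorts (control n=5, fasting n=6) grow over a 14-day time course and are
imaged every other day; a 4-day fast suppresses density accrual and halts
geometric growth, density recovers rapidly on refeeding, and a persistent
mineral-redistribution term (cortical mineral shifted inward: a thicker
but proportionally less dense shell at constant total mineral) lowers the
cross-sectional moments at matched BMD -- the phantom's stand-in for the
non-recovering "bone quality" component.

Every quantity the measurement pipeline estimates has a closed-form
ground-truth value recorded per subject and imaging day, which makes the
whole chain testable by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack_io import CalibratedStack, RESULT_COLUMNS

__all__ = [
    "VERTEBRAE",
    "CONTROL",
    "FASTING",
    "GrowthRates",
    "FastingEffect",
    "PhantomParams",
    "StudyDesign",
    "DayState",
    "subject_states",
    "generate_slice",
    "generate_stack",
    "generate_study",
    "study_ground_truth",
    "simulate_measurements",
    "annulus_map",
    "render_cross_section",
]

VERTEBRAE = ("L2", "L3", "L4")
CONTROL, FASTING = "control", "fasting"
_GROUP_CODE = {CONTROL: 0, FASTING: 1}

# rng stream tags (spawn-key offsets), fixed so regeneration is
# independent of iteration order
_TAG_SUBJECT, _TAG_IMAGING, _TAG_MEASURE = 0, 1000, 5000


@dataclass(frozen=True)
class GrowthRates:
    """Per-day fractional increase of each geometric/density parameter.

    Applied multiplicatively per day; over 14 days the defaults give a
    roughly linear-looking rise of all parameters, as seen in growing
    young rats.
    """

    semiaxes: float = 0.007
    thickness: float = 0.007
    height: float = 0.010
    cortical_density: float = 0.012
    cancellous_density: float = 0.015


@dataclass(frozen=True)
class FastingEffect:
    """Multipliers and decays describing the fasting intervention.

    During the fast, each growth rate g becomes g * mult (a negative
    density multiplier models net resorption).  After refeeding the
    relative deficit against the control trajectory decays geometrically
    per day by the given factor (1.0 = the deficit persists).  The
    redistribution term q accrues per fast day and persists afterwards:
    the cortical shell thickens to (1+q)*t with its density scaled down to
    conserve shell mineral, which lowers I_min and J at unchanged BMD.
    """

    density_growth_mult: float = -3.0
    geometry_growth_mult: float = 0.0
    density_recovery_decay: float = 0.3
    height_recovery_decay: float = 0.3
    width_recovery_decay: float = 1.0
    redistribution_rate: float = 0.2

    @classmethod
    def null(cls) -> "FastingEffect":
        """A neutral effect: fasting subjects are exchangeable with controls."""
        return cls(1.0, 1.0, 1.0, 1.0, 1.0, 0.0)


@dataclass(frozen=True)
class StudyDesign:
    """Two-cohort longitudinal design (days are integers from 0)."""

    n_control: int = 5
    n_fasting: int = 6
    total_days: int = 14
    fast_start_day: int = 0
    fast_end_day: int = 4
    imaging_days: tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12, 14)

    def validate(self) -> None:
        if self.n_control <= 0:
            raise ValueError("n_control must be positive")
        if self.n_fasting <= 0:
            raise ValueError("n_fasting must be positive")
        if not (0 <= self.fast_start_day < self.fast_end_day <= self.total_days):
            raise ValueError(
                "require 0 <= fast_start_day < fast_end_day <= total_days"
            )
        days = list(self.imaging_days)
        if days != sorted(set(days)) or not days:
            raise ValueError("imaging_days must be sorted and unique")
        if days[0] < 0 or days[-1] > self.total_days:
            raise ValueError("imaging_days must lie within [0, total_days]")

    @property
    def recovery_day(self) -> int:
        """First day at which the BMD deficit is considered recovered
        (four days after refeeding, matching the reported time course)."""
        return self.fast_end_day + 4

    def subjects(self) -> list[tuple[str, str, int]]:
        """(subject_id, group, within-group index) for every animal."""
        out = [(f"C{i + 1:02d}", CONTROL, i) for i in range(self.n_control)]
        out += [(f"F{i + 1:02d}", FASTING, i) for i in range(self.n_fasting)]
        return out


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, densities, imaging and variability of the phantom.

    Lengths in cm, densities in mg/cm^3.  ``outer_semiaxes`` is the
    (half-width, half-depth) of the mid-body cross-section of the middle
    vertebra; ``vertebra_scale`` scales L2/L3/L4 and ``taper`` tilts the
    within-vertebra cross-section linearly from superior to inferior so
    the superior and inferior diameters straddle the mid value.
    """

    outer_semiaxes: tuple[float, float] = (0.35, 0.28)
    cortical_thickness: float = 0.05
    body_height: float = 0.55
    cortical_density: float = 850.0
    cancellous_density_mean: float = 250.0
    cancellous_texture_sd: float = 30.0
    pixel_spacing: float = 0.01
    slice_interval_d: float = 0.1
    blur_sigma: float = 0.8
    noise_sd: float = 15.0
    growth_rates: GrowthRates = field(default_factory=GrowthRates)
    fasting_effect: FastingEffect = field(default_factory=FastingEffect)
    subject_size_cv: float = 0.01
    subject_density_cv: float = 0.03
    measurement_cv: float = 0.002
    taper: float = 0.06
    vertebra_scale: tuple[float, float, float] = (0.97, 1.0, 1.03)
    fov_cm: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        a, b = self.outer_semiaxes
        if min(a, b) <= 0 or self.cortical_thickness <= 0:
            raise ValueError("all lengths must be > 0")
        if self.cortical_thickness >= min(a, b):
            raise ValueError("cortical_thickness must be < min(outer_semiaxes)")
        if self.body_height <= 0 or self.pixel_spacing <= 0 or self.slice_interval_d <= 0:
            raise ValueError("all lengths must be > 0")
        if not self.cortical_density > self.cancellous_density_mean >= 0:
            raise ValueError("require cortical_density > cancellous_density_mean >= 0")
        if self.fov_cm < 2 * max(a, b):
            raise ValueError("fov_cm too small for the phantom cross-section")

    def noiseless(self, pixel_spacing: float | None = None) -> "PhantomParams":
        """Copy with imaging noise, blur, texture and subject jitter off."""
        return replace(
            self,
            blur_sigma=0.0,
            noise_sd=0.0,
            cancellous_texture_sd=0.0,
            subject_size_cv=0.0,
            subject_density_cv=0.0,
            measurement_cv=0.0,
            pixel_spacing=pixel_spacing or self.pixel_spacing,
        )

    def grid_size(self) -> int:
        return int(round(self.fov_cm / self.pixel_spacing))


@dataclass(frozen=True)
class DayState:
    """True geometry and density of one subject on one day."""

    day: int
    a: float
    b: float
    t: float
    h: float
    rho_cort: float
    rho_canc: float
    q: float

    @property
    def t_eff(self) -> float:
        """Shell thickness after the inward mineral redistribution."""
        return min(self.t * (1.0 + self.q), 0.9 * min(self.a, self.b))


def _rng(params: PhantomParams, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=params.seed, spawn_key=tuple(key))
    return np.random.default_rng(ss)


def _trajectory(
    v0: float,
    g: float,
    total_days: int,
    fasting: bool,
    fast_start: int,
    fast_end: int,
    mult: float,
    decay: float,
) -> np.ndarray:
    """Daily values of one quantity under multiplicative growth.

    Controls grow at (1+g) per day.  Fasting subjects grow at (1+g*mult)
    during the fast; afterwards the relative deficit against the control
    trajectory decays geometrically by ``decay`` per day.
    """
    days = np.arange(total_days + 1)
    control = v0 * (1.0 + g) ** days
    if not fasting:
        return control
    v = np.empty(total_days + 1)
    v[0] = v0
    for d in range(total_days):
        rate = g * mult if fast_start <= d < fast_end else g
        v[d + 1] = v[d] * (1.0 + rate)
    deficit_end = 1.0 - v[fast_end] / control[fast_end]
    for d in range(fast_end + 1, total_days + 1):
        v[d] = control[d] * (1.0 - deficit_end * decay ** (d - fast_end))
    return v


def subject_states(
    params: PhantomParams, design: StudyDesign, group: str, subject_index: int
) -> dict[int, DayState]:
    """Deterministic per-day true state of one subject, for all study days.

    Per-subject size and density scale factors come from an independent
    random substream derived from the master seed, so regeneration does not
    depend on iteration order.
    """
    params.validate()
    design.validate()
    fasting = group == FASTING
    rng = _rng(params, _GROUP_CODE[group], subject_index, _TAG_SUBJECT)
    size = 1.0 + params.subject_size_cv * rng.standard_normal()
    dens = 1.0 + params.subject_density_cv * rng.standard_normal()

    g = params.growth_rates
    eff = params.fasting_effect
    fs, fe, total = design.fast_start_day, design.fast_end_day, design.total_days
    a0, b0 = params.outer_semiaxes

    def traj(v0, rate, mult, decay):
        return _trajectory(v0, rate, total, fasting, fs, fe, mult, decay)

    a = traj(a0 * size, g.semiaxes, eff.geometry_growth_mult, eff.width_recovery_decay)
    b = traj(b0 * size, g.semiaxes, eff.geometry_growth_mult, eff.width_recovery_decay)
    # thickness growth pauses with the rest of the geometry during the
    # fast, keeping the shell area fraction (and hence composite BMD)
    # unbiased; the quality perturbation acts through q instead
    t = traj(params.cortical_thickness * size, g.thickness,
             eff.geometry_growth_mult, eff.width_recovery_decay)
    h = traj(params.body_height * size, g.height, eff.geometry_growth_mult,
             eff.height_recovery_decay)
    rc = traj(params.cortical_density * dens, g.cortical_density,
              eff.density_growth_mult, eff.density_recovery_decay)
    rn = traj(params.cancellous_density_mean * dens, g.cancellous_density,
              eff.density_growth_mult, eff.density_recovery_decay)

    states = {}
    for day in range(total + 1):
        q = eff.redistribution_rate * max(0, min(day, fe) - fs) if fasting else 0.0
        states[day] = DayState(
            day=day, a=float(a[day]), b=float(b[day]), t=float(t[day]),
            h=float(h[day]), rho_cort=float(rc[day]), rho_canc=float(rn[day]), q=q,
        )
    return states


# ---------------------------------------------------------------------------
# slice geometry


@dataclass(frozen=True)
class _SlicePlan:
    vertebra: str
    a: float
    b: float


def slice_plans(
    params: PhantomParams, state: DayState
) -> tuple[list[_SlicePlan], dict[str, tuple[int, int]]]:
    """Per-slice cross-section geometry and the vertebra label ranges."""
    plans: list[_SlicePlan] = []
    labels: dict[str, tuple[int, int]] = {}
    for name, vs in zip(VERTEBRAE, params.vertebra_scale):
        n = max(2, int(round(state.h * vs / params.slice_interval_d)))
        first = len(plans)
        for k in range(n):
            s = 1.0 + params.taper * (k / (n - 1) - 0.5)
            plans.append(_SlicePlan(name, state.a * vs * s, state.b * vs * s))
        labels[name] = (first, len(plans) - 1)
    return plans, labels


def _shell_area(a: float, b: float, t: float) -> float:
    return math.pi * (a * b - (a - t) * (b - t))


def _cortical_density_eff(a: float, b: float, state: DayState) -> tuple[float, float]:
    """(effective shell thickness, effective shell density) for one slice.

    The redistributed shell conserves mineral exactly: the thickened shell
    carries the nominal shell mineral plus the cancellous mineral of the
    annexed interior band, spread over the larger shell area, so the
    slice's total mineral content (and hence BMD) is unchanged while the
    mass distribution moves inward.
    """
    if state.q == 0.0:
        return state.t, state.rho_cort
    t_eff = min(state.t * (1.0 + state.q), 0.9 * min(a, b))
    t_nom = min(state.t, t_eff)
    area_nom = _shell_area(a, b, t_nom)
    area_eff = _shell_area(a, b, t_eff)
    rho = (state.rho_cort * area_nom + state.rho_canc * (area_eff - area_nom)) / area_eff
    return t_eff, rho


def render_cross_section(
    a: float,
    b: float,
    t: float,
    rho_cort: float,
    rho_canc: float,
    *,
    pixel_spacing: float,
    grid_size: int,
    texture_sd: float = 0.0,
    blur_sigma: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    rotation: float = 0.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render one elliptical shell cross-section as a density map.

    Pixels are classified by their center point: inside the outer ellipse
    but outside the inner (a-t, b-t) ellipse they carry the cortical
    density, inside the inner ellipse the cancellous density plus a
    smoothed Gaussian texture; background is exactly zero before blur and
    noise are applied.
    """
    n = grid_size
    ax = (np.arange(n) + 0.5) * pixel_spacing
    X, Y = np.meshgrid(ax, ax)
    cx, cy = center if center is not None else (n * pixel_spacing / 2.0,) * 2
    cr, sr = math.cos(rotation), math.sin(rotation)
    u = cr * (X - cx) + sr * (Y - cy)
    v = -sr * (X - cx) + cr * (Y - cy)
    outer = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    ai, bi = a - t, b - t
    inner = (u / ai) ** 2 + (v / bi) ** 2 <= 1.0 if min(ai, bi) > 0 else np.zeros_like(outer)

    img = np.zeros((n, n))
    img[outer & ~inner] = rho_cort
    img[inner] = rho_canc
    if texture_sd > 0:
        if rng is None:
            raise ValueError("texture requires an rng stream")
        fluct = gaussian_filter(rng.standard_normal((n, n)), 2.0)
        sd = fluct.std()
        if sd > 0:
            img[inner] += (texture_sd / sd) * fluct[inner]
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an rng stream")
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def generate_slice(
    params: PhantomParams,
    state: DayState,
    slice_index: int,
    rng: np.random.Generator,
    *,
    rotation: float = 0.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Density map of one slice; all-zero (flagged empty) outside the body."""
    plans, _ = slice_plans(params, state)
    n = params.grid_size()
    if not 0 <= slice_index < len(plans):
        return np.zeros((n, n))
    p = plans[slice_index]
    t_eff, rho_eff = _cortical_density_eff(p.a, p.b, state)
    return render_cross_section(
        p.a, p.b, t_eff, rho_eff, state.rho_canc,
        pixel_spacing=params.pixel_spacing, grid_size=n,
        texture_sd=params.cancellous_texture_sd,
        blur_sigma=params.blur_sigma, noise_sd=params.noise_sd,
        rng=rng, rotation=rotation, center=center,
    )


def generate_stack(
    params: PhantomParams,
    state: DayState,
    rng: np.random.Generator,
    *,
    rotation: float = 0.0,
    center: tuple[float, float] | None = None,
) -> CalibratedStack:
    """Render the full L2-L4 stack of one subject on one day."""
    plans, labels = slice_plans(params, state)
    slices = [
        generate_slice(params, state, i, rng, rotation=rotation, center=center)
        for i in range(len(plans))
    ]
    return CalibratedStack(
        slices=np.stack(slices),
        pixel_spacing=params.pixel_spacing,
        slice_interval_d=params.slice_interval_d,
        vertebra_labels=labels,
    )


def iter_study_stacks(
    params: PhantomParams, design: StudyDesign
) -> Iterator[tuple[str, str, int, CalibratedStack]]:
    """Yield (subject_id, group, day, stack) for every subject and imaging day.

    Imaging noise uses an independent substream per (subject, day), so any
    single stack can be regenerated bit-identically in isolation.
    """
    params.validate()
    design.validate()
    for subject_id, group, idx in design.subjects():
        states = subject_states(params, design, group, idx)
        for day in design.imaging_days:
            rng = _rng(params, _GROUP_CODE[group], idx, _TAG_IMAGING + day)
            yield subject_id, group, day, generate_stack(params, states[day], rng)


def generate_study(
    params: PhantomParams, design: StudyDesign
) -> tuple[dict[str, dict[int, CalibratedStack]], pd.DataFrame]:
    """In-memory study: per-subject per-day stacks plus the ground truth."""
    stacks: dict[str, dict[int, CalibratedStack]] = {}
    for subject_id, _group, day, stack in iter_study_stacks(params, design):
        stacks.setdefault(subject_id, {})[day] = stack
    return stacks, study_ground_truth(params, design)


# ---------------------------------------------------------------------------
# analytic ground truth


def _ellipse_ix(a: float, b: float) -> float:
    """Second moment of a unit-density ellipse about its horizontal axis."""
    return math.pi * a * b**3 / 4.0


def analytic_morphometry(params: PhantomParams, state: DayState) -> dict[str, float]:
    """Closed-form per-animal morphometry of the phantom on one day.

    Moments follow the same slice-averaging convention the measurement
    pipeline uses; the composite per-slice moments combine the shell and
    interior ellipse integrals.
    """
    plans, labels = slice_plans(params, state)
    d = params.slice_interval_d
    areas, minerals, imins, polars = [], [], [], []
    for p in plans:
        t_eff, rho_sh = _cortical_density_eff(p.a, p.b, state)
        ai, bi = p.a - t_eff, p.b - t_eff
        area = math.pi * p.a * p.b
        area_in = math.pi * ai * bi
        minerals.append(rho_sh * (area - area_in) + state.rho_canc * area_in)
        ix = rho_sh * (_ellipse_ix(p.a, p.b) - _ellipse_ix(ai, bi))
        ix += state.rho_canc * _ellipse_ix(ai, bi)
        iy = rho_sh * (_ellipse_ix(p.b, p.a) - _ellipse_ix(bi, ai))
        iy += state.rho_canc * _ellipse_ix(bi, ai)
        areas.append(area)
        imins.append(min(ix, iy))
        polars.append(ix + iy)
    volume = d * sum(areas)
    mineral = d * sum(minerals)
    heights, widths = [], []
    for name, vs in zip(VERTEBRAE, params.vertebra_scale):
        first, last = labels[name]
        heights.append((last - first + 1) * d * 10.0)
        widths.append((plans[first].a + plans[last].a) * 10.0)  # mean of 2a at ends
    return {
        "bmd": mineral / volume,
        "mineral_content": mineral,
        "volume": volume,
        "cortical_thickness": state.t_eff * 10.0,
        "body_height": float(np.mean(heights)),
        "body_width": float(np.mean(widths)),
        "min_moment": float(np.mean(imins)),
        "polar_moment": float(np.mean(polars)),
    }


def study_ground_truth(params: PhantomParams, design: StudyDesign) -> pd.DataFrame:
    """One ground-truth record per (subject, imaging day)."""
    params.validate()
    design.validate()
    rows = []
    for subject_id, group, idx in design.subjects():
        states = subject_states(params, design, group, idx)
        for day in design.imaging_days:
            rec = {"subject_id": subject_id, "group": group, "day": day}
            rec.update(analytic_morphometry(params, states[day]))
            rows.append(rec)
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def simulate_measurements(params: PhantomParams, design: StudyDesign) -> pd.DataFrame:
    """A StudyTable drawn from the generator's measurement model.

    Each measured value is the analytic ground truth times an independent
    multiplicative Gaussian error of CV ``measurement_cv``, emulating the
    repeat-scan precision of the imaging chain without rendering images.
    """
    truth = study_ground_truth(params, design)
    out = truth.copy()
    value_cols = [c for c in RESULT_COLUMNS if c not in ("subject_id", "group", "day")]
    for subject_id, group, idx in design.subjects():
        for day in design.imaging_days:
            rng = _rng(params, _GROUP_CODE[group], idx, _TAG_MEASURE + day)
            sel = (out["subject_id"] == subject_id) & (out["day"] == day)
            noise = 1.0 + params.measurement_cv * rng.standard_normal(len(value_cols))
            out.loc[sel, value_cols] = out.loc[sel, value_cols].to_numpy() * noise
    return out


# ---------------------------------------------------------------------------
# simple reference objects


def annulus_map(
    outer_radius: float = 0.40,
    inner_radius: float = 0.30,
    density: float = 300.0,
    pixel_spacing: float = 0.005,
    margin: float = 0.05,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Uniform-density circular annulus and its center, for oracle checks."""
    half = outer_radius + margin
    n = int(round(2 * half / pixel_spacing))
    ax = (np.arange(n) + 0.5) * pixel_spacing
    X, Y = np.meshgrid(ax, ax)
    c = n * pixel_spacing / 2.0
    r2 = (X - c) ** 2 + (Y - c) ** 2
    img = np.zeros((n, n))
    img[(r2 <= outer_radius**2) & (r2 >= inner_radius**2)] = density
    return img, (c, c)
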