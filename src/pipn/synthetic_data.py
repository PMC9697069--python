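"""Synthetic-data generators with known ground truth for all three arms.

Every generator is a pure function of its parameters and seed.

* :func:`generate_reports` emulates a spontaneous-report universe: each
  report independently lists the target drug (paclitaxel), then — if it
  does — the concomitant exposure drug, and acquires case status with odds
  equal to the baseline odds times ``exposure_odds_multiplier`` when
  exposed.  Case status is generated on the odds scale so that the
  multiplier is exactly the estimand of the reporting odds ratio under
  non-differential reporting, making parameter recovery a clean check.
  Decoy drugs and events are attached independently of case status (no
  confounding) from a random stream separate from the core draws, so the
  realized 2x2 table is identical with or without them.

* :func:`generate_updown_session` simulates the von Frey staircase with a
  logistic psychometric function in log10 force.

* :func:`generate_nerve_cross_section` lays non-overlapping fibers in a
  square field; at degeneration level 0 every boundary is a regular 64-gon
  circle approximation, and increasing degeneration adds smooth radial
  perturbation (boundary irregularity) and inflates the g-ratio toward 1
  (myelin thinning).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from pipn.disproportionality import ContingencyTable
from pipn.errors import ValidationError
from pipn.morphometry import FiberGeometry
from pipn.report_model import AdverseEventReport, ReportSet
from pipn.vonfrey import DEFAULT_FILAMENTS_G, UpDownSession, _truncate

logger = logging.getLogger(__name__)

TARGET_DRUG = "paclitaxel"
EXPOSURE_DRUG = "tamsulosin"
CASE_TERMS = (
    "peripheral neuropathy",
    "peripheral sensory neuropathy",
    "peripheral sensorimotor neuropathy",
)


# --------------------------------------------------------------------------
# adverse-event reports
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticReportParams:
    """Parameters of the synthetic report universe.

    Defaults emulate the paclitaxel stratum of a large spontaneous-report
    database: a ~4.6% background PIPN reporting rate among unexposed
    paclitaxel reports and a concomitant-exposure prevalence of 10%, with
    the null multiplier 1.0.
    """

    n_reports: int = 20_000
    p_target_drug: float = 0.5
    p_exposed_given_target: float = 0.10
    baseline_event_prob: float = 0.0458
    exposure_odds_multiplier: float = 1.0
    n_decoy_drugs: int = 20
    n_decoy_events: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValidationError("n_reports must be >= 1")
        for name in ("p_target_drug", "p_exposed_given_target", "baseline_event_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.exposure_odds_multiplier <= 0:
            raise ValidationError("exposure_odds_multiplier must be > 0")
        if self.baseline_event_prob >= 1 and self.exposure_odds_multiplier != 1:
            raise ValidationError(
                "baseline_event_prob = 1 with a multiplier != 1 pushes the exposed odds "
                "out of range"
            )
        if self.n_decoy_drugs < 1 or self.n_decoy_events < 0:
            raise ValidationError("need >=1 decoy drug (non-target reports must list a drug)")


@dataclass(frozen=True)
class ReportGroundTruth:
    """Realized counts of the generated universe (paclitaxel stratum)."""

    table: ContingencyTable
    n_target: int
    true_odds_multiplier: float


def _exposed_event_prob(p0: float, multiplier: float) -> float:
    if p0 == 0:
        return 0.0
    if p0 == 1:
        return 1.0
    odds = p0 / (1 - p0) * multiplier
    return odds / (1 + odds)


def _core_draws(params: SyntheticReportParams, rng: np.random.Generator):
    """Vectorized target/exposure/case indicators for every report."""
    n = params.n_reports
    is_target = rng.random(n) < params.p_target_drug
    exposed = is_target & (rng.random(n) < params.p_exposed_given_target)
    p1 = _exposed_event_prob(params.baseline_event_prob, params.exposure_odds_multiplier)
    u = rng.random(n)
    case = is_target & np.where(exposed, u < p1, u < params.baseline_event_prob)
    return is_target, exposed, case


def _ground_truth(params, is_target, exposed, case) -> ReportGroundTruth:
    n11 = int(np.sum(exposed & case))
    n12 = int(np.sum(exposed & ~case & is_target))
    n21 = int(np.sum(~exposed & case & is_target))
    n22 = int(np.sum(~exposed & ~case & is_target))
    if n11 + n12 + n21 + n22 == 0:
        raise ValidationError("no reports list the target drug (empty stratum)")
    return ReportGroundTruth(
        ContingencyTable(n11, n12, n21, n22),
        n_target=int(is_target.sum()),
        true_odds_multiplier=params.exposure_odds_multiplier,
    )


def realized_contingency(params: SyntheticReportParams) -> ReportGroundTruth:
    """The realized 2x2 table of the universe, without materializing reports.

    Uses the same core random stream as :func:`generate_reports`, so the
    counts equal what ``build_contingency`` would return on the full
    generated :class:`~pipn.report_model.ReportSet`.
    """
    core_rng, _ = _spawn_rngs(params.seed)
    return _ground_truth(params, *_core_draws(params, core_rng))


def _spawn_rngs(seed: int):
    core_ss, decoy_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(core_ss), np.random.default_rng(decoy_ss)


def generate_reports(params: SyntheticReportParams) -> tuple[ReportSet, ReportGroundTruth]:
    """Generate a report universe and its realized ground-truth counts."""
    core_rng, decoy_rng = _spawn_rngs(params.seed)
    is_target, exposed, case = _core_draws(params, core_rng)
    truth = _ground_truth(params, is_target, exposed, case)

    n = params.n_reports
    decoy_drugs = [f"drug_{i:03d}" for i in range(params.n_decoy_drugs)]
    decoy_events = [f"event_{i:03d}" for i in range(params.n_decoy_events)]
    # decoy attachment is independent of case status (no confounding)
    n_extra_drugs = decoy_rng.poisson(1.0, size=n)
    n_extra_events = decoy_rng.poisson(0.7, size=n) if decoy_events else np.zeros(n, int)
    case_term_idx = decoy_rng.integers(0, len(CASE_TERMS), size=n)

    reports = []
    width = len(str(n))
    for i in range(n):
        drugs = set()
        if is_target[i]:
            drugs.add(TARGET_DRUG)
        if exposed[i]:
            drugs.add(EXPOSURE_DRUG)
        k = n_extra_drugs[i] + (0 if drugs else 1)  # every report lists >=1 drug
        if k:
            drugs.update(decoy_rng.choice(decoy_drugs, size=min(k, len(decoy_drugs)), replace=False))
        events = set()
        if case[i]:
            events.add(CASE_TERMS[case_term_idx[i]])
        ke = n_extra_events[i]
        if ke and decoy_events:
            events.update(decoy_rng.choice(decoy_events, size=min(ke, len(decoy_events)), replace=False))
        reports.append(AdverseEventReport(f"r{i:0{width}d}", frozenset(drugs), frozenset(events)))
    rs = ReportSet(reports, provenance=f"synthetic seed={params.seed}")
    return rs, truth


# --------------------------------------------------------------------------
# von Frey staircases
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UpDownSimParams:
    """Psychometric simulation of one up-down session.

    ``slope`` is the steepness of the logistic response curve on the log10
    force scale (response probability 0.5 at the true threshold); large
    slopes make responses near-deterministic.
    """

    true_threshold_g: float = 2.0
    slope: float = 8.0
    filament_forces_g: tuple[float, ...] = DEFAULT_FILAMENTS_G
    max_trials: int = 9
    n_after_reversal: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        forces = np.asarray(self.filament_forces_g, dtype=float)
        if forces.ndim != 1 or len(forces) < 2 or not np.all(np.diff(forces) > 0):
            raise ValidationError("filament_forces_g must be strictly increasing")
        if np.any(forces <= 0) or self.true_threshold_g <= 0:
            raise ValidationError("forces and threshold must be positive")
        if self.slope <= 0:
            raise ValidationError("slope must be positive")
        object.__setattr__(self, "filament_forces_g", tuple(float(f) for f in forces))


def generate_updown_session(params: UpDownSimParams, session_id: str = "s0") -> UpDownSession:
    """Simulate one staircase, starting at the mid-series filament.

    A positive (withdrawal) response steps down one filament, a negative
    response steps up; steps beyond the series clamp at the boundary
    filament.  Trials stop four trials after the first reversal or at
    ``max_trials``.
    """
    rng = np.random.default_rng(params.seed)
    log_forces = np.log10(np.asarray(params.filament_forces_g))
    mu = math.log10(params.true_threshold_g)
    idx = (len(log_forces) - 1) // 2
    trials: list[tuple[float, bool]] = []
    first_rev: int | None = None
    while True:
        x = log_forces[idx]
        p = float(expit(params.slope * (x - mu)))
        resp = bool(rng.random() < p)
        trials.append((float(x), resp))
        i = len(trials) - 1
        if first_rev is None and i >= 1 and trials[i][1] != trials[i - 1][1]:
            first_rev = i
        done_by_reversal = first_rev is not None and len(trials) >= first_rev + 1 + params.n_after_reversal
        if done_by_reversal or len(trials) >= params.max_trials:
            break
        idx = max(0, idx - 1) if resp else min(len(log_forces) - 1, idx + 1)
    return UpDownSession(session_id, trials, log_forces.tolist())


# --------------------------------------------------------------------------
# nerve cross-sections
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NerveSynthParams:
    """Geometry of a synthetic nerve cross-section.

    Fiber diameters are lognormal with the given mean and SD (in um);
    g-ratios normal truncated to (0, 1).  ``degeneration_level`` in [0, 1]
    scales both the smooth radial boundary perturbation and the myelin
    thinning (g-ratio inflated toward 1); level 0 yields perfect regular
    64-gon circles.
    """

    n_fibers: int = 100
    fiber_diameter_mean_um: float = 8.0
    fiber_diameter_sd_um: float = 2.0
    g_ratio_mean: float = 0.6
    g_ratio_sd: float = 0.05
    degeneration_level: float = 0.0
    field_size_um: float = 120.0
    n_vertices: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValidationError("n_fibers must be >= 1")
        if not 0 <= self.degeneration_level <= 1:
            raise ValidationError("degeneration_level must be in [0, 1]")
        if not 0 < self.g_ratio_mean < 1:
            raise ValidationError("g_ratio_mean must be in (0, 1)")
        if min(self.fiber_diameter_mean_um, self.field_size_um) <= 0 or self.fiber_diameter_sd_um < 0:
            raise ValidationError("diameters and field size must be positive")
        if self.n_vertices < 8:
            raise ValidationError("n_vertices must be >= 8")


# myelin thinning: fraction of the remaining (1 - g) closed at level 1
_THINNING_GAIN = 0.5
# radial perturbation amplitude (fraction of radius) at level 1
_PERTURB_GAIN = 0.25


def _perturbed_ring(rng, center, base_radius, amplitude, theta) -> np.ndarray:
    """Closed polygon with a smooth low-order radial perturbation."""
    if amplitude == 0:
        r = np.full_like(theta, base_radius)
    else:
        s = np.zeros_like(theta)
        for m in range(2, 6):
            s += rng.normal() * np.cos(m * theta) + rng.normal() * np.sin(m * theta)
        s /= max(np.abs(s).max(), 1e-12)
        r = base_radius * (1 + amplitude * s)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def generate_nerve_cross_section(params: NerveSynthParams) -> list[FiberGeometry]:
    """Place non-overlapping fibers and return their polygon geometry.

    Placement is rejection sampling on circumscribing circles; if the
    requested density cannot be met within a bounded number of attempts the
    shortfall is logged and fewer fibers are returned (never an infinite
    loop).
    """
    rng = np.random.default_rng(params.seed)
    mean, sd = params.fiber_diameter_mean_um, params.fiber_diameter_sd_um
    if sd > 0:
        sigma2 = math.log(1 + (sd / mean) ** 2)
        mu_ln = math.log(mean) - sigma2 / 2
        diameters = rng.lognormal(mu_ln, math.sqrt(sigma2), size=params.n_fibers)
    else:
        diameters = np.full(params.n_fibers, mean)

    level = params.degeneration_level
    margin = 1 + _PERTURB_GAIN * level  # worst-case outward perturbation
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 200 * params.n_fibers
    attempts = 0
    for d in diameters:
        r = d / 2
        placed = False
        while attempts < max_attempts:
            attempts += 1
            bound = r * margin
            if 2 * bound >= params.field_size_um:
                break  # fiber cannot fit at all
            c = rng.uniform(bound, params.field_size_um - bound, size=2)
            if all(
                math.hypot(c[0] - cx, c[1] - cy) > (r + rr) * margin * 1.02
                for (cx, cy), rr in zip(centers, radii)
            ):
                centers.append((float(c[0]), float(c[1])))
                radii.append(float(r))
                placed = True
                break
        if not placed and attempts >= max_attempts:
            break
    if len(centers) < params.n_fibers:
        logger.warning(
            "placed %d of %d fibers (field too dense)", len(centers), params.n_fibers
        )

    theta = np.linspace(0, 2 * math.pi, params.n_vertices, endpoint=False)
    fibers = []
    for i, (center, r) in enumerate(zip(centers, radii)):
        g = rng.normal(params.g_ratio_mean, params.g_ratio_sd) if params.g_ratio_sd > 0 else params.g_ratio_mean
        g = min(max(g, 1e-3), 1 - 1e-3)
        g_eff = g + _THINNING_GAIN * level * (1 - g)  # myelin thinning
        outer = _perturbed_ring(rng, center, r, _PERTURB_GAIN * level, theta)
        inner = _perturbed_ring(rng, center, g_eff * r, _PERTURB_GAIN * level, theta)
        # keep the axon strictly inside the fiber under perturbation
        outer_r = np.hypot(outer[:, 0] - center[0], outer[:, 1] - center[1])
        inner_r = np.hypot(inner[:, 0] - center[0], inner[:, 1] - center[1])
        shrink = np.minimum(1.0, 0.97 * outer_r / inner_r)
        inner = np.column_stack(
            [center[0] + inner_r * shrink * np.cos(theta), center[1] + inner_r * shrink * np.sin(theta)]
        )
        fibers.append(FiberGeometry(f"fiber_{i + 1:04d}", outer, inner))
    return fibers


def rasterize_fibers(
    fibers: Sequence[FiberGeometry], pixel_size_um: float, field_size_um: float
) -> np.ndarray:
    """Integer label mask of the fibers (axon = 2k, myelin = 2k+1, k >= 1).

    Rasterization is a lossy export of the exact polygon geometry.
    """
    from skimage.draw import polygon as draw_polygon

    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    size = int(round(field_size_um / pixel_size_um))
    mask = np.zeros((size, size), dtype=np.int32)
    for k, f in enumerate(fibers, start=1):
        for verts, label in ((f.outer, 2 * k + 1), (f.inner, 2 * k)):
            rr, cc = draw_polygon(verts[:, 1] / pixel_size_um, verts[:, 0] / pixel_size_um, mask.shape)
            mask[rr, cc] = label
    return mask
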