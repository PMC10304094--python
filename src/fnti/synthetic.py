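"""Synthetic cohorts and geometric scenes with known ground truth.

Two generators make the whole pipeline testable without any radiographs:

* :func:`generate_cohort` draws per-grade "true" FNTi values from truncated
  normal distributions whose defaults match the study cohort structure —
  five FCI grades with (mean, SD, n) of (0.809, 0.024, 19), (0.835, 0.044,
  23), (0.868, 0.022, 24), (0.903, 0.033, 24) and (0.923, 0.068, 16), 106
  hips in total, truncated to (0.70, 1.05) to cover the observed global
  range (0.757–1.036).  :func:`apply_examiner` then adds an
  additive examiner/session error (bias + homoscedastic Gaussian noise)
  calibrated so the session-1 − session-2 differences of examiner 1 have
  SD ≈ 0.019 with mean ≈ −0.001, and the examiner-1 − examiner-2
  differences have SD ≈ 0.021 with mean ≈ −0.007.

* :func:`generate_scene` builds a landmark-level hip annotation (no pixels)
  with exactly known femoral head diameter, neck thickness and Norberg
  angle, optionally perturbed by Gaussian landmark jitter, so the geometry
  code can be validated against ground truth.

All randomness flows from a single seed through numpy ``SeedSequence``
spawning, so every generator is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import HipAnnotation, Margin, Point2D

#: study cohort structure: grade -> (mean FNTi, SD, n hips)
DEFAULT_GRADE_PARAMS: dict[str, tuple[float, float, int]] = {
    "A": (0.809, 0.024, 19),
    "B": (0.835, 0.044, 23),
    "C": (0.868, 0.022, 24),
    "D": (0.903, 0.033, 24),
    "E": (0.923, 0.068, 16),
}

#: FNTi truncation bounds covering the observed global min/max
DEFAULT_TRUNCATION: tuple[float, float] = (0.70, 1.05)


@dataclass(frozen=True)
class ExaminerModel:
    """Additive measurement-error model: observed = true + bias + N(0, sd).

    ``heteroscedasticity`` (default 0 = homoscedastic) inflates the noise SD
    proportionally for thicker necks — sd_i = noise_sd * (1 + h * (true_i −
    0.86)) — emulating the harder delineation of modelled, osteophyte-laden
    contours at high FNTi.
    """

    bias: float
    noise_sd: float
    heteroscedasticity: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# Calibration: intra-examiner difference SD 0.019 => per-session noise
# 0.019/sqrt(2); inter-examiner difference SD 0.021 => examiner-2 noise
# sqrt(0.021^2 - 0.019^2/2).  Biases reproduce difference means -0.001
# (E1S1-E1S2) and -0.007 (E1S1-E2) under the first-minus-second convention.
_E1_NOISE = 0.019 / math.sqrt(2.0)
_E2_NOISE = math.sqrt(0.021**2 - 0.019**2 / 2.0)

DEFAULT_EXAMINER_MODELS: dict[tuple[str, str], ExaminerModel] = {
    ("E1", "S1"): ExaminerModel(bias=0.0, noise_sd=_E1_NOISE),
    ("E1", "S2"): ExaminerModel(bias=0.001, noise_sd=_E1_NOISE),
    ("E2", "S1"): ExaminerModel(bias=0.007, noise_sd=_E2_NOISE),
}


@dataclass
class SyntheticCohortConfig:
    grade_params: Mapping[str, tuple[float, float, int]] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_PARAMS)
    )
    truncation: tuple[float, float] = DEFAULT_TRUNCATION
    examiner_models: Mapping[tuple[str, str], ExaminerModel] = field(
        default_factory=lambda: dict(DEFAULT_EXAMINER_MODELS)
    )
    #: correlation between the two hips of one dog (default 0: independent)
    intra_dog_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.truncation
        if not lo < hi:
            raise ValueError("truncation interval must satisfy lo < hi")
        if not 0.0 <= self.intra_dog_correlation < 1.0:
            raise ValueError("intra_dog_correlation must lie in [0, 1)")
        for grade, (mu, sigma, n) in self.grade_params.items():
            if sigma <= 0:
                raise ValueError(f"grade {grade}: sigma must be > 0")
            if not lo < mu < hi:
                raise ValueError(f"grade {grade}: mean must lie inside the truncation interval")
            if n < 1:
                raise ValueError(f"grade {grade}: n must be >= 1")


def _truncnorm_loc_scale(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    """Location/scale of a truncated normal whose mean and SD equal (mu, sigma).

    The configured per-grade moments are the *observed* moments of the
    bounded index, so the generator moment-matches: when the bounds bite
    (within ~6 sigma), solve for the pre-truncation (loc, scale) whose
    truncated distribution has exactly the requested mean and SD.
    """
    if lo < mu - 6 * sigma and hi > mu + 6 * sigma:
        return mu, sigma  # truncation negligible

    def moments(p):
        loc, scale = p
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mu, math.sqrt(v) - sigma]

    sol = optimize.root(moments, x0=[mu, sigma])
    if not sol.success:  # pragma: no cover - well-conditioned for sane configs
        raise ValueError(f"cannot moment-match truncated normal for mu={mu}, sigma={sigma}")
    return float(sol.x[0]), float(sol.x[1])


def generate_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Draw per-grade true FNTi values (truncated normal), one row per hip.

    Returns a frame with columns ``hip_id``, ``dog_id``, ``grade``,
    ``true_fnti``; grade counts are exactly as configured, every value
    respects the truncation bounds, and each grade's distribution has the
    configured mean and SD (moment-matched under truncation).
    """
    lo, hi = config.truncation
    rho = config.intra_dog_correlation
    streams = np.random.SeedSequence(config.seed).spawn(len(config.grade_params))
    frames = []
    for (grade, (mu, sigma, n)), ss in zip(sorted(config.grade_params.items()), streams):
        rng = np.random.default_rng(ss)
        loc, scale = _truncnorm_loc_scale(mu, sigma, lo, hi)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        if rho == 0.0:
            vals = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
        else:
            # two hips of one dog share a dog effect; truncation by rejection
            dog = np.repeat(rng.normal(0.0, 1.0, (n + 1) // 2), 2)[:n]
            vals = loc + scale * (math.sqrt(rho) * dog + math.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, n))
            bad = (vals < lo) | (vals > hi)
            while bad.any():
                vals[bad] = loc + scale * (
                    math.sqrt(rho) * dog[bad] + math.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, bad.sum())
                )
                bad = (vals < lo) | (vals > hi)
        assert np.all((vals >= lo) & (vals <= hi)), "truncation bounds violated"
        frames.append(
            pd.DataFrame(
                {
                    "hip_id": [f"{grade}{i:04d}" for i in range(n)],
                    "dog_id": [f"{grade}d{i // 2:03d}" for i in range(n)],
                    "grade": grade,
                    "true_fnti": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def apply_examiner(
    truth: pd.DataFrame,
    examiner_models: Mapping[tuple[str, str], ExaminerModel] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn true FNTi values into observed measurements per examiner/session.

    observed = true + bias_e + eps, eps ~ N(0, noise_sd_e), independently
    per hip and per examiner/session stream.
    """
    models = dict(DEFAULT_EXAMINER_MODELS) if examiner_models is None else dict(examiner_models)
    if not models:
        raise ValueError("no examiner models given")
    streams = np.random.SeedSequence(seed).spawn(len(models))
    frames = []
    for ((examiner, session), model), ss in zip(sorted(models.items()), streams):
        rng = np.random.default_rng(ss)
        if model.noise_sd > 0:
            sd = model.noise_sd * (
                1.0 + model.heteroscedasticity * (truth["true_fnti"].to_numpy() - 0.86)
            )
            eps = rng.normal(0.0, 1.0, size=len(truth)) * np.clip(sd, 0.0, None)
        else:
            eps = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "hip_id": truth["hip_id"].to_numpy(),
                    "grade": truth["grade"].to_numpy(),
                    "examiner": examiner,
                    "session": session,
                    "fnti": truth["true_fnti"].to_numpy() + model.bias + eps,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SceneConfig:
    """Ground-truth parameters for one synthetic landmark scene."""

    fhd: float = 31.5
    fnt: float = 28.7
    na: float = 105.0
    jitter_sd: float = 0.0
    n_boundary_points: int = 24
    n_margin_points: int = 8
    #: how far the margins flare away from the waist toward head and shaft
    neck_flare: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fnt < 1.2 * self.fhd:
            raise ValueError("need 0 < fnt < 1.2 * fhd for a feasible neck")
        if not 0.0 < self.na < 180.0:
            raise ValueError("na must lie in (0, 180)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_boundary_points < 3 or self.n_margin_points < 2:
            raise ValueError("too few landmark points")


@dataclass
class SceneTruth:
    fhd: float
    fnt: float
    fnti: float
    na: float
    head_centre: Point2D


def generate_scene(
    config: SceneConfig, dog_id: str = "synthetic", side: str = "left"
) -> tuple[HipAnnotation, SceneTruth]:
    """Build a landmark annotation with exactly known FHd, FNT and NA.

    Head-boundary points lie on a circle of diameter ``fhd`` centred at
    (60, 60).  The neck margins are two waisted polylines below the head —
    the neck is narrowest directly below the head and flares toward the
    head and the shaft — built so their minimal separation is exactly
    ``fnt`` at the waist vertex pair.  The contralateral head centre sits
    medially and the rim point realizes the requested Norberg angle.
    Gaussian jitter of SD ``jitter_sd`` is then added to boundary and
    margin landmarks (truth records the noiseless values).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    r = config.fhd / 2.0
    cx, cy = 60.0, 60.0

    theta = np.linspace(0.0, 2.0 * math.pi, config.n_boundary_points, endpoint=False)
    boundary = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])

    # waisted neck margins: parabolic flare c(y) about the waist; sampling
    # always includes the waist vertex so the polyline minimum is exact
    y0, y1 = cy + 0.9 * r, cy + 2.2 * r
    y_waist = (y0 + y1) / 2.0
    ys = np.unique(np.concatenate([np.linspace(y0, y1, config.n_margin_points), [y_waist]]))
    flare = config.neck_flare * ((ys - y_waist) / ((y1 - y0) / 2.0)) ** 2
    prox = np.column_stack([cx - config.fnt / 2.0 - flare, ys])
    dist = np.column_stack([cx + config.fnt / 2.0 + flare, ys])

    if config.jitter_sd > 0:
        boundary = boundary + rng.normal(0.0, config.jitter_sd, boundary.shape)
        prox = prox + rng.normal(0.0, config.jitter_sd, prox.shape)
        dist = dist + rng.normal(0.0, config.jitter_sd, dist.shape)

    # contralateral head centre medially along -x; rim at the requested NA
    contra = Point2D(cx - 3.0 * config.fhd, cy)
    phi = math.radians(config.na)
    rim = Point2D(
        cx + 0.8 * r * (-math.cos(phi)),
        cy + 0.8 * r * (-math.sin(phi)),
    )

    annotation = HipAnnotation(
        dog_id=dog_id,
        side=side,
        head_boundary=boundary,
        proximal_margin=Margin(prox),
        distal_margin=Margin(dist),
        rim_point=rim,
        contra_head_centre=contra,
    )
    truth = SceneTruth(
        fhd=config.fhd,
        fnt=config.fnt,
        fnti=config.fnt / config.fhd,
        na=config.na,
        head_centre=Point2D(cx, cy),
    )
    return annotation, truth
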