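"""Procedural synthetic fundus phantoms with exact ground truth.

Real fundus cohorts and GAN outputs are not redistributable, so every
downstream stage in this package is exercised on procedurally generated
fundus-like images for which the truth is known *exactly*:

* a circular retina of uniform background level ``b`` on a dark frame,
* a bright optic disc and a gently darkened macula,
* a branching dark-vessel tree grown by a recursive random walk from the
  disc rim, rendered as a top-hat profile of intensity ``b - c`` with a
  known per-pixel mask and per-branch centreline/half-width,
* additive Gaussian pixel noise of known standard deviation ``sigma``.

With the top-hat profile the zone-B SNR of every vessel point is
analytically ``(b - c) / sigma``, which makes the whole measurement chain
verifiable to a few percent.  The module also simulates clustered binary
reader responses for image-Turing-test analysis: a logistic model with
Gaussian reader and image random effects on the logit scale, the same
correlation structure a GEE analysis of a reader study assumes.

Default intensity levels place the analytic SNR at 1.7, the operating
regime reported for real fundus cohorts.

All randomness flows from one master seed through counter-based
``numpy.random.SeedSequence`` substreams, so cohorts are bit-reproducible
regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit, logit

from .preprocessing import FundusImage, save_image
from .vessel_metrics import DiscGeometry

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "ReaderProfile",
    "ConfigurationError",
    "generate_fundus",
    "generate_cohorts",
    "simulate_reader_responses",
    "default_reader_panel",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "id", "cohort", "path_image", "path_mask",
    "disc_row", "disc_col", "disc_diameter",
    "b", "c", "sigma", "expected_snr", "vessel_pixel_count",
]


class ConfigurationError(ValueError):
    """Generator geometry or levels violate the config invariants."""


@dataclass
class SynthConfig:
    """Parameters of one synthetic fundus image.

    Geometry fields left at ``None`` are resolved as fixed fractions of
    ``image_size`` (retina radius 0.47, disc diameter 0.117 with the disc
    at 0.71 of the frame width on the horizontal midline, macula on the
    opposite side), so one config scales coherently to any frame size.

    Intensities are on the [0, 1] scale: ``background_level`` b is the
    retina background, vessels render at ``b - vessel_contrast``,
    ``noise_sigma`` is the additive Gaussian noise std.  With
    ``edge_blur = 0`` (top-hat profile) the analytic zone-B SNR is
    ``(b - c) / sigma``.
    """

    image_size: int = 1024
    retina_radius: float | None = None
    background_level: float = 0.60
    disc_center: tuple[float, float] | None = None
    disc_diameter: float | None = None
    disc_level: float = 0.88
    macula_center: tuple[float, float] | None = None
    macula_radius: float | None = None
    macula_darkening: float = 0.05
    n_root_vessels: int = 4
    branch_probability: float = 0.015
    initial_half_width: float = 4.0
    width_taper: float = 0.8
    tortuosity: float = 0.05
    vessel_contrast: float = 0.26
    noise_sigma: float = 0.20
    edge_blur: float = 0.0
    seed: int = 0

    def resolved(self) -> "SynthConfig":
        """Return a copy with all geometry defaults made concrete."""
        s = self.image_size
        out = replace(self)
        if out.retina_radius is None:
            out.retina_radius = round(0.47 * s)
        if out.disc_diameter is None:
            out.disc_diameter = round(0.117 * s)
        if out.disc_center is None:
            out.disc_center = ((s - 1) / 2.0, round(0.71 * s))
        if out.macula_center is None:
            out.macula_center = ((s - 1) / 2.0, round(0.33 * s))
        if out.macula_radius is None:
            out.macula_radius = round(0.08 * s)
        return out

    def validate(self) -> "SynthConfig":
        cfg = self.resolved()
        problems: list[str] = []
        if cfg.image_size < 32:
            problems.append("image_size must be >= 32")
        if not (0.0 < cfg.background_level <= 1.0):
            problems.append("background_level must lie in (0, 1]")
        if not (0.0 <= cfg.vessel_contrast < cfg.background_level):
            problems.append("vessel_contrast must satisfy 0 <= c < b")
        if cfg.noise_sigma < 0:
            problems.append("noise_sigma must be >= 0")
        if not cfg.disc_diameter > 0:
            problems.append("disc_diameter must be > 0")
        if cfg.n_root_vessels < 1:
            problems.append("n_root_vessels must be >= 1")
        if not (0 < cfg.width_taper <= 1):
            problems.append("width_taper must lie in (0, 1]")
        if cfg.initial_half_width <= 0:
            problems.append("initial_half_width must be > 0")
        half = cfg.image_size / 2.0
        cr, cc = cfg.disc_center
        if cfg.retina_radius > half + 0.5:
            problems.append("retina circle exceeds the frame")
        if not (0 <= cr < cfg.image_size and 0 <= cc < cfg.image_size):
            problems.append("disc_center outside the frame")
        dist_disc = math.hypot(cr - (cfg.image_size - 1) / 2.0,
                               cc - (cfg.image_size - 1) / 2.0)
        if dist_disc + cfg.disc_diameter / 2.0 > cfg.retina_radius:
            problems.append("optic disc not inside the retina circle")
        if problems:
            raise ConfigurationError("; ".join(problems))
        return cfg


@dataclass
class GroundTruth:
    """Exact per-image truth for verifying the measurement chain."""

    vessel_mask: np.ndarray            # bool raster
    vessel_pixel_count: int
    disc: DiscGeometry
    expected_snr: float                # (b - c) / sigma; NaN when sigma == 0
    centerlines: list[tuple[np.ndarray, float]]  # (points (N,2), half_width)


@dataclass
class ReaderProfile:
    """Latent operating point and clustering scales of one simulated reader.

    ``latent_sensitivity`` / ``latent_specificity`` are *marginal*
    (population-average) correct-answer probabilities for real and
    synthesized images respectively — the quantities a GEE-style analysis
    estimates.  ``reader_effect_sd`` and ``image_effect_sd`` are Gaussian
    random-effect standard deviations on the logit scale; either > 0
    induces within-reader / within-image correlation.
    """

    reader_id: str
    specialty: str = "resident"           # resident | non_retina | retina
    experience: str = "<5y"               # "<5y" | ">=5y"
    latent_sensitivity: float = 0.711
    latent_specificity: float = 0.369
    reader_effect_sd: float = 0.9
    image_effect_sd: float = 0.5
    mean_time: float = 5.0                # seconds per image (log-normal)
    time_sd: float = 2.0

    def __post_init__(self) -> None:
        for p in (self.latent_sensitivity, self.latent_specificity):
            if not (0.0 <= p <= 1.0):
                raise ValueError("latent probabilities must lie in [0, 1]")
        for s in (self.reader_effect_sd, self.image_effect_sd, self.time_sd):
            if s < 0:
                raise ValueError("effect/time standard deviations must be >= 0")
        if self.mean_time <= 0:
            raise ValueError("mean_time must be positive")


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _stamp_offsets(half_width: float) -> np.ndarray:
    r = int(math.ceil(half_width))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dr * dr + dc * dc <= half_width * half_width
    return np.column_stack([dr[keep], dc[keep]])


def _grow_tree(
    cfg: SynthConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, float]]:
    """Recursive random-walk vessel tree; list of (centreline, half_width)."""
    s = cfg.image_size
    center = np.array([(s - 1) / 2.0, (s - 1) / 2.0])
    disc = np.array(cfg.disc_center, dtype=float)
    # sweep the roots around the direction from the disc toward the retina centre
    toward = math.atan2(center[0] - disc[0], center[1] - disc[1])
    n = cfg.n_root_vessels
    fan = np.linspace(-1.9, 1.9, n) if n > 1 else np.array([0.0])
    step = 1.0
    min_hw = 0.8
    branches: list[tuple[np.ndarray, float]] = []
    stack: list[tuple[np.ndarray, float, float, int]] = []
    for off in fan[::-1]:
        ang = toward + off + rng.normal(0.0, 0.1)
        start = disc + (cfg.disc_diameter / 2.0 + 1.0) * np.array(
            [math.sin(ang), math.cos(ang)]
        )
        stack.append((start, ang, cfg.initial_half_width, 0))

    max_steps = 12 * s  # per-branch guard
    while stack:
        pos, ang, hw, depth = stack.pop()
        pts = [pos.copy()]
        for _ in range(max_steps):
            ang += rng.normal(0.0, cfg.tortuosity)
            pos = pos + step * np.array([math.sin(ang), math.cos(ang)])
            margin = hw + 12.0
            if np.hypot(*(pos - center)) > cfg.retina_radius - margin:
                break
            pts.append(pos.copy())
            if (
                len(pts) > 15
                and depth < 12
                and hw * cfg.width_taper >= min_hw
                and rng.random() < cfg.branch_probability
            ):
                child_hw = hw * cfg.width_taper
                dtheta = rng.uniform(0.3, 0.7)
                stack.append((pos.copy(), ang + dtheta, child_hw, depth + 1))
                stack.append((pos.copy(), ang - dtheta, child_hw, depth + 1))
                break
        if len(pts) >= 2:
            branches.append((np.array(pts), hw))
    return branches


def _render_mask(
    branches: Sequence[tuple[np.ndarray, float]], size: int
) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    for pts, hw in branches:
        offs = _stamp_offsets(hw)
        ip = np.round(pts).astype(int)
        rows = (ip[:, 0][:, None] + offs[:, 0][None, :]).ravel()
        cols = (ip[:, 1][:, None] + offs[:, 1][None, :]).ravel()
        keep = (rows >= 0) & (rows < size) & (cols >= 0) & (cols < size)
        mask[rows[keep], cols[keep]] = True
    return mask


def generate_fundus(config: SynthConfig) -> tuple[FundusImage, GroundTruth]:
    """Render one synthetic fundus image with its exact ground truth.

    Deterministic for a fixed ``config`` (including ``seed``): the same
    call twice yields bit-identical pixels and masks.
    """
    cfg = config.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_tree, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    s = cfg.image_size

    rr = np.arange(s)[:, None] - (s - 1) / 2.0
    cc = np.arange(s)[None, :] - (s - 1) / 2.0
    inside_retina = np.hypot(rr, cc) <= cfg.retina_radius

    img = np.zeros((s, s), dtype=float)
    img[inside_retina] = cfg.background_level

    # macula: gentle Gaussian darkening, clipped to the retina
    mr = np.arange(s)[:, None] - cfg.macula_center[0]
    mc = np.arange(s)[None, :] - cfg.macula_center[1]
    mdist2 = mr * mr + mc * mc
    sigma_m = max(cfg.macula_radius / 2.0, 1.0)
    img -= cfg.macula_darkening * np.exp(-mdist2 / (2 * sigma_m**2)) * inside_retina

    # optic disc: bright plateau
    dr = np.arange(s)[:, None] - cfg.disc_center[0]
    dc = np.arange(s)[None, :] - cfg.disc_center[1]
    disc_px = np.hypot(dr, dc) <= cfg.disc_diameter / 2.0
    img[disc_px] = cfg.disc_level

    branches = _grow_tree(cfg, rng_tree)
    mask = _render_mask(branches, s)
    img[mask] = cfg.background_level - cfg.vessel_contrast  # top-hat profile

    if cfg.edge_blur > 0:
        img = ndimage.gaussian_filter(img, cfg.edge_blur)

    if cfg.noise_sigma > 0:
        img = img + rng_noise.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    expected = (
        (cfg.background_level - cfg.vessel_contrast) / cfg.noise_sigma
        if cfg.noise_sigma > 0
        else float("nan")
    )
    truth = GroundTruth(
        vessel_mask=mask,
        vessel_pixel_count=int(mask.sum()),
        disc=DiscGeometry(center=cfg.disc_center, diameter=float(cfg.disc_diameter)),
        expected_snr=expected,
        centerlines=branches,
    )
    image = FundusImage(img, id=f"synth_{cfg.seed}", cohort="", provenance="synthetic")
    return image, truth


def derive_seed(master_seed: int, *key: int) -> int:
    """A reproducible 31-bit subseed for substream ``key`` of ``master_seed``."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def generate_cohorts(
    config_a: SynthConfig,
    config_b: SynthConfig,
    n_per_cohort: int,
    out_dir: str | Path,
    cohort_names: tuple[str, str] = ("real", "synthesized"),
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Write two cohorts of images + masks + a CSV manifest to ``out_dir``.

    Per-image seeds are derived from the master seed (default:
    ``config_a.seed``) by counter-based substreams, so the cohort is
    bit-reproducible and independent of generation order.
    """
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config_a.seed if master_seed is None else master_seed
    rows = []
    for ci, (name, cfg0) in enumerate(zip(cohort_names, (config_a, config_b))):
        cfg0.validate()
        for i in range(n_per_cohort):
            cfg = replace(cfg0, seed=derive_seed(master, ci, i))
            image, truth = generate_fundus(cfg)
            rcfg = cfg.resolved()
            img_id = f"{name}_{i:04d}"
            p_img = out / f"{img_id}.png"
            p_mask = out / f"{img_id}_mask.png"
            save_image(image, p_img)
            save_image(truth.vessel_mask.astype(float), p_mask)
            rows.append({
                "id": img_id,
                "cohort": name,
                "path_image": p_img.name,
                "path_mask": p_mask.name,
                "disc_row": truth.disc.center[0],
                "disc_col": truth.disc.center[1],
                "disc_diameter": truth.disc.diameter,
                "b": rcfg.background_level,
                "c": rcfg.vessel_contrast,
                "sigma": rcfg.noise_sigma,
                "expected_snr": truth.expected_snr,
                "vessel_pixel_count": truth.vessel_pixel_count,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# reader-response simulation
# ---------------------------------------------------------------------------

def _marginal_intercept(p: float, sigma: float) -> float:
    """Intercept a with E[expit(a + sigma Z)] = p for Z ~ N(0, 1).

    Gauss-Hermite quadrature + bracketing root find; reduces to logit(p)
    when sigma == 0.  Keeps the simulated *marginal* rates on the requested
    operating point (a GEE estimates exactly these marginal rates).
    """
    if sigma == 0.0 or p <= 0.0 or p >= 1.0:
        return float(logit(min(max(p, 1e-12), 1 - 1e-12)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def marginal(a: float) -> float:
        return float(np.sum(weights * expit(a + sigma * nodes)) - p)

    lo = float(logit(p)) - 6.0 * sigma - 1.0
    hi = float(logit(p)) + 6.0 * sigma + 1.0
    return float(brentq(marginal, lo, hi, xtol=1e-10))


def default_reader_panel(
    n_residents: int = 12,
    n_non_retina: int = 14,
    n_retina: int = 14,
    latent_sensitivity: float = 0.711,
    latent_specificity: float = 0.369,
    reader_effect_sd: float = 0.9,
    image_effect_sd: float = 0.5,
) -> list[ReaderProfile]:
    """A 40-reader panel (12 residents, 14 non-retina, 14 retina specialists).

    Residents are all junior (< 5 years); specialists split evenly across
    the 5-year experience criterion.  Examination-time means rise with
    seniority (a stylized choice).
    """
    panel: list[ReaderProfile] = []
    counts = [("resident", n_residents, 4.0), ("non_retina", n_non_retina, 5.0),
              ("retina", n_retina, 6.0)]
    k = 0
    for specialty, n, mean_time in counts:
        for j in range(n):
            if specialty == "resident":
                exp = "<5y"
            else:
                exp = "<5y" if j < n // 2 else ">=5y"
            panel.append(ReaderProfile(
                reader_id=f"r{k:02d}", specialty=specialty, experience=exp,
                latent_sensitivity=latent_sensitivity,
                latent_specificity=latent_specificity,
                reader_effect_sd=reader_effect_sd,
                image_effect_sd=image_effect_sd,
                mean_time=mean_time,
            ))
            k += 1
    return panel


def simulate_reader_responses(
    profiles: Sequence[ReaderProfile],
    truths: Mapping[str, str] | pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one clustered reader-study response table.

    ``truths`` maps image id -> ``"real"`` or ``"synthesized"``.  Each
    (reader, image) answer is Bernoulli-correct with
    ``logit p = a(class) + u_reader + image_effect_sd * z_image`` where the
    intercept ``a`` is calibrated so the marginal correct rate equals the
    profile's latent sensitivity (real images) or specificity (synthesized
    images).  ``z_image`` is shared across readers, inducing within-image
    correlation; ``u_reader`` is shared across a reader's answers.  Elapsed
    times are log-normal with the profile's mean/sd.  One row per
    (reader, image).
    """
    if len(profiles) == 0:
        raise ValueError("at least one reader profile is required")
    truths = dict(truths)
    if len(truths) == 0:
        raise ValueError("at least one image is required")
    bad = {v for v in truths.values()} - {"real", "synthesized"}
    if bad:
        raise ValueError(f"truth labels must be real/synthesized, got {bad}")

    image_ids = list(truths.keys())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z_img = {img: rng.normal() for img in image_ids}

    # calibrated intercepts are shared across profiles with identical params
    cache: dict[tuple[float, float], float] = {}

    def intercept(p: float, sig: float) -> float:
        key = (p, sig)
        if key not in cache:
            cache[key] = _marginal_intercept(p, sig)
        return cache[key]

    rows = []
    for prof in profiles:
        u = rng.normal(0.0, prof.reader_effect_sd) if prof.reader_effect_sd else 0.0
        sig_total = math.hypot(prof.reader_effect_sd, prof.image_effect_sd)
        if prof.time_sd > 0:
            s2 = math.log(1.0 + (prof.time_sd / prof.mean_time) ** 2)
            mu_t, sd_t = math.log(prof.mean_time) - s2 / 2.0, math.sqrt(s2)
        else:
            mu_t = sd_t = None
        for img in image_ids:
            truth = truths[img]
            latent = (prof.latent_sensitivity if truth == "real"
                      else prof.latent_specificity)
            if latent in (0.0, 1.0) and sig_total == 0.0:
                p_correct = latent
            else:
                a = intercept(latent, sig_total)
                p_correct = float(expit(a + u + prof.image_effect_sd * z_img[img]))
            correct = rng.random() < p_correct
            answer = truth if correct else (
                "synthesized" if truth == "real" else "real"
            )
            elapsed = (prof.mean_time if mu_t is None
                       else float(rng.lognormal(mu_t, sd_t)))
            rows.append({
                "reader_id": prof.reader_id,
                "specialty": prof.specialty,
                "experience": prof.experience,
                "image_id": img,
                "truth": truth,
                "answer": answer,
                "elapsed_s": elapsed,
            })
    return pd.DataFrame(rows)
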