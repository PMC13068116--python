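"""Synthetic radiometric phantoms with exact ground truth.

The clinical thermography database this pipeline targets is not public, so the
package ships a phantom generator that emulates what those bedside frames
contain: a warm patient silhouette (~33-37 deg C, warmer at the trunk than at
the silhouette edge) on a cool background (~20-26 deg C), partially covered by
a blanket that attenuates the apparent temperature through its thermal
resistance, crossed by cooler ventilatory tubes, with a warm monitor screen in
a corner, all under i.i.d. Gaussian sensor noise.

The blanket is rendered with the *forward* thermal-resistance model
``T_cloth = T_skin - phi * R_t`` where ``phi`` is the Stefan-Boltzmann flux of
the mean bare-skin temperature against ambient — exactly the flux estimator the
analysis stage uses — so that the analysis-side inversion
``T_skin = T_cloth + phi * R_t`` is consistent to machine precision on
noiseless phantoms.

Every phantom carries a :class:`PhantomTruth`: the label mask, the true
(pre-occlusion, pre-noise) skin field, the bare-skin mask, and the true TEE
per unit area computed from the noiseless skin field over all patient pixels.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage.draw import line, polygon
from skimage.morphology import dilation, footprint_rectangle

from . import energetics
from .heat import MaterialSpec
from .io import BACKGROUND, PATIENT, SCREEN, TUBE, LabelMask, PatientRecord, ThermalFrame

__all__ = [
    "Ellipse",
    "Disc",
    "Blanket",
    "Tube",
    "Screen",
    "PhantomSpec",
    "PhantomTruth",
    "default_spec",
    "random_scene_spec",
    "generate_training_set",
    "generate_phantom",
    "solve_core_for_tee",
    "sample_cohort_targets",
    "generate_cohort",
    "DEFAULT_AGE_MODEL",
]


@dataclasses.dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (row, col) half-extents, px
    rotation_deg: float = 0.0


@dataclasses.dataclass(frozen=True)
class Disc:
    center: tuple[float, float]
    radius: float


@dataclasses.dataclass(frozen=True)
class Blanket:
    polygon: tuple[tuple[float, float], ...]  # (row, col) vertices
    material: MaterialSpec = MaterialSpec("fleece-blanket", 0.15)


@dataclasses.dataclass(frozen=True)
class Tube:
    polyline: tuple[tuple[float, float], ...]
    width_px: int = 3
    temp_c: float = 28.0  # tubes run cooler than skin


@dataclasses.dataclass(frozen=True)
class Screen:
    rect: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    temp_c: float = 30.0  # screens run warmer than ambient


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Scene description for one synthetic frame.

    ``skin_core_c`` is the temperature at the body centre; the true skin field
    falls off linearly with normalized radial distance, losing
    ``skin_gradient_c`` from centre to silhouette edge.  Sensor noise is
    i.i.d. Gaussian with sd ``noise_sd_c``, added last.
    """

    shape: tuple[int, int] = (120, 160)
    ambient_c: float = 23.0
    skin_core_c: float = 36.5
    skin_gradient_c: float = 1.5
    body: Ellipse = Ellipse((60.0, 90.0), (27.5, 45.0))
    head: Disc | None = Disc((60.0, 32.0), 15.5)
    blanket: Blanket | None = None
    tube: Tube | None = None
    screen: Screen | None = None
    noise_sd_c: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.skin_core_c <= self.ambient_c:
            raise ValueError(
                "skin_core_c must exceed ambient_c: exposed skin is warmer than background"
            )
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be >= 0")
        if self.skin_gradient_c < 0:
            raise ValueError("skin_gradient_c must be >= 0")


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth for a generated frame (the test oracle).

    ``skin_field_c`` holds the true pre-occlusion, pre-noise skin temperature
    over patient pixels (NaN elsewhere); ``bare_mask`` marks the uncovered
    patient pixels; ``true_tee_area`` is the energetics chain applied to the
    mean of the noiseless skin field over all patient pixels.
    """

    mask: LabelMask
    skin_field_c: np.ndarray
    bare_mask: np.ndarray
    true_tee_area: float


def default_spec(shape: tuple[int, int] = (120, 160), **overrides) -> PhantomSpec:
    """A typical bedside scene scaled to ``shape``: torso ellipse + head disc,
    blanket over the lower body, a tube near the head, a screen in the top-right
    corner.  Any :class:`PhantomSpec` field can be overridden."""
    h, w = shape
    base = dict(
        shape=shape,
        body=Ellipse((0.50 * h, 0.56 * w), (0.23 * h, 0.28 * w)),
        head=Disc((0.50 * h, 0.20 * w), 0.13 * h),
        blanket=Blanket(
            polygon=(
                (0.30 * h, 0.50 * w),
                (0.24 * h, 0.95 * w),
                (0.92 * h, 0.95 * w),
                (0.86 * h, 0.44 * w),
            )
        ),
        tube=Tube(
            polyline=((0.12 * h, 0.04 * w), (0.46 * h, 0.22 * w)),
            width_px=max(2, h // 40),
        ),
        screen=Screen(rect=(max(1, int(0.03 * h)), int(0.78 * w), int(0.22 * h), int(0.97 * w))),
    )
    base.update(overrides)
    return PhantomSpec(**base)


def random_scene_spec(
    rng: np.random.Generator,
    shape: tuple[int, int] = (120, 160),
    noise_sd_c: float = 0.1,
) -> PhantomSpec:
    """Draw a randomized scene for segmentation training/validation.

    Varies body position, size and orientation, skin core (34.5-38 deg C),
    ambient (21-26 deg C), radial gradient (1-2 deg C), and independently
    drops the blanket, tube or screen with probability 0.3 each, so a trained
    model sees occluded and unoccluded anatomy alike.
    """
    h, w = shape
    kw: dict = {}
    if rng.random() < 0.3:
        kw["blanket"] = None
    if rng.random() < 0.3:
        kw["tube"] = None
    if rng.random() < 0.3:
        kw["screen"] = None
    return default_spec(
        shape=shape,
        ambient_c=float(rng.uniform(21.0, 26.0)),
        skin_core_c=float(rng.uniform(34.5, 38.0)),
        skin_gradient_c=float(rng.uniform(1.0, 2.0)),
        body=Ellipse(
            (float(rng.uniform(0.42, 0.58)) * h, float(rng.uniform(0.50, 0.62)) * w),
            (float(rng.uniform(0.18, 0.27)) * h, float(rng.uniform(0.22, 0.32)) * w),
            float(rng.uniform(-20.0, 20.0)),
        ),
        noise_sd_c=noise_sd_c,
        seed=int(rng.integers(0, 2**31 - 1)),
        **kw,
    )


def generate_training_set(
    n: int,
    seed: int = 0,
    shape: tuple[int, int] = (120, 160),
    noise_sd_c: float = 0.1,
) -> list[tuple[ThermalFrame, PhantomTruth]]:
    """``n`` randomized phantoms with truth, deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    return [generate_phantom(random_scene_spec(rng, shape, noise_sd_c)) for _ in range(n)]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _scene(spec: PhantomSpec):
    """Rasterize the geometry: returns (labels, r_norm, covered_mask)."""
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w]

    # body = ellipse (optionally rotated) union head disc; r_norm in [0, 1]
    theta = np.deg2rad(spec.body.rotation_deg)
    dy = rr - spec.body.center[0]
    dx = cc - spec.body.center[1]
    u = np.cos(theta) * dy + np.sin(theta) * dx
    v = -np.sin(theta) * dy + np.cos(theta) * dx
    r_ell = np.sqrt((u / spec.body.semi_axes[0]) ** 2 + (v / spec.body.semi_axes[1]) ** 2)
    r_norm = r_ell
    if spec.head is not None:
        r_disc = (
            np.sqrt((rr - spec.head.center[0]) ** 2 + (cc - spec.head.center[1]) ** 2)
            / spec.head.radius
        )
        r_norm = np.minimum(r_ell, r_disc)
    body = r_norm <= 1.0

    labels = np.full(spec.shape, BACKGROUND, dtype=np.uint8)
    labels[body] = PATIENT

    covered = np.zeros(spec.shape, dtype=bool)
    if spec.blanket is not None:
        poly = np.asarray(spec.blanket.polygon)
        pr, pc = polygon(poly[:, 0], poly[:, 1], shape=spec.shape)
        blanket = np.zeros(spec.shape, dtype=bool)
        blanket[pr, pc] = True
        covered = blanket & body
        if not covered.any():
            warnings.warn("blanket polygon disjoint from body; whole body is bare")

    if spec.tube is not None:
        tube = np.zeros(spec.shape, dtype=bool)
        pts = [(int(round(r)), int(round(c))) for r, c in spec.tube.polyline]
        for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
            lr, lc = line(r0, c0, r1, c1)
            keep = (lr >= 0) & (lr < h) & (lc >= 0) & (lc < w)
            tube[lr[keep], lc[keep]] = True
        rad = max(0, (spec.tube.width_px - 1) // 2)
        if rad:
            tube = dilation(tube, footprint_rectangle((2 * rad + 1, 2 * rad + 1)))
        labels[tube] = TUBE

    if spec.screen is not None:
        r0, c0, r1, c1 = spec.screen.rect
        labels[r0:r1, c0:c1] = SCREEN

    return labels, np.clip(r_norm, 0.0, 1.0), covered


def generate_phantom(
    spec: PhantomSpec,
    constants: energetics.PhysicsConstants = energetics.DEFAULT_CONSTANTS,
) -> tuple[ThermalFrame, PhantomTruth]:
    """Render one phantom frame and its ground truth.

    Deterministic given ``spec.seed``.  The truth records the pre-noise state;
    noise is added to every pixel last.
    """
    rng = np.random.default_rng(spec.seed)
    labels, r_norm, covered = _scene(spec)
    patient = labels == PATIENT  # tube/screen already carved out
    covered &= patient
    bare = patient & ~covered

    skin_field = np.full(spec.shape, np.nan)
    skin_field[patient] = spec.skin_core_c - spec.skin_gradient_c * r_norm[patient]

    temps = np.full(spec.shape, spec.ambient_c, dtype=float)
    temps[patient] = skin_field[patient]

    if covered.any():
        mean_bare = float(skin_field[bare].mean()) if bare.any() else float(
            skin_field[patient].mean()
        )
        phi = float(energetics.radiative_power(mean_bare, spec.ambient_c, constants))
        phi = max(phi, 0.0)
        temps[covered] = skin_field[covered] - phi * spec.blanket.material.r_t

    if spec.tube is not None:
        temps[labels == TUBE] = spec.tube.temp_c
    if spec.screen is not None:
        temps[labels == SCREEN] = spec.screen.temp_c

    if spec.noise_sd_c > 0:
        temps = temps + rng.normal(0.0, spec.noise_sd_c, size=spec.shape)

    true_mean_skin = float(skin_field[patient].mean())
    true_tee = float(
        energetics.tee_per_area(
            energetics.radiative_power(true_mean_skin, spec.ambient_c, constants), constants
        )
    )
    frame = ThermalFrame(temps=temps, ambient_c=spec.ambient_c, frame_id=f"phantom-{spec.seed}")
    truth = PhantomTruth(
        mask=LabelMask(labels=labels),
        skin_field_c=skin_field,
        bare_mask=bare,
        true_tee_area=true_tee,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Cohort TEE-vs-age model: TEE_i = intercept + slope * age_i + N(0, sd),
#: kcal/m^2/day.  Chosen to land near a realistic pediatric cohort (mean TEE
#: in the mid-1500s with a mild negative age trend) without claiming to
#: reproduce any particular one.
DEFAULT_AGE_MODEL = {"intercept": 1800.0, "slope": -40.0, "sd": 150.0}

_TEE_CLIP = (500.0, 2500.0)


def solve_core_for_tee(
    spec: PhantomSpec,
    tee_target: float,
    constants: energetics.PhysicsConstants = energetics.DEFAULT_CONSTANTS,
) -> tuple[float, bool]:
    """Skin-core temperature that makes the phantom's true TEE equal the target.

    Inverts the energetics chain for the mean skin temperature, then shifts by
    the radial gradient's mean over the patient pixels.  Returns
    ``(skin_core_c, clipped)``; when the required mean would not exceed
    ambient, the core is clipped to ambient + 0.5 deg C and flagged.
    """
    labels, r_norm, _ = _scene(spec)
    patient = labels == PATIENT
    mean_r = float(r_norm[patient].mean())
    p = tee_target / float(energetics.tee_per_area(1.0, constants))
    t_amb_k = spec.ambient_c + 273.15
    t4 = p / (constants.emissivity * constants.sigma) + t_amb_k**4
    clipped = False
    if t4 <= 0:
        clipped = True
        mean_skin = spec.ambient_c + 0.5
    else:
        mean_skin = t4**0.25 - 273.15
        if mean_skin <= spec.ambient_c + 0.2:
            clipped = True
            mean_skin = spec.ambient_c + 0.5
    return mean_skin + spec.skin_gradient_c * mean_r, clipped


def sample_cohort_targets(
    n: int,
    age_model: dict = DEFAULT_AGE_MODEL,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``(ages, tee_targets, weights)`` from the cohort generative model.

    Ages are right-skewed on [0, 17] (gamma, shape 0.5, scale 4.6 — infants
    dominate a PICU census); TEE targets follow the linear age model clipped
    to [500, 2500] kcal/m^2/day; weights rise with age with lognormal-ish
    noise, clipped to [2, 60] kg.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    ages = np.clip(rng.gamma(shape=0.5, scale=4.6, size=n), 0.0, 17.0)
    tee = age_model["intercept"] + age_model["slope"] * ages + rng.normal(
        0.0, age_model["sd"], size=n
    )
    tee = np.clip(tee, *_TEE_CLIP)
    weights = 3.4 + 2.75 * ages + rng.normal(0.0, 1.0 + 0.15 * ages, size=n)
    weights = np.clip(weights, 2.0, 60.0)
    return ages, tee, weights


def generate_cohort(
    n: int,
    age_model: dict = DEFAULT_AGE_MODEL,
    seed: int = 0,
    shape: tuple[int, int] = (120, 160),
    noise_sd_c: float = 0.1,
    constants: energetics.PhysicsConstants = energetics.DEFAULT_CONSTANTS,
) -> list[tuple[ThermalFrame, PhantomTruth, PatientRecord]]:
    """Generate a synthetic cohort of phantoms with TEE tied to age.

    Each patient gets the default scene at ``shape``, an ambient temperature
    drawn in [22, 25] deg C, and a skin-core temperature solved so that the
    phantom's true TEE equals the age-model draw.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    ages, tees, weights = sample_cohort_targets(n, age_model, rng=rng)
    sexes = rng.choice(["female", "male"], size=n)
    out = []
    for i in range(n):
        ambient = float(rng.uniform(22.0, 25.0))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        proto = default_spec(shape=shape, ambient_c=ambient, noise_sd_c=noise_sd_c,
                             seed=sub_seed)
        core, _clipped = solve_core_for_tee(proto, float(tees[i]), constants)
        spec = dataclasses.replace(proto, skin_core_c=core)
        frame, truth = generate_phantom(spec, constants)
        frame = dataclasses.replace(frame, frame_id=f"cohort-{seed}-{i:03d}")
        record = PatientRecord(
            weight_kg=float(weights[i]), age_years=float(ages[i]), sex=str(sexes[i])
        )
        out.append((frame, truth, record))
    return out
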