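"""Bare-skin isolation and textile-occlusion correction inside the patient mask.

Blankets, bandages and clothing lower the apparent temperature of the covered
skin because they act as thermal resistances.  This module

* clusters the patient-pixel temperatures with 1-D K-means (temperature is the
  sole feature) and takes the warmest cluster as bare skin,
* estimates the surface heat flux from the bare-skin mean via the
  Stefan-Boltzmann law, and
* inverts the occlusion with the thermal-resistance model
  ``T_skin = T_cloth + phi * R_t``, where ``R_t`` (K m^2/W) is the
  material-specific resistance measured on a heating plate as
  ``R_t = dT * A / Q``.

In one dimension the optimal K-means clusters are contiguous intervals of the
sorted values, so the exact optimum is computable by dynamic programming in
``O(k n log n)`` — no Lloyd iterations, no restarts, no initialization
sensitivity.  ``kmeans_1d`` implements that exact solver; the warmest-cluster
rule is then well defined and deterministic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import energetics
from .io import PATIENT, SCREEN, TUBE, LabelMask, ThermalFrame

__all__ = [
    "MaterialSpec",
    "HeatPartition",
    "kmeans_1d",
    "bare_skin_mask",
    "correct_occluded",
    "estimate_flux",
    "thermal_resistance",
    "partition_and_correct",
    "load_material_table",
]

#: Warmest-cluster guard: a "bare skin" cluster smaller than this fraction of
#: the patient pixels is treated as a hot-spot artifact and merged downward.
MIN_BARE_FRACTION = 0.05


@dataclasses.dataclass(frozen=True)
class MaterialSpec:
    """A named occluder material with thermal resistance ``r_t`` in K m^2/W."""

    name: str
    r_t: float

    def __post_init__(self) -> None:
        if self.r_t < 0:
            raise ValueError(f"thermal resistance must be >= 0, got {self.r_t}")


@dataclasses.dataclass
class HeatPartition:
    """Result of the bare/covered split over the patient pixels.

    ``bare_mask`` and ``covered_mask`` are disjoint boolean images whose union
    is the patient region (tube/screen pixels excluded).  ``centroids`` are the
    cluster centres in deg C, descending.  ``corrected_c`` (if computed) holds
    the occlusion-corrected skin temperature over covered pixels, NaN
    elsewhere; ``phi`` is the surface heat flux in W/m^2 used for the
    correction.
    """

    bare_mask: np.ndarray
    covered_mask: np.ndarray
    centroids: list[float]
    corrected_c: np.ndarray | None = None
    phi: float | None = None
    flags: tuple[str, ...] = ()


class EmptyPartitionError(ValueError):
    """The mask contains no patient pixels to partition."""


def _dc_fill_row(dp_prev: np.ndarray, dp_row: np.ndarray, arg_row: np.ndarray,
                 cost, lo: int, hi: int, opt_lo: int, opt_hi: int) -> None:
    """Divide-and-conquer DP row fill, exploiting argmin monotonicity.

    ``dp_row[j] = min_i dp_prev[i] + cost(i, j)`` for j in [lo, hi); the
    optimal split index is non-decreasing in j, so each half restricts the
    candidate range.  Iterative stack to avoid recursion limits.
    """
    stack = [(lo, hi, opt_lo, opt_hi)]
    while stack:
        lo, hi, olo, ohi = stack.pop()
        if lo >= hi:
            continue
        mid = (lo + hi) // 2
        cand = np.arange(olo, min(ohi, mid) + 1)
        vals = dp_prev[cand] + cost(cand, mid)
        best = int(np.argmin(vals))
        dp_row[mid] = vals[best]
        arg_row[mid] = cand[best]
        stack.append((lo, mid, olo, int(cand[best])))
        stack.append((mid + 1, hi, int(cand[best]), ohi))


def kmeans_1d(
    values: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D K-means by dynamic programming over the sorted values.

    Optimal 1-D clusters are contiguous intervals in sorted order, so the
    globally optimal (minimum within-cluster sum of squares) partition is
    found exactly in ``O(k n log n)`` with divide-and-conquer over the
    monotone split points.  Deterministic; ``seed`` is accepted for interface
    stability but the solution does not depend on it.

    Returns ``(labels, centroids)`` with centroids sorted descending and
    labels renumbered so label 0 is the warmest cluster.  If the data has
    fewer distinct values than ``k``, ``k`` is reduced to the number of
    distinct values (a warning is emitted).
    """
    values = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if values.size < k:
        raise ValueError(f"need at least k={k} values, got {values.size}")
    n_distinct = np.unique(values).size
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct values; reducing k from {k}", stacklevel=2
        )
        k = n_distinct
    n = values.size
    order = np.argsort(values, kind="stable")
    x = values[order]
    s = np.concatenate([[0.0], np.cumsum(x)])
    ss = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):  # WCSS of x[i:j+1]; i array-like, j scalar (0-based points)
        i = np.asarray(i)
        m = j - i + 1
        seg = s[j + 1] - s[i]
        return (ss[j + 1] - ss[i]) - seg * seg / m

    # dp_prev[j] = optimal cost of clustering x[0..j] into the current number
    # of clusters; one cluster has the closed form below
    js = np.arange(n)
    dp_prev = ss[js + 1] - s[js + 1] ** 2 / (js + 1)
    args = np.zeros((k, n), dtype=int)
    for c in range(1, k):
        dp_row = np.empty(n)
        arg_row = np.zeros(n, dtype=int)
        # cluster c starts at index i; previous clusters cover x[0..i-1]
        shifted_prev = np.concatenate([[np.inf], dp_prev[:-1]])
        _dc_fill_row(shifted_prev, dp_row, arg_row, cost, c, n, c, n - 1)
        dp_row[:c] = np.inf
        args[c] = arg_row
        dp_prev = dp_row

    # backtrack cluster boundaries
    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = n
    j = n - 1
    for c in range(k - 1, 0, -1):
        start = int(args[c][j])
        bounds[c] = start
        j = start - 1
    bounds[0] = 0
    sorted_labels = np.empty(n, dtype=int)
    centroids = np.empty(k)
    for c in range(k):
        sorted_labels[bounds[c]:bounds[c + 1]] = c
        centroids[c] = x[bounds[c]:bounds[c + 1]].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = sorted_labels
    # centroids are ascending by construction; flip so label 0 is warmest
    remap = (k - 1) - np.arange(k)
    return remap[labels], centroids[::-1].copy()


def bare_skin_mask(
    frame: ThermalFrame,
    mask: LabelMask,
    k: int = 2,
    seed: int = 0,
) -> HeatPartition:
    """Split the patient region into bare skin (warmest cluster) vs covered.

    Tube and screen pixels are excluded before clustering.  If the warmest
    cluster holds fewer than 5% of the patient pixels it is merged with the
    next cluster and the partition is flagged ``cluster-guard`` (a few hot
    pixels must not hijack the bare-skin rule).
    """
    if frame.shape != mask.shape:
        raise ValueError(f"frame {frame.shape} and mask {mask.shape} differ in shape")
    frame = frame.filled()
    patient = mask.class_mask(PATIENT) & ~mask.class_mask(TUBE) & ~mask.class_mask(SCREEN)
    n_patient = int(patient.sum())
    if n_patient == 0:
        raise EmptyPartitionError("mask contains no patient pixels")
    k = min(k, n_patient)
    vals = frame.temps[patient]
    labels, centroids = kmeans_1d(vals, k=k, seed=seed)
    flags: list[str] = []
    bare_lbls = {0}
    if len(centroids) > 1:
        while (np.isin(labels, list(bare_lbls)).sum() < MIN_BARE_FRACTION * n_patient
               and max(bare_lbls) + 1 < len(centroids)):
            bare_lbls.add(max(bare_lbls) + 1)
            flags.append("cluster-guard")
    bare_sel = np.isin(labels, list(bare_lbls))
    bare = np.zeros(frame.shape, dtype=bool)
    covered = np.zeros(frame.shape, dtype=bool)
    rr, cc = np.where(patient)
    bare[rr[bare_sel], cc[bare_sel]] = True
    covered[rr[~bare_sel], cc[~bare_sel]] = True
    return HeatPartition(
        bare_mask=bare,
        covered_mask=covered,
        centroids=[float(c) for c in centroids],
        flags=tuple(flags),
    )


def correct_occluded(
    t_cloth: float | np.ndarray, phi: float, material: MaterialSpec
) -> float | np.ndarray:
    """Recover sub-textile skin temperature: ``T_skin = T_cloth + phi * R_t``.

    The K m^2/W x W/m^2 product is a temperature difference in kelvin-sized
    degrees, so the formula is valid directly on the deg C scale.
    """
    if phi < 0:
        raise ValueError(f"surface heat flux must be >= 0, got {phi}")
    out = np.asarray(t_cloth, dtype=float) + phi * material.r_t
    return float(out) if np.ndim(t_cloth) == 0 else out


def estimate_flux(
    frame: ThermalFrame,
    partition: HeatPartition,
    ambient_c: float,
    emissivity: float = 0.98,
    constants: energetics.PhysicsConstants | None = None,
) -> float:
    """Default estimator of the occlusion heat flux phi, W/m^2.

    The flux through the textile is not observable directly; the bare-skin
    radiative flux against ambient is the proxy: Stefan-Boltzmann on the mean
    bare-skin temperature.
    """
    if not partition.bare_mask.any():
        raise EmptyPartitionError(
            "empty bare mask: estimate the flux from ambient alone or supply phi"
        )
    if constants is None:
        constants = dataclasses.replace(energetics.DEFAULT_CONSTANTS, emissivity=emissivity)
    mean_bare = float(frame.filled().temps[partition.bare_mask].mean())
    return float(energetics.radiative_power(mean_bare, ambient_c, constants))


def thermal_resistance(delta_t: float, area: float, q: float, name: str = "sample") -> MaterialSpec:
    """Material thermal resistance from a heating-plate measurement.

    ``R_t = dT * A / Q`` with the temperature drop ``dT`` across the textile
    in K, sample area ``A`` in m^2, and steady-state heat flux ``Q`` in W.
    """
    if q <= 0:
        raise ValueError(f"heat flux q must be positive, got {q}")
    if area <= 0:
        raise ValueError(f"sample area must be positive, got {area}")
    if delta_t < 0:
        raise ValueError(f"temperature drop must be >= 0, got {delta_t}")
    return MaterialSpec(name=name, r_t=delta_t * area / q)


def partition_and_correct(
    frame: ThermalFrame,
    mask: LabelMask,
    material: MaterialSpec,
    k: int = 2,
    seed: int = 0,
    ambient_c: float | None = None,
    constants: energetics.PhysicsConstants | None = None,
    refine: bool = False,
    refine_tol_c: float = 0.01,
    refine_max_iter: int = 5,
) -> HeatPartition:
    """Full heat-partition stage: cluster, estimate phi, correct covered pixels.

    With ``refine=True`` the flux is re-estimated from the pooled
    bare+corrected mean and the correction repeated until the corrected mean
    moves by less than ``refine_tol_c`` (at most ``refine_max_iter`` passes);
    off by default.
    """
    if constants is None:
        constants = energetics.DEFAULT_CONSTANTS
    frame = frame.filled()
    if ambient_c is None:
        ambient_c, _ = frame.ambient_or_fallback()
    part = bare_skin_mask(frame, mask, k=k, seed=seed)
    phi = estimate_flux(frame, part, ambient_c, constants=constants)
    if phi < 0:  # skin cooler than ambient: no outward flux to invert
        phi = 0.0
        part = dataclasses.replace(part, flags=part.flags + ("negative-flux",))
    corrected = np.full(frame.shape, np.nan)
    corrected[part.covered_mask] = correct_occluded(
        frame.temps[part.covered_mask], phi, material
    )
    if refine and part.covered_mask.any():
        for _ in range(refine_max_iter):
            pooled = np.concatenate(
                [frame.temps[part.bare_mask], corrected[part.covered_mask]]
            )
            phi_new = float(
                energetics.radiative_power(float(pooled.mean()), ambient_c, constants)
            )
            new_corr = correct_occluded(frame.temps[part.covered_mask], phi_new, material)
            shift = float(np.abs(new_corr - corrected[part.covered_mask]).mean())
            corrected[part.covered_mask] = new_corr
            phi = phi_new
            if shift < refine_tol_c:
                break
    return dataclasses.replace(part, corrected_c=corrected, phi=phi)


def load_material_table(path) -> dict[str, MaterialSpec]:
    """Load ``name,r_t`` lines into a material lookup table."""
    out: dict[str, MaterialSpec] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, r_t = [x.strip() for x in line.split(",")]
            out[name] = MaterialSpec(name=name, r_t=float(r_t))
    return out
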