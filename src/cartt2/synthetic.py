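"""Synthetic MESE phantoms and subject cohorts with known ground truth.

The original cohort's MR images are access-controlled, so every pipeline
stage is exercised on synthetic data instead:

* **Phantoms** — extruded slab and curved-shell cartilage plates carrying a
  through-thickness T2 gradient (linear or two-compartment step), imaged by
  the mono-exponential MESE forward model with an optional stimulated-echo
  inflation of the first echo and additive noise.
* **Cohorts** — subject tables with the three-group structure of the
  reference study (riskROA / earlyROA / healthy), drawing demographics and
  per plate x layer T2 values from the published group summaries, with
  optional linear covariate effects to inject confounding.

Ground-truth depth is computed by exhaustive all-pairs distances to the
boundary voxels — deliberately a different algorithm from the pipeline's
distance-transform implementation, so agreement between the two is a real
cross-check.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import reference
from .errors import InvalidGeometryError, InvalidParameterError
from .fitting import MESESeries
from .laminar import DEEP, SUPERFICIAL, CartilageSegmentation

__all__ = [
    "SlabPlate", "ShellPlate", "PhantomSpec", "GroundTruth",
    "simulate_mese_signal", "generate_phantom",
    "CellSpec", "GroupSpec", "CovariateEffects", "CohortSpec",
    "generate_synthetic_cohort", "default_phantom_spec", "reference_cohort_spec",
]


# --------------------------------------------------------------------------
# MESE forward model
# --------------------------------------------------------------------------

def simulate_mese_signal(
    s0: float,
    t2_ms: float,
    echo_times_ms=reference.ECHO_TIMES_MS,
    first_echo_bias_frac: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    noise_model: str = "gaussian",
    size: int | None = None,
) -> np.ndarray:
    """Simulate one voxel's echo train: s0*exp(-TE/T2) + contamination + noise.

    Echo 1 is multiplied by ``(1 + first_echo_bias_frac)`` to emulate
    stimulated-echo contamination.  Noise is zero-mean Gaussian of SD
    ``noise_sd`` by default; ``noise_model='rician'`` returns the magnitude
    of the complex signal with independent Gaussian noise on both channels.
    With ``size`` set, an array of shape ``(n_echoes, size)`` of independent
    replicate voxels is returned.
    """
    if s0 <= 0 or t2_ms <= 0:
        raise InvalidParameterError("s0 and t2_ms must be positive")
    if first_echo_bias_frac < 0 or noise_sd < 0:
        raise InvalidParameterError("first_echo_bias_frac and noise_sd must be >= 0")
    tes = np.asarray(echo_times_ms, dtype=float)
    if np.any(np.diff(tes) <= 0):
        raise InvalidParameterError("echo_times_ms must be strictly increasing")
    clean = s0 * np.exp(-tes / t2_ms)
    clean[0] *= 1.0 + first_echo_bias_frac
    if size is not None:
        clean = np.repeat(clean[:, np.newaxis], size, axis=1)
    if noise_sd == 0:
        return clean
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_model == "gaussian":
        return clean + rng.normal(0.0, noise_sd, clean.shape)
    if noise_model == "rician":
        re = clean + rng.normal(0.0, noise_sd, clean.shape)
        im = rng.normal(0.0, noise_sd, clean.shape)
        return np.hypot(re, im)
    raise InvalidParameterError(f"unknown noise_model {noise_model!r}")


# --------------------------------------------------------------------------
# Phantom geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabPlate:
    """Rectangular cartilage slab, extruded over slices.

    Rows span the thickness: the top row (lowest row index) is the articular
    surface, the bottom row the bone interface.
    """

    origin: tuple[int, int, int]  # (slice, row, col) of the surface corner
    thickness: int                # rows
    length: int                   # cols
    n_slices: int = 1


@dataclass(frozen=True)
class ShellPlate:
    """Upper-half annular shell (condyle-like), extruded over slices.

    Bone lies at the inner radius, the articular surface at the outer radius.
    """

    center: tuple[int, int]       # (row, col) of the annulus center
    inner_radius: float           # voxels
    thickness: int                # radial voxels
    z0: int = 0
    n_slices: int = 1


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic MESE knee phantom.

    ``t2_deep_ms`` / ``t2_superficial_ms`` may be scalars or per-plate dicts;
    ``t2_profile`` is ``'linear'`` (linear in normalized depth) or ``'step'``
    (two-compartment: deep value below depth 0.5, superficial above).
    ``noise_sd`` is in image-intensity units; ``first_echo_bias_frac``
    fractionally inflates echo 1 only.
    """

    plate_shapes: Mapping[str, SlabPlate | ShellPlate]
    volume_shape: tuple[int, int, int]
    t2_deep_ms: float | Mapping[str, float] = 35.8
    t2_superficial_ms: float | Mapping[str, float] = 45.4
    t2_profile: str = "step"
    s0: float = 100.0
    noise_sd: float = 0.0
    first_echo_bias_frac: float = 0.0
    noise_model: str = "gaussian"
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 0.3125, 0.3125)
    echo_times_ms: tuple[float, ...] = reference.ECHO_TIMES_MS
    tr_ms: float = reference.TR_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.echo_times_ms) <= 0):
            raise InvalidParameterError("echo_times_ms must be strictly increasing")
        if self.s0 <= 0 or self.noise_sd < 0 or self.first_echo_bias_frac < 0:
            raise InvalidParameterError("s0 > 0, noise_sd >= 0, bias >= 0 required")
        if self.t2_profile not in ("linear", "step"):
            raise InvalidParameterError("t2_profile must be 'linear' or 'step'")
        for name, shape in self.plate_shapes.items():
            if shape.thickness < 2:
                raise InvalidGeometryError(
                    f"plate {name!r}: thickness {shape.thickness} < 2 voxels; "
                    "both layers must be nonempty"
                )
        for vals in (self.t2_deep_ms, self.t2_superficial_ms):
            it = vals.values() if isinstance(vals, Mapping) else (vals,)
            if any(v <= 0 for v in it):
                raise InvalidParameterError("T2 values must be positive")

    def t2_levels(self, plate: str) -> tuple[float, float]:
        deep = self.t2_deep_ms[plate] if isinstance(self.t2_deep_ms, Mapping) else self.t2_deep_ms
        sup = (
            self.t2_superficial_ms[plate]
            if isinstance(self.t2_superficial_ms, Mapping)
            else self.t2_superficial_ms
        )
        return float(deep), float(sup)


@dataclass
class GroundTruth:
    """Generator-side truth on cartilage voxels (NaN / 0 elsewhere)."""

    true_t2_ms: np.ndarray
    true_depth: np.ndarray
    true_layer: np.ndarray  # int8, DEEP / SUPERFICIAL inside the mask
    mask: np.ndarray


def t2_at_depth(depth, t2_deep: float, t2_superficial: float, profile: str):
    """Through-thickness T2 profile evaluated at normalized depth."""
    depth = np.asarray(depth, dtype=float)
    if profile == "linear":
        return t2_deep + (t2_superficial - t2_deep) * depth
    if profile == "step":
        return np.where(depth > 0.5, t2_superficial, t2_deep)
    raise InvalidParameterError(f"unknown t2_profile {profile!r}")


def _rasterize_plate(shape, plate) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (mask, bone_interface, surface) volumes for one plate."""
    mask = np.zeros(shape, dtype=bool)
    bone = np.zeros(shape, dtype=bool)
    surf = np.zeros(shape, dtype=bool)
    if isinstance(plate, SlabPlate):
        z0, y0, x0 = plate.origin
        zs = slice(z0, z0 + plate.n_slices)
        xs = slice(x0, x0 + plate.length)
        if (
            z0 < 0 or y0 < 0 or x0 < 0
            or z0 + plate.n_slices > shape[0]
            or y0 + plate.thickness > shape[1]
            or x0 + plate.length > shape[2]
        ):
            raise InvalidGeometryError("slab extends outside the volume")
        mask[zs, y0 : y0 + plate.thickness, xs] = True
        surf[zs, y0, xs] = True
        bone[zs, y0 + plate.thickness - 1, xs] = True
        return mask, bone, surf
    if isinstance(plate, ShellPlate):
        yc, xc = plate.center
        rows, cols = np.mgrid[0 : shape[1], 0 : shape[2]]
        rho = np.hypot(rows - yc, cols - xc)
        r_in = plate.inner_radius
        ring = (rho >= r_in) & (rho < r_in + plate.thickness) & (rows <= yc)
        bone2d = ring & (rho < r_in + 1)
        surf2d = ring & (rho >= r_in + plate.thickness - 1)
        if plate.z0 < 0 or plate.z0 + plate.n_slices > shape[0]:
            raise InvalidGeometryError("shell extends outside the volume")
        if np.any(ring[[0, -1], :]) or np.any(ring[:, [0, -1]]):
            raise InvalidGeometryError("shell extends outside the volume")
        for z in range(plate.z0, plate.z0 + plate.n_slices):
            mask[z] = ring
            bone[z] = bone2d
            surf[z] = surf2d
        return mask, bone, surf
    raise InvalidParameterError(f"unknown plate shape {type(plate).__name__}")


def _brute_force_depth(mask2d, bone2d, surf2d, spacing2) -> np.ndarray:
    """Normalized depth on one slice via exhaustive boundary distances."""
    depth = np.full(mask2d.shape, np.nan)
    pts = np.argwhere(mask2d) * np.asarray(spacing2)
    bpts = np.argwhere(bone2d) * np.asarray(spacing2)
    spts = np.argwhere(surf2d) * np.asarray(spacing2)
    d_bone = cdist(pts, bpts).min(axis=1)
    d_surf = cdist(pts, spts).min(axis=1)
    total = d_bone + d_surf
    vals = np.where(total > 0, d_bone / np.where(total > 0, total, 1.0), 0.5)
    depth[mask2d] = vals
    return depth


def generate_phantom(spec: PhantomSpec) -> tuple[MESESeries, CartilageSegmentation, GroundTruth]:
    """Render a phantom: MESE stack, segmentation with boundaries, and truth.

    Deterministic given ``spec`` (including its seed): two calls with the
    same spec return bit-identical volumes.
    """
    shape = tuple(spec.volume_shape)
    plate_masks: dict[str, np.ndarray] = {}
    bone = np.zeros(shape, dtype=bool)
    surf = np.zeros(shape, dtype=bool)
    true_t2 = np.full(shape, np.nan)
    true_depth = np.full(shape, np.nan)
    landmarks: dict[str, int] = {}

    for name, plate in spec.plate_shapes.items():
        m, b, s = _rasterize_plate(shape, plate)
        for prev, pm in plate_masks.items():
            if np.any(pm & m):
                raise InvalidGeometryError(f"plates {prev!r} and {name!r} overlap")
        plate_masks[name] = m
        bone |= b
        surf |= s
        t2_deep, t2_sup = spec.t2_levels(name)
        for z in range(shape[0]):
            if not m[z].any():
                continue
            d = _brute_force_depth(m[z], b[z], s[z], spec.voxel_spacing_mm[1:])
            true_depth[z][m[z]] = d[m[z]]
        true_t2[m] = t2_at_depth(true_depth[m], t2_deep, t2_sup, spec.t2_profile)
        # anterior-most column doubles as the notch landmark for femoral ROIs
        landmarks[name] = int(np.min(np.nonzero(m.any(axis=(0, 1)))[0]))

    mask = np.zeros(shape, dtype=bool)
    for m in plate_masks.values():
        mask |= m
    true_layer = np.zeros(shape, dtype=np.int8)
    true_layer[mask] = np.where(true_depth[mask] > 0.5, SUPERFICIAL, DEEP)

    tes = np.asarray(spec.echo_times_ms, dtype=float)
    volumes = np.zeros((tes.size,) + shape)
    decay = np.exp(-tes[:, None] / true_t2[mask][None, :])
    decay[0] *= 1.0 + spec.first_echo_bias_frac
    volumes[(slice(None),) + tuple(np.argwhere(mask).T)] = spec.s0 * decay
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            volumes += rng.normal(0.0, spec.noise_sd, volumes.shape)
        elif spec.noise_model == "rician":
            re = volumes + rng.normal(0.0, spec.noise_sd, volumes.shape)
            im = rng.normal(0.0, spec.noise_sd, volumes.shape)
            volumes = np.hypot(re, im)
        else:
            raise InvalidParameterError(f"unknown noise_model {spec.noise_model!r}")

    series = MESESeries(
        volumes=volumes,
        echo_times_ms=tuple(tes),
        tr_ms=spec.tr_ms,
        voxel_spacing_mm=spec.voxel_spacing_mm,
    )
    seg = CartilageSegmentation(
        plate_masks=plate_masks,
        bone_interface=bone,
        surface=surf,
        voxel_spacing_mm=spec.voxel_spacing_mm,
        landmarks=landmarks,
    )
    truth = GroundTruth(
        true_t2_ms=true_t2, true_depth=true_depth, true_layer=true_layer, mask=mask
    )
    return series, seg, truth


def default_phantom_spec(
    n_slices: int = 1,
    noise_sd: float = 2.0,
    first_echo_bias_frac: float = 0.0,
    t2_profile: str = "step",
    seed: int = 0,
    healthy_levels: bool = True,
) -> PhantomSpec:
    """Four-plate demonstration phantom: two tibial slabs, two femoral shells.

    With ``healthy_levels`` the per-plate deep/superficial T2 targets are the
    healthy reference group's published plate means; noise_sd defaults to 2
    at s0 = 100, i.e. 2% of the proton-density scale.
    """
    shapes = {
        "MT": SlabPlate(origin=(0, 42, 8), thickness=10, length=44, n_slices=n_slices),
        "LT": SlabPlate(origin=(0, 42, 98), thickness=10, length=44, n_slices=n_slices),
        "cMF": ShellPlate(center=(38, 30), inner_radius=14, thickness=10, n_slices=n_slices),
        "cLF": ShellPlate(center=(38, 120), inner_radius=14, thickness=10, n_slices=n_slices),
    }
    if healthy_levels:
        deep = {p: reference.BASELINE_T2[("healthy", p, "deep")][0] for p in reference.PLATES}
        sup = {p: reference.BASELINE_T2[("healthy", p, "superficial")][0] for p in reference.PLATES}
    else:
        deep, sup = 35.8, 45.4
    return PhantomSpec(
        plate_shapes=shapes,
        volume_shape=(n_slices, 60, 150),
        t2_deep_ms=deep,
        t2_superficial_ms=sup,
        t2_profile=t2_profile,
        s0=100.0,
        noise_sd=noise_sd,
        first_echo_bias_frac=first_echo_bias_frac,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Synthetic cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """Baseline and one-year-change distribution of one plate x layer cell."""

    baseline_mean: float
    baseline_sd: float
    change_mean: float = 0.0
    change_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.change_sd < 0:
            raise InvalidParameterError("SDs must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """One group's size, demographics and T2 cell distributions."""

    n: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    female_fraction: float
    cells: Mapping[tuple[str, str], CellSpec]
    n_followup: int | None = None  # None -> everyone has a year-1 visit

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("each group needs n >= 2")
        if self.age_sd < 0 or self.bmi_sd < 0:
            raise InvalidParameterError("SDs must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InvalidParameterError("female_fraction must lie in [0, 1]")
        if self.n_followup is not None and not 0 <= self.n_followup <= self.n:
            raise InvalidParameterError("n_followup must lie in [0, n]")


@dataclass(frozen=True)
class CovariateEffects:
    """Linear effects of covariates on T2 (ms per unit), zero by default.

    Effects are referenced to ``age_ref`` years and ``bmi_ref`` kg/m^2, so a
    nonzero age coefficient combined with between-group age differences
    injects genuine confounding into the crude group contrast.
    """

    age: float = 0.0      # ms per year
    female: float = 0.0   # ms, female vs male
    bmi: float = 0.0      # ms per kg/m^2
    age_ref: float = 57.0
    bmi_ref: float = 26.0


@dataclass(frozen=True)
class CohortSpec:
    """Three-group cohort description for the synthetic generator."""

    groups: Mapping[str, GroupSpec]
    covariate_effects: CovariateEffects = CovariateEffects()
    baseline_change_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.baseline_change_corr <= 1.0:
            raise InvalidParameterError("baseline_change_corr must lie in [-1, 1]")


def reference_cohort_spec(
    plates: tuple[str, ...] = ("Avg",),
    layers: tuple[str, ...] = reference.LAYERS,
    covariate_effects: CovariateEffects = CovariateEffects(),
    baseline_change_corr: float = 0.0,
    seed: int = 0,
) -> CohortSpec:
    """Cohort spec populated from the published three-group summaries."""
    groups = {}
    for g, demo in reference.DEMOGRAPHICS.items():
        cells = {}
        for p in plates:
            for lay in layers:
                bm, bs = reference.BASELINE_T2[(g, p, lay)]
                cm, cs = reference.T2_CHANGE[(g, p, lay)]
                cells[(p, lay)] = CellSpec(bm, bs, cm, cs)
        groups[g] = GroupSpec(
            n=int(demo["n"]),
            age_mean=demo["age_mean"], age_sd=demo["age_sd"],
            bmi_mean=demo["bmi_mean"], bmi_sd=demo["bmi_sd"],
            female_fraction=demo["female_fraction"],
            cells=cells,
            n_followup=int(demo["n_followup"]),
        )
    return CohortSpec(
        groups=groups,
        covariate_effects=covariate_effects,
        baseline_change_corr=baseline_change_corr,
        seed=seed,
    )


def generate_synthetic_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subject-level cohort table from a CohortSpec.

    Returns a long-format DataFrame with columns (subject_id, group, age,
    sex, bmi, visit, plate, layer, t2_ms).  Baseline values are normal with
    the cell's mean/SD plus any covariate effects; year-1 values add an
    independently drawn change (correlation with the baseline draw available
    via ``baseline_change_corr``).  Follow-up rows exist only for the
    group's follow-up subset.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    eff = spec.covariate_effects
    rho = spec.baseline_change_corr
    records: list[dict] = []
    for gname, grp in spec.groups.items():
        n = grp.n
        ages = rng.normal(grp.age_mean, grp.age_sd, n)
        bmis = rng.normal(grp.bmi_mean, grp.bmi_sd, n)
        n_female = int(round(grp.female_fraction * n))
        sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
        rng.shuffle(sexes)
        n_fu = grp.n_followup if grp.n_followup is not None else n
        followup = np.zeros(n, dtype=bool)
        followup[rng.choice(n, size=n_fu, replace=False)] = True
        shift = (
            eff.age * (ages - eff.age_ref)
            + eff.bmi * (bmis - eff.bmi_ref)
            + eff.female * (sexes == "female")
        )
        for (plate, layer), cell in grp.cells.items():
            z_base = rng.standard_normal(n)
            z_extra = rng.standard_normal(n)
            baseline = cell.baseline_mean + shift + cell.baseline_sd * z_base
            z_change = rho * z_base + np.sqrt(max(0.0, 1.0 - rho * rho)) * z_extra
            change = cell.change_mean + cell.change_sd * z_change
            for i in range(n):
                sid = f"{gname}_{i:04d}"
                base_rec = {
                    "subject_id": sid, "group": gname,
                    "age": float(ages[i]), "sex": str(sexes[i]), "bmi": float(bmis[i]),
                    "plate": plate, "layer": layer,
                }
                records.append({**base_rec, "visit": "baseline", "t2_ms": float(baseline[i])})
                if followup[i]:
                    records.append(
                        {**base_rec, "visit": "year1", "t2_ms": float(baseline[i] + change[i])}
                    )
    df = pd.DataFrame.from_records(records)
    cols = ["subject_id", "group", "age", "sex", "bmi", "visit", "plate", "layer", "t2_ms"]
    return df[cols]
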