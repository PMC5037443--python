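"""Voxelwise T2 mapping from multi-echo spin-echo (MESE) series.

The transverse relaxation model is mono-exponential,

    S(TE) = S0 * exp(-TE / T2),

fitted per voxel by nonlinear least squares.  The first echo is excluded by
default because stimulated echoes inflate it, and voxels whose fit achieves
R^2 below a quality threshold (default 0.66) are eliminated from downstream
laminar averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Default T2 search bounds in ms; a fit landing on a bound is flagged
#: non-converged rather than trusted.
T2_BOUNDS_MS = (1.0, 1000.0)

#: Default goodness-of-fit threshold: voxels with R^2 < 0.66 are eliminated.
DEFAULT_R2_THRESHOLD = 0.66


@dataclass(frozen=True)
class MESESeries:
    """A multi-echo image stack: one volume per echo time.

    ``volumes`` has shape ``(n_echoes, *spatial)``; ``echo_times_ms`` is
    strictly increasing.  ``tr_ms`` is carried for provenance (the model does
    not use it; T1 weighting is constant across echoes at fixed TR).
    """

    volumes: np.ndarray
    echo_times_ms: tuple[float, ...]
    tr_ms: float = 2700.0
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 0.3125, 0.3125)

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "volumes", vols)
        tes = tuple(float(t) for t in self.echo_times_ms)
        object.__setattr__(self, "echo_times_ms", tes)
        if vols.ndim < 2 or vols.shape[0] != len(tes):
            raise InvalidParameterError(
                f"volumes leading axis ({vols.shape[0]}) must index the "
                f"{len(tes)} echoes"
            )
        if len(tes) < 4:
            raise InsufficientDataError(
                "need >= 4 echoes so that >= 3 remain after first-echo exclusion"
            )
        if np.any(np.diff(tes) <= 0):
            raise InvalidParameterError("echo_times_ms must be strictly increasing")
        if self.tr_ms <= 0:
            raise InvalidParameterError("tr_ms must be positive")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.volumes.shape[1:]

    @property
    def n_echoes(self) -> int:
        return self.volumes.shape[0]


@dataclass(frozen=True)
class FitSettings:
    """Settings of the voxelwise mono-exponential fit."""

    exclude_first: bool = True
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    t2_bounds_ms: tuple[float, float] = T2_BOUNDS_MS

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise InvalidParameterError("r2_threshold must lie in [0, 1]")
        lo, hi = self.t2_bounds_ms
        if not 0 < lo < hi:
            raise InvalidParameterError("t2 bounds must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class FitResult:
    """Per-voxel outcome of the mono-exponential fit."""

    s0: float
    t2_ms: float
    r_squared: float
    converged: bool
    n_echoes_used: int


@dataclass
class T2Map:
    """Per-voxel T2 map with validity flags and fit provenance.

    Invalid voxels hold NaN in ``t2_ms`` — never a silent zero.
    ``valid`` is True only where the fit converged and R^2 cleared the
    threshold recorded in ``provenance``.
    """

    t2_ms: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


def coefficient_of_determination(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """R^2 = 1 - SS_res / SS_tot, with SS_tot about the mean of ``observed``.

    Returns NaN when SS_tot is zero (constant observations), where R^2 is
    undefined.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise InvalidParameterError(
            f"observed and fitted lengths differ: {obs.shape} vs {fit.shape}"
        )
    ss_res = float(np.sum((obs - fit) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def _loglinear_init(tes: np.ndarray, ys: np.ndarray, t2_bounds: tuple[float, float]) -> tuple[float, float]:
    """Initial (S0, T2) from the OLS line fit of log(intensity) vs TE.

    Non-positive intensities cannot enter the log fit; with fewer than 3
    positive echoes a fixed fallback (S0 = max intensity, T2 = 40 ms) is used.
    """
    pos = ys > 0
    if np.count_nonzero(pos) < 3:
        return float(max(ys.max(), 1.0)), 40.0
    slope, intercept = np.polyfit(tes[pos], np.log(ys[pos]), 1)
    s0 = float(np.exp(intercept))
    t2 = -1.0 / slope if slope < 0 else t2_bounds[1]
    t2 = float(np.clip(t2, t2_bounds[0], t2_bounds[1]))
    return s0, t2


def fit_monoexponential(
    intensities: Sequence[float],
    echo_times_ms: Sequence[float],
    exclude_first: bool = True,
    t2_bounds_ms: tuple[float, float] = T2_BOUNDS_MS,
) -> FitResult:
    """Fit S0*exp(-TE/T2) to one voxel's echo-train intensities.

    Trust-region nonlinear least squares on (S0, T2), initialized from the
    log-linear closed form.  With ``exclude_first`` the 10 ms echo is dropped
    before fitting, so any stimulated-echo contamination of echo 1 cannot
    influence the estimate.  R^2 is computed over the echoes actually used.

    A fit that lands on a parameter bound, or a voxel with no positive
    signal, is returned with ``converged=False`` (T2 is NaN in the latter
    case) instead of raising.
    """
    ys = np.asarray(intensities, dtype=float)
    tes = np.asarray(echo_times_ms, dtype=float)
    if ys.shape != tes.shape:
        raise InvalidParameterError("intensities and echo_times_ms lengths differ")
    if np.any(np.diff(tes) <= 0):
        raise InvalidParameterError("echo_times_ms must be strictly increasing")
    if exclude_first:
        ys, tes = ys[1:], tes[1:]
    n_used = ys.size
    if n_used < 3:
        raise InsufficientDataError(
            f"need >= 3 usable echoes for a meaningful fit, got {n_used}"
        )

    if not np.any(ys > 0):
        return FitResult(0.0, float("nan"), float("nan"), False, n_used)

    t2_lo, t2_hi = t2_bounds_ms
    s0_hi = 10.0 * float(ys.max())
    x0 = _loglinear_init(tes, ys, t2_bounds_ms)
    x0 = (float(np.clip(x0[0], 1e-12, s0_hi)), x0[1])

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-tes / p[1]) - ys

    sol = least_squares(
        resid, x0=x0, bounds=([0.0, t2_lo], [s0_hi, t2_hi]), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    s0_hat, t2_hat = float(sol.x[0]), float(sol.x[1])
    fitted = s0_hat * np.exp(-tes / t2_hat)
    r2 = coefficient_of_determination(ys, fitted)

    eps = 1e-9
    on_bound = (
        t2_hat <= t2_lo * (1 + eps)
        or t2_hat >= t2_hi * (1 - eps)
        or s0_hat >= s0_hi * (1 - eps)
    )
    converged = bool(sol.success) and not on_bound
    return FitResult(s0_hat, t2_hat, r2, converged, n_used)


def build_t2_map(
    series: MESESeries,
    mask: np.ndarray,
    settings: FitSettings | None = None,
) -> T2Map:
    """Fit every masked voxel of a MESE series and apply the R^2 filter.

    Voxels are fitted independently (no spatial coupling), so the result does
    not depend on traversal order.  Validity requires convergence and
    R^2 >= ``settings.r2_threshold``.
    """
    settings = settings or FitSettings()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise InvalidParameterError(
            f"mask shape {mask.shape} != series spatial shape {series.spatial_shape}"
        )
    shape = series.spatial_shape
    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    idx = np.argwhere(mask)
    if idx.size == 0:
        logger.warning("build_t2_map called with an empty mask")
    signals = series.volumes[(slice(None),) + tuple(idx.T)]  # (n_echo, n_vox)
    for k, vox in enumerate(map(tuple, idx)):
        res = fit_monoexponential(
            signals[:, k],
            series.echo_times_ms,
            exclude_first=settings.exclude_first,
            t2_bounds_ms=settings.t2_bounds_ms,
        )
        t2[vox] = res.t2_ms
        s0[vox] = res.s0
        r2[vox] = res.r_squared
        valid[vox] = res.converged and (
            np.isfinite(res.r_squared) and res.r_squared >= settings.r2_threshold
        )

    n_rejected = int(np.count_nonzero(mask) - np.count_nonzero(valid))
    logger.info(
        "T2 map: %d/%d masked voxels valid (%d rejected by convergence/R^2 >= %.2f)",
        int(np.count_nonzero(valid)), int(np.count_nonzero(mask)),
        n_rejected, settings.r2_threshold,
    )
    provenance = {
        "exclude_first": settings.exclude_first,
        "r2_threshold": settings.r2_threshold,
        "t2_bounds_ms": list(settings.t2_bounds_ms),
        "echo_times_ms": list(series.echo_times_ms),
        "n_masked": int(np.count_nonzero(mask)),
        "n_rejected": n_rejected,
    }
    return T2Map(t2_ms=t2, s0=s0, r_squared=r2, valid=valid, provenance=provenance)


def apply_quality_filter(t2map: T2Map, r2_threshold: float) -> T2Map:
    """Invalidate voxels with R^2 below ``r2_threshold`` (strict ``<``).

    Idempotent; never resurrects voxels already invalid (e.g. non-converged).
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise InvalidParameterError("r2_threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        keep = np.where(np.isfinite(t2map.r_squared), t2map.r_squared >= r2_threshold, False)
    new_valid = t2map.valid & keep
    provenance = dict(t2map.provenance)
    provenance["r2_threshold"] = r2_threshold
    return T2Map(
        t2_ms=t2map.t2_ms, s0=t2map.s0, r_squared=t2map.r_squared,
        valid=new_valid, provenance=provenance,
    )
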