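"""Spatially correlated insult profiles and calibrated multi-contributor pairs.

A lesion template is drawn from a stationary Gaussian random field on the
cylinder (periodic in the circumferential direction via chordal distances),
normalized to a compact-support severity profile ``theta_star`` in [0, 1].
Each template is then split into the two mechanobiological contributors

    ``theta_ce    = s * w * 0.48 * theta_star``   (elastic fiber integrity)
    ``theta_delta = s * (1 - w) * 0.28 * theta_star``  (mechanosensing)

where the mixture weight ``w`` sets which contributor dominates and the
scale ``s`` is calibrated per record so the simulated lesion reaches a
maximum dilatation of ~1.5 — the aneurysmal threshold at which all records
are closely matched in size, isolating the inverse problem of identifying
the underlying mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .domain import GridSpec
from .exceptions import (CalibrationError, DataError, NumericalError,
                         ParameterError, PipelineError)
from .gr_membrane import WallParams, simulate_taa
from . import maps as maps_mod

__all__ = [
    "CAP_CE",
    "CAP_DELTA",
    "DEFAULT_COMBOS",
    "GRFKernel",
    "InsultProfile",
    "InsultPair",
    "sample_insult_profile",
    "normalize_profile",
    "make_insult_pair",
    "calibrate_scale",
    "build_dataset",
]

#: Caps on the two contributor fields.
CAP_CE = 0.48
CAP_DELTA = 0.28

#: Mixture weights spanning pure-mechanosensing (0) to pure-elastic (1).
DEFAULT_COMBOS: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class GRFKernel:
    """Squared-exponential covariance on the cylinder surface.

    Circumferential distances are chordal (``2 sin(dtheta / 2)`` scaled by
    the correlation length in radians), which keeps the covariance periodic
    and positive semi-definite.
    """

    variance: float = 1.0
    length_theta: float = 1.0  # radians
    length_z: float = 0.25  # in z units (default grid length 1)
    family: str = "squared_exponential"

    def __post_init__(self) -> None:
        if self.length_theta <= 0 or self.length_z <= 0:
            raise ParameterError("correlation lengths must be positive")
        if self.variance < 0:
            raise ParameterError("variance must be non-negative")
        if self.family != "squared_exponential":
            raise ParameterError(f"unknown kernel family {self.family!r}")

    def covariance(self, grid: GridSpec) -> np.ndarray:
        """Dense covariance over the flattened grid (theta-major order)."""
        th, zz = np.meshgrid(grid.theta, grid.z, indexing="ij")
        th = th.reshape(-1)
        zz = zz.reshape(-1)
        dth = th[:, None] - th[None, :]
        chord = 2.0 * np.sin(0.5 * dth)
        dz = zz[:, None] - zz[None, :]
        q = (chord / self.length_theta) ** 2 + (dz / self.length_z) ** 2
        return self.variance * np.exp(-0.5 * q)


@dataclass(frozen=True)
class InsultProfile:
    """Normalized severity template ``theta_star`` in [0, 1] on the grid."""

    field: np.ndarray
    profile_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.field
        if not np.all(np.isfinite(f)):
            raise DataError("profile field contains non-finite values")
        if f.min() < -1e-12 or f.max() > 1.0 + 1e-12:
            raise DataError("profile field must lie in [0, 1]")

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.field == 0.0))


@dataclass(frozen=True)
class InsultPair:
    """The two contributor fields plus the mixture that produced them."""

    theta_ce: np.ndarray
    theta_delta: np.ndarray
    mixture_weight: float
    scale: float
    profile_id: str = ""
    combo_id: str = ""

    def __post_init__(self) -> None:
        if self.theta_ce.max(initial=0.0) > CAP_CE + 1e-12:
            raise ParameterError("theta_ce exceeds its cap")
        if self.theta_delta.max(initial=0.0) > CAP_DELTA + 1e-12:
            raise ParameterError("theta_delta exceeds its cap")


@lru_cache(maxsize=8)
def _cholesky_factor(grid: GridSpec, kernel: GRFKernel) -> np.ndarray:
    """Lower Cholesky factor of the kernel covariance, with jitter escalation."""
    cov = kernel.covariance(grid)
    if kernel.variance == 0.0:
        return np.zeros_like(cov)
    jitter = 1e-12 * kernel.variance
    for _ in range(8):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalError("covariance factorization failed at maximum jitter")


def sample_insult_profile(grid: GridSpec, kernel: GRFKernel, seed: int,
                          floor_frac: float = 0.3,
                          taper_exponent: float = 1.0,
                          profile_id: str = "") -> InsultProfile:
    """Draw one normalized insult profile; deterministic in ``seed``.

    The raw field is first mapped affinely to [0, 1], then multiplied by an
    axial taper ``sin(pi * z_hat) ** taper_exponent`` so the lesion vanishes
    at the vessel ends (dilatation is measured relative to the end radius,
    so the template must leave the ends unperturbed), and finally floored
    and rescaled by :func:`normalize_profile`.
    """
    chol = _cholesky_factor(grid, kernel)
    rng = np.random.default_rng(seed)
    raw = chol @ rng.standard_normal(chol.shape[0])
    raw = raw.reshape(grid.shape)
    span = raw.max() - raw.min()
    if span > 0:
        raw = (raw - raw.min()) / span
    if taper_exponent > 0:
        window = np.sin(np.pi * grid.z_hat) ** taper_exponent
        raw = raw * window[None, :]
    return normalize_profile(raw, floor_frac=floor_frac,
                             profile_id=profile_id, seed=seed)


def normalize_profile(raw: np.ndarray, floor_frac: float = 0.3,
                      profile_id: str = "", seed: int = 0,
                      degenerate_tol: float = 1e-12) -> InsultProfile:
    """Normalize a raw field to a compact-support severity profile.

    The field is affinely mapped so its range becomes [0, 1]; values below
    the floor fraction ``floor_frac`` of the range are then squashed to zero
    by shifting and rescaling (``max(0, (x - t0) / (1 - t0))``), which keeps
    the profile continuous, pins the maximum at exactly 1 and gives the
    lesion a compact support with a zero far field.  A (near-)constant raw
    field maps to the zero profile.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise DataError("raw field contains non-finite values")
    if not 0.0 <= floor_frac < 1.0:
        raise ParameterError("floor_frac must be in [0, 1)")
    span = raw.max() - raw.min()
    if span <= degenerate_tol * max(1.0, abs(raw.max())):
        return InsultProfile(field=np.zeros_like(raw), profile_id=profile_id,
                             seed=seed)
    x = (raw - raw.min()) / span
    if floor_frac > 0.0:
        x = np.maximum(0.0, (x - floor_frac) / (1.0 - floor_frac))
    return InsultProfile(field=x, profile_id=profile_id, seed=seed)


def make_insult_pair(profile: InsultProfile, w: float, s: float,
                     combo_id: str = "") -> InsultPair:
    """Scale a severity template into the two capped contributor fields."""
    if not 0.0 <= w <= 1.0:
        raise ParameterError("mixture weight w must be in [0, 1]")
    if s <= 0.0:
        raise ParameterError("scale s must be positive")
    if s * w > 1.0 + 1e-12 or s * (1.0 - w) > 1.0 + 1e-12:
        raise ParameterError(
            f"scale {s} with weight {w} violates the contributor caps")
    return InsultPair(theta_ce=s * w * CAP_CE * profile.field,
                      theta_delta=s * (1.0 - w) * CAP_DELTA * profile.field,
                      mixture_weight=w, scale=s,
                      profile_id=profile.profile_id, combo_id=combo_id)


def _dmax(profile: InsultProfile, w: float, s: float, params: WallParams,
          grid: GridSpec, smooth_width: int) -> float:
    pair = make_insult_pair(profile, w, s)
    fields = simulate_taa(pair, params, grid, smooth_width=smooth_width)
    d = maps_mod.dilatation_field(fields.r_dia)
    return float(d.max())


def calibrate_scale(profile: InsultProfile, w: float, params: WallParams,
                    grid: GridSpec, target_dmax: float = 1.5,
                    tol: float = 0.01, max_iter: int = 60,
                    smooth_width: int = 3) -> float:
    """Bisection on the insult scale until max dilatation hits the target.

    Maximum dilatation is monotone nondecreasing in the scale (asserted on
    the evaluated sequence); the admissible bracket is ``(0, s_max]`` with
    ``s_max`` the cap-saturating scale ``1 / max(w, 1 - w)``.
    """
    if tol <= 0:
        raise ParameterError("tolerance must be positive")
    s_max = 1.0 / max(w, 1.0 - w)
    evaluated: list[tuple[float, float]] = []

    def f(s: float) -> float:
        val = _dmax(profile, w, s, params, grid, smooth_width)
        evaluated.append((s, val))
        return val

    d_hi = f(s_max)
    if d_hi < target_dmax - tol:
        raise CalibrationError(
            f"profile {profile.profile_id or '<anonymous>'} cannot reach "
            f"dmax {target_dmax} at cap-saturating scale (got {d_hi:.4f})")
    if abs(d_hi - target_dmax) <= tol:
        return s_max
    lo, hi = 0.0, s_max
    s = s_max
    for _ in range(max_iter):
        s = 0.5 * (lo + hi)
        d = f(s)
        if abs(d - target_dmax) <= tol:
            break
        if d < target_dmax:
            lo = s
        else:
            hi = s
    else:
        raise CalibrationError(
            f"bisection did not reach |dmax - {target_dmax}| <= {tol} "
            f"within {max_iter} iterations")
    order = sorted(evaluated)
    dvals = [d for _, d in order]
    if any(b < a - 5e-3 for a, b in zip(dvals, dvals[1:])):
        raise NumericalError("max dilatation not monotone in insult scale")
    return s


def _derive_seed(base_seed: int, *key: int) -> int:
    """Derive an independent child seed from a base seed and integer keys."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, key)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def build_dataset(n_profiles: int, combos: Sequence[float] = DEFAULT_COMBOS,
                  base_seed: int = 0, sim_params: WallParams | None = None,
                  grid: GridSpec | None = None,
                  kernel: GRFKernel | None = None,
                  target_dmax: float = 1.5, tol: float = 0.01,
                  floor_frac: float = 0.3, smooth_width: int = 3,
                  max_resamples: int = 10) -> list["maps_mod.SampleRecord"]:
    """Generate the full synthetic record set.

    Each of ``n_profiles`` severity templates is combined with every mixture
    weight in ``combos``; each combination is scale-calibrated to the target
    maximum dilatation, simulated, and converted to dilatation and
    distensibility maps in both encodings.  Profiles for which any
    combination fails to calibrate are resampled with a derived replacement
    seed.  The whole set is a pure function of ``(base_seed, config)``.
    """
    if n_profiles < 1:
        raise ParameterError("n_profiles must be >= 1")
    if len(combos) == 0:
        raise ParameterError("combos must be nonempty")
    from .gr_membrane import homeostatic_calibration
    if sim_params is None:
        sim_params = homeostatic_calibration()
    grid = grid or GridSpec()
    kernel = kernel or GRFKernel(length_z=0.25 * grid.length)

    records: list[maps_mod.SampleRecord] = []
    for p_idx in range(n_profiles):
        for attempt in range(max_resamples + 1):
            seed = _derive_seed(base_seed, p_idx, attempt)
            profile = sample_insult_profile(
                grid, kernel, seed, floor_frac=floor_frac,
                profile_id=f"p{p_idx:03d}")
            try:
                prof_records = []
                for c_idx, w in enumerate(combos):
                    s = calibrate_scale(profile, w, sim_params, grid,
                                        target_dmax=target_dmax, tol=tol,
                                        smooth_width=smooth_width)
                    pair = make_insult_pair(profile, w, s,
                                            combo_id=f"c{c_idx}")
                    fields = simulate_taa(pair, sim_params, grid,
                                          smooth_width=smooth_width)
                    prof_records.append(maps_mod.make_record(
                        profile, pair, fields, grid))
                records.extend(prof_records)
                break
            except CalibrationError:
                continue
        else:
            raise PipelineError(
                f"profile index {p_idx}: calibration failed for "
                f"{max_resamples + 1} consecutive resampled profiles")
    return records
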