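"""Dilatation/distensibility maps, encodings, dataset assembly and storage.

Dilatation ``d`` is the loaded inner radius at diastole normalized by the
mean diastolic radius over the vessel-end node rows; distensibility ``D``
is the fractional radius change ``(rS - rD) / rD`` over the cardiac cycle.
Both are stored as physical-valued "heat" maps and as 8-bit "grayscale"
maps quantized with dataset-wide fixed ranges (one range for all dilatation
maps, a separate one for all distensibility maps), emulating the two input
formats an imaging pipeline would hand to a network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from typing import TYPE_CHECKING, Sequence

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .domain import GridSpec
from .exceptions import DataError, DataFormatError, ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .gr_membrane import VesselFields
    from .grf_insults import InsultPair, InsultProfile

__all__ = [
    "DEFAULT_D_RANGE",
    "DEFAULT_DIST_RANGE",
    "MapPair",
    "SampleRecord",
    "DatasetSplit",
    "dilatation_field",
    "distensibility_field",
    "resample_to_grid",
    "encode_grayscale",
    "decode_grayscale",
    "make_record",
    "split_dataset",
    "write_dataset",
    "read_dataset",
]

#: Dataset-wide physical ranges used for 8-bit quantization.
DEFAULT_D_RANGE = (0.9, 1.8)
DEFAULT_DIST_RANGE = (0.0, 0.08)


@dataclass(frozen=True)
class MapPair:
    """One dilatation/distensibility map pair in a single encoding."""

    d: np.ndarray
    D: np.ndarray
    encoding: str  # "heat" | "grayscale"
    d_range: tuple[float, float] = DEFAULT_D_RANGE
    D_range: tuple[float, float] = DEFAULT_DIST_RANGE

    def __post_init__(self) -> None:
        if self.encoding not in ("heat", "grayscale"):
            raise ParameterError(f"unknown encoding {self.encoding!r}")
        if self.d.shape != self.D.shape:
            raise DataError("d and D must share a grid")
        if self.encoding == "grayscale":
            if self.d.dtype != np.uint8 or self.D.dtype != np.uint8:
                raise DataError("grayscale maps must be 8-bit")


@dataclass
class SampleRecord:
    """One simulated lesion: ground truth, simulator fields and both maps."""

    profile_id: str
    combo_id: str
    profile: np.ndarray  # severity template theta_star
    pair: "InsultPair"
    fields: "VesselFields"
    heat: MapPair
    gray: MapPair
    seed: int = 0

    @property
    def record_id(self) -> str:
        return f"{self.profile_id}_{self.combo_id}"


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[str, ...]
    test: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise DataError("train and test ids overlap")


def dilatation_field(r_dia: np.ndarray, n_end_rows: int = 1) -> np.ndarray:
    """Radius map normalized by the mean radius over the vessel-end rows.

    End rows are the first and last ``n_end_rows`` axial node rows (axis 1).
    """
    if n_end_rows < 1:
        raise ParameterError("n_end_rows must be >= 1")
    r = np.asarray(r_dia, dtype=float)
    ends = np.concatenate([r[:, :n_end_rows], r[:, -n_end_rows:]], axis=1)
    denom = ends.mean()
    if denom <= 0:
        raise DataError("mean end radius is not positive")
    return r / denom


def distensibility_field(r_sys: np.ndarray, r_dia: np.ndarray) -> np.ndarray:
    """Pointwise ``(rS - rD) / rD``."""
    r_sys = np.asarray(r_sys, dtype=float)
    r_dia = np.asarray(r_dia, dtype=float)
    if np.any(r_dia <= 0):
        raise DataError("diastolic radius must be positive")
    out = (r_sys - r_dia) / r_dia
    if out.min() < -1e-9:
        raise DataError("negative distensibility: systole below diastole")
    return out


def resample_to_grid(values: np.ndarray, src_theta: np.ndarray,
                     src_z: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Bilinear resampling onto the target grid with circumferential wrap.

    Returns the input unchanged (bitwise) when the source coordinates
    already equal the target grid nodes.
    """
    values = np.asarray(values, dtype=float)
    src_theta = np.asarray(src_theta, dtype=float)
    src_z = np.asarray(src_z, dtype=float)
    if values.shape != (src_theta.size, src_z.size):
        raise DataError("values shape does not match source coordinates")
    if src_theta.size == grid.n_theta and src_z.size == grid.n_z \
            and np.array_equal(src_theta, grid.theta) \
            and np.array_equal(src_z, grid.z):
        return values.copy()
    if src_z.min() > grid.z.min() + 1e-12 or src_z.max() < grid.z.max() - 1e-12:
        raise DataError("source axial coverage does not span the target grid")
    # periodic extension in theta: append the first angular row at theta+2*pi
    theta_ext = np.concatenate([src_theta, [src_theta[0] + 2.0 * np.pi]])
    values_ext = np.concatenate([values, values[:1, :]], axis=0)
    interp = RegularGridInterpolator((theta_ext, src_z), values_ext,
                                     method="linear", bounds_error=False,
                                     fill_value=None)
    th, zz = np.meshgrid(np.mod(grid.theta, 2.0 * np.pi), grid.z,
                         indexing="ij")
    pts = np.stack([th.reshape(-1), zz.reshape(-1)], axis=1)
    return interp(pts).reshape(grid.shape)


def encode_grayscale(field: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Quantize a physical field to 8-bit intensities over ``[lo, hi]``.

    Values are clipped to the range and rounded half-away-from-zero.
    """
    if hi <= lo:
        raise ParameterError("grayscale range must satisfy hi > lo")
    x = np.clip(np.asarray(field, dtype=float), lo, hi)
    scaled = (x - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def decode_grayscale(gray: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map 8-bit intensities back to physical values (quantization remains)."""
    if hi <= lo:
        raise ParameterError("grayscale range must satisfy hi > lo")
    return lo + np.asarray(gray, dtype=float) / 255.0 * (hi - lo)


def make_record(profile: "InsultProfile", pair: "InsultPair",
                fields: "VesselFields", grid: GridSpec,
                d_range: tuple[float, float] = DEFAULT_D_RANGE,
                D_range: tuple[float, float] = DEFAULT_DIST_RANGE,
                n_end_rows: int = 1) -> SampleRecord:
    """Assemble maps in both encodings for one simulated lesion."""
    d = dilatation_field(fields.r_dia, n_end_rows=n_end_rows)
    D = distensibility_field(fields.r_sys, fields.r_dia)
    heat = MapPair(d=d, D=D, encoding="heat", d_range=d_range, D_range=D_range)
    gray = MapPair(d=encode_grayscale(d, *d_range),
                   D=encode_grayscale(D, *D_range),
                   encoding="grayscale", d_range=d_range, D_range=D_range)
    return SampleRecord(profile_id=pair.profile_id, combo_id=pair.combo_id,
                        profile=profile.field.copy(), pair=pair,
                        fields=fields, heat=heat, gray=gray,
                        seed=profile.seed)


def split_dataset(records: Sequence[SampleRecord], n_train: int = 450,
                  seed: int = 0) -> DatasetSplit:
    """Uniform random train/test split, reproducible in ``seed``."""
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("record ids are not unique")
    if not 0 < n_train < len(ids):
        raise ParameterError("n_train must be in (0, n_records)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = tuple(ids[i] for i in perm[:n_train])
    test = tuple(ids[i] for i in perm[n_train:])
    return DatasetSplit(train=train, test=test, seed=seed)


# ----------------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------------

_FLOAT_FIELDS = ("insult_ce", "insult_delta", "profile", "d_heat", "D_heat",
                 "lam", "m_plus", "h", "r_dia", "r_sys", "sigma_tt",
                 "sigma_zz", "shear_analog")
_GRAY_FIELDS = ("d_gray", "D_gray")


def write_dataset(records: Sequence[SampleRecord], split: DatasetSplit,
                  path, config: dict | None = None) -> None:
    """Persist records, split and config into one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["d_range"] = records[0].heat.d_range
        f.attrs["D_range"] = records[0].heat.D_range
        grp = f.create_group("records")
        for rec in records:
            g = grp.create_group(rec.record_id)
            g.attrs["profile_id"] = rec.profile_id
            g.attrs["combo_id"] = rec.combo_id
            g.attrs["mixture_weight"] = rec.pair.mixture_weight
            g.attrs["scale"] = rec.pair.scale
            g.attrs["seed"] = rec.seed
            g.create_dataset("insult_ce", data=rec.pair.theta_ce)
            g.create_dataset("insult_delta", data=rec.pair.theta_delta)
            g.create_dataset("profile", data=rec.profile)
            g.create_dataset("d_heat", data=rec.heat.d)
            g.create_dataset("D_heat", data=rec.heat.D)
            g.create_dataset("d_gray", data=rec.gray.d, dtype=np.uint8)
            g.create_dataset("D_gray", data=rec.gray.D, dtype=np.uint8)
            fl = rec.fields
            for name, arr in (("lam", fl.lam), ("m_plus", fl.m_plus),
                              ("h", fl.h), ("r_dia", fl.r_dia),
                              ("r_sys", fl.r_sys), ("sigma_tt", fl.sigma_tt),
                              ("sigma_zz", fl.sigma_zz),
                              ("shear_analog", fl.shear_analog)):
                g.create_dataset(name, data=arr)
        sg = f.create_group("split")
        dt = h5py.string_dtype()
        sg.create_dataset("train", data=np.array(split.train, dtype=dt))
        sg.create_dataset("test", data=np.array(split.test, dtype=dt))
        sg.attrs["seed"] = split.seed
        f.create_dataset("config", data=json.dumps(config or {}))


def read_dataset(path):
    """Load a container written by :func:`write_dataset`.

    Returns ``(records, split, config)``.  Raises ``DataFormatError`` on
    missing groups or wrong grayscale dtypes.
    """
    from .gr_membrane import VesselFields
    from .grf_insults import InsultPair

    with h5py.File(path, "r") as f:
        for group in ("records", "split"):
            if group not in f:
                raise DataFormatError(f"container is missing /{group}")
        if "config" not in f:
            raise DataFormatError("container is missing /config")
        d_range = tuple(f.attrs["d_range"])
        D_range = tuple(f.attrs["D_range"])
        records = []
        for rid in sorted(f["records"]):
            g = f["records"][rid]
            missing = [n for n in (*_FLOAT_FIELDS, *_GRAY_FIELDS)
                       if n not in g]
            if missing:
                raise DataFormatError(
                    f"/records/{rid} is missing datasets {missing}")
            for n in _GRAY_FIELDS:
                if g[n].dtype != np.uint8:
                    raise DataFormatError(
                        f"/records/{rid}/{n} must be 8-bit, got {g[n].dtype}")
            arr = {n: g[n][()] for n in (*_FLOAT_FIELDS, *_GRAY_FIELDS)}
            pair = InsultPair(theta_ce=arr["insult_ce"],
                              theta_delta=arr["insult_delta"],
                              mixture_weight=float(g.attrs["mixture_weight"]),
                              scale=float(g.attrs["scale"]),
                              profile_id=str(g.attrs["profile_id"]),
                              combo_id=str(g.attrs["combo_id"]))
            fields = VesselFields(lam=arr["lam"], m_plus=arr["m_plus"],
                                  h=arr["h"], r_dia=arr["r_dia"],
                                  r_sys=arr["r_sys"],
                                  sigma_tt=arr["sigma_tt"],
                                  sigma_zz=arr["sigma_zz"],
                                  shear_analog=arr["shear_analog"])
            heat = MapPair(d=arr["d_heat"], D=arr["D_heat"], encoding="heat",
                           d_range=d_range, D_range=D_range)
            gray = MapPair(d=arr["d_gray"], D=arr["D_gray"],
                           encoding="grayscale", d_range=d_range,
                           D_range=D_range)
            records.append(SampleRecord(
                profile_id=str(g.attrs["profile_id"]),
                combo_id=str(g.attrs["combo_id"]), profile=arr["profile"],
                pair=pair, fields=fields, heat=heat, gray=gray,
                seed=int(g.attrs["seed"])))
        split = DatasetSplit(
            train=tuple(s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["split"]["train"][()]),
            test=tuple(s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["split"]["test"][()]),
            seed=int(f["split"].attrs["seed"]))
        config = json.loads(f["config"][()])
    return records, split, config
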