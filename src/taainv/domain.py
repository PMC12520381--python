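"""Cylindrical computation domain.

The vessel surface is parameterized by the circumferential angle
``theta`` in ``[0, 2*pi)`` (periodic) and the axial coordinate ``z`` in
``[0, L]``.  All fields live on a uniform tensor grid whose first axis is
circumferential and whose second axis is axial, so ``field[i, j]`` is the
value at ``(theta_i, z_j)`` and ``numpy.roll(field, k, axis=0)`` is a rigid
rotation of the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid on the cylinder surface.

    Parameters
    ----------
    n_theta:
        Number of circumferential nodes covering ``[0, 2*pi)``; the node at
        ``2*pi`` is identified with the node at ``0`` and not duplicated.
    n_z:
        Number of axial nodes covering ``[0, length]`` inclusive.
    length:
        Nondimensional axial length of the segment.
    """

    n_theta: int = 41
    n_z: int = 41
    length: float = 1.0

    def __post_init__(self) -> None:
        if self.n_theta < 2 or self.n_z < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_theta, self.n_z)

    @property
    def theta(self) -> np.ndarray:
        """Circumferential node angles in radians, endpoint excluded."""
        return np.linspace(0.0, 2.0 * np.pi, self.n_theta, endpoint=False)

    @property
    def z(self) -> np.ndarray:
        """Axial node coordinates, endpoints included."""
        return np.linspace(0.0, self.length, self.n_z)

    @property
    def theta_hat(self) -> np.ndarray:
        """Normalized circumferential coordinate in ``[0, 1)``."""
        return self.theta / (2.0 * np.pi)

    @property
    def z_hat(self) -> np.ndarray:
        """Normalized axial coordinate in ``[0, 1]``."""
        return self.z / self.length

    def coords(self) -> np.ndarray:
        """Flattened ``(n_theta * n_z, 2)`` array of ``{theta_hat, z_hat}``.

        Row ordering matches ``field.reshape(-1)`` for fields of shape
        ``(n_theta, n_z)``.  These normalized coordinates are what the
        operator trunk networks consume.
        """
        th, zz = np.meshgrid(self.theta_hat, self.z_hat, indexing="ij")
        return np.stack([th.reshape(-1), zz.reshape(-1)], axis=1)
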