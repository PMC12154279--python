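"""Phase-encoded FID-CSI acquisition geometry and timing.

Models a 2-D phase-encoded FID-CSI read-out: one free-induction decay per
phase-encoding step, concentric (center-out) encode ordering over a
circularly reduced k-space, a variable flip angle (VFA) schedule that
compensates the non-recoverable consumption of hyperpolarized
magnetization, and a fixed delay between excitation and the start of data
acquisition that truncates the first FID samples.

Conventions (locked so enumeration oracles are well defined):

* k-space grid indices ``0..matrix-1`` map to integer k coordinates
  ``k = index - matrix//2`` (half-open grid ``[-matrix/2, matrix/2)``,
  k = 0 at index ``matrix//2``).
* circular reduction keeps encodes with ``||k|| <= matrix/2`` (inclusive);
* concentric ordering sorts by increasing ``||k||``, ties broken by polar
  angle ``atan2(ky, kx)`` in [0, 2*pi), then by ky.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import DEFAULT_F0_MHZ

__all__ = [
    "AcquisitionParams",
    "k_coords",
    "circular_mask",
    "concentric_order",
    "default_flip_schedule",
    "encode_times",
]


def k_coords(matrix: int) -> np.ndarray:
    """Integer k coordinates for each grid index (k = index - matrix//2)."""
    return np.arange(matrix) - matrix // 2


def circular_mask(matrix: int) -> np.ndarray:
    """Boolean (ky, kx) mask of encodes with ||k|| <= matrix/2."""
    k = k_coords(matrix)
    ky, kx = np.meshgrid(k, k, indexing="ij")
    return ky**2 + kx**2 <= (matrix / 2) ** 2


def concentric_order(mask: np.ndarray) -> np.ndarray:
    """Sampled encodes as (iy, ix) index pairs in center-out acquisition order."""
    matrix = mask.shape[0]
    k = k_coords(matrix)
    iy, ix = np.nonzero(mask)
    ky, kx = k[iy], k[ix]
    radius = np.hypot(ky, kx)
    angle = np.mod(np.arctan2(ky, kx), 2 * np.pi)
    order = np.lexsort((ky, angle, radius))
    return np.column_stack((iy[order], ix[order]))


def default_flip_schedule(n_encodes: int) -> np.ndarray:
    """Constant-transverse-signal VFA schedule, degrees.

    theta_i = arctan(1 / sqrt(N - i)) for i = 1..N; the final excitation is
    90 deg so every remaining unit of longitudinal magnetization is used.
    Ignoring relaxation, sin(theta_i) * prod_{j<i} cos(theta_j) is constant.
    """
    i = np.arange(1, n_encodes + 1)
    remaining = np.sqrt((n_encodes - i).astype(float))
    return np.degrees(np.arctan2(1.0, remaining))


@dataclass(frozen=True)
class AcquisitionParams:
    """FID-CSI protocol parameters (defaults mirror the simulated protocol:
    16x16 matrix, 60 mm FOV, 256 spectral points at 5 kHz bandwidth, 8 mm
    slice, 16 s total acquisition starting 30 s after bolus start)."""

    matrix: int = 16
    fov_mm: float = 60.0
    n_spectral: int = 256
    spectral_bw_hz: float = 5000.0
    slice_mm: float = 8.0
    total_time_s: float = 16.0
    n_missing: int = 4
    field_t: float = 3.0
    f0_mhz: float = DEFAULT_F0_MHZ
    start_time_s: float = 30.0
    noise_sigma: float = 0.0
    seed: int = 0
    flip_schedule: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.matrix < 2 or self.matrix % 2:
            raise ValueError("matrix must be a positive even integer")
        if self.n_spectral < 8:
            raise ValueError("n_spectral too small")
        if self.n_missing < 0 or self.n_missing >= self.n_spectral:
            raise ValueError("n_missing must be in [0, n_spectral)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        n_enc = self.n_encodes
        readout = self.n_spectral / self.spectral_bw_hz
        if readout > self.total_time_s / n_enc:
            raise ValueError(
                f"readout ({readout:.3f} s) exceeds the per-encode window "
                f"({self.total_time_s / n_enc:.3f} s)"
            )
        if self.flip_schedule is not None:
            flips = np.asarray(self.flip_schedule, dtype=float)
            if len(flips) != n_enc:
                raise ValueError(
                    f"flip_schedule has {len(flips)} entries but "
                    f"{n_enc} encodes are sampled"
                )
            if np.any(flips <= 0) or np.any(flips > 90):
                raise ValueError("flip angles must lie in (0, 90] degrees")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_bw_hz

    @property
    def n_encodes(self) -> int:
        return int(circular_mask(self.matrix).sum())

    def flips_deg(self) -> np.ndarray:
        if self.flip_schedule is not None:
            return np.asarray(self.flip_schedule, dtype=float)
        return default_flip_schedule(self.n_encodes)


def encode_times(acq: AcquisitionParams) -> np.ndarray:
    """Excitation times (s, from bolus start) of each encode, uniformly
    spread over the total acquisition window."""
    n = acq.n_encodes
    return acq.start_time_s + np.arange(n) * (acq.total_time_s / n)
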