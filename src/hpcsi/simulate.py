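"""Forward synthesis of phase-encoded FID-CSI raw data.

Each compartment of the phantom carries the metabolite magnetization
curves from :mod:`hpcsi.kinetics`.  At encode ``e`` (excitation time
``t_e``, flip ``theta_e``) the transverse signal of metabolite ``m`` in a
voxel of compartment ``c`` is

    A = M_{m,c}(t_e) * sin(theta_e) * prod_{j<e} cos(theta_j)

i.e. the longitudinal pool is depleted by cos(theta) at every previous
excitation (hyperpolarized magnetization is not recovered).  The voxel FID
is ``sum_m A_m * exp(i*2*pi*df_m*t - t/T2*_m)`` and the k-space sample is
the 2-D discrete Fourier transform of the voxel image at each FID time
point.  The first ``n_missing`` FID points (excitation-acquisition delay)
are discarded; the stored FID therefore starts at ``t = n_missing*dwell``
and has length ``n_spectral - n_missing``, with ``n_missing`` kept as
metadata so reconstruction can restore the full length by backward linear
prediction.  Independent circular complex Gaussian noise (per-component
standard deviation ``noise_sigma``) is added to every stored sample of
every sampled encode; encodes outside the circular mask are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams, circular_mask, concentric_order, encode_times
from .kinetics import BolusInput, simulate_bolus, simulate_metabolite_dynamics
from .peaks import DEFAULT_PEAKS, METABOLITES, MetabolitePeak, offset_hz
from .phantom import Phantom

__all__ = [
    "KSpaceData",
    "synthesize_kspace",
    "calibrate_noise_sigma",
    "compartment_signal_amplitudes",
    "ground_truth_roi_ratio",
]


@dataclass
class KSpaceData:
    """Raw phase-encoded FID-CSI data.

    ``data`` is complex, shaped (n_ky, n_kx, n_t) with the truncated FID on
    the last axis; ``mask`` marks sampled encodes; ``encode_order`` lists
    (iy, ix) index pairs in acquisition order.
    """

    data: np.ndarray
    mask: np.ndarray
    encode_order: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("k-space data must be (n_ky, n_kx, n_t) with square grid")
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match the k-space grid")
        order_set = {tuple(p) for p in np.asarray(self.encode_order)}
        mask_set = {tuple(p) for p in np.column_stack(np.nonzero(self.mask))}
        if order_set != mask_set or len(order_set) != len(self.encode_order):
            raise ValueError("encode_order must cover exactly the sampled encodes, once each")
        if np.any(self.data[~self.mask]):
            raise ValueError("unsampled encodes must be exactly zero")

    @property
    def n_stored(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "KSpaceData":
        return KSpaceData(
            self.data.copy(), self.mask.copy(), self.encode_order.copy(), self.acq
        )


def _centered_fft2(image: np.ndarray) -> np.ndarray:
    """2-D DFT with the image/k-space origin at index matrix//2."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))


def _encode_weights(flips_deg: np.ndarray) -> np.ndarray:
    """sin(theta_e) * prod_{j<e} cos(theta_j) per encode."""
    th = np.radians(flips_deg)
    depletion = np.concatenate(([1.0], np.cumprod(np.cos(th))[:-1]))
    return np.sin(th) * depletion


def compartment_signal_amplitudes(
    phantom: Phantom,
    acq: AcquisitionParams,
    peaks: tuple[MetabolitePeak, ...] = DEFAULT_PEAKS,
    bolus: BolusInput | None = None,
    hydrate_fraction: float = 0.0,
) -> dict[int, np.ndarray]:
    """Per-compartment transverse amplitudes A[peak, encode] (a.u.).

    Combines the kinetic magnetization at each encode's excitation time
    with the VFA depletion law.  The optional pyruvate-hydrate confounder
    takes ``hydrate_fraction`` of the pyruvate pool.
    """
    if not 0 <= hydrate_fraction < 1:
        raise ValueError("hydrate_fraction must be in [0, 1)")
    names = [p.name for p in peaks]
    if hydrate_fraction > 0 and "pyruvate_hydrate" not in names:
        raise ValueError("hydrate_fraction > 0 requires a pyruvate_hydrate peak")

    t_enc = encode_times(acq)
    weights = _encode_weights(acq.flips_deg())
    bolus = bolus if bolus is not None else BolusInput()
    fine_t = np.linspace(0.0, float(t_enc[-1]), 2048)
    u = simulate_bolus(bolus, fine_t)

    amplitudes: dict[int, np.ndarray] = {}
    for label, kin in phantom.kinetics_by_label.items():
        curves = simulate_metabolite_dynamics(kin, u, fine_t)
        at_enc = np.vstack([np.interp(t_enc, fine_t, c) for c in curves])
        pool = dict(zip(METABOLITES, at_enc))
        rows = []
        for peak in peaks:
            if peak.name == "pyruvate":
                rows.append((1.0 - hydrate_fraction) * pool["pyruvate"])
            elif peak.name == "pyruvate_hydrate":
                rows.append(hydrate_fraction * pool["pyruvate"])
            else:
                rows.append(pool[peak.name])
        amplitudes[label] = np.vstack(rows) * weights
    return amplitudes


def synthesize_kspace(
    phantom: Phantom,
    acq: AcquisitionParams,
    peaks: tuple[MetabolitePeak, ...] = DEFAULT_PEAKS,
    bolus: BolusInput | None = None,
    hydrate_fraction: float = 0.0,
) -> KSpaceData:
    """Simulate raw k-space data for one subject (deterministic per seed)."""
    m = acq.matrix
    if phantom.label_map.shape != (m, m):
        raise ValueError("phantom grid must match the acquisition matrix")

    mask = circular_mask(m)
    order = concentric_order(mask)
    amplitudes = compartment_signal_amplitudes(
        phantom, acq, peaks, bolus, hydrate_fraction
    )

    n_keep = acq.n_spectral - acq.n_missing
    t_fid = (acq.n_missing + np.arange(n_keep)) * acq.dwell_s
    basis = np.vstack(
        [
            np.exp((2j * np.pi * offset_hz(p, acq.f0_mhz) - 1.0 / p.t2star) * t_fid)
            for p in peaks
        ]
    )  # (n_peaks, n_t)

    labels = sorted(amplitudes)
    # spatial spectrum of each compartment indicator
    fvals = np.vstack(
        [
            _centered_fft2((phantom.label_map == lab).astype(float))[
                order[:, 0], order[:, 1]
            ]
            for lab in labels
        ]
    )  # (n_labels, n_enc)
    amp = np.stack([amplitudes[lab] for lab in labels])  # (n_labels, n_peaks, n_enc)

    # FID of each (label, encode): (n_labels, n_enc, n_t)
    fids = np.einsum("lpe,pt->let", amp, basis)
    enc_fids = np.einsum("le,let->et", fvals, fids)

    data = np.zeros((m, m, n_keep), dtype=complex)
    data[order[:, 0], order[:, 1], :] = enc_fids
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(acq.seed)
        noise = acq.noise_sigma * (
            rng.standard_normal((len(order), n_keep))
            + 1j * rng.standard_normal((len(order), n_keep))
        )
        data[order[:, 0], order[:, 1], :] += noise
    return KSpaceData(data, mask, order, acq)


def calibrate_noise_sigma(
    phantom: Phantom,
    acq: AcquisitionParams,
    target_snr: float,
    peaks: tuple[MetabolitePeak, ...] = DEFAULT_PEAKS,
    bolus: BolusInput | None = None,
) -> float:
    """Noise level giving the requested raw-data SNR.

    SNR is defined as the peak magnitude of the k-space-center FID
    (dominated by pyruvate) divided by the per-component noise standard
    deviation.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    noiseless = synthesize_kspace(phantom, acq, peaks, bolus)
    c = acq.matrix // 2
    peak_signal = float(np.abs(noiseless.data[c, c, :]).max())
    return peak_signal / target_snr


def ground_truth_roi_ratio(
    phantom: Phantom,
    acq: AcquisitionParams,
    roi: np.ndarray,
    numerator: str = "bicarbonate",
    denominator: str = "pyruvate",
    peaks: tuple[MetabolitePeak, ...] = DEFAULT_PEAKS,
    bolus: BolusInput | None = None,
) -> float:
    """Kinetics-level (point-spread-free) metabolite signal ratio in *roi*.

    Sums each metabolite's encode amplitudes over the acquisition and
    averages over the ROI voxels on the native grid.  This ignores the
    acquisition PSF and so differs from reconstructed ratios near
    compartment boundaries.
    """
    names = [p.name for p in peaks]
    amplitudes = compartment_signal_amplitudes(phantom, acq, peaks, bolus)
    totals = {lab: a.sum(axis=1) for lab, a in amplitudes.items()}  # per-peak sums
    num = den = 0.0
    for lab in np.unique(phantom.label_map[roi]):
        if lab == 0:
            continue
        n_vox = int(((phantom.label_map == lab) & roi).sum())
        num += n_vox * totals[lab][names.index(numerator)]
        den += n_vox * totals[lab][names.index(denominator)]
    if den == 0:
        raise ValueError("denominator signal is zero in the ROI")
    return float(num / den)
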