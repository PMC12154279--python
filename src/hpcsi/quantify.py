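"""Metabolite maps, ratio maps, ROI spectra and peak quantification.

Metabolite maps integrate the phased (absorption-mode) spectrum over a
44 Hz window centered on each resonance; ROI-level quantification fits a
Gaussian plus constant baseline to each peak of the ROI-averaged spectrum.
Peak centers are referenced globally: the pyruvate resonance is located in
the highest-SNR pyruvate voxel and all other centers follow at their fixed
chemical-shift offsets (per-voxel searches would fail for low-SNR
bicarbonate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .peaks import DEFAULT_PEAKS, MetabolitePeak, offset_hz
from .recon import SpectralImage

__all__ = [
    "DEFAULT_WINDOW_HZ",
    "MetaboliteMaps",
    "PeakFit",
    "RATIO_PAIRS",
    "integrate_peak",
    "compute_metabolite_maps",
    "compute_ratio_maps",
    "average_roi_spectrum",
    "fit_peak_gaussian",
    "quantify_rois",
    "ratio_table",
]

DEFAULT_WINDOW_HZ = 44.0

#: (name, numerator, denominator) of the reported ratio metrics
RATIO_PAIRS = (
    ("lac_pyr", "lactate", "pyruvate"),
    ("bic_pyr", "bicarbonate", "pyruvate"),
    ("bic_lac", "bicarbonate", "lactate"),
    ("ala_pyr", "alanine", "pyruvate"),
)


@dataclass
class MetaboliteMaps:
    """Per-metabolite absorption-mode integral maps (a.u.)."""

    maps: dict[str, np.ndarray]
    window_hz: float
    centers_hz: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        for name, m in self.maps.items():
            if not np.all(np.isfinite(m)):
                raise ValueError(f"non-finite values in {name} map")


@dataclass
class PeakFit:
    """Result of a Gaussian peak fit: area = amplitude * sigma * sqrt(2*pi)."""

    center: float
    amplitude: float
    sigma: float
    area: float
    rmse: float
    rejected: bool = False


def integrate_peak(
    spectrum: np.ndarray,
    freq_hz: np.ndarray,
    center: float,
    window: float = DEFAULT_WINDOW_HZ,
) -> float:
    """Absorption-mode peak area: sum of the real part over the bins whose
    centers lie in [center - window/2, center + window/2], times the bin
    width."""
    freq = np.asarray(freq_hz)
    df = float(freq[1] - freq[0])
    if window <= df:
        raise ValueError("integration window must exceed the spectral bin width")
    if center - window / 2 < freq[0] or center + window / 2 > freq[-1]:
        raise ValueError("integration window extends beyond the frequency axis")
    sel = np.abs(freq - center) <= window / 2
    return float(np.sum(np.real(np.asarray(spectrum)[..., sel]), axis=-1) * df)


def _global_reference_shift(
    img: SpectralImage, peaks: tuple[MetabolitePeak, ...], search_hz: float
) -> tuple[float, tuple[int, int]]:
    """Frequency calibration offset from the maximum-SNR pyruvate voxel."""
    pyr = next(p for p in peaks if p.name == "pyruvate")
    f0 = img.provenance["acq"].f0_mhz if "acq" in img.provenance else None
    nominal = offset_hz(pyr, f0) if f0 else offset_hz(pyr)
    sel = np.abs(img.freq_hz - nominal) <= search_hz / 2
    windowed = np.abs(img.spectra[:, :, sel])
    flat = windowed.max(axis=2)
    iy, ix = np.unravel_index(np.argmax(flat), flat.shape)
    spec = np.real(img.spectra[iy, ix, sel])
    found = img.freq_hz[sel][np.argmax(spec)]
    return float(found - nominal), (int(iy), int(ix))


def compute_metabolite_maps(
    img: SpectralImage,
    peaks: tuple[MetabolitePeak, ...] = DEFAULT_PEAKS,
    window_hz: float = DEFAULT_WINDOW_HZ,
    search_hz: float = 60.0,
    source: str = "",
) -> MetaboliteMaps:
    """Integrate each metabolite window in every voxel of a phased image."""
    if not img.phased:
        raise ValueError("spectra must be phased before absorption-mode integration")
    f0 = img.provenance["acq"].f0_mhz if "acq" in img.provenance else None
    nominal = {p.name: (offset_hz(p, f0) if f0 else offset_hz(p)) for p in peaks}
    names = sorted(nominal, key=nominal.get)
    for a, b in zip(names, names[1:]):
        if nominal[b] - nominal[a] < window_hz:
            raise ValueError(
                f"integration windows of {a!r} and {b!r} overlap "
                f"({nominal[a]:.1f} and {nominal[b]:.1f} Hz)"
            )
    shift, _ = _global_reference_shift(img, peaks, search_hz)
    centers = {name: nominal[name] + shift for name in nominal}

    df = img.df_hz
    maps = {}
    for name, center in centers.items():
        sel = np.abs(img.freq_hz - center) <= window_hz / 2
        maps[name] = np.real(img.spectra[:, :, sel]).sum(axis=2) * df
    return MetaboliteMaps(maps, window_hz, centers, source=source)


def compute_ratio_maps(
    maps: MetaboliteMaps,
    brain_mask: np.ndarray,
    floor: float | None = None,
) -> dict[str, np.ndarray]:
    """Voxelwise ratio maps inside *brain_mask*.

    Voxels with denominator below *floor* are undefined (NaN), not zero.
    The default floor is 3x the noise SD of the denominator map, estimated
    robustly (1.4826*MAD) from voxels outside the mask.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    if floor is not None and floor < 0:
        raise ValueError("floor must be >= 0")

    out: dict[str, np.ndarray] = {}
    for name, num_name, den_name in RATIO_PAIRS:
        num, den = maps.maps[num_name], maps.maps[den_name]
        if floor is None:
            bg = den[~mask]
            f = 3.0 * 1.4826 * float(np.median(np.abs(bg - np.median(bg))))
        else:
            f = floor
        ratio = np.full(den.shape, np.nan)
        ok = mask & (den > f)
        ratio[ok] = num[ok] / den[ok]
        out[name] = ratio
    return out


def average_roi_spectrum(img: SpectralImage, roi: np.ndarray) -> np.ndarray:
    """Complex mean spectrum over the ROI voxels."""
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != img.spectra.shape[:2]:
        raise ValueError("ROI shape does not match the image grid")
    if not mask.any():
        raise ValueError("ROI is empty")
    return img.spectra[mask, :].mean(axis=0)


def _gaussian_baseline(f, amplitude, center, sigma, baseline):
    return amplitude * np.exp(-((f - center) ** 2) / (2.0 * sigma**2)) + baseline


def fit_peak_gaussian(
    spectrum: np.ndarray,
    freq_hz: np.ndarray,
    center: float,
    search_window: float = 60.0,
    noise_sd: float | None = None,
    sigma_bounds: tuple[float, float] | None = None,
) -> PeakFit:
    """Gaussian + constant-baseline least-squares fit of one peak.

    Initialized from the window maximum and second moment.  The fit is
    rejected (``area = nan``) if the fitted amplitude is below 3x the
    spectral noise SD (estimated from the spectrum edges when not given).
    Non-convergence yields a rejected result, not an exception.
    ``sigma_bounds`` constrains the linewidth, e.g. to that of a strong
    reference peak when all species share the processing-dominated
    lineshape.
    """
    f = np.asarray(freq_hz, dtype=float)
    y = np.real(np.asarray(spectrum, dtype=complex))
    if noise_sd is None:
        n_edge = max(8, f.size // 20)
        edge = np.concatenate([y[:n_edge], y[-n_edge:]])
        noise_sd = float(np.std(edge))

    sel = np.abs(f - center) <= search_window / 2
    if sel.sum() < 6:
        raise ValueError("search window contains too few spectral bins")
    fw, yw = f[sel], y[sel]

    baseline0 = float(np.median(yw))
    amp0 = float(yw.max() - baseline0)
    c0 = float(fw[np.argmax(yw)])
    w = np.clip(yw - baseline0, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (fw - c0) ** 2) / w.sum())) if w.sum() > 0 else 5.0
    bin_width = float(fw[1] - fw[0])
    sigma_lo, sigma_hi = sigma_bounds or (bin_width / 2.0, search_window / 3.0)
    sigma0 = float(np.clip(sigma0, sigma_lo, sigma_hi))
    # the peak is known to lie near *center* (global frequency reference);
    # bounding the center keeps the fit off neighbouring resonances
    c_half = search_window / 4.0

    try:
        popt, _ = curve_fit(
            _gaussian_baseline,
            fw,
            yw,
            p0=(amp0, np.clip(c0, center - c_half, center + c_half), sigma0, baseline0),
            bounds=(
                (-np.inf, center - c_half, sigma_lo, -np.inf),
                (np.inf, center + c_half, sigma_hi, np.inf),
            ),
            maxfev=5000,
        )
    except RuntimeError:
        return PeakFit(center, 0.0, np.nan, np.nan, np.nan, rejected=True)

    amplitude, c_fit, sigma, baseline = popt
    resid = yw - _gaussian_baseline(fw, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    rejected = bool(amplitude < 3.0 * noise_sd)
    area = float(amplitude * sigma * np.sqrt(2.0 * np.pi))
    if rejected:
        area = np.nan
    return PeakFit(float(c_fit), float(amplitude), float(sigma), area, rmse, rejected)


def quantify_rois(
    img: SpectralImage,
    rois: dict[str, np.ndarray],
    peaks: tuple[MetabolitePeak, ...] = DEFAULT_PEAKS,
    subject: str = "subject",
    group: str = "naive",
    window_hz: float = DEFAULT_WINDOW_HZ,
    search_hz: float = 60.0,
    fit_window_hz: float = 120.0,
) -> pd.DataFrame:
    """Fit every metabolite in every ROI-averaged spectrum.

    Returns a tidy table with one row per (ROI, metabolite): fitted area,
    fit diagnostics and a rejection flag.  Requires ``ipsi``, ``contra``
    and ``muscle`` ROIs (the latter provides the Ala_muscle normalization
    downstream).  ``fit_window_hz`` is the span handed to the Gaussian
    fit; it is wider than the integration window so the baseline is
    identifiable next to the full linewidth.
    """
    for required in ("ipsi", "contra", "muscle"):
        if required not in rois:
            raise ValueError(f"missing required ROI {required!r}")
    if not img.phased:
        raise ValueError("spectra must be phased before quantification")

    f0 = img.provenance["acq"].f0_mhz if "acq" in img.provenance else None
    nominal = {p.name: (offset_hz(p, f0) if f0 else offset_hz(p)) for p in peaks}
    shift, _ = _global_reference_shift(img, peaks, search_hz)

    ordered = sorted(peaks, key=lambda p: p.name != "pyruvate")  # reference first
    rows = []
    for roi_name, roi in rois.items():
        spec = average_roi_spectrum(img, roi)
        sigma_ref = None
        for peak in ordered:
            # weak resonances share the processing-dominated linewidth of
            # the pyruvate reference fit in the same spectrum
            bounds = (0.6 * sigma_ref, 1.5 * sigma_ref) if sigma_ref else None
            fit = fit_peak_gaussian(
                spec,
                img.freq_hz,
                nominal[peak.name] + shift,
                search_window=fit_window_hz,
                sigma_bounds=bounds,
            )
            if peak.name == "pyruvate" and not fit.rejected and np.isfinite(fit.sigma):
                sigma_ref = fit.sigma
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "roi": roi_name,
                    "metabolite": peak.name,
                    "area": fit.area,
                    "amplitude": fit.amplitude,
                    "sigma_hz": fit.sigma,
                    "center_hz": fit.center,
                    "rmse": fit.rmse,
                    "rejected": fit.rejected,
                }
            )
    return pd.DataFrame(rows)


def ratio_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(subject, ROI) table of fitted areas and derived ratios.

    Adds ``lac_pyr``, ``bic_pyr``, ``bic_lac``, ``ala_pyr`` and the
    ``*_ala_muscle`` normalizations (brain areas divided by the muscle-ROI
    alanine area of the same subject).  Ratios are NaN wherever the
    denominator is rejected or non-positive.
    """
    wide = quant.pivot_table(
        index=["subject", "group", "roi"],
        columns="metabolite",
        values="area",
        dropna=False,
    ).reset_index()
    wide.columns.name = None

    for name, num, den in RATIO_PAIRS:
        if num in wide.columns and den in wide.columns:
            d = wide[den].to_numpy(dtype=float)
            n = wide[num].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                wide[name] = np.where(d > 0, n / d, np.nan)
        else:
            wide[name] = np.nan

    muscle_ala = (
        quant[(quant.roi == "muscle") & (quant.metabolite == "alanine")]
        .set_index("subject")["area"]
    )
    if muscle_ala.isna().any() or muscle_ala.empty:
        warnings.warn(
            "muscle alanine fit missing/rejected; *_ala_muscle columns undefined",
            stacklevel=2,
        )
    ref = wide["subject"].map(muscle_ala).to_numpy(dtype=float)
    for met in ("pyruvate", "lactate", "bicarbonate", "alanine"):
        if met in wide:
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = wide[met].to_numpy(dtype=float) / ref
            wide[f"{met[:3]}_ala_muscle"] = np.where(ref > 0, vals, np.nan)
    return wide
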