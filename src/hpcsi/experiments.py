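"""Cohort-level simulation experiments and calibration studies.

Everything here is deterministic given a seed: subject seeds are drawn
from a single generator, inter-subject biological variability is modelled
as lognormal jitter on the conversion rates, and the receive-chain noise
level is calibrated once per cohort to the requested raw-data SNR.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .config import CohortConfig, PipelineConfig, SimConfig
from .peaks import DEFAULT_PEAKS, PYRUVATE_HYDRATE
from .phantom import Phantom, PhantomSpec, build_phantom, roi_masks
from .quantify import quantify_rois, ratio_table
from .recon import phase_correct, reconstruct
from .simulate import (
    calibrate_noise_sigma,
    ground_truth_roi_ratio,
    synthesize_kspace,
)
from .stats import GroupSample, group_compare, paired_compare, relative_difference

__all__ = [
    "acquisition_from_sim",
    "make_phantom",
    "jitter_kinetics",
    "simulate_subject",
    "cohort_table",
    "noiseless_rel_diff",
    "kinetics_level_rel_diff",
    "hemisphere_recovery_experiment",
    "type1_error_calibration",
    "paired_power_calibration",
]

_MAX_SEED = 2**31 - 1


def acquisition_from_sim(
    sim: SimConfig, seed: int = 0, noise_sigma: float = 0.0
) -> AcquisitionParams:
    return AcquisitionParams(
        matrix=sim.matrix,
        fov_mm=sim.fov_mm,
        n_spectral=sim.n_spectral,
        spectral_bw_hz=sim.spectral_bw_hz,
        slice_mm=sim.slice_mm,
        total_time_s=sim.total_time_s,
        n_missing=sim.n_missing,
        f0_mhz=sim.f0_mhz,
        start_time_s=sim.start_time_s,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_phantom(sim: SimConfig, cohort: CohortConfig, injured: bool) -> Phantom:
    return build_phantom(
        PhantomSpec(
            matrix=sim.matrix,
            fov_mm=sim.fov_mm,
            injured=injured,
            lesion_kpb_scale=cohort.lesion_kpb_scale,
        )
    )


def jitter_kinetics(
    phantom: Phantom, rng: np.random.Generator, sd: float
) -> Phantom:
    """Per-subject biological variability: one lognormal factor per
    conversion pathway, shared across compartments (so the lesion-to-
    healthy k_PB contrast is preserved within a subject)."""
    if sd == 0:
        return phantom
    f_pl, f_pb, f_pa = np.exp(rng.normal(0.0, sd, size=3))
    new = {
        lab: replace(
            kin, k_pl=kin.k_pl * f_pl, k_pb=kin.k_pb * f_pb, k_pa=kin.k_pa * f_pa
        )
        for lab, kin in phantom.kinetics_by_label.items()
    }
    return Phantom(phantom.label_map, new, phantom.grid_fov_mm, phantom.spec)


def simulate_subject(
    cfg: PipelineConfig,
    injured: bool,
    subject_seed: int,
    subject_id: str,
    noise_sigma: float,
    jitter_rng: np.random.Generator | None = None,
    return_objects: bool = False,
):
    """Simulate, reconstruct and quantify one subject.

    Returns the wide per-ROI ratio table (one row per ROI); with
    ``return_objects`` also the raw k-space and phased spectral image.
    """
    phantom = make_phantom(cfg.sim, cfg.cohort, injured)
    if jitter_rng is not None:
        phantom = jitter_kinetics(phantom, jitter_rng, cfg.cohort.rate_jitter_sd)
    acq = acquisition_from_sim(cfg.sim, seed=subject_seed, noise_sigma=noise_sigma)
    peaks = DEFAULT_PEAKS
    if cfg.sim.hydrate_fraction > 0:
        peaks = DEFAULT_PEAKS + (PYRUVATE_HYDRATE,)
    k = synthesize_kspace(
        phantom, acq, peaks=peaks, hydrate_fraction=cfg.sim.hydrate_fraction
    )
    img = phase_correct(reconstruct(k, cfg.recon))
    rois = roi_masks(phantom, upsample=cfg.recon.spatial_zf_factor)
    quant = quantify_rois(
        img,
        {name: rois[name] for name in ("ipsi", "contra", "muscle")},
        peaks=DEFAULT_PEAKS,
        subject=subject_id,
        group="injury" if injured else "naive",
        window_hz=cfg.quantify.window_hz,
        search_hz=cfg.quantify.search_hz,
    )
    wide = ratio_table(quant)
    if return_objects:
        return wide, k, img, quant
    return wide


def cohort_table(cfg: PipelineConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate a full cohort and return the stacked per-ROI ratio table."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sigma_by_group = {
        injured: calibrate_noise_sigma(
            make_phantom(cfg.sim, cfg.cohort, injured),
            acquisition_from_sim(cfg.sim),
            cfg.cohort.target_snr,
        )
        for injured in (False, True)
    }
    frames = []
    plan = [("naive", False, cfg.cohort.n_naive), ("injury", True, cfg.cohort.n_injury)]
    for group, injured, n in plan:
        for i in range(n):
            subject_seed = int(rng.integers(0, _MAX_SEED))
            frames.append(
                simulate_subject(
                    cfg,
                    injured,
                    subject_seed,
                    f"{group}_{i + 1:02d}",
                    sigma_by_group[injured],
                    jitter_rng=rng,
                )
            )
    return pd.concat(frames, ignore_index=True)


def _subject_rel_diff(wide: pd.DataFrame, metric: str) -> float:
    by_roi = wide.set_index("roi")[metric]
    return relative_difference(float(by_roi["ipsi"]), float(by_roi["contra"]))


def noiseless_rel_diff(cfg: PipelineConfig, metric: str = "bic_pyr") -> float:
    """Ground-truth hemisphere relative difference of the deterministic
    forward model: one injured subject, no noise, no jitter, full
    reconstruction and quantification."""
    wide = simulate_subject(cfg, True, 0, "truth", noise_sigma=0.0)
    return _subject_rel_diff(wide, metric)


def kinetics_level_rel_diff(cfg: PipelineConfig) -> float:
    """PSF-free Bic/Pyr hemisphere relative difference straight from the
    compartment kinetics (reference value; ignores spatial encoding)."""
    phantom = make_phantom(cfg.sim, cfg.cohort, injured=True)
    acq = acquisition_from_sim(cfg.sim)
    rois = roi_masks(phantom, upsample=1)
    r_ipsi = ground_truth_roi_ratio(phantom, acq, rois["ipsi"])
    r_contra = ground_truth_roi_ratio(phantom, acq, rois["contra"])
    return relative_difference(r_ipsi, r_contra)


def hemisphere_recovery_experiment(
    cfg: PipelineConfig,
    seed: int,
    n_seeds: int = 20,
    n_per_group: int = 5,
) -> pd.DataFrame:
    """Repeated-cohort recovery study of the Bic/Pyr hemisphere asymmetry.

    For each of *n_seeds* replicate cohorts (*n_per_group* injured and
    naive subjects each) the per-subject relative differences are
    computed; the returned frame has one row per replicate with the
    injured-cohort mean, the naive-cohort mean and the naive paired
    ipsi-vs-contra p-value.
    """
    cfg = replace(
        cfg, cohort=replace(cfg.cohort, n_naive=n_per_group, n_injury=n_per_group)
    )
    master = np.random.default_rng(seed)
    rows = []
    for rep in range(n_seeds):
        table = cohort_table(cfg, seed=int(master.integers(0, _MAX_SEED)))
        rel = {
            group: np.array(
                [
                    _subject_rel_diff(sub, "bic_pyr")
                    for _, sub in table[table.group == group].groupby("subject")
                ]
            )
            for group in ("injury", "naive")
        }
        naive = table[table.group == "naive"]
        ipsi = naive[naive.roi == "ipsi"].sort_values("subject")["bic_pyr"]
        contra = naive[naive.roi == "contra"].sort_values("subject")["bic_pyr"]
        ok = ipsi.notna().to_numpy() & contra.notna().to_numpy()
        paired = paired_compare(
            GroupSample(tuple(ipsi[ok]), "naive", "bic_pyr"),
            GroupSample(tuple(contra[ok]), "naive", "bic_pyr"),
        )
        rows.append(
            {
                "replicate": rep,
                "injury_rel_diff_mean": float(np.nanmean(rel["injury"])),
                "naive_rel_diff_mean": float(np.nanmean(rel["naive"])),
                "naive_paired_p": paired.p_value,
                "n_injury_valid": int(np.isfinite(rel["injury"]).sum()),
                "n_naive_valid": int(np.isfinite(rel["naive"]).sum()),
            }
        )
    return pd.DataFrame(rows)


def type1_error_calibration(
    seed: int, n_reps: int = 10_000, n_per_group: int = 5
) -> float:
    """Empirical type-I error of the gated group comparison under the null
    (both groups standard normal)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = GroupSample(tuple(rng.standard_normal(n_per_group)), "a")
        b = GroupSample(tuple(rng.standard_normal(n_per_group)), "b")
        if group_compare(a, b).p_value < 0.05:
            rejections += 1
    return rejections / n_reps


def paired_power_calibration(
    seed: int,
    n_reps: int = 10_000,
    n: int = 5,
    delta: float = 1.0,
    sigma: float = 1.0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Empirical power of the paired t-test vs the noncentral-t closed form.

    Paired differences are N(delta, sigma^2); returns (empirical, theory).
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        contra = rng.standard_normal(n)
        ipsi = contra + delta + sigma * rng.standard_normal(n)
        if paired_compare(GroupSample(tuple(ipsi)), GroupSample(tuple(contra))).p_value < alpha:
            hits += 1
    df = n - 1
    nc = delta / (sigma / np.sqrt(n))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    theory = float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    return hits / n_reps, theory
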