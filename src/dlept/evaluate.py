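"""Quantitative evaluation of reconstructed electrical-property maps.

Per-tissue statistics over eroded regions of interest, normalized RMSE,
relative errors, SNR sweeps and the tumor-detection harness.  Statistics
are computed only over the intersection of the eroded tissue ROI and the
reconstruction's valid mask; standard deviations use the population
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hept import EpsMaps, erode_rois
from .models import TissueModel, LABEL_NAMES
from .noise import NoiseSpec, corrupt_acquisition

__all__ = ["EvalReport", "roi_statistics", "nrmse", "relative_error",
           "snr_sweep", "tumor_experiment", "contrast_to_noise"]


@dataclass
class EvalReport:
    """Per-tissue means/SDs plus global error metrics for one method."""

    method: str
    per_tissue: dict = field(default_factory=dict)   # name -> dict of stats
    nrmse_sigma: float = np.nan
    nrmse_epsr: float = np.nan
    rel_error: dict = field(default_factory=dict)    # name -> dict of %
    seeds: tuple = ()

    def as_dict(self):
        return {"method": self.method, "per_tissue": self.per_tissue,
                "nrmse_sigma": self.nrmse_sigma, "nrmse_epsr": self.nrmse_epsr,
                "rel_error": self.rel_error, "seeds": list(self.seeds)}


def roi_statistics(maps: EpsMaps, labels: np.ndarray, erosion: int = 3):
    """Mean and population SD of sigma and epsr per eroded tissue region.

    Regions that are empty after erosion (or after intersecting the
    valid mask) are omitted with a warning.
    """
    if labels.shape != maps.sigma_map.shape:
        raise ValueError("labels and maps are on different grids")
    eroded = erode_rois(labels, erosion)
    stats = {}
    for lab in np.unique(eroded):
        if lab == 0:
            continue
        roi = (eroded == lab) & maps.valid_mask
        name = LABEL_NAMES.get(int(lab), str(lab))
        if not roi.any():
            warnings.warn(f"ROI {name} empty after erosion/valid-mask")
            continue
        stats[name] = {
            "sigma_mean": float(maps.sigma_map[roi].mean()),
            "sigma_sd": float(maps.sigma_map[roi].std()),
            "epsr_mean": float(maps.epsr_map[roi].mean()),
            "epsr_sd": float(maps.epsr_map[roi].std()),
            "n_voxels": int(roi.sum()),
        }
    return stats


def nrmse(recon: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """RMSE over the mask normalized by the mean of the truth there."""
    if not mask.any():
        raise ValueError("empty evaluation mask")
    t = truth[mask]
    denom = t.mean()
    if denom == 0:
        raise ValueError("truth has zero mean over the mask")
    return float(np.sqrt(np.mean((recon[mask] - t) ** 2)) / denom)


def relative_error(recon_mean: float, truth: float) -> float:
    """Relative error of a reconstructed ROI mean, in percent."""
    if truth == 0:
        raise ValueError("truth value is zero")
    return float(100.0 * abs(recon_mean - truth) / abs(truth))


def contrast_to_noise(maps: EpsMaps, roi_a: np.ndarray, roi_b: np.ndarray,
                      which: str = "sigma") -> float:
    """CNR between two ROIs: |mean difference| / pooled SD."""
    m = maps.sigma_map if which == "sigma" else maps.epsr_map
    a = m[roi_a & maps.valid_mask]
    b = m[roi_b & maps.valid_mask]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    pooled = np.sqrt(0.5 * (a.std() ** 2 + b.std() ** 2))
    if pooled == 0:
        return np.inf if a.mean() != b.mean() else 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def snr_sweep(reconstruct, model: TissueModel, clean_acq, snr_levels,
              erosion: int = 3, n_seeds: int = 3, seed: int = 0,
              phase_sd_ref: float = 9e-3, snr_ref: float = 90.0):
    """Repeat corrupt -> reconstruct -> ROI statistics across SNR levels.

    ``reconstruct`` maps an Acquisition to EpsMaps (H-EPT closure or a
    trained-network predictor).  Phase noise is scaled with the
    magnitude noise (phase SD = phase_sd_ref * snr_ref / snr), keeping
    the two channels' noise levels consistent as in an acquisition whose
    overall SNR changes.  Returns a list of row dicts, one per
    (snr, seed), machine-readable.
    """
    rows = []
    for snr in snr_levels:
        for k in range(n_seeds):
            if np.isinf(snr):
                spec = NoiseSpec(snr_mag=np.inf, phase_sd=0.0,
                                 seed=seed + 997 * k)
            else:
                spec = NoiseSpec(snr_mag=snr,
                                 phase_sd=phase_sd_ref * snr_ref / snr,
                                 seed=seed + 997 * k)
            maps = reconstruct(corrupt_acquisition(clean_acq, spec))
            stats = roi_statistics(maps, model.label_grid, erosion)
            rows.append({"snr": float(snr), "seed": spec.seed,
                         "method": maps.method, "per_tissue": stats})
    return rows


def tumor_experiment(head: TissueModel, acq_noisy, predictors,
                     surround_label: int = 1, erosion: int = 3):
    """Tumor-detection comparison on a head with an inclusion.

    ``predictors`` maps method names to callables Acquisition -> EpsMaps
    (include an H-EPT closure for the baseline).  Reports tumor-ROI
    mean/SD, relative errors against the assigned tumor properties, and
    the tumor-to-surround contrast-to-noise ratio per method.
    """
    from .models import LABELS

    tumor_lab = LABELS["tumor"]
    if not np.any(head.label_grid == tumor_lab):
        raise ValueError("head model carries no tumor label")
    truth_sigma, truth_epsr = head.region_properties[tumor_lab]
    eroded = erode_rois(head.label_grid, erosion)
    tumor_roi = eroded == tumor_lab
    surround_roi = eroded == surround_label
    out = {}
    for name, rec_fn in predictors.items():
        maps = rec_fn(acq_noisy)
        res = {}
        for which, truth in (("sigma", truth_sigma), ("epsr", truth_epsr)):
            m = maps.sigma_map if which == "sigma" else maps.epsr_map
            roi = tumor_roi & maps.valid_mask
            if not roi.any():
                continue
            res[f"{which}_mean"] = float(m[roi].mean())
            res[f"{which}_sd"] = float(m[roi].std())
            res[f"{which}_rel_error"] = relative_error(m[roi].mean(), truth)
            res[f"{which}_cnr"] = contrast_to_noise(maps, tumor_roi,
                                                    surround_roi, which)
        out[name] = res
    return out
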