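"""End-to-end pipeline: simulate (or load) a study, build parametric maps,
fit kinetics, derive ROIs and summarize — with a reproducibility manifest.

The stage chain mirrors the analysis of a dynamic HP-13C exam:

1. AUC maps per metabolite; background noise sd; aSNR maps; SNR masks
   (aSNR >= 5).
2. SNR-masked metabolite ratio maps and brain-wide percentile rank maps.
3. Voxel-wise inputless kinetic fit on brain voxels passing the pyruvate
   SNR mask; modeling-error masks at 30% (kPL) / 50% (kPB).
4. 1H mask algebra (NEL, NAWM), mutually exclusive 30%/50% downsampling
   onto the 13C grid, lesion volumes.
5. Per-ROI medians and patient-internal NAWM normalization.

Every run is deterministic given its configuration (which includes the
phantom seed); the manifest records per-stage voxel counts and content
hashes of every artifact.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .acquisition import METABOLITES, AcquisitionParams
from .kinetics import KPB_ERROR_THRESHOLD, KPL_ERROR_THRESHOLD, KineticMaps, fit_map
from .maps import (
    ASNR_THRESHOLD,
    RatioMaps,
    compute_asnr,
    compute_auc,
    estimate_noise_sigma,
    percentile_rank_map,
    ratio_maps,
    snr_mask,
)
from .phantom import PhantomConfig, SyntheticStudy, generate_phantom
from .rois import MaskSet, RoiLabelMap, block_fractions, derive_rois, downsample_rois, volume_cc
from .summary import ScanSummary, normalize_to_nawm, parse_clinical_table, summarize_scan

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_parameter_maps", "brain_mask_13c"]

#: minimum fraction of a 13C voxel inside the 1H brain mask to count as brain
BRAIN_FRACTION_13C = 0.5


@dataclass
class PipelineConfig:
    """All constants of an end-to-end run.

    Threshold defaults are the published analysis constants: aSNR cutoff
    5, modeling-error cutoffs 30% (kPL) and 50% (kPB), ROI downsampling
    thresholds 30% (T2L) and 50% (NAWM).
    """

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    asnr_threshold: float = ASNR_THRESHOLD
    kpl_error_threshold: float = KPL_ERROR_THRESHOLD
    kpb_error_threshold: float = KPB_ERROR_THRESHOLD
    t2l_threshold: float = 0.30
    nawm_threshold: float = 0.50

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "acquisition": asdict(self.acquisition),
            "phantom": asdict(self.phantom),
            "thresholds": {
                "asnr": self.asnr_threshold,
                "kpl_error": self.kpl_error_threshold,
                "kpb_error": self.kpb_error_threshold,
                "t2l_fraction": self.t2l_threshold,
                "nawm_fraction": self.nawm_threshold,
            },
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        acq = payload.get("acquisition", {})
        pha = payload.get("phantom", {})
        for key in ("grid_13c", "brain_axes_frac", "lesion_center_frac", "lesion_axes_frac"):
            if key in pha and isinstance(pha[key], list):
                pha[key] = tuple(pha[key])
        thr = payload.get("thresholds", {})
        return cls(
            acquisition=AcquisitionParams(**acq),
            phantom=PhantomConfig(**pha),
            asnr_threshold=thr.get("asnr", ASNR_THRESHOLD),
            kpl_error_threshold=thr.get("kpl_error", KPL_ERROR_THRESHOLD),
            kpb_error_threshold=thr.get("kpb_error", KPB_ERROR_THRESHOLD),
            t2l_threshold=thr.get("t2l_fraction", 0.30),
            nawm_threshold=thr.get("nawm_fraction", 0.50),
        )

    def with_seed(self, seed: int) -> "PipelineConfig":
        from dataclasses import replace

        return replace(self, phantom=replace(self.phantom, seed=int(seed)))


@dataclass
class PipelineResult:
    """Everything one pipeline run produces, in memory."""

    study: SyntheticStudy
    brain_13c: np.ndarray
    aucs: dict[str, np.ndarray]
    sigmas: dict[str, float]
    asnr: dict[str, np.ndarray]
    snr_masks: dict[str, np.ndarray]
    ratios: RatioMaps
    percentiles: dict[str, np.ndarray]
    kinetic_maps: KineticMaps
    masks: MaskSet
    label_map: RoiLabelMap
    volumes_cc: dict[str, float]
    param_maps: dict[str, np.ndarray]
    summary: ScanSummary
    manifest: dict


def brain_mask_13c(brain_1h: np.ndarray, factor: int, min_fraction: float = BRAIN_FRACTION_13C) -> np.ndarray:
    """Majority-overlap downsampling of the 1H brain mask to the 13C grid."""
    return block_fractions(brain_1h, factor) >= min_fraction


def build_parameter_maps(
    percentiles: dict[str, np.ndarray],
    ratios: RatioMaps,
    kinetic_maps: KineticMaps,
) -> dict[str, np.ndarray]:
    """Assemble the eight summarized parameter maps with NaN-invalid voxels.

    Percentile maps are valid on all brain voxels (no SNR filtering);
    ratio maps only where both constituent metabolites pass SNR; rate
    maps only where the fit passes its modeling-error mask.
    """
    kpl = np.where(kinetic_maps.kpl_error_mask, kinetic_maps.kpl_map, np.nan)
    kpb = np.where(kinetic_maps.kpb_error_mask, kinetic_maps.kpb_map, np.nan)
    return {
        "pyr_pct": percentiles["pyruvate"],
        "lac_pct": percentiles["lactate"],
        "bic_pct": percentiles["bicarbonate"],
        "lac_pyr": ratios.lac_pyr,
        "bic_pyr": ratios.bic_pyr,
        "bic_lac": ratios.bic_lac,
        "kpl": kpl,
        "kpb": kpb,
    }


def analyze_study(
    study: SyntheticStudy,
    config: PipelineConfig,
    patient_id: str | None = None,
    months_post_treatment: float = 0.0,
) -> PipelineResult:
    """Run all analysis stages on an in-memory study."""
    params = study.params
    factor = study.config.upsample_factor
    brain_13c = brain_mask_13c(study.masks.brain, factor)

    aucs, sigmas, asnrs, masks_snr = {}, {}, {}, {}
    for m in METABOLITES:
        aucs[m] = compute_auc(study.dynamics[m])
        sigmas[m] = estimate_noise_sigma(study.dynamics[m], brain_13c)
        asnrs[m] = compute_asnr(aucs[m], sigmas[m], params.n_timepoints)
        masks_snr[m] = snr_mask(asnrs[m], config.asnr_threshold)

    ratios = ratio_maps(aucs, masks_snr)
    percentiles = {m: percentile_rank_map(aucs[m], brain_13c) for m in METABOLITES}

    kinetic_maps = fit_map(
        study.dynamics,
        fit_mask=brain_13c,
        params=params,
        kpl_error_threshold=config.kpl_error_threshold,
        kpb_error_threshold=config.kpb_error_threshold,
        snr_mask=masks_snr["pyruvate"],
    )

    masks = derive_rois(study.masks)
    label_map = downsample_rois(
        masks.t2l, masks.nawm, factor, config.t2l_threshold, config.nawm_threshold
    )
    volumes = {
        "t2l_cc": volume_cc(masks.t2l, masks.voxel_mm),
        "cel_cc": volume_cc(masks.cel, masks.voxel_mm),
        "nel_cc": volume_cc(masks.nel, masks.voxel_mm),
    }

    param_maps = build_parameter_maps(percentiles, ratios, kinetic_maps)
    pid = patient_id if patient_id is not None else str(study.clinical_row.get("patient_id", ""))
    summary = normalize_to_nawm(
        summarize_scan(param_maps, label_map, patient_id=pid, months_post_treatment=months_post_treatment)
    )

    manifest = {
        "stages": {
            "snr_filter": {m: int(masks_snr[m].sum()) for m in METABOLITES},
            "brain_13c_voxels": int(brain_13c.sum()),
            "kpl_error_mask_voxels": int(kinetic_maps.kpl_error_mask.sum()),
            "kpb_error_mask_voxels": int(kinetic_maps.kpb_error_mask.sum()),
            "t2l_13c_voxels": int(label_map.t2l.sum()),
            "nawm_13c_voxels": int(label_map.nawm.sum()),
        },
        "noise_sigma": {m: float(sigmas[m]) for m in METABOLITES},
        "volumes_cc": volumes,
        "hashes": {},
    }
    return PipelineResult(
        study=study,
        brain_13c=brain_13c,
        aucs=aucs,
        sigmas=sigmas,
        asnr=asnrs,
        snr_masks=masks_snr,
        ratios=ratios,
        percentiles=percentiles,
        kinetic_maps=kinetic_maps,
        masks=masks,
        label_map=label_map,
        volumes_cc=volumes,
        param_maps=param_maps,
        summary=summary,
        manifest=manifest,
    )


def _summary_frame(summary: ScanSummary) -> pd.DataFrame:
    rows = []
    for p in summary.t2l_median:
        rows.append(
            {
                "patient_id": summary.patient_id,
                "month": summary.months_post_treatment,
                "parameter": p,
                "t2l_median": summary.t2l_median[p],
                "nawm_median": summary.nawm_median[p],
                "normalized_t2l": summary.normalized_t2l.get(p, float("nan")),
                "t2l_n_voxels": summary.t2l_n_voxels[p],
                "nawm_n_voxels": summary.nawm_n_voxels[p],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    outdir=None,
    clinical_csv=None,
) -> PipelineResult:
    """Simulate a study, analyze it, and (optionally) write all artifacts.

    With ``outdir`` set, writes the study NIfTIs, derived maps, the
    per-scan summary CSV and a manifest JSON with content hashes of every
    artifact.  ``clinical_csv``, if given, is parsed and its cohort
    counts recorded in the manifest.
    """
    study = generate_phantom(config.phantom, config.acquisition)
    result = analyze_study(study, config)

    hashes = {
        **{f"dynamic_{m}": hio.array_sha256(study.dynamics[m].data) for m in METABOLITES},
        **{f"auc_{m}": hio.array_sha256(result.aucs[m]) for m in METABOLITES},
        "kpl_map": hio.array_sha256(result.kinetic_maps.kpl_map),
        "kpb_map": hio.array_sha256(result.kinetic_maps.kpb_map),
        "roi_labels": hio.array_sha256(result.label_map.labels),
    }
    result.manifest["hashes"] = hashes
    result.manifest["seed"] = int(config.phantom.seed)

    if clinical_csv is not None:
        _, counts = parse_clinical_table(clinical_csv)
        result.manifest["clinical_counts"] = counts

    if outdir is not None:
        outdir = Path(outdir)
        paths = hio.write_study(study, outdir / "study")
        voxel = study.config.voxel_13c
        for m in METABOLITES:
            paths[f"auc_{m}"] = str(hio.save_nifti(result.aucs[m], outdir / f"auc_{m}.nii.gz", voxel))
            paths[f"asnr_{m}"] = str(hio.save_nifti(result.asnr[m], outdir / f"asnr_{m}.nii.gz", voxel))
            paths[f"pct_{m}"] = str(hio.save_nifti(result.percentiles[m], outdir / f"pct_{m}.nii.gz", voxel))
        for name, arr in result.ratios.as_dict().items():
            paths[f"ratio_{name}"] = str(hio.save_nifti(arr, outdir / f"ratio_{name}.nii.gz", voxel))
        paths["kpl_map"] = str(hio.save_nifti(result.kinetic_maps.kpl_map, outdir / "kpl_map.nii.gz", voxel))
        paths["kpb_map"] = str(hio.save_nifti(result.kinetic_maps.kpb_map, outdir / "kpb_map.nii.gz", voxel))
        paths["kpl_error_mask"] = str(
            hio.save_nifti(result.kinetic_maps.kpl_error_mask, outdir / "kpl_error_mask.nii.gz", voxel)
        )
        paths["kpb_error_mask"] = str(
            hio.save_nifti(result.kinetic_maps.kpb_error_mask, outdir / "kpb_error_mask.nii.gz", voxel)
        )
        paths["roi_labels"] = str(hio.save_nifti(result.label_map.labels, outdir / "roi_labels.nii.gz", voxel))
        _summary_frame(result.summary).to_csv(outdir / "scan_summary.csv", index=False)
        paths["scan_summary"] = str(outdir / "scan_summary.csv")
        result.manifest["artifacts"] = paths
        hio.write_json(result.manifest, outdir / "manifest.json")
    return result
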