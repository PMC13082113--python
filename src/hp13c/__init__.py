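"""hp13c: dynamic hyperpolarized [1-13C]pyruvate MRI treatment-response analysis.

Voxel-wise inputless kinetic modeling (kPL, kPB), AUC/aSNR/ratio and
percentile-rank parametric maps, mutually exclusive 1H-to-13C ROI
downsampling, NAWM-normalized lesion summaries and longitudinal group
trajectories — plus a synthetic dynamic-13C phantom generator with known
kinetic ground truth.
"""

from importlib import resources

from .acquisition import METABOLITES, AcquisitionParams, DynamicMetaboliteImage
from .kinetics import KineticFitResult, KineticMaps, fit_map, fit_voxel_inputless
from .maps import (
    compute_asnr,
    compute_auc,
    estimate_noise_sigma,
    percentile_rank_map,
    ratio_maps,
    snr_mask,
)
from .phantom import PhantomConfig, SyntheticStudy, generate_phantom, simulate_bolus, simulate_voxel_dynamics
from .pipeline import PipelineConfig, PipelineResult, analyze_study, run_pipeline
from .rois import (
    MaskSet,
    RoiLabel,
    RoiLabelMap,
    derive_rois,
    downsample_rois,
    volume_cc,
    volume_percent_change,
)
from .summary import (
    PARAMETERS,
    PairedVoxelComparison,
    ScanSummary,
    assign_groups,
    classify_treatment,
    cohort_table,
    group_trajectories,
    normalize_to_nawm,
    paired_voxel_change,
    parse_clinical_table,
    summarize_scan,
)

__version__ = "0.1.0"


def clinical_table_path():
    """Path to the packaged clinical summary table (20-patient cohort)."""
    return resources.files("hp13c").joinpath("data/clinical_table.csv")
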