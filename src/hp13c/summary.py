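"""Per-scan ROI summaries, NAWM normalization, treatment grouping and
longitudinal group trajectories.

Each scan is reduced to per-parameter medians over the 13C T2-lesion and
NAWM ROIs (valid voxels only; SNR and modeling-error filtering happens
upstream, invalid voxels are NaN).  Lesion values are normalized by the
patient-specific median NAWM value of the same parameter, making them
comparable across patients and scan days.  Patients are grouped by
treatment (BEV+ / EVER+ / ALKYL+ / control) or by progression status
(early vs late, from the 6-month progression-free-survival flag), and
group trajectories report mean, SD, SE and N per month bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rois import RoiLabel, RoiLabelMap

__all__ = [
    "PARAMETERS",
    "ScanSummary",
    "PairedVoxelComparison",
    "summarize_scan",
    "normalize_to_nawm",
    "classify_treatment",
    "assign_groups",
    "cohort_table",
    "group_trajectories",
    "paired_voxel_change",
    "parse_clinical_table",
]

#: parameters summarized per ROI, in reporting order
PARAMETERS = ("pyr_pct", "lac_pct", "bic_pct", "lac_pyr", "bic_pyr", "bic_lac", "kpl", "kpb")

_ALKYLATING = {"tmz", "temozolomide", "ccnu", "lomustine"}


@dataclass
class ScanSummary:
    """Per-scan, per-ROI parameter medians with NAWM-normalized lesion values."""

    patient_id: str
    months_post_treatment: float
    t2l_median: dict[str, float] = field(default_factory=dict)
    nawm_median: dict[str, float] = field(default_factory=dict)
    normalized_t2l: dict[str, float] = field(default_factory=dict)
    t2l_n_voxels: dict[str, int] = field(default_factory=dict)
    nawm_n_voxels: dict[str, int] = field(default_factory=dict)


def _roi_median(values: np.ndarray, roi: np.ndarray) -> tuple[float, int]:
    sel = values[roi]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        return float("nan"), 0
    return float(np.median(sel)), int(sel.size)


def summarize_scan(
    param_maps: dict[str, np.ndarray],
    labels: RoiLabelMap,
    patient_id: str = "",
    months_post_treatment: float = 0.0,
) -> ScanSummary:
    """Median of each parameter map over the T2L and NAWM 13C ROIs.

    ``param_maps`` carry NaN at invalid voxels (outside brain, below SNR,
    or failing the modeling-error mask); only finite voxels contribute.
    An empty ROI yields a missing median with a zero voxel count.
    """
    summary = ScanSummary(patient_id=patient_id, months_post_treatment=months_post_treatment)
    t2l, nawm = labels.t2l, labels.nawm
    for name, values in param_maps.items():
        values = np.asarray(values, dtype=float)
        if values.shape != labels.labels.shape:
            raise ValueError(
                f"map {name!r} shape {values.shape} does not match label grid {labels.labels.shape}"
            )
        summary.t2l_median[name], summary.t2l_n_voxels[name] = _roi_median(values, t2l)
        summary.nawm_median[name], summary.nawm_n_voxels[name] = _roi_median(values, nawm)
    return summary


def normalize_to_nawm(summary: ScanSummary) -> ScanSummary:
    """Fill NAWM-normalized lesion values: T2L median / NAWM median.

    Missing or zero NAWM medians yield a missing normalized value.
    Returns a new summary; the input is unmodified.
    """
    out = replace(
        summary,
        t2l_median=dict(summary.t2l_median),
        nawm_median=dict(summary.nawm_median),
        normalized_t2l={},
        t2l_n_voxels=dict(summary.t2l_n_voxels),
        nawm_n_voxels=dict(summary.nawm_n_voxels),
    )
    for name, t2l_val in summary.t2l_median.items():
        nawm_val = summary.nawm_median.get(name, float("nan"))
        if np.isfinite(nawm_val) and nawm_val != 0 and np.isfinite(t2l_val):
            out.normalized_t2l[name] = float(t2l_val / nawm_val)
        else:
            out.normalized_t2l[name] = float("nan")
    return out


# ---------------------------------------------------------------------------
# clinical table and grouping
# ---------------------------------------------------------------------------

def _agents(treatment: str) -> list[str]:
    text = re.sub(r"[\[\]]", " ", str(treatment))
    return [tok.strip().lower() for tok in re.split(r"[+,;]", text) if tok.strip()]


def classify_treatment(treatment: str) -> str:
    """Treatment group from the regimen string.

    Priority: any bevacizumab -> ``BEV+``; else any everolimus ->
    ``EVER+``; else multi-agent regimens containing an alkylating agent
    (TMZ/temozolomide, CCNU/lomustine) -> ``ALKYL+``; else single-agent
    TMZ or CCNU -> ``control``.  Anything else is ``unclassified``.
    """
    agents = _agents(treatment)
    if not agents:
        return "unclassified"
    if any("bevacizumab" in a for a in agents):
        return "BEV+"
    if any("everolimus" in a for a in agents):
        return "EVER+"
    alkylating = any(a in _ALKYLATING for a in agents)
    if alkylating and len(agents) > 1:
        return "ALKYL+"
    if alkylating and len(agents) == 1:
        return "control"
    return "unclassified"


def assign_groups(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add ``treatment_group`` and ``progressor_class`` columns.

    ``pfs6_flag`` = 1 marks progression within 6 months of baseline
    (early progressor); 0 marks a late progressor.
    """
    out = clinical.copy()
    out["treatment_group"] = out["treatment"].map(classify_treatment)
    out["progressor_class"] = np.where(out["pfs6_flag"].astype(int) == 1, "early", "late")
    return out


_MONTH_TOKEN = re.compile(r"^(\d+)\s*m$")


def _parse_followups(tokens: str, patient_id: str) -> list[int]:
    if tokens is None or (isinstance(tokens, float) and np.isnan(tokens)):
        return []
    text = str(tokens).strip()
    if not text:
        return []
    months = []
    for tok in text.split(","):
        tok = tok.strip()
        match = _MONTH_TOKEN.match(tok)
        if not match:
            raise ValueError(f"malformed follow-up month token {tok!r} in row for patient {patient_id}")
        months.append(int(match.group(1)))
    return months


def parse_clinical_table(source) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parse the clinical summary CSV into per-patient records and counts.

    Required columns: ``patient_id``, ``treatment``, ``pfs6_flag``,
    ``baseline_acquired`` (Yes/No) and ``followup_months``
    (comma-separated ``Nm`` tokens).  Returns the parsed table (with
    group assignments, follow-up month lists and per-patient scan counts)
    and a dictionary of cohort-level counts.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"patient_id", "treatment", "pfs6_flag", "baseline_acquired", "followup_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table is missing columns: {sorted(missing)}")

    df = assign_groups(df)
    df["has_baseline"] = (
        df["baseline_acquired"].astype(str).str.strip().str.lower().isin({"yes", "y", "true", "1"})
    )
    df["followup_list"] = [
        _parse_followups(tok, pid) for tok, pid in zip(df["followup_months"], df["patient_id"])
    ]
    df["n_scans"] = df["has_baseline"].astype(int) + df["followup_list"].map(len)

    counts = {
        "n_patients": int(len(df)),
        "n_baseline_scans": int(df["has_baseline"].sum()),
        "n_total_scans": int(df["n_scans"].sum()),
        "n_early_progressors": int((df["progressor_class"] == "early").sum()),
        "n_controls": int((df["treatment_group"] == "control").sum()),
    }
    return df, counts


# ---------------------------------------------------------------------------
# cohort assembly and trajectories
# ---------------------------------------------------------------------------

def cohort_table(summaries: list[ScanSummary], clinical: pd.DataFrame) -> pd.DataFrame:
    """Join per-scan summaries with clinical grouping into one wide table.

    One row per scan with ``t2l_<param>``, ``nawm_<param>`` and
    ``norm_<param>`` columns; months are binned to integers (baseline = 0).
    """
    clin = clinical if "treatment_group" in clinical.columns else assign_groups(clinical)
    meta = clin.set_index("patient_id")
    rows = []
    for s in summaries:
        row: dict = {
            "patient_id": s.patient_id,
            "month": int(round(s.months_post_treatment)),
        }
        if s.patient_id in meta.index:
            row["treatment_group"] = meta.loc[s.patient_id, "treatment_group"]
            row["progressor_class"] = meta.loc[s.patient_id, "progressor_class"]
        for p in PARAMETERS:
            row[f"t2l_{p}"] = s.t2l_median.get(p, np.nan)
            row[f"nawm_{p}"] = s.nawm_median.get(p, np.nan)
            row[f"norm_{p}"] = s.normalized_t2l.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def group_trajectories(
    cohort: pd.DataFrame,
    value: str,
    grouping: str = "treatment",
) -> pd.DataFrame:
    """Group-level longitudinal statistics of one summary column.

    ``grouping`` selects ``treatment_group`` or ``progressor_class``.
    Within each (group, month) bin the mean of patient-level values is
    reported with SD (ddof=1) and SE = SD/sqrt(N); SD and SE are missing
    when only one patient contributes.  If a patient has several scans in
    one bin, the first is used.  Empty bins are omitted.
    """
    group_col = {"treatment": "treatment_group", "progressor": "progressor_class"}.get(grouping, grouping)
    if group_col not in cohort.columns:
        raise ValueError(f"grouping column {group_col!r} not in cohort table")
    data = cohort.dropna(subset=[value]).drop_duplicates(subset=["patient_id", "month"], keep="first")
    records = []
    for (group, month), sub in data.groupby([group_col, "month"], sort=True):
        vals = sub[value].to_numpy(dtype=float)
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        records.append(
            {
                "group": group,
                "month": month,
                "mean": float(vals.mean()),
                "sd": sd,
                "se": sd / np.sqrt(n) if n > 1 else float("nan"),
                "n": n,
            }
        )
    return pd.DataFrame(records, columns=["group", "month", "mean", "sd", "se", "n"])


# ---------------------------------------------------------------------------
# paired voxel-wise serial comparison
# ---------------------------------------------------------------------------

@dataclass
class PairedVoxelComparison:
    """Voxel-wise serial changes within an ROI present at both timepoints."""

    roi: RoiLabel
    n_voxels: dict[str, int] = field(default_factory=dict)
    mean_pct_change: dict[str, float] = field(default_factory=dict)
    pct_changes: dict[str, np.ndarray] = field(default_factory=dict)


def paired_voxel_change(
    maps_a: dict[str, np.ndarray],
    maps_b: dict[str, np.ndarray],
    labels_a: RoiLabelMap,
    labels_b: RoiLabelMap,
    roi: RoiLabel = RoiLabel.T2L,
) -> PairedVoxelComparison:
    """Per-voxel percent change between two scans on a shared template grid.

    Only voxels classified in ``roi`` at BOTH timepoints and carrying a
    finite, nonzero value in both maps contribute; the selected voxel set
    is therefore symmetric in scan order.  Percent change is
    ``100 * (b - a) / a``.  Voxel counts may differ between parameters
    because SNR and modeling-error masks differ.
    """
    if labels_a.labels.shape != labels_b.labels.shape:
        raise ValueError("the two scans must share the template 13C grid")
    in_roi = (labels_a.labels == roi) & (labels_b.labels == roi)
    out = PairedVoxelComparison(roi=roi)
    for name in maps_a:
        a = np.asarray(maps_a[name], dtype=float)
        b = np.asarray(maps_b[name], dtype=float)
        valid = in_roi & np.isfinite(a) & np.isfinite(b) & (a != 0) & (b != 0)
        pct = 100.0 * (b[valid] - a[valid]) / a[valid]
        out.pct_changes[name] = pct
        out.n_voxels[name] = int(pct.size)
        out.mean_pct_change[name] = float(pct.mean()) if pct.size else float("nan")
    return out
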