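"""Patient-level aggregation and cohort statistics.

Slides are scored per sample; patients with several FFPE samples get the
unweighted mean of their per-sample tumor and background intensities, and
the patient TBR is recomputed from those averaged means (not averaged over
per-sample ratios).  Biomarkers are summarized across patients, and two
classical tests compare staining: a paired t-test of tumor vs adjacent
healthy intensity within patients, and an unpaired (pooled-variance by
default, Welch optional) t-test between preoperative-therapy subgroups.
Significance is declared at p <= 0.05, two-sided; no multiple-testing
correction is applied.

The t statistics are computed from explicit sums so they can be checked
against independent references; only the t distribution's CDF comes from
scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import DegenerateTestError, InvalidParameterError, SampleSizeError
from .scoring import SlideScore

DEFAULT_ALPHA = 0.05
DEFAULT_EXPRESSION_THRESHOLD = 10.0

__all__ = [
    "PatientScore",
    "BiomarkerSummary",
    "TestResult",
    "aggregate_patient",
    "aggregate_cohort",
    "summarize_biomarker",
    "paired_t",
    "unpaired_t",
    "preop_subgroup_report",
    "paired_intensity_table",
    "DEFAULT_ALPHA",
    "DEFAULT_EXPRESSION_THRESHOLD",
]


@dataclass(frozen=True)
class PatientScore:
    """One patient's averaged staining intensities for one biomarker."""

    patient_id: str
    biomarker: str
    tumor_mean: float
    tumor_sd_mean: float
    background_mean: float
    tbr: float
    preop_therapy: bool | None = None
    grade: str | None = None
    location: str | None = None


@dataclass(frozen=True)
class BiomarkerSummary:
    """Cohort-level summary of one biomarker across patients."""

    biomarker: str
    n_patients: int
    mean_tumor_intensity: float
    mean_within_roi_sd: float
    mean_tbr: float
    n_tbr_below_1: int
    fraction_expressed: float

    def __post_init__(self) -> None:
        if self.n_tbr_below_1 > self.n_patients:
            raise InvalidParameterError("n_tbr_below_1 cannot exceed n_patients")
        if not (0.0 <= self.fraction_expressed <= 1.0):
            raise InvalidParameterError("fraction_expressed must lie in [0, 1]")


@dataclass(frozen=True)
class TestResult:
    """A two-sided t-test outcome."""

    statistic: float
    p: float
    n: int | tuple[int, int]
    alpha: float = DEFAULT_ALPHA
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise InvalidParameterError(f"p-value {self.p} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha


def aggregate_patient(scores: Sequence[SlideScore]) -> PatientScore:
    """Collapse one patient's samples (same biomarker) to a single score.

    Unweighted means over samples; TBR recomputed from the averaged means.
    """
    if len(scores) == 0:
        raise InvalidParameterError("aggregate_patient needs at least one slide score")
    biomarkers = {s.biomarker for s in scores}
    if len(biomarkers) > 1:
        raise InvalidParameterError(
            f"cannot aggregate mixed biomarkers: {sorted(biomarkers)}"
        )
    tumor_mean = float(np.mean([s.tumor.mean for s in scores]))
    bg_mean = float(np.mean([s.background.mean for s in scores]))
    if bg_mean == 0:
        raise InvalidParameterError("averaged background mean is 0; patient TBR undefined")
    return PatientScore(
        patient_id=scores[0].sample_id,
        biomarker=scores[0].biomarker,
        tumor_mean=tumor_mean,
        tumor_sd_mean=float(np.mean([s.tumor.sd for s in scores])),
        background_mean=bg_mean,
        tbr=tumor_mean / bg_mean,
    )


def aggregate_cohort(scores_df: pd.DataFrame, metadata_df: pd.DataFrame) -> list[PatientScore]:
    """Join per-sample scores with cohort metadata and aggregate per patient.

    ``scores_df`` follows the scoring CSV schema (sample_id, biomarker,
    tumor_mean, tumor_sd, bg_mean, tbr, ...); ``metadata_df`` is keyed by
    sample_id and provides patient_id, preoperative_therapy, grade, location.
    """
    required = {"sample_id", "biomarker", "tumor_mean", "tumor_sd", "bg_mean"}
    missing = required - set(scores_df.columns)
    if missing:
        raise InvalidParameterError(f"scores table missing columns: {sorted(missing)}")
    if "sample_id" not in metadata_df.columns or "patient_id" not in metadata_df.columns:
        raise InvalidParameterError("metadata table needs sample_id and patient_id columns")
    merged = scores_df.merge(
        metadata_df, on="sample_id", how="left", validate="one_to_one", suffixes=("", "_meta")
    )
    if "biomarker_meta" in merged.columns:
        # Metadata is authoritative for sample identity; fill gaps in the
        # scores' own biomarker column from it.
        blank = merged["biomarker"].isna() | (merged["biomarker"].astype(str) == "")
        merged.loc[blank, "biomarker"] = merged.loc[blank, "biomarker_meta"]
    orphans = merged.loc[merged["patient_id"].isna(), "sample_id"].tolist()
    if orphans:
        raise InvalidParameterError(f"samples missing from metadata: {orphans}")
    patients: list[PatientScore] = []
    for (pid, biomarker), grp in merged.groupby(["patient_id", "biomarker"], sort=True):
        tumor_mean = float(grp["tumor_mean"].mean())
        bg_mean = float(grp["bg_mean"].mean())
        if bg_mean == 0:
            raise InvalidParameterError(f"patient {pid}: averaged background mean is 0")
        first = grp.iloc[0]
        preop = first.get("preoperative_therapy")
        patients.append(
            PatientScore(
                patient_id=str(pid),
                biomarker=str(biomarker),
                tumor_mean=tumor_mean,
                tumor_sd_mean=float(grp["tumor_sd"].mean()),
                background_mean=bg_mean,
                tbr=tumor_mean / bg_mean,
                preop_therapy=None if pd.isna(preop) else str(preop).lower() != "none",
                grade=None if pd.isna(first.get("grade")) else str(first.get("grade")),
                location=None if pd.isna(first.get("location")) else str(first.get("location")),
            )
        )
    return patients


def summarize_biomarker(
    patients: Sequence[PatientScore],
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> BiomarkerSummary:
    """Cohort summary for one biomarker.

    A patient "expresses" the biomarker when the tumor mean intensity reaches
    ``expression_threshold`` on the 0-255 inverted scale; the threshold is
    explicit configuration, not a hidden constant.
    """
    if len(patients) == 0:
        raise InvalidParameterError("summarize_biomarker needs at least one patient")
    biomarkers = {p.biomarker for p in patients}
    if len(biomarkers) > 1:
        raise InvalidParameterError(f"mixed biomarkers in summary: {sorted(biomarkers)}")
    tumor_means = np.array([p.tumor_mean for p in patients], float)
    tbrs = np.array([p.tbr for p in patients], float)
    return BiomarkerSummary(
        biomarker=patients[0].biomarker,
        n_patients=len(patients),
        mean_tumor_intensity=float(tumor_means.mean()),
        mean_within_roi_sd=float(np.mean([p.tumor_sd_mean for p in patients])),
        mean_tbr=float(tbrs.mean()),
        n_tbr_below_1=int((tbrs < 1.0).sum()),
        fraction_expressed=float((tumor_means >= expression_threshold).mean()),
    )


def paired_t(
    tumor_means: Sequence[float],
    background_means: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Paired two-sided t-test of within-patient tumor vs background means.

    t = mean(d) / (sd(d) / sqrt(n)) with d = tumor - background and sample
    (n-1) SD; p from the t distribution with n-1 degrees of freedom.
    """
    a = np.asarray(tumor_means, dtype=np.float64)
    b = np.asarray(background_means, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired_t needs two equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise SampleSizeError(f"paired t-test needs n >= 2, got n={n}")
    d = a - b
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("differences have zero variance; paired t undefined")
    t = float(d.mean()) / (sd / math.sqrt(n))
    p = 2.0 * float(_st.t.sf(abs(t), df=n - 1))
    return TestResult(statistic=t, p=min(p, 1.0), n=n, alpha=alpha, df=n - 1)


def unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Two-sample two-sided t-test (pooled variance by default, Welch optional)."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise SampleSizeError(f"unpaired t-test needs >= 2 per group, got {n1} and {n2}")
    v1, v2 = float(a.var(ddof=1)), float(b.var(ddof=1))
    if equal_var:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        num = (v1 / n1 + v2 / n2) ** 2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        df = num / den if den > 0 else n1 + n2 - 2
    if se == 0.0:
        raise DegenerateTestError("both groups have zero variance; t undefined")
    t = (float(a.mean()) - float(b.mean())) / se
    p = 2.0 * float(_st.t.sf(abs(t), df=df))
    return TestResult(statistic=t, p=min(p, 1.0), n=(n1, n2), alpha=alpha, df=float(df))


def preop_subgroup_report(
    patients: Sequence[PatientScore],
    equal_var: bool = True,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-biomarker comparison of patients with vs without preoperative therapy.

    For each biomarker, reports subgroup means of tumor intensity and TBR
    with the unpaired-t p-value.  If a subgroup is empty the report is still
    emitted with p-values marked not-computable (NaN).
    """
    rows = []
    frame = pd.DataFrame(
        {
            "biomarker": [p.biomarker for p in patients],
            "tumor_mean": [p.tumor_mean for p in patients],
            "tbr": [p.tbr for p in patients],
            "preop": [p.preop_therapy for p in patients],
        }
    )
    if frame.empty:
        raise InvalidParameterError("subgroup report needs at least one patient")
    if frame["preop"].isna().any():
        raise InvalidParameterError("all patients need a preoperative-therapy flag")
    for biomarker, grp in frame.groupby("biomarker", sort=True):
        preop = grp[grp["preop"].astype(bool)]
        nonpreop = grp[~grp["preop"].astype(bool)]
        for metric in ("tumor_mean", "tbr"):
            pre_vals = preop[metric].to_numpy()
            non_vals = nonpreop[metric].to_numpy()
            try:
                res = unpaired_t(pre_vals, non_vals, equal_var=equal_var, alpha=alpha)
                t_stat, p_val = res.statistic, res.p
            except (SampleSizeError, DegenerateTestError):
                t_stat, p_val = float("nan"), float("nan")
            rows.append(
                {
                    "biomarker": biomarker,
                    "metric": "mean_tumor_intensity" if metric == "tumor_mean" else "mean_tbr",
                    "preop_mean": float(pre_vals.mean()) if pre_vals.size else float("nan"),
                    "no_preop_mean": float(non_vals.mean()) if non_vals.size else float("nan"),
                    "n_preop": int(pre_vals.size),
                    "n_no_preop": int(non_vals.size),
                    "t": t_stat,
                    "p": p_val,
                }
            )
    return pd.DataFrame(rows)


def paired_intensity_table(patients: Sequence[PatientScore]) -> pd.DataFrame:
    """Per-patient tumor/background intensity pairs (plot-ready long table)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "biomarker": [p.biomarker for p in patients],
            "tumor_mean": [p.tumor_mean for p in patients],
            "background_mean": [p.background_mean for p in patients],
            "tbr": [p.tbr for p in patients],
        }
    )
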