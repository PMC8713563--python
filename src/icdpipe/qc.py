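"""Trauma-exposure scoring and participant-level quality control.

Exposure is measured by nine binary PTSD-screen items (1 = event
experienced).  The subject-level exposure variable is the unweighted sum
of items, capped at 3 because subjects with three or more events are
pooled into one group for regression stability.

Inclusion filters, applied in a fixed order with the first triggered
reason recorded per subject:

1. mean motion per TR > 0.3 mm
2. censor fraction > 30%
3. failed anatomical coregistration (optional input flag; never computed)
4. serious brain injury (self-reported history)
5. missing trauma-item block
6. missing maternal education

Boundary values (exactly 0.3 mm, exactly 30%) pass: the rules are strict
inequalities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_TRAUMA_ITEMS = 9
TE_CAP = 3

#: exclusion reasons in the order they are tested
EXCLUSION_ORDER = (
    "motion",
    "censor_fraction",
    "coregistration",
    "brain_injury",
    "missing_trauma",
    "missing_maternal_education",
)


@dataclass
class SubjectRecord:
    """Covariates, trauma items, derived exposure and QC state for one participant."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years
    maternal_education: Optional[float] = None  # years; None = missing
    trauma_items: Optional[tuple[int, ...]] = None  # 9 binary; None = missing block
    te_count_raw: Optional[int] = None
    te_coded: Optional[int] = None
    mean_motion_per_tr: Optional[float] = None  # mm
    censor_fraction: Optional[float] = None
    brain_injury: bool = False
    coreg_fail: bool = False
    qc_pass: Optional[bool] = None
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.trauma_items is not None and self.te_count_raw is None:
            raw, coded = score_te(self.trauma_items)
            self.te_count_raw = raw
            self.te_coded = coded


def score_te(items: Sequence[int]) -> tuple[int, int]:
    """Score the nine-item trauma screen.

    Returns ``(te_count_raw, te_coded)`` where the raw count is the
    unweighted sum and the coded count caps it at 3.
    """
    items = tuple(int(v) for v in items)
    if len(items) != N_TRAUMA_ITEMS:
        raise ValueError(f"expected {N_TRAUMA_ITEMS} items, got {len(items)}")
    if any(v not in (0, 1) for v in items):
        raise ValueError(f"items must be binary 0/1, got {items}")
    raw = sum(items)
    return raw, min(raw, TE_CAP)


def _first_exclusion(
    s: SubjectRecord, motion_mm: float, censor_frac: float
) -> Optional[str]:
    if s.mean_motion_per_tr is not None and s.mean_motion_per_tr > motion_mm:
        return "motion"
    if s.censor_fraction is not None and s.censor_fraction > censor_frac:
        return "censor_fraction"
    if s.coreg_fail:
        return "coregistration"
    if s.brain_injury:
        return "brain_injury"
    if s.trauma_items is None:
        return "missing_trauma"
    if s.maternal_education is None or (
        isinstance(s.maternal_education, float) and np.isnan(s.maternal_education)
    ):
        return "missing_maternal_education"
    return None


def apply_qc(
    subjects: Iterable[SubjectRecord],
    motion_mm: float = 0.3,
    censor_frac: float = 0.30,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Apply inclusion filters; returns ``(included, excluded)``.

    Thresholds are strict: a subject at exactly `motion_mm` or
    `censor_frac` passes.  Each excluded record carries only the first
    reason triggered, so per-reason counts are disjoint.
    """
    included: list[SubjectRecord] = []
    excluded: list[SubjectRecord] = []
    counts: dict[str, int] = {r: 0 for r in EXCLUSION_ORDER}
    for s in subjects:
        reason = _first_exclusion(s, motion_mm, censor_frac)
        rec = replace(s, qc_pass=reason is None, exclusion_reason=reason)
        if reason is None:
            included.append(rec)
        else:
            counts[reason] += 1
            excluded.append(rec)
    logger.info(
        "QC: %d included, %d excluded (%s)",
        len(included),
        len(excluded),
        ", ".join(f"{k}={v}" for k, v in counts.items() if v),
    )
    if not included:
        warnings.warn("QC excluded every subject", stacklevel=2)
    return included, excluded


def demographics_table(included: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-exposure-level demographic summary (n, % female, age, maternal education)."""
    if not included:
        raise ValueError("demographics_table requires a nonempty include set")
    df = subjects_to_frame(included)
    rows = []
    for te, grp in df.groupby("te_coded"):
        rows.append(
            {
                "te_coded": int(te),
                "n": len(grp),
                "pct_female": 100.0 * (grp["sex"] == "female").mean(),
                "age_mean": grp["age"].mean(),
                "age_sd": grp["age"].std(ddof=1),  # NaN when n = 1
                "maternal_education_mean": grp["maternal_education"].mean(),
                "maternal_education_sd": grp["maternal_education"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("te_coded").sort_index()


# ---------------------------------------------------------------------------
# Tabular I/O (covariate TSV with one row per subject)

_ITEM_COLS = [f"trauma_item_{i + 1}" for i in range(N_TRAUMA_ITEMS)]


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "age": s.age,
            "maternal_education": s.maternal_education,
            "te_count_raw": s.te_count_raw,
            "te_coded": s.te_coded,
            "mean_motion_per_tr": s.mean_motion_per_tr,
            "censor_fraction": s.censor_fraction,
            "brain_injury": int(s.brain_injury),
            "coreg_fail": int(s.coreg_fail),
            "qc_pass": None if s.qc_pass is None else int(s.qc_pass),
            "exclusion_reason": s.exclusion_reason or "",
        }
        for j, col in enumerate(_ITEM_COLS):
            row[col] = None if s.trauma_items is None else s.trauma_items[j]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    out = []
    for _, row in df.iterrows():
        items_raw = [row.get(c) for c in _ITEM_COLS]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in items_raw):
            items = None
        else:
            items = tuple(int(v) for v in items_raw)
        medu = row.get("maternal_education")
        if medu is not None and isinstance(medu, float) and np.isnan(medu):
            medu = None

        def _opt(name):
            v = row.get(name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return float(v)

        out.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                maternal_education=medu,
                trauma_items=items,
                mean_motion_per_tr=_opt("mean_motion_per_tr"),
                censor_fraction=_opt("censor_fraction"),
                brain_injury=bool(int(row.get("brain_injury", 0) or 0)),
                coreg_fail=bool(int(row.get("coreg_fail", 0) or 0)),
            )
        )
    return out


def write_covariates(subjects: Sequence[SubjectRecord], path) -> None:
    subjects_to_frame(subjects).to_csv(path, sep="\t", index=False)


def read_covariates(path) -> list[SubjectRecord]:
    return frame_to_subjects(pd.read_csv(path, sep="\t"))
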