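"""Kruijt major/minor albinism criteria and cohort phenotype summaries.

Major criteria: foveal hypoplasia (Thomas grade) >= 2, optic-pathway
misrouting, and ocular hypopigmentation (iris transillumination OR fundus
hypopigmentation grade >= 2).  Minor criteria: nystagmus, skin/hair
hypopigmentation, fundus hypopigmentation grade 1, foveal hypoplasia
grade 1.  Clinical diagnosis requires three major criteria, or two major
plus two minor; with a molecular diagnosis one major criterion or two
minor criteria suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

MAJOR_CRITERIA = ("fh_ge2", "misrouting", "ocular_hypopigmentation")
MINOR_CRITERIA = (
    "nystagmus",
    "skin_hair_hypopigmentation",
    "fundus_grade_1",
    "fh_grade_1",
)


@dataclass
class PhenotypeRecord:
    """One patient's phenotype, mirroring the standard clinical chart."""

    patient_id: str
    sex: str  # F | M
    age_years: float
    fh_grade: int  # Thomas foveal-hypoplasia grade 1-4
    bcva_logmar_re: float
    bcva_logmar_le: float
    iris_transillumination: bool
    nystagmus: bool
    misrouting: bool
    strabismus: bool
    fundus_pigmentation_grade: int  # Kruijt grade 0-3
    skin_hair_hypopigmentation: bool

    def __post_init__(self) -> None:
        if self.fh_grade not in (1, 2, 3, 4):
            raise ValueError(f"{self.patient_id}: foveal hypoplasia grade must be 1-4")
        if self.fundus_pigmentation_grade not in (0, 1, 2, 3):
            raise ValueError(f"{self.patient_id}: fundus grade must be 0-3")
        for v in (self.bcva_logmar_re, self.bcva_logmar_le):
            if v < -0.3:
                raise ValueError(f"{self.patient_id}: BCVA {v} below -0.3 LogMAR")

    @property
    def bcva_mean(self) -> float:
        return (self.bcva_logmar_re + self.bcva_logmar_le) / 2.0


@dataclass
class KruijtAssessment:
    patient_id: str
    major_met: tuple
    minor_met: tuple
    diagnostic_clinical: bool
    diagnostic_with_molecular: bool


def assess_kruijt(record: PhenotypeRecord, has_molecular_dx: bool = False) -> KruijtAssessment:
    """Evaluate the major/minor criteria for one patient.

    ``diagnostic_with_molecular`` applies the relaxed rule only when
    ``has_molecular_dx`` is True; otherwise it equals the clinical verdict
    (a molecular diagnosis can only relax, never tighten, the decision).
    Raises on missing (None) fields, naming them.
    """
    missing = [f.name for f in fields(record) if getattr(record, f.name) is None]
    if missing:
        raise ValueError(f"record unassessable, missing fields: {missing}")
    major = []
    if record.fh_grade >= 2:
        major.append("fh_ge2")
    if record.misrouting:
        major.append("misrouting")
    if record.iris_transillumination or record.fundus_pigmentation_grade >= 2:
        major.append("ocular_hypopigmentation")
    minor = []
    if record.nystagmus:
        minor.append("nystagmus")
    if record.skin_hair_hypopigmentation:
        minor.append("skin_hair_hypopigmentation")
    if record.fundus_pigmentation_grade == 1:
        minor.append("fundus_grade_1")
    if record.fh_grade == 1:
        minor.append("fh_grade_1")
    clinical = len(major) >= 3 or (len(major) >= 2 and len(minor) >= 2)
    molecular = clinical or (
        has_molecular_dx and (len(major) >= 1 or len(minor) >= 2)
    )
    return KruijtAssessment(
        patient_id=record.patient_id,
        major_met=tuple(major),
        minor_met=tuple(minor),
        diagnostic_clinical=clinical,
        diagnostic_with_molecular=molecular,
    )


@dataclass
class CohortSummary:
    n: int
    mean_bcva_pooled: float  # over all eyes
    mean_bcva_per_patient: float  # mean of per-patient means
    bcva_range: tuple
    mean_age: float
    age_range: tuple
    fh_grade_counts: dict
    fh_grade_pct: dict
    fundus_grade_counts: dict
    fundus_grade_pct: dict
    strabismus_count: int
    strabismus_pct: float
    nystagmus_count: int
    nystagmus_pct: float
    iris_transillumination_count: int
    iris_transillumination_pct: float
    misrouting_count: int
    misrouting_pct: float
    notes: tuple = ()


def _pct(count: int, n: int) -> float:
    return 100.0 * count / n


def summarize_cohort(records) -> CohortSummary:
    """Descriptive summary of a phenotype cohort.

    Mean BCVA pools all eyes (2 per patient) by default; the per-patient
    average is reported alongside (identical whenever eyes are balanced).
    """
    records = list(records)
    n = len(records)
    if n < 1:
        raise ValueError("need at least one record")
    eyes = np.array(
        [v for r in records for v in (r.bcva_logmar_re, r.bcva_logmar_le)]
    )
    per_patient = np.array([r.bcva_mean for r in records])
    ages = np.array([r.age_years for r in records])
    fh = pd.Series([r.fh_grade for r in records])
    fundus = pd.Series([r.fundus_pigmentation_grade for r in records])
    fh_counts = fh.value_counts().sort_index().to_dict()
    fundus_counts = fundus.value_counts().sort_index().to_dict()
    strab = sum(r.strabismus for r in records)
    nyst = sum(r.nystagmus for r in records)
    iris = sum(r.iris_transillumination for r in records)
    misr = sum(r.misrouting for r in records)
    return CohortSummary(
        n=n,
        mean_bcva_pooled=float(eyes.mean()),
        mean_bcva_per_patient=float(per_patient.mean()),
        bcva_range=(float(eyes.min()), float(eyes.max())),
        mean_age=float(ages.mean()),
        age_range=(float(ages.min()), float(ages.max())),
        fh_grade_counts={int(k): int(v) for k, v in fh_counts.items()},
        fh_grade_pct={int(k): _pct(v, n) for k, v in fh_counts.items()},
        fundus_grade_counts={int(k): int(v) for k, v in fundus_counts.items()},
        fundus_grade_pct={int(k): _pct(v, n) for k, v in fundus_counts.items()},
        strabismus_count=int(strab),
        strabismus_pct=_pct(strab, n),
        nystagmus_count=int(nyst),
        nystagmus_pct=_pct(nyst, n),
        iris_transillumination_count=int(iris),
        iris_transillumination_pct=_pct(iris, n),
        misrouting_count=int(misr),
        misrouting_pct=_pct(misr, n),
    )
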