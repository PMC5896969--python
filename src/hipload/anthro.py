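"""Subject anthropometrics and the instrumented-implant validation cohort.

The pipeline is driven by a small set of per-subject quantities: body mass and
height (which set segment masses, lengths and the muscle cross-section scale),
the operated side, and the hip joint width (HJW) — the distance between the two
hip joint centers — measured on postoperative CT images.  The ten subjects of
the public telemetry cohort (two women, eight men, instrumented hip stems) are
shipped as the default cohort for synthetic studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import pandas as pd

__all__ = ["Anthropometrics", "compute_bmi", "reference_cohort", "load_cohort", "save_cohort"]


def compute_bmi(mass: float, height: float) -> float:
    """Body mass index mass/height**2 in kg/m^2, rounded to 1 decimal.

    Raises ``ValueError`` for non-positive height.
    """
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    return round(mass / height**2, 1)


@dataclass(frozen=True)
class Anthropometrics:
    """Per-subject body parameters.

    Parameters
    ----------
    subject_id : str
    side : {"L", "R"}
        Instrumented (analysed) side.
    age : float
        Years.
    sex : {"m", "f"}
    mass : float
        Body mass, kg.
    height : float
        Body height, m.
    hjw_ct : float
        CT-measured distance between the hip joint centers, mm.
    bmi : float, optional
        kg/m^2; computed from mass and height when omitted.
    """

    subject_id: str
    side: str
    age: float
    sex: str
    mass: float
    height: float
    hjw_ct: float
    bmi: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.sex not in ("m", "f"):
            raise ValueError(f"sex must be 'm' or 'f', got {self.sex!r}")
        if self.mass <= 0 or self.height <= 0:
            raise ValueError("mass and height must be positive")
        if self.hjw_ct <= 0:
            raise ValueError("hjw_ct must be positive")
        if self.bmi is None:
            object.__setattr__(self, "bmi", compute_bmi(self.mass, self.height))
        elif abs(self.bmi - self.mass / self.height**2) > 0.055 + 1e-9:
            raise ValueError(
                f"bmi {self.bmi} inconsistent with mass/height^2 = "
                f"{self.mass / self.height ** 2:.2f}"
            )

    @property
    def body_weight_n(self) -> float:
        """Body weight in newtons (g = 9.81 m/s^2)."""
        return self.mass * 9.81


# Published anthropometrics of the ten instrumented-implant subjects
# (columns: id, side, age, sex, mass kg, height m, BMI kg/m^2, CT HJW mm).
_COHORT_CSV = """subject_id,side,age,sex,mass,height,bmi,hjw_ct
H1L,L,55,m,77.5,1.78,24.5,166
H2R,R,61,m,78.2,1.72,26.4,160
H3L,L,59,m,90.9,1.68,32.2,174
H4L,L,50,m,81.1,1.78,25.6,174
H5L,L,62,f,87.2,1.68,30.9,186
H6R,R,68,m,83.1,1.76,26.8,157
H7R,R,52,m,93.4,1.79,29.1,172
H8L,L,55,m,85.2,1.78,26.9,180
H9L,L,54,m,122.0,1.81,37.2,174
H10R,R,53,f,101.4,1.62,38.6,176
"""


def _from_frame(df: pd.DataFrame) -> list[Anthropometrics]:
    subjects = []
    for row in df.itertuples(index=False):
        subjects.append(
            Anthropometrics(
                subject_id=str(row.subject_id),
                side=str(row.side),
                age=float(row.age),
                sex=str(row.sex),
                mass=float(row.mass),
                height=float(row.height),
                hjw_ct=float(row.hjw_ct),
                bmi=float(row.bmi) if "bmi" in df.columns else None,
            )
        )
    return subjects


def reference_cohort() -> list[Anthropometrics]:
    """The ten instrumented-implant subjects used for validation studies."""
    return _from_frame(pd.read_csv(StringIO(_COHORT_CSV)))


def load_cohort(path) -> list[Anthropometrics]:
    """Read a cohort CSV (columns subject_id, side, age, sex, mass, height[, bmi], hjw_ct)."""
    return _from_frame(pd.read_csv(path))


def save_cohort(subjects: list[Anthropometrics], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "side": s.side,
                "age": s.age,
                "sex": s.sex,
                "mass": s.mass,
                "height": s.height,
                "bmi": s.bmi,
                "hjw_ct": s.hjw_ct,
            }
            for s in subjects
        ]
    ).to_csv(path, index=False)
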