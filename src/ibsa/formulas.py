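"""Anthropometric body-surface-area models and error propagation.

Five classical height/weight BSA formulas (Du Bois & Du Bois, Mosteller,
Haycock, Boyd, Gehan & George).  The public interface always takes height
in metres and weight in kilograms; each formula's native units (Du Bois
uses metres, the others centimetres, Boyd grams) are handled internally.

The Du Bois model

    BSA = 0.20247 · H^0.725 · W^0.425        (H in m, W in kg, BSA in m²)

also yields the first-order error-propagation relation

    ΔBSA/BSA = 0.725 · ΔH/H + 0.425 · ΔW/W

which quantifies how input (scale / stature) errors transfer to the BSA
used for chemotherapy dosing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ImplausibleAnthropometricsError, UnknownModelError

MODELS = ("dubois", "mosteller", "haycock", "boyd", "gehan_george")

DUBOIS_HEIGHT_EXPONENT = 0.725
DUBOIS_WEIGHT_EXPONENT = 0.425


@dataclass
class Subject:
    """A subject's anthropometrics: stature in metres, mass in kilograms."""

    height_m: float
    weight_kg: float
    id: str = ""

    def __post_init__(self) -> None:
        if not (0.3 <= self.height_m <= 2.6):
            raise ImplausibleAnthropometricsError(
                f"implausible anthropometrics: height {self.height_m} m"
            )
        if not (1.0 <= self.weight_kg <= 400.0):
            raise ImplausibleAnthropometricsError(
                f"implausible anthropometrics: weight {self.weight_kg} kg"
            )


@dataclass
class BsaEstimate:
    value_m2: float
    model: str


def bsa_formula(model: str, subject: Subject) -> BsaEstimate:
    """Evaluate one of the five anthropometric BSA models, in m²."""
    h_m, w_kg = subject.height_m, subject.weight_kg
    h_cm = h_m * 100.0
    if model == "dubois":
        v = 0.20247 * h_m**0.725 * w_kg**0.425
    elif model == "mosteller":
        v = math.sqrt(h_cm * w_kg / 3600.0)
    elif model == "haycock":
        v = 0.024265 * h_cm**0.3964 * w_kg**0.5378
    elif model == "gehan_george":
        v = 0.0235 * h_cm**0.42246 * w_kg**0.51456
    elif model == "boyd":
        w_g = w_kg * 1000.0
        v = 0.0003207 * h_cm**0.3 * w_g ** (0.7285 - 0.0188 * math.log10(w_g))
    else:
        raise UnknownModelError(f"unknown model: {model!r}")
    return BsaEstimate(value_m2=v, model=model)


def bsa_relative_error(subject: Subject, d_height_m: float = 0.0,
                       d_weight_kg: float = 0.0) -> float:
    """First-order relative BSA error (signed percent) under the Du Bois model.

    Returns 100·(0.725·ΔH/H + 0.425·ΔW/W).
    """
    if subject.height_m == 0 or subject.weight_kg == 0:
        raise ZeroDivisionError("division by zero: height and weight must be nonzero")
    return 100.0 * (
        DUBOIS_HEIGHT_EXPONENT * d_height_m / subject.height_m
        + DUBOIS_WEIGHT_EXPONENT * d_weight_kg / subject.weight_kg
    )


def bsa_table(subjects: list[Subject]) -> pd.DataFrame:
    """All five model estimates for a list of subjects, one column per model."""
    rows = []
    for s in subjects:
        row = {"id": s.id, "height_m": s.height_m, "weight_kg": s.weight_kg}
        for m in MODELS:
            row[f"bsa_{m}_m2"] = bsa_formula(m, s).value_m2
        rows.append(row)
    return pd.DataFrame(rows)


def read_subjects_csv(path: str) -> list[Subject]:
    """Read a subject CSV with columns id, height_m, weight_kg."""
    df = pd.read_csv(path)
    return [
        Subject(height_m=float(r.height_m), weight_kg=float(r.weight_kg),
                id=str(r.id))
        for r in df.itertuples(index=False)
    ]
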