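"""Survey-record preparation: BMI, obesity labelling, exclusions, normalization, oversampling.

The individual track of the analysis starts from survey-like records with
height/weight and coded feature responses.  Records carrying a 'no response'
sentinel in any feature are dropped outright (the record, not the cell).
District-level aggregates are put on a per-capita scale by dividing by the
district population.  Because the obese class is the minority (~30%
prevalence), the minority class is randomly oversampled with replacement to a
1:1 ratio before model fitting — inside training folds only, never before the
cross-validation split (see :func:`obesifact.classify.kfold_cv`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: BMI cut-point separating obese from non-obese (kg/m^2), WHO Asian-Pacific
#: practice for Korea; the boundary value itself counts as obese.
DEFAULT_BMI_THRESHOLD = 25.0

#: Sentinel the synthetic generator uses for a 'no response' survey answer.
DEFAULT_NO_RESPONSE_CODE = -1


@dataclass
class IndividualRecord:
    """One survey respondent: coded features, anthropometrics, derived label."""

    record_id: str
    district_id: str
    features: dict
    height_m: float
    weight_kg: float
    bmi: float | None = None
    obese: bool | None = None

    def with_label(self, threshold: float = DEFAULT_BMI_THRESHOLD) -> "IndividualRecord":
        """Return a copy with ``bmi`` and ``obese`` filled in."""
        bmi = compute_bmi(self.height_m, self.weight_kg)
        return IndividualRecord(
            record_id=self.record_id,
            district_id=self.district_id,
            features=dict(self.features),
            height_m=self.height_m,
            weight_kg=self.weight_kg,
            bmi=bmi,
            obese=label_obesity(bmi, threshold),
        )


def compute_bmi(height_m: float, weight_kg: float) -> float:
    """Body mass index, weight (kg) / height (m) squared.

    Raises
    ------
    ValueError
        If either measurement is nonpositive or non-finite.
    """
    if not (math.isfinite(height_m) and height_m > 0):
        raise ValueError(f"height_m must be positive and finite, got {height_m!r}")
    if not (math.isfinite(weight_kg) and weight_kg > 0):
        raise ValueError(f"weight_kg must be positive and finite, got {weight_kg!r}")
    return weight_kg / (height_m * height_m)


def label_obesity(bmi: float, threshold: float = DEFAULT_BMI_THRESHOLD) -> bool:
    """True iff ``bmi`` >= ``threshold`` (boundary inclusive)."""
    if not math.isfinite(bmi):
        raise ValueError(f"bmi must be finite, got {bmi!r}")
    return bmi >= threshold


def drop_no_response(
    records: Sequence[IndividualRecord],
    no_response_codes: set = frozenset({DEFAULT_NO_RESPONSE_CODE}),
) -> list[IndividualRecord]:
    """Remove every record that carries a no-response code in any feature.

    The whole record is excluded, not just the offending cell; survivor order
    is preserved.  Idempotent.
    """
    codes = set(no_response_codes)
    if not codes:
        raise ValueError("no_response_codes must be nonempty")
    return [r for r in records if not any(v in codes for v in r.features.values())]


def per_capita_normalize(
    district_values: Mapping[str, float],
    populations: Mapping[str, int],
) -> dict[str, float]:
    """Divide each district aggregate by that district's population."""
    if set(district_values) != set(populations):
        missing = set(district_values) ^ set(populations)
        raise ValueError(f"district keys differ between values and populations: {sorted(missing)}")
    out: dict[str, float] = {}
    for d, value in district_values.items():
        pop = populations[d]
        if pop <= 0:
            raise ValueError(f"population for district {d!r} must be positive, got {pop}")
        if value < 0:
            raise ValueError(f"value for district {d!r} must be nonnegative, got {value}")
        out[d] = value / pop
    return out


def oversample_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Index array realizing 1:1 random oversampling of the minority class.

    Returns the original indices followed by with-replacement draws from the
    minority class; the majority class is untouched.  Balanced input returns
    the identity.
    """
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to oversample")
    base = np.arange(labels.size)
    if n_pos == n_neg:
        return base
    minority = base[labels] if n_pos < n_neg else base[~labels]
    extra = rng.choice(minority, size=abs(n_neg - n_pos), replace=True)
    return np.concatenate([base, extra])


def random_oversample(
    records: Sequence[IndividualRecord] | pd.DataFrame,
    seed: int,
    label_col: str = "obese",
):
    """Random oversampling of the minority class to exact 1:1 balance.

    Accepts either a list of labelled :class:`IndividualRecord` or a
    DataFrame with a boolean ``label_col``.  Deterministic under ``seed``.
    Every added row is a copy of an existing minority row.
    """
    rng = np.random.default_rng(seed)
    if isinstance(records, pd.DataFrame):
        idx = oversample_indices(records[label_col].to_numpy(), rng)
        return records.iloc[idx].reset_index(drop=True)
    labels = np.array([bool(r.obese) for r in records])
    idx = oversample_indices(labels, rng)
    return [records[i] for i in idx]
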