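"""Subject-level data container shared by IO, likelihood and descriptives."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IndividualRecord", "GENOTYPE_LABELS", "genotype_code", "genotype_label"]

#: text labels used in delimited files <-> integer codes (None = unknown)
GENOTYPE_LABELS = {"carrier": 0, "noncarrier": 1, "unknown": None}
_CODE_TO_LABEL = {0: "carrier", 1: "noncarrier", None: "unknown"}


def genotype_code(label: str):
    try:
        return GENOTYPE_LABELS[label]
    except KeyError:
        raise ValueError(f"unknown genotype label {label!r}") from None


def genotype_label(code) -> str:
    try:
        return _CODE_TO_LABEL[None if code is None else int(code)]
    except (KeyError, TypeError):
        raise ValueError(f"unknown genotype code {code!r}") from None


@dataclass
class IndividualRecord:
    """One subject: measurement series, genotype status and survival outcome.

    ``genotype`` is 1 (known noncarrier), 0 (known carrier) or None
    (not genotyped).  ``event`` is True for an observed death at
    ``event_age``, False for censoring.
    """

    id: str
    sex: str
    genotype: int | None
    ages: np.ndarray
    values: np.ndarray
    event_age: float
    event: bool

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_measurements(self) -> int:
        return len(self.ages)

    def validate(self, censor_lag: float = 2.0) -> "IndividualRecord":
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValueError(f"record {self.id}: ages/values must be matching 1-d arrays")
        if self.n_measurements == 0:
            raise ValueError(f"record {self.id}: no measurements")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(
                f"record {self.id}: measurement ages must be strictly increasing"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"record {self.id}: non-finite measurement values")
        if self.event_age is None or not np.isfinite(self.event_age):
            raise ValueError(f"record {self.id}: missing survival information")
        if self.event_age < self.ages[-1] - 1e-9:
            raise ValueError(
                f"record {self.id}: event age {self.event_age} precedes last "
                f"measurement at {self.ages[-1]}"
            )
        if self.event_age - self.ages[-1] > censor_lag + 1e-9:
            kind = "death" if self.event else "censoring"
            raise ValueError(
                f"record {self.id}: {kind} {self.event_age - self.ages[-1]:.1f} years "
                f"after the last measurement violates the {censor_lag}-year censoring "
                "rule (load raw follow-up data with schema='raw' to apply it)"
            )
        if self.genotype not in (0, 1, None):
            raise ValueError(f"record {self.id}: genotype must be 0, 1 or None")
        return self
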