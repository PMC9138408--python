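"""Sample-group annotation for two-group leukemia cohorts.

Group labels are the binary ETP / non-ETP assignment every two-group operation
needs; an optional subtype map carries finer labels (B-ALL, T-ALL, AML, ...)
for multi-cohort inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import DataFormatError

ETP = "ETP"
NONETP = "NONETP"
VALID_GROUPS = (ETP, NONETP)


@dataclass(frozen=True)
class CohortLabels:
    """Mapping of sample id -> group label (``ETP`` or ``NONETP``).

    Parameters
    ----------
    assignment
        Sample id -> group label. Labels must be ``ETP`` or ``NONETP``.
    subtype
        Optional sample id -> free-text subtype (e.g. ``B-ALL``), for inputs
        such as the multi-leukemia reference cohorts.
    """

    assignment: Mapping[str, str]
    subtype: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sample, group in self.assignment.items():
            if group not in VALID_GROUPS:
                raise DataFormatError(
                    f"sample {sample!r} has group {group!r}; "
                    f"expected one of {VALID_GROUPS}"
                )

    def samples(self, group: str) -> list[str]:
        """Ordered sample ids carrying ``group``."""
        if group not in VALID_GROUPS:
            raise DataFormatError(f"unknown group {group!r}")
        return [s for s, g in self.assignment.items() if g == group]

    @property
    def etp_samples(self) -> list[str]:
        return self.samples(ETP)

    @property
    def nonetp_samples(self) -> list[str]:
        return self.samples(NONETP)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Raise unless every id in ``sample_ids`` is labelled."""
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise DataFormatError(f"unlabelled samples: {missing[:10]}")

    def require_two_groups(self, min_per_group: int = 1) -> None:
        for group in VALID_GROUPS:
            n = len(self.samples(group))
            if n < min_per_group:
                raise DataFormatError(
                    f"group {group} has {n} samples; need >= {min_per_group}"
                )
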