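"""Column quality control: retention-time repeatability and specificity.

Repeatability over repeated injections of a probe ligand is summarized
as the relative standard deviation (RSD) of retention times; specificity
compares capacity factors on the receptor column with those on a control
column packed with bare silica, flagging analytes whose control
retention is a substantial fraction of the test retention (nonspecific
adsorption to the support rather than receptor binding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = ["StabilityRecord", "SpecificityReport", "rsd", "specificity_report"]


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean.

    Sample (n-1 denominator) SD; needs at least two positive values.
    Scale invariant: rsd(c * values) == rsd(values) for any c > 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("RSD needs at least two values")
    if np.any(arr <= 0):
        raise ValidationError("retention times must be positive")
    return float(100.0 * arr.std(ddof=1) / arr.mean())


@dataclass(frozen=True)
class StabilityRecord:
    """Retention-time repeatability for one probe analyte."""

    analyte: str
    retention_times: tuple
    rsd: float

    @classmethod
    def from_times(cls, analyte: str, times) -> "StabilityRecord":
        return cls(analyte=analyte, retention_times=tuple(times), rsd=rsd(times))


@dataclass(frozen=True)
class SpecificityReport:
    """Per-analyte capacity factors on test vs control column with flags.

    ``nonspecific`` maps analyte -> True when the control-column k'
    exceeds ``threshold`` times the test-column k'.
    """

    test_k: dict
    control_k: dict
    threshold: float
    nonspecific: dict

    @property
    def flagged(self) -> list[str]:
        return sorted(a for a, bad in self.nonspecific.items() if bad)


def specificity_report(
    test_k: dict[str, float],
    control_k: dict[str, float],
    threshold: float = 0.1,
) -> SpecificityReport:
    """Compare receptor-column and control-column capacity factors.

    An analyte is flagged nonspecific when control k' > threshold * test
    k'. Flags are deterministic given inputs and threshold, and monotone
    in the threshold (raising it can only clear flags).
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    missing = set(test_k) ^ set(control_k)
    if missing:
        raise ValidationError(
            f"analytes missing from one of the maps: {sorted(missing)}"
        )
    flags = {
        analyte: control_k[analyte] > threshold * test_k[analyte]
        for analyte in test_k
    }
    return SpecificityReport(
        test_k=dict(test_k),
        control_k=dict(control_k),
        threshold=threshold,
        nonspecific=flags,
    )
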