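"""Chromatographic frame of reference: void time, flow rate, capacity factors.

The void (dead) time t0 is the elution time of a non-retained marker
(sodium nitrite on the immobilized-CysLTR1 column). Every retention
observation is reduced to the dimensionless capacity factor

    k' = (t_R - t0) / t0

and the mobile-phase (void) volume V_m = t0 * F converts retention into
the volume coordinate the binding model works in.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ElutesBeforeVoidError, ValidationError

__all__ = ["ColumnSystem", "capacity_factor", "void_volume"]


def void_volume(t0: float, flow_rate: float) -> float:
    """Void volume V_m in litres from t0 (min) and flow rate (mL/min).

    V_m = t0 * F / 1000 (the factor converts mL to L).
    """
    if t0 <= 0:
        raise ValidationError(f"void time must be positive, got {t0}")
    if flow_rate <= 0:
        raise ValidationError(f"flow rate must be positive, got {flow_rate}")
    return t0 * flow_rate / 1000.0


def capacity_factor(t_r: float, t0: float, *, allow_early: bool = False) -> float:
    """Capacity factor k' = (t_R - t0) / t0.

    Parameters
    ----------
    t_r
        Observed retention time, minutes.
    t0
        Void time, minutes; must be positive.
    allow_early
        If False (default) a retention time earlier than the void raises
        :class:`ElutesBeforeVoidError` — such an observation cannot enter
        the binding analysis. QC reports on control columns pass True and
        receive the (possibly negative) raw value.
    """
    if t0 <= 0:
        raise ValidationError(f"void time must be positive, got {t0}")
    k = (t_r - t0) / t0
    if t_r < t0 and not allow_early:
        raise ElutesBeforeVoidError(
            f"t_R = {t_r} min elutes before void (t0 = {t0} min); "
            "invalid for binding analysis"
        )
    return k


@dataclass(frozen=True)
class ColumnSystem:
    """Immobilized-receptor column plus its running conditions.

    Attributes
    ----------
    t0 : float
        Void time in minutes (non-retained marker retention time).
    flow_rate : float
        Mobile-phase flow rate in mL/min.
    column_dims : str | None
        Informational geometry string, e.g. ``"4.6 x 30 mm"``.
    """

    t0: float
    flow_rate: float
    column_dims: str | None = None

    def __post_init__(self):
        if self.t0 <= 0:
            raise ValidationError(f"void time must be positive, got {self.t0}")
        if self.flow_rate <= 0:
            raise ValidationError(
                f"flow rate must be positive, got {self.flow_rate}"
            )

    @property
    def void_volume(self) -> float:
        """V_m in litres, t0 * F / 1000."""
        return void_volume(self.t0, self.flow_rate)

    def capacity_factor(self, t_r: float, *, allow_early: bool = False) -> float:
        return capacity_factor(t_r, self.t0, allow_early=allow_early)
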