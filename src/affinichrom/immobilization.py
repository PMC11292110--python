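"""Receptor-immobilization yield from SDS-PAGE densitometry.

The amount of receptor captured on the gel is inferred from the drop in
the receptor band's densitometric fraction of the lysate supernatant
before vs after contact with the gel, scaled by the total protein in the
supernatant and normalized per gram of gel:

    immobilized (mg/g) = (f_before - f_after) * total_protein / gel_mass

Band fractions come from gel-image densitometry (performed upstream of
this package); total supernatant protein must be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["DensitometryRecord", "immobilized_amount"]


@dataclass(frozen=True)
class DensitometryRecord:
    """Densitometric band fractions around one immobilization reaction.

    ``band_fraction_before``/``band_fraction_after`` are the receptor
    band's fractions of total lane intensity (dimensionless, in [0, 1])
    before and after the supernatant contacted the gel;
    ``total_protein`` is the supernatant protein in mg and ``gel_mass``
    the gel in g.
    """

    band_fraction_before: float
    band_fraction_after: float
    total_protein: float
    gel_mass: float

    def __post_init__(self):
        if not (0.0 <= self.band_fraction_after <= self.band_fraction_before <= 1.0):
            raise ValidationError(
                "need 0 <= band_fraction_after <= band_fraction_before <= 1 "
                f"(got before={self.band_fraction_before}, "
                f"after={self.band_fraction_after}); a larger after-fraction "
                "would mean negative immobilization"
            )
        if self.total_protein <= 0 or self.gel_mass <= 0:
            raise ValidationError("total_protein and gel_mass must be positive")


def immobilized_amount(rec: DensitometryRecord) -> float:
    """Receptor immobilized per gram of gel, in mg/g.

    Linear in total protein, inversely linear in gel mass; zero when the
    band fraction did not change.
    """
    depleted = rec.band_fraction_before - rec.band_fraction_after
    return depleted * rec.total_protein / rec.gel_mass
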