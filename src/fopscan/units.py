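"""Physical quantities for serving sizes, reference amounts and basis amounts.

Only two units occur on Canadian Nutrition Facts serving declarations: grams
for solids and millilitres for beverages.  Crossing between them requires an
explicit density (g/mL), configured per category in the regulatory scheme;
nothing here guesses one.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, field_validator

from .errors import UnitMismatchError

Unit = Literal["g", "mL"]


class Quantity(BaseModel, frozen=True):
    """A strictly positive amount with a unit (``g`` or ``mL``)."""

    value: float
    unit: Unit

    @field_validator("value")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError(f"quantity must be > 0, got {v}")
        return v

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:g} {self.unit}"


def convert(q: Quantity, to_unit: Unit, density_g_per_ml: Optional[float] = None) -> Quantity:
    """Convert ``q`` to ``to_unit``.

    Mass<->volume conversion needs ``density_g_per_ml``; without it a
    :class:`UnitMismatchError` is raised rather than assuming water density.
    """
    if q.unit == to_unit:
        return q
    if density_g_per_ml is None or density_g_per_ml <= 0:
        raise UnitMismatchError(
            f"cannot convert {q} to {to_unit}: no density (g/mL) configured"
        )
    if q.unit == "mL" and to_unit == "g":
        return Quantity(value=q.value * density_g_per_ml, unit="g")
    return Quantity(value=q.value / density_g_per_ml, unit="mL")
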