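"""Prescriptions and the clinical dose ladder.

Advanced-stage NSCLC prescriptions in this protocol come from a fixed
ladder of total doses with bound fractionation schemes: 30, 39 and 45 Gy
in 3 Gy fractions, 55 Gy in 2.75 Gy fractions, 60 Gy in 2 Gy fractions,
60.5 Gy in 2.75 Gy fractions and the intended 66 Gy in 2 Gy fractions.
When 66 Gy is not achievable without violating organ tolerances the dose
is lowered along the ladder; conversely, automated planning can attempt to
climb it back up: 45 -> 55, 55 -> 60.5, 60 or 60.5 -> 66.  Intermediate
dose levels are never returned.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Prescription", "LADDER", "ladder_prescription", "escalation_step"]


@dataclass(frozen=True)
class Prescription:
    """A total dose with its fractionation.

    ``total_dose_gy = dose_per_fraction_gy * n_fractions`` must hold
    exactly (to float precision); ``intent`` is a free-text tag.
    """

    total_dose_gy: float
    dose_per_fraction_gy: float
    n_fractions: int
    intent: str = "curative"

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0 or self.dose_per_fraction_gy <= 0 or self.n_fractions < 1:
            raise ValueError("prescription doses and fraction count must be positive")
        if abs(self.dose_per_fraction_gy * self.n_fractions - self.total_dose_gy) > 1e-6:
            raise ValueError(
                f"inconsistent prescription: {self.n_fractions} x "
                f"{self.dose_per_fraction_gy} Gy != {self.total_dose_gy} Gy"
            )

    def to_dict(self) -> dict:
        return {
            "total_dose_gy": self.total_dose_gy,
            "dose_per_fraction_gy": self.dose_per_fraction_gy,
            "n_fractions": self.n_fractions,
            "intent": self.intent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Prescription":
        d = dict(d)
        if "n_fractions" not in d:
            d["n_fractions"] = round(d["total_dose_gy"] / d["dose_per_fraction_gy"])
        return cls(**d)


def _rx(total: float, per_fraction: float) -> Prescription:
    return Prescription(total, per_fraction, round(total / per_fraction))


#: the clinical prescription ladder, lowest to highest total dose
LADDER: tuple[Prescription, ...] = (
    _rx(30.0, 3.0),
    _rx(39.0, 3.0),
    _rx(45.0, 3.0),
    _rx(55.0, 2.75),
    _rx(60.0, 2.0),
    _rx(60.5, 2.75),
    _rx(66.0, 2.0),
)

_LADDER_BY_DOSE = {p.total_dose_gy: p for p in LADDER}

# upward moves; 60 and 60.5 both feed 66
_UP = {30.0: 39.0, 39.0: 45.0, 45.0: 55.0, 55.0: 60.5, 60.0: 66.0, 60.5: 66.0}
# downward moves; the 66 -> 60 vs 60.5 fork is fractionation-dependent
_DOWN = {60.0: 55.0, 60.5: 55.0, 55.0: 45.0, 45.0: 39.0, 39.0: 30.0}


def ladder_prescription(total_dose_gy: float) -> Prescription:
    """The ladder prescription with the given total dose."""
    try:
        return _LADDER_BY_DOSE[float(total_dose_gy)]
    except KeyError:
        raise ValueError(
            f"{total_dose_gy} Gy is not on the clinical ladder "
            f"{sorted(_LADDER_BY_DOSE)}"
        ) from None


def escalation_step(
    rx: Prescription, direction: str, fractionation_gy: float | None = None
) -> Prescription | None:
    """One step along the clinical ladder, or ``None`` at the ladder's end.

    ``direction`` is ``"up"`` or ``"down"``.  Stepping down from 66 Gy
    forks on the patient's fractionation scheme (2 Gy/fraction -> 60 Gy,
    2.75 Gy/fraction -> 60.5 Gy); pass ``fractionation_gy`` to pick the
    branch, defaulting to the prescription's own scheme.
    """
    if rx.total_dose_gy not in _LADDER_BY_DOSE:
        raise ValueError(f"prescription {rx.total_dose_gy} Gy is not on the ladder")
    if direction == "up":
        nxt = _UP.get(rx.total_dose_gy)
    elif direction == "down":
        if rx.total_dose_gy == 66.0:
            frac = fractionation_gy if fractionation_gy is not None else rx.dose_per_fraction_gy
            nxt = 60.5 if abs(frac - 2.75) < 1e-9 else 60.0
        else:
            nxt = _DOWN.get(rx.total_dose_gy)
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return None if nxt is None else _LADDER_BY_DOSE[nxt]
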