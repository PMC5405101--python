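"""The planning wishlist: hard constraints plus prioritized objectives.

A wishlist is the declarative input that drives automated multicriteria
planning: a short list of hard constraints that any plan must satisfy, and
an ordered list of objectives optimized one priority at a time.  The
packaged NSCLC wishlist (``data/nsclc_wishlist.yaml``) carries 6 hard
constraints and 13 objectives: LTCP coverage of CTV and PTV first, then a
conformity cap far from the target, mean-lung-dose reduction, two falloff
shells, an esophagus gEUD stage and a tail of mean/max objectives on the
remaining organs at risk.

Goals and limits may be written in Gy, as a percentage of the prescribed
dose, or (for LTCP) dimensionless.  :func:`resolve_wishlist` binds a
wishlist to a concrete prescription: percentages become Gy and the cord /
plexus hard limits become the minimum of the wishlist value and the
fractionation-specific clinical tolerance, so neither printed bound is
ever exceeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .prescription import Prescription

__all__ = [
    "HardConstraint",
    "Objective",
    "Wishlist",
    "WishlistValidationError",
    "load_wishlist",
    "save_wishlist",
    "nsclc_wishlist",
    "resolve_wishlist",
]

UNIT_GY = "gy"
UNIT_PERCENT = "percent_of_prescription"
UNIT_NONE = "dimensionless"

COST_KINDS = ("ltcp", "eud", "mean", "max")
METRICS = ("max", "mean")

#: clinical max-dose tolerances (Gy) by dose per fraction: (spinal cord, plexus)
FRACTIONATION_TOLERANCES_GY: dict[float, tuple[float, float]] = {
    3.0: (46.3, 56.6),
    2.75: (49.3, 60.0),
    2.0: (50.0, 66.0),
}


class WishlistValidationError(ValueError):
    """Invalid wishlist; the message lists every offending entry."""


@dataclass(frozen=True)
class HardConstraint:
    """A never-to-be-violated dose bound on one structure."""

    volume: str
    metric: str  # "max" or "mean"
    limit: float
    unit: str = UNIT_GY
    #: optional per-fractionation clinical tolerance overriding the limit downward
    fractionation_tolerance_gy: dict[float, float] | None = None

    def limit_gy(self, rx: Prescription) -> float:
        """The effective limit in Gy under a prescription."""
        base = self.limit * rx.total_dose_gy / 100.0 if self.unit == UNIT_PERCENT else self.limit
        if self.fractionation_tolerance_gy is not None:
            try:
                tol = self.fractionation_tolerance_gy[rx.dose_per_fraction_gy]
            except KeyError:
                raise ValueError(
                    f"no {self.volume} tolerance for {rx.dose_per_fraction_gy} Gy/fraction; "
                    f"known: {sorted(self.fractionation_tolerance_gy)}"
                ) from None
            base = min(base, tol)
        return base


@dataclass(frozen=True)
class Objective:
    """One prioritized objective: minimize ``cost`` on ``volume`` toward ``goal``."""

    priority: int
    volume: str
    cost: str  # one of COST_KINDS
    goal: float
    unit: str = UNIT_GY
    alpha: float | None = None  # LTCP sensitivity, 1/Gy
    k: float | None = None  # gEUD volume-effect exponent
    #: apply to the cord-subtracted target when the cord is close to the PTV
    cord_conditional: bool = False

    def goal_value(self, rx: Prescription) -> float:
        """The goal on its natural scale (Gy, or dimensionless for LTCP)."""
        if self.unit == UNIT_PERCENT:
            return self.goal * rx.total_dose_gy / 100.0
        return self.goal


@dataclass
class Wishlist:
    """Ordered hard constraints and prioritized objectives."""

    name: str
    constraints: list[HardConstraint]
    objectives: list[Objective]
    #: set after resolve_wishlist: the prescription everything is expressed for
    resolved_for: Prescription | None = None

    def validate(self) -> None:
        errors: list[str] = []
        for c in self.constraints:
            if c.metric not in METRICS:
                errors.append(f"constraint on {c.volume!r}: unknown metric {c.metric!r}")
            if c.limit <= 0:
                errors.append(f"constraint on {c.volume!r}: limit must be > 0, got {c.limit}")
            if c.unit not in (UNIT_GY, UNIT_PERCENT):
                errors.append(f"constraint on {c.volume!r}: unknown unit {c.unit!r}")
        priorities = [o.priority for o in self.objectives]
        if sorted(priorities) != list(range(1, len(priorities) + 1)):
            dupes = sorted({p for p in priorities if priorities.count(p) > 1})
            errors.append(
                f"objective priorities must be 1..{len(priorities)} with no gaps or "
                f"duplicates, got {sorted(priorities)}"
                + (f" (duplicated: {dupes})" if dupes else "")
            )
        for o in self.objectives:
            tag = f"objective p{o.priority} on {o.volume!r}"
            if o.cost not in COST_KINDS:
                errors.append(f"{tag}: unknown cost kind {o.cost!r}")
            if o.cost == "ltcp":
                if o.unit != UNIT_NONE:
                    errors.append(f"{tag}: LTCP goal must be dimensionless")
                if o.alpha is None or o.alpha <= 0:
                    errors.append(f"{tag}: LTCP needs sensitivity alpha > 0")
            if o.cost == "eud" and (o.k is None or o.k < 1):
                errors.append(f"{tag}: EUD needs exponent k >= 1")
            if o.cost in ("mean", "max") and o.unit not in (UNIT_GY, UNIT_PERCENT):
                errors.append(f"{tag}: unknown unit {o.unit!r}")
            if o.goal < 0:
                errors.append(f"{tag}: goal must be >= 0")
        if errors:
            raise WishlistValidationError(
                "invalid wishlist:\n  - " + "\n  - ".join(errors)
            )

    def objective(self, priority: int) -> Objective:
        for o in self.objectives:
            if o.priority == priority:
                return o
        raise KeyError(f"no objective with priority {priority}")

    def volumes(self) -> set[str]:
        return {c.volume for c in self.constraints} | {o.volume for o in self.objectives}


# ---------------------------------------------------------------------------
# serialization

def _limit_to_dict(value: float, unit: str) -> object:
    if unit == UNIT_PERCENT:
        return {UNIT_PERCENT: value}
    return value


def _parse_limit(raw: object, what: str) -> tuple[float, str]:
    if isinstance(raw, dict):
        if list(raw) == [UNIT_PERCENT]:
            return float(raw[UNIT_PERCENT]), UNIT_PERCENT
        if list(raw) == [UNIT_GY]:
            return float(raw[UNIT_GY]), UNIT_GY
        raise WishlistValidationError(f"{what}: cannot parse limit/goal {raw!r}")
    return float(raw), UNIT_GY


def wishlist_to_dict(wl: Wishlist) -> dict:
    d: dict = {"name": wl.name, "constraints": [], "objectives": []}
    for c in wl.constraints:
        cd: dict = {
            "volume": c.volume,
            "metric": c.metric,
            "limit": _limit_to_dict(c.limit, c.unit),
        }
        if c.fractionation_tolerance_gy:
            cd["fractionation_tolerance_gy"] = {
                str(k): v for k, v in sorted(c.fractionation_tolerance_gy.items())
            }
        d["constraints"].append(cd)
    for o in wl.objectives:
        od: dict = {"priority": o.priority, "volume": o.volume, "cost": o.cost}
        od["goal"] = o.goal if o.cost == "ltcp" else _limit_to_dict(o.goal, o.unit)
        if o.alpha is not None:
            od["alpha"] = o.alpha
        if o.k is not None:
            od["k"] = o.k
        if o.cord_conditional:
            od["cord_conditional"] = True
        d["objectives"].append(od)
    if wl.resolved_for is not None:
        d["resolved_for"] = wl.resolved_for.to_dict()
    return d


def wishlist_from_dict(d: dict) -> Wishlist:
    constraints = []
    for cd in d.get("constraints", []):
        limit, unit = _parse_limit(cd["limit"], f"constraint on {cd.get('volume')!r}")
        tol = cd.get("fractionation_tolerance_gy")
        if tol is not None:
            tol = {float(k): float(v) for k, v in tol.items()}
        constraints.append(
            HardConstraint(cd["volume"], cd["metric"], limit, unit, tol)
        )
    objectives = []
    for od in d.get("objectives", []):
        cost = od["cost"]
        if cost == "ltcp":
            goal, unit = float(od["goal"]), UNIT_NONE
        else:
            goal, unit = _parse_limit(od["goal"], f"objective p{od.get('priority')}")
        objectives.append(
            Objective(
                priority=int(od["priority"]),
                volume=od["volume"],
                cost=cost,
                goal=goal,
                unit=unit,
                alpha=od.get("alpha"),
                k=od.get("k"),
                cord_conditional=bool(od.get("cord_conditional", False)),
            )
        )
    resolved_for = d.get("resolved_for")
    wl = Wishlist(
        name=d.get("name", "unnamed"),
        constraints=constraints,
        objectives=objectives,
        resolved_for=Prescription.from_dict(resolved_for) if resolved_for else None,
    )
    wl.validate()
    return wl


def load_wishlist(path: str | Path) -> Wishlist:
    """Load and validate a wishlist from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise WishlistValidationError(f"{path}: expected a mapping at top level")
    return wishlist_from_dict(data)


def save_wishlist(wl: Wishlist, path: str | Path) -> None:
    """Write a wishlist to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    d = wishlist_to_dict(wl)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def nsclc_wishlist() -> Wishlist:
    """The packaged advanced-stage NSCLC wishlist (6 constraints, 13 objectives)."""
    text = resources.files("prioplan.data").joinpath("nsclc_wishlist.yaml").read_text()
    return wishlist_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# resolution against a prescription

def resolve_wishlist(template: Wishlist, rx: Prescription) -> Wishlist:
    """Bind a wishlist to a prescription.

    Percent-of-prescription entries become Gy and cord/plexus hard limits
    are capped at the fractionation-specific clinical tolerance.  The
    operation is idempotent: resolving an already-resolved wishlist (for
    the same prescription) is the identity.
    """
    if template.resolved_for is not None and template.resolved_for != rx:
        raise ValueError(
            f"wishlist already resolved for {template.resolved_for.total_dose_gy} Gy; "
            f"cannot re-resolve for {rx.total_dose_gy} Gy"
        )
    constraints = [
        HardConstraint(c.volume, c.metric, c.limit_gy(rx), UNIT_GY, None)
        for c in template.constraints
    ]
    objectives = [
        replace(
            o,
            goal=o.goal_value(rx),
            unit=UNIT_NONE if o.cost == "ltcp" else UNIT_GY,
        )
        for o in template.objectives
    ]
    wl = Wishlist(template.name, constraints, objectives, resolved_for=rx)
    wl.validate()
    return wl
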