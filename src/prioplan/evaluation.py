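"""DVH computation, plan-quality indices, protocol acceptability, escalation.

All reported V/D indices come from exact order statistics on the unbinned
dose vector of a structure; the binned cumulative DVH exists for plotting
only.  Conventions:

- ``V(t)``: percentage of the structure's volume receiving at least ``t`` Gy.
- ``D(x%)``: the minimum dose received by the hottest ``x``% of the volume,
  i.e. the largest dose level covering at least ``x``% of the structure.
- ``R50``: conformity — the patient volume receiving at least half the
  prescription, divided by the PTV volume.
- ``HI``: target homogeneity — ``(D2% - D98%) / D50%``.

Protocol acceptability distinguishes binding rules (target coverage, mean
lung dose < 20 Gy, lung V20 < 35%, cord/plexus fractionation tolerances)
from advisory ones (lung V5 < 60%, esophagus V45 < 25%) that flag but do
not fail a plan.  Threshold comparisons happen at the 0.1 reporting
precision used clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .prescription import Prescription, escalation_step
from .structures import StructureSet
from .wishlist import FRACTIONATION_TOLERANCES_GY

__all__ = [
    "DVH",
    "MetricReport",
    "AcceptabilityRule",
    "AcceptabilityResult",
    "dvh",
    "v_index",
    "d_index",
    "r50",
    "homogeneity_index",
    "compute_metric_report",
    "check_acceptability",
    "attempt_escalation",
    "EscalationTrail",
]


def _structure_doses(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, float).ravel()
    sel = np.asarray(mask, bool).ravel()
    if dose.shape != sel.shape:
        raise ValueError(f"dose length {dose.size} != mask size {sel.size}")
    d = dose[sel]
    if d.size == 0:
        raise ValueError("structure mask is empty")
    return d


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure (plotting carrier)."""

    structure: str
    bin_edges_gy: np.ndarray
    cumulative_volume_fraction: np.ndarray

    def v(self, dose_gy: float) -> float:
        """Volume fraction receiving >= ``dose_gy``, interpolated between bins."""
        return float(
            np.interp(
                dose_gy,
                self.bin_edges_gy,
                self.cumulative_volume_fraction,
                left=1.0,
                right=0.0,
            )
        )

    def d(self, percent_volume: float) -> float:
        """Dose covering ``percent_volume``% of the structure, interpolated."""
        if not 0 < percent_volume <= 100:
            raise ValueError("percent_volume must be in (0, 100]")
        frac = percent_volume / 100.0
        cv = self.cumulative_volume_fraction
        # cv is nonincreasing; interpolate on the reversed arrays
        return float(np.interp(frac, cv[::-1], self.bin_edges_gy[::-1]))


def dvh(dose: np.ndarray, mask: np.ndarray, structure: str = "", bin_width_gy: float = 0.1) -> DVH:
    """Cumulative DVH with ``bin_width_gy`` bins from 0 past the max dose."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    d = _structure_doses(dose, mask)
    top = max(float(d.max()), bin_width_gy) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    return DVH(structure, edges, frac)


def v_index(dose: np.ndarray, mask: np.ndarray, threshold_gy: float) -> float:
    """Percentage of the structure receiving at least ``threshold_gy``."""
    d = _structure_doses(dose, mask)
    return float((d >= threshold_gy).mean() * 100.0)


def d_index(dose: np.ndarray, mask: np.ndarray, percent_volume: float) -> float:
    """Minimum dose (Gy) received by the hottest ``percent_volume``% of voxels.

    Exact order statistic: with doses sorted descending, the value at rank
    ``ceil(x * N / 100)``.
    """
    if not 0 < percent_volume <= 100:
        raise ValueError(f"percent_volume must be in (0, 100], got {percent_volume}")
    d = np.sort(_structure_doses(dose, mask))[::-1]
    k = int(np.ceil(percent_volume * d.size / 100.0 - 1e-9))
    return float(d[k - 1])


def r50(dose: np.ndarray, ptv_mask: np.ndarray, patient_mask: np.ndarray, d_p: float) -> float:
    """Conformity index: patient volume at >= 50% prescription over PTV volume."""
    n_ptv = int(np.asarray(ptv_mask, bool).sum())
    if n_ptv == 0:
        raise ValueError("PTV mask is empty")
    d = _structure_doses(dose, patient_mask)
    return float((d >= 0.5 * d_p).sum() / n_ptv)


def homogeneity_index(dose: np.ndarray, ptv_mask: np.ndarray) -> float:
    """PTV homogeneity: (D2% - D98%) / D50%, from exact order statistics."""
    d2 = d_index(dose, ptv_mask, 2.0)
    d98 = d_index(dose, ptv_mask, 98.0)
    d50 = d_index(dose, ptv_mask, 50.0)
    if d50 == 0:
        raise ValueError("homogeneity index undefined: D50% is zero")
    return float((d2 - d98) / d50)


@dataclass
class MetricReport:
    """The dosimetric indices used for plan comparison and acceptability."""

    ptv_v95_pct: float
    ptv_v90_pct: float
    ptv_d99_gy: float
    ctv_v95_pct: float
    r50: float
    hi: float
    mean_lung_dose_gy: float
    lungs_v5_pct: float
    lungs_v20_pct: float
    heart_mean_gy: float
    esophagus_mean_gy: float
    esophagus_v45_pct: float
    cord_max_gy: float
    plexus_max_gy: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def metric_names(cls) -> list[str]:
        return list(cls.__dataclass_fields__)


def compute_metric_report(dose: np.ndarray, ss: StructureSet, rx: Prescription) -> MetricReport:
    """Evaluate every reported index for one plan.

    Lung metrics (mean, V5, V20) are computed on lungs-minus-GTV; the cord
    maximum on the 3 mm expanded cord, matching the planning constraint.
    """
    d_p = rx.total_dose_gy
    dose = np.asarray(dose, float).ravel()
    lungs = ss["lungs_minus_gtv"]

    def smax(name: str) -> float:
        return float(_structure_doses(dose, ss[name]).max())

    def smean(mask: np.ndarray) -> float:
        return float(_structure_doses(dose, mask).mean())

    return MetricReport(
        ptv_v95_pct=v_index(dose, ss["ptv"], 0.95 * d_p),
        ptv_v90_pct=v_index(dose, ss["ptv"], 0.90 * d_p),
        ptv_d99_gy=d_index(dose, ss["ptv"], 99.0),
        ctv_v95_pct=v_index(dose, ss["ctv"], 0.95 * d_p),
        r50=r50(dose, ss["ptv"], ss["patient"], d_p),
        hi=homogeneity_index(dose, ss["ptv"]),
        mean_lung_dose_gy=smean(lungs),
        lungs_v5_pct=v_index(dose, lungs, 5.0),
        lungs_v20_pct=v_index(dose, lungs, 20.0),
        heart_mean_gy=smean(ss["heart"]),
        esophagus_mean_gy=smean(ss["esophagus"]),
        esophagus_v45_pct=v_index(dose, ss["esophagus"], 45.0),
        cord_max_gy=smax("cord_plus_3mm"),
        plexus_max_gy=smax("plexus"),
    )


@dataclass
class AcceptabilityRule:
    name: str
    value: float
    threshold: float
    comparison: str  # ">=", "<", "<="
    binding: bool
    passed: bool


@dataclass
class AcceptabilityResult:
    rules: list[AcceptabilityRule]
    acceptable: bool
    advisory_flags: list[str] = field(default_factory=list)

    def rule(self, name: str) -> AcceptabilityRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)


def _compare(value: float, threshold: float, op: str) -> bool:
    # clinical thresholds are read at one decimal of reporting precision
    v = round(value, 1)
    if op == ">=":
        return v >= threshold
    if op == "<":
        return v < threshold
    if op == "<=":
        return v <= threshold
    raise ValueError(op)


def check_acceptability(report: MetricReport, rx: Prescription) -> AcceptabilityResult:
    """Protocol acceptability of a plan's metric report.

    Binding: PTV V95 >= 95%, CTV V95 >= 99%, PTV V90 >= 99%, mean lung
    dose < 20 Gy, lung V20 < 35%, cord and plexus maxima within the
    fractionation tolerance.  Advisory: lung V5 < 60%, esophagus
    V45 < 25%.  The overall verdict depends on binding rules only.
    """
    try:
        cord_tol, plexus_tol = FRACTIONATION_TOLERANCES_GY[rx.dose_per_fraction_gy]
    except KeyError:
        raise ValueError(
            f"no cord/plexus tolerance for {rx.dose_per_fraction_gy} Gy/fraction"
        ) from None

    spec = [
        ("ptv_v95", report.ptv_v95_pct, 95.0, ">=", True),
        ("ctv_v95", report.ctv_v95_pct, 99.0, ">=", True),
        ("ptv_v90", report.ptv_v90_pct, 99.0, ">=", True),
        ("mean_lung_dose", report.mean_lung_dose_gy, 20.0, "<", True),
        ("lungs_v20", report.lungs_v20_pct, 35.0, "<", True),
        ("cord_max", report.cord_max_gy, cord_tol, "<=", True),
        ("plexus_max", report.plexus_max_gy, plexus_tol, "<=", True),
        ("lungs_v5", report.lungs_v5_pct, 60.0, "<", False),
        ("esophagus_v45", report.esophagus_v45_pct, 25.0, "<", False),
    ]
    rules = [
        AcceptabilityRule(name, value, thr, op, binding, _compare(value, thr, op))
        for name, value, thr, op, binding in spec
    ]
    acceptable = all(r.passed for r in rules if r.binding)
    advisory = [r.name for r in rules if not r.binding and not r.passed]
    return AcceptabilityResult(rules, acceptable, advisory)


@dataclass
class EscalationAttempt:
    prescription_gy: float
    acceptable: bool
    failed_rules: list[str]


@dataclass
class EscalationTrail:
    attempts: list[EscalationAttempt]
    final_prescription: Prescription
    direction: str  # "up", "down" or "none"


def attempt_escalation(
    plan_and_evaluate,
    start_rx: Prescription,
    max_steps: int = 10,
) -> tuple[object, Prescription, EscalationTrail]:
    """Climb (or descend) the prescription ladder by replanning.

    ``plan_and_evaluate(rx)`` must return ``(plan, AcceptabilityResult)``
    for a prescription; this function walks the clinical ladder: if the
    starting prescription yields an acceptable plan, escalate stepwise
    until a step fails or the ladder tops out, keeping the highest
    acceptable plan; otherwise de-escalate until a prescription becomes
    acceptable (or the ladder bottoms out).

    Returns ``(best_plan, final_prescription, trail)``.
    """
    attempts: list[EscalationAttempt] = []

    def try_rx(rx: Prescription):
        plan, acc = plan_and_evaluate(rx)
        failed = [r.name for r in acc.rules if r.binding and not r.passed]
        attempts.append(EscalationAttempt(rx.total_dose_gy, acc.acceptable, failed))
        return plan, acc

    plan, acc = try_rx(start_rx)
    rx = start_rx
    if acc.acceptable:
        best_plan, best_rx = plan, rx
        for _ in range(max_steps):
            nxt = escalation_step(rx, "up")
            if nxt is None:
                break
            plan, acc = try_rx(nxt)
            if not acc.acceptable:
                break
            best_plan, best_rx, rx = plan, nxt, nxt
        direction = "up" if best_rx != start_rx else "none"
        return best_plan, best_rx, EscalationTrail(attempts, best_rx, direction)

    # de-escalate until acceptable
    for _ in range(max_steps):
        nxt = escalation_step(rx, "down")
        if nxt is None:
            break
        plan, acc = try_rx(nxt)
        rx = nxt
        if acc.acceptable:
            return plan, rx, EscalationTrail(attempts, rx, "down")
    return plan, rx, EscalationTrail(attempts, rx, "down")
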