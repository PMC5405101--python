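"""Synthetic patient cohorts and paired plan comparison.

Emulates a planning-study workflow: generate a seeded cohort of thorax
phantoms with varying tumor size and location, plan every patient under
two arms — a deliberately degraded baseline (few beams, one weighted-sum
solve) versus the full prioritized wishlist — and summarize the paired
per-patient metric differences with means, standard deviations and
two-tailed Wilcoxon signed-rank tests, in the layout of a clinical
comparison table.

The real comparator arm of a clinical study (human-made plans) cannot be
reproduced; the degraded arm stands in for it, so only the *direction* of
cohort differences is meaningful, never their magnitude.

Sign convention for differences: positive favors arm B (the wishlist
arm), i.e. ``B - A`` for higher-is-better metrics (coverage) and
``A - B`` for lower-is-better ones (organ doses, R50, HI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import PhantomConfig, build_phantom
from .prescription import Prescription, ladder_prescription
from .structures import StructureSet

__all__ = [
    "CohortSpec",
    "CohortMember",
    "generate_cohort",
    "wilcoxon_signed_rank",
    "paired_summary",
    "ComparisonTable",
    "HIGHER_IS_BETTER",
]

#: orientation of each comparison metric (True: larger values are better)
HIGHER_IS_BETTER: dict[str, bool] = {
    "ptv_v95_pct": True,
    "ptv_v90_pct": True,
    "ptv_d99_gy": True,
    "ctv_v95_pct": True,
    "r50": False,
    "hi": False,
    "mean_lung_dose_gy": False,
    "lungs_v5_pct": False,
    "lungs_v20_pct": False,
    "heart_mean_gy": False,
    "esophagus_mean_gy": False,
    "esophagus_v45_pct": False,
    "cord_max_gy": False,
    "plexus_max_gy": False,
}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-tailed p by convolution over the 2^n sign assignments.

    Doubled midranks are integers, so the null distribution of
    ``2 * W+`` lives on an integer lattice; the subset-sum convolution
    enumerates it without listing the assignments.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    differences: np.ndarray, exact_max_n: int = 25, zero_method: str = "drop"
) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Returns ``(W+, p)``.  Zero differences are dropped before ranking
    (``zero_method="drop"``; ``"pratt"`` keeps them in the ranking but
    excludes them from the statistic); ties get midranks.  For ``n <=
    exact_max_n`` nonzero pairs the p-value comes from the exact null
    distribution (sign-assignment enumeration by convolution), above that
    from the normal approximation with continuity and tie correction.
    An all-zero difference vector degenerates to ``p = 1`` with a warning.
    """
    d = np.asarray(differences, float).ravel()
    if d.size == 0:
        raise ValueError("need at least one paired difference")
    if zero_method not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    if zero_method == "pratt":
        ranks_all = stats.rankdata(np.abs(d))
        nz = d != 0
        d_nz, ranks = d[nz], ranks_all[nz]
    else:
        d_nz = d[d != 0]
        ranks = stats.rankdata(np.abs(d_nz))

    if d_nz.size == 0:
        warnings.warn("all paired differences are zero; p degenerates to 1")
        return 0.0, 1.0

    w_plus = float(ranks[d_nz > 0].sum())
    n = d_nz.size
    if n <= exact_max_n and zero_method == "drop":
        return w_plus, _exact_signed_rank_p(w_plus, ranks)

    mean = ranks.sum() / 2.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# paired summary table

@dataclass
class ComparisonTable:
    """Per-metric paired cohort summary in clinical-table layout."""

    table: pd.DataFrame
    arm_a: str
    arm_b: str

    def to_text(self) -> str:
        cols = [
            ("mean_a", f"{self.arm_a} mean"),
            ("sd_a", "SD"),
            ("mean_b", f"{self.arm_b} mean"),
            ("sd_b", "SD"),
            ("diff_mean", "diff mean"),
            ("diff_sd", "diff SD"),
            ("diff_of_means", "mean diff"),
            ("p_value", "p"),
        ]
        df = self.table[[c for c, _ in cols]].rename(columns=dict(cols))
        return df.round(3).to_string()

    def row(self, metric: str) -> pd.Series:
        return self.table.loc[metric]


def paired_summary(
    metrics_a: pd.DataFrame, metrics_b: pd.DataFrame, arm_a: str = "A", arm_b: str = "B"
) -> ComparisonTable:
    """Paired comparison of two per-patient metric tables.

    Both frames must be indexed by patient with identical index and share
    their metric columns.  For every metric the table reports per-arm mean
    and SD, the patient-wise mean +/- SD of oriented differences (positive
    favoring arm B), the difference of the arm means under the same
    orientation, and the exact/approximate Wilcoxon p.
    """
    if not metrics_a.index.equals(metrics_b.index):
        raise ValueError("metric tables cover different patient sets")
    common = [c for c in metrics_a.columns if c in metrics_b.columns]
    rows = {}
    for m in common:
        a = metrics_a[m].to_numpy(float)
        b = metrics_b[m].to_numpy(float)
        oriented = (b - a) if HIGHER_IS_BETTER.get(m, False) else (a - b)
        _, p = wilcoxon_signed_rank(oriented)
        rows[m] = {
            "mean_a": a.mean(),
            "sd_a": a.std(ddof=1) if a.size > 1 else 0.0,
            "mean_b": b.mean(),
            "sd_b": b.std(ddof=1) if b.size > 1 else 0.0,
            "diff_mean": oriented.mean(),
            "diff_sd": oriented.std(ddof=1) if oriented.size > 1 else 0.0,
            "diff_of_means": (b.mean() - a.mean())
            if HIGHER_IS_BETTER.get(m, False)
            else (a.mean() - b.mean()),
            "p_value": p,
        }
    table = pd.DataFrame(rows).T
    table.index.name = "metric"
    return ComparisonTable(table, arm_a, arm_b)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortMember:
    patient_id: int
    config: PhantomConfig
    prescription: Prescription
    #: constructed so the intended 66 Gy prescription should fail acceptability
    constructed_difficult: bool = False

    def build(self) -> StructureSet:
        return build_phantom(self.config)


@dataclass
class CohortSpec:
    """Distributional spec of a synthetic validation cohort.

    Tumor radius and center are drawn uniformly from the given ranges
    (mm; centers relative to the thorax center, mirrored for left-sided
    patients).  ``difficult_fraction`` of the cohort is constructed
    "difficult": mediastinal tumors abutting or overlapping the spinal
    cord, so the cord maximum-dose tolerance caps achievable PTV coverage
    and the intended 66 Gy prescription fails acceptability — the
    geometry that exercises the reduced-prescription and escalation
    paths.
    """

    n_patients: int = 10
    tumor_radius_range_mm: tuple[float, float] = (7.0, 10.0)
    tumor_center_x_range_mm: tuple[float, float] = (40.0, 58.0)
    tumor_center_y_range_mm: tuple[float, float] = (-12.0, 10.0)
    difficult_fraction: float = 16.0 / 41.0
    difficult_radius_range_mm: tuple[float, float] = (12.0, 16.0)
    difficult_center_x_range_mm: tuple[float, float] = (8.0, 16.0)
    difficult_center_y_range_mm: tuple[float, float] = (-50.0, -40.0)
    prescription_gy: float = 66.0
    shape: tuple[int, int, int] = (40, 34, 1)
    spacing: tuple[float, float, float] = (6.0, 6.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("tumor_radius_range_mm", "tumor_center_x_range_mm",
                     "tumor_center_y_range_mm", "difficult_radius_range_mm",
                     "difficult_center_x_range_mm", "difficult_center_y_range_mm"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if not 0 <= self.difficult_fraction <= 1:
            raise ValueError("difficult_fraction must be in [0, 1]")


def generate_cohort(spec: CohortSpec) -> list[CohortMember]:
    """Draw a reproducible cohort of phantoms from a spec.

    The first ``round(difficult_fraction * n)`` patients (in id order) get
    the difficult geometry; all parameter draws come from one generator
    seeded by ``spec.seed``, so a fixed seed reproduces the cohort
    bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    n_difficult = int(round(spec.difficult_fraction * spec.n_patients))
    members = []
    rx = ladder_prescription(spec.prescription_gy)
    for pid in range(spec.n_patients):
        difficult = pid < n_difficult
        config = None
        for _ in range(50):
            if difficult:
                radius = rng.uniform(*spec.difficult_radius_range_mm)
                cx = rng.uniform(*spec.difficult_center_x_range_mm)
                cy = rng.uniform(*spec.difficult_center_y_range_mm)
            else:
                radius = rng.uniform(*spec.tumor_radius_range_mm)
                cx = rng.uniform(*spec.tumor_center_x_range_mm)
                cy = rng.uniform(*spec.tumor_center_y_range_mm)
            laterality = "left" if rng.random() < 0.5 else "right"
            config = PhantomConfig(
                shape=spec.shape,
                spacing=spec.spacing,
                tumor_center=(float(cx), float(cy), 0.0),
                tumor_radius=float(radius),
                laterality=laterality,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if not difficult:
                break
            # difficult construction is verified: the PTV must overlap the
            # expanded cord, so the cord max-dose cap provably breaks the
            # 99% coverage rule at the intended prescription
            ss = build_phantom(config)
            if int((ss["cord_plus_3mm"] & ss["ptv"]).sum()) >= 1:
                break
        members.append(CohortMember(pid, config, rx, difficult))
    return members


def plan_member(
    member: CohortMember,
    mode: str = "wishlist",
    n_beams: int | None = None,
    wishlist=None,
    opts=None,
    rx: Prescription | None = None,
):
    """Plan one cohort member and evaluate it.

    ``mode`` selects the arm: ``"wishlist"`` runs the full prioritized
    optimization with the packaged NSCLC wishlist; ``"baseline"`` runs the
    degraded comparator — default 7 beams (the clinical fixed-field
    range) and a single coverage-only solve under the hard constraints,
    with no organ-sparing objectives and no priority structure.
    Returns ``(plan, MetricReport, AcceptabilityResult)``.
    """
    from .beams import make_beamset
    from .evaluation import check_acceptability, compute_metric_report
    from .influence import compute_dose_influence
    from .optimizer import prioritized_optimize, weighted_sum_optimize
    from .wishlist import nsclc_wishlist

    if mode not in ("wishlist", "baseline"):
        raise ValueError(f"unknown arm mode {mode!r}")
    wl = wishlist if wishlist is not None else nsclc_wishlist()
    rx = rx or member.prescription
    ss = member.build()
    if n_beams is None:
        n_beams = 15 if mode == "wishlist" else 7
    bs = make_beamset(ss, n_beams=n_beams)
    dij = compute_dose_influence(ss, bs)
    if mode == "wishlist":
        plan, _ = prioritized_optimize(dij, wl, ss, rx, opts)
    else:
        plan, _ = weighted_sum_optimize(dij, wl, ss, rx, opts, include="coverage")
    report = compute_metric_report(plan.dose, ss, rx)
    acc = check_acceptability(report, rx)
    return plan, report, acc


def run_cohort_comparison(
    members: list[CohortMember],
    n_beams_baseline: int = 7,
    n_beams_wishlist: int = 15,
    opts=None,
) -> tuple[pd.DataFrame, pd.DataFrame, ComparisonTable]:
    """Plan a cohort under both arms and summarize the paired differences.

    Returns ``(baseline_metrics, wishlist_metrics, comparison_table)``;
    the metric frames are indexed by patient id.
    """
    rows_a, rows_b = {}, {}
    for m in members:
        _, rep_a, _ = plan_member(m, "baseline", n_beams_baseline, opts=opts)
        _, rep_b, _ = plan_member(m, "wishlist", n_beams_wishlist, opts=opts)
        rows_a[m.patient_id] = rep_a.to_dict()
        rows_b[m.patient_id] = rep_b.to_dict()
    df_a = pd.DataFrame(rows_a).T.sort_index()
    df_b = pd.DataFrame(rows_b).T.sort_index()
    df_a.index.name = df_b.index.name = "patient"
    table = paired_summary(df_a, df_b, arm_a="baseline", arm_b="autoplan")
    return df_a, df_b, table


def plot_difference_bars(table: ComparisonTable, path: str) -> None:
    """Bar chart of per-metric oriented mean differences (positive favors arm B)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.table
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(df.index, df["diff_mean"], yerr=df["diff_sd"], capsize=3)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel(f"difference (positive favors {table.arm_b})")
    ax.tick_params(axis="x", rotation=75)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
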