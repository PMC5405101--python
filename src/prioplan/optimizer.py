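"""Lexicographic (prioritized) fluence-map optimization.

The optimizer realizes the two-phase wishlist procedure.  Phase 1 walks
the objectives in priority order; for each it minimizes that objective's
cost subject to the hard constraints and every previously fixed objective
bound.  If the optimum is better than the objective's goal, the bound is
fixed at the goal itself — not the optimum — so lower priorities can spend
the freed room; otherwise the achieved value is fixed with a bit of
multiplicative slack as a constraint for all later stages.  Phase 2
revisits the objectives in the same order and re-minimizes each one to
its fullest extent under all other bounds, tightening its own bound to
the newly achieved value.  A final minimum-total-fluence pass breaks ties
among equally optimal fluences deterministically.

Every stage is a convex program over nonnegative beamlet fluences, solved
by sequential linearization over HiGHS linear programs:

- max-dose terms are per-voxel linear constraints (epigraph form when
  they are the objective); mean terms are linear;
- LTCP and gEUD bounds are *separable* convex sums of per-voxel scalar
  functions, encoded with one auxiliary variable per voxel supported by
  adaptively refined tangent lines (plus the per-voxel dose floor or cap
  the bound itself implies, which keeps LP coefficients moderate);
- an LTCP or gEUD objective is minimized through Kelley cuts on its
  smooth convex form (LTCP via its logarithm — a logsumexp, convex and
  overflow-free).

Tangents and cuts underestimate their convex functions, so the LP is
always a relaxation: an infeasible LP certifies an infeasible stage, and
refinement stops when the true constraint violation and objective gap
drop below tolerance.  A linear-programming feasibility pre-check reports
infeasible hard constraints instead of auto-relaxing them.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, sparse

from .costs import eud, eud_grad_dose, log_ltcp, log_ltcp_grad_dose
from .influence import DoseInfluenceMatrix, Plan, compute_dose
from .prescription import Prescription
from .structures import StructureSet, cord_close_to_target
from .wishlist import HardConstraint, Objective, Wishlist

__all__ = [
    "SolverOptions",
    "StageResult",
    "SolveReport",
    "InfeasibleProblemError",
    "prioritized_optimize",
    "select_target_volume_for_ptv_objective",
    "check_hard_constraints",
    "ConstraintCheck",
    "weighted_sum_optimize",
]


class InfeasibleProblemError(RuntimeError):
    """Hard constraints admit no fluence; the message names the violation."""


@dataclass
class SolverOptions:
    """Knobs of the prioritized solve.

    ``slack`` is the multiplicative "bit of slack" applied when fixing an
    achieved objective value as a constraint (3% by default, with an
    additive floor for near-zero values); ``clamp_at_goal`` keeps the
    goal-clamping rule (disable only for experiments); ``phase2_sweeps``
    is the number of final-phase passes over the objectives; ``tol_rel``
    bounds both the relative constraint violation and the relative
    objective gap accepted from each stage's sequential-linearization
    loop.
    """

    slack: float = 0.03
    slack_floor: float = 1e-3
    clamp_at_goal: bool = True
    phase2_sweeps: int = 1
    min_fluence_pass: bool = True
    maxiter: int = 60
    tol_rel: float = 1e-4


@dataclass
class StageResult:
    priority: int
    phase: int
    volume: str
    cost: str
    achieved: float
    goal: float
    clamped_at_goal: bool
    fixed_bound: float
    status: str
    n_iterations: int

    def to_dict(self) -> dict:
        return {
            "priority": self.priority,
            "phase": self.phase,
            "volume": self.volume,
            "cost": self.cost,
            "achieved": self.achieved,
            "goal": self.goal,
            "clamped_at_goal": self.clamped_at_goal,
            "fixed_bound": self.fixed_bound,
            "status": self.status,
            "n_iterations": self.n_iterations,
        }


@dataclass
class SolveReport:
    stages: list[StageResult] = field(default_factory=list)
    solve_time_s: float = 0.0
    feasible: bool = True

    def phase1(self) -> list[StageResult]:
        return [s for s in self.stages if s.phase == 1]

    def phase2(self) -> list[StageResult]:
        return [s for s in self.stages if s.phase == 2]

    def stage(self, priority: int, phase: int = 1) -> StageResult:
        for s in self.stages:
            if s.priority == priority and s.phase == phase:
                return s
        raise KeyError(f"no stage with priority {priority} in phase {phase}")

    def to_dict(self) -> dict:
        return {
            "stages": [s.to_dict() for s in self.stages],
            "solve_time_s": self.solve_time_s,
            "feasible": self.feasible,
        }


# ---------------------------------------------------------------------------
# compiled objective pieces

@dataclass
class _Compiled:
    """An objective bound to its dose-influence rows."""

    objective: Objective
    volume: str
    A: np.ndarray  # dense (n_structure_voxels, n_beamlets)
    goal: float
    d_p: float  # prescription total dose (LTCP reference)

    def value(self, x: np.ndarray) -> float:
        """Natural-scale cost value at a fluence."""
        d = self.A @ x
        o = self.objective
        if o.cost == "mean":
            return float(d.mean())
        if o.cost == "max":
            return float(d.max())
        if o.cost == "eud":
            return eud(d, o.k)
        if o.cost == "ltcp":
            return float(np.exp(log_ltcp(d, self.d_p, o.alpha)))
        raise ValueError(o.cost)


def select_target_volume_for_ptv_objective(ss: StructureSet) -> str:
    """Volume the PTV coverage objective applies to.

    ``"ptv_minus_cord5"`` when the 5 mm expanded spinal cord touches or
    overlaps the PTV (locating the acceptable underdosage next to the
    cord), else ``"ptv"``.
    """
    return "ptv_minus_cord5" if cord_close_to_target(ss) else "ptv"


def _compile_objectives(
    wl: Wishlist, dij: DoseInfluenceMatrix, ss: StructureSet, rx: Prescription
) -> list[_Compiled]:
    out = []
    for o in sorted(wl.objectives, key=lambda o: o.priority):
        vol = o.volume
        if o.cord_conditional:
            vol = select_target_volume_for_ptv_objective(ss)
            if not ss[vol].any():  # degenerate: PTV swallowed by the cord expansion
                vol = "ptv"
        if vol not in ss:
            raise KeyError(f"objective p{o.priority} refers to unknown volume {vol!r}")
        out.append(_Compiled(o, vol, dij.rows(ss[vol]), o.goal_value(rx), rx.total_dose_gy))
    return out


def _mean_row(A: sparse.spmatrix) -> np.ndarray:
    return np.asarray(A.mean(axis=0)).ravel()


def _hard_constraint_rows(
    wl: Wishlist, dij: DoseInfluenceMatrix, ss: StructureSet, rx: Prescription
) -> tuple[sparse.csr_matrix, np.ndarray, list[HardConstraint]]:
    """Stack all hard constraints as sparse G x <= h."""
    Gs, hs, metas = [], [], []
    for c in wl.constraints:
        if c.volume not in ss:
            raise KeyError(f"hard constraint refers to unknown volume {c.volume!r}")
        mask = ss[c.volume]
        if not mask.any():
            continue
        A = dij.rows(mask)
        limit = c.limit_gy(rx)
        if c.metric == "max":
            Gs.append(A)
            hs.append(np.full(A.shape[0], limit))
        else:  # mean
            Gs.append(sparse.csr_matrix(_mean_row(A)))
            hs.append(np.array([limit]))
        metas.append(c)
    if not Gs:
        return sparse.csr_matrix((0, dij.n_beamlets)), np.zeros(0), []
    return sparse.vstack(Gs, format="csr"), np.concatenate(hs), metas


def _feasibility_check(G: sparse.spmatrix, h: np.ndarray, n: int) -> np.ndarray:
    """LP feasibility of {x >= 0 : G x <= h}; returns a feasible point."""
    has_rows = G.shape[0] > 0
    res = optimize.linprog(
        c=np.zeros(n), A_ub=G if has_rows else None, b_ub=h if has_rows else None,
        bounds=[(0, None)] * n, method="highs",
    )
    if not res.success:
        raise InfeasibleProblemError(
            "hard constraints are infeasible: " + (res.message or "LP failed")
        )
    return res.x


def _variable_bounds(G: sparse.spmatrix, h: np.ndarray, n: int) -> np.ndarray:
    """Per-beamlet upper bounds implied by single-variable relaxations."""
    ub = np.full(n, 1e6)
    coo = sparse.coo_matrix(G)
    pos = coo.data > 1e-12
    if pos.any():
        np.minimum.at(ub, coo.col[pos], h[coo.row[pos]] / coo.data[pos])
    return ub


# ---------------------------------------------------------------------------
# separable convex bounds (LTCP / gEUD as constraints)

@dataclass
class _SeparableBlock:
    """A separable convex sum ``sum_i phi(d_i)`` over one structure.

    Used either as a bound (``rhs`` set: ``sum phi <= rhs``) or as a
    stage objective (``rhs`` None: minimize ``weight * sum y``).  Encoded
    in the LP with one auxiliary variable per voxel supported by tangent
    lines of ``phi``; tangents underestimate the convex ``phi``, so the
    encoding is always a relaxation, tightened adaptively at the realized
    per-voxel doses.  ``d_floor``/``d_cap`` are per-voxel dose rows
    implied by a bound (they also keep LP coefficients moderate).
    """

    label: str
    A: np.ndarray
    phi: Callable[[np.ndarray], np.ndarray]
    dphi: Callable[[np.ndarray], np.ndarray]
    tangent_points: list[float]
    rhs: float | None = None
    weight: float = 1.0
    d_floor: float | None = None
    d_cap: float | None = None
    # per-voxel refinement tangents as (voxel_index, dose) pairs
    refinements: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_vox(self) -> int:
        return self.A.shape[0]

    @property
    def is_objective(self) -> bool:
        return self.rhs is None

    def true_sum(self, x: np.ndarray) -> float:
        return float(self.phi(self.A @ x).sum())

    def violation(self, x: np.ndarray) -> float:
        return (self.true_sum(x) - self.rhs) / max(abs(self.rhs), 1e-9)

    def refine(self, x: np.ndarray, y: np.ndarray | None = None, max_new: int = 24) -> int:
        """Add tangents at the realized doses of the worst voxels.

        "Worst" means largest underestimation gap ``phi(d_i) - y_i`` when
        the LP auxiliaries are given, else largest ``phi(d_i)``.  Returns
        the number of tangents added.
        """
        d = self.A @ x
        score = self.phi(d) - (y if y is not None else 0.0)
        order = np.argsort(score)[::-1][:max_new]
        existing = {(i, round(float(dd), 3)) for i, dd in self.refinements}
        added = 0
        for i in order:
            key = (int(i), round(float(d[i]), 3))
            if key not in existing:
                self.refinements.append((int(i), float(d[i])))
                added += 1
        return added


def _ltcp_phi(d_p: float, alpha: float):
    phi = lambda d: np.exp(-alpha * (np.asarray(d, float) - d_p))
    dphi = lambda d: -alpha * phi(d)
    return phi, dphi


def _ltcp_bound(A: np.ndarray, bound: float, d_p: float, alpha: float) -> _SeparableBlock:
    n_v = A.shape[0]
    rhs = n_v * max(bound, 1e-12)
    phi, dphi = _ltcp_phi(d_p, alpha)
    # any voxel with phi(d) > rhs alone violates the bound
    d_floor = d_p - np.log(rhs) / alpha
    hi = d_p + 5.0 / alpha  # phi ~ 6.7e-3 beyond; flat tail covered by y >= 0
    pts = list(np.linspace(d_floor, hi, 10))
    return _SeparableBlock(f"ltcp<={bound:.4g}", A, phi, dphi, pts, rhs=rhs, d_floor=d_floor)


def _ltcp_objective_block(A: np.ndarray, d_p: float, alpha: float) -> _SeparableBlock:
    n_v = A.shape[0]
    phi, dphi = _ltcp_phi(d_p, alpha)
    # tangents over the clinically plausible dose range; tangents are global
    # underestimators, so clipping the grid only loosens the approximation
    # below it (refinement tightens wherever iterates actually land)
    lo, hi = d_p - 25.0 / alpha, d_p + 5.0 / alpha
    pts = list(np.linspace(lo, hi, 12))
    return _SeparableBlock("ltcp-objective", A, phi, dphi, pts, weight=1.0 / n_v)


def _eud_bound(A: np.ndarray, bound: float, k: float) -> _SeparableBlock:
    # normalized dose u = d / bound keeps u^k coefficients O(1)
    n_v = A.shape[0]
    scale = max(bound, 1e-9)
    phi = lambda u: np.maximum(np.asarray(u, float), 0.0) ** k
    dphi = lambda u: k * np.maximum(np.asarray(u, float), 0.0) ** (k - 1)
    cap = n_v ** (1.0 / k)  # a voxel above this alone violates the bound
    pts = list(np.linspace(0.0, cap, 10))
    return _SeparableBlock(
        f"eud<={bound:.4g}", A / scale, phi, dphi, pts, rhs=float(n_v), d_cap=cap
    )


def _eud_objective_block(A: np.ndarray, k: float, d_ref: float) -> _SeparableBlock:
    # minimizing mean(u^k) is a monotone transform of minimizing the gEUD
    n_v = A.shape[0]
    phi = lambda u: np.maximum(np.asarray(u, float), 0.0) ** k
    dphi = lambda u: k * np.maximum(np.asarray(u, float), 0.0) ** (k - 1)
    pts = list(np.linspace(0.0, 1.5, 12))
    return _SeparableBlock("eud-objective", A / d_ref, phi, dphi, pts, weight=1.0 / n_v)


def _fixed_constraint_term(comp: _Compiled, bound: float):
    """Compile value(x) <= bound as linear rows or a separable bound."""
    o = comp.objective
    if o.cost == "max":
        return ("lin", comp.A, np.full(comp.A.shape[0], bound))
    if o.cost == "mean" or (o.cost == "eud" and o.k == 1):
        return ("lin", sparse.csr_matrix(_mean_row(comp.A)), np.array([bound]))
    if o.cost == "eud":
        return ("sep", _eud_bound(comp.A, bound, o.k))
    if o.cost == "ltcp":
        return ("sep", _ltcp_bound(comp.A, bound, comp.d_p, o.alpha))
    raise ValueError(o.cost)


class _StageSolver:
    """Sequential-linearization solve of one convex stage.

    minimize   objective ("lin", c) | ("maxrows", A) | ("sep", block)
    subject to G x <= h, separable bounds, 0 <= x <= ub.

    Column layout: x | per-block voxel auxiliaries | t (max epigraph).
    """

    def __init__(
        self,
        n: int,
        G: np.ndarray,
        h: np.ndarray,
        sep: list[_SeparableBlock],
        ub: np.ndarray,
        opts: SolverOptions,
    ):
        self.n = n
        self.G = G
        self.h = h
        self.sep = sep
        self.ub = ub
        self.opts = opts

    def _assemble(self, blocks, ncols, has_t, epi_rows, epi_rhs, offsets):
        """Sparse A_ub, b_ub for the current tangent sets."""
        n = self.n
        rows, rhs = [], []

        def xpad(block_x):
            m = block_x.shape[0]
            return sparse.hstack(
                [block_x, sparse.csr_matrix((m, ncols - n))], format="csr"
            )

        def ycoupled(block_x, y_cols, y_vals):
            m = block_x.shape[0]
            Y = sparse.csr_matrix(
                (y_vals, (np.arange(m), np.asarray(y_cols) - n)),
                shape=(m, ncols - n),
            )
            return sparse.hstack([block_x, Y], format="csr")

        if self.G.shape[0]:
            rows.append(xpad(self.G))
            rhs.append(self.h)
        for b, off in zip(blocks, offsets):
            nv = b.n_vox
            ycols = off + np.arange(nv)
            if b.d_floor is not None:
                rows.append(xpad(-b.A))
                rhs.append(np.full(nv, -b.d_floor))
            if b.d_cap is not None:
                rows.append(xpad(b.A))
                rhs.append(np.full(nv, b.d_cap))
            # shared tangents: for every voxel i and point p:
            #   dphi(p) * d_i - y_i <= dphi(p) p - phi(p)
            for p in b.tangent_points:
                s, v = float(b.dphi(p)), float(b.phi(p))
                rows.append(ycoupled(s * b.A, ycols, -np.ones(nv)))
                rhs.append(np.full(nv, s * p - v))
            if b.refinements:
                idx = np.array([i for i, _ in b.refinements])
                pts = np.array([p for _, p in b.refinements])
                s, v = b.dphi(pts), b.phi(pts)
                scaled = sparse.diags(s) @ b.A[idx]
                rows.append(ycoupled(scaled, ycols[0] + idx, -np.ones(len(idx))))
                rhs.append(s * pts - v)
            if b.rhs is not None:
                sum_row = sparse.csr_matrix(
                    (np.ones(nv), (np.zeros(nv, int), ycols)), shape=(1, ncols)
                )
                rows.append(sum_row)
                rhs.append(np.array([b.rhs]))
        if epi_rows is not None:
            m = epi_rows.shape[0]
            t_col = sparse.csr_matrix(
                (-np.ones(m), (np.arange(m), np.full(m, ncols - n - 1, int))),
                shape=(m, ncols - n),
            )
            rows.append(sparse.hstack([epi_rows, t_col], format="csr"))
            rhs.append(epi_rhs)
        if not rows:
            return None, None
        return sparse.vstack(rows, format="csr"), np.concatenate(rhs)

    def solve(self, objective, x0: np.ndarray):
        """Returns (x, solver-scale objective value, status, lp count).

        ``objective`` is ("lin", c) | ("maxrows", A) | ("sep", block) |
        ("multi", c_lin, [blocks]); a "multi" objective sums a linear part
        and any number of separable blocks.
        """
        opts = self.opts
        n = self.n
        kind = objective[0]
        if kind == "sep":
            kind, objective = "multi", ("multi", np.zeros(n), [objective[1]])
        has_t = kind == "maxrows"
        obj_blocks: list[_SeparableBlock] = list(objective[2]) if kind == "multi" else []
        blocks = self.sep + obj_blocks

        offsets, col = [], n
        for b in blocks:
            offsets.append(col)
            col += b.n_vox
        ncols = col + (1 if has_t else 0)
        obj_offsets = offsets[len(self.sep) :]

        c = np.zeros(ncols)
        epi_rows = epi_rhs = None
        if kind == "lin":
            c[:n] = objective[1]
        elif kind == "maxrows":
            c[-1] = 1.0
            epi_rows, epi_rhs = objective[1], np.zeros(objective[1].shape[0])
        else:
            c[:n] = objective[1]
            for b, off in zip(obj_blocks, obj_offsets):
                c[off : off + b.n_vox] = b.weight

        bounds = [(0.0, float(u)) for u in self.ub]
        for b in blocks:
            bounds += [(0.0, None)] * b.n_vox
        if has_t:
            bounds.append((0.0, None))

        x = x0
        fval = np.inf
        best_x, best_val = None, np.inf
        status = "iteration limit"
        it = 0
        for it in range(1, opts.maxiter + 1):
            A_ub, b_ub = self._assemble(blocks, ncols, has_t, epi_rows, epi_rhs, offsets)
            lp = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
            if lp.status == 2:
                raise InfeasibleProblemError(
                    "stage subproblem infeasible (the relaxation excludes no feasible "
                    "point, so the stage constraints conflict)"
                )
            if not lp.success:
                status = f"LP solver: {lp.message}"
                break
            x = np.maximum(lp.x[:n], 0.0)
            viol = 0.0
            for b, off in zip(self.sep, offsets):
                v = b.violation(x)
                if v > opts.tol_rel:
                    b.refine(x, y=lp.x[off : off + b.n_vox])
                viol = max(viol, v)
            if kind == "multi":
                fval = float(c[:n] @ x)
                f_lp = fval
                for b, off in zip(obj_blocks, obj_offsets):
                    y = lp.x[off : off + b.n_vox]
                    fval += b.weight * b.true_sum(x)
                    f_lp += b.weight * float(y.sum())
                gap = (fval - f_lp) / max(1.0, abs(fval))
                if gap > opts.tol_rel:
                    for b, off in zip(obj_blocks, obj_offsets):
                        b.refine(x, y=lp.x[off : off + b.n_vox])
            elif kind == "maxrows":
                fval = float((objective[1] @ x).max())
                gap = 0.0
            else:
                fval = float(c[:n] @ x)
                gap = 0.0
            if viol <= opts.tol_rel and fval < best_val:
                best_x, best_val = x, fval
            if viol <= opts.tol_rel and gap <= opts.tol_rel:
                status = "converged"
                break
        if best_x is None:
            best_x, best_val = x, fval  # nearly feasible final iterate
        return best_x, best_val, status, it


def _fix_bound(achieved: float, goal: float, clamped: bool, opts: SolverOptions) -> float:
    if clamped:
        return goal
    return max(achieved * (1.0 + opts.slack), achieved + opts.slack_floor)


def _stage_objective(comp: _Compiled):
    o = comp.objective
    if o.cost == "mean" or (o.cost == "eud" and o.k == 1):
        return ("lin", _mean_row(comp.A))
    if o.cost == "max":
        return ("maxrows", comp.A)
    if o.cost == "eud":
        return ("sep", _eud_objective_block(comp.A, o.k, comp.d_p))
    return ("sep", _ltcp_objective_block(comp.A, comp.d_p, o.alpha))


def prioritized_optimize(
    dij: DoseInfluenceMatrix,
    wl: Wishlist,
    ss: StructureSet,
    rx: Prescription,
    opts: SolverOptions | None = None,
) -> tuple[Plan, SolveReport]:
    """Run the full two-phase prioritized optimization.

    ``wl`` may be a template or an already-resolved wishlist; limits and
    goals are always evaluated against ``rx``.  Returns the plan (fluence,
    dose, per-stage log) and the solve report.  Raises
    :class:`InfeasibleProblemError` when the hard constraints admit no
    fluence.
    """
    opts = opts or SolverOptions()
    t0 = time.perf_counter()
    report = SolveReport()

    G, h, _ = _hard_constraint_rows(wl, dij, ss, rx)
    n = dij.n_beamlets
    x = _feasibility_check(G, h, n)
    ub = _variable_bounds(G, h, n)

    # warm start: uniform fluence scaled just inside the hard constraints
    ones = np.ones(n)
    load = G @ ones if G.shape[0] else np.zeros(0)
    pos = load > 0
    if pos.any():
        x = ones * 0.95 * float(np.min(h[pos] / load[pos]))

    compiled = _compile_objectives(wl, dij, ss, rx)
    fixed: dict[int, tuple[_Compiled, float]] = {}
    # separable bound blocks cached per priority so tangent refinements
    # accumulate across stages; rebuilt when the bound value changes
    term_cache: dict[int, tuple[float, tuple]] = {}

    def fixed_term(prio: int) -> tuple:
        comp, bound = fixed[prio]
        hit = term_cache.get(prio)
        if hit is None or hit[0] != bound:
            term_cache[prio] = (bound, _fixed_constraint_term(comp, bound))
        return term_cache[prio][1]

    def solver_for_current_bounds(extra_term: tuple | None = None) -> _StageSolver:
        lin_G, lin_h, sep = ([G] if G.shape[0] else []), ([h] if h.shape[0] else []), []
        terms = [fixed_term(p) for p in fixed]
        if extra_term is not None:
            terms.append(extra_term)
        for term in terms:
            if term[0] == "lin":
                lin_G.append(term[1])
                lin_h.append(term[2])
            else:
                sep.append(term[1])
        Gs = sparse.vstack(lin_G, format="csr") if lin_G else sparse.csr_matrix((0, n))
        hs = np.concatenate(lin_h) if lin_h else np.zeros(0)
        # drop max rows that no admissible fluence can activate
        if Gs.shape[0]:
            keep = np.asarray(Gs @ ub).ravel() > hs - 1e-9
            Gs, hs = Gs[keep], hs[keep]
        return _StageSolver(n, Gs, hs, sep, ub, opts)

    def try_goal(comp: _Compiled) -> tuple[np.ndarray, str, int, tuple] | None:
        """Feasibility of {cost <= goal}: minimum-fluence point or None."""
        term = _fixed_constraint_term(comp, comp.goal)
        solver = solver_for_current_bounds(term)
        try:
            x_new, _, status, nit = solver.solve(("lin", np.ones(n)), x)
        except InfeasibleProblemError:
            return None
        if status != "converged" or comp.value(x_new) > comp.goal * (1 + 10 * opts.tol_rel):
            return None
        return x_new, status, nit, term

    def run_stage(comp: _Compiled) -> tuple[float, str, int]:
        nonlocal x
        solver = solver_for_current_bounds()
        x_new, _, status, nit = solver.solve(_stage_objective(comp), x)
        x = x_new
        return comp.value(x), status, nit

    # ---- phase 1: priority order; stop at the goal when it is achievable,
    # otherwise minimize and fix the achieved value with slack
    for comp in compiled:
        o = comp.objective
        if comp.A.shape[0] == 0:
            report.stages.append(StageResult(
                o.priority, 1, comp.volume, o.cost, float("nan"), comp.goal,
                False, float("nan"), "skipped (empty volume)", 0,
            ))
            continue
        goal_hit = try_goal(comp) if opts.clamp_at_goal else None
        if goal_hit is not None:
            x, status, nit, term = goal_hit
            achieved, clamped = comp.value(x), True
            term_cache[o.priority] = (comp.goal, term)  # keep its refinements
        else:
            achieved, status, nit = run_stage(comp)
            clamped = opts.clamp_at_goal and achieved <= comp.goal
        bound = _fix_bound(achieved, comp.goal, clamped, opts)
        fixed[o.priority] = (comp, bound)
        report.stages.append(StageResult(
            o.priority, 1, comp.volume, o.cost, achieved, comp.goal,
            clamped, bound, status, nit,
        ))

    # ---- phase 2: re-minimize each objective fully under the other bounds
    for _ in range(opts.phase2_sweeps):
        for comp in compiled:
            o = comp.objective
            if o.priority not in fixed:
                continue
            achieved, status, nit = run_stage(comp)
            old_bound = fixed[o.priority][1]
            new_bound = min(old_bound, _fix_bound(achieved, comp.goal, False, opts))
            fixed[o.priority] = (comp, new_bound)
            report.stages.append(StageResult(
                o.priority, 2, comp.volume, o.cost, achieved, comp.goal,
                False, new_bound, status, nit,
            ))

    # ---- deterministic tie-break: minimum total fluence within all bounds
    if opts.min_fluence_pass:
        solver = solver_for_current_bounds()
        try:
            x_new, _, status, _ = solver.solve(("lin", np.ones(n)), x)
            if status == "converged":
                x = x_new
        except InfeasibleProblemError:
            pass  # keep the last stage iterate

    dose = compute_dose(dij, x)
    plan = Plan(
        fluence=x,
        dose=dose,
        prescription=rx,
        wishlist_name=wl.name,
        solver_log=[s.to_dict() for s in report.stages],
    )
    report.solve_time_s = time.perf_counter() - t0
    return plan, report


@dataclass
class ConstraintCheck:
    volume: str
    metric: str
    value: float
    limit: float
    margin: float
    passed: bool


def check_hard_constraints(
    plan: Plan,
    wl: Wishlist,
    ss: StructureSet,
    rx: Prescription | None = None,
    tol_rel: float = 1e-3,
) -> list[ConstraintCheck]:
    """Evaluate every hard constraint on a plan's dose.

    ``passed`` allows a relative tolerance ``tol_rel`` on the limit
    (solver feasibility tolerance); the signed ``margin`` (limit - value)
    is reported untouched.
    """
    rx = rx or plan.prescription
    if rx is None:
        raise ValueError("need a prescription to evaluate percent-of-dose limits")
    dose = plan.dose
    out = []
    for c in wl.constraints:
        mask = ss[c.volume]
        if not mask.any():
            continue
        d = dose.ravel()[np.flatnonzero(mask.ravel())]
        value = float(d.max() if c.metric == "max" else d.mean())
        limit = c.limit_gy(rx)
        out.append(ConstraintCheck(
            c.volume, c.metric, value, limit, limit - value,
            value <= limit * (1.0 + tol_rel) + 1e-9,
        ))
    return out


def weighted_sum_optimize(
    dij: DoseInfluenceMatrix,
    wl: Wishlist,
    ss: StructureSet,
    rx: Prescription,
    opts: SolverOptions | None = None,
    include: str = "all",
) -> tuple[Plan, SolveReport]:
    """Single weighted-sum solve with no priority structure.

    The deliberately crude comparator arm for cohort studies.  With
    ``include="all"`` every objective enters one scalarized cost with
    equal weight (dose terms scaled by the prescription; max objectives
    degraded to mean terms).  With ``include="coverage"`` only the target
    LTCP terms are optimized under the hard constraints — a minimal-effort
    plan that covers the target and respects the limits but makes no
    organ-sparing effort at all.
    """
    opts = opts or SolverOptions()
    t0 = time.perf_counter()
    G, h, _ = _hard_constraint_rows(wl, dij, ss, rx)
    n = dij.n_beamlets
    x0 = _feasibility_check(G, h, n)
    ub = _variable_bounds(G, h, n)
    ones = np.ones(n)
    load = G @ ones if G.shape[0] else np.zeros(0)
    pos = load > 0
    if pos.any():
        x0 = ones * 0.95 * float(np.min(h[pos] / load[pos]))

    compiled = [c for c in _compile_objectives(wl, dij, ss, rx) if c.A.shape[0] > 0]
    dp = rx.total_dose_gy

    if include not in ("all", "coverage"):
        raise ValueError(f"include must be 'all' or 'coverage', got {include!r}")
    c_lin = np.zeros(n)
    blocks: list[_SeparableBlock] = []
    for comp in compiled:
        o = comp.objective
        if o.cost == "ltcp":
            blocks.append(_ltcp_objective_block(comp.A, dp, o.alpha))
        elif include == "coverage":
            continue
        elif o.cost == "eud" and o.k > 1:
            blocks.append(_eud_objective_block(comp.A, o.k, dp))
        else:  # mean, eud(k=1) and max-as-mean
            c_lin += _mean_row(comp.A) / dp

    solver = _StageSolver(n, G, h, [], ub, opts)
    x, val, status, nit = solver.solve(("multi", c_lin, blocks), x0)
    report = SolveReport(
        stages=[StageResult(0, 1, "all", "weighted_sum", float(val), float("nan"),
                            False, float("nan"), status, nit)],
        solve_time_s=time.perf_counter() - t0,
    )
    plan = Plan(x, compute_dose(dij, x), rx, wl.name, [report.stages[0].to_dict()])
    return plan, report
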