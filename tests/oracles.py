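"""Independent brute-force oracles used by the test suite.

Everything here recomputes a quantity from first principles — per-voxel
boolean evaluation, explicit sorting, exhaustive grid search, sign-
assignment enumeration — without touching the implementation paths it
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# geometry

def margin_expansion_bruteforce(mask, margins, grid):
    """Per-voxel scaled-Euclidean margin check over all voxel pairs."""
    mask = np.asarray(mask, bool)
    m = np.asarray(margins, float) if np.iterable(margins) else np.full(3, float(margins))
    centers = grid.voxel_centers().reshape(grid.shape + (3,))
    src = centers[mask]
    out = mask.copy()
    flat = centers.reshape(-1, 3)
    scale = np.where(m > 0, m, 1e-12)
    for i, c in enumerate(flat):
        if out.ravel()[i]:
            continue
        delta = (src - c) / scale
        if np.any((delta**2).sum(axis=1) <= 1.0 + 1e-9):
            out.ravel()[i] = True
    return out


# ---------------------------------------------------------------------------
# dose-volume statistics

def v_index_oracle(dose, mask, threshold):
    d = np.asarray(dose, float).ravel()[np.asarray(mask, bool).ravel()]
    return 100.0 * np.count_nonzero(d >= threshold) / d.size


def d_index_oracle(dose, mask, percent):
    d = np.sort(np.asarray(dose, float).ravel()[np.asarray(mask, bool).ravel()])[::-1]
    k = int(np.ceil(percent * d.size / 100.0 - 1e-9))
    return float(d[k - 1])


def r50_oracle(dose, ptv_mask, patient_mask, d_p):
    d = np.asarray(dose, float).ravel()
    n_hot = int(np.count_nonzero(d[np.asarray(patient_mask, bool).ravel()] >= 0.5 * d_p))
    return n_hot / int(np.asarray(ptv_mask, bool).sum())


def hi_oracle(dose, ptv_mask):
    d2 = d_index_oracle(dose, ptv_mask, 2.0)
    d98 = d_index_oracle(dose, ptv_mask, 98.0)
    d50 = d_index_oracle(dose, ptv_mask, 50.0)
    return (d2 - d98) / d50


# ---------------------------------------------------------------------------
# Wilcoxon signed rank: full 2^n sign enumeration

def wilcoxon_exact_enumeration(differences):
    """Two-tailed p by listing all 2^n sign assignments explicitly."""
    from scipy.stats import rankdata

    d = np.asarray(differences, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        ranks[np.array(signs, bool)].sum() for signs in product([0, 1], repeat=n)
    ])
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# tiny prioritized-optimization instances + lexicographic grid search

@dataclass
class TinyObjective:
    cost: str  # mean | max | eud | ltcp
    rows: np.ndarray  # voxel indices of its volume
    goal: float
    alpha: float | None = None
    k: float | None = None

    def value(self, doses: np.ndarray) -> np.ndarray:
        """Vectorized cost over a batch of dose matrices (batch, n_vox)."""
        d = doses[:, self.rows]
        if self.cost == "mean":
            return d.mean(axis=1)
        if self.cost == "max":
            return d.max(axis=1)
        if self.cost == "eud":
            return (np.mean(d**self.k, axis=1)) ** (1.0 / self.k)
        if self.cost == "ltcp":
            return np.mean(np.exp(-self.alpha * (d - self.d_p)), axis=1)
        raise ValueError(self.cost)

    d_p: float = 66.0


@dataclass
class TinyInstance:
    """A random fluence-optimization problem small enough to grid-search."""

    D: np.ndarray  # (n_vox, n_beamlets)
    max_rows: np.ndarray  # voxel indices with a max-dose hard constraint
    max_limit: float
    mean_rows: np.ndarray
    mean_limit: float
    objectives: list[TinyObjective]
    d_p: float = 66.0

    @property
    def n_beamlets(self) -> int:
        return self.D.shape[1]

    def feasible(self, doses: np.ndarray) -> np.ndarray:
        ok = doses[:, self.max_rows].max(axis=1) <= self.max_limit + 1e-9
        ok &= doses[:, self.mean_rows].mean(axis=1) <= self.mean_limit + 1e-9
        return ok

    def fluence_box(self) -> np.ndarray:
        """Upper bound per beamlet from single-variable relaxations."""
        ub = np.full(self.n_beamlets, np.inf)
        for i in self.max_rows:
            row = self.D[i]
            pos = row > 1e-12
            ub[pos] = np.minimum(ub[pos], self.max_limit / row[pos])
        mean_row = self.D[self.mean_rows].mean(axis=0)
        pos = mean_row > 1e-12
        ub[pos] = np.minimum(ub[pos], self.mean_limit / mean_row[pos])
        return np.where(np.isfinite(ub), ub, 10.0)


def random_tiny_instance(rng: np.random.Generator, n_beamlets=2, n_vox=30) -> TinyInstance:
    D = rng.uniform(0.0, 1.0, size=(n_vox, n_beamlets))
    D[rng.random(D.shape) < 0.3] = 0.0
    # ensure every beamlet irradiates something
    for j in range(n_beamlets):
        if D[:, j].max() == 0:
            D[rng.integers(n_vox), j] = rng.uniform(0.5, 1.0)
    idx = rng.permutation(n_vox)
    target = idx[: n_vox // 3]
    oar = idx[n_vox // 3 : 2 * n_vox // 3]
    d_p = 60.0
    objectives = [
        TinyObjective("ltcp", target, goal=float(rng.uniform(0.5, 2.0)), alpha=0.25, d_p=d_p),
        TinyObjective("mean", oar, goal=float(rng.uniform(5.0, 20.0))),
    ]
    if rng.random() < 0.5:
        objectives.append(TinyObjective("eud", oar, goal=float(rng.uniform(10.0, 30.0)), k=4.0))
    else:
        objectives.append(TinyObjective("max", oar, goal=float(rng.uniform(15.0, 40.0))))
    return TinyInstance(
        D=D,
        max_rows=np.arange(n_vox),
        max_limit=1.07 * d_p,
        mean_rows=oar,
        mean_limit=float(rng.uniform(20.0, 40.0)),
        objectives=objectives,
        d_p=d_p,
    )


def lexicographic_grid_search(
    inst: TinyInstance, slack=0.03, slack_floor=1e-3, steps=101, chunk=200_000
):
    """Exhaustive lexicographic optimum over a fluence grid.

    Mirrors the prioritized procedure: walk objectives in order, keep the
    grid points within the fixed bound (the goal when the stage optimum
    beats it, otherwise optimum * (1 + slack)).  Returns per-stage
    (optimum, bound, clamped) triples.
    """
    ub = inst.fluence_box()
    axes = [np.linspace(0.0, u, steps) for u in ub]
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.column_stack([m.ravel() for m in mesh])

    keep_chunks = []
    for start in range(0, len(X), chunk):
        xs = X[start : start + chunk]
        doses = xs @ inst.D.T
        keep_chunks.append(xs[inst.feasible(doses)])
    X = np.vstack(keep_chunks)
    if len(X) == 0:
        raise RuntimeError("no feasible grid point")

    results = []
    for obj in inst.objectives:
        doses = X @ inst.D.T
        vals = obj.value(doses)
        opt = float(vals.min())
        grid_tol = 1e-9 + 1e-3 * max(1.0, abs(opt))
        if opt <= obj.goal:
            bound, clamped = obj.goal, True
        else:
            bound, clamped = max(opt * (1 + slack), opt + slack_floor), False
        results.append((opt, bound, clamped))
        X = X[vals <= bound + grid_tol]
    return results
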