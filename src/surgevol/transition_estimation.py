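"""Estimate banded 4x4 transition matrices from consecutive poll proportions.

The restriction process is a birth-death chain on four ordered severity
states: in one week a hospital can only stay put or move to an adjacent
severity level, so six entries of the transition matrix are structurally
zero.  With only aggregate proportions observed, each weekly matrix is
estimated by constrained least squares over a two-step window, solved as a
quadratic program with row-sum equality constraints and [0, 1] bounds.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize

from .io_tables import PollSeries

N_STATES = 4

#: The 10 free entries, row-major: (i, j) pairs allowed by the band.
FREE_ENTRIES: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1),
    (1, 0), (1, 1), (1, 2),
    (2, 1), (2, 2), (2, 3),
    (3, 2), (3, 3),
)

#: Structurally-zero entries (moves across more than one severity level).
ZERO_ENTRIES: tuple[tuple[int, int], ...] = (
    (0, 2), (0, 3), (1, 3), (2, 0), (3, 0), (3, 1),
)

_PARAM_INDEX = {ij: k for k, ij in enumerate(FREE_ENTRIES)}

#: For each destination state j, the source states allowed to enter it.
SOURCES_INTO = tuple(
    tuple(i for i in range(N_STATES) if (i, j) in _PARAM_INDEX)
    for j in range(N_STATES)
)


def _row_sum_matrix() -> np.ndarray:
    a = np.zeros((N_STATES, len(FREE_ENTRIES)))
    for k, (i, _) in enumerate(FREE_ENTRIES):
        a[i, k] = 1.0
    return a


ROW_SUM_A = _row_sum_matrix()


class SolverError(RuntimeError):
    """QP backend failed; carries the backend status message."""


@dataclass
class TransitionMatrix:
    """A banded row-stochastic 4x4 matrix.

    ``values`` is the cleaned solution (clipped to [0, 1], rows re-normalized
    exactly); ``raw`` keeps the solver output before cleanup and ``sse`` the
    unridged squared residual of the fitting window, when estimated.
    """

    values: np.ndarray
    raw: np.ndarray | None = None
    sse: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 4x4")
        for i, j in ZERO_ENTRIES:
            if self.values[i, j] != 0.0:
                raise ValueError(f"entry ({i + 1},{j + 1}) must be exactly 0")
        if np.any(self.values < -1e-8) or np.any(self.values > 1 + 1e-8):
            raise ValueError("entries must lie in [0, 1] within 1e-8")
        rows = self.values.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-8):
            raise ValueError("rows must sum to 1 within 1e-8")
        self.values = np.clip(self.values, 0.0, 1.0)
        self.values /= self.values.sum(axis=1, keepdims=True)

    @classmethod
    def identity(cls) -> "TransitionMatrix":
        return cls(np.eye(N_STATES))

    @classmethod
    def from_free(cls, p: np.ndarray, **kw) -> "TransitionMatrix":
        m = np.zeros((N_STATES, N_STATES))
        for k, (i, j) in enumerate(FREE_ENTRIES):
            m[i, j] = p[k]
        return cls(m, **kw)

    def to_free(self) -> np.ndarray:
        return np.array([self.values[i, j] for i, j in FREE_ENTRIES])


@dataclass
class QPWindow:
    """Design of one weekly estimation problem.

    Stacks the two transition equations around poll t (previous -> current
    and current -> next).  Row ``2*j + w`` of ``design`` predicts the
    destination-j proportion in window w from the occupancies of the source
    states allowed to enter j; ``target`` holds the corresponding observed
    proportions.
    """

    design: np.ndarray
    target: np.ndarray
    equality: np.ndarray = field(default_factory=lambda: ROW_SUM_A.copy())

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    def objective(self, p: np.ndarray) -> float:
        """Unridged squared residual ||target - design @ p||^2."""
        r = self.target - self.design @ np.asarray(p, dtype=float)
        return float(r @ r)

    def identifiable(self, threshold: float = 0.05) -> np.ndarray:
        """Boolean mask over free parameters whose source state is occupied
        (>= threshold) in at least one stacked equation, i.e. informed by
        data."""
        occ = np.zeros(len(FREE_ENTRIES), dtype=bool)
        for k, (i, _) in enumerate(FREE_ENTRIES):
            occ[k] = bool(np.any(self._sources[:, i] >= threshold))
        return occ

    _sources: np.ndarray = field(default=None, repr=False)


def _check_prob_vector(y, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"{name} must have length {N_STATES}")
    if abs(y.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must sum to 1 within 1e-6 (got {y.sum()})")
    return y


def build_qp_window(y_prev, y_curr, y_next) -> QPWindow:
    """Assemble the 8x10 design and 8-vector target for one window."""
    y_prev = _check_prob_vector(y_prev, "y_prev")
    y_curr = _check_prob_vector(y_curr, "y_curr")
    y_next = _check_prob_vector(y_next, "y_next")
    design = np.zeros((2 * N_STATES, len(FREE_ENTRIES)))
    target = np.zeros(2 * N_STATES)
    for j in range(N_STATES):
        for w, (src, dst) in enumerate([(y_prev, y_curr), (y_curr, y_next)]):
            row = 2 * j + w
            for i in SOURCES_INTO[j]:
                design[row, _PARAM_INDEX[(i, j)]] = src[i]
            target[row] = dst[j]
    win = QPWindow(design=design, target=target)
    win._sources = np.vstack([y_prev, y_curr])
    return win


def _default_prior() -> np.ndarray:
    return TransitionMatrix.identity().to_free()


def _solve_working_set(Xa, ya, A, b, fixed: dict[int, float]):
    """Minimize 1/2 ||Xa x - ya||^2 s.t. Ax = b with some variables pinned.

    Returns (x, mu) where mu are the equality multipliers.  Solved in
    least-squares form through the equality nullspace (SVD), which keeps the
    conditioning at the square root of the normal-equations KKT system —
    essential for the near-singular windows this estimator meets.
    """
    n = Xa.shape[1]
    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    x = np.zeros(n)
    for i, v in fixed.items():
        x[i] = v
    Af = A[:, free]
    rhs_eq = b - A @ x
    u, s, vt = np.linalg.svd(Af, full_matrices=True)
    rank = int(np.sum(s > 1e-12))
    # particular solution of Af xf = rhs_eq and nullspace basis
    xf0 = vt[:rank].T @ ((u.T @ rhs_eq)[:rank] / s[:rank])
    Z = vt[rank:].T
    resid = ya - Xa @ x - Xa[:, free] @ xf0
    if Z.shape[1]:
        q = np.linalg.lstsq(Xa[:, free] @ Z, resid, rcond=None)[0]
        xf = xf0 + Z @ q
    else:
        xf = xf0
    x[free] = xf
    # equality multipliers from stationarity on the free coordinates
    g = Xa.T @ (Xa @ x - ya)
    mu = np.linalg.lstsq(Af.T, -g[free], rcond=None)[0] if len(free) else \
        np.zeros(A.shape[0])
    return x, mu


def _active_set_qp(Xa, ya, A, b, x0, max_iter: int = 200) -> np.ndarray:
    """Exact primal active-set solver for a strictly convex box/equality QP
    in least-squares form.

    minimize 1/2 ||Xa x - ya||^2   s.t.  Ax = b,  0 <= x <= 1.

    Starts from a feasible ``x0``; terminates finitely for a full-rank Xa.
    Solutions are exact up to the least-squares solves, which is what lets
    estimates agree with independent solvers to high precision.
    """
    x = np.asarray(x0, dtype=float).copy()
    fixed: dict[int, float] = {}
    for _ in range(max_iter):
        target, mu = _solve_working_set(Xa, ya, A, b, fixed)
        d = target - x
        if np.max(np.abs(d)) <= 1e-13:
            # at the working-set optimum: check bound multipliers
            g = Xa.T @ (Xa @ x - ya) + A.T @ mu
            worst, worst_i = -1e-11, None
            for i, v in fixed.items():
                lam = g[i] if v == 0.0 else -g[i]
                if lam < worst:
                    worst, worst_i = lam, i
            if worst_i is None:
                return x
            del fixed[worst_i]
            continue
        # ratio test against bounds of moving variables
        alpha, blocker = 1.0, None
        for i in range(len(x)):
            if i in fixed or d[i] == 0.0:
                continue
            if d[i] < 0:
                a = (0.0 - x[i]) / d[i]
                bound = 0.0
            else:
                a = (1.0 - x[i]) / d[i]
                bound = 1.0
            if a < alpha - 1e-15:
                alpha, blocker = a, (i, bound)
        x = x + max(alpha, 0.0) * d
        if blocker is not None:
            i, bound = blocker
            x[i] = bound
            fixed[i] = bound
    raise SolverError("active-set QP failed to converge")


DEFAULT_RIDGE = 1e-12


def solve_transition_qp(window: QPWindow, ridge: float = DEFAULT_RIDGE,
                        prior: TransitionMatrix | None = None) -> TransitionMatrix:
    """Solve one window's constrained least-squares problem.

    Minimizes ``1/2 p'(X'X + lam I)p - (X'y + lam * prior)'p`` subject to the
    four row-sum equalities and [0, 1] bounds, where
    ``lam = ridge * trace(X'X)``.  The ridge keeps the Hessian positive
    definite (the window has 8 equations for 10 unknowns) and pins rows of
    unoccupied source states to the persistence ``prior`` (identity by
    default); where the data carry information the ridge is a vanishing
    perturbation.

    Solved with an exact primal active-set method; a trust-region
    constrained minimizer is kept as a fallback.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    X, y = window.design, window.target
    prior_free = _default_prior() if prior is None else prior.to_free()
    Q = X.T @ X
    lam = max(ridge * np.trace(Q), 1e-13)  # strict convexity floor
    Q = Q + lam * np.eye(window.n_params)
    c = X.T @ y + lam * prior_free
    # augmented least-squares form of the same ridged objective
    Xa = np.vstack([X, np.sqrt(lam) * np.eye(window.n_params)])
    ya = np.concatenate([y, np.sqrt(lam) * prior_free])

    try:
        p = _active_set_qp(Xa, ya, ROW_SUM_A, np.ones(N_STATES), prior_free)
    except SolverError:
        res = minimize(
            lambda v: 0.5 * v @ Q @ v - c @ v,
            x0=prior_free,
            jac=lambda v: Q @ v - c,
            hess=lambda v: Q,
            method="trust-constr",
            constraints=[LinearConstraint(ROW_SUM_A, 1.0, 1.0)],
            bounds=Bounds(0.0, 1.0),
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000},
        )
        if not res.success and res.status not in (1, 2):
            raise SolverError(f"QP solver failed: {res.message}")
        p = res.x
    if np.any(p < -1e-8) or np.any(p > 1 + 1e-8):
        raise SolverError("QP solution violates bounds beyond tolerance")
    return TransitionMatrix.from_free(np.clip(p, 0.0, 1.0), raw=p.copy(),
                                      sse=window.objective(p))


@dataclass
class TransitionChain:
    """Ordered weekly transition matrices with one-step-ahead fitted values.

    ``matrices[t-1]`` is the matrix estimated for week t (t = 1..T-1 for T
    polls); ``fitted[k]`` predicts poll k+1 from poll k (poll 0 being the
    pre-period baseline).
    """

    matrices: list[TransitionMatrix]
    dates: list[dt.date] | None = None
    fitted: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, t: int) -> TransitionMatrix:
        return self.matrices[t]

    def propagate(self, y0) -> np.ndarray:
        """Chained forward propagation of a start distribution through the
        chain; returns (len+1, 4) including the start."""
        y = np.asarray(y0, dtype=float)
        out = [y]
        for m in self.matrices:
            y = y @ m.values
            out.append(y)
        return np.vstack(out)

    def to_json(self, path) -> None:
        payload = {
            "dates": [d.isoformat() for d in self.dates] if self.dates else None,
            "matrices": [m.values.tolist() for m in self.matrices],
            "sse": [m.sse for m in self.matrices],
            "fitted": self.fitted.tolist() if self.fitted is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TransitionChain":
        with open(path) as fh:
            payload = json.load(fh)
        mats = [TransitionMatrix(np.asarray(m), sse=s)
                for m, s in zip(payload["matrices"], payload["sse"])]
        dates = ([dt.date.fromisoformat(d) for d in payload["dates"]]
                 if payload.get("dates") else None)
        fitted = (np.asarray(payload["fitted"])
                  if payload.get("fitted") is not None else None)
        return cls(matrices=mats, dates=dates, fitted=fitted)


def estimate_transition_chain(polls: PollSeries, ridge: float = DEFAULT_RIDGE,
                              prior: TransitionMatrix | None = None) -> TransitionChain:
    """Estimate the weekly chain from a poll series.

    For T observed polls, matrices are estimated at t = 1..T-1, each from
    the window (y_{t-1}, y_t, y_{t+1}) with y_0 the pre-period baseline.
    Fitted values are one-step-ahead: poll k+1 predicted from poll k through
    the matrix whose window covers that transition.
    """
    T = len(polls)
    if T < 3:
        raise ValueError("need at least 3 polls to estimate a chain")
    y = np.vstack([polls.baseline, polls.proportions])  # rows 0..T
    matrices = []
    for t in range(1, T):
        window = build_qp_window(y[t - 1], y[t], y[t + 1])
        matrices.append(solve_transition_qp(window, ridge=ridge, prior=prior))
    # fitted[k] predicts poll k+1 from poll k: transition k -> k+1 is the
    # first equation of window k+1 for k=0, else the second equation of
    # window k.
    fitted = np.vstack([y[k] @ matrices[max(k - 1, 0)].values
                        for k in range(T)])
    fitted /= fitted.sum(axis=1, keepdims=True)
    return TransitionChain(matrices=matrices, dates=list(polls.dates),
                           fitted=fitted)


def build_pooled_window(polls: PollSeries) -> QPWindow:
    """Stack every observed transition into one design, for fitting a single
    time-constant matrix.

    With T polls this yields 4(T) equations (baseline -> poll 1 through
    poll T-1 -> poll T), which is strongly overdetermined and, unlike a
    single two-step window, conditions the 10 free parameters well whenever
    the occupancies move during the series.
    """
    y = np.vstack([polls.baseline, polls.proportions])
    n_trans = y.shape[0] - 1
    design = np.zeros((N_STATES * n_trans, len(FREE_ENTRIES)))
    target = np.zeros(N_STATES * n_trans)
    for t in range(n_trans):
        for j in range(N_STATES):
            row = N_STATES * t + j
            for i in SOURCES_INTO[j]:
                design[row, _PARAM_INDEX[(i, j)]] = y[t, i]
            target[row] = y[t + 1, j]
    win = QPWindow(design=design, target=target)
    win._sources = y[:-1]
    return win


def estimate_constant_transition(polls: PollSeries,
                                 ridge: float = DEFAULT_RIDGE,
                                 prior: TransitionMatrix | None = None) -> TransitionMatrix:
    """Fit one banded matrix to the whole series (constant-dynamics model).

    Used for recovery diagnostics and as a parsimonious alternative to the
    weekly chain when the series is short.
    """
    return solve_transition_qp(build_pooled_window(polls), ridge=ridge,
                               prior=prior)
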