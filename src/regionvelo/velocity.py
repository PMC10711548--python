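"""Region-velocity kinetic model.

The model tracks, per gene, the exonic count e(t) and intronic count i(t)
of a cell's transcripts through the RNA lifecycle:

    di/dt = theta * alpha(t) - beta * i(t)
    de/dt = (1 - theta) * alpha(t) - gamma * e(t)

where ``alpha`` is the transcription rate, ``beta`` the splicing rate
(fixed to 1, which sets the time unit), ``gamma`` the degradation rate and
``theta`` the intronic fraction of nascent transcription.  Transcription is
on (``alpha > 0``) during induction and switches off at ``t_switch``.

At steady state ``theta*alpha = beta*i`` and ``(1-theta)*alpha = gamma*e``,
hence the steady-state relation

    gamma = (i / e) * (1 - theta) / theta        (beta = 1)

used to estimate ``gamma`` from the extreme-quantile slope of the
intron-vs-exon phase portrait.  The per-cell velocity of the exonic signal
follows by substituting the intron quasi-steady state ``alpha = i/theta``:

    velocity_e = ((1 - theta)/theta) * i - gamma * e

The classic spliced/unspliced RNA-velocity model (du/dt = alpha - beta*u,
ds/dt = beta*u - gamma*s) is provided as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "TrajectoryParams",
    "Trajectory",
    "VelocityConfig",
    "simulate_trajectory",
    "simulate_spliced_trajectory",
    "pool_knn",
    "estimate_theta",
    "fit_steady_state",
    "fit_kinetics",
    "filter_genes",
    "region_velocity",
    "rna_velocity_baseline",
    "fit_dynamical_em",
    "dynamical_velocity",
    "EMResult",
]

EPS = 1e-12
THETA_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# parameters and configuration
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryParams:
    """Kinetic rates of a single gene.

    alpha : transcription rate during induction (molecules / unit time)
    beta : splicing rate (per unit time); fixed to 1 by convention, which
        anchors the time unit of every other rate
    gamma : degradation rate of the exonic (mature) signal (per unit time)
    theta : intronic fraction of nascent transcription, in (0, 1)
    t_switch : time at which transcription switches from induction
        (alpha > 0) to repression (alpha = 0)
    """

    alpha: float
    gamma: float
    theta: float
    t_switch: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must be in (0,1), got {self.theta}")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be > 0 (closed form degenerates)")
        if self.t_switch <= 0:
            raise ValueError("t_switch must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class Trajectory:
    """Deterministic (e, i) trajectory sampled on a time grid."""

    t: np.ndarray
    e: np.ndarray
    i: np.ndarray
    phase: np.ndarray  # "induction" | "repression" per point


@dataclass
class VelocityConfig:
    """Estimation defaults of the steady-state velocity fit."""

    fit_quantile: float = 0.05
    min_corr: float = 0.2
    min_slope: float = 0.2
    k_cells: int = 10
    delta_t: float = 1.0
    theta_mode: str = "quantile_ratio"  # or "induction_slope", "population_ratio"

    def __post_init__(self) -> None:
        if not (0.0 < self.fit_quantile < 0.5):
            raise ValueError("fit_quantile must be in (0, 0.5)")
        if self.k_cells < 1:
            raise ValueError("k_cells must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# closed-form trajectories
# ---------------------------------------------------------------------------

def _induction(t, params: TrajectoryParams, e0=0.0, i0=0.0):
    a, b, g, th = params.alpha, params.beta, params.gamma, params.theta
    i = i0 * np.exp(-b * t) + (th * a / b) * (1.0 - np.exp(-b * t))
    e = e0 * np.exp(-g * t) + ((1.0 - th) * a / g) * (1.0 - np.exp(-g * t))
    return e, i


def simulate_trajectory(params: TrajectoryParams, t=None, n_points: int = 200,
                        e0: float = 0.0, i0: float = 0.0) -> Trajectory:
    """Closed-form (e(t), i(t)) over [0, 4*t_switch].

    Induction (t <= ts, alpha = alpha0) followed by pure decay
    (t > ts, alpha = 0) from the phase-boundary values; the trajectory is
    continuous at ts.
    """
    ts = params.t_switch
    if t is None:
        t = np.linspace(0.0, 4.0 * ts, n_points)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    e = np.empty_like(t)
    i = np.empty_like(t)
    ind = t <= ts
    e[ind], i[ind] = _induction(t[ind], params, e0, i0)
    e_s, i_s = _induction(np.array([ts]), params, e0, i0)
    tau = t[~ind] - ts
    i[~ind] = i_s[0] * np.exp(-params.beta * tau)
    e[~ind] = e_s[0] * np.exp(-params.gamma * tau)
    phase = np.where(ind, "induction", "repression")
    return Trajectory(t=t, e=e, i=i, phase=phase)


def simulate_spliced_trajectory(params: TrajectoryParams, t=None,
                                n_points: int = 200) -> Trajectory:
    """Closed-form (s(t), u(t)) of the classic spliced/unspliced model.

    du/dt = alpha - beta*u ; ds/dt = beta*u - gamma*s, zero initial state,
    with the same induction/repression switch at ``t_switch``.  Returned as
    a :class:`Trajectory` with ``e`` holding s and ``i`` holding u so the
    two model families share plotting / noise machinery.
    """
    a, b, g, ts = params.alpha, params.beta, params.gamma, params.t_switch
    if t is None:
        t = np.linspace(0.0, 4.0 * ts, n_points)
    t = np.asarray(t, dtype=float)

    def _u_ind(tt):
        return (a / b) * (1.0 - np.exp(-b * tt))

    def _s_ind(tt):
        if abs(g - b) < 1e-9:
            # degenerate limit beta == gamma
            return (a / g) * (1.0 - np.exp(-g * tt)) - a * tt * np.exp(-g * tt)
        return (a / g) * (1.0 - np.exp(-g * tt)) + (a / (g - b)) * (
            np.exp(-g * tt) - np.exp(-b * tt))

    u = np.empty_like(t)
    s = np.empty_like(t)
    ind = t <= ts
    u[ind] = _u_ind(t[ind])
    s[ind] = _s_ind(t[ind])
    u_s, s_s = _u_ind(ts), _s_ind(ts)
    tau = t[~ind] - ts
    u[~ind] = u_s * np.exp(-b * tau)
    if abs(g - b) < 1e-9:
        s[~ind] = s_s * np.exp(-g * tau) + b * u_s * tau * np.exp(-g * tau)
    else:
        s[~ind] = s_s * np.exp(-g * tau) + (b * u_s / (g - b)) * (
            np.exp(-b * tau) - np.exp(-g * tau))
    phase = np.where(ind, "induction", "repression")
    return Trajectory(t=t, e=s, i=u, phase=phase)


# ---------------------------------------------------------------------------
# kNN pooling
# ---------------------------------------------------------------------------

def pool_knn(matrices, coords, k: int = 10, balanced: bool = True,
             max_used: int | None = None):
    """Sum each cell's counts with its k-1 nearest neighbours.

    ``coords`` is a cells x d low-dimensional representation (PCA or an
    embedding).  The balanced variant caps how often any cell may serve as
    a neighbour (default cap 4*k), which guards dense regions against a few
    hub cells dominating the pool.

    Accepts a single matrix or a sequence of matrices (pooled with the same
    neighbour sets); returns the same shape(s) as float arrays.
    """
    single = isinstance(matrices, np.ndarray)
    mats = [matrices] if single else list(matrices)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    for m in mats:
        if m.shape[0] != n:
            raise ValueError("matrix rows must match coords rows")
    if k == 1:
        out = [np.asarray(m, dtype=float).copy() for m in mats]
        return out[0] if single else out

    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    dist, idx = nn.kneighbors(coords)  # includes self at distance 0
    if balanced:
        cap = max_used if max_used is not None else 4 * k
        usage = np.zeros(n, dtype=int)
        keep = np.zeros_like(idx, dtype=bool)
        # greedy pass in order of neighbour distance keeps close pairs
        order = np.argsort(dist[:, 1:], axis=None)
        rows, cols = np.unravel_index(order, dist[:, 1:].shape)
        for r, c in zip(rows, cols):
            j = idx[r, c + 1]
            if usage[j] < cap:
                usage[j] += 1
                keep[r, c + 1] = True
        keep[:, 0] = True
    else:
        keep = np.ones_like(idx, dtype=bool)

    pooled = []
    for m in mats:
        m = np.asarray(m, dtype=float)
        out = np.zeros_like(m)
        for c in range(n):
            out[c] = m[idx[c][keep[c]]].sum(axis=0)
        pooled.append(out)
    return pooled[0] if single else pooled


# ---------------------------------------------------------------------------
# steady-state estimation
# ---------------------------------------------------------------------------

def _clamp_theta(theta: float) -> float:
    return float(np.clip(theta, THETA_CLAMP, 1.0 - THETA_CLAMP))


def estimate_theta(exon_col, intron_col, fit_quantile: float = 0.05,
                   mode: str = "quantile_ratio") -> float:
    """Estimate the intronic fraction theta of one gene.

    ``quantile_ratio`` (default): count ratio sum(i)/(sum(i)+sum(e)) over
    cells above the (1-fit_quantile) quantile of total expression e+i,
    a proxy for cells in active transcription.  On steady-state data this
    ratio equals theta*gamma / (theta*gamma + (1-theta)*beta), i.e. it is
    exact when gamma == beta and biased otherwise.

    ``induction_slope``: zero-intercept slope of i on e restricted to
    low-expression cells sitting above the phase-portrait diagonal -- the
    early induction limb, where di/de -> theta/(1-theta) as t -> 0.  This
    estimator does not require gamma == beta but needs off-steady-state
    cells.

    ``population_ratio``: the count ratio over all cells.
    """
    e = np.asarray(exon_col, dtype=float).ravel()
    i = np.asarray(intron_col, dtype=float).ravel()
    tot = e + i
    if tot.sum() <= 0:
        raise ValueError("all-zero gene: theta undefined")
    if mode == "population_ratio":
        return _clamp_theta(i.sum() / tot.sum())
    if mode == "quantile_ratio":
        thr = np.quantile(tot, 1.0 - fit_quantile)
        sel = tot >= thr
        return _clamp_theta(i[sel].sum() / max(tot[sel].sum(), EPS))
    if mode == "induction_slope":
        # cells above the gross diagonal with low expression: early limb
        scale_i = max(i.max(), EPS)
        scale_e = max(e.max(), EPS)
        above = i / scale_i >= e / scale_e
        low = tot <= np.quantile(tot, 0.5)
        sel = above & low & (tot > 0)
        if sel.sum() < 3:
            return estimate_theta(e, i, fit_quantile, "quantile_ratio")
        m = float(np.dot(e[sel], i[sel]) / max(np.dot(e[sel], e[sel]), EPS))
        return _clamp_theta(m / (1.0 + m))
    raise ValueError(f"unknown theta mode {mode!r}")


def fit_steady_state(e, i, theta_hat: float, fit_quantile: float = 0.05):
    """Extreme-quantile zero-intercept fit of intron on exon.

    Cells in the top and bottom ``fit_quantile`` of exon expression are
    selected; the slope is the zero-intercept least-squares slope of i on
    e over those cells, gamma_hat = slope * (1-theta)/theta (beta = 1), and
    corr_r is the Pearson correlation of i and e over all cells.
    """
    e = np.asarray(e, dtype=float).ravel()
    i = np.asarray(i, dtype=float).ravel()
    n = e.size
    if n < 4:
        raise ValueError("need at least 4 cells")
    lo = np.quantile(e, fit_quantile)
    hi = np.quantile(e, 1.0 - fit_quantile)
    sel = (e <= lo) | (e >= hi)
    denom = float(np.dot(e[sel], e[sel]))
    if denom <= EPS:
        raise ValueError("degenerate exon column (no variation in tails)")
    slope = float(np.dot(e[sel], i[sel]) / denom)
    if np.std(e) <= EPS or np.std(i) <= EPS:
        corr = 0.0
    else:
        corr = float(np.corrcoef(e, i)[0, 1])
    theta_hat = _clamp_theta(theta_hat)
    gamma_hat = slope * (1.0 - theta_hat) / theta_hat
    return slope, gamma_hat, corr


def fit_kinetics(E, I, config: VelocityConfig | None = None) -> pd.DataFrame:
    """Per-gene steady-state kinetics table for cells x genes matrices.

    Returns a DataFrame with columns theta_hat, slope_k, gamma_hat, corr_r,
    passes_filter (genes with no signal or a degenerate fit are marked
    failed rather than raising).
    """
    config = config or VelocityConfig()
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    if E.shape != I.shape:
        raise ValueError("exon and intron matrices must share shape")
    rows = []
    for g in range(E.shape[1]):
        e, i = E[:, g], I[:, g]
        try:
            th = estimate_theta(e, i, config.fit_quantile, config.theta_mode)
            slope, gamma, corr = fit_steady_state(e, i, th, config.fit_quantile)
            ok = (corr >= config.min_corr) and (slope >= config.min_slope)
            rows.append((th, slope, gamma, corr, ok))
        except ValueError:
            rows.append((np.nan, np.nan, np.nan, np.nan, False))
    kin = pd.DataFrame(rows, columns=["theta_hat", "slope_k", "gamma_hat",
                                      "corr_r", "passes_filter"])
    return kin


def filter_genes(kinetics: pd.DataFrame, min_corr: float = 0.2,
                 min_slope: float = 0.2) -> np.ndarray:
    """Indices of genes passing the correlation and slope thresholds."""
    ok = ((kinetics["corr_r"] >= min_corr)
          & (kinetics["slope_k"] >= min_slope)).to_numpy()
    ok &= np.isfinite(kinetics["gamma_hat"].to_numpy())
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError(
            "no gene passes the velocity filters "
            f"(min_corr={min_corr}, min_slope={min_slope}); "
            f"best corr={np.nanmax(kinetics['corr_r'].to_numpy(), initial=np.nan)}")
    return idx


def region_velocity(E, I, kinetics: pd.DataFrame, delta_t: float = 1.0):
    """Per-cell, per-gene exonic velocity and linearly extrapolated state.

    velocity_e = ((1-theta)/theta) * i - gamma_hat * e ; the extrapolated
    exon state is clipped at zero.  Genes failing the filter get zero
    velocity (and an unchanged extrapolated state).
    """
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    th = kinetics["theta_hat"].to_numpy()
    gam = kinetics["gamma_hat"].to_numpy()
    ok = kinetics["passes_filter"].to_numpy().astype(bool)
    V = np.zeros_like(E)
    coef = np.where(ok, (1.0 - th) / np.clip(th, THETA_CLAMP, None), 0.0)
    gcol = np.where(ok, gam, 0.0)
    V = I * coef[None, :] - E * gcol[None, :]
    V[:, ~ok] = 0.0
    E_next = np.clip(E + V * delta_t, 0.0, None)
    return V, E_next


def rna_velocity_baseline(S, U, config: VelocityConfig | None = None,
                          delta_t: float | None = None):
    """Classic spliced/unspliced steady-state velocity (beta = 1).

    gamma_hat per gene comes from the same extreme-quantile zero-intercept
    fit of u on s; velocity_s = u - gamma_hat * s; the same correlation and
    slope filters apply.  Returns (kinetics, velocity, extrapolated_s).
    """
    config = config or VelocityConfig()
    dt = config.delta_t if delta_t is None else delta_t
    S = np.asarray(S, dtype=float)
    U = np.asarray(U, dtype=float)
    rows = []
    for g in range(S.shape[1]):
        s, u = S[:, g], U[:, g]
        try:
            if (s + u).sum() <= 0:
                raise ValueError("all-zero gene")
            slope, _, corr = fit_steady_state(s, u, 0.5, config.fit_quantile)
            ok = (corr >= config.min_corr) and (slope >= config.min_slope)
            rows.append((slope, corr, ok))
        except ValueError:
            rows.append((np.nan, np.nan, False))
    kin = pd.DataFrame(rows, columns=["gamma_hat", "corr_r", "passes_filter"])
    kin["slope_k"] = kin["gamma_hat"]
    ok = kin["passes_filter"].to_numpy().astype(bool)
    gam = np.where(ok, kin["gamma_hat"].to_numpy(), 0.0)
    V = U - S * gam[None, :]
    V[:, ~ok] = 0.0
    S_next = np.clip(S + V * dt, 0.0, None)
    return kin, V, S_next


# ---------------------------------------------------------------------------
# dynamical EM fit
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    params: TrajectoryParams
    latent_time: np.ndarray
    phase: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)


def _traj_ACg(t, A, C, g, ts):
    """Trajectory in the (A, C, gamma) parametrisation.

    A = theta*alpha (intron steady level, beta=1); C = (1-theta)*alpha/gamma
    (exon steady level).  Returns (e, i) at times t.
    """
    t = np.asarray(t, dtype=float)
    i = np.where(t <= ts,
                 A * (1.0 - np.exp(-t)),
                 A * (1.0 - np.exp(-ts)) * np.exp(-(t - ts)))
    e = np.where(t <= ts,
                 C * (1.0 - np.exp(-g * t)),
                 C * (1.0 - np.exp(-g * ts)) * np.exp(-g * (t - ts)))
    return e, i


def _assign_times(e, i, A, C, g, ts, n_grid, se, si):
    t_grid = np.linspace(0.0, 4.0 * ts, n_grid)
    eg, ig = _traj_ACg(t_grid, A, C, g, ts)
    d = ((e[:, None] - eg[None, :]) / se) ** 2 \
        + ((i[:, None] - ig[None, :]) / si) ** 2
    j = np.argmin(d, axis=1)
    return t_grid[j], d[np.arange(e.size), j]


def _marginal_loglik(e, i, A, C, g, ts, n_grid, sig_e, sig_i):
    """Log-likelihood with the latent time integrated out (uniform prior
    on [0, 4*ts]).  Unlike the nearest-point distance, this sees the cell
    density along the trajectory, which is what identifies ts once
    induction has saturated."""
    from scipy.special import logsumexp

    t_grid = np.linspace(0.0, 4.0 * ts, n_grid)
    eg, ig = _traj_ACg(t_grid, A, C, g, ts)
    d = ((e[:, None] - eg[None, :]) / sig_e) ** 2 \
        + ((i[:, None] - ig[None, :]) / sig_i) ** 2
    ll = logsumexp(-0.5 * d, axis=1) - np.log(n_grid) \
        - np.log(2 * np.pi * sig_e * sig_i)
    return float(ll.sum())


def fit_dynamical_em(e, i, max_iter: int = 20, tol: float = 1e-5,
                     n_grid: int = 200, n_grid_ts: int = 600,
                     init: TrajectoryParams | None = None,
                     fit_quantile: float = 0.05,
                     max_cells: int = 600) -> EMResult:
    """EM fit of the full kinetic trajectory to one gene's (e, i) cloud.

    The latent time of each cell is integrated out against a uniform prior
    on [0, 4*ts] (the observation window): the E-step computes soft
    responsibilities over a dense time grid, and the M-step refits the
    steady levels A = theta*alpha and C = (1-theta)*alpha/gamma, the rate
    gamma and the Gaussian noise scales from the expected sufficient
    statistics.  The switch time is the outer profile-likelihood
    parameter: a coarse log-grid scan followed by local refinement, each
    candidate fitted by the inner EM ("step 4" of the procedure, solving
    the transcription switch time by iteration).  The marginal Gaussian
    log-likelihood is reported and ranks driver genes (genes whose clouds
    trace a clean spindle score high).

    beta is fixed at 1, which makes (alpha, gamma, theta, ts) identifiable
    from the two limbs of the spindle plus the cell density along them:
    the intron asymptote gives A, the exon asymptote gives C, the limb
    curvature gives gamma, and alpha = A + gamma*C, theta = A / alpha.
    """
    e = np.asarray(e, dtype=float).ravel()
    i = np.asarray(i, dtype=float).ravel()
    e_full, i_full = e, i
    if e.size < 20:
        raise ValueError("need at least 20 cells for the dynamical fit")
    if e.size > max_cells:
        # deterministic subsample: fit cost is linear in cells and the
        # estimator is sampling-noise limited well below this size
        sub = np.random.default_rng(0).choice(e.size, max_cells,
                                              replace=False)
        e, i = e[sub], i[sub]
    n = e.size
    se = max(float(np.std(e)), EPS)
    si = max(float(np.std(i)), EPS)

    # noise floor at 2% of the data spread: keeps the discrete grid sum a
    # faithful quadrature of the continuum time integral (grid spacing
    # along the curve stays below sigma), without which the likelihood
    # rewards shrinking the time span
    floor_e, floor_i = 2e-2 * se, 2e-2 * si
    sum_e2, sum_i2 = float(np.dot(e, e)), float(np.dot(i, i))
    A0 = float(np.quantile(i, 0.975))
    C0 = float(np.quantile(e, 0.975))
    if init is not None:
        A0 = init.theta * init.alpha
        C0 = (1.0 - init.theta) * init.alpha / init.gamma
        g0 = init.gamma
    else:
        try:
            th0 = estimate_theta(e, i, fit_quantile, "induction_slope")
            _, g0, _ = fit_steady_state(e, i, th0, fit_quantile)
        except ValueError:
            g0 = 1.0
    g0 = float(np.clip(g0, 0.05, 20.0))

    def _fit_at_ts(ts, iters, warm=None):
        """Inner EM over (A, C, gamma, sigmas) at fixed switch time.

        Runs from the cold (quantile) initialisation and, when given, also
        from a warm start at another candidate's converged parameters;
        the better fit wins.  This guards the profile against inner-EM
        local optima at individual switch-time candidates.
        """
        if warm is not None:
            cold = _fit_at_ts(ts, iters)
            w = _fit_at_ts_single(ts, iters, warm)
            return w if w[0] > cold[0] else cold
        return _fit_at_ts_single(ts, iters, None)

    def _fit_at_ts_single(ts, iters, warm):
        if warm is None:
            A, C, g = A0, C0, g0
            sig_e, sig_i = max(0.05 * se, EPS), max(0.05 * si, EPS)
        else:
            _, A, C, g, _, sig_e, sig_i = warm
            sig_e = max(sig_e, floor_e)
            sig_i = max(sig_i, floor_i)
        t_grid = np.linspace(0.0, 4.0 * ts, n_grid)
        ll_prev = -np.inf
        for it in range(iters):
            eg, ig = _traj_ACg(t_grid, A, C, g, ts)
            logR = -0.5 * (((e[:, None] - eg[None, :]) / sig_e) ** 2
                           + ((i[:, None] - ig[None, :]) / sig_i) ** 2)
            logR -= logR.max(axis=1, keepdims=True)
            R = np.exp(logR)
            R /= R.sum(axis=1, keepdims=True)
            w = R.sum(axis=0)
            Re, Ri = R.T @ e, R.T @ i
            wm = np.maximum(w, EPS)
            ebar, ibar = Re / wm, Ri / wm
            sw = np.sqrt(w)

            def resid(p):
                eg_, ig_ = _traj_ACg(t_grid, p[0], p[1], p[2], ts)
                return np.concatenate([sw * (ebar - eg_) / sig_e,
                                       sw * (ibar - ig_) / sig_i])

            sol = least_squares(resid, x0=[A, C, g],
                                bounds=([EPS, EPS, 1e-3],
                                        [np.inf, np.inf, 50.0]),
                                max_nfev=40)
            A, C, g = sol.x

            eg, ig = _traj_ACg(t_grid, A, C, g, ts)
            sse_e = sum_e2 - 2.0 * float(eg @ Re) + float(w @ (eg * eg))
            sse_i = sum_i2 - 2.0 * float(ig @ Ri) + float(w @ (ig * ig))
            sig_e = max(float(np.sqrt(max(sse_e, 0.0) / n)), floor_e)
            sig_i = max(float(np.sqrt(max(sse_i, 0.0) / n)), floor_i)
            # cheap surrogate for convergence between sweeps
            ll_it = -n * (np.log(sig_e) + np.log(sig_i))
            if it > 0 and abs(ll_it - ll_prev) < tol * (1.0 + abs(ll_prev)):
                break
            ll_prev = ll_it
        ll = _marginal_loglik(e, i, A, C, g, ts, n_grid_ts, sig_e, sig_i)
        return ll, A, C, g, float(ts), sig_e, sig_i

    # profile likelihood over the switch time: coarse log-grid scan ...
    if init is not None:
        coarse = [init.t_switch * f for f in (0.6, 1.0, 1.6)]
    else:
        coarse = list(np.exp(np.linspace(np.log(0.5), np.log(10.0), 9)))
    fits = [_fit_at_ts(ts, max(8, max_iter // 2)) for ts in coarse]
    k0 = int(np.argmax([f[0] for f in fits]))
    best = fits[k0]
    # ... then two local refinement sweeps around the running best, warm-
    # started from it
    local = [best[4] * f for f in (0.6, 0.78, 1.0, 1.28, 1.65)]
    fits = [_fit_at_ts(ts, max_iter, warm=best) for ts in local]
    kb = int(np.argmax([f[0] for f in fits]))
    best = fits[kb]
    local2 = [best[4] * f for f in (0.87, 1.0, 1.15)]
    fits2 = [best if f == 1.0 else _fit_at_ts(best[4] * f, max_iter,
                                              warm=best)
             for f in (0.87, 1.0, 1.15)]
    local, fits = local2, fits2
    lls = np.array([f[0] for f in fits])
    kb = int(np.argmax(lls))
    # parabolic interpolation on (log ts, loglik) around the winner
    if 0 < kb < len(local) - 1:
        x = np.log([local[kb - 1], local[kb], local[kb + 1]])
        y = lls[kb - 1: kb + 2]
        denom = (y[0] - 2 * y[1] + y[2])
        if denom < 0:
            x_star = x[1] - 0.5 * (x[2] - x[0]) * (y[2] - y[0]) / (2 * denom)
            cand = _fit_at_ts(float(np.exp(x_star)), max_iter,
                              warm=fits[kb])
            if cand[0] >= lls[kb]:
                fits.append(cand)
                kb = len(fits) - 1
                lls = np.append(lls, cand[0])
    loglik, A, C, g, ts, sig_e, sig_i = fits[kb]
    history = sorted(lls.tolist())

    alpha = A + g * C
    theta = _clamp_theta(A / max(alpha, EPS))
    params = TrajectoryParams(alpha=float(alpha), gamma=float(g),
                              theta=theta, t_switch=float(ts))
    t_c, _ = _assign_times(e_full, i_full, A, C, g, ts, n_grid, se, si)
    phase = np.where(t_c <= ts, "induction", "repression")
    return EMResult(params=params, latent_time=t_c, phase=phase,
                    log_likelihood=float(loglik), n_iter=len(fits),
                    converged=True, history=history)


def dynamical_velocity(E, I, kinetics: pd.DataFrame | None = None,
                       config: VelocityConfig | None = None,
                       delta_t: float = 1.0, max_cells: int = 400):
    """Per-cell velocity from the dynamical (EM) model with a consensus
    latent time.

    Each passing gene is fitted by :func:`fit_dynamical_em`; the per-gene
    latent-time fractions are combined into one consensus pseudotime per
    cell (the median across genes, which is what makes early-induction
    cells -- where a single gene's (e, i) is ambiguous between the start
    and the end of the loop -- resolvable).  The velocity is the model
    de/dt evaluated on each gene's fitted trajectory at the consensus
    time: (1-theta)*alpha during induction, -gamma*e(t) after the switch.
    Unlike the steady-state estimate, this does not assume the intron
    pool has equilibrated, so it stays unbiased in the induction
    transient.

    Returns (velocity, extrapolated, kinetics, consensus_fraction, fits).
    """
    config = config or VelocityConfig()
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    if kinetics is None:
        kinetics = fit_kinetics(E, I, config)
    ok = np.flatnonzero(kinetics["passes_filter"].to_numpy())
    if ok.size == 0:
        raise ValueError("no gene passes the velocity filters")
    fits = {}
    fracs = np.zeros((E.shape[0], ok.size))
    for j, g in enumerate(ok):
        res = fit_dynamical_em(E[:, g], I[:, g], max_cells=max_cells,
                               fit_quantile=config.fit_quantile)
        fits[int(g)] = res
        fracs[:, j] = res.latent_time / (4.0 * res.params.t_switch)
    consensus = np.median(fracs, axis=1)
    V = np.zeros_like(E)
    for g, res in fits.items():
        p = res.params
        t_c = consensus * 4.0 * p.t_switch
        tr = simulate_trajectory(p, t=t_c)
        alpha_t = np.where(t_c <= p.t_switch, p.alpha, 0.0)
        V[:, g] = (1.0 - p.theta) * alpha_t - p.gamma * tr.e
    E_next = np.clip(E + V * delta_t, 0.0, None)
    return V, E_next, kinetics, consensus, fits
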