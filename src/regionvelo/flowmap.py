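"""Velocity projection onto a 2-D embedding and evaluation metrics.

Per-cell velocities are turned into transition probabilities toward
embedding neighbours via the correlation kernel of the original velocity
framework: the score of neighbour j for cell c is the Pearson correlation
between the predicted expression change of c and the expression offset of
j from c, passed through an exponential kernel.  Arrows are expected unit
displacements minus the neighbourhood's null expectation, and are
averaged on an n x n grid (default 20) for display.

Evaluation follows the angular-separation protocol: observed per-cell
directions come from a local principal-axis regression over embedding
neighbours, signed by an ordering signal (latent time or pseudotime); a
prediction succeeds when the angle between predicted and observed
directions is strictly below 90 degrees.  Gene-level tendency matching
compares the sign of each gene's predicted change against the sign of the
change toward ordering-forward neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EvalReport", "neighbor_graph", "transition_probabilities",
    "project_velocity", "grid_flow", "observed_directions",
    "angular_separation", "tendency_match",
]

EPS = 1e-12


@dataclass
class EvalReport:
    angles: np.ndarray
    success_fraction: float
    per_cluster: dict
    n_excluded: int


def neighbor_graph(embedding, n_neighbors: int = 50):
    """k nearest neighbours in embedding space, excluding self."""
    X = np.asarray(embedding, dtype=float)
    k = min(n_neighbors + 1, X.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    return idx[:, 1:]


def _row_correlations(delta, offsets):
    """Pearson correlation of one cell's velocity with each neighbour
    offset (rows of ``offsets``)."""
    d = delta - delta.mean()
    o = offsets - offsets.mean(axis=1, keepdims=True)
    num = o @ d
    den = np.sqrt((o * o).sum(axis=1) * (d * d).sum()) + EPS
    return num / den


def transition_probabilities(expression, extrapolated, neighbors,
                             kernel_sigma: float = 0.05) -> np.ndarray:
    """Per-cell transition probability rows over embedding neighbours.

    Rows sum to one; cells with zero predicted change (or isolated cells)
    get uniform rows.
    """
    E = np.asarray(expression, dtype=float)
    X = np.asarray(extrapolated, dtype=float)
    n, k = neighbors.shape
    P = np.empty((n, k))
    delta_all = X - E
    for c in range(n):
        nb = neighbors[c]
        delta = delta_all[c]
        if np.abs(delta).sum() <= EPS or k == 0:
            P[c] = 1.0 / max(k, 1)
            continue
        corr = _row_correlations(delta, E[nb] - E[c])
        z = corr / kernel_sigma
        w = np.exp(z - z.max())
        P[c] = w / w.sum()
    return P


def project_velocity(probabilities, embedding, neighbors) -> np.ndarray:
    """Per-cell 2-D arrows: expected unit displacement toward neighbours
    minus the null (uniform) expectation, so zero-information rows give
    zero arrows."""
    X = np.asarray(embedding, dtype=float)
    n, k = neighbors.shape
    arrows = np.zeros((n, 2))
    for c in range(n):
        disp = X[neighbors[c]] - X[c]
        norm = np.linalg.norm(disp, axis=1)
        ok = norm > EPS
        if not ok.any():
            continue
        unit = np.zeros_like(disp)
        unit[ok] = disp[ok] / norm[ok, None]
        p = probabilities[c]
        arrows[c] = p @ unit - unit.mean(axis=0)
    return arrows


def grid_flow(arrows, embedding, n_grid: int = 20,
              min_cells_per_box: int = 1) -> pd.DataFrame:
    """Average member-cell arrows on an n_grid x n_grid lattice."""
    X = np.asarray(embedding, dtype=float)
    A = np.asarray(arrows, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi - lo > EPS, hi - lo, 1.0)
    ij = np.minimum(((X - lo) / span * n_grid).astype(int), n_grid - 1)
    rows = []
    for gx in range(n_grid):
        for gy in range(n_grid):
            sel = (ij[:, 0] == gx) & (ij[:, 1] == gy)
            if sel.sum() < min_cells_per_box:
                continue
            cx, cy = lo + (np.array([gx, gy]) + 0.5) / n_grid * span
            dx, dy = A[sel].mean(axis=0)
            rows.append((cx, cy, dx, dy, int(sel.sum())))
    return pd.DataFrame(rows, columns=["x", "y", "dx", "dy", "n_cells"])


def observed_directions(embedding, ordering, n_neighbors: int = 30):
    """Local principal-axis direction per cell, signed by the ordering.

    For each cell the first principal axis of its embedding neighbourhood
    (total least squares -- the embedding has no privileged axis) gives
    the local line; its sign is oriented so the ordering signal increases
    along it.  Cells with a degenerate neighbourhood get NaN directions.
    """
    X = np.asarray(embedding, dtype=float)
    t = np.asarray(ordering, dtype=float)
    nbrs = neighbor_graph(X, n_neighbors=n_neighbors)
    out = np.full((X.shape[0], 2), np.nan)
    for c in range(X.shape[0]):
        pts = np.vstack([X[nbrs[c]], X[c]])
        tt = np.concatenate([t[nbrs[c]], [t[c]]])
        ctr = pts - pts.mean(axis=0)
        cov = ctr.T @ ctr
        if np.linalg.norm(cov) <= EPS:
            continue
        w, v = np.linalg.eigh(cov)
        axis = v[:, np.argmax(w)]
        proj = ctr @ axis
        if np.std(proj) <= EPS or np.std(tt) <= EPS:
            continue
        sign = np.sign(np.corrcoef(proj, tt)[0, 1])
        if sign == 0:
            continue
        out[c] = axis * sign
    return out


def angular_separation(predicted, observed, clusters=None) -> EvalReport:
    """Angles (degrees) between predicted arrows and observed directions.

    Success = strict angle < 90 degrees; cells with a zero-length
    predicted arrow or an undefined observed direction are excluded and
    counted.  ``clusters`` adds per-cluster success fractions (the overall
    fraction is reported under "All").
    """
    P = np.asarray(predicted, dtype=float)
    O = np.asarray(observed, dtype=float)
    pn = np.linalg.norm(P, axis=1)
    on = np.linalg.norm(O, axis=1)
    valid = (pn > EPS) & (on > EPS) & np.isfinite(on)
    angles = np.full(P.shape[0], np.nan)
    cosv = np.clip((P[valid] * O[valid]).sum(axis=1)
                   / (pn[valid] * on[valid]), -1.0, 1.0)
    angles[valid] = np.degrees(np.arccos(cosv))
    success = float(np.mean(angles[valid] < 90.0)) if valid.any() else 0.0
    per_cluster = {"All": success}
    if clusters is not None:
        cl = np.asarray(clusters)
        for name in pd.unique(cl):
            sel = valid & (cl == name)
            if sel.any():
                per_cluster[str(name)] = float(np.mean(angles[sel] < 90.0))
    return EvalReport(angles=angles, success_fraction=success,
                      per_cluster=per_cluster,
                      n_excluded=int((~valid).sum()))


def tendency_match(expression, extrapolated, ordering,
                   n_neighbors: int = 30) -> pd.Series:
    """Per-gene matched-hit percentage of predicted change direction.

    For each cell, the sign of (extrapolated - observed) expression is
    compared with the sign of (mean over ordering-forward neighbours -
    observed); the per-gene score is the fraction of cells where the signs
    agree, over cells where both changes are nonzero.  Genes with no
    usable cell are dropped.
    """
    E = np.asarray(expression, dtype=float)
    X = np.asarray(extrapolated, dtype=float)
    t = np.asarray(ordering, dtype=float)
    n = E.shape[0]
    order = np.argsort(t)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    fwd_mean = np.empty_like(E)
    for c in range(n):
        r = rank[c]
        fwd = order[r + 1: r + 1 + n_neighbors]
        fwd_mean[c] = E[fwd].mean(axis=0) if fwd.size else np.nan
    pred_sign = np.sign(X - E)
    obs_sign = np.sign(fwd_mean - E)
    usable = (pred_sign != 0) & (obs_sign != 0) & np.isfinite(obs_sign)
    scores = {}
    for g in range(E.shape[1]):
        u = usable[:, g]
        if not u.any():
            continue
        scores[g] = float(np.mean(pred_sign[u, g] == obs_sign[u, g]))
    return pd.Series(scores, name="matched_hit_fraction")
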