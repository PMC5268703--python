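"""Helix axes, inter-helix angles and intra-helix bending from Cα traces.

The helix axis is obtained in the classical cylinder-fit spirit: each
interior Cα contributes a local axis-center estimate via the bisector
construction (the bisector of the two bond vectors at a Cα points at the
helix axis, and the local twist fixes the radius), and the axis is the
principal line through these centers, oriented N→C.  For an ideal
α-helix the construction is exact.

Bending is measured from local axis points computed over sliding
windows of ``bendix_window`` consecutive Cα (step 1).  The bend angle at
an axis point is the angle between the two axis chords spanning
``window`` points before and after it; the per-frame maximum over axis
points summarizes the kinking of a helix.  Measuring the turn between
chords a full window apart (rather than between neighbouring chords)
keeps a localized kink from being smeared below detection by the
overlapping windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FitError, InsufficientDataError
from .io_core import (
    AnalysisConfig,
    HelixDefinition,
    Topology,
    TrajectoryEnsemble,
)
from .stats import bootstrap_se

_COLLINEAR_TOL = 1e-8


@dataclass
class HelixAxisFit:
    """Fitted axis of one helix: unit vector (N→C), centroid, residual."""

    helix: HelixDefinition | None
    axis: np.ndarray
    centroid: np.ndarray
    fit_rms: float


def _bisector_centers(ca: np.ndarray) -> np.ndarray:
    """Local helix-center estimate at each interior Cα.

    At Cα i the normalized bond vectors to i−1 and i+1 are summed; the
    resulting bisector points from the Cα at the axis.  The radius is
    recovered from the chord |p_{i+1} − p_{i−1}| and the local twist
    angle between consecutive bisectors, so no canonical helix
    parameters are assumed.
    """
    n = len(ca)
    if n < 4:
        raise InsufficientDataError("bisector construction needs >= 4 Cα")
    # unit bisectors at interior residues 1..n-2
    prev = ca[:-2] - ca[1:-1]
    nxt = ca[2:] - ca[1:-1]
    prev_n = np.linalg.norm(prev, axis=1, keepdims=True)
    nxt_n = np.linalg.norm(nxt, axis=1, keepdims=True)
    if np.any(prev_n < _COLLINEAR_TOL) or np.any(nxt_n < _COLLINEAR_TOL):
        raise FitError("coincident consecutive Cα positions")
    bis = prev / prev_n + nxt / nxt_n
    bis_n = np.linalg.norm(bis, axis=1, keepdims=True)
    if np.any(bis_n < 1e-6):
        raise FitError("collinear Cα trace: helix geometry is degenerate")
    bis = bis / bis_n

    acc = np.zeros((n - 2, 3))
    counts = np.zeros(n - 2)
    for k in range(n - 3):
        # adjacent interior residues k+1, k+2 with bisectors bis[k], bis[k+1]
        b1, b2 = bis[k], bis[k + 1]
        d = np.cross(b1, b2)
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            raise FitError("degenerate local helix geometry (parallel bisectors)")
        d = d / nd
        chord = ca[k + 2] - ca[k + 1]
        chord_perp = chord - np.dot(chord, d) * d
        # local twist between the bisectors in the plane normal to d
        b1p = b1 - np.dot(b1, d) * d
        b2p = b2 - np.dot(b2, d) * d
        n1, n2 = np.linalg.norm(b1p), np.linalg.norm(b2p)
        if n1 < 1e-9 or n2 < 1e-9:
            raise FitError("degenerate local helix geometry (axial bisector)")
        cos_t = np.clip(np.dot(b1p, b2p) / (n1 * n2), -1.0, 1.0)
        half = np.arccos(cos_t) / 2.0
        if np.sin(half) < 1e-6:
            raise FitError("vanishing local twist: cannot place helix centers")
        radius = np.linalg.norm(chord_perp) / (2.0 * np.sin(half))
        acc[k] += ca[k + 1] + radius * (b1p / n1)
        counts[k] += 1
        acc[k + 1] += ca[k + 2] + radius * (b2p / n2)
        counts[k + 1] += 1
    return acc / counts[:, None]


def _principal_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through points: (direction, centroid, rms)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(points) > 1 and s[0] < _COLLINEAR_TOL:
        raise FitError("axis points coincide; cannot orient an axis")
    direction = vt[0]
    perp = centered - np.outer(centered @ direction, direction)
    rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return direction, centroid, rms


def _refine_cylinder_axis(
    ca: np.ndarray, direction: np.ndarray, point: np.ndarray, max_iter: int = 20
) -> tuple[np.ndarray, np.ndarray, float]:
    """Levenberg–Marquardt refinement of the cylinder axis.

    Minimizes sum_i (|perp(x_i − p)| − r)² over axis point p, direction d
    and radius r, starting from the bisector-construction estimate.  The
    Jacobian is evaluated numerically; d is renormalized every step and
    the damping absorbs the gauge freedoms (|d| and p along d).
    """

    def residuals(params):
        p, d, r = params[:3], params[3:6], params[6]
        d = d / np.linalg.norm(d)
        rel = ca - p
        perp = rel - np.outer(rel @ d, d)
        return np.linalg.norm(perp, axis=1) - r

    rel = ca - point
    perp = rel - np.outer(rel @ direction, direction)
    params = np.concatenate(
        [point, direction, [np.mean(np.linalg.norm(perp, axis=1))]]
    )
    lam = 1e-3
    cost = float(np.sum(residuals(params) ** 2))
    for _ in range(max_iter):
        f0 = residuals(params)
        jac = np.empty((len(f0), 7))
        for j in range(7):
            step = np.zeros(7)
            step[j] = 1e-6
            jac[:, j] = (residuals(params + step) - f0) / 1e-6
        jtj = jac.T @ jac
        delta = np.linalg.solve(
            jtj + lam * np.diag(np.diag(jtj) + 1e-12), -jac.T @ f0
        )
        trial = params + delta
        trial[3:6] /= np.linalg.norm(trial[3:6])
        new_cost = float(np.sum(residuals(trial) ** 2))
        if new_cost < cost:
            improvement = cost - new_cost
            params, cost = trial, new_cost
            lam = max(lam / 3.0, 1e-12)
            if improvement < 1e-14 * (1.0 + cost):
                break
        else:
            lam *= 10.0
            if lam > 1e8:
                break
    d = params[3:6] / np.linalg.norm(params[3:6])
    rel = ca - params[:3]
    perp = rel - np.outer(rel @ d, d)
    fit_rms = float(np.std(np.linalg.norm(perp, axis=1)))
    # report the axis point closest to the Cα centroid
    centroid = params[:3] + np.dot(ca.mean(axis=0) - params[:3], d) * d
    return d, centroid, fit_rms


def fit_helix_axis(
    ca_coords: np.ndarray, helix: HelixDefinition | None = None
) -> HelixAxisFit:
    """Fit the axis of one helix from its ordered Cα trace.

    Requires at least 5 Cα.  The bisector construction provides local
    helix-center estimates; the principal line through them initializes
    a least-squares cylinder refinement against the Cα radial distances.
    The returned axis is a unit vector oriented from the N- to the
    C-terminal end of the trace; ``fit_rms`` is the spread of Cα radial
    distances about the fitted radius.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise InsufficientDataError("ca_coords must be an (n, 3) array")
    if len(ca) < 5:
        raise InsufficientDataError(f"need >= 5 Cα to fit a helix axis, got {len(ca)}")
    centers = _bisector_centers(ca)
    direction, centroid, _ = _principal_line(centers)
    direction, centroid, rms = _refine_cylinder_axis(ca, direction, centroid)
    span = ca[-1] - ca[0]
    if abs(np.dot(direction, span)) < _COLLINEAR_TOL:
        raise FitError("fitted axis is perpendicular to the helix span")
    if np.dot(direction, span) < 0:
        direction = -direction
    return HelixAxisFit(helix, direction, centroid, rms)


def interhelix_angle(fit_a: HelixAxisFit, fit_b: HelixAxisFit) -> float:
    """Angle (degrees, in [0, 180]) between two N→C oriented helix axes.

    Antiparallel helices give angles near 180°; no folding to [0, 90].
    """
    cos = float(np.clip(np.dot(fit_a.axis, fit_b.axis), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def local_axes(
    ca_coords: np.ndarray, window: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Local axis points and directions along a helix.

    One axis point per sliding window of ``window`` consecutive Cα
    (step 1): the mean of the bisector-center estimates of the window's
    interior residues.  Directions are the differences of successive
    axis points.  Returns (axis_points, directions) with
    ``n − window + 1`` points and one fewer direction.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if window < 2:
        raise ConfigurationError("window must be >= 2")
    n = len(ca)
    if n < window + 1:
        raise InsufficientDataError(
            f"helix of {n} residues is shorter than window + 1 = {window + 1}"
        )
    centers = _bisector_centers(ca)  # one per interior residue, index i -> residue i+1
    points = np.empty((n - window + 1, 3))
    # interior residues of window [j, j+window-1] are j+1 .. j+window-2;
    # a window of 2 has none, so it borrows the nearest interior center.
    w_int = max(window - 2, 1)
    for j in range(n - window + 1):
        lo = min(j, (n - 2) - w_int)
        points[j] = centers[lo : lo + w_int].mean(axis=0)
    directions = np.diff(points, axis=0)
    return points, directions


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise FitError("zero-length axis chord")
    cos = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def max_bend_angle(
    ca_coords: np.ndarray,
    window: int = 4,
    spacing: int | None = None,
    gap: int | None = None,
) -> float:
    """Maximum bending angle (degrees) along one helix in one frame.

    Local axis chords of ``spacing`` axis points (default: the window
    size) are compared after skipping ``gap`` axis points (default: the
    window size): the bend at position j is the angle between
    (a_{j+s} − a_j) and (a_{j+s+g+s} − a_{j+s+g}), maximized over j.
    The gap matters because the ``window − 1`` axis points whose windows
    straddle a kink blend the two segment axes; comparing chords that
    clear the blended region recovers a localized kink at its full
    angle instead of a smeared fraction of it.
    """
    points, _ = local_axes(ca_coords, window)
    s = window if spacing is None else spacing
    g = window if gap is None else gap
    if s < 1 or g < 0:
        raise ConfigurationError("spacing must be >= 1 and gap >= 0")
    m = len(points)
    if m < 2 * s + g + 1:
        raise InsufficientDataError(
            f"{m} axis points cannot support bend chords of spacing {s} "
            f"and gap {g}"
        )
    best = 0.0
    for j in range(0, m - 2 * s - g):
        ang = _angle_between(
            points[j + s] - points[j],
            points[j + 2 * s + g] - points[j + s + g],
        )
        best = max(best, ang)
    return best


@dataclass
class HelixGeometryResult:
    """Per-frame helix geometry plus pooled ensemble summaries."""

    per_frame: pd.DataFrame
    summary: pd.DataFrame
    per_replica_means: pd.DataFrame


def _helix_ca_indices(topology: Topology, helix: HelixDefinition) -> list[int]:
    idx = []
    for resnum in range(helix.first_residue, helix.last_residue + 1):
        i = topology.ca_index(helix.chain_id, resnum)
        if i is None:
            raise ConfigurationError(
                f"helix {helix.name}: residue {helix.chain_id}{resnum} "
                "has no Cα in the topology"
            )
        idx.append(i)
    return idx


def ensemble_geometry(
    ensemble: TrajectoryEnsemble,
    helices: list[HelixDefinition],
    helix_pairs: list[tuple[str, str]],
    config: AnalysisConfig,
) -> HelixGeometryResult:
    """Per-frame inter-helix angles and max bends, with pooled means and
    bootstrap standard errors.

    ``helix_pairs`` name helices by their ``HelixDefinition.name``.  The
    ensemble is expected to be equilibration-filtered.  Frames are
    pooled over replicas for the summary; per-replica means are also
    reported.
    """
    by_name = {h.name: h for h in helices}
    for a, b in helix_pairs:
        if a not in by_name or b not in by_name:
            raise ConfigurationError(f"helix pair ({a}, {b}) references unknown helix")
    ca_idx = {h.name: _helix_ca_indices(ensemble.topology, h) for h in helices}

    rows = []
    for r, t, frame in ensemble.iter_frames():
        fits = {
            name: fit_helix_axis(frame[idx], by_name[name])
            for name, idx in ca_idx.items()
        }
        row = {"replica": r, "time_ns": t}
        for a, b in helix_pairs:
            row[f"angle_{a}-{b}"] = interhelix_angle(fits[a], fits[b])
        for h in helices:
            row[f"bend_{h.name}"] = max_bend_angle(
                frame[ca_idx[h.name]], config.bendix_window
            )
        rows.append(row)
    per_frame = pd.DataFrame(rows)

    observables = [c for c in per_frame.columns if c not in ("replica", "time_ns")]
    rng_children = np.random.SeedSequence(config.rng_seed).spawn(len(observables))
    summary_rows = []
    for obs, ss in zip(observables, rng_children):
        values = per_frame[obs].to_numpy()
        se = bootstrap_se(
            values, config.bootstrap_reps, np.random.default_rng(ss)
        )
        summary_rows.append(
            {
                "observable": obs,
                "mean": float(values.mean()),
                "bootstrap_se": se,
                "n": len(values),
            }
        )
    summary = pd.DataFrame(summary_rows)
    per_replica_means = per_frame.groupby("replica")[observables].mean().reset_index()
    return HelixGeometryResult(per_frame, summary, per_replica_means)
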