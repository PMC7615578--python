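"""Along-tract profiling and tract volume quantification.

A bundle's centerline is a smoothing spline through the pointwise mean of
arc-length-resampled, consistently-oriented streamlines, re-parametrized by
arc length and sampled at twenty equidistant nodes.  Voxel-level quantities
are projected onto nodes by nearest-node assignment; per-subject profiles
are aligned across the cohort by a linear translation+rescaling of the node
axis; tract volume is the count of voxels visited by at least one
streamline (each streamline counted once per voxel), normalized by brain
volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.optimize import minimize_scalar

__all__ = [
    "Centerline",
    "TractProfile",
    "orient_and_resample",
    "compute_centerline",
    "project_to_nodes",
    "align_profiles",
    "tract_volume",
    "centerline_qc_ratio",
    "read_streamlines",
    "write_streamlines",
]

N_NODES = 20


@dataclass(frozen=True)
class Centerline:
    """Arc-length parametrized bundle centerline with 20 equidistant nodes."""

    points: np.ndarray       # dense samples, (n, 3), mm
    arc_length: float        # total length, mm
    nodes: np.ndarray        # (20, 3) node coordinates

    def __post_init__(self) -> None:
        if self.nodes.shape != (N_NODES, 3):
            raise ValueError(f"expected {N_NODES} nodes")


@dataclass(frozen=True)
class TractProfile:
    """Along-tract node values plus normalized volume for one bundle/subject."""

    tract: str
    node_values: dict            # quantity name -> array of 20 values
    volume_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name, vals in self.node_values.items():
            if len(vals) != N_NODES:
                raise ValueError(f"{name}: expected {N_NODES} node values")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Resampling and orientation
# ---------------------------------------------------------------------------

def _resample_arclength(points: np.ndarray, n_points: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0.0:
        raise ValueError("zero-length streamline")
    targets = np.linspace(0.0, arc[-1], n_points)
    return np.stack([np.interp(targets, arc, points[:, k]) for k in range(3)], axis=1)


def orient_and_resample(streamlines, n_points: int = 60) -> np.ndarray:
    """Resample each streamline to equidistant arc-length samples and flip
    those running opposite to the first streamline (start-point clustering).

    Zero-length streamlines are skipped with a warning.  Returns an array
    of shape (n_streamlines, n_points, 3).
    """
    import warnings

    out = []
    for i, s in enumerate(streamlines):
        s = np.asarray(s, dtype=float)
        try:
            r = _resample_arclength(s, n_points)
        except ValueError:
            warnings.warn(f"skipping zero-length streamline {i}", stacklevel=2)
            continue
        out.append(r)
    if not out:
        raise ValueError("no usable streamlines")
    ref_start = out[0][0]
    ref_end = out[0][-1]
    aligned = []
    for r in out:
        if np.linalg.norm(r[0] - ref_start) + np.linalg.norm(r[-1] - ref_end) > (
            np.linalg.norm(r[-1] - ref_start) + np.linalg.norm(r[0] - ref_end)
        ):
            r = r[::-1]
        aligned.append(r)
    return np.stack(aligned, axis=0)


# ---------------------------------------------------------------------------
# Centerline
# ---------------------------------------------------------------------------

def compute_centerline(
    streamlines, smoothing: float = 1.0, n_points: int = 60, n_dense: int = 1000
) -> Centerline:
    """Cubic smoothing spline through the pointwise mean streamline,
    re-parametrized by arc length with 20 equidistant nodes."""
    mat = (
        streamlines
        if isinstance(streamlines, np.ndarray) and streamlines.ndim == 3
        else orient_and_resample(streamlines, n_points)
    )
    mean_curve = mat.mean(axis=0)
    distinct = np.unique(np.round(mean_curve, 9), axis=0)
    if distinct.shape[0] < 2:
        raise ValueError("need at least 2 distinct points for a centerline")
    try:
        tck, _ = splprep(mean_curve.T, s=smoothing, k=min(3, mean_curve.shape[0] - 1))
        u = np.linspace(0.0, 1.0, n_dense)
        dense = np.stack(splev(u, tck), axis=1)
    except Exception:
        dense = mean_curve  # degenerate geometry: fall back to the polyline
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arc[-1])
    node_arc = np.linspace(0.0, total, N_NODES)
    nodes = np.stack([np.interp(node_arc, arc, dense[:, k]) for k in range(3)], axis=1)
    return Centerline(points=dense, arc_length=total, nodes=nodes)


def centerline_qc_ratio(centerline: Centerline) -> float:
    """Arc length over endpoint distance; a reproducible surrogate for
    visual QC — bundles with self-folding centerlines score high."""
    chord = float(np.linalg.norm(centerline.nodes[-1] - centerline.nodes[0]))
    if chord == 0.0:
        return np.inf
    return centerline.arc_length / chord


# ---------------------------------------------------------------------------
# Node projection
# ---------------------------------------------------------------------------

def project_to_nodes(
    voxel_values: np.ndarray,
    voxel_coords: np.ndarray,
    centerline: Centerline,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-node average of voxel values.

    Each voxel goes to the node whose center is closest (ties: the
    lower-index node, via argmin's first-occurrence rule).  Returns
    (node_values, node_counts); empty nodes carry NaN.
    """
    vals = np.asarray(voxel_values, dtype=float)
    coords = np.asarray(voxel_coords, dtype=float)
    if vals.shape[0] == 0:
        raise ValueError("empty voxel set")
    d = np.linalg.norm(coords[:, None, :] - centerline.nodes[None, :, :], axis=2)
    assign = np.argmin(d, axis=1)
    node_values = np.full(N_NODES, np.nan)
    counts = np.zeros(N_NODES, dtype=int)
    for n in range(N_NODES):
        sel = assign == n
        counts[n] = int(sel.sum())
        if counts[n]:
            node_values[n] = float(vals[sel].mean())
    if np.all(counts == 0):
        raise ValueError("no voxel assigned to any node")
    return node_values, counts


# ---------------------------------------------------------------------------
# Profile alignment
# ---------------------------------------------------------------------------

def _interp_profile(profile: np.ndarray, shift: float, scale: float) -> np.ndarray:
    """Sample the profile at node positions shift + scale * i."""
    x = np.arange(N_NODES, dtype=float)
    src = shift + scale * x
    return np.interp(src, x, profile)


def align_profiles(
    profiles: np.ndarray,
    max_shift: float = 3.0,
    scale_range: tuple[float, float] = (0.7, 1.3),
) -> tuple[np.ndarray, np.ndarray]:
    """Align per-subject profiles to the cohort mean by a linear map of the
    node axis (translation + rescaling), maximizing correlation.

    ``profiles`` is (n_subjects, 20).  Constant (degenerate) profiles keep
    the identity map and are flagged.  Returns (aligned, params) with
    ``params[s] = (shift, scale, degenerate_flag)``.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2 or P.shape[1] != N_NODES:
        raise ValueError("profiles must be (n_subjects>=2, 20)")
    ref = P.mean(axis=0)
    aligned = np.empty_like(P)
    params = np.zeros((P.shape[0], 3))
    ref_c = ref - ref.mean()
    for s in range(P.shape[0]):
        prof = P[s]
        if np.std(prof) < 1e-12 or np.std(ref_c) < 1e-12:
            aligned[s] = prof
            params[s] = (0.0, 1.0, 1.0)
            continue

        def neg_corr(shift: float, scale: float) -> float:
            q = _interp_profile(prof, shift, scale)
            qc = q - q.mean()
            denom = np.linalg.norm(qc) * np.linalg.norm(ref_c)
            if denom == 0:
                return 0.0
            return -float(qc @ ref_c) / denom

        best = (0.0, 1.0, 0.0)
        for shift in np.arange(-max_shift, max_shift + 0.5, 0.5):
            for scale in np.linspace(scale_range[0], scale_range[1], 13):
                c = neg_corr(shift, scale)
                if c < best[2]:
                    best = (shift, scale, c)
        shift0, scale0, _ = best
        # local refinement, coordinate-wise
        r = minimize_scalar(
            lambda sh: neg_corr(sh, scale0),
            bounds=(shift0 - 0.5, shift0 + 0.5), method="bounded",
        )
        shift0 = float(r.x)
        r = minimize_scalar(
            lambda sc: neg_corr(shift0, sc),
            bounds=(max(scale_range[0], scale0 - 0.06),
                    min(scale_range[1], scale0 + 0.06)),
            method="bounded",
        )
        scale0 = float(r.x)
        aligned[s] = _interp_profile(prof, shift0, scale0)
        params[s] = (shift0, scale0, 0.0)
    return aligned, params


# ---------------------------------------------------------------------------
# Tract volume
# ---------------------------------------------------------------------------

def tract_volume(
    streamlines, voxel_size: float, brain_volume: float
) -> tuple[int, float]:
    """(voxel count, volume fraction) from the tract density map.

    Each streamline contributes at most one visit per voxel, so the count
    is independent of point density along streamlines.
    """
    if brain_volume <= 0:
        raise ValueError("brain_volume must be positive")
    visited = set()
    for s in streamlines:
        vox = np.floor(np.asarray(s, dtype=float) / voxel_size).astype(int)
        visited.update({tuple(v) for v in np.unique(vox, axis=0)})
    count = len(visited)
    fraction = count * voxel_size**3 / brain_volume
    return count, float(min(fraction, 1.0))


# ---------------------------------------------------------------------------
# Streamline IO (TCK / TRK via nibabel)
# ---------------------------------------------------------------------------

def write_streamlines(streamlines, path) -> None:
    """Write streamlines (mm, RAS) as TCK or TRK based on the extension."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    tg = Tractogram([np.asarray(s, dtype=np.float32) for s in streamlines],
                    affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tg, str(path))


def read_streamlines(path) -> list[np.ndarray]:
    """Read a TCK/TRK file; returns streamlines in mm (RAS)."""
    import nibabel as nib

    tf = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
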