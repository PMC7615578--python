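"""Multishell acquisition schemes and Stejskal-Tanner pulse math.

A diffusion acquisition is described per volume by a b-value and a unit
gradient direction, plus the pulse timings (gradient separation ``Δ`` and
duration ``δ``) shared by all volumes.  Internally b is carried in ms/µm²
and diffusivities in µm²/ms, so that b = 6000 s/mm² reads as 6.0 — O(1)
numbers keep the downstream nonlinear fits well conditioned.  The file
readers/writers speak the FSL bval/bvec dialect in s/mm² and convert.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "GradientScheme",
    "Shell",
    "b_from_gradient",
    "gradient_from_b",
    "group_shells",
    "generate_directions",
    "make_default_protocol",
    "read_gradient_table",
    "write_gradient_table",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752219e8

#: conversion: b [s/mm^2] = 1000 * b [ms/µm^2]
S_PER_MM2_PER_INTERNAL = 1000.0

_DIRECTION_NORM_TOL = 1e-6


def _as_unit_or_zero(vecs: np.ndarray, bvals: np.ndarray) -> None:
    """Validate that every diffusion-weighted direction is unit norm."""
    norms = np.linalg.norm(vecs, axis=1)
    weighted = bvals > 0
    bad = weighted & (np.abs(norms - 1.0) > _DIRECTION_NORM_TOL)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"direction of volume {idx} has norm {norms[idx]:.6g}, expected 1 "
            f"(b={bvals[idx]:.3g} ms/µm²)"
        )


@dataclass(frozen=True)
class GradientScheme:
    """Acquisition contract: per-volume b-values and directions plus timings.

    Parameters
    ----------
    bvals
        b-value per volume, ms/µm² (b = 6000 s/mm² is stored as 6.0).
    bvecs
        Unit direction per volume; the zero vector is allowed for b=0.
    delta_big
        Gradient separation Δ, ms.
    delta_small
        Gradient duration δ, ms.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    delta_big: float = 23.3
    delta_small: float = 7.0

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError("bvecs must be an (n_volumes, 3) array")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"volume count mismatch: {bvals.shape[0]} bvals vs "
                f"{bvecs.shape[0]} bvecs"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        if not self.delta_small < self.delta_big:
            raise ValueError("require delta_small < delta_big")
        _as_unit_or_zero(bvecs, bvals)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def __eq__(self, other: object) -> bool:  # array fields need explicit eq
        if not isinstance(other, GradientScheme):
            return NotImplemented
        return (
            np.array_equal(self.bvals, other.bvals)
            and np.array_equal(self.bvecs, other.bvecs)
            and self.delta_big == other.delta_big
            and self.delta_small == other.delta_small
        )

    def isclose(self, other: "GradientScheme", atol: float = 1e-6) -> bool:
        return (
            np.allclose(self.bvals, other.bvals, atol=atol)
            and np.allclose(self.bvecs, other.bvecs, atol=atol)
            and np.isclose(self.delta_big, other.delta_big, atol=atol)
            and np.isclose(self.delta_small, other.delta_small, atol=atol)
        )


@dataclass(frozen=True)
class Shell:
    """Volumes sharing one nominal b-value."""

    b: float
    directions: np.ndarray
    volume_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.b > 0 and len(self.directions) == 0:
            raise ValueError("weighted shell must have directions")

    @property
    def n_directions(self) -> int:
        return int(len(self.volume_indices))


# ---------------------------------------------------------------------------
# Stejskal-Tanner pulse math
# ---------------------------------------------------------------------------

def b_from_gradient(
    G: float,
    delta_small: float = 7.0,
    delta_big: float = 23.3,
    gamma: float = GAMMA_PROTON,
) -> float:
    """b-value (s/mm²) of a Stejskal-Tanner pulse pair.

    b = γ² G² δ² (Δ − δ/3).

    Parameters
    ----------
    G : gradient amplitude, mT/m (0 allowed: b=0).
    delta_small : gradient duration δ, ms.
    delta_big : gradient separation Δ, ms.
    gamma : gyromagnetic ratio, rad s⁻¹ T⁻¹.
    """
    if G < 0:
        raise ValueError("gradient amplitude must be non-negative")
    if delta_small <= 0 or delta_big <= 0:
        raise ValueError("pulse timings must be positive")
    if not delta_small < delta_big:
        raise ValueError("require delta_small < delta_big")
    # SI: G in T/m, times in s -> b in s/m²; 1 s/m² = 1e-6 s/mm².
    G_si = G * 1e-3
    d = delta_small * 1e-3
    D = delta_big * 1e-3
    b_si = (gamma * G_si * d) ** 2 * (D - d / 3.0)
    return b_si * 1e-6


def gradient_from_b(
    b: float,
    delta_small: float = 7.0,
    delta_big: float = 23.3,
    gamma: float = GAMMA_PROTON,
) -> float:
    """Inverse of :func:`b_from_gradient`: amplitude (mT/m) giving b (s/mm²)."""
    if b < 0:
        raise ValueError("b must be non-negative")
    if delta_small <= 0 or delta_big <= 0 or not delta_small < delta_big:
        raise ValueError("invalid pulse timings")
    d = delta_small * 1e-3
    D = delta_big * 1e-3
    b_si = b * 1e6
    G_si = np.sqrt(b_si / (D - d / 3.0)) / (gamma * d)
    return float(G_si * 1e3)


# ---------------------------------------------------------------------------
# Shell grouping
# ---------------------------------------------------------------------------

def group_shells(scheme: GradientScheme, tolerance: float = 0.1) -> list[Shell]:
    """Partition a scheme's volumes into shells of near-equal b.

    b=0 volumes always form their own shell.  Nominal shell b is the mean of
    member b-values.  A volume lying within ``tolerance`` of two distinct
    nominal values is ambiguous and raises.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    bvals = scheme.bvals
    order = np.argsort(bvals, kind="stable")
    groups: list[list[int]] = []
    for idx in order:
        b = bvals[idx]
        if groups and (b - bvals[groups[-1][0]]) <= tolerance and not (
            b == 0.0
        ) != (bvals[groups[-1][0]] == 0.0):
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    shells = []
    for members in groups:
        nominal = float(np.mean(bvals[members]))
        shells.append(
            Shell(
                b=0.0 if bvals[members[0]] == 0 else nominal,
                directions=scheme.bvecs[members],
                volume_indices=np.asarray(members, dtype=int),
            )
        )
    # ambiguity check: volume within tolerance of a *different* shell nominal
    nominals = np.array([s.b for s in shells])
    for s in shells:
        for idx in s.volume_indices:
            close = np.abs(nominals - bvals[idx]) <= tolerance
            if np.sum(close) > 1:
                raise ValueError(
                    f"volume {int(idx)} (b={bvals[idx]:.3g}) is within "
                    f"tolerance of shells {nominals[close]}"
                )
    return shells


# ---------------------------------------------------------------------------
# Direction generation (seeded electrostatic repulsion)
# ---------------------------------------------------------------------------

def generate_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """``n`` unit vectors spread by antipodally-symmetric repulsion.

    Points interact with Coulomb 1/r potentials against both the other
    points and their antipodes, the natural symmetry for diffusion sampling
    where g and -g are equivalent.  Deterministic for fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    step = 0.1
    energy = _repulsion_energy(x)
    for _ in range(n_iter):
        g = _repulsion_grad(x)
        # project gradient onto the tangent plane of the sphere
        g -= np.sum(g * x, axis=1, keepdims=True) * x
        trial = x - step * g
        trial /= np.linalg.norm(trial, axis=1, keepdims=True)
        e_trial = _repulsion_energy(trial)
        if e_trial < energy:
            x, energy = trial, e_trial
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return x


def _pair_diffs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d_minus = x[:, None, :] - x[None, :, :]
    d_plus = x[:, None, :] + x[None, :, :]
    return d_minus, d_plus


def _repulsion_energy(x: np.ndarray) -> float:
    d_minus, d_plus = _pair_diffs(x)
    n = x.shape[0]
    rm = np.linalg.norm(d_minus, axis=-1)
    rp = np.linalg.norm(d_plus, axis=-1)
    iu = np.triu_indices(n, k=1)
    return float(np.sum(1.0 / rm[iu]) + np.sum(1.0 / rp[iu]))


def _repulsion_grad(x: np.ndarray) -> np.ndarray:
    d_minus, d_plus = _pair_diffs(x)
    rm = np.linalg.norm(d_minus, axis=-1)
    rp = np.linalg.norm(d_plus, axis=-1)
    np.fill_diagonal(rm, np.inf)
    np.fill_diagonal(rp, np.inf)
    gm = -d_minus / rm[..., None] ** 3
    gp = -d_plus / rp[..., None] ** 3
    return np.sum(gm, axis=1) + np.sum(gp, axis=1)


# ---------------------------------------------------------------------------
# The study's five-shell ultra-strong-gradient protocol
# ---------------------------------------------------------------------------

#: (b in ms/µm², number of directions); 30 dirs for b<=1.2, 60 for b>=2.4.
DEFAULT_SHELLS: tuple[tuple[float, int], ...] = (
    (0.5, 30),
    (1.2, 30),
    (2.4, 60),
    (4.0, 60),
    (6.0, 60),
)
DEFAULT_N_B0 = 14


def make_default_protocol(seed: int = 0) -> GradientScheme:
    """Five-shell scheme: b = 0.5, 1.2, 2.4, 4.0, 6.0 ms/µm² with
    30/30/60/60/60 directions plus 14 interleaved b=0 volumes; Δ = 23.3 ms,
    δ = 7 ms.  Directions come from seeded electrostatic repulsion (the
    vendor tables are not public), so the set is reproducible per seed.
    """
    bvals: list[float] = [0.0] * DEFAULT_N_B0
    bvecs: list[np.ndarray] = [np.zeros(3)] * DEFAULT_N_B0
    for k, (b, n_dir) in enumerate(DEFAULT_SHELLS):
        dirs = generate_directions(n_dir, seed=seed * 101 + k)
        bvals.extend([b] * n_dir)
        bvecs.extend(dirs)
    return GradientScheme(np.array(bvals), np.vstack(bvecs))


# ---------------------------------------------------------------------------
# FSL bval/bvec IO
# ---------------------------------------------------------------------------

def scheme_from_config(config) -> GradientScheme:
    """Build a scheme from a config mapping or YAML file path.

    Keys: ``shells`` (list of b-values, s/mm²), ``directions`` (list of
    per-shell direction counts), ``n_b0``, ``delta_big``, ``delta_small``
    (ms), ``seed``.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    shells = [float(b) / S_PER_MM2_PER_INTERNAL for b in config["shells"]]
    counts = [int(c) for c in config["directions"]]
    if len(shells) != len(counts):
        raise ValueError("shells and directions must have equal length")
    n_b0 = int(config.get("n_b0", DEFAULT_N_B0))
    seed = int(config.get("seed", 0))
    bvals: list[float] = [0.0] * n_b0
    bvecs: list[np.ndarray] = [np.zeros(3)] * n_b0
    for k, (b, n_dir) in enumerate(zip(shells, counts)):
        dirs = generate_directions(n_dir, seed=seed * 101 + k)
        bvals.extend([b] * n_dir)
        bvecs.extend(dirs)
    return GradientScheme(
        np.array(bvals),
        np.vstack(bvecs),
        delta_big=float(config.get("delta_big", 23.3)),
        delta_small=float(config.get("delta_small", 7.0)),
    )


def read_gradient_table(
    bval_path,
    bvec_path,
    delta_big: float = 23.3,
    delta_small: float = 7.0,
) -> GradientScheme:
    """Read FSL-dialect gradient files.

    bvals: one whitespace-separated row, s/mm².  bvecs: three rows (x, y, z).
    b is converted to ms/µm² internally.
    """
    with open(bval_path) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) != 1:
        raise ValueError(f"{bval_path}: expected 1 row of b-values, got {len(rows)}")
    bvals = np.array([float(v) for v in rows[0]]) / S_PER_MM2_PER_INTERNAL
    with open(bvec_path) as fh:
        vrows = [line.split() for line in fh if line.strip()]
    if len(vrows) != 3:
        raise ValueError(f"{bvec_path}: expected 3 rows (x, y, z), got {len(vrows)}")
    for i, row in enumerate(vrows):
        if len(row) != bvals.shape[0]:
            raise ValueError(
                f"{bvec_path}: row {i + 1} has {len(row)} entries, "
                f"expected {bvals.shape[0]}"
            )
    bvecs = np.array([[float(v) for v in row] for row in vrows]).T
    return GradientScheme(bvals, bvecs, delta_big=delta_big, delta_small=delta_small)


def write_gradient_table(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient files (bvals in s/mm²)."""
    bvals = scheme.bvals * S_PER_MM2_PER_INTERNAL
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:.6g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.10g}" for v in scheme.bvecs[:, axis]) + "\n")
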