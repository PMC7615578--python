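"""The eleven observable diffusion metrics.

Per voxel (or per segment-averaged signal) the panel is: DTI-derived FA,
D̄, D⊥, D∥ (fit on b ≤ 1.2 ms/µm²); DKI-derived K̄, K⊥, K∥ (fit on
b ≤ 2.4 ms/µm²); and per-shell spherical mean / spherical standard
deviation of the normalized signal at the lowest and highest shells
(b = 0.5 and 6.0 ms/µm²).  Spherical moments are computed from real
even-order spherical-harmonic fits and normalized by the mean b=0 signal,
so they are dimensionless fractions of s0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .protocol import GradientScheme, Shell, group_shells

__all__ = [
    "ShellSH",
    "MetricVector",
    "real_even_sh_basis",
    "fit_shell_sh",
    "spherical_moments",
    "fit_dti",
    "fit_dki",
    "compute_metric_vector",
]

METRIC_NAMES = (
    "fa", "md", "rd", "ad",
    "mk", "rk", "ak",
    "smean_low", "smean_high", "svar_low", "svar_high",
)

B_LOW = 0.5
B_HIGH = 6.0
B_MAX_DTI = 1.25
B_MAX_DKI = 2.5


@dataclass(frozen=True)
class ShellSH:
    """Real even-order spherical-harmonic expansion of one shell's signal."""

    b: float
    coeffs: np.ndarray
    l_max: int
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        expected = (self.l_max + 1) * (self.l_max + 2) // 2
        if len(self.coeffs) != expected:
            raise ValueError(
                f"even basis up to l_max={self.l_max} has {expected} "
                f"coefficients, got {len(self.coeffs)}"
            )


@dataclass(frozen=True)
class MetricVector:
    """The 11-metric panel for one ROI/segment of one subject."""

    fa: float
    md: float
    rd: float
    ad: float
    mk: float
    rk: float
    ak: float
    smean_low: float
    smean_high: float
    svar_low: float
    svar_high: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRIC_NAMES])


# ---------------------------------------------------------------------------
# Real even spherical-harmonic basis
# ---------------------------------------------------------------------------

def _even_lm(l_max: int) -> list[tuple[int, int]]:
    return [(l, m) for l in range(0, l_max + 1, 2) for m in range(-l, l + 1)]


def real_even_sh_basis(directions: np.ndarray, l_max: int) -> np.ndarray:
    """Design matrix of real even-order spherical harmonics.

    Real convention: Y_{l,-m} = √2·Im(Y_l^m), Y_{l,0} = Y_l^0,
    Y_{l,+m} = √2·Re(Y_l^m) (orthonormal on the sphere).  Rows follow the
    direction order, columns the (l, m) order of ``_even_lm``.
    """
    d = np.asarray(directions, dtype=float)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols = []
    for l, m in _even_lm(l_max):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * y.imag)
        elif m == 0:
            cols.append(y.real)
        else:
            cols.append(np.sqrt(2.0) * y.real)
    return np.stack(cols, axis=1)


def fit_shell_sh(
    signal: np.ndarray,
    directions: np.ndarray,
    l_max: int,
    b: float = 0.0,
    design_pinv: np.ndarray | None = None,
) -> ShellSH:
    """Least-squares SH fit of one shell's per-direction signal.

    ``design_pinv`` allows reusing a precomputed pseudoinverse when many
    voxels share the same direction set.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("fit_shell_sh expects one voxel's per-direction signal")
    n_coef = (l_max + 1) * (l_max + 2) // 2
    if signal.shape[0] < n_coef:
        raise ValueError(
            f"underdetermined SH fit: l_max={l_max} needs >= {n_coef} "
            f"directions, got {signal.shape[0]}"
        )
    B = real_even_sh_basis(directions, l_max)
    pinv = np.linalg.pinv(B) if design_pinv is None else design_pinv
    coeffs = pinv @ signal
    rms = float(np.sqrt(np.mean((B @ coeffs - signal) ** 2)))
    return ShellSH(b=b, coeffs=coeffs, l_max=l_max, residual_rms=rms)


def spherical_moments(sh: ShellSH, s0: float) -> tuple[float, float]:
    """(spherical mean, spherical standard deviation), s0-normalized.

    mean = c₀₀ / (2√π) / s0; the 'variance' metric is reported on the
    standard-deviation scale: sqrt(Σ_{l≥2,m} c_lm² / 4π) / s0.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    c = sh.coeffs
    smean = float(c[0] / (2.0 * np.sqrt(np.pi)) / s0)
    svar = float(np.sqrt(np.sum(c[1:] ** 2) / (4.0 * np.pi)) / s0)
    return smean, svar


def default_shell_lmax(n_directions: int) -> int:
    """l_max policy: 4 for 30-direction shells, 6 for 60-direction shells."""
    if n_directions >= 28:  # 28 coefficients at l_max=6
        return 6 if n_directions >= 45 else 4
    if n_directions >= 15:
        return 4
    if n_directions >= 6:
        return 2
    return 0


# ---------------------------------------------------------------------------
# DTI
# ---------------------------------------------------------------------------

_DT_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _dti_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(bvals)]
    for (i, j) in _DT_IDX:
        mult = 1.0 if i == j else 2.0
        cols.append(-bvals * mult * bvecs[:, i] * bvecs[:, j])
    return np.stack(cols, axis=1)


def _tensor_from_vec(v: np.ndarray) -> np.ndarray:
    D = np.empty((3, 3))
    for k, (i, j) in enumerate(_DT_IDX):
        D[i, j] = D[j, i] = v[k]
    return D


def fit_dti(
    signal: np.ndarray,
    scheme: GradientScheme,
    b_max_dti: float = B_MAX_DTI,
) -> tuple[np.ndarray, dict[str, float]]:
    """Weighted linear least-squares tensor fit on ln S.

    Uses volumes with 0 < b ≤ b_max_dti plus all b=0 volumes; weights are
    the squared (predicted-from-OLS) signals, the standard WLLS scheme.
    Eigenvalues are sorted descending and clipped at zero.

    Returns (3x3 tensor, dict with fa/md/rd/ad and s0).
    """
    signal = np.asarray(signal, dtype=float)
    use = scheme.bvals <= b_max_dti
    if not np.any(scheme.bvals[use] > 0):
        raise ValueError("DTI fit needs at least one diffusion-weighted volume")
    n_dw = int(np.sum(scheme.bvals[use] > 0))
    if n_dw < 6:
        raise ValueError(f"DTI fit needs >= 6 weighted directions, got {n_dw}")
    b = scheme.bvals[use]
    g = scheme.bvecs[use]
    s = np.clip(signal[use], 1e-10, None)
    X = _dti_design(b, g)
    y = np.log(s)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    w = np.exp(X @ beta)  # predicted signals as WLLS weights
    Xw = X * w[:, None]
    beta = np.linalg.lstsq(Xw, y * w, rcond=None)[0]
    D = _tensor_from_vec(beta[1:])
    evals = np.linalg.eigvalsh(D)[::-1]
    evals = np.clip(evals, 0.0, None)
    md = float(np.mean(evals))
    ad = float(evals[0])
    rd = float((evals[1] + evals[2]) / 2.0)
    denom = np.sqrt(np.sum(evals**2))
    fa = 0.0 if denom == 0 else float(
        np.sqrt(1.5) * np.sqrt(np.sum((evals - md) ** 2)) / denom
    )
    return D, {"fa": fa, "md": md, "rd": rd, "ad": ad, "s0": float(np.exp(beta[0]))}


# ---------------------------------------------------------------------------
# DKI
# ---------------------------------------------------------------------------

def _w_idx() -> list[tuple[int, int, int, int]]:
    idx = []
    for i in range(3):
        for j in range(i, 3):
            for k in range(j, 3):
                for l in range(k, 3):
                    idx.append((i, j, k, l))
    return idx


_W_IDX = _w_idx()  # 15 unique components


def _w_multiplicity(ijkl: tuple[int, int, int, int]) -> int:
    from math import factorial
    counts = [ijkl.count(a) for a in range(3)]
    return factorial(4) // (factorial(counts[0]) * factorial(counts[1]) * factorial(counts[2]))


_W_MULT = np.array([_w_multiplicity(t) for t in _W_IDX], dtype=float)


def _w_tensor_from_vec(v: np.ndarray) -> np.ndarray:
    from itertools import permutations
    W = np.zeros((3, 3, 3, 3))
    for val, ijkl in zip(v, _W_IDX):
        for perm in set(permutations(ijkl)):
            W[perm] = val
    return W


def _w_contract(W: np.ndarray, g: np.ndarray) -> np.ndarray:
    return np.einsum("vi,vj,vk,vl,ijkl->v", g, g, g, g, W)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform direction set (for directional averages)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def fit_dki(
    signal: np.ndarray,
    scheme: GradientScheme,
    b_max_dki: float = B_MAX_DKI,
    n_avg_directions: int = 10000,
):
    """Weighted linear least-squares kurtosis fit on ln S.

    22 unknowns: ln s0, 6 tensor elements, 15 elements of D̄²·W.  Mean
    kurtosis is the average apparent kurtosis over a deterministic
    quasi-uniform set of ``n_avg_directions`` directions; axial kurtosis is
    along the principal eigenvector; radial kurtosis averages over the
    perpendicular plane.

    Returns (TensorKurtosisParams, dict with mk/rk/ak).
    """
    from .forward_models import TensorKurtosisParams

    signal = np.asarray(signal, dtype=float)
    use = scheme.bvals <= b_max_dki
    b = scheme.bvals[use]
    g = scheme.bvecs[use]
    shells = {round(float(x), 6) for x in b[b > 0]}
    if len(shells) < 2:
        raise ValueError("DKI fit needs >= 2 nonzero shells")
    if int(np.sum(b > 0)) < 21:
        raise ValueError("DKI fit needs >= 21 weighted directions")
    s = np.clip(signal[use], 1e-10, None)
    y = np.log(s)
    cols = [np.ones_like(b)]
    for (i, j) in _DT_IDX:
        mult = 1.0 if i == j else 2.0
        cols.append(-b * mult * g[:, i] * g[:, j])
    gprod = np.stack(
        [g[:, i] * g[:, j] * g[:, k] * g[:, l] for (i, j, k, l) in _W_IDX], axis=1
    )
    cols.extend((b**2 / 6.0) * _W_MULT[k] * gprod[:, k] for k in range(15))
    X = np.stack(cols, axis=1)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    w = np.exp(X @ beta)
    beta = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)[0]

    D = _tensor_from_vec(beta[1:7])
    md = float(np.trace(D) / 3.0)
    if md <= 0:
        raise ValueError("non-positive mean diffusivity in DKI fit")
    W = _w_tensor_from_vec(beta[7:] / md**2)
    params = TensorKurtosisParams(s0=float(np.exp(beta[0])), dt=_psd_clip(D), wt=W)

    w_vec = beta[7:] / md**2  # 15 unique components

    def k_app(dirs: np.ndarray) -> np.ndarray:
        d_app = np.einsum("vi,ij,vj->v", dirs, D, dirs)
        d_app = np.clip(d_app, 1e-10, None)
        gp = np.stack(
            [dirs[:, i] * dirs[:, j] * dirs[:, k] * dirs[:, l]
             for (i, j, k, l) in _W_IDX], axis=1)
        return (md / d_app) ** 2 * (gp @ (_W_MULT * w_vec))

    dirs = _fibonacci_sphere(n_avg_directions)
    mk = float(np.mean(k_app(dirs)))
    evals, evecs = np.linalg.eigh(D)
    e1 = evecs[:, np.argmax(evals)]
    ak = float(k_app(e1[None, :])[0])
    # orthonormal frame perpendicular to e1
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(tmp @ e1) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    u = np.cross(e1, tmp)
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    ang = np.linspace(0, np.pi, 180, endpoint=False)
    perp = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    rk = float(np.mean(k_app(perp)))
    return params, {"mk": mk, "rk": rk, "ak": ak}


def _psd_clip(D: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(D)
    return (evecs * np.clip(evals, 0.0, None)) @ evecs.T


# ---------------------------------------------------------------------------
# The full panel
# ---------------------------------------------------------------------------

def compute_metric_vector(
    signal: np.ndarray,
    scheme: GradientScheme,
    shell_tolerance: float = 0.1,
) -> MetricVector:
    """Assemble the 11-metric panel from one multishell signal.

    s0 is the mean over b=0 volumes.  Spherical moments are taken from the
    lowest (b=0.5) and highest (b=6.0) shells present.
    """
    signal = np.asarray(signal, dtype=float)
    shells = group_shells(scheme, tolerance=shell_tolerance)
    weighted = [s for s in shells if s.b > 0]
    if not weighted:
        raise ValueError("need at least one weighted shell")
    b0_shell = [s for s in shells if s.b == 0]
    if not b0_shell:
        raise ValueError("need b=0 volumes to normalize")
    s0 = float(np.mean(signal[b0_shell[0].volume_indices]))

    _, dti = fit_dti(signal, scheme)
    _, dki = fit_dki(signal, scheme)

    lo = min(weighted, key=lambda s: s.b)
    hi = max(weighted, key=lambda s: s.b)
    moments = {}
    for tag, shell in (("low", lo), ("high", hi)):
        l_max = default_shell_lmax(shell.n_directions)
        sh = fit_shell_sh(signal[shell.volume_indices], shell.directions, l_max)
        moments[f"smean_{tag}"], moments[f"svar_{tag}"] = spherical_moments(sh, s0)

    return MetricVector(
        fa=dti["fa"], md=dti["md"], rd=dti["rd"], ad=dti["ad"],
        mk=dki["mk"], rk=dki["rk"], ak=dki["ak"],
        smean_low=moments["smean_low"], smean_high=moments["smean_high"],
        svar_low=moments["svar_low"], svar_high=moments["svar_high"],
    )
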