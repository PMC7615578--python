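"""Synthetic study generator.

Emulates the study design end to end so every downstream stage is testable
without participant data: a typically-developing (TD) cohort of 92 children
aged 8-18, an age/sex-matched subset of 22 (ASM), and a deletion-syndrome
group (DEL) of 9 children aged ~12-15; per-subject ground-truth Standard
Model parameter fields carrying linear age trends and DEL-vs-ASM group
shifts; synthetic streamline bundles; and simulated five-shell signals with
Rician noise.

Default effect sizes are the study's reported percent differences:
f +9% over the 8-18 age range; DEL vs ASM: f +5%, De⊥ −4.6%, De∥ −3.6%,
κ −1.6%.  Baseline Standard Model values (f=0.6, D_c=2.2, De∥=2.0,
De⊥=0.7, κ=16) are generator conventions for healthy deep white matter.
All effects are overridable through :class:`CohortSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward_models import SMParams, add_noise, sm_signal_batch
from .protocol import GradientScheme

__all__ = [
    "Subject",
    "CohortSpec",
    "BundlePhantom",
    "BASELINE_SM",
    "generate_cohort",
    "ground_truth_params",
    "generate_bundle",
    "simulate_subject_signals",
    "subjects_to_frame",
]

BASELINE_SM = SMParams(f=0.6, d_c=2.2, de_par=2.0, de_perp=0.7, kappa=16.0)

#: relative change per 10 years of age, anchored at the youngest TD age
DEFAULT_AGE_EFFECTS = {"f": 0.09, "de_perp": -0.05, "kappa": -0.02}
#: relative DEL-vs-same-age-TD differences
DEFAULT_GROUP_EFFECTS = {"f": 0.05, "de_perp": -0.046, "de_par": -0.036, "kappa": -0.016}

#: amplitude of the seeded smooth along-tract modulation (fractional)
TRACT_PROFILE_AMPLITUDE = 0.03


@dataclass(frozen=True)
class Subject:
    """One study participant."""

    id: str
    age: float
    sex: str
    group: str  # TD, DEL; ASM subjects carry group TD plus the asm flag
    asm: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be F or M")
        if self.group not in ("TD", "DEL"):
            raise ValueError("group must be TD or DEL")
        if self.asm and self.group != "TD":
            raise ValueError("the age/sex-matched flag marks TD subjects only")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the generator."""

    n_td: int = 92
    td_age_range: tuple[float, float] = (8.0, 18.0)
    n_asm: int = 22
    n_del: int = 9
    del_age_range: tuple[float, float] = (11.8, 15.2)
    del_sex_counts: tuple[int, int] = (7, 2)  # (F, M)
    age_effects: dict = field(default_factory=lambda: dict(DEFAULT_AGE_EFFECTS))
    group_effects: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    snr: float = 50.0
    #: coefficient of variation of between-subject biological variability
    #: applied multiplicatively to each Standard Model parameter (the age
    #: models of developmental cohorts leave most variance unexplained, so
    #: a cohort without this term is unrealistically collinear)
    subject_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_td <= 0 or self.n_del < 0 or self.n_asm < 0:
            raise ValueError("cohort counts must be positive")
        if self.n_asm > self.n_td:
            raise ValueError("n_asm cannot exceed n_td")
        for eff in (self.age_effects, self.group_effects):
            for k, v in eff.items():
                if not -1.0 < v < 1.0:
                    raise ValueError(f"relative effect {k}={v} outside (-1, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass(frozen=True)
class BundlePhantom:
    """Synthetic streamline bundle with its generating centerline."""

    name: str
    streamlines: list
    centerline: np.ndarray  # the noise-free generating curve, densely sampled
    voxel_size: float = 2.0
    node_params: tuple | None = None  # optional 20 SMParams along the bundle

    def __post_init__(self) -> None:
        if self.node_params is not None and len(self.node_params) != 20:
            raise ValueError("node_params must hold exactly 20 entries")
        for s in self.streamlines:
            if len(s) < 2:
                raise ValueError("every streamline needs >= 2 points")
            steps = np.linalg.norm(np.diff(np.asarray(s), axis=0), axis=1)
            if np.any(steps > 2.0 * self.voxel_size):
                raise ValueError("streamline step exceeds 2x voxel size")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Seed-deterministic subject list: TD (with ASM flags) then DEL.

    Ages are uniform within the group range.  The ASM subset is chosen by
    repeated nearest-age, same-sex matching against the DEL members
    (sampling TD without replacement) until ``n_asm`` subjects are flagged.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.td_age_range
    td_ages = rng.uniform(lo, hi, spec.n_td)
    td_sexes = np.where(np.arange(spec.n_td) % 2 == 0, "F", "M")
    rng.shuffle(td_sexes)
    dlo, dhi = spec.del_age_range
    del_ages = rng.uniform(dlo, dhi, spec.n_del)
    n_f, n_m = spec.del_sex_counts
    del_sexes = (["F"] * n_f + ["M"] * n_m)[: spec.n_del]
    while len(del_sexes) < spec.n_del:
        del_sexes.append("F")

    asm_flags = np.zeros(spec.n_td, dtype=bool)
    if spec.n_del > 0 and spec.n_asm > 0:
        available = np.ones(spec.n_td, dtype=bool)
        k = 0
        while int(asm_flags.sum()) < spec.n_asm:
            d_idx = k % spec.n_del
            cand = available & (td_sexes == del_sexes[d_idx])
            if not np.any(cand):
                cand = available
            if not np.any(cand):
                raise ValueError("TD pool exhausted before n_asm matches found")
            dist = np.abs(td_ages - del_ages[d_idx])
            dist[~cand] = np.inf
            j = int(np.argmin(dist))
            asm_flags[j] = True
            available[j] = False
            k += 1
    elif spec.n_asm > 0:
        asm_flags[: spec.n_asm] = True

    subjects = [
        Subject(
            id=f"td{str(i + 1).zfill(3)}", age=float(td_ages[i]),
            sex=str(td_sexes[i]), group="TD", asm=bool(asm_flags[i]),
        )
        for i in range(spec.n_td)
    ]
    subjects += [
        Subject(
            id=f"del{str(i + 1).zfill(3)}", age=float(del_ages[i]),
            sex=del_sexes[i], group="DEL",
        )
        for i in range(spec.n_del)
    ]
    return subjects


def subjects_to_frame(subjects: list[Subject]):
    """Subject table as a DataFrame (id, age, sex, group, asm)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"id": s.id, "age": s.age, "sex": s.sex, "group": s.group, "asm": s.asm}
            for s in subjects
        ]
    )


# ---------------------------------------------------------------------------
# Ground truth parameter fields
# ---------------------------------------------------------------------------

def _stable_hash(*parts) -> int:
    """Process-independent hash (Python's str hash is salted per run)."""
    import zlib

    key = "|".join(str(p) for p in parts).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _node_modulation(spec_seed: int, tract: str, node: int, param: str) -> float:
    """Seeded smooth along-tract modulation, identical across subjects."""
    h = _stable_hash(spec_seed, tract, param)
    phase = 2.0 * np.pi * (h / 2**31)
    return TRACT_PROFILE_AMPLITUDE * float(np.sin(2.0 * np.pi * node / 19.0 + phase))


def ground_truth_params(
    subject: Subject,
    tract: str,
    node: int,
    spec: CohortSpec,
    baseline: SMParams = BASELINE_SM,
) -> SMParams:
    """Ground-truth Standard Model parameters for one subject at one node.

    Each parameter is the baseline scaled multiplicatively by
    (1 + age_effect · (age − age_min)/10) — linear in age, anchored at the
    youngest TD age so the stated relative change accrues over the 10-year
    range — by (1 + group_effect) for DEL subjects, and by a seeded smooth
    along-tract profile shared by all subjects.  Results are clipped into
    the physical box if an extreme combination would leave it.
    """
    if not 0 <= node < 20:
        raise ValueError("node must lie in 0..19")
    age_min = spec.td_age_range[0]
    values = {
        "f": baseline.f, "d_c": baseline.d_c, "de_par": baseline.de_par,
        "de_perp": baseline.de_perp, "kappa": baseline.kappa,
    }
    subj_rng = np.random.default_rng(_stable_hash(spec.seed, subject.id, "bio"))
    bio = subj_rng.standard_normal(len(values))
    for k, name in enumerate(values):
        scale = 1.0
        if name in spec.age_effects:
            scale *= 1.0 + spec.age_effects[name] * (subject.age - age_min) / 10.0
        if subject.group == "DEL" and name in spec.group_effects:
            scale *= 1.0 + spec.group_effects[name]
        scale *= 1.0 + _node_modulation(spec.seed, tract, node, name)
        if spec.subject_cv > 0:
            scale *= max(1.0 + spec.subject_cv * bio[k], 0.05)
        values[name] *= scale
    # keep the extracellular ordering and physical boxes
    values["f"] = float(np.clip(values["f"], 0.0, 1.0))
    values["d_c"] = float(np.clip(values["d_c"], 0.0, 3.5))
    values["de_par"] = float(np.clip(values["de_par"], 0.0, 3.5))
    values["de_perp"] = float(np.clip(values["de_perp"], 0.0, values["de_par"]))
    values["kappa"] = float(max(values["kappa"], 0.0))
    return replace(baseline, **values)


# ---------------------------------------------------------------------------
# Bundle phantoms
# ---------------------------------------------------------------------------

def _parametric_curve(geometry: str, length: float, n_samples: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_samples)
    if geometry == "straight":
        return np.stack([length * t, np.zeros_like(t), np.zeros_like(t)], axis=1)
    if geometry == "arc":
        # quarter-circle arc of the given arc length
        radius = length / (np.pi / 2.0)
        ang = (np.pi / 2.0) * t
        return np.stack(
            [radius * np.sin(ang), radius * (1.0 - np.cos(ang)), np.zeros_like(t)],
            axis=1,
        )
    if geometry == "helix":
        turns = 1.5
        r = length / 12.0
        pitch_total = 0.8 * length
        ang = 2.0 * np.pi * turns * t
        return np.stack([r * np.cos(ang), r * np.sin(ang), pitch_total * t], axis=1)
    raise ValueError(f"unknown geometry {geometry!r}")


def generate_bundle(
    geometry: str = "straight",
    n_streamlines: int = 100,
    length: float = 80.0,
    radius: float = 2.0,
    seed: int = 0,
    n_points: int = 60,
    voxel_size: float = 2.0,
    name: str | None = None,
    jitter: str = "gaussian",
) -> BundlePhantom:
    """Bundle of jittered copies of a parametric centerline (mm units).

    Transverse jitter is applied in the local normal plane;
    ``jitter='gaussian'`` uses a smooth Gaussian offset (SD = radius/2,
    capped at radius) for realistic fuzzy bundles, ``jitter='disk'`` draws
    a constant offset uniform in the disk of the given radius, giving a
    bundle with hard cylindrical support for volume phantoms.  The
    generating curve is retained as ground truth for centerline-recovery
    tests.
    """
    if n_streamlines < 1:
        raise ValueError("need at least one streamline")
    curve = _parametric_curve(geometry, length, n_points)
    tangents = np.gradient(curve, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # local normal frames
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(tangents, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    rng = np.random.default_rng(seed)
    streamlines = []
    sd = radius / 2.0
    for _ in range(n_streamlines):
        if radius == 0:
            streamlines.append(curve.copy())
            continue
        if jitter == "disk":
            r = radius * np.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * np.pi)
            streamlines.append(
                curve + r * np.cos(ang) * n1 + r * np.sin(ang) * n2
            )
            continue
        if jitter != "gaussian":
            raise ValueError(f"unknown jitter model {jitter!r}")
        # smooth per-streamline offset: constant + slow sinusoid along arc
        a1, a2 = np.clip(rng.normal(0.0, sd, 2), -radius, radius)
        b1, b2 = np.clip(rng.normal(0.0, sd / 2.0, 2), -radius, radius)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.linspace(0, 2 * np.pi, n_points)
        off1 = a1 + b1 * np.sin(t + phase)
        off2 = a2 + b2 * np.cos(t + phase)
        streamlines.append(curve + off1[:, None] * n1 + off2[:, None] * n2)
    return BundlePhantom(
        name=name or geometry,
        streamlines=streamlines,
        centerline=curve,
        voxel_size=voxel_size,
    )


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

def voxelize(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """0-based voxel indices on a corner-anchored grid: floor(x / size)."""
    return np.floor(np.asarray(points) / voxel_size).astype(int)


def simulate_subject_signals(
    subject: Subject,
    phantom: BundlePhantom,
    scheme: GradientScheme,
    spec: CohortSpec,
    seed_offset: int = 0,
    l_max: int = 20,
):
    """Simulate per-voxel multishell signals for one subject on one bundle.

    Every voxel traversed by streamlines receives the Standard Model signal
    of its nearest along-tract node (ground-truth params from
    :func:`ground_truth_params` unless the phantom carries its own), with
    the local fiber axis set to the mean streamline tangent in the voxel,
    plus Rician noise at ``spec.snr``.

    Returns ``(signals, info)`` where ``signals`` is (n_voxels, n_volumes)
    and ``info`` is a dict with voxel indices, node assignment, fiber axes
    and the ground-truth :class:`SMParams` per voxel.
    """
    # gather streamline points and tangents
    pts, tans = [], []
    for s in phantom.streamlines:
        s = np.asarray(s, dtype=float)
        t = np.gradient(s, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        pts.append(s)
        tans.append(t)
    pts = np.concatenate(pts, axis=0)
    tans = np.concatenate(tans, axis=0)
    vox = voxelize(pts, phantom.voxel_size)
    uniq, inverse = np.unique(vox, axis=0, return_inverse=True)

    # node centers along the generating curve (equidistant in arc length)
    cl = phantom.centerline
    seglen = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    node_arc = np.linspace(0.0, arc[-1], 20)
    node_xyz = np.stack([np.interp(node_arc, arc, cl[:, k]) for k in range(3)], axis=1)

    if phantom.node_params is not None:
        node_params = list(phantom.node_params)
    else:
        node_params = [
            ground_truth_params(subject, phantom.name, n, spec) for n in range(20)
        ]

    n_vox = uniq.shape[0]
    axes = np.zeros((n_vox, 3))
    centers = np.zeros((n_vox, 3))
    for v in range(n_vox):
        sel = inverse == v
        centers[v] = pts[sel].mean(axis=0)
        a = tans[sel]
        # average tangents with antipodal alignment to the first
        sgn = np.sign(a @ a[0])
        sgn[sgn == 0] = 1.0
        m = (a * sgn[:, None]).mean(axis=0)
        axes[v] = m / np.linalg.norm(m)
    d2 = np.linalg.norm(centers[:, None, :] - node_xyz[None, :, :], axis=2)
    node_of_voxel = np.argmin(d2, axis=1)

    p_arr = {
        k: np.array([getattr(node_params[n], k) for n in node_of_voxel])
        for k in ("f", "d_c", "de_par", "de_perp", "kappa", "s0")
    }
    clean = sm_signal_batch(
        p_arr["f"], p_arr["d_c"], p_arr["de_par"], p_arr["de_perp"],
        p_arr["kappa"], axes, p_arr["s0"], scheme, l_max=l_max,
    )
    noise_seed = _stable_hash(spec.seed, subject.id, seed_offset)
    signals = add_noise(clean, spec.snr, model="rician", seed=noise_seed)
    info = {
        "voxels": uniq,
        "voxel_centers": centers,
        "node_of_voxel": node_of_voxel,
        "fiber_axes": axes,
        "node_params": node_params,
        "clean_signals": clean,
        "sigma": 1.0 / spec.snr if np.isfinite(spec.snr) else 0.0,
    }
    return signals, info


def export_signals_nifti(signals, info, voxel_size: float, path) -> None:
    """Write simulated per-voxel signals as a 4-D NIfTI volume.

    Voxels outside the bundle are zero; the affine carries the voxel size
    with the grid origin at the bundle's bounding-box corner.
    """
    import nibabel as nib

    vox = np.asarray(info["voxels"])
    origin = vox.min(axis=0)
    shape = tuple(vox.max(axis=0) - origin + 1) + (signals.shape[1],)
    data = np.zeros(shape, dtype=np.float32)
    idx = vox - origin
    data[idx[:, 0], idx[:, 1], idx[:, 2], :] = signals
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = origin * voxel_size
    nib.save(nib.Nifti1Image(data, affine), str(path))
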