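"""Biophysical principal components and cohort statistics.

Eleven diffusion metrics per subject are decorrelated by PCA on the
correlation matrix; Horn's parallel analysis selects the retained component
count; an oblique (oblimin, γ=0) rotation yields pattern loadings that are
allowed to correlate — the three resulting components group into an
intracellular-signal axis (FA and the high-b spherical moments), an
extracellular-mobility axis (the diffusivities and the low-b spherical
mean) and a tissue-complexity axis (the kurtosis metrics).  Sampling
adequacy is checked with the KMO statistic and Bartlett's sphericity test.

Cohort statistics: linear-vs-quadratic age models compared by AICc with
predicted values at the age-range endpoints; pooled-variance two-sample
t-tests with Hedge's small-sample-corrected g for group contrasts; the
Benjamini-Hochberg step-up procedure controls the FDR within each analysis
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.factor_rotation import rotate_factors

from .metrics import METRIC_NAMES

__all__ = [
    "REFERENCE_LOADINGS",
    "BPCResult",
    "GroupStats",
    "AgeStats",
    "kmo",
    "bartlett_sphericity",
    "parallel_analysis",
    "pca_oblique",
    "simulate_from_loadings",
    "fit_age_models",
    "group_compare",
    "bh_fdr",
    "run_full_analysis",
]

#: Published standardized three-component pattern loadings for the
#: 11-metric total-white-matter panel (rows follow METRIC_NAMES order,
#: columns: intracellular signal, extracellular mobility, tissue
#: complexity).  Used as a generating pattern for synthetic cohorts.
REFERENCE_LOADINGS = np.array(
    [
        [0.96, -0.13, -0.12],   # fa
        [-0.10, 0.97, 0.09],    # md
        [-0.30, 0.87, 0.09],    # rd
        [0.26, 1.02, 0.01],     # ad
        [0.02, 0.06, 0.99],     # mk
        [0.04, 0.07, 0.92],     # rk
        [-0.04, -0.14, 0.86],   # ak
        [0.08, -0.85, 0.25],    # smean_low
        [0.68, -0.11, 0.41],    # smean_high
        [1.00, 0.13, -0.03],    # svar_low
        [0.79, -0.10, 0.28],    # svar_high
    ]
)


@dataclass(frozen=True)
class BPCResult:
    """Oblique-rotated PCA solution on the metric panel."""

    loadings: np.ndarray              # pattern matrix, p x k
    structure: np.ndarray             # structure matrix, p x k
    variance_explained: np.ndarray    # post-rotation fractions, length k
    variance_explained_unrotated: np.ndarray
    component_correlations: np.ndarray
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    scores: np.ndarray                # subjects x k
    metric_names: tuple = METRIC_NAMES


@dataclass(frozen=True)
class GroupStats:
    """Pooled two-sample comparison with Hedge's g."""

    t: float
    df: int
    p: float
    g: float
    percent_diff: float


@dataclass(frozen=True)
class AgeStats:
    """Linear age model summary with AICc model comparison."""

    r2: float
    beta: float
    p: float
    aicc_linear: float
    aicc_quadratic: float
    pred8: float
    pred18: float
    percent_diff_8_18: float


# ---------------------------------------------------------------------------
# Adequacy statistics
# ---------------------------------------------------------------------------

def kmo(correlation_matrix: np.ndarray, ridge: float = 0.0) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy.

    KMO = Σ r²_ij / (Σ r²_ij + Σ q²_ij) over i≠j, with q the anti-image
    (negative partial) correlations from the inverse correlation matrix.
    A singular matrix raises; retry with ``ridge`` > 0 to regularize.
    """
    R = np.asarray(correlation_matrix, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or p < 2:
        raise ValueError("need a square correlation matrix with p >= 2")
    if ridge > 0:
        R = R + ridge * np.eye(p)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    try:
        M = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular correlation matrix; retry with ridge > 0"
        ) from exc
    if np.any(np.diag(M) <= 0):  # numerically indefinite inverse
        raise np.linalg.LinAlgError(
            "singular correlation matrix; retry with ridge > 0"
        )
    d = np.sqrt(np.diag(M))
    Q = -M / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(
    correlation_matrix: np.ndarray, n: int
) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: (chi2, df, p).

    chi2 = −(n−1−(2p+5)/6)·ln det(R), df = p(p−1)/2.
    """
    R = np.asarray(correlation_matrix, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need more subjects than variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("non-positive determinant in correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(sps.chi2.sf(max(chi2, 0.0), df))
    return float(chi2), int(df), pval


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------

def parallel_analysis(
    data: np.ndarray,
    n_sim: int = 200,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis on the correlation-matrix eigenvalues.

    Retains the leading components whose observed eigenvalue exceeds the
    given percentile of the rank-matched eigenvalues from ``n_sim`` seeded
    standard-normal datasets of the same shape (consecutive-from-top rule).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sim = np.empty((n_sim, p))
    for s in range(n_sim):
        Z = rng.standard_normal((n, p))
        sim[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresh = np.percentile(sim, percentile, axis=0)
    k = 0
    while k < p and obs[k] > thresh[k]:
        k += 1
    return k


# ---------------------------------------------------------------------------
# Oblique PCA
# ---------------------------------------------------------------------------

def pca_oblique(
    data: np.ndarray,
    n_components: int,
    standardize: tuple[np.ndarray, np.ndarray] | None = None,
) -> BPCResult:
    """PCA on the correlation matrix with oblimin (γ=0) rotation.

    Pattern loadings, component correlations, pre- and post-rotation
    variance-explained fractions, KMO/Bartlett adequacy statistics and
    regression-method component scores.  The sign convention makes each
    component's largest-|loading| entry positive.  ``standardize`` may
    supply (mean, sd) from a training cohort so scores for new subjects
    live on the training scale.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= p:
        raise ValueError("n_components must lie in 1..p")
    mu, sd = (X.mean(axis=0), X.std(axis=0, ddof=1)) if standardize is None else standardize
    if np.any(sd == 0):
        raise ValueError("constant metric column; cannot standardize")
    Z = (X - mu) / sd
    R = np.corrcoef(X, rowvar=False) if standardize is None else np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    A = evecs[:, :n_components] * np.sqrt(np.clip(evals[:n_components], 0, None))
    var_unrot = evals[:n_components] / p

    if n_components == 1:
        L, Phi = A.copy(), np.ones((1, 1))
    else:
        L, T = rotate_factors(A, "oblimin", 0.0, "oblique")
        Phi = T.T @ T
    # sign convention
    flips = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(n_components)])
    flips[flips == 0] = 1.0
    L = L * flips
    Phi = Phi * np.outer(flips, flips)
    S = L @ Phi  # structure matrix
    var_rot = np.sum(S**2, axis=0) / p

    kmo_v = np.nan
    for ridge in (0.0, 1e-8, 1e-3):
        try:
            kmo_v = kmo(R, ridge=ridge)
            break
        except np.linalg.LinAlgError:
            continue
    try:
        chi2, dfb, pb = bartlett_sphericity(R, n)
    except ValueError:
        chi2, dfb, pb = np.nan, p * (p - 1) // 2, np.nan
    scores = Z @ np.linalg.lstsq(R, S, rcond=None)[0]  # regression scores
    return BPCResult(
        loadings=L,
        structure=S,
        variance_explained=var_rot,
        variance_explained_unrotated=var_unrot,
        component_correlations=Phi,
        kmo=kmo_v,
        bartlett_chi2=chi2,
        bartlett_df=dfb,
        bartlett_p=pb,
        scores=scores,
    )


#: Default component correlations for the synthetic generator.  Signs follow
#: the reported developmental directions of the three components
#: (intracellular signal and tissue complexity rise with age, extracellular
#: mobility falls), magnitude 0.2-0.3 as a moderate oblique correlation.
DEFAULT_COMPONENT_CORR = np.array(
    [[1.0, -0.3, 0.3], [-0.3, 1.0, -0.2], [0.3, -0.2, 1.0]]
)


def simulate_from_loadings(
    loadings: np.ndarray,
    n: int,
    seed: int = 0,
    component_corr: np.ndarray | None = None,
    min_unique_variance: float = 0.05,
) -> np.ndarray:
    """Draw an (n, p) metric matrix from a pattern-loading model.

    Implied covariance Σ = ΛΦΛᵀ + Ψ with unique variances
    ψ_i = max(1 − communality_i, ``min_unique_variance``), rescaled to unit
    diagonal (pattern loadings from an oblique solution may exceed 1, so
    communalities can nominally pass 1).
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    Phi = DEFAULT_COMPONENT_CORR[:k, :k] if component_corr is None else component_corr
    common = L @ Phi @ L.T
    psi = np.clip(1.0 - np.diag(common), min_unique_variance, None)
    Sigma = common + np.diag(psi)
    d = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(d, d)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(p), Sigma, size=n, method="cholesky")


# ---------------------------------------------------------------------------
# Age and group statistics
# ---------------------------------------------------------------------------

def _aicc_ols(y: np.ndarray, X: np.ndarray) -> float:
    import statsmodels.api as sm

    model = sm.OLS(y, X).fit()
    k = X.shape[1]
    n = len(y)
    if n - k - 1 <= 0:
        return np.inf
    return float(model.aic + 2.0 * k * (k + 1) / (n - k - 1))


def fit_age_models(
    values: np.ndarray,
    ages: np.ndarray,
    pred_ages: tuple[float, float] = (8.0, 18.0),
) -> AgeStats:
    """Linear age regression with AICc comparison against the quadratic.

    Reports the linear model's r², unstandardized slope β and p-value,
    predicted values at the range endpoints and their percent difference
    (denominator: the younger prediction).
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(y) < 10:
        raise ValueError("need >= 10 subjects")
    if np.std(a) == 0:
        raise ValueError("constant ages")
    X1 = sm.add_constant(a)
    X2 = sm.add_constant(np.column_stack([a, a**2]))
    lin = sm.OLS(y, X1).fit()
    lo, hi = pred_ages
    pred8 = float(lin.params[0] + lin.params[1] * lo)
    pred18 = float(lin.params[0] + lin.params[1] * hi)
    pct = np.nan if pred8 == 0 else (pred18 - pred8) / pred8 * 100.0
    return AgeStats(
        r2=float(lin.rsquared),
        beta=float(lin.params[1]),
        p=float(lin.pvalues[1]),
        aicc_linear=_aicc_ols(y, X1),
        aicc_quadratic=_aicc_ols(y, X2),
        pred8=pred8,
        pred18=pred18,
        percent_diff_8_18=float(pct),
    )


def group_compare(values_a: np.ndarray, values_b: np.ndarray) -> GroupStats:
    """Student pooled-variance t-test of a vs b with Hedge's g.

    g = J·(m̄_a − m̄_b)/s_pooled, J = 1 − 3/(4(n1+n2)−9);
    percent_diff = (m̄_a − m̄_b)/m̄_b × 100.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = J * (a.mean() - b.mean()) / np.sqrt(sp2)
    pct = np.nan if b.mean() == 0 else (a.mean() - b.mean()) / b.mean() * 100.0
    return GroupStats(
        t=float(t), df=n1 + n2 - 2, p=float(p), g=float(g), percent_diff=float(pct)
    )


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: (rejection mask, data-dependent threshold).

    The threshold is p_(i*) for the largest i* with p_(i*) ≤ i*·q/m, or 0.0
    when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p)
    ranked = p[order]
    crit = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(ranked <= crit)
    reject = np.zeros(m, dtype=bool)
    if passing.size == 0:
        return reject, 0.0
    i_star = passing[-1]
    reject[order[: i_star + 1]] = True
    return reject, float(ranked[i_star])


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

ALL_STAGES = ("metrics", "bpc", "age", "group", "tractometry", "bsm")

#: metrics expected to rise in the deletion group (intracellular signal)
#: and to fall (extracellular mobility), given the default generator effects
INTRACELLULAR_METRICS = ("fa", "smean_high", "svar_low", "svar_high")
EXTRACELLULAR_METRICS = ("md", "rd")


def run_full_analysis(
    spec=None,
    scheme=None,
    stages: tuple = ALL_STAGES,
    fdr_q: float = 0.05,
    bundle_kwargs: dict | None = None,
    pa_sims: int = 200,
    bsm_n_starts: int = 16,
    brain_volume: float = 1.2e6,
) -> dict:
    """Simulate a cohort and run the full analysis; returns report tables.

    Stages: per-subject signal simulation and the 11-metric panel on the
    Rician-corrected segment-averaged signal; BPC construction on the TD
    cohort with scores for everyone; TD age regressions and DEL-vs-ASM
    comparisons, each BH-FDR corrected as one family; along-tract profiles
    with alignment and tract volume; segment-averaged Standard Model fits.
    Fully deterministic given ``spec.seed``.
    """
    from .bsm_fit import (
        fit_standard_model,
        magnitude_bias_correct,
        rotinv_from_signal,
        segment_average,
    )
    from .metrics import compute_metric_vector
    from .protocol import make_default_protocol
    from .synthetic_cohort import (
        CohortSpec,
        generate_bundle,
        generate_cohort,
        simulate_subject_signals,
        subjects_to_frame,
    )
    from .tractometry import align_profiles, compute_centerline, project_to_nodes, tract_volume

    spec = CohortSpec() if spec is None else spec
    scheme = make_default_protocol(spec.seed) if scheme is None else scheme
    bk = dict(geometry="straight", n_streamlines=30, length=60.0, radius=2.0,
              n_points=40, voxel_size=2.0, name="bundle")
    if bundle_kwargs:
        bk.update(bundle_kwargs)
    bk.setdefault("seed", spec.seed + 17)
    phantom = generate_bundle(**bk)
    subjects = generate_cohort(spec)
    report: dict = {"subjects": subjects_to_frame(subjects)}

    sigma = 1.0 / spec.snr if np.isfinite(spec.snr) else 0.0
    metric_rows = []
    bsm_rows = []
    profile_rows = []
    centerline = compute_centerline(phantom.streamlines) if (
        "tractometry" in stages
    ) else None
    for subj in subjects:
        signals, info = simulate_subject_signals(subj, phantom, scheme, spec)
        corrected = magnitude_bias_correct(signals, sigma) if sigma else signals
        avg = corrected.mean(axis=0)
        mv = compute_metric_vector(avg, scheme)
        row = {"id": subj.id, "age": subj.age, "sex": subj.sex,
               "group": subj.group, "asm": subj.asm}
        row.update({m: getattr(mv, m) for m in METRIC_NAMES})
        metric_rows.append(row)

        if "bsm" in stages:
            invs = rotinv_from_signal(signals, scheme, sigma=sigma)
            fit = fit_standard_model(
                segment_average(invs), n_starts=bsm_n_starts, seed=spec.seed
            )
            bsm_rows.append(
                {
                    "id": subj.id, "age": subj.age, "group": subj.group,
                    "asm": subj.asm, "f": fit.params.f, "d_c": fit.params.d_c,
                    "de_par": fit.params.de_par, "de_perp": fit.params.de_perp,
                    "kappa": fit.params.kappa, "p2": fit.p2,
                    "residual": fit.fit_residual, "ambiguous": fit.ambiguous,
                }
            )
        if "tractometry" in stages:
            invs = rotinv_from_signal(signals, scheme, sigma=sigma)
            smean_high = np.array([inv.s_l0[-1] for inv in invs])
            centers = info["voxel_centers"]
            node_vals, _ = project_to_nodes(smean_high, centers, centerline)
            profile_rows.append(node_vals)

    metrics_df = pd.DataFrame(metric_rows)
    report["metrics"] = metrics_df
    td = metrics_df[metrics_df.group == "TD"]
    asm = metrics_df[metrics_df.asm]
    dele = metrics_df[metrics_df.group == "DEL"]

    if "bpc" in stages:
        X_td = td[list(METRIC_NAMES)].to_numpy()
        k = parallel_analysis(X_td, n_sim=pa_sims, seed=spec.seed + 1)
        k = max(k, 1)
        bpc = pca_oblique(X_td, n_components=k)
        mu = X_td.mean(axis=0)
        sd = X_td.std(axis=0, ddof=1)
        Z_all = (metrics_df[list(METRIC_NAMES)].to_numpy() - mu) / sd
        R = np.corrcoef(X_td, rowvar=False)
        scores_all = Z_all @ np.linalg.lstsq(R, bpc.structure, rcond=None)[0]
        report["bpc"] = bpc
        report["bpc_loadings"] = pd.DataFrame(
            bpc.loadings, index=METRIC_NAMES,
            columns=[f"BPC{i + 1}" for i in range(k)],
        )
        report["bpc_scores"] = pd.DataFrame(
            scores_all, columns=[f"BPC{i + 1}" for i in range(k)]
        ).assign(id=metrics_df.id.to_numpy())

    if "age" in stages:
        rows = []
        for m in METRIC_NAMES:
            st = fit_age_models(td[m].to_numpy(), td.age.to_numpy(),
                                pred_ages=spec.td_age_range)
            rows.append({"quantity": m, **st.__dict__})
        age_df = pd.DataFrame(rows)
        rej, thr = bh_fdr(age_df.p.to_numpy(), q=fdr_q)
        age_df["fdr_significant"] = rej
        age_df.attrs["fdr_threshold"] = thr
        report["age_stats"] = age_df

    if "group" in stages:
        rows = []
        for m in METRIC_NAMES:
            st = group_compare(dele[m].to_numpy(), asm[m].to_numpy())
            rows.append({"quantity": m, **st.__dict__})
        grp_df = pd.DataFrame(rows)
        rej, thr = bh_fdr(grp_df.p.to_numpy(), q=fdr_q)
        grp_df["fdr_significant"] = rej
        grp_df.attrs["fdr_threshold"] = thr
        report["group_stats"] = grp_df

    if "bsm" in stages:
        bsm_df = pd.DataFrame(bsm_rows)
        report["bsm_params"] = bsm_df
        rows = []
        a = bsm_df[bsm_df.asm]
        d = bsm_df[bsm_df.group == "DEL"]
        if len(a) >= 2 and len(d) >= 2:
            for par in ("f", "d_c", "de_par", "de_perp", "kappa"):
                st = group_compare(d[par].to_numpy(), a[par].to_numpy())
                rows.append({"quantity": par, **st.__dict__})
            bsm_grp = pd.DataFrame(rows)
            rej, thr = bh_fdr(bsm_grp.p.to_numpy(), q=fdr_q)
            bsm_grp["fdr_significant"] = rej
            bsm_grp.attrs["fdr_threshold"] = thr
            report["bsm_group_stats"] = bsm_grp

    if "tractometry" in stages:
        profiles = np.vstack(profile_rows)
        aligned, align_params = align_profiles(profiles)
        report["profiles"] = pd.DataFrame(
            aligned, columns=[f"node{n:02d}" for n in range(aligned.shape[1])]
        ).assign(id=metrics_df.id.to_numpy())
        count, frac = tract_volume(
            phantom.streamlines, phantom.voxel_size, brain_volume
        )
        report["volumes"] = pd.DataFrame(
            [{"tract": phantom.name, "voxel_count": count, "volume_fraction": frac}]
        )
    return report
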