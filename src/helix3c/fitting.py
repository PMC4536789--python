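"""Weighted nonlinear least-squares fitting of contact-decay models.

Fits the unconstrained-chain and statistical-helix models (and globule
power laws) to relative contact-frequency profiles, mirroring an ``nls``-
style weighted least-squares objective: minimise
``sum_i w_i * (X_i - model(s_i))**2`` with ``w_i = 1/sem_i**2`` when every
observation carries a positive SEM, uniform weights otherwise.

The helix objective is oscillatory in (D, P); a deterministic multi-start
grid plus a start seeded from the nested unconstrained fit guards against
local minima.  Standard errors are asymptotic, from the Jacobian at the
optimum.  Note that in the unconstrained model K and L enter only through
the product ``K * (L*S)**-3``: with L free, only that amplitude and S are
identifiable and the (K, L) split is a reported convention anchored at the
optimizer start.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    HelixParams,
    LocalChromatinParams,
    PowerLawParams,
    helix_turn_length,
    model_curve,
    powerlaw_frequency,
)

__all__ = [
    "ContactObservation",
    "ContactProfile",
    "FitOptions",
    "FitResult",
    "fit_unconstrained",
    "fit_helix",
    "fit_powerlaw",
    "r_squared",
    "compare_fits",
    "pool_profiles",
    "profile_from_arrays",
]

TAD_CLASSES = ("gene-rich", "gene-poor", "gene-desert", "unknown")


@dataclass(frozen=True)
class ContactObservation:
    """One (separation, frequency) reading from a 3C-style profile."""

    separation: float  # kb, > 0
    frequency: float   # relative contact frequency, >= 0
    sem: float | None = None
    anchor_id: str = ""
    locus: str = ""

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError(f"separation must be > 0, got {self.separation}")
        if self.frequency < 0:
            raise ValueError(f"frequency must be >= 0, got {self.frequency}")
        if self.sem is not None and self.sem < 0:
            raise ValueError(f"sem must be >= 0, got {self.sem}")


@dataclass(frozen=True)
class ContactProfile:
    """Ordered contact observations from one locus / pooled anchor set."""

    observations: tuple[ContactObservation, ...]
    cell_type: str = ""
    tad_class: str = "unknown"
    fixed_L: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if self.tad_class not in TAD_CLASSES:
            raise ValueError(f"unknown tad_class {self.tad_class!r}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def separations(self) -> np.ndarray:
        return np.array([o.separation for o in self.observations])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([o.frequency for o in self.observations])

    @property
    def sems(self) -> np.ndarray | None:
        vals = [o.sem for o in self.observations]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)


def profile_from_arrays(separations, frequencies, sems=None, **kwargs) -> ContactProfile:
    seps = np.asarray(separations, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    if seps.shape != freqs.shape:
        raise ValueError("separations and frequencies must have equal length")
    sem_arr = None if sems is None else np.asarray(sems, dtype=float)
    obs = tuple(
        ContactObservation(
            separation=float(s),
            frequency=float(x),
            sem=None if sem_arr is None else float(sem_arr[i]),
        )
        for i, (s, x) in enumerate(zip(seps, freqs))
    )
    return ContactProfile(observations=obs, **kwargs)


def pool_profiles(profiles, **kwargs) -> ContactProfile:
    """Pool observations of several profiles into one (Fig.-style compiled
    graph: fits are performed on pooled anchors within a TAD class)."""
    obs = tuple(itertools.chain.from_iterable(p.observations for p in profiles))
    defaults = dict(
        cell_type=profiles[0].cell_type,
        tad_class=profiles[0].tad_class,
        fixed_L=profiles[0].fixed_L,
    )
    defaults.update(kwargs)
    return ContactProfile(observations=obs, **defaults)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration (all defaults are the package defaults).

    weight_mode: "sem" uses w = 1/sem**2 when every SEM is present and
    positive (uniform otherwise); "uniform" forces equal weights.
    """

    weight_mode: str = "sem"
    d_starts: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0)
    p_starts: tuple[float, ...] = (50.0, 150.0, 250.0, 400.0)
    s_starts: tuple[float, ...] = (2.0, 4.0)
    l_start: float = 10.5
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    #: evaluation budget per multi-start exploration run; the single best
    #: solution is then polished with the full ``max_nfev`` budget.
    max_nfev_explore: int = 1_000
    max_nfev: int = 10_000


DEFAULT_OPTIONS = FitOptions()


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit.

    ``params`` holds every model parameter (fitted and fixed); ``stderr``
    holds asymptotic standard errors for the free parameters only.
    ``sh_kb`` (Eq.-4 helix-turn length from the fitted D, P, L) is present
    only for helix fits.
    """

    model_id: str
    params: dict[str, float]
    stderr: dict[str, float]
    r_squared: float
    ssr: float
    n_obs: int
    converged: bool
    n_starts: int
    sh_kb: float | None = None

    def to_row(self) -> dict:
        row = {"model": self.model_id, "n_obs": self.n_obs,
               "r_squared": self.r_squared, "ssr": self.ssr,
               "converged": self.converged, "n_starts": self.n_starts}
        for k, v in self.params.items():
            row[k] = v
        for k, v in self.stderr.items():
            row[f"se_{k}"] = v
        if self.sh_kb is not None:
            row["sh_kb"] = self.sh_kb
        return row


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (about the observed
    mean).  May be negative for poor nonlinear fits."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _weights(profile: ContactProfile, options: FitOptions) -> np.ndarray:
    n = len(profile)
    if options.weight_mode == "uniform":
        return np.ones(n)
    sems = profile.sems
    if sems is None or np.any(sems <= 0):
        return np.ones(n)
    return 1.0 / sems**2


def _optimal_scale(x_obs, m_unit, w) -> float:
    """Closed-form weighted LS optimum of X = K * m for the linear scale K."""
    denom = float(np.sum(w * m_unit**2))
    if denom <= 0 or not np.isfinite(denom):
        return 1.0
    return max(float(np.sum(w * x_obs * m_unit)) / denom, 1e-300)


def _stderr(jac: np.ndarray, ssr: float, n: int, names) -> dict[str, float]:
    p = jac.shape[1]
    dof = max(n - p, 1)
    jtj = jac.T @ jac
    cov = np.linalg.pinv(jtj) * (ssr / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return {name: float(v) for name, v in zip(names, se)}


def _run_starts(residual, starts, bounds, options: FitOptions):
    """Run bounded least squares from every start; return the best result."""
    best = None
    n_ok = 0
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), bounds[0], bounds[1])
        try:
            res = least_squares(
                residual, x0, bounds=bounds, method="trf", x_scale="jac",
                ftol=options.ftol, xtol=options.xtol, gtol=options.gtol,
                max_nfev=options.max_nfev_explore,
            )
        except Exception:
            continue
        if res.success:
            n_ok += 1
        if best is None or (2 * res.cost) < (2 * best.cost):
            best = res
    if best is not None and np.all(best.x > np.asarray(bounds[0])):
        # polish away from the bounds with plain Levenberg-Marquardt,
        # which converges tighter on narrow ridges than bounded trf
        try:
            res = least_squares(residual, best.x, method="lm",
                                ftol=options.ftol, xtol=options.xtol,
                                gtol=options.gtol, max_nfev=options.max_nfev)
            if (res.cost <= best.cost
                    and np.all(res.x >= np.asarray(bounds[0]))
                    and np.all(res.x <= np.asarray(bounds[1]))):
                if res.success:
                    n_ok += 1
                best = res
        except Exception:
            pass
    return best, n_ok, len(starts)


def _residual_scale(x_obs, w) -> float:
    """Characteristic weighted-residual magnitude; dividing residuals by it
    keeps the optimizer's gradient thresholds meaningful for profiles whose
    frequencies live on arbitrarily small relative scales."""
    ref = float(np.max(np.abs(x_obs) * np.sqrt(w)))
    return ref if ref > 0 else 1.0


def _finalize(model_id, profile, sw_fit, ref, best, n_ok, n_starts, free_names,
              make_params, helix_from=None) -> FitResult:
    x_obs = profile.frequencies
    ssr = float(2 * best.cost) * ref**2
    params = make_params(best.x)
    pred = x_obs + best.fun / sw_fit
    r2 = r_squared(x_obs, pred)
    se = _stderr(best.jac, float(2 * best.cost), len(profile), free_names)
    sh = None
    if helix_from is not None:
        helix, l_val = helix_from(best.x)
        sh = helix_turn_length(helix, l_val)
    return FitResult(
        model_id=model_id, params=params, stderr=se, r_squared=r2, ssr=ssr,
        n_obs=len(profile), converged=bool(best.success and n_ok > 0),
        n_starts=n_starts, sh_kb=sh,
    )


def fit_unconstrained(profile: ContactProfile, l_mode: str = "fixed",
                      options: FitOptions = DEFAULT_OPTIONS) -> FitResult:
    """Fit the unconstrained-chain model.

    l_mode="fixed" fits (K, S) with L taken from ``profile.fixed_L``;
    l_mode="free" fits (K, L, S) jointly — note the K/L amplitude
    degeneracy documented in the module docstring.
    """
    if l_mode not in ("fixed", "free"):
        raise ValueError("l_mode must be 'fixed' or 'free'")
    if len(profile) < 4:
        raise ValueError("need at least 4 observations to fit")
    if l_mode == "fixed" and profile.fixed_L is None:
        raise ValueError("l_mode='fixed' requires profile.fixed_L")
    s = profile.separations
    x_obs = profile.frequencies
    w = _weights(profile, options)
    ref = _residual_scale(x_obs, w)
    sw = np.sqrt(w) / ref

    if l_mode == "fixed":
        l_val = float(profile.fixed_L)

        def residual(x):
            p = LocalChromatinParams(K=x[0], L=l_val, S=x[1])
            return sw * (model_curve(s, p) - x_obs)

        starts = []
        for s0 in options.s_starts:
            m_unit = model_curve(s, LocalChromatinParams(K=1.0, L=l_val, S=s0))
            starts.append([_optimal_scale(x_obs, m_unit, w), s0])
        bounds = ([0.0, 1e-6], [np.inf, np.inf])
        best, n_ok, n_starts = _run_starts(residual, starts, bounds, options)
        return _finalize(
            "unconstrained", profile, sw, ref, best, n_ok, n_starts,
            ["K", "S"],
            lambda x: {"K": float(x[0]), "L": l_val, "S": float(x[1])},
        )

    def residual(x):
        p = LocalChromatinParams(K=x[0], L=x[1], S=x[2])
        return sw * (model_curve(s, p) - x_obs)

    starts = []
    for s0 in options.s_starts:
        m_unit = model_curve(
            s, LocalChromatinParams(K=1.0, L=options.l_start, S=s0))
        starts.append([_optimal_scale(x_obs, m_unit, w), options.l_start, s0])
    bounds = ([0.0, 1e-6, 1e-6], [np.inf, np.inf, np.inf])
    best, n_ok, n_starts = _run_starts(residual, starts, bounds, options)
    return _finalize(
        "unconstrained", profile, sw, ref, best, n_ok, n_starts,
        ["K", "L", "S"],
        lambda x: {"K": float(x[0]), "L": float(x[1]), "S": float(x[2])},
    )


def fit_helix(profile: ContactProfile, L: float | None = None,
              options: FitOptions = DEFAULT_OPTIONS) -> FitResult:
    """Fit the statistical-helix model over (K, S, D, P) with L fixed.

    L defaults to ``profile.fixed_L`` (mouse analyses fix L from the
    nucleosome repeat length).  A deterministic multi-start grid over
    (D, P, S), with K given its closed-form optimum at each start, plus a
    degenerate-helix start seeded from the unconstrained fit, guards the
    oscillatory objective against local minima.
    """
    if L is None:
        L = profile.fixed_L
    if L is None:
        raise ValueError("helix fit requires a fixed L (argument or profile.fixed_L)")
    if len(profile) < 5:
        raise ValueError("need at least 5 observations for a helix fit")
    l_val = float(L)
    s = profile.separations
    x_obs = profile.frequencies
    w = _weights(profile, options)
    ref = _residual_scale(x_obs, w)
    sw = np.sqrt(w) / ref

    def residual(x):
        p = LocalChromatinParams(K=x[0], L=l_val, S=x[1])
        return sw * (model_curve(s, p, HelixParams(D=x[2], P=x[3])) - x_obs)

    starts = []
    for d0, p0, s0 in itertools.product(
            options.d_starts, options.p_starts, options.s_starts):
        m_unit = model_curve(
            s, LocalChromatinParams(K=1.0, L=l_val, S=s0),
            HelixParams(D=d0, P=p0))
        starts.append([_optimal_scale(x_obs, m_unit, w), s0, d0, p0])
    # degenerate-helix start from the nested unconstrained fit: guarantees
    # the helix optimum is never worse than the unconstrained one.
    try:
        base = fit_unconstrained(
            replace(profile, fixed_L=l_val), "fixed", options)
        starts.append([base.params["K"], base.params["S"], 0.0, 200.0])
    except Exception:
        pass
    bounds = ([0.0, 1e-6, 0.0, 1e-6], [np.inf] * 4)
    best, n_ok, n_starts = _run_starts(residual, starts, bounds, options)
    return _finalize(
        "helix", profile, sw, ref, best, n_ok, n_starts,
        ["K", "S", "D", "P"],
        lambda x: {"K": float(x[0]), "L": l_val, "S": float(x[1]),
                   "D": float(x[2]), "P": float(x[3])},
        helix_from=lambda x: (HelixParams(D=float(x[2]), P=float(x[3])), l_val),
    )


def fit_powerlaw(profile: ContactProfile,
                 options: FitOptions = DEFAULT_OPTIONS) -> FitResult:
    """Fit X = k * s**alpha by linear-scale (weighted) nonlinear least
    squares — not a log-log linear regression; a log-log regression only
    seeds the start."""
    if len(profile) < 3:
        raise ValueError("need at least 3 observations to fit a power law")
    s = profile.separations
    x_obs = profile.frequencies
    w = _weights(profile, options)
    ref = _residual_scale(x_obs, w)
    sw = np.sqrt(w) / ref

    pos = x_obs > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(s[pos]), np.log(x_obs[pos]), 1)
        k0, a0 = float(np.exp(intercept)), float(slope)
    else:
        k0, a0 = max(float(np.median(x_obs * s)), 1e-12), -1.0

    def residual(x):
        return sw * (x[0] * s ** x[1] - x_obs)

    bounds = ([1e-300, -10.0], [np.inf, 10.0])
    best, n_ok, n_starts = _run_starts(residual, [[k0, a0]], bounds, options)
    return _finalize(
        "powerlaw", profile, sw, ref, best, n_ok, n_starts,
        ["k", "alpha"],
        lambda x: {"k": float(x[0]), "alpha": float(x[1])},
    )


def compare_fits(fits) -> pd.DataFrame:
    """Rank fits of one profile by R² (descending); ties broken by
    model_id for a stable order."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    rows = [f.to_row() for f in fits]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["r_squared", "model"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
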