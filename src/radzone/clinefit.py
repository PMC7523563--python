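"""Geographic cline models with exponential introgression tails.

The core model is the standard hybrid-zone sigmoid
``y(x) = 1 / (1 + exp(-4 (x - c) / w))`` with center ``c`` (km, where the
focal allele frequency crosses 1/2) and width ``w`` (km, the inverse of the
maximum slope).  Optional exponential tails of length ``delta`` and slope
``tau`` (the Szymura-Barton tension-zone parameterization) replace the
sigmoid beyond ``c - delta_L`` / ``c + delta_R``; the tail joins the core
continuously.  Fitting maximizes the binomial likelihood of population
allele counts by bounded multistart local optimization; 95% intervals come
from the profile likelihood (drop of 1.92 log-units), and tail models are
compared by AIC.

The focal allele is the one whose frequency increases along the transect
(here: the B. spinosus-diagnostic allele, 0 at the northeastern end).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

TAIL_CONFIGS = ("none", "left", "right", "mirror", "both")

#: free-parameter names per tail configuration (p_min/p_max are fixed)
_PARAM_NAMES = {
    "none": ["c", "w"],
    "left": ["c", "w", "delta_L", "tau_L"],
    "right": ["c", "w", "delta_R", "tau_R"],
    "mirror": ["c", "w", "delta", "tau"],
    "both": ["c", "w", "delta_L", "tau_L", "delta_R", "tau_R"],
}

_EPS = 1e-9


@dataclass
class ClineModel:
    """Sigmoid cline with optional exponential tails.

    Unused tail parameters are ignored per ``tail_config``; ``mirror`` ties
    the two tails (delta_L = delta_R, tau_L = tau_R).
    """

    c: float
    w: float
    tail_config: str = "none"
    delta_L: float = 0.0
    delta_R: float = 0.0
    tau_L: float = 1.0
    tau_R: float = 1.0
    p_min: float = 0.0
    p_max: float = 1.0

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError("cline width w must be positive")
        if self.tail_config not in TAIL_CONFIGS:
            raise ValueError(f"tail_config must be one of {TAIL_CONFIGS}")
        if self.delta_L < 0 or self.delta_R < 0:
            raise ValueError("tail lengths must be >= 0")
        if not (0 <= self.tau_L <= 1 and 0 <= self.tau_R <= 1):
            raise ValueError("tail slopes tau must be in [0, 1]")
        if not self.p_min < self.p_max:
            raise ValueError("p_min must be < p_max")

    @property
    def k(self) -> int:
        """Number of free parameters (2, 4 or 6)."""
        return len(_PARAM_NAMES[self.tail_config])

    def theta(self) -> np.ndarray:
        if self.tail_config == "mirror":
            return np.array([self.c, self.w, self.delta_L, self.tau_L])
        return np.array([getattr(self, p) for p in _PARAM_NAMES[self.tail_config]])

    @classmethod
    def from_theta(cls, theta, tail_config: str, p_min: float = 0.0,
                   p_max: float = 1.0) -> "ClineModel":
        c, w = theta[0], theta[1]
        kw = dict(c=float(c), w=float(w), tail_config=tail_config,
                  p_min=p_min, p_max=p_max)
        if tail_config == "left":
            kw.update(delta_L=float(theta[2]), tau_L=float(theta[3]))
        elif tail_config == "right":
            kw.update(delta_R=float(theta[2]), tau_R=float(theta[3]))
        elif tail_config == "mirror":
            kw.update(delta_L=float(theta[2]), tau_L=float(theta[3]),
                      delta_R=float(theta[2]), tau_R=float(theta[3]))
        elif tail_config == "both":
            kw.update(delta_L=float(theta[2]), tau_L=float(theta[3]),
                      delta_R=float(theta[4]), tau_R=float(theta[5]))
        return cls(**kw)


def _unit_cline(x: np.ndarray, c: float, w: float, tail_config: str,
                dL: float, tL: float, dR: float, tR: float) -> np.ndarray:
    """Cline on the [0, 1] scale before p_min/p_max rescaling."""
    x = np.asarray(x, dtype=float)
    y = expit(4.0 * (x - c) / w)
    left = tail_config in ("left", "mirror", "both")
    right = tail_config in ("right", "mirror", "both")
    if left:
        mask = x < c - dL
        if mask.any():
            y_join = expit(-4.0 * dL / w)  # = 1/(1+exp(4 dL / w))
            denom = w * (1.0 + np.exp(-4.0 * dL / w))
            # exponent <= 0 wherever the mask holds; clip to keep the
            # unmasked branch of np.where from overflowing
            expo = np.minimum(4.0 * tL * (x - c + dL) / denom, 0.0)
            y = np.where(mask, y_join * np.exp(expo), y)
    if right:
        mask = x > c + dR
        if mask.any():
            y_join = expit(-4.0 * dR / w)
            denom = w * (1.0 + np.exp(-4.0 * dR / w))
            expo = np.minimum(-4.0 * tR * (x - c - dR) / denom, 0.0)
            y = np.where(mask, 1.0 - y_join * np.exp(expo), y)
    return y


def cline_value(x, m: ClineModel):
    """Evaluate the cline at position(s) ``x`` (km)."""
    dL, dR = m.delta_L, m.delta_R
    tL, tR = m.tau_L, m.tau_R
    if m.tail_config == "mirror":
        dR, tR = dL, tL
    y = _unit_cline(np.asarray(x, dtype=float), m.c, m.w, m.tail_config, dL, tL, dR, tR)
    out = m.p_min + (m.p_max - m.p_min) * y
    return out if np.ndim(x) else float(out)


def cline_loglik(m: ClineModel, freqs: pd.DataFrame) -> float:
    """Binomial log-likelihood of a population frequency table under ``m``."""
    if len(freqs) == 0:
        raise ValueError("frequency table is empty")
    x = freqs["distance_km"].to_numpy(dtype=float)
    n = freqs["n_alleles"].to_numpy(dtype=float)
    k = freqs["focal_allele_count"].to_numpy(dtype=float)
    y = np.clip(cline_value(x, m), _EPS, 1.0 - _EPS)
    return float(np.sum(k * np.log(y) + (n - k) * np.log1p(-y)))


@dataclass
class ClineFit:
    """A fitted cline: point estimates, likelihood, AIC and diagnostics."""

    model: ClineModel
    logL: float
    aic: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_pops: int = 0
    converged: bool = True
    hit_bounds: dict[str, bool] = field(default_factory=dict)

    @property
    def any_bound_hit(self) -> bool:
        return any(self.hit_bounds.values())


def _default_bounds(x: np.ndarray, tail_config: str) -> list[tuple[float, float]]:
    span = float(x.max() - x.min())
    b = [(float(x.min()) - 50.0, float(x.max()) + 50.0), (0.1, 2.0 * span)]
    n_tail = (len(_PARAM_NAMES[tail_config]) - 2) // 2
    for _ in range(n_tail):
        b += [(0.0, span), (0.0, 1.0)]
    return b


def _moment_initials(x: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Center from the 0.5 crossing (linear interpolation); width from the
    distance between the 0.2 and 0.8 crossings."""
    def crossing(level):
        d = p - level
        for i in range(len(x) - 1):
            if d[i] == 0:
                return float(x[i])
            if d[i] * d[i + 1] < 0:
                f = d[i] / (d[i] - d[i + 1])
                return float(x[i] + f * (x[i + 1] - x[i]))
        if d[-1] == 0:
            return float(x[-1])
        return float(x[np.argmin(np.abs(d))])

    c0 = crossing(0.5)
    w0 = abs(crossing(0.8) - crossing(0.2))
    span = float(x.max() - x.min())
    w0 = float(np.clip(w0, 0.5, span))
    return c0, w0


def fit_cline(
    freqs: pd.DataFrame,
    tail_config: str = "none",
    bounds: list[tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    compute_ci: bool = True,
) -> ClineFit:
    """Maximum-likelihood cline fit by bounded multistart optimization.

    Starts are jittered around moment-based initials (0.5-crossing center,
    0.2-0.8 crossing width).  95% intervals are profile-likelihood based
    (logL drop of 1.92); parameters within numerical tolerance of the
    optimizer box are flagged in ``hit_bounds``.
    """
    if tail_config not in TAIL_CONFIGS:
        raise ValueError(f"tail_config must be one of {TAIL_CONFIGS}")
    names = _PARAM_NAMES[tail_config]
    k = len(names)
    x = freqs["distance_km"].to_numpy(dtype=float)
    n = freqs["n_alleles"].to_numpy(dtype=float)
    cnt = freqs["focal_allele_count"].to_numpy(dtype=float)
    p_obs = cnt / n
    if len(freqs) < k:
        raise ValueError(f"need >= {k} populations for a {k}-parameter fit")
    if not ((cnt > 0).any() and (cnt < n).any()):
        raise ValueError("all frequencies 0 or all 1: nothing to fit")

    bounds = bounds or _default_bounds(x, tail_config)
    c0, w0 = _moment_initials(x, p_obs)
    theta0 = [c0, w0] + [1.0, 0.5] * ((k - 2) // 2)
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

    def nll(theta):
        y = _unit_theta(x, theta, tail_config)
        y = np.clip(y, _EPS, 1.0 - _EPS)
        return -np.sum(cnt * np.log(y) + (n - cnt) * np.log1p(-y))

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.asarray(theta0, dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        jit = np.asarray(theta0, dtype=float).copy()
        jit[0] += rng.normal(0, max(w0, 2.0))
        jit[1] *= np.exp(rng.normal(0, 0.5))
        for j in range(2, k):
            jit[j] = rng.uniform(lo[j], hi[j])
        starts.append(np.clip(jit, lo, hi))

    best = None
    any_ok = False
    for s in starts:
        res = optimize.minimize(nll, s, method="L-BFGS-B", bounds=bounds)
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    logL = -float(best.fun)
    model = ClineModel.from_theta(theta_hat, tail_config)
    tol = 1e-6
    hit = {
        nm: bool(theta_hat[i] <= lo[i] + tol * max(1.0, abs(lo[i]))
                 or theta_hat[i] >= hi[i] - tol * max(1.0, abs(hi[i])))
        for i, nm in enumerate(names)
    }
    ci = {}
    if compute_ci:
        ci = _profile_ci(nll, theta_hat, logL, bounds, names)
    fit = ClineFit(
        model=model,
        logL=logL,
        aic=2.0 * k - 2.0 * logL,
        ci=ci,
        n_pops=len(freqs),
        converged=bool(any_ok),
        hit_bounds=hit,
    )
    return fit


def _unit_theta(x, theta, tail_config):
    c, w = theta[0], max(theta[1], 1e-12)
    dL = tL = dR = tR = 0.0
    if tail_config == "left":
        dL, tL = theta[2], theta[3]
    elif tail_config == "right":
        dR, tR = theta[2], theta[3]
    elif tail_config == "mirror":
        dL = dR = theta[2]
        tL = tR = theta[3]
    elif tail_config == "both":
        dL, tL, dR, tR = theta[2], theta[3], theta[4], theta[5]
    return _unit_cline(x, c, w, tail_config, dL, tL, dR, tR)


_CHI2_95_DROP = 1.92  # chi2(1df, 0.95) / 2


def _profile_ci(nll, theta_hat, logL_max, bounds, names):
    """95% profile-likelihood intervals: where the re-optimized logL has
    dropped 1.92 units below its maximum."""
    target = -logL_max + _CHI2_95_DROP  # on the nll scale
    k = len(theta_hat)
    ci = {}

    def prof(i, v):
        if k == 1:
            return nll(np.array([v]))
        free = [j for j in range(k) if j != i]

        def sub(th_free):
            th = np.empty(k)
            th[i] = v
            th[free] = th_free
            return nll(th)

        res = optimize.minimize(
            sub, theta_hat[free], method="L-BFGS-B",
            bounds=[bounds[j] for j in free],
        )
        return res.fun

    for i, nm in enumerate(names):
        lo_b, hi_b = bounds[i]
        scale = max(abs(theta_hat[i]) * 0.1, (hi_b - lo_b) * 0.01, 1e-3)
        ends = []
        for direction in (-1.0, +1.0):
            limit = lo_b if direction < 0 else hi_b
            v_in, step = theta_hat[i], scale
            v_out = None
            for _ in range(60):
                v = v_in + direction * step
                if direction * (v - limit) >= 0:
                    v = limit
                if prof(i, v) > target:
                    v_out = v
                    break
                v_in = v
                if v == limit:
                    break
                step *= 1.8
            if v_out is None:
                ends.append(limit)
            else:
                try:
                    ends.append(
                        float(optimize.brentq(
                            lambda v: prof(i, v) - target, min(v_in, v_out),
                            max(v_in, v_out), xtol=1e-4,
                        ))
                    )
                except ValueError:
                    ends.append(v_out)
        ci[nm] = (min(ends), max(ends))
    return ci


def model_select(
    freqs: pd.DataFrame,
    configs: tuple[str, ...] = TAIL_CONFIGS,
    n_starts: int = 20,
    seed: int = 0,
    compute_ci: bool = False,
) -> tuple[ClineFit, dict[str, ClineFit]]:
    """Fit every requested tail configuration; pick minimal AIC.

    Ties break toward fewer parameters; only converged fits compete.
    """
    table: dict[str, ClineFit] = {}
    errors: dict[str, Exception] = {}
    for i, cfg in enumerate(configs):
        try:
            table[cfg] = fit_cline(freqs, cfg, n_starts=n_starts,
                                   seed=seed + i, compute_ci=compute_ci)
        except ValueError as e:
            errors[cfg] = e
    candidates = {c: f for c, f in table.items() if f.converged} or table
    if not candidates:
        raise ValueError(f"no cline model could be fitted: {errors}")
    best_cfg = min(candidates, key=lambda c: (round(candidates[c].aic, 9),
                                              candidates[c].model.k))
    return candidates[best_cfg], table


def fit_all_loci(
    tables: dict[str, pd.DataFrame],
    tail_config: str = "both",
    n_starts: int = 6,
    seed: int = 0,
) -> tuple[dict[str, ClineFit], pd.DataFrame]:
    """Fit each locus independently (default: full 6-parameter model for
    comparability across loci) and summarize the parameter distributions.

    Returns ``(fits, summary)`` where ``summary`` has the median and the
    2.5%/97.5% quantiles of the fitted centers and widths; failed loci are
    excluded from the summary and counted in ``summary.attrs['n_failed']``.
    """
    if not tables:
        raise ValueError("no loci supplied")
    fits: dict[str, ClineFit] = {}
    failed = 0
    for i, (locus_id, tab) in enumerate(tables.items()):
        try:
            fits[locus_id] = fit_cline(tab, tail_config, n_starts=n_starts,
                                       seed=seed + i, compute_ci=False)
        except ValueError:
            failed += 1
    cs = np.array([f.model.c for f in fits.values()])
    ws = np.array([f.model.w for f in fits.values()])
    rows = []
    for name, vals in (("c", cs), ("w", ws)):
        if len(vals):
            rows.append({
                "parameter": name,
                "median": float(np.median(vals)),
                "q2.5": float(np.percentile(vals, 2.5)),
                "q97.5": float(np.percentile(vals, 97.5)),
                "n": len(vals),
            })
    summary = pd.DataFrame(rows)
    summary.attrs["n_failed"] = failed
    return fits, summary


def tail_asymmetry_test(fits: list[ClineFit] | dict[str, ClineFit]):
    """Paired Wilcoxon signed-rank test of tail asymmetry across loci.

    Compares the left (B. bufo side) against the right (B. spinosus side)
    tail length delta and slope tau over per-locus both-tail fits.  Loci
    whose fits did not converge, or whose two delta estimates both sit on
    the optimizer bounds, are dropped (and counted).
    Returns a dict with two-sided p-values, per-side medians and n_used.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    usable = []
    dropped = 0
    for f in fits:
        if f.model.tail_config != "both" or not f.converged:
            dropped += 1
            continue
        if f.hit_bounds.get("delta_L") and f.hit_bounds.get("delta_R"):
            dropped += 1
            continue
        usable.append(f)
    if len(usable) < 6:
        raise ValueError(
            f"need >= 6 usable both-tail fits, got {len(usable)} "
            f"({dropped} dropped)"
        )
    dL = np.array([f.model.delta_L for f in usable])
    dR = np.array([f.model.delta_R for f in usable])
    tL = np.array([f.model.tau_L for f in usable])
    tR = np.array([f.model.tau_R for f in usable])

    def paired_p(a, b):
        diff = a - b
        if np.all(diff == 0):
            return 1.0
        return float(stats.wilcoxon(a, b, zero_method="wilcox",
                                    alternative="two-sided").pvalue)

    return {
        "delta_p": paired_p(dL, dR),
        "tau_p": paired_p(tL, tR),
        "median_delta_L": float(np.median(dL)),
        "median_delta_R": float(np.median(dR)),
        "median_tau_L": float(np.median(tL)),
        "median_tau_R": float(np.median(tR)),
        "n_used": len(usable),
        "n_dropped": dropped,
    }
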