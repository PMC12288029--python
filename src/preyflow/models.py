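"""Random-intercept GLMMs and AICc model comparison for the trial metrics.

Each per-trial response is modelled with a family matched to its support —
beta (logit link) for the proportion of frames above threshold, gamma (log
link) for the mean magnitude within those frames, negative binomial (NB2,
log link) for the number of detection events, and Gaussian (identity) for
the mean event duration — always with a random intercept for the holding
tank of origin.  A null model (tank intercept only) is compared against
seven single-hypothesis alternatives: temperature, turbidity, their additive
and interactive combinations, group size, trial order (repeated testing),
and minutes from midnight (time of day).  Models are ranked by AICc, with
differences above 2 units read as strong support.

The marginal likelihood integrates the tank intercept out by adaptive
Gauss-Hermite quadrature (default 15 nodes; 1 node is the Laplace
approximation): per tank, the integrand's mode and curvature are found by
Newton iteration and the quadrature grid is centred and scaled there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

RESPONSE_KINDS = ("proportion", "mean_magnitude", "n_events", "mean_duration")

RESPONSE_FAMILY = {
    "proportion": "beta",
    "mean_magnitude": "gamma",
    "n_events": "negbinom",
    "mean_duration": "gaussian",
}

RESPONSE_COLUMN = {
    "proportion": "prop_above",
    "mean_magnitude": "mean_mag_above",
    "n_events": "n_events",
    "mean_duration": "mean_event_duration",
}

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "Null": (),
    "Temperature": ("temp",),
    "Turbidity": ("turb",),
    "Temp+Turb": ("temp", "turb"),
    "Temp×Turb": ("temp", "turb", "temp_x_turb"),
    "NumberOfFish": ("n_fish_z",),
    "RepeatedTesting": ("trial_order",),
    "MinFromMidnight": ("minutes_z",),
}


# ---------------------------------------------------------------------------
# Families: log-density and its first two derivatives w.r.t. the linear
# predictor eta.  `aux` is the family parameter on log scale (log sd, log
# shape, log size, log precision).


class _Gaussian:
    name = "gaussian"
    support = "real"

    @staticmethod
    def logpdf(y, eta, aux):
        s2 = np.exp(2 * aux)
        return -0.5 * np.log(2 * np.pi * s2) - (y - eta) ** 2 / (2 * s2)

    @staticmethod
    def score(y, eta, aux):
        return (y - eta) / np.exp(2 * aux)

    @staticmethod
    def hess(y, eta, aux):
        return np.full_like(eta, -np.exp(-2 * aux))


class _Gamma:
    name = "gamma"
    support = "positive"

    @staticmethod
    def logpdf(y, eta, aux):
        a = np.exp(aux)
        return a * aux - special.gammaln(a) + (a - 1) * np.log(y) - a * eta - a * y * np.exp(-eta)

    @staticmethod
    def score(y, eta, aux):
        a = np.exp(aux)
        return a * (y * np.exp(-eta) - 1.0)

    @staticmethod
    def hess(y, eta, aux):
        a = np.exp(aux)
        return -a * y * np.exp(-eta)


class _NegBinom:
    """NB2: Var = mu + mu^2 / r, log link; aux = log r."""

    name = "negbinom"
    support = "count"

    @staticmethod
    def logpdf(y, eta, aux):
        r = np.exp(aux)
        mu = np.exp(eta)
        return (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * aux
            + y * eta
            - (y + r) * np.log(r + mu)
        )

    @staticmethod
    def score(y, eta, aux):
        r = np.exp(aux)
        mu = np.exp(eta)
        return y - (y + r) * mu / (r + mu)

    @staticmethod
    def hess(y, eta, aux):
        r = np.exp(aux)
        mu = np.exp(eta)
        return -(y + r) * r * mu / (r + mu) ** 2


class _Beta:
    """Mean-precision beta regression, logit link; aux = log phi."""

    name = "beta"
    support = "unit"

    @staticmethod
    def logpdf(y, eta, aux):
        phi = np.exp(aux)
        mu = special.expit(eta)
        a = mu * phi
        b = (1 - mu) * phi
        return (
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1) * np.log(y)
            + (b - 1) * np.log1p(-y)
        )

    @staticmethod
    def score(y, eta, aux):
        phi = np.exp(aux)
        mu = special.expit(eta)
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
        return phi * (ystar - mustar) * mu * (1 - mu)

    @staticmethod
    def hess(y, eta, aux):
        phi = np.exp(aux)
        mu = special.expit(eta)
        dmu = mu * (1 - mu)
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
        dmustar = phi * (special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi))
        return phi * (-dmustar * dmu**2 + (ystar - mustar) * (1 - 2 * mu) * dmu)


FAMILIES = {f.name: f for f in (_Gaussian, _Gamma, _NegBinom, _Beta)}


# ---------------------------------------------------------------------------
# Model specification and design matrix


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: fixed terms + family; tank intercept is implied."""

    name: str
    fixed_terms: tuple[str, ...]
    family: str

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.fixed_terms)  # intercept included


def build_candidate_set(response_kind: str) -> list[ModelSpec]:
    """The null model plus the seven single-hypothesis alternatives."""
    if response_kind not in RESPONSE_KINDS:
        raise ValueError(f"unknown response_kind {response_kind!r}")
    family = RESPONSE_FAMILY[response_kind]
    return [ModelSpec(name, terms, family) for name, terms in MODEL_TERMS.items()]


def build_design(metadata: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Covariate columns for the candidate models, plus scaling info.

    Temperature and turbidity are 0/1 dummies (22 C / 0 NTU reference);
    trial order is numeric 1-4; group size and minutes from midnight are
    centred and scaled for optimizer stability.  Returns the design frame
    and a dict of (mean, sd) used for the scaled columns so coefficients can
    be reported on the original scale.
    """
    temp = (metadata["temperature_C"].to_numpy() == 29).astype(float)
    turb = (metadata["turbidity_NTU"].to_numpy() == 5).astype(float)
    scales: dict[str, tuple[float, float]] = {}

    def zscore(col: str, name: str) -> np.ndarray:
        x = metadata[col].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std())
        sd = sd if sd > 0 else 1.0
        scales[name] = (mu, sd)
        return (x - mu) / sd

    design = pd.DataFrame(
        {
            "temp": temp,
            "turb": turb,
            "temp_x_turb": temp * turb,
            "n_fish_z": zscore("n_fish", "n_fish_z"),
            "trial_order": metadata["trial_order"].to_numpy(dtype=float),
            "minutes_z": zscore("minutes_from_midnight", "minutes_z"),
        },
        index=metadata.index,
    )
    design["tank"] = metadata["tank"].to_numpy()
    return design, scales


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate GLMM."""

    spec: ModelSpec
    coefficients: dict[str, float]
    #: slopes of centred/scaled covariates mapped back to natural units
    coefficients_original_scale: dict[str, float]
    se: dict[str, float]
    dispersion: float  # sd (gaussian), shape (gamma), size (NB), precision (beta)
    re_sd: float  # random-intercept standard deviation
    log_likelihood: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_quad: int
    params: np.ndarray = field(repr=False, default=None)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc undefined: need n > k + 1")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def compress_unit_interval(y: np.ndarray) -> np.ndarray:
    """Shrink proportions off the boundary: (y (n-1) + 0.5) / n.

    Applied to the whole vector whenever any value sits at 0 or 1, so the
    beta likelihood is finite; interior-only vectors pass through untouched.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        n = y.size
        return (y * (n - 1) + 0.5) / n
    return y


def _start_values(family, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Heuristic starts: link-scale least squares + moment dispersion."""
    if family.name == "gaussian":
        z = y
    elif family.name in ("gamma",):
        z = np.log(y)
    elif family.name == "negbinom":
        z = np.log(y + 0.5)
    else:
        z = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta0
    rvar = max(float(resid.var()), 1e-4)
    if family.name == "gaussian":
        aux0 = 0.5 * math.log(rvar)
    elif family.name == "gamma":
        aux0 = math.log(max(1.0 / rvar, 0.1))
    elif family.name == "negbinom":
        m = max(float(y.mean()), 0.1)
        v = max(float(y.var()), m * 1.05)
        aux0 = math.log(np.clip(m**2 / (v - m), 0.05, 1e4))
    else:
        aux0 = math.log(10.0)
    sb0 = math.log(max(0.3 * math.sqrt(rvar), 1e-3))
    return np.concatenate([beta0, [aux0, sb0]])


def _marginal_nll_factory(family, y, X, cluster_idx, n_clusters, n_quad):
    """Negative marginal log-likelihood with the tank intercept integrated
    out by adaptive Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights)
    p = X.shape[1]
    warm_b = np.zeros(n_clusters)  # warm start for the inner Newton

    def cluster_logsum(eta):
        return np.bincount(cluster_idx, weights=eta, minlength=n_clusters)

    def nll(theta: np.ndarray) -> float:
        beta, aux, log_sb = theta[:p], theta[p], theta[p + 1]
        sb2 = math.exp(2.0 * log_sb)
        eta0 = X @ beta

        b = warm_b.copy()
        g1 = None
        for _ in range(60):
            eta = eta0 + b[cluster_idx]
            with np.errstate(all="ignore"):
                sc = family.score(y, eta, aux)
                h = family.hess(y, eta, aux)
            if not (np.all(np.isfinite(sc)) and np.all(np.isfinite(h))):
                return 1e10
            g1 = cluster_logsum(sc) - b / sb2
            g2 = np.minimum(cluster_logsum(h) - 1.0 / sb2, -1e-10)
            step = np.clip(g1 / g2, -3.0, 3.0)
            b = b - step
            if np.max(np.abs(g1)) < 1e-9:
                break
        # curvature at the mode
        eta = eta0 + b[cluster_idx]
        with np.errstate(all="ignore"):
            h = family.hess(y, eta, aux)
        g2 = np.minimum(cluster_logsum(h) - 1.0 / sb2, -1e-10)
        s = np.sqrt(-1.0 / g2)

        # adaptive nodes: b_jk = bhat_j + sqrt(2) s_j x_k
        bk = b[:, None] + math.sqrt(2.0) * s[:, None] * nodes[None, :]
        eta_k = eta0[:, None] + bk[cluster_idx]
        with np.errstate(all="ignore"):
            lp = family.logpdf(y[:, None], eta_k, aux)
        if not np.all(np.isfinite(lp)):
            return 1e10
        g_k = np.zeros((n_clusters, n_quad))
        for k in range(n_quad):
            g_k[:, k] = cluster_logsum(lp[:, k])
        g_k += -0.5 * math.log(2 * math.pi * sb2) - bk**2 / (2 * sb2)
        terms = log_w[None, :] + nodes[None, :] ** 2 + g_k
        ll = np.sum(special.logsumexp(terms, axis=1) + 0.5 * np.log(2.0 * s**2))
        if not np.isfinite(ll):
            return 1e10
        warm_b[:] = b
        return -ll

    return nll


def fit_glmm(
    y,
    metadata: pd.DataFrame,
    spec: ModelSpec,
    n_quad: int = 15,
    seed: int = 0,
    max_restarts: int = 5,
    compute_se: bool = True,
) -> FitResult:
    """Fit one candidate GLMM by maximum likelihood.

    ``y`` is the response vector aligned with ``metadata`` rows; missing
    responses (NaN) are dropped case-wise with ``n`` recorded accordingly.
    Non-convergence after jittered restarts is flagged, never silently
    returned as converged.
    """
    family = FAMILIES[spec.family]
    design, scales = build_design(metadata)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    design = design.loc[keep]
    n = int(y.size)
    if n == 0:
        raise ValueError("no usable observations")

    if family.support == "unit":
        y = compress_unit_interval(y)
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("beta family needs responses strictly inside (0, 1)")
    elif family.support == "positive" and np.any(y <= 0):
        raise ValueError("gamma family needs positive responses")
    elif family.support == "count" and (np.any(y < 0) or np.any(y != np.round(y))):
        raise ValueError("negative-binomial family needs non-negative integers")

    cols = ["const"] + list(spec.fixed_terms)
    X = np.column_stack([np.ones(n)] + [design[t].to_numpy() for t in spec.fixed_terms])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design")
    tanks, cluster_idx = np.unique(design["tank"].to_numpy(), return_inverse=True)
    if len(tanks) < 1:
        raise ValueError("need at least one tank level")

    p = X.shape[1]
    k = p + 2  # fixed effects + family dispersion + RE variance
    nll = _marginal_nll_factory(family, y, X, cluster_idx, len(tanks), n_quad)
    x0 = _start_values(family, y, X)
    bounds = [(None, None)] * p + [(-10.0, 12.0), (-8.0, 4.0)]

    rng = np.random.default_rng(seed)
    attempts: list[tuple[float, bool, optimize.OptimizeResult]] = []
    for attempt in range(max_restarts + 1):
        xi = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.3, size=x0.size)
        res = optimize.minimize(
            nll, xi, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
        )
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun < 1e9
        attempts.append((float(res.fun), ok, res))
        if ok:
            break
    _, converged, best = min(attempts, key=lambda t: t[0])

    theta = best.x
    ll = -float(best.fun)
    se = {c: float("nan") for c in cols}
    if compute_se and converged:
        H = _numerical_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.all(d[:p] > 0):
                se = {c: float(np.sqrt(d[i])) for i, c in enumerate(cols)}
        except np.linalg.LinAlgError:
            pass

    coefficients = {c: float(theta[i]) for i, c in enumerate(cols)}
    original = dict(coefficients)
    natural_names = {"n_fish_z": "n_fish", "minutes_z": "minutes_from_midnight"}
    for term, (mu, sd) in scales.items():
        if term in original:
            slope = original[term]
            original[natural_names.get(term, term)] = slope / sd
            original["const"] -= slope * mu / sd
            del original[term]
    return FitResult(
        spec=spec,
        coefficients=coefficients,
        coefficients_original_scale=original,
        se=se,
        dispersion=float(np.exp(theta[p])),
        re_sd=float(np.exp(theta[p + 1])),
        log_likelihood=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        converged=bool(converged),
        n_quad=n_quad,
        params=theta,
    )


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    hi = h * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hi[i]
            ej = np.zeros(n); ej[j] = hi[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hi[i] * hi[j])
    return H


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """AICc ranking table: best first, with support annotations.

    ``delta_aicc`` is the distance to the best model; models within 2 units
    are annotated "equivalent" unless they carry more parameters than an
    equally-supported smaller model, in which case the extra-parameter
    caveat is flagged (the similar AICc likely reflects the added parameter,
    not a better fit).
    """
    usable = [f for f in fits if np.isfinite(f.aicc)]
    if sum(f.converged for f in usable) < 2:
        raise ValueError("need at least 2 converged fits to rank")
    rows = sorted(usable, key=lambda f: f.aicc)
    best_aicc = rows[0].aicc
    table = pd.DataFrame(
        {
            "model": [f.spec.name for f in rows],
            "delta_aicc": [f.aicc - best_aicc for f in rows],
            "df": [f.k for f in rows],
            "aicc": [f.aicc for f in rows],
            "loglik": [f.log_likelihood for f in rows],
            "converged": [f.converged for f in rows],
        }
    )
    gap_next = table["delta_aicc"].iloc[1] if len(table) > 1 else np.inf
    support = []
    caveat = []
    for i, row in table.iterrows():
        if row["delta_aicc"] == 0:
            support.append("strong" if gap_next > 2 else "equivalent")
        elif row["delta_aicc"] <= 2:
            support.append("equivalent")
        else:
            support.append("unsupported")
        caveat.append(
            bool(
                row["delta_aicc"] <= 2
                and any(
                    (table["df"].iloc[j] < row["df"]) and (table["aicc"].iloc[j] <= row["aicc"])
                    for j in range(len(table))
                    if j != i
                )
            )
        )
    table["support"] = support
    table["extra_param_caveat"] = caveat
    return table


def rank_all(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSE_KINDS,
    levels: tuple[float, ...] | None = None,
    n_quad: int = 15,
    seed: int = 0,
    compute_se: bool = False,
) -> dict[tuple[str, float], pd.DataFrame]:
    """Fit all 8 candidates for every response x percentile level and rank.

    ``metrics`` is the tidy per-trial metrics table; rows are matched to
    ``metadata`` by trial_id.  Returns {(response_kind, level): ranking}.
    """
    if levels is None:
        levels = tuple(sorted(metrics["percentile_level"].unique(), reverse=True))
    meta_indexed = metadata.set_index("trial_id")
    out: dict[tuple[str, float], pd.DataFrame] = {}
    for level in levels:
        sub = metrics[metrics["percentile_level"] == level]
        meta = meta_indexed.loc[sub["trial_id"]].reset_index()
        for kind in responses:
            y = sub[RESPONSE_COLUMN[kind]].to_numpy(dtype=float)
            fits = [
                fit_glmm(y, meta, spec, n_quad=n_quad, seed=seed, compute_se=compute_se)
                for spec in build_candidate_set(kind)
            ]
            out[(kind, level)] = rank_models(fits)
    return out


def simulate_family_response(
    family: str, eta: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw responses from a family given the linear predictor (link scale).

    Used for parameter-recovery simulations: ``dispersion`` is the sd
    (gaussian), shape (gamma), size (NB2) or precision (beta).
    """
    if family == "gaussian":
        return rng.normal(eta, dispersion)
    if family == "gamma":
        mu = np.exp(eta)
        return rng.gamma(dispersion, mu / dispersion)
    if family == "negbinom":
        mu = np.exp(eta)
        r = dispersion
        return rng.negative_binomial(r, r / (r + mu)).astype(float)
    if family == "beta":
        mu = special.expit(eta)
        return rng.beta(mu * dispersion, (1 - mu) * dispersion)
    raise ValueError(f"unknown family {family!r}")
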