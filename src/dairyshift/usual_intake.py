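"""Usual-intake estimation from two repeated 24-h recalls.

The measurement-error model follows the NCI two-part approach for short-term
dietary instruments.  Daily intake on consumption days is modeled on a
Box-Cox-transformed scale as a linear mixed model

    g(Y_ij; lam) = beta0 + beta_seq * 1[day j is recall 2]
                 + beta_wk * 1[day j is a weekend day] + u_i + e_ij,

with person random effect u_i ~ N(0, sigma2_u) and within-person day-to-day
error e_ij ~ N(0, sigma2_e).  For episodically consumed foods (here: total
dairy) a companion logistic mixed model describes the probability of any
consumption on a day.  The usual (long-run average) intake of person i is

    T_i = p_i * E_e[ g^{-1}(x' beta + u_i + e) ],

with the nuisance covariates balanced out (recall sequence set to Day 1,
weekend weighted 2/7), estimated by Monte Carlo over pseudo-persons.

Everything is fitted by weighted maximum likelihood, each person's cluster
log-likelihood multiplied by the first-day survey sampling weight, so that
the resulting distribution of usual intake is population-representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "AmountModelParams",
    "ProbabilityModelParams",
    "UsualIntakeDistribution",
    "FitError",
    "LAMBDA_GRID",
    "boxcox_transform",
    "boxcox_inverse",
    "back_transform_mean",
    "fit_amount_model",
    "fit_consumption_model",
    "simulate_usual_distribution",
]

#: Box-Cox exponent search grid used by profile-likelihood selection.
LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))

WEEKEND_SHARE = 2.0 / 7.0


class FitError(RuntimeError):
    """Model fitting failed to converge; carries the best-so-far parameters."""

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


# ---------------------------------------------------------------------------
# Box-Cox transform
# ---------------------------------------------------------------------------

def boxcox_transform(x, lam: float):
    """g(x; lam) = (x^lam - 1)/lam, with g(x; 0) = ln x.  Requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox transform requires strictly positive values")
    if lam == 0:
        out = np.log(x)
    else:
        out = (np.power(x, lam) - 1.0) / lam
    return out.item() if out.ndim == 0 else out


def boxcox_inverse(z, lam: float):
    """Inverse transform g^{-1}(z; lam) = (1 + lam z)^{1/lam}; e^z at lam=0."""
    z = np.asarray(z, dtype=float)
    if lam == 0:
        out = np.exp(z)
    else:
        base = 1.0 + lam * z
        if np.any(base <= 0):
            raise ValueError("inverse Box-Cox undefined: 1 + lam*z <= 0")
        out = np.power(base, 1.0 / lam)
    return out.item() if out.ndim == 0 else out


def back_transform_mean(
    z,
    sigma2_e: float,
    lam: float,
    method: str = "auto",
    n_nodes: int = 9,
    clip: bool = False,
):
    """E[g^{-1}(z + e; lam)] for e ~ N(0, sigma2_e): the usual-amount mean.

    Exact closed forms are used at the boundary exponents: lam=1 gives z+1
    (linear inverse, the noise averages out) and lam=0 gives the lognormal
    mean exp(z + sigma2_e/2).  For interior lam the default is a second-order
    Taylor expansion g^{-1}(z) + 0.5*sigma2_e*(1-lam)*(1+lam z)^{1/lam-2};
    ``method='quadrature'`` evaluates the expectation by Gauss-Hermite
    quadrature instead.

    The Taylor approximation requires g^{-1} to be defined throughout a
    +/- 3 sd neighbourhood of z; outside that region a ValueError is raised
    unless ``clip=True``, in which case a clamped quadrature evaluation is
    substituted (negative-domain mass treated as zero intake).
    """
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    if sigma2_e < 0:
        raise ValueError("sigma2_e must be >= 0")
    sig = np.sqrt(sigma2_e)

    if lam == 1:
        out = z + 1.0
    elif lam == 0:
        out = np.exp(z + 0.5 * sigma2_e)
    elif method in ("auto", "taylor"):
        base_lo = 1.0 + lam * (z - 3.0 * sig)
        valid = base_lo > 0
        if not np.all(valid) and not clip:
            raise ValueError(
                "Taylor back-transformation invalid: inverse undefined within "
                "+/- 3 sd of the transformed-scale value"
            )
        out = np.empty_like(z)
        zb = np.where(valid, z, 0.0)
        base = 1.0 + lam * zb
        out_valid = np.power(base, 1.0 / lam) + (
            0.5 * sigma2_e * (1.0 - lam) * np.power(base, 1.0 / lam - 2.0)
        )
        out = np.where(valid, out_valid, _quadrature_mean(z, sig, lam, n_nodes))
    elif method == "quadrature":
        out = _quadrature_mean(z, sig, lam, n_nodes)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = np.maximum(out, 0.0)
    return out.item() if scalar else out


def _quadrature_mean(z: np.ndarray, sig: float, lam: float, n_nodes: int) -> np.ndarray:
    """Gauss-Hermite E[g^{-1}(z+e)], clamping the inverse to 0 off-domain."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    zz = z[..., None] + np.sqrt(2.0) * sig * nodes
    base = np.maximum(1.0 + lam * zz, 0.0)
    vals = np.power(base, 1.0 / lam)
    return vals @ (weights / np.sqrt(np.pi))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmountModelParams:
    """Fitted consumption-day amount model on the Box-Cox scale."""

    lam: float
    beta: tuple[float, float, float]  # intercept, sequence (Day2), weekend
    sigma2_u: float
    sigma2_e: float
    loglik: float
    converged: bool = True
    shift: float = 0.0  # epsilon added to zero amounts before transforming
    n_participants: int = 0

    @property
    def intercept(self) -> float:
        return self.beta[0]

    @property
    def weekend_effect(self) -> float:
        return self.beta[2]


@dataclass(frozen=True)
class ProbabilityModelParams:
    """Fitted any-consumption logistic mixed model."""

    beta: tuple[float, float, float]  # intercept, sequence (Day2), weekend
    sigma2_u: float
    rho: float = 0.0  # correlation with the amount random effect (0 = uncorrelated)
    loglik: float = np.nan
    converged: bool = True
    degenerate: bool = False  # every observed day was a consumption day

    def usual_probability(self, v) -> np.ndarray:
        """Long-run consumption probability for random effect v (weekend 2/7,
        sequence at Day 1)."""
        b0, _, bwk = self.beta
        v = np.asarray(v, dtype=float)
        return (1.0 - WEEKEND_SHARE) * special.expit(b0 + v) + WEEKEND_SHARE * special.expit(
            b0 + bwk + v
        )


@dataclass
class UsualIntakeDistribution:
    """Weighted Monte Carlo draws of usual intake (original scale).

    ``m`` pseudo-persons are generated per source participant; each draw keeps
    its source participant's id and survey weight so that weighted statistics
    remain population-representative.
    """

    values: np.ndarray
    source_ids: np.ndarray
    weights: np.ndarray
    nutrient: str
    seed: int
    m: int = field(default=0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.source_ids = np.asarray(self.source_ids)
        if self.values.shape != self.weights.shape or self.values.shape != self.source_ids.shape:
            raise ValueError("values, weights and source_ids must be aligned")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if np.any(self.values < 0):
            raise ValueError("usual-intake draws must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def weighted_mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))

    def percentile(self, q) -> np.ndarray | float:
        """Weighted percentile(s) of usual intake (q in 0..100)."""
        order = np.argsort(self.values, kind="stable")
        v = self.values[order]
        w = self.weights[order]
        cum = np.cumsum(w) - 0.5 * w
        cum /= np.sum(w)
        return np.interp(np.asarray(q, dtype=float) / 100.0, cum, v)

    def shifted(self, per_source: dict, nutrient: str | None = None) -> "UsualIntakeDistribution":
        """New distribution with each draw shifted by its source participant's
        entry in ``per_source`` (missing source -> 0)."""
        add = np.array([float(per_source.get(s, 0.0)) for s in self.source_ids])
        return UsualIntakeDistribution(
            values=self.values + add,
            source_ids=self.source_ids.copy(),
            weights=self.weights.copy(),
            nutrient=nutrient or self.nutrient,
            seed=self.seed,
            m=self.m,
        )


# ---------------------------------------------------------------------------
# Amount model (weighted linear mixed model, clusters of size <= 2)
# ---------------------------------------------------------------------------

class _Clusters:
    """Pre-indexed per-person day structure for the <=2-day mixed model."""

    def __init__(self, person_ids, seq2, weekend, weights):
        person_ids = np.asarray(person_ids)
        seq2 = np.asarray(seq2, dtype=float)
        weekend = np.asarray(weekend, dtype=float)
        weights = np.asarray(weights, dtype=float)
        uniq, inverse, counts = np.unique(person_ids, return_inverse=True, return_counts=True)
        if np.any(counts > 2):
            raise ValueError("at most 2 recall days per participant")
        self.n_persons = len(uniq)
        # normalize person weights to mean 1 (scale-free likelihood)
        wp = np.zeros(self.n_persons)
        wp[inverse] = weights  # weight is a person attribute repeated per day
        wp = wp / wp.mean()
        X = np.column_stack([np.ones(len(person_ids)), seq2, weekend])

        order = np.lexsort((np.arange(len(person_ids)), inverse))
        inv_sorted = inverse[order]
        first = np.searchsorted(inv_sorted, np.arange(self.n_persons), side="left")
        self.pair_mask = counts == 2
        pairs = np.where(self.pair_mask)[0]
        singles = np.where(~self.pair_mask)[0]
        i1 = order[first[pairs]]
        i2 = order[first[pairs] + 1]
        js = order[first[singles]]

        self.X1, self.X2 = X[i1], X[i2]
        self.Xs = X[js]
        self.w_pair = wp[pairs]
        self.w_single = wp[singles]
        self.idx_pair1, self.idx_pair2, self.idx_single = i1, i2, js
        self.n_days = len(person_ids)
        self.day_weight = wp[inverse]

    def split(self, y: np.ndarray):
        return y[self.idx_pair1], y[self.idx_pair2], y[self.idx_single]

    def gls_beta(self, y1, y2, ys, a: float, b: float) -> np.ndarray:
        """Weighted GLS fixed effects for variance components (a, b)."""
        det = b * (b + 2.0 * a)
        c11 = (a + b) / det
        c12 = -a / det
        w = self.w_pair
        A = (
            np.einsum("i,ij,ik->jk", w * c11, self.X1, self.X1)
            + np.einsum("i,ij,ik->jk", w * c11, self.X2, self.X2)
            + np.einsum("i,ij,ik->jk", w * c12, self.X1, self.X2)
            + np.einsum("i,ij,ik->jk", w * c12, self.X2, self.X1)
        )
        rhs = (
            self.X1.T @ (w * (c11 * y1 + c12 * y2))
            + self.X2.T @ (w * (c11 * y2 + c12 * y1))
        )
        if len(self.Xs):
            ws = self.w_single / (a + b)
            A += np.einsum("i,ij,ik->jk", ws, self.Xs, self.Xs)
            rhs += self.Xs.T @ (ws * ys)
        # lstsq tolerates rank-deficient designs (e.g. a constant covariate
        # column when no recall day falls on a weekend)
        beta, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        return beta

    def profile_loglik(self, y: np.ndarray, a: float, b: float) -> tuple[float, np.ndarray]:
        """Weighted Gaussian log-likelihood with beta profiled out by GLS."""
        y1, y2, ys = self.split(y)
        beta = self.gls_beta(y1, y2, ys, a, b)
        det = b * (b + 2.0 * a)
        r1 = y1 - self.X1 @ beta
        r2 = y2 - self.X2 @ beta
        quad = ((a + b) * (r1 * r1 + r2 * r2) - 2.0 * a * r1 * r2) / det
        ll = -0.5 * np.sum(self.w_pair * (np.log(det) + quad + 2.0 * np.log(2.0 * np.pi)))
        if len(self.Xs):
            rs = ys - self.Xs @ beta
            ll += -0.5 * np.sum(
                self.w_single
                * (np.log(a + b) + rs * rs / (a + b) + np.log(2.0 * np.pi))
            )
        return ll, beta

    def start_values(self, y: np.ndarray) -> tuple[float, float]:
        """Moment starts: OLS residual within/between decomposition."""
        X = np.vstack([self.X1, self.X2, self.Xs])
        yy = np.concatenate(self.split(y))
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        y1, y2, _ = self.split(y)
        r1 = y1 - self.X1 @ beta
        r2 = y2 - self.X2 @ beta
        if len(r1):
            b0 = 0.5 * float(np.average((r1 - r2) ** 2, weights=self.w_pair))
        else:
            b0 = 0.0
        tot = float(np.var(np.concatenate([r1, r2])) if len(r1) else 1.0)
        a0 = max(tot - b0, 0.05 * max(tot, 1e-8))
        return max(a0, 1e-8), max(b0, 1e-8)


def fit_amount_model(
    amounts,
    person_ids,
    seq2,
    weekend,
    weights,
    lam_grid=LAMBDA_GRID,
    shift: float | None = None,
) -> AmountModelParams:
    """Fit the Box-Cox amount model by weighted ML with profile-likelihood
    selection of the transform exponent over ``lam_grid``.

    Parameters are day-level arrays; ``weights`` is the (first-day) survey
    weight of the day's participant.  ``shift`` is added to all amounts before
    transforming when zeros are present (default: half the smallest positive
    amount); it is recorded on the returned params and undone downstream.
    """
    amounts = np.asarray(amounts, dtype=float)
    if len(amounts) == 0:
        raise ValueError("no consumption days to fit")
    if np.any(amounts < 0):
        raise ValueError("amounts must be >= 0")
    if shift is None:
        shift = 0.0
        if np.any(amounts == 0):
            positive = amounts[amounts > 0]
            if len(positive) == 0:
                raise ValueError("all amounts are zero; nothing to fit")
            shift = 0.5 * float(positive.min())
    y_raw = amounts + shift
    clusters = _Clusters(person_ids, seq2, weekend, weights)
    if clusters.n_persons < 2:
        raise ValueError("need >= 2 participants to identify variance components")

    logy_term = float(np.sum(clusters.day_weight * np.log(y_raw)))

    best: AmountModelParams | None = None
    any_converged = False
    for lam in lam_grid:
        yt = boxcox_transform(y_raw, lam)
        a0, b0 = clusters.start_values(yt)

        def nll(theta):
            a, b = np.exp(theta)
            ll, _ = clusters.profile_loglik(yt, a, b)
            return -ll

        res = optimize.minimize(
            nll,
            x0=np.log([a0, b0]),
            method="L-BFGS-B",
            bounds=[(np.log(1e-10), 15.0)] * 2,
        )
        a, b = np.exp(res.x)
        ll, beta = clusters.profile_loglik(yt, a, b)
        ll_total = ll + (lam - 1.0) * logy_term  # Box-Cox Jacobian
        params = AmountModelParams(
            lam=float(lam),
            beta=tuple(beta),
            sigma2_u=float(a),
            sigma2_e=float(b),
            loglik=float(ll_total),
            converged=bool(res.success),
            shift=float(shift),
            n_participants=clusters.n_persons,
        )
        if best is None or ll_total > best.loglik:
            best = params
        any_converged = any_converged or res.success
    assert best is not None
    if not any_converged:
        raise FitError("amount model failed to converge at every lambda", params=best)
    return best


# ---------------------------------------------------------------------------
# Consumption-probability model (logistic, Gauss-Hermite random intercept)
# ---------------------------------------------------------------------------

def fit_consumption_model(
    consumed,
    person_ids,
    seq2,
    weekend,
    weights,
    n_nodes: int = 25,
) -> ProbabilityModelParams:
    """Fit the any-consumption logistic mixed model by weighted ML with
    Gauss-Hermite quadrature over the person random intercept.

    If every day is a consumption day the model is degenerate (p = 1): a
    flagged fallback is returned and estimation proceeds amount-only.
    """
    consumed = np.asarray(consumed, dtype=bool)
    if consumed.all():
        return ProbabilityModelParams(
            beta=(np.inf, 0.0, 0.0), sigma2_u=0.0, degenerate=True, loglik=0.0
        )
    if not consumed.any():
        raise ValueError("no consumption days at all; probability model unidentifiable")

    person_ids = np.asarray(person_ids)
    uniq, inverse = np.unique(person_ids, return_inverse=True)
    n = len(uniq)
    wp = np.zeros(n)
    wp[inverse] = np.asarray(weights, dtype=float)
    wp = wp / wp.mean()
    X = np.column_stack(
        [np.ones(len(person_ids)), np.asarray(seq2, float), np.asarray(weekend, float)]
    )
    y = consumed.astype(float)
    sgn = 2.0 * y - 1.0  # logistic log-density: log expit(sgn * eta)

    nodes, ghw = np.polynomial.hermite.hermgauss(n_nodes)
    log_ghw = np.log(ghw / np.sqrt(np.pi))

    def nll(theta):
        beta = theta[:3]
        sig = np.exp(theta[3])
        eta = X @ beta  # (n_days,)
        # (n_days, K): per-day log-likelihood at each quadrature node
        contrib = special.log_expit(sgn[:, None] * (eta[:, None] + np.sqrt(2.0) * sig * nodes))
        per_person = np.zeros((n, n_nodes))
        np.add.at(per_person, inverse, contrib)
        ll_i = special.logsumexp(per_person + log_ghw, axis=1)
        return -float(np.sum(wp * ll_i))

    p_bar = float(np.average(y, weights=wp[inverse]))
    x0 = np.array([special.logit(min(max(p_bar, 1e-3), 1 - 1e-3)), 0.0, 0.0, np.log(0.5)])
    res = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": 500})
    # polish: BFGS often stops on precision loss near the optimum
    res2 = optimize.minimize(nll, res.x, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    if res2.fun <= res.fun:
        res = res2
    beta = tuple(res.x[:3])
    sigma2 = float(np.exp(res.x[3]) ** 2)
    return ProbabilityModelParams(
        beta=beta,
        sigma2_u=sigma2,
        loglik=-float(res.fun),
        converged=bool(res.success or res2.success),
    )


# ---------------------------------------------------------------------------
# Monte Carlo usual-intake distribution
# ---------------------------------------------------------------------------

def simulate_usual_distribution(
    amount: AmountModelParams,
    prob: ProbabilityModelParams | None,
    participants,
    m: int = 100,
    seed: int = 0,
    nutrient: str = "",
    bt_method: str = "auto",
) -> UsualIntakeDistribution:
    """Monte Carlo distribution of usual intake: ``m`` pseudo-persons per
    participant, each a fresh draw of the person random effect(s).

    Covariates are balanced to the population day mix: weekend weighted 2/7
    and recall sequence held at Day 1.  Deterministic given ``seed``.
    """
    participants = list(participants)
    n = len(participants)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m * n > 10_000_000:
        raise ValueError(
            f"m * n = {m * n} pseudo-persons exceeds 1e7; lower m (or split the cohort)"
        )
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(max(amount.sigma2_u, 0.0)), size=n * m)
    b0, _, bwk = amount.beta
    z_wd = b0 + u
    z_we = z_wd + bwk
    mean_wd = back_transform_mean(z_wd, amount.sigma2_e, amount.lam, method=bt_method, clip=True)
    mean_we = back_transform_mean(z_we, amount.sigma2_e, amount.lam, method=bt_method, clip=True)
    usual_amount = (1.0 - WEEKEND_SHARE) * mean_wd + WEEKEND_SHARE * mean_we
    usual_amount = np.maximum(usual_amount - amount.shift, 0.0)

    if prob is not None and not prob.degenerate:
        v = rng.normal(0.0, np.sqrt(max(prob.sigma2_u, 0.0)), size=n * m)
        usual = prob.usual_probability(v) * usual_amount
    else:
        usual = usual_amount

    ids = np.repeat([p.id for p in participants], m)
    weights = np.repeat([p.sample_weight for p in participants], m)
    return UsualIntakeDistribution(
        values=usual,
        source_ids=ids,
        weights=weights,
        nutrient=nutrient,
        seed=seed,
        m=m,
    )
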