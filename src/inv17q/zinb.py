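"""Weighted zero-inflated negative-binomial (ZINB) regression.

The response is the number of children per individual (NCI) with small
families (0-3 by default) recoded to zero as "non-events": the count
component then models only larger-than-average family sizes, while the
zero component absorbs the bulk of subjects.  Count component: NB2 with log
link, mean mu_i = exp(x_i' beta) and variance mu + mu^2/theta; zero
component: logit link, structural-zero probability pi_i.  Per-subject
weights (inverse age-bin sizes, rescaled to sum to N) enter the
log-likelihood multiplicatively.

The likelihood, analytic score and quasi-Newton fit are implemented here
from first principles; term tests are Wald chi-squares on the count-part
coefficient blocks, and overdispersion is judged from the Wald p-value of
log(theta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

LOG_THETA_CAP = 20.0  # theta ~ 4.85e8; beyond this the NB is numerically Poisson


class ModelNotFormedError(RuntimeError):
    """Raised when the design cannot support the model (e.g. a single
    genotype class after recoding)."""


def recode_nonevents(nci: np.ndarray, threshold: int = 3) -> np.ndarray:
    """Recode counts <= ``threshold`` to zero; larger counts pass through
    unshifted (support {0} u {threshold+1, ...})."""
    nci = np.asarray(nci)
    if np.any(nci < 0):
        raise ValueError("negative children counts")
    return np.where(nci <= threshold, 0, nci)


def age_bin_weights(ages: np.ndarray) -> np.ndarray:
    """Inverse age-bin-size weights scaled to sum to the subject count.

    Bins are integer years: raw_i = 1 / n_{bin(i)}, then w_i = raw_i * N /
    sum(raw), which equals N / (B * n_{bin(i)}) with B distinct bins.  Age
    groups thus contribute equally regardless of enrolment imbalance.
    """
    ages = np.asarray(ages)
    if ages.size == 0:
        raise ValueError("empty age vector")
    bins = np.round(ages).astype(int)
    _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    raw = 1.0 / counts[inverse]
    return raw * len(ages) / raw.sum()


@dataclass
class ModelSpec:
    """Design for one ZINB fit.  Both components share the covariate set by
    default; ``term_blocks`` maps term names to count-part column indices for
    the Wald term tests."""

    y: np.ndarray
    X: np.ndarray  # count-part design (includes intercept)
    Z: np.ndarray  # zero-part design (includes intercept)
    weights: np.ndarray | None = None
    count_names: list[str] = field(default_factory=list)
    zero_names: list[str] = field(default_factory=list)
    term_blocks: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("design and response lengths differ")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.count_names:
            self.count_names = [f"x{j}" for j in range(self.X.shape[1])]
        if not self.zero_names:
            self.zero_names = [f"z{j}" for j in range(self.Z.shape[1])]

    @property
    def n_params(self) -> int:
        return self.X.shape[1] + self.Z.shape[1] + 1


@dataclass
class ZinbParams:
    beta: np.ndarray
    gamma: np.ndarray
    log_theta: float

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma, [self.log_theta]])

    @staticmethod
    def unpack(vec: np.ndarray, k_count: int, k_zero: int) -> "ZinbParams":
        return ZinbParams(
            beta=np.asarray(vec[:k_count], dtype=float),
            gamma=np.asarray(vec[k_count : k_count + k_zero], dtype=float),
            log_theta=float(vec[k_count + k_zero]),
        )

    @property
    def theta(self) -> float:
        return float(np.exp(self.log_theta))


@dataclass
class ZinbFit:
    params: ZinbParams
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    vcov: np.ndarray
    spec: ModelSpec
    status: str = "ok"
    theta_at_boundary: bool = False
    term_table: pd.DataFrame | None = None

    @property
    def param_names(self) -> list[str]:
        return (
            [f"count_{n}" for n in self.spec.count_names]
            + [f"zero_{n}" for n in self.spec.zero_names]
            + ["log_theta"]
        )

    def summary_frame(self) -> pd.DataFrame:
        est = self.params.pack()
        comp = (
            ["count"] * len(self.spec.count_names)
            + ["zero"] * len(self.spec.zero_names)
            + ["dispersion"]
        )
        names = self.spec.count_names + self.spec.zero_names + ["log_theta"]
        return pd.DataFrame(
            {
                "component": comp,
                "coefficient": names,
                "estimate": est,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )


def _lgamma_ratio(y: np.ndarray, theta: float) -> np.ndarray:
    """log Gamma(y+theta) - log Gamma(theta) = sum_{i<y} log(theta+i),
    computed as the explicit sum for integer-valued y (no cancellation even
    at very large theta)."""
    ymax = int(np.max(y)) if len(y) else 0
    yi = y.astype(int)
    if ymax > 100_000 or np.any(yi != y):
        return special.gammaln(y + theta) - special.gammaln(theta)
    cum = np.concatenate([[0.0], np.cumsum(np.log(theta + np.arange(ymax)))])
    return cum[yi]


def _digamma_ratio(y: np.ndarray, theta: float) -> np.ndarray:
    """digamma(y+theta) - digamma(theta) = sum_{i<y} 1/(theta+i)."""
    ymax = int(np.max(y)) if len(y) else 0
    yi = y.astype(int)
    if ymax > 100_000 or np.any(yi != y):
        return special.digamma(y + theta) - special.digamma(theta)
    cum = np.concatenate([[0.0], np.cumsum(1.0 / (theta + np.arange(ymax)))])
    return cum[yi]


def _loglik_terms(params: ZinbParams, spec: ModelSpec) -> np.ndarray:
    """Per-subject unweighted log-likelihood contributions, in log space.

    All large-theta terms are arranged to avoid cancellation: the Gamma
    ratio is a rising-factorial log sum and log(theta/(theta+mu)) is
    -softplus(eta - rho), so the Poisson limit is numerically exact.
    """
    eta = spec.X @ params.beta
    zeta = spec.Z @ params.gamma
    theta = params.theta
    rho = params.log_theta
    y = spec.y
    # log pi and log(1-pi) via stable softplus
    log_pi = -np.logaddexp(0.0, -zeta)
    log_1mpi = -np.logaddexp(0.0, zeta)
    sp = np.logaddexp(0.0, eta - rho)  # softplus(eta - rho) = log((theta+mu)/theta)
    log_theta_mu = rho + sp  # log(theta + mu)
    lognb = (
        _lgamma_ratio(y, theta)
        - special.gammaln(y + 1)
        - theta * sp
        + y * (eta - log_theta_mu)
    )
    zero = y == 0
    out = np.empty_like(y, dtype=float)
    out[zero] = np.logaddexp(log_pi[zero], log_1mpi[zero] + lognb[zero])
    out[~zero] = log_1mpi[~zero] + lognb[~zero]
    return out


def zinb_loglik(params: ZinbParams, spec: ModelSpec) -> float:
    """Weighted ZINB log-likelihood."""
    terms = _loglik_terms(params, spec)
    if not np.all(np.isfinite(terms)):
        bad = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise FloatingPointError(f"non-finite log-likelihood at subject index {bad}")
    return float(np.sum(spec.weights * terms))


def zinb_score(params: ZinbParams, spec: ModelSpec) -> np.ndarray:
    """Analytic gradient of the weighted log-likelihood in (beta, gamma, log_theta)."""
    eta = spec.X @ params.beta
    zeta = spec.Z @ params.gamma
    theta = params.theta
    rho = params.log_theta
    y = spec.y
    w = spec.weights
    pi = special.expit(zeta)
    sp = np.logaddexp(0.0, eta - rho)  # log((theta+mu)/theta)
    mu_frac = special.expit(eta - rho)  # mu / (theta + mu)
    theta_mu_frac = theta * mu_frac  # theta*mu/(theta+mu), stable product

    zero = y == 0
    d_eta = np.empty_like(y)
    d_zeta = np.empty_like(y)
    d_rho = np.empty_like(y)

    # y > 0 branch
    pos = ~zero
    yp = y[pos]
    d_eta[pos] = yp - yp * mu_frac[pos] - theta_mu_frac[pos]
    d_zeta[pos] = -pi[pos]
    # theta * d(log f)/d(theta); theta*(mu-y)/(theta+mu) written as a
    # difference of bounded factors so extreme eta cannot overflow
    d_rho[pos] = (
        theta * _digamma_ratio(yp, theta)
        - theta * sp[pos]
        + theta_mu_frac[pos]
        - yp * special.expit(rho - eta[pos])
    )

    # y == 0 branch: l = logaddexp(log pi, log(1-pi) + l0), l0 = -theta*softplus(eta-rho)
    log_pi = -np.logaddexp(0.0, -zeta[zero])
    log_1mpi = -np.logaddexp(0.0, zeta[zero])
    l0 = -theta * sp[zero]
    li = np.logaddexp(log_pi, log_1mpi + l0)
    wA = np.exp(log_pi - li)  # posterior of structural zero
    wB = np.exp(log_1mpi + l0 - li)
    d_eta[zero] = wB * (-theta_mu_frac[zero])
    d_zeta[zero] = wA * (1 - pi[zero]) - wB * pi[zero]
    d_rho[zero] = wB * (-theta * sp[zero] + theta_mu_frac[zero])

    g_beta = spec.X.T @ (w * d_eta)
    g_gamma = spec.Z.T @ (w * d_zeta)
    g_rho = np.sum(w * d_rho)
    return np.concatenate([g_beta, g_gamma, [g_rho]])


def _numeric_hessian(grad_fun, x0: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Hessian as the symmetrized central-difference Jacobian of the analytic
    score — far more accurate than second differences of the log-likelihood."""
    k = len(x0)
    h = eps * np.maximum(1.0, np.abs(x0))
    jac = np.empty((k, k))
    for i in range(k):
        xp = x0.copy(); xp[i] += h[i]
        xm = x0.copy(); xm[i] -= h[i]
        jac[i] = (grad_fun(xp) - grad_fun(xm)) / (2 * h[i])
    return 0.5 * (jac + jac.T)


def _poisson_start(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Poisson IRLS for count-part starting values."""
    k = X.shape[1]
    beta = np.zeros(k)
    ybar = max(np.average(y, weights=w), 0.1)
    if np.all(X[:, 0] == 1):
        beta[0] = np.log(ybar)
    for _ in range(25):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        W = w * mu
        z = X @ beta + (y - mu) / np.maximum(mu, 1e-10)
        try:
            new = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    return beta


def _logistic_start(y01: np.ndarray, Z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted logistic IRLS for zero-part starting values."""
    k = Z.shape[1]
    gamma = np.zeros(k)
    pbar = np.clip(np.average(y01, weights=w), 1e-3, 1 - 1e-3)
    if np.all(Z[:, 0] == 1):
        gamma[0] = np.log(pbar / (1 - pbar))
    for _ in range(25):
        p = special.expit(np.clip(Z @ gamma, -30, 30))
        W = w * p * (1 - p)
        W = np.maximum(W, 1e-10)
        z = Z @ gamma + (y01 - p) / W * w
        try:
            new = np.linalg.solve((Z * W[:, None]).T @ Z, (Z * W[:, None]).T @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - gamma)) < 1e-8:
            gamma = new
            break
        gamma = new
    return gamma


def fit_zinb(
    spec: ModelSpec,
    maxiter: int = 2000,
    gtol: float = 1e-6,
    start: ZinbParams | None = None,
    compute_se: bool = True,
) -> ZinbFit:
    """Maximize the weighted ZINB log-likelihood by L-BFGS with the analytic
    score; log(theta) is box-bounded at +/-``LOG_THETA_CAP``.

    Starting values: weighted Poisson regression for the count part, weighted
    logistic regression of 1{y=0} for the zero part, log_theta = 0.  Standard
    errors come from the inverse observed information (numerical Hessian of
    the log-likelihood at the optimum).
    """
    y, X, Z, w = spec.y, spec.X, spec.Z, spec.weights
    if len(np.unique(y)) < 2:
        raise ModelNotFormedError("response has a single level after recoding")
    for name, M in (("count", X), ("zero", Z)):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ModelNotFormedError(f"{name}-part design is rank deficient")
    k_count, k_zero = X.shape[1], Z.shape[1]

    if start is None:
        beta0 = _poisson_start(y, X, w)
        gamma0 = _logistic_start((y == 0).astype(float), Z, w)
        start = ZinbParams(beta=beta0, gamma=gamma0, log_theta=0.0)
    ll0 = zinb_loglik(start, spec)

    # optimize on column-scaled designs (raw covariates such as age make the
    # problem needlessly ill-conditioned); coefficients are unscaled after
    sx = np.maximum(np.max(np.abs(X), axis=0), 1e-12)
    sz = np.maximum(np.max(np.abs(Z), axis=0), 1e-12)
    scaled = ModelSpec(
        y=y, X=X / sx, Z=Z / sz, weights=w,
        count_names=spec.count_names, zero_names=spec.zero_names,
    )
    scale = np.concatenate([sx, sz, [1.0]])
    x0 = start.pack() * scale

    def negloglik(vec: np.ndarray) -> tuple[float, np.ndarray]:
        p = ZinbParams.unpack(vec, k_count, k_zero)
        terms = _loglik_terms(p, scaled)
        if not np.all(np.isfinite(terms)):
            return np.inf, np.zeros_like(vec)
        ll = float(np.sum(w * terms))
        return -ll, -zinb_score(p, scaled)

    bounds = [(None, None)] * (k_count + k_zero) + [(-LOG_THETA_CAP, LOG_THETA_CAP)]
    res = optimize.minimize(
        negloglik,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
    )
    # Newton polish: interaction designs leave L-BFGS crawling near the
    # optimum; a few damped Newton steps with the score Jacobian finish it
    x = res.x.copy()
    fval = float(res.fun)
    n_newton = 0
    for _ in range(25):
        g = zinb_score(ZinbParams.unpack(x, k_count, k_zero), scaled)
        if np.max(np.abs(g)) < gtol * 10:
            break
        H = _numeric_hessian(
            lambda v: zinb_score(ZinbParams.unpack(v, k_count, k_zero), scaled), x
        )
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
            cand = x - damp * step
            cand[-1] = np.clip(cand[-1], -LOG_THETA_CAP, LOG_THETA_CAP)
            fc, _ = negloglik(cand)
            if fc < fval:
                x, fval = cand, fc
                improved = True
                n_newton += 1
                break
        if not improved:
            break
    res.x, res.fun = x, fval
    res.jac = -zinb_score(ZinbParams.unpack(x, k_count, k_zero), scaled)

    res.x = res.x / scale
    params = ZinbParams.unpack(res.x, k_count, k_zero)
    loglik = -float(res.fun)
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
    if loglik < ll0 - 1e-8:
        logger.warning("fit_zinb: optimizer ended below the starting log-likelihood")
        converged = False
    if not converged:
        logger.warning("fit_zinb: non-convergence (%s)", res.message)
    theta_boundary = abs(params.log_theta) >= LOG_THETA_CAP - 1e-6

    k = spec.n_params
    se = np.full(k, np.nan)
    zvals = np.full(k, np.nan)
    pvals = np.full(k, np.nan)
    vcov = np.full((k, k), np.nan)
    if compute_se:
        def grad_fun(vec: np.ndarray) -> np.ndarray:
            return zinb_score(ZinbParams.unpack(vec, k_count, k_zero), spec)

        hess = _numeric_hessian(grad_fun, res.x)
        info = -hess
        if theta_boundary:
            # curvature in log_theta vanishes at the cap; keep the block out
            info_core = info[:-1, :-1]
            try:
                vc = np.linalg.inv(info_core)
            except np.linalg.LinAlgError:
                vc = np.linalg.pinv(info_core)
            vcov[:-1, :-1] = vc
        else:
            try:
                vcov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                vcov = np.linalg.pinv(info)
        diag = np.diag(vcov).copy()
        ok = np.isfinite(diag) & (diag > 0)
        se[ok] = np.sqrt(diag[ok])
        zvals[ok] = res.x[ok] / se[ok]
        pvals[ok] = 2 * stats.norm.sf(np.abs(zvals[ok]))

    return ZinbFit(
        params=params,
        se=se,
        z=zvals,
        p=pvals,
        loglik=loglik,
        converged=converged,
        n_iter=int(res.nit),
        vcov=vcov,
        spec=spec,
        theta_at_boundary=theta_boundary,
    )


def term_tests(fit: ZinbFit, terms: dict[str, list[int]] | None = None) -> pd.DataFrame:
    """Type-II style Wald chi-square per model term on the count-component
    coefficient block: W = b' V^-1 b, df = block size.

    ``terms`` maps term name to count-part column indices; defaults to the
    spec's ``term_blocks``.  For a single-coefficient term W equals z^2 and
    the p-value equals the coefficient's Wald p.
    """
    terms = terms if terms is not None else fit.spec.term_blocks
    if not terms:
        raise ValueError("no term blocks defined")
    rows = []
    for name, cols in terms.items():
        cols = list(cols)
        b = fit.params.beta[cols]
        V = fit.vcov[np.ix_(cols, cols)]
        try:
            W = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            logger.warning("term_tests: singular covariance block for term %r", name)
            rows.append({"term": name, "df": len(cols), "chisq": np.nan, "p": np.nan})
            continue
        rows.append(
            {"term": name, "df": len(cols), "chisq": W, "p": float(stats.chi2.sf(W, df=len(cols)))}
        )
    table = pd.DataFrame(rows, columns=["term", "df", "chisq", "p"])
    fit.term_table = table
    return table


def overdispersion_check(fit: ZinbFit, alpha: float = 0.05) -> tuple[bool, float, str]:
    """Wald test of log(theta); returns (overdispersed, p, note).

    A significant log(theta) indicates residual overdispersion in the count
    component.  When theta sits at the numerical cap the likelihood is flat
    in log(theta) (Poisson limit) and p is reported as 1 with a note.
    """
    idx = fit.spec.n_params - 1
    if fit.theta_at_boundary or not np.isfinite(fit.se[idx]):
        return False, 1.0, "theta at boundary"
    p = float(fit.p[idx])
    return p < alpha, p, ""


def bonferroni(p_values, m: int = 7, alpha: float = 0.05) -> list[bool]:
    """Significance decisions at the Bonferroni-adjusted level alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    thresh = alpha / m
    return [bool(p < thresh) for p in np.atleast_1d(p_values)]


# --- design construction -------------------------------------------------

def build_design(
    genotype: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    nci: np.ndarray,
    weights: np.ndarray | None = None,
    threshold: int = 3,
    interactions: bool = False,
    reference: str | None = None,
) -> ModelSpec:
    """Assemble the ZINB design from genotype labels, age and sex.

    ``genotype`` holds class labels (e.g. TT/CT/CC or H1_H1/H1_H2/H2_H2).
    The reference level defaults to the smaller homozygote class — the
    H2-homozygote group in practice, matching the published coefficient
    table where CT and TT enter as dummies against a CC baseline — and the
    remaining classes enter heterozygote-first.  Both components receive the
    same covariates.  With ``interactions`` the full genotype x age x sex
    factorial enters both parts.
    """
    genotype = np.asarray(genotype)
    classes, counts = np.unique(genotype, return_counts=True)
    if len(classes) < 2:
        raise ModelNotFormedError("fewer than two genotype classes present")
    count_of = dict(zip(classes.tolist(), counts.tolist()))

    def is_het(label: str) -> bool:
        s = str(label)
        return (len(s) == 2 and s[0] != s[1]) or s == "H1_H2"

    if reference is None:
        homs = [c for c in classes if not is_het(c)]
        pool = homs if homs else list(classes)
        reference = min(pool, key=lambda c: (count_of[c], str(c)))
    others = [c for c in classes if c != reference]
    # heterozygote dummy first, then remaining classes by descending size
    others.sort(key=lambda c: (0 if is_het(c) else 1, -count_of[c], str(c)))

    y = recode_nonevents(np.asarray(nci), threshold=threshold)
    n = len(y)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    geno_cols: list[int] = []
    for c in others:
        cols.append((genotype == c).astype(float))
        names.append(f"SNP:{c}")
        geno_cols.append(len(cols) - 1)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    cols.append(age)
    names.append("Age")
    age_col = len(cols) - 1
    cols.append(sex)
    names.append("Sex")
    sex_col = len(cols) - 1
    term_blocks = {"SNP": list(geno_cols), "Age": [age_col], "Sex": [sex_col]}

    if interactions:
        for c, gc in zip(others, geno_cols):
            cols.append(cols[gc] * age)
            names.append(f"SNP:{c}:Age")
        for c, gc in zip(others, geno_cols):
            cols.append(cols[gc] * sex)
            names.append(f"SNP:{c}:Sex")
        cols.append(age * sex)
        names.append("Age:Sex")
        for c, gc in zip(others, geno_cols):
            cols.append(cols[gc] * age * sex)
            names.append(f"SNP:{c}:Age:Sex")

    X = np.column_stack(cols)
    return ModelSpec(
        y=y,
        X=X,
        Z=X.copy(),
        weights=weights,
        count_names=list(names),
        zero_names=list(names),
        term_blocks=term_blocks,
    )


def interaction_pvalues(fit: ZinbFit) -> np.ndarray:
    """Wald p-values of every interaction coefficient in both components."""
    idx = [
        i
        for i, name in enumerate(fit.param_names)
        if ":" in name.split("_", 1)[-1].replace("SNP:", "", 1)
    ]
    return fit.p[idx]


def prune_interactions(
    genotype: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    nci: np.ndarray,
    weights: np.ndarray | None = None,
    threshold: int = 3,
    alpha: float = 0.05,
    reference: str | None = None,
) -> tuple[ZinbFit, bool]:
    """Fit the full genotype x age x sex model; drop all interactions when none
    is significant at ``alpha`` (main effects are always retained).

    Returns (final fit, interactions_kept).  If the full model cannot be
    formed or fails to converge, falls back to the main-effects model.
    """
    mains = build_design(
        genotype, age, sex, nci, weights=weights, threshold=threshold,
        interactions=False, reference=reference,
    )
    try:
        full_spec = build_design(
            genotype, age, sex, nci, weights=weights, threshold=threshold,
            interactions=True, reference=reference,
        )
        full = fit_zinb(full_spec)
        if not full.converged:
            raise ModelNotFormedError("full interaction model did not converge")
    except (ModelNotFormedError, FloatingPointError) as exc:
        logger.warning("prune_interactions: falling back to main effects (%s)", exc)
        return fit_zinb(mains), False
    pvals = interaction_pvalues(full)
    pvals = pvals[np.isfinite(pvals)]
    if len(pvals) and np.min(pvals) < alpha:
        return full, True
    return fit_zinb(mains), False
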