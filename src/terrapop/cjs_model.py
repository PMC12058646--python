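"""Cormack-Jolly-Seber survival estimation with covariate structure.

Maximum-likelihood estimation of apparent survival (phi) and detection
probability (p) from 0/1 encounter histories, conditional on first capture.
The likelihood is the standard product over individuals of interval survival
and detection terms, closed by the chi recursion

    chi_K = 1,   chi_t = (1 - phi~_t) + phi~_t (1 - p_{t+1}) chi_{t+1}

where chi_t is the probability an animal alive at occasion t is never seen
again.  Occasions may be unequally spaced: annual survival is exponentiated
by interval length, phi~_t = phi_t ** dt (the convention used by Program
MARK for unequal intervals).

Covariates enter on the logit scale: survival over {sex, year-as-factor,
hurricane interval, linear year trend} and detection over {sex, annual
effort, occasion-as-factor}.  The terminal survival and detection of a
fully time-varying model are confounded (only their product is likelihood-
identified); :func:`fit` detects such directions from the null space of the
observed information and flags the affected real parameters inestimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.special import expit

from .encounter_io import EncounterHistorySet

__all__ = [
    "CJSDesign",
    "CJSFit",
    "build_design",
    "negloglik",
    "fit",
    "real_params",
]

PHI_TERMS = ("sex", "year", "hurricane", "trend")
P_TERMS = ("sex", "effort", "time")

_SEXLAB = ("female", "male")


class CJSError(RuntimeError):
    pass


@dataclass
class CJSDesign:
    """Logit-scale design matrices for a CJS model.

    ``x_phi`` has shape (2, n_intervals, k_phi) indexed by (sex, interval);
    ``x_p`` has shape (2, n_occasions - 1, k_p) indexed by (sex, occasion)
    where occasion j refers to sampling occasion j+1 (detection applies from
    the second occasion onward, conditional on first capture).
    """

    years: list[int]
    interval_lengths: np.ndarray
    x_phi: np.ndarray
    x_p: np.ndarray
    phi_names: list[str]
    p_names: list[str]
    phi_terms: tuple[str, ...]
    p_terms: tuple[str, ...]
    aliased: list[str] = field(default_factory=list)

    @property
    def k_phi(self) -> int:
        return self.x_phi.shape[2]

    @property
    def k_p(self) -> int:
        return self.x_p.shape[2]

    @property
    def n_params(self) -> int:
        return self.k_phi + self.k_p

    @property
    def n_intervals(self) -> int:
        return self.x_phi.shape[1]

    def split(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_params,):
            raise CJSError(
                f"beta has shape {beta.shape}, design expects ({self.n_params},)"
            )
        return beta[: self.k_phi], beta[self.k_phi :]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def build_design(
    ehs: EncounterHistorySet,
    phi_spec: tuple[str, ...] = ("sex", "year"),
    p_spec: tuple[str, ...] = ("sex", "effort"),
) -> CJSDesign:
    """Construct the CJS design matrices for the requested covariates.

    Survival covariates are interval-level (year factor levels per interval,
    hurricane indicator on the interval containing the storm, standardized
    linear year trend); detection covariates are occasion-level (annual
    effort hours, standardized).  Sex enters both as a group covariate.
    Aliased (rank-deficient) columns are reported in ``design.aliased``, not
    silently dropped: fitting an aliased design relies on the pseudoinverse
    and the estimability flags downstream.
    """
    for t in phi_spec:
        if t not in PHI_TERMS:
            raise CJSError(f"unknown survival covariate {t!r}; choose from {PHI_TERMS}")
    for t in p_spec:
        if t not in P_TERMS:
            raise CJSError(f"unknown detection covariate {t!r}; choose from {P_TERMS}")

    years = ehs.years
    n_occ = len(years)
    if n_occ < 2:
        raise CJSError("need at least two occasions")
    n_int = n_occ - 1
    dt = ehs.interval_lengths.astype(float)
    # hurricane flag is carried on the occasion that *ends* the interval
    hurr_int = np.array([int(ehs.occasions[t + 1].hurricane) for t in range(n_int)])
    effort = np.array([o.effort_hours for o in ehs.occasions], dtype=float)
    z_effort = _standardize(effort)
    interval_start = np.asarray(years[:-1], dtype=float)
    z_trend = _standardize(interval_start)

    # --- phi design: rows (sex, interval) ---
    cols_phi: list[np.ndarray] = []
    names_phi: list[str] = []

    def add_phi(col_f: np.ndarray, col_m: np.ndarray, name: str) -> None:
        cols_phi.append(np.stack([col_f, col_m]))
        names_phi.append(name)

    ones = np.ones(n_int)
    add_phi(ones, ones, "phi:(intercept)")
    if "sex" in phi_spec:
        add_phi(np.zeros(n_int), np.ones(n_int), "phi:sex[male]")
    if "year" in phi_spec:
        for t in range(1, n_int):
            col = np.zeros(n_int)
            col[t] = 1.0
            add_phi(col, col, f"phi:year[{years[t]}-{years[t + 1]}]")
    if "trend" in phi_spec:
        add_phi(z_trend, z_trend, "phi:trend")
    if "hurricane" in phi_spec:
        add_phi(hurr_int.astype(float), hurr_int.astype(float), "phi:hurricane")
    x_phi = np.stack([np.column_stack([c[0] for c in cols_phi]),
                      np.column_stack([c[1] for c in cols_phi])])

    # --- p design: rows (sex, occasion 2..K) ---
    cols_p: list[np.ndarray] = []
    names_p: list[str] = []

    def add_p(col_f: np.ndarray, col_m: np.ndarray, name: str) -> None:
        cols_p.append(np.stack([col_f, col_m]))
        names_p.append(name)

    ones_p = np.ones(n_occ - 1)
    add_p(ones_p, ones_p, "p:(intercept)")
    if "sex" in p_spec:
        add_p(np.zeros(n_occ - 1), np.ones(n_occ - 1), "p:sex[male]")
    if "effort" in p_spec:
        ze = z_effort[1:]
        add_p(ze, ze, "p:effort")
    if "time" in p_spec:
        for j in range(1, n_occ - 1):
            col = np.zeros(n_occ - 1)
            col[j] = 1.0
            add_p(col, col, f"p:time[{years[j + 1]}]")
    x_p = np.stack([np.column_stack([c[0] for c in cols_p]),
                    np.column_stack([c[1] for c in cols_p])])

    # --- aliasing report: QR with pivoting on the stacked block design ---
    n_rows = 2 * n_int + 2 * (n_occ - 1)
    k = x_phi.shape[2] + x_p.shape[2]
    big = np.zeros((n_rows, k))
    big[: 2 * n_int, : x_phi.shape[2]] = x_phi.reshape(2 * n_int, -1)
    big[2 * n_int :, x_phi.shape[2] :] = x_p.reshape(2 * (n_occ - 1), -1)
    names = names_phi + names_p
    # sequential aliasing check: a column is aliased if it lies in the span
    # of the columns before it, so later-added terms (e.g. a hurricane
    # indicator after a full year factor) are the ones reported
    aliased: list[str] = []
    basis: list[np.ndarray] = []
    for j in range(k):
        col = big[:, j].astype(float)
        norm0 = np.linalg.norm(col)
        for q in basis:
            col = col - (q @ col) * q
        if np.linalg.norm(col) <= 1e-10 * max(norm0, 1.0):
            aliased.append(names[j])
        else:
            basis.append(col / np.linalg.norm(col))

    return CJSDesign(
        years=years,
        interval_lengths=dt,
        x_phi=x_phi,
        x_p=x_p,
        phi_names=names_phi,
        p_names=names_p,
        phi_terms=tuple(phi_spec),
        p_terms=tuple(p_spec),
        aliased=aliased,
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _real_rates(beta: np.ndarray, design: CJSDesign):
    """(2, n_int) interval survival phi~ (dt-exponentiated) and (2, n_occ-1) p."""
    b_phi, b_p = design.split(beta)
    eta_phi = design.x_phi @ b_phi  # (2, n_int)
    eta_p = design.x_p @ b_p  # (2, n_occ-1)
    # clip away exact 0/1 so the log-likelihood stays finite over the whole
    # link-scale parameter space (line searches can wander far out)
    tiny = 1e-12
    phi_annual = np.clip(expit(eta_phi), tiny, 1.0 - tiny)
    phi_int = phi_annual ** design.interval_lengths[None, :]
    p = np.clip(expit(eta_p), tiny, 1.0 - tiny)
    return phi_int, p


def _prepare(ehs: EncounterHistorySet):
    """Collapse to unique (sex, history) rows with multiplicity weights;
    the likelihood is a weighted sum over distinct histories."""
    det = ehs.detection_matrix()
    sex = ehs.sex_codes()
    stacked = np.column_stack([sex, det])
    uniq, counts = np.unique(stacked, axis=0, return_counts=True)
    sex_u = uniq[:, 0]
    det_u = uniq[:, 1:]
    first = det_u.argmax(axis=1)
    last = det_u.shape[1] - 1 - det_u[:, ::-1].argmax(axis=1)
    return det_u, sex_u, first, last, counts


def negloglik(beta: np.ndarray, design: CJSDesign, ehs: EncounterHistorySet) -> float:
    """Negative log-likelihood, conditional on each animal's first capture."""
    if not ehs.individuals:
        raise CJSError("empty encounter-history set")
    return _negloglik_prepared(beta, design, _prepare(ehs))


def _negloglik_prepared(beta: np.ndarray, design: CJSDesign, prep) -> float:
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise CJSError("non-finite coefficients")
    phi_int, p = _real_rates(beta, design)
    n_occ = len(design.years)
    n_int = n_occ - 1

    with np.errstate(divide="ignore"):
        logphi = np.log(phi_int)  # (2, n_int)
        log1mphi = np.log1p(-phi_int)
        logp = np.log(p)  # (2, n_occ-1)
        log1mp = np.log1p(-p)

    # chi recursion per sex: chi[t] = P(alive at occasion t, never seen again)
    chi = np.ones((2, n_occ))
    for t in range(n_occ - 2, -1, -1):
        chi[:, t] = (1.0 - phi_int[:, t]) + phi_int[:, t] * (1.0 - p[:, t]) * chi[:, t + 1]
    with np.errstate(divide="ignore"):
        logchi = np.log(chi)

    det, sex, first, last, weights = prep
    occ_idx = np.arange(n_occ)

    # survival terms: sum_{t=first}^{last-1} log phi~[sex, t]
    cum = np.concatenate([np.zeros((2, 1)), np.cumsum(logphi, axis=1)], axis=1)
    surv = cum[sex, last] - cum[sex, first]

    # detection terms over occasions (first, last]
    window = (occ_idx[None, :] > first[:, None]) & (occ_idx[None, :] <= last[:, None])
    # p is indexed by occasion-1 (no detection parameter for occasion 1)
    logp_full = np.concatenate([np.full((2, 1), -np.inf), logp], axis=1)
    log1mp_full = np.concatenate([np.full((2, 1), -np.inf), log1mp], axis=1)
    det_terms = np.where(det == 1, logp_full[sex], log1mp_full[sex])
    det_sum = np.where(window, det_terms, 0.0).sum(axis=1)

    ll = surv + det_sum + logchi[sex, last]
    total = float(np.sum(weights * ll))
    if not np.isfinite(total):
        raise CJSError(
            "non-finite log-likelihood; coefficients may have overflowed the "
            "link scale (rescale covariates or tighten starts)"
        )
    return -total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class CJSFit:
    """A converged CJS fit with real-scale summaries."""

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    design: CJSDesign
    real_phi: pd.DataFrame  # sex, year_start, year_end, estimate, se, lcl, ucl, estimable
    real_p: pd.DataFrame  # sex, year, estimate, se, lcl, ucl, estimable
    converged: bool
    n_individuals: int
    null_directions: np.ndarray  # (n_params, n_null) basis of the information null space

    def to_tidy(self) -> pd.DataFrame:
        phi = self.real_phi.copy()
        phi.insert(0, "parameter", "phi")
        phi = phi.rename(columns={"year_start": "year"})
        p = self.real_p.copy()
        p.insert(0, "parameter", "p")
        cols = ["parameter", "sex", "year", "estimate", "lcl", "ucl", "estimable"]
        return pd.concat([phi[cols], p[cols]], ignore_index=True)


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return hess


def fit(
    ehs: EncounterHistorySet,
    design: CJSDesign | None = None,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    se_threshold: float = 0.45,
    eta_threshold: float = 10.0,
) -> CJSFit:
    """Maximize the CJS likelihood from multiple deterministic starts.

    Quasi-Newton (BFGS) optimization from five fixed starting points (all
    zeros, and +/-1 on each block's intercept); the best optimum is kept.
    ``vcov`` is the pseudoinverse of the observed information; directions in
    its numerical null space (confounded parameters, e.g. the terminal
    phi/p pair of a fully time-varying model) and real parameters with
    real-scale SE above ``se_threshold`` or |logit| above ``eta_threshold``
    are flagged inestimable.
    """
    if design is None:
        design = build_design(ehs)
    prep = _prepare(ehs)
    det, _, first, _, _ = prep
    if not np.any(first < det.shape[1] - 1):
        raise CJSError("no individual released before the final occasion")

    k = design.n_params
    obj = lambda b: _negloglik_prepared(b, design, prep)

    starts = [np.zeros(k)]
    for idx in (0, design.k_phi):
        for v in (1.0, -1.0):
            s = np.zeros(k)
            s[idx] = v
            starts.append(s)
    if start is not None:
        starts.insert(0, np.asarray(start, dtype=float))

    best = None
    for s in starts:
        res = scipy.optimize.minimize(
            obj, s, method="BFGS", options={"gtol": tol, "maxiter": max_iter}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise CJSError("optimization failed from every start")
    if not best.success and np.linalg.norm(best.jac) > 1e-3 * max(1.0, abs(best.fun)):
        raise CJSError(
            f"no convergence after {max_iter} iterations "
            f"(best negloglik {best.fun:.6f}, |grad| {np.linalg.norm(best.jac):.2e})"
        )

    hess = _numerical_hessian(obj, best.x)
    hess = 0.5 * (hess + hess.T)
    evals, evecs = np.linalg.eigh(hess)
    null_tol = max(1e-6, np.abs(evals).max() * 1e-8)
    null_mask = evals < null_tol
    null_dirs = evecs[:, null_mask]
    inv = np.where(null_mask, 0.0, 1.0 / np.where(null_mask, 1.0, evals))
    vcov = (evecs * inv) @ evecs.T

    loglik = -best.fun
    fitted = CJSFit(
        beta=best.x,
        vcov=vcov,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        design=design,
        real_phi=pd.DataFrame(),
        real_p=pd.DataFrame(),
        converged=True,
        n_individuals=len(ehs.individuals),
        null_directions=null_dirs,
    )
    fitted.real_phi, fitted.real_p = real_params(
        fitted, design, se_threshold=se_threshold, eta_threshold=eta_threshold
    )
    return fitted


def real_params(
    fitted: CJSFit,
    design: CJSDesign | None = None,
    se_threshold: float = 0.45,
    eta_threshold: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Back-transform a fit to real-scale survival and detection tables.

    Point estimates are inverse-logits of the linear predictors; 95%
    confidence intervals are inverse-logits of eta +/- 1.96 SE(eta), with
    SE(eta) from the delta method on the coefficient covariance, so bounds
    are always ordered and inside [0, 1].  Survival rows report *annual*
    survival (the interval rate is the annual rate to the power of the
    interval length).
    """
    if design is None:
        design = fitted.design
    beta = fitted.beta
    vcov = fitted.vcov
    b_phi, b_p = design.split(beta)
    years = design.years
    z = 1.959963984540054

    def rows(x_block, b_block, offset, kind):
        out = []
        for s in (0, 1):
            for t in range(x_block.shape[1]):
                x = x_block[s, t]
                eta = float(x @ b_block)
                xf = np.zeros(design.n_params)
                xf[offset : offset + x.size] = x
                var = float(xf @ vcov @ xf)
                se_eta = np.sqrt(max(var, 0.0))
                est = float(expit(eta))
                lcl = float(expit(eta - z * se_eta))
                ucl = float(expit(eta + z * se_eta))
                se_real = se_eta * est * (1 - est)
                confounded = bool(
                    fitted.null_directions.size
                    and np.any(np.abs(fitted.null_directions.T @ xf) > 1e-6 * max(1.0, np.linalg.norm(xf)))
                )
                estimable = not (
                    confounded or se_real > se_threshold or abs(eta) > eta_threshold
                )
                out.append((s, t, est, se_real, lcl, ucl, estimable))
        return out

    phi_rows = rows(design.x_phi, b_phi, 0, "phi")
    real_phi = pd.DataFrame(
        {
            "sex": [_SEXLAB[s] for s, *_ in phi_rows],
            "year_start": [years[t] for _, t, *_ in phi_rows],
            "year_end": [years[t + 1] for _, t, *_ in phi_rows],
            "estimate": [r[2] for r in phi_rows],
            "se": [r[3] for r in phi_rows],
            "lcl": [r[4] for r in phi_rows],
            "ucl": [r[5] for r in phi_rows],
            "estimable": [r[6] for r in phi_rows],
        }
    )
    p_rows = rows(design.x_p, b_p, design.k_phi, "p")
    real_p = pd.DataFrame(
        {
            "sex": [_SEXLAB[s] for s, *_ in p_rows],
            "year": [years[t + 1] for _, t, *_ in p_rows],
            "estimate": [r[2] for r in p_rows],
            "se": [r[3] for r in p_rows],
            "lcl": [r[4] for r in p_rows],
            "ucl": [r[5] for r in p_rows],
            "estimable": [r[6] for r in p_rows],
        }
    )
    return real_phi, real_p
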