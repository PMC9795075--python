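"""Latent class regression: class membership depends on a covariate.

Same measurement model as plain latent class analysis, but the class priors
become observation-specific through a multinomial logit,

    p_ir = exp(x_i' beta_r) / sum_q exp(x_i' beta_q),    beta_1 = 0,

with the stimulus-direction covariate coded numerically (down-only = 1,
up-only = 2, random = 3) so each non-reference class carries one intercept and
one DIRECTION coefficient. The EM M-step updates the outcome probabilities in
closed form and maximizes the expected multinomial-logit log-likelihood over
beta by Newton's method, so the observed log-likelihood is monotone.

Wald inference on the coefficients uses the observed information of the
profile log-likelihood: a numerical Hessian in beta where the outcome
probabilities are re-maximized (inner EM) at every perturbed beta, so the
uncertainty in the measurement model propagates into the coefficient SEs.
p-values come from a Student t reference with ``N - npar`` residual degrees
of freedom.

A full-length fit can demand more parameters than there are observations
(e.g. three classes on all 30 trials at N = 108); such fits are refused with
an explicit parameter-deficit diagnostic, which is why phase-wise fits on
blocks of 10 trials exist (:func:`fit_phases`).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .lca import LatentClassAnalysis, _as_matrix, _log_class_scores, _m_step
from .matrix import ResponseMatrix

log = logging.getLogger(__name__)


class DegreesOfFreedomError(ValueError):
    """The model asks for more parameters than the data can identify."""


def _softmax_rows(Z):
    return np.exp(Z - logsumexp(Z, axis=1)[:, None])


def _newton_logit(Xd, theta, B0, max_iter=100, grad_tol=1e-10, ridge=1e-10):
    """Maximize Q(B) = sum_ir theta_ir ln softmax(Xd B)_ir over the free rows
    B[1:]; row 0 stays the reference (zeros). Newton with step halving."""
    N, C = Xd.shape
    R = theta.shape[1]
    B = B0.copy()

    def q_of(Bm):
        Z = Xd @ Bm.T
        return float((theta * (Z - logsumexp(Z, axis=1)[:, None])).sum())

    q = q_of(B)
    for _ in range(max_iter):
        P = _softmax_rows(Xd @ B.T)
        G = Xd.T @ (theta[:, 1:] - P[:, 1:])  # (C, R-1)
        g = G.T.ravel()
        if np.max(np.abs(g)) < grad_tol:
            break
        H = np.zeros(((R - 1) * C, (R - 1) * C))
        for r in range(1, R):
            for s in range(1, R):
                w = P[:, r] * ((r == s) - P[:, s])
                H[(r - 1) * C:r * C, (s - 1) * C:s * C] = -(Xd.T * w) @ Xd
        scale = max(1.0, np.trace(-H) / H.shape[0])
        step = np.linalg.solve(-H + ridge * scale * np.eye(H.shape[0]), g)
        t = 1.0
        for _ in range(30):
            Bt = B.copy()
            Bt[1:] += t * step.reshape(R - 1, C)
            qt = q_of(Bt)
            if qt >= q - 1e-12:
                B, q = Bt, qt
                break
            t *= 0.5
        else:  # no ascent possible: converged to numerical precision
            break
    return B


class LatentClassRegression(LatentClassAnalysis):
    """Latent class model whose priors follow a multinomial logit in a
    covariate. Fit with ``fit(X)`` where X is a :class:`ResponseMatrix`
    carrying a covariate (or pass ``covariate=`` explicitly).

    Additional fitted attributes: ``coef_`` (R, C) with the reference class
    (largest share) as row 0 of zeros, ``se_``, ``tvalues_``, ``pvalues_``
    (NaN on the reference row), ``design_columns_``, ``prior_per_obs_``
    (N, R), ``residual_df_``.
    """

    def __init__(self, n_classes=3, n_restarts=30, max_iter=1000, tol=1e-10,
                 random_state=None, covariate_coding="numeric"):
        super().__init__(n_classes=n_classes, n_restarts=n_restarts,
                         max_iter=max_iter, tol=tol, random_state=random_state)
        self.covariate_coding = covariate_coding

    def get_params(self, deep=True):
        params = super().get_params(deep=deep)
        params["covariate_coding"] = self.covariate_coding
        return params

    # ------------------------------------------------------------- design
    def _design(self, x, levels=None):
        x = np.asarray(x, dtype=float)
        if self.covariate_coding == "numeric":
            return np.column_stack([np.ones_like(x), x]), ["intercept", "DIRECTION"]
        if self.covariate_coding == "dummy":
            levels = np.unique(x) if levels is None else levels
            cols = [np.ones_like(x)]
            names = ["intercept"]
            for lv in levels[1:]:
                cols.append((x == lv).astype(float))
                names.append(f"DIRECTION[{lv:g}]")
            return np.column_stack(cols), names
        raise ValueError(f"unknown covariate_coding {self.covariate_coding!r}")

    # ----------------------------------------------------------------- fit
    def fit(self, X, y=None, covariate=None):
        m = _as_matrix(X)
        x = m.covariate if covariate is None else np.asarray(covariate, float)
        if x is None:
            raise ValueError("a covariate is required for latent class regression")
        R = int(self.n_classes)
        Yidx, cats = m.encoded()
        Kj = np.array([len(c) for c in cats])
        Xd, design_names = self._design(x)
        C = Xd.shape[1]
        npar = int(R * np.sum(Kj - 1) + (R - 1) * C)
        if npar >= m.N:
            raise DegreesOfFreedomError(
                f"model needs {npar} parameters but only {m.N} observations are "
                f"available (deficit {npar - m.N + 1}): residual degrees of "
                f"freedom would be negative; fit shorter trial blocks instead")
        if m.N <= R:
            raise ValueError("need more observations than classes")
        Kmax = int(Kj.max())
        H = np.zeros((m.N, m.J, Kmax))
        np.put_along_axis(H, Yidx[:, :, None], 1.0, axis=2)

        root = np.random.SeedSequence(self.random_state)
        best = None
        for rep, child in enumerate(root.spawn(max(1, self.n_restarts))):
            rng = np.random.default_rng(child)
            run = self._em_single(Yidx, H, Kj, R, Xd, rng)
            if best is None or run[0] > best[0]:
                best, best_rep = run, rep
        ll, B, pi, theta, n_iter, converged, history = best
        if not converged:
            log.warning("EM did not converge within max_iter=%d", self.max_iter)

        prior = _softmax_rows(Xd @ B.T)
        order = np.argsort(-prior.mean(axis=0), kind="stable")
        B = B[order] - B[order][0]  # re-express against the largest class
        pi = pi[:, order, :]
        theta = theta[:, order]
        prior = prior[:, order]

        self.coef_ = B
        self.design_columns_ = design_names
        self.covariate_levels_ = np.unique(x)
        self.class_probs_ = pi
        self.posterior_ = theta
        self.prior_per_obs_ = prior
        self.priors_ = prior.mean(axis=0)
        self.loglik_ = ll
        self.loglik_history_ = history
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.best_restart_ = best_rep
        self.column_categories_ = cats
        self.n_obs_ = m.N
        self.n_parameters_ = npar
        self.residual_df_ = m.N - npar
        self.aic_ = -2.0 * ll + 2.0 * npar
        self.bic_ = -2.0 * ll + npar * np.log(m.N)
        from .lca import posterior_entropy
        self.entropy_ = posterior_entropy(theta)
        self.relative_entropy_ = 1.0 - self.entropy_ / np.log(R) if R > 1 else 1.0
        self._Yidx, self._H, self._Kj, self._Xd = Yidx, H, Kj, Xd
        inf = self.coefficient_inference(reference=0)
        self.se_ = inf["se"]
        self.tvalues_ = inf["t"]
        self.pvalues_ = inf["p"]
        self.labels_ = self.assign_classes()
        self.class_names_ = self.describe_classes()
        return self

    def _em_single(self, Yidx, H, Kj, R, Xd, rng):
        N, C = Xd.shape
        theta = rng.dirichlet(np.ones(R), size=N)
        B = np.zeros((R, C))
        prev = -np.inf
        history = []
        converged = False
        with np.errstate(divide="ignore"):
            for it in range(1, self.max_iter + 1):
                _, pi = _m_step(theta, H, Kj)
                B = _newton_logit(Xd, theta, B)
                log_prior = Xd @ B.T
                log_prior -= logsumexp(log_prior, axis=1)[:, None]
                S = _log_class_scores(Yidx, np.log(pi)) + log_prior
                norm = logsumexp(S, axis=1)
                ll = float(norm.sum())
                theta = np.exp(S - norm[:, None])
                history.append(ll)
                if ll < prev - 1e-8:
                    raise RuntimeError(
                        f"log-likelihood decreased at iteration {it}: "
                        f"{prev:.10f} -> {ll:.10f}")
                if abs(ll - prev) < self.tol:
                    converged = True
                    break
                prev = ll
        return ll, B, pi, theta, it, converged, history

    # ------------------------------------------------------------ inference
    def _pi_em(self, log_prior, pi0, tol=1e-11, max_iter=500):
        """Re-maximize the outcome probabilities at fixed per-observation
        priors (EM in pi only, warm-started); returns (pi, theta)."""
        pi = pi0
        prev = -np.inf
        with np.errstate(divide="ignore"):
            for _ in range(max_iter):
                S = _log_class_scores(self._Yidx, np.log(pi)) + log_prior
                norm = logsumexp(S, axis=1)
                ll = float(norm.sum())
                theta = np.exp(S - norm[:, None])
                if abs(ll - prev) < tol:
                    break
                prev = ll
                _, pi = _m_step(theta, self._H, self._Kj)
        return pi, theta

    def _profile_score(self, b_free, pi0, order):
        """Score of the profile log-likelihood in beta (envelope theorem: the
        partial beta-gradient at the inner pi maximum)."""
        R = len(self.priors_)
        C = self._Xd.shape[1]
        B = np.vstack([np.zeros(C), b_free.reshape(R - 1, C)])
        Z = self._Xd @ B.T
        log_prior = Z - logsumexp(Z, axis=1)[:, None]
        _, theta = self._pi_em(log_prior, pi0)
        P = np.exp(log_prior)
        return (self._Xd.T @ (theta[:, 1:] - P[:, 1:])).T.ravel()

    def coefficient_inference(self, reference: int = 0) -> dict:
        """Wald inference for the coefficients re-expressed against the given
        reference class index. Returns {'coef', 'se', 't', 'p'} arrays of
        shape (R, C); the reference row is 0 for coef and NaN for se/t/p, and
        rows keep the fitted class order.
        """
        self._check_fitted()
        R = len(self.priors_)
        C = self._Xd.shape[1]
        order = [reference] + [r for r in range(R) if r != reference]
        B = self.coef_[order] - self.coef_[reference]
        pi0 = self.class_probs_[:, order, :].copy()
        b = B[1:].ravel()
        n_free = b.size
        info = np.zeros((n_free, n_free))
        # step size large enough that incomplete inner maximization cannot
        # masquerade as curvature (the profile ridge is flat near the MLE)
        for l in range(n_free):
            h = 2e-2 * max(1.0, abs(b[l]))
            bp, bm = b.copy(), b.copy()
            bp[l] += h
            bm[l] -= h
            info[:, l] = -(self._profile_score(bp, pi0, order)
                           - self._profile_score(bm, pi0, order)) / (2 * h)
        info = 0.5 * (info + info.T)
        cov = np.linalg.pinv(info)
        se_free = np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(R - 1, C)
        coef = np.full((R, C), np.nan)
        se = np.full((R, C), np.nan)
        coef[reference] = 0.0
        for pos, r in enumerate(order[1:], start=1):
            coef[r] = B[pos]
            se[r] = se_free[pos - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / se
        df = max(self.residual_df_, 1)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        return {"coef": coef, "se": se, "t": t, "p": p}

    def predict_priors(self, levels) -> pd.DataFrame:
        """Prior class-membership probabilities at the requested covariate
        codes (multinomial logit); rows sum to 1. Unseen codes warn but are
        still evaluated (extrapolation)."""
        self._check_fitted()
        levels = np.atleast_1d(np.asarray(levels, dtype=float))
        unseen = ~np.isin(levels, self.covariate_levels_)
        if unseen.any():
            warnings.warn(
                f"covariate codes {levels[unseen].tolist()} were not observed "
                "during fitting; priors are extrapolated")
        Xd, _ = self._design(levels, levels=self.covariate_levels_)
        P = _softmax_rows(Xd @ self.coef_.T)
        return pd.DataFrame(
            P, index=pd.Index(levels, name="direction_code"),
            columns=[f"class_{r + 1}" for r in range(P.shape[1])])

    def predict_proba(self, X, covariate=None) -> np.ndarray:
        self._check_fitted()
        m = _as_matrix(X)
        x = m.covariate if covariate is None else np.asarray(covariate, float)
        if x is None:
            raise ValueError("a covariate is required")
        Yidx = np.empty_like(m.Y)
        for j, c in enumerate(self.column_categories_):
            pos = np.clip(np.searchsorted(c, m.Y[:, j]), 0, len(c) - 1)
            if not np.array_equal(c[pos], m.Y[:, j]):
                raise ValueError("X contains categories unseen during fitting")
            Yidx[:, j] = pos
        Xd, _ = self._design(x, levels=self.covariate_levels_)
        log_prior = Xd @ self.coef_.T
        log_prior -= logsumexp(log_prior, axis=1)[:, None]
        with np.errstate(divide="ignore"):
            S = _log_class_scores(Yidx, np.log(self.class_probs_)) + log_prior
        return np.exp(S - logsumexp(S, axis=1)[:, None])


def fit_lca_regression(matrix, n_classes=3, n_restarts=30, max_iter=1000,
                       tol=1e-10, seed=None, covariate=None,
                       covariate_coding="numeric") -> LatentClassRegression:
    """Functional wrapper over :class:`LatentClassRegression`."""
    return LatentClassRegression(
        n_classes=n_classes, n_restarts=n_restarts, max_iter=max_iter,
        tol=tol, random_state=seed, covariate_coding=covariate_coding,
    ).fit(matrix, covariate=covariate)


def fit_phases(matrix: ResponseMatrix, n_classes=3, phase_length=10,
               n_restarts=30, seed=None, **kwargs) -> dict:
    """Independent latent class regressions on consecutive trial blocks
    (initial / middle / final phase for J = 30, phase_length = 10).

    Returns {phase_name: fitted model or the exception it raised}; one failing
    phase does not abort the others.
    """
    if matrix.J % phase_length:
        raise ValueError(
            f"J={matrix.J} is not divisible by phase_length={phase_length}")
    n_phases = matrix.J // phase_length
    canonical = {3: ("initial", "middle", "final")}
    names = canonical.get(n_phases,
                          tuple(f"phase_{i + 1}" for i in range(n_phases)))
    root = np.random.SeedSequence(seed)
    out = {}
    for i, child in enumerate(root.spawn(n_phases)):
        sub = matrix.subset_columns(i * phase_length, (i + 1) * phase_length)
        phase_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            out[names[i]] = fit_lca_regression(
                sub, n_classes=n_classes, n_restarts=n_restarts,
                seed=phase_seed, **kwargs)
        except Exception as err:  # propagate per phase, keep the rest running
            log.warning("phase %s failed: %s", names[i], err)
            out[names[i]] = err
    return out


def coefficient_table(phase_fits: dict) -> pd.DataFrame:
    """Long-format coefficient table over phases: one row per phase x class x
    design column with estimate, SE, t and p."""
    rows = []
    for phase, fit in phase_fits.items():
        if isinstance(fit, Exception):
            continue
        for r in range(1, len(fit.priors_)):
            for c, name in enumerate(fit.design_columns_):
                rows.append({
                    "phase": phase,
                    "class": r + 1,
                    "class_name": fit.class_names_[r],
                    "term": name,
                    "estimate": fit.coef_[r, c],
                    "se": fit.se_[r, c],
                    "t": fit.tvalues_[r, c],
                    "p": fit.pvalues_[r, c],
                })
    return pd.DataFrame(rows)


def predicted_priors_table(phase_fits: dict, levels=(1, 2, 3)) -> pd.DataFrame:
    """Predicted prior class probabilities per phase x direction code."""
    frames = []
    for phase, fit in phase_fits.items():
        if isinstance(fit, Exception):
            continue
        t = fit.predict_priors(list(levels)).reset_index()
        t.insert(0, "phase", phase)
        frames.append(t)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
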