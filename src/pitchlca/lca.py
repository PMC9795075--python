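"""Polytomous latent class analysis by maximum likelihood.

The model: each observation i belongs to one of R unobserved classes with
prior probability ``p_r``; conditional on class r, its J categorical manifest
variables are independent, outcome k on variable j having probability
``pi_jrk``. The log-likelihood maximized is

    lnL = sum_i ln sum_r p_r prod_j prod_k pi_jrk ** Y_ijk

with ``Y_ijk`` the outcome indicator. Estimation is EM with multiple random
restarts (the study's nrep = 30): the E-step computes posterior class
memberships ``theta_ir``, the M-step sets ``p_r`` to the posterior mean and
``pi_jrk`` to posterior-weighted outcome frequencies. All likelihood work is
done in the log domain so J = 30 products cannot underflow.

Model selection reports AIC, BIC and posterior entropy per class count and
annotates the "strong support for the more complex model" region
(2 < AIC_{R+1} - AIC_R < 4).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .matrix import OUTCOME_CODES, ResponseMatrix

log = logging.getLogger(__name__)

PROB_FLOOR = 1e-10


def _as_matrix(X) -> ResponseMatrix:
    return X if isinstance(X, ResponseMatrix) else ResponseMatrix(np.asarray(X))


def _log_class_scores(Yidx: np.ndarray, log_pi: np.ndarray) -> np.ndarray:
    """S[i, r] = sum_j log pi[j, r, Y_ij]; shapes (N,J), (J,R,Kmax) -> (N,R)."""
    J = Yidx.shape[1]
    return log_pi[np.arange(J)[None, :], :, Yidx].sum(axis=1)


def loglikelihood(matrix, priors, probs) -> float:
    """Evaluate lnL = sum_i ln sum_r p_r prod_j pi_{j r y_ij} in the log domain.

    ``probs`` has shape (J, R, Kmax), slot k of column j referring to the j-th
    column's k-th *observed* category (matrix.column_categories order).
    """
    m = _as_matrix(matrix)
    priors = np.asarray(priors, dtype=float)
    probs = np.asarray(probs, dtype=float)
    R = priors.size
    if probs.shape[0] != m.J or probs.shape[1] != R:
        raise ValueError(f"probs shape {probs.shape} does not match J={m.J}, R={R}")
    Yidx, _ = m.encoded()
    with np.errstate(divide="ignore"):
        S = _log_class_scores(Yidx, np.log(probs))
        lp = np.log(priors)
    return float(logsumexp(lp[None, :] + S, axis=1).sum())


def _m_step(theta: np.ndarray, H: np.ndarray, Kj: np.ndarray):
    """Closed-form M-step: priors = posterior means, probs = weighted
    outcome frequencies, floored and renormalized over observed categories."""
    p = theta.mean(axis=0)
    if (p < PROB_FLOOR).any():
        log.debug("prior floor active")
    p = np.maximum(p, PROB_FLOOR)
    p /= p.sum()
    weight = theta.sum(axis=0)  # (R,)
    pi = np.einsum("ir,ijk->jrk", theta, H) / weight[None, :, None]
    Kmax = pi.shape[2]
    observed = np.arange(Kmax)[None, None, :] < Kj[:, None, None]
    pi = np.where(observed, np.maximum(pi, PROB_FLOOR), 0.0)
    pi /= pi.sum(axis=2, keepdims=True)
    return p, pi


def _em_single(Yidx, H, Kj, R, rng, max_iter, tol):
    """One EM run from a random Dirichlet posterior start.

    Returns (loglik, priors, probs, theta, n_iter, converged, history)."""
    N = Yidx.shape[0]
    theta = rng.dirichlet(np.ones(R), size=N)
    prev = -np.inf
    history = []
    converged = False
    for it in range(1, max_iter + 1):
        p, pi = _m_step(theta, H, Kj)
        with np.errstate(divide="ignore"):
            S = _log_class_scores(Yidx, np.log(pi)) + np.log(p)[None, :]
        norm = logsumexp(S, axis=1)
        ll = float(norm.sum())
        theta = np.exp(S - norm[:, None])
        history.append(ll)
        if ll + 1e-9 < prev:  # EM guarantees monotonicity up to rounding
            raise RuntimeError(f"log-likelihood decreased at iteration {it}")
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
    return ll, p, pi, theta, it, converged, history


def n_parameters(Kj, R: int) -> int:
    """R * sum_j (Kj - 1) free outcome probabilities + R - 1 free priors."""
    return int(R * np.sum(np.asarray(Kj) - 1) + (R - 1))


def posterior_entropy(theta: np.ndarray) -> float:
    """Average posterior-assignment entropy -(1/N) sum_ir theta ln theta
    (0 for a perfectly separated fit)."""
    t = np.clip(theta, 1e-300, 1.0)
    return float(-(theta * np.log(t)).sum() / theta.shape[0])


class LatentClassAnalysis:
    """Latent class model for polytomous sequences, scikit-learn style.

    Parameters
    ----------
    n_classes : int
        Number of latent classes R.
    n_restarts : int, default 30
        EM restarts from random initial posteriors; the best lnL wins.
    max_iter : int, default 1000
        Maximum EM iterations per restart.
    tol : float, default 1e-10
        Convergence threshold on the lnL change.
    random_state : int or None
        Master seed; spawns one child seed per restart.

    Fitted attributes (classes ordered by descending prior share):
    ``priors_`` (R,), ``class_probs_`` (J, R, Kmax), ``posterior_`` (N, R),
    ``loglik_``, ``n_parameters_``, ``aic_``, ``bic_``, ``entropy_``,
    ``relative_entropy_``, ``labels_``, ``class_names_``, ``converged_``,
    ``n_iter_``, ``best_restart_``, ``column_categories_``.
    """

    def __init__(self, n_classes=2, n_restarts=30, max_iter=1000, tol=1e-10,
                 random_state=None):
        self.n_classes = n_classes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # sklearn plumbing ------------------------------------------------------
    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("n_classes", "n_restarts", "max_iter", "tol", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------- fit
    def fit(self, X, y=None):
        m = _as_matrix(X)
        R = int(self.n_classes)
        if R < 1:
            raise ValueError("n_classes must be >= 1")
        if m.N < R:
            raise ValueError(f"need at least {R} observations for {R} classes")
        Yidx, cats = m.encoded()
        Kj = np.array([len(c) for c in cats])
        Kmax = int(Kj.max())
        H = np.zeros((m.N, m.J, Kmax))
        np.put_along_axis(H, Yidx[:, :, None], 1.0, axis=2)

        root = np.random.SeedSequence(self.random_state)
        best = None
        for rep, child in enumerate(root.spawn(max(1, self.n_restarts))):
            rng = np.random.default_rng(child)
            run = _em_single(Yidx, H, Kj, R, rng, self.max_iter, self.tol)
            if best is None or run[0] > best[0]:
                best, best_rep = run, rep
        ll, p, pi, theta, n_iter, converged, history = best
        if not converged:
            log.warning("EM did not converge within max_iter=%d", self.max_iter)

        order = np.argsort(-p, kind="stable")  # canonical: descending share
        self.priors_ = p[order]
        self.class_probs_ = pi[:, order, :]
        self.posterior_ = theta[:, order]
        self.loglik_ = ll
        self.loglik_history_ = history
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.best_restart_ = best_rep
        self.column_categories_ = cats
        self.n_obs_ = m.N
        self.n_parameters_ = n_parameters(Kj, R)
        self.aic_ = -2.0 * ll + 2.0 * self.n_parameters_
        self.bic_ = -2.0 * ll + self.n_parameters_ * np.log(m.N)
        self.entropy_ = posterior_entropy(self.posterior_)
        self.relative_entropy_ = (
            1.0 - self.entropy_ / np.log(R) if R > 1 else 1.0)
        self.labels_ = self.assign_classes()
        self.class_names_ = self.describe_classes()
        return self

    # ------------------------------------------------------------- inference
    def _check_fitted(self):
        if not hasattr(self, "priors_"):
            raise RuntimeError("model is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class-membership probabilities for new sequences."""
        self._check_fitted()
        m = _as_matrix(X)
        Yidx = np.empty_like(m.Y)
        for j, c in enumerate(self.column_categories_):
            pos = np.searchsorted(c, m.Y[:, j])
            pos = np.clip(pos, 0, len(c) - 1)
            if not np.array_equal(c[pos], m.Y[:, j]):
                raise ValueError("X contains categories unseen during fitting")
            Yidx[:, j] = pos
        with np.errstate(divide="ignore"):
            S = _log_class_scores(Yidx, np.log(self.class_probs_))
            S = S + np.log(self.priors_)[None, :]
        return np.exp(S - logsumexp(S, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        """Total log-likelihood of X under the fitted parameters."""
        self._check_fitted()
        m = _as_matrix(X)
        Yidx = np.empty_like(m.Y)
        for j, c in enumerate(self.column_categories_):
            pos = np.clip(np.searchsorted(c, m.Y[:, j]), 0, len(c) - 1)
            if not np.array_equal(c[pos], m.Y[:, j]):
                raise ValueError("X contains categories unseen during fitting")
            Yidx[:, j] = pos
        with np.errstate(divide="ignore"):
            S = _log_class_scores(Yidx, np.log(self.class_probs_))
            S = S + np.log(self.priors_)[None, :]
        return float(logsumexp(S, axis=1).sum())

    def assign_classes(self, theta=None) -> np.ndarray:
        """Modal class per observation (argmax posterior; ties -> lower index)."""
        self._check_fitted()
        theta = self.posterior_ if theta is None else theta
        return np.argmax(theta, axis=1)

    def describe_classes(self, opposing_threshold=0.6, following_threshold=0.6):
        """Descriptive class names from the fitted outcome profiles: a class
        whose mean opposing probability across trials exceeds the threshold is
        an 'opposer', mean following probability -> 'follower', else
        'switcher'."""
        self._check_fitted()
        names = []
        for r in range(len(self.priors_)):
            p_opp = np.mean([
                self.class_probs_[j, r, list(c).index(OUTCOME_CODES["opposing"])]
                if OUTCOME_CODES["opposing"] in c else 0.0
                for j, c in enumerate(self.column_categories_)
            ])
            p_fol = np.mean([
                self.class_probs_[j, r, list(c).index(OUTCOME_CODES["following"])]
                if OUTCOME_CODES["following"] in c else 0.0
                for j, c in enumerate(self.column_categories_)
            ])
            if p_opp > opposing_threshold:
                names.append("opposer")
            elif p_fol > following_threshold:
                names.append("follower")
            else:
                names.append("switcher")
        return names


def fit_lca(matrix, n_classes, n_restarts=30, max_iter=1000, tol=1e-10,
            seed=None) -> LatentClassAnalysis:
    """Functional wrapper over :class:`LatentClassAnalysis`."""
    return LatentClassAnalysis(
        n_classes=n_classes, n_restarts=n_restarts, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(matrix)


def fit_indices(fit: LatentClassAnalysis) -> dict:
    """(npar, AIC, BIC, posterior entropy) of a fitted model."""
    return {
        "n_parameters": fit.n_parameters_,
        "aic": fit.aic_,
        "bic": fit.bic_,
        "entropy_posterior": fit.entropy_,
        "relative_entropy": fit.relative_entropy_,
    }


def select_model(fits: list[LatentClassAnalysis]) -> pd.DataFrame:
    """Model-selection report over fits of the same data with different R.

    Flags the AIC and BIC minimizers and annotates rows where the AIC increase
    from the previous (simpler) model lies strictly inside (2, 4) — the
    "strong support for the more complex model" band.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    n_obs = {f.n_obs_ for f in fits}
    shapes = {len(f.column_categories_) for f in fits}
    if len(n_obs) > 1 or len(shapes) > 1:
        raise ValueError("fits compare different matrices")
    fits = sorted(fits, key=lambda f: len(f.priors_))
    rows = []
    prev_aic = None
    for f in fits:
        R = len(f.priors_)
        delta = None if prev_aic is None else f.aic_ - prev_aic
        rows.append({
            "n_classes": R,
            "loglik": f.loglik_,
            "n_parameters": f.n_parameters_,
            "n": f.n_obs_,
            "aic": f.aic_,
            "bic": f.bic_,
            "entropy_posterior": f.entropy_,
            "delta_aic": delta,
            "strong_support_more_complex":
                delta is not None and 2.0 < delta < 4.0,
        })
        prev_aic = f.aic_
    report = pd.DataFrame(rows)
    report["aic_best"] = report["aic"] == report["aic"].min()
    report["bic_best"] = report["bic"] == report["bic"].min()
    return report


def aic_delta_report(table: pd.DataFrame) -> pd.DataFrame:
    """Same selection arithmetic applied to an already-tabulated set of fit
    indices (columns n_classes, aic, bic, ...), e.g. a published table."""
    t = table.sort_values("n_classes").reset_index(drop=True).copy()
    t["delta_aic"] = t["aic"].diff()
    t["strong_support_more_complex"] = t["delta_aic"].apply(
        lambda d: bool(pd.notna(d) and 2.0 < d < 4.0))
    t["aic_best"] = t["aic"] == t["aic"].min()
    t["bic_best"] = t["bic"] == t["bic"].min()
    return t
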