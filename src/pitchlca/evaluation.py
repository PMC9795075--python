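"""Helpers for comparing fitted latent classes with a generating truth.

Latent class labels are only identified up to permutation; these utilities
find the best label matching (Hungarian assignment on the agreement matrix)
before computing agreement rates or share errors.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def match_labels(true_labels, fitted_labels, n_classes=None):
    """Permutation of fitted labels maximizing agreement with the truth.

    Returns ``(mapping, remapped)`` where ``mapping[r]`` is the true-class
    index assigned to fitted class r.
    """
    t = np.asarray(true_labels)
    f = np.asarray(fitted_labels)
    R = int(max(t.max(), f.max()) + 1) if n_classes is None else n_classes
    agreement = np.zeros((R, R))
    for r in range(R):
        for s in range(R):
            agreement[r, s] = np.sum((f == r) & (t == s))
    rows, cols = linear_sum_assignment(-agreement)
    mapping = {int(r): int(s) for r, s in zip(rows, cols)}
    remapped = np.array([mapping[int(r)] for r in f])
    return mapping, remapped


def label_agreement(true_labels, fitted_labels, n_classes=None) -> float:
    """Fraction of observations on which the best-matched fitted labels agree
    with the truth."""
    _, remapped = match_labels(true_labels, fitted_labels, n_classes)
    return float(np.mean(remapped == np.asarray(true_labels)))


def matched_share_errors(true_shares, priors, mapping) -> np.ndarray:
    """|estimated share - true share| per true class after label matching."""
    true_shares = np.asarray(true_shares, dtype=float)
    err = np.empty_like(true_shares)
    for r, s in mapping.items():
        err[s] = abs(priors[r] - true_shares[s])
    return err
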