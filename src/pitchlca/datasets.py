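"""Packaged reference tables.

``load_trial_counts`` returns the published per-trial response-type counts
(36 participants x 3 conditions x 30 trials); ``load_fit_indices`` returns the
published latent-class fit-index table (2–5 classes: LL, parameter count, n,
AIC, BIC, entropy).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("pitchlca.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_trial_counts() -> pd.DataFrame:
    """Per-trial counts: condition, trial, opposing/following/nonresponse/error."""
    return _read("table1_counts.csv")


def load_fit_indices() -> pd.DataFrame:
    """Published fit indices per class count (LL, n_parameters, n, AIC, BIC)."""
    return _read("table2_fit_indices.csv")
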