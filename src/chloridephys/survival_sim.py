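"""Synthetic per-culture neuronal survival counts."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError

SURVIVAL_COLUMNS = ["culture_id", "condition", "vital", "degenerated"]


def generate_survival_counts(true_fractions: dict, cells_per_culture: int = 200,
                             n_cultures: int = 6, seed: int = 0) -> pd.DataFrame:
    """Binomial per-culture counts of vital vs degenerated neurons.

    Parameters
    ----------
    true_fractions : dict condition -> survival probability in [0, 1]
    cells_per_culture : transfected neurons scored per culture and condition
    n_cultures : independent cultures; fewer than 2 triggers a warning
        because downstream statistics need replicates.

    Returns a tidy DataFrame with columns culture_id, condition, vital,
    degenerated.  Reproducible given ``seed``.
    """
    for cond, p in true_fractions.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"survival probability for {cond!r} must be in [0, 1]")
    if cells_per_culture < 1:
        raise ConfigError("cells_per_culture must be >= 1")
    if n_cultures < 2:
        warnings.warn("fewer than 2 cultures: downstream statistics need replicates",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cultures):
        culture = f"culture_{c:02d}"
        for cond, p in true_fractions.items():
            vital = int(rng.binomial(cells_per_culture, p))
            rows.append((culture, cond, vital, cells_per_culture - vital))
    return pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)
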