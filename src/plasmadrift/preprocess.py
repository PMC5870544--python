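"""Probabilistic quotient normalization (PQN) of feature tables.

PQN removes sample-level dilution-like intensity effects: each sample is
divided by the median of its feature-wise quotients against a reference
spectrum (Dieterle-style most-probable quotient).  The reference defaults to
the feature-wise median spectrum of the table itself; an external reference
vector is accepted so that a later batch (e.g. legacy samples measured months
apart) can be normalized against the training batch, bridging global
peak-shape batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import FeatureTable


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of PQN: normalized table, per-sample factors and the reference.

    Invariant: ``normalized * factors[:, None] == original`` to machine
    precision, and every factor is strictly positive.
    """

    normalized: FeatureTable
    factors: pd.Series
    reference: pd.Series


def median_reference(table: FeatureTable) -> pd.Series:
    """Feature-wise median spectrum across all samples."""
    return table.data.median(axis=0)


def pqn_normalize(
    table: FeatureTable, reference: pd.Series | np.ndarray | None = None
) -> NormalizationResult:
    """Normalize each sample by its most probable quotient against a reference.

    For sample ``i`` the factor is the median over features ``f`` of
    ``x[i, f] / r[f]``, restricted to features positive in both the sample and
    the reference; the normalized intensity is ``x[i, f] / factor_i``.
    All-zero feature columns are simply excluded from the quotient computation.

    Parameters
    ----------
    table:
        Non-empty feature table.
    reference:
        Optional external reference spectrum aligned to ``table`` features
        (by name when a Series).  Default: feature-wise median of ``table``.
    """
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("cannot normalize an empty feature table")
    if reference is None:
        ref = median_reference(table)
    elif isinstance(reference, pd.Series):
        missing = [f for f in table.feature_ids if f not in reference.index]
        if missing:
            raise ValueError(f"reference lacks features: {missing[:5]}")
        ref = reference.loc[table.data.columns].astype(float)
    else:
        ref = pd.Series(np.asarray(reference, dtype=float), index=table.data.columns)
    if (ref < 0).any() or not np.isfinite(ref).all():
        raise ValueError("reference spectrum must be finite and non-negative")

    x = table.values
    r = ref.to_numpy()
    factors = np.empty(table.n_samples)
    for i in range(table.n_samples):
        mask = (r > 0) & (x[i] > 0)
        if not mask.any():
            raise ValueError(
                f"sample {table.sample_ids[i]!r} has no positive overlap "
                "with the reference spectrum"
            )
        factors[i] = np.median(x[i, mask] / r[mask])
    normalized = FeatureTable(table.data.div(factors, axis=0))
    return NormalizationResult(
        normalized=normalized,
        factors=pd.Series(factors, index=table.data.index, name="pqn_factor"),
        reference=ref.rename("reference"),
    )
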