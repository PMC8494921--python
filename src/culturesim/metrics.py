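"""Population-level summary statistics recorded each time step."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import PayoffPool

__all__ = ["gini_simpson", "mean_payoff"]


def gini_simpson(variants: Sequence[int] | np.ndarray) -> float:
    """Gini-Simpson diversity index, ``1 - sum_v (n_v / N)^2``.

    The probability that two agents drawn at random (with replacement) hold
    different variants: 0 when one variant is fixed, ``1 - 1/N`` when all N
    agents hold distinct variants (e.g. 0.9 for N=10, 0.995 for N=200).
    The plain index is used, not the finite-sample unbiased correction.
    """
    variants = np.asarray(variants)
    if variants.size == 0:
        raise ValueError("variants must be non-empty")
    _, counts = np.unique(variants, return_counts=True)
    freqs = counts / variants.size
    return float(1.0 - np.sum(freqs**2))


def mean_payoff(variants: Sequence[int] | np.ndarray, pool: PayoffPool) -> float:
    """Arithmetic mean of the agents' variant payoffs."""
    variants = np.asarray(variants)
    if variants.size == 0:
        raise ValueError("variants must be non-empty")
    if (variants < 0).any() or (variants >= pool.size).any():
        raise ValueError("every variant id must index the pool")
    return float(pool.payoffs[variants].mean())
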