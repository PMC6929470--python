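"""The MG94xHKY omega^k codon model.

A model is a transition/transversion ratio kappa, equilibrium codon
frequencies pi, a mixture of omega (dN/dS) categories with proportions,
and a selection-intensity exponent k.  Reference branches evolve with
omega_i per category; test branches with omega_i^k.  k = 1 makes the two
processes identical; k < 1 relaxes selection on the test branches
(omega drawn towards 1), k > 1 intensifies it (omega pushed away
from 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import validate_freqs

K_MAX = 50.0  # upper bound on the selection-intensity exponent


@dataclass
class CodonModel:
    kappa: float
    codon_freqs: np.ndarray
    omega_categories: list[tuple[float, float]]  # (omega_i, proportion p_i)
    k: float = 1.0

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        self.codon_freqs = validate_freqs(self.codon_freqs)
        if not self.omega_categories:
            raise ValueError("at least one omega category is required")
        omegas = np.array([w for w, _ in self.omega_categories], dtype=float)
        props = np.array([p for _, p in self.omega_categories], dtype=float)
        if np.any(omegas < 0):
            raise ValueError("omega values must be >= 0")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-6:
            raise ValueError("category proportions must be >= 0 and sum to 1")
        if not (0.0 <= self.k <= K_MAX):
            raise ValueError(f"k must lie in [0, {K_MAX:g}], got {self.k}")
        self.omega_categories = [
            (float(w), float(p / props.sum())) for w, p in zip(omegas, props)
        ]

    @property
    def omegas(self) -> np.ndarray:
        return np.array([w for w, _ in self.omega_categories])

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for _, p in self.omega_categories])

    def test_omegas(self) -> np.ndarray:
        """Effective omega on test branches: omega_i^k."""
        return self.omegas**self.k
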