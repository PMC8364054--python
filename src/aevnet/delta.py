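"""Delta-learning combiner: baseline docking score + learned correction.

Baseline scores ``S`` (kcal/mol, AutoDock-Vina-style, negative =
favourable) are converted to pK via ``pK = -log10(exp(S / RT))``
= ``-S / (R T ln 10)`` and the model is trained on the residuals
``pk_exp - pK(S)``; the final prediction is the sum of both parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhysicalConstants",
    "DeltaPrediction",
    "vina_to_pk",
    "delta_train_targets",
    "delta_predict",
]

#: Ideal gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class PhysicalConstants:
    R: float = GAS_CONSTANT_KCAL  # kcal mol^-1 K^-1
    T: float = 295.0  # K
    c0: float = 1.0  # M, standard concentration implicit in pK

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class DeltaPrediction:
    S_pk: float  # baseline score converted to pK
    delta: float  # learned correction, pK
    std: Optional[float] = None

    @property
    def total(self) -> float:
        return self.S_pk + self.delta


def vina_to_pk(S: float, constants: PhysicalConstants = PhysicalConstants()) -> float:
    """Convert a docking score in kcal/mol to pK units (linear, decreasing)."""
    if not np.all(np.isfinite(S)):
        raise ValueError("baseline score must be finite")
    out = -np.asarray(S, dtype=np.float64) / (constants.R * constants.T * math.log(10.0))
    return float(out) if out.ndim == 0 else out


def delta_train_targets(
    records: Sequence[tuple[str, float, Optional[float]]],
    constants: PhysicalConstants = PhysicalConstants(),
) -> list[float]:
    """Residual regression targets ``pk_exp - vina_to_pk(S)``.

    ``records`` are (id, pk_exp, baseline_score) triples; a missing
    baseline is an error listing all offending ids.
    """
    missing = [rid for rid, _, S in records if S is None]
    if missing:
        raise ValueError(f"records without baseline_score: {missing}")
    return [pk_exp - vina_to_pk(S, constants) for _, pk_exp, S in records]


def delta_predict(model, aevs, species, S: float,
                  constants: PhysicalConstants = PhysicalConstants()) -> DeltaPrediction:
    """Total affinity = converted baseline + model correction.

    ``model`` is any object with a ``predict(aevs, species)`` method
    returning a pk (single model or ensemble).
    """
    pred = model.predict(aevs, species)
    return DeltaPrediction(S_pk=vina_to_pk(S, constants), delta=pred.pk,
                           std=getattr(pred, "std", None))
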