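"""Interpretability: coordinate gradients and per-atom contributions.

The model is differentiable end to end, so the gradient of the predicted
affinity with respect to atomic coordinates is available analytically by
chaining the network's input gradients through the featurizer's backward
pass. Contributions and gradient norms can be written into the PDB
B-factor column for visualisation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .aev import AEVParams, compute_aevs, aev_backward
from .chem_io import AtomicSystem

__all__ = [
    "AttributionResult",
    "coordinate_gradients",
    "atomic_contributions",
    "attribute",
    "write_attributed_pdb",
    "optimize_pose",
]


@dataclass
class AttributionResult:
    grad: np.ndarray  # (N, 3), pK / Angstrom
    contributions: np.ndarray  # (N,), pK
    pk: float

    @property
    def grad_norm(self) -> np.ndarray:
        return np.linalg.norm(self.grad, axis=1)


def _featurize(model, system: AtomicSystem):
    aevs = compute_aevs(system, model.aev_params)
    sp = model.species_indices(system.elements)
    return aevs, sp


def coordinate_gradients(model, system: AtomicSystem) -> np.ndarray:
    """d(predicted pK)/d(coords), shape (N, 3)."""
    aevs, sp = _featurize(model, system)
    grad_aev = model.input_gradients(aevs, sp)
    return aev_backward(system, model.aev_params, grad_aev)


def atomic_contributions(model, system: AtomicSystem) -> np.ndarray:
    """Per-atom network outputs (pK); they sum exactly to the prediction."""
    aevs, sp = _featurize(model, system)
    return model.predict(aevs, sp).atomic_contributions


def attribute(model, system: AtomicSystem) -> AttributionResult:
    aevs, sp = _featurize(model, system)
    pred = model.predict(aevs, sp)
    grad_aev = model.input_gradients(aevs, sp)
    grad = aev_backward(system, model.aev_params, grad_aev)
    return AttributionResult(grad=grad, contributions=pred.atomic_contributions,
                             pk=pred.pk)


def write_attributed_pdb(system: AtomicSystem, values: np.ndarray, path) -> None:
    """Write the system as PDB with ``values`` in the B-factor column."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (system.n_atoms,):
        raise ValueError("values must be one scalar per atom")
    with open(path, "w") as fh:
        for k, (el, xyz, is_lig) in enumerate(
            zip(system.elements, system.coords, system.ligand_mask), start=1
        ):
            resname = "LIG" if is_lig else "PRT"
            name = (el[:2] + str(k))[:4]
            fh.write(
                f"HETATM{k:5d} {name:<4s}{resname:>4s} A{1 if is_lig else 2:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}"
                f"{np.clip(values[k - 1], -999.99, 999.99):6.2f}          "
                f"{el:>2s}\n"
            )
        fh.write("END\n")


def write_attribution_csv(system: AtomicSystem, result: AttributionResult, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["atom", "element", "is_ligand", "contribution_pk",
                    "grad_x", "grad_y", "grad_z", "grad_norm"])
        for k in range(system.n_atoms):
            w.writerow([
                k, system.elements[k], bool(system.ligand_mask[k]),
                result.contributions[k], *result.grad[k], result.grad_norm[k],
            ])


def optimize_pose(model, system: AtomicSystem, n_steps: int = 10,
                  step: float = 0.01, max_step: float = 0.05) -> AtomicSystem:
    """Experimental: gradient ascent of the prediction over ligand coordinates.

    Moves only ligand atoms, with a per-atom displacement cap per step.
    """
    coords = system.coords.copy()
    lig = system.ligand_mask
    current = AtomicSystem(list(system.elements), coords, lig.copy())
    for _ in range(n_steps):
        g = coordinate_gradients(model, current)
        move = step * g
        norms = np.linalg.norm(move, axis=1, keepdims=True)
        scale = np.where(norms > max_step, max_step / np.maximum(norms, 1e-12), 1.0)
        coords = coords + move * scale * lig[:, None]
        current = AtomicSystem(list(system.elements), coords, lig.copy())
    return current
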