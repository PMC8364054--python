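"""Atom-centred symmetry functions and atomic environment vectors (AEVs).

Each atom ``i`` is described by a fixed-length feature vector built from
radial and angular symmetry functions of its neighbourhood:

* cutoff:   ``f_c(R) = 1/2 [cos(pi R / Rc) + 1]`` for ``R <= Rc``, else 0
* radial:   ``G^R_(i; a, m) = sum_{j != i, j in a} exp(-eta_R (R_ij - R_s)^2) f_c(R_ij)``
* angular:  ``G^A_(i; {a,b}, m) = 2^(1-zeta) sum_{(j,k)} [1 + cos(theta_ijk - theta_s)]^zeta
  * exp(-eta_A ((R_ij + R_ik)/2 - R_s)^2) f_c(R_ij) f_c(R_ik)``

where the angular sum runs over *unordered* neighbour pairs ``(j, k)``,
each counted once and assigned to the unordered species pair ``{a, b}``.

Feature layout (frozen; trained weights depend on it):
radial blocks for each species in ``params.species`` order, each of length
``len(radial_shifts)``; then angular blocks for species pairs in
lexicographic index order (``a_idx <= b_idx``), each block iterating
theta shifts (outer) then angular radial shifts (inner).

All accumulation is done in double precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "AEVParams",
    "AEVMatrix",
    "cutoff",
    "cutoff_derivative",
    "radial_terms",
    "angular_terms",
    "compute_aevs",
    "aev_backward",
    "aev_length",
]

# ANI-1x symmetry-function constants (external reference values, not fitted
# here); used as overridable defaults.
_ANI1X_RADIAL_RC = 5.2
_ANI1X_ETA_R = 16.0
_ANI1X_N_RADIAL_SHIFTS = 16
_ANI1X_RADIAL_SHIFT_START = 0.9
_ANI1X_ANGULAR_RC = 3.5
_ANI1X_ETA_A = 8.0
_ANI1X_ZETA = 32.0


def _default_radial_shifts() -> list[float]:
    start, rc, n = _ANI1X_RADIAL_SHIFT_START, _ANI1X_RADIAL_RC, _ANI1X_N_RADIAL_SHIFTS
    step = (rc - start) / n
    return [start + k * step for k in range(n)]


@dataclass(frozen=True)
class AEVParams:
    """Hyperparameters of the symmetry functions plus the species order.

    The species order together with the shift grids fully determines the
    AEV layout, so instances should be persisted alongside trained models.
    """

    species: tuple[str, ...]
    Rc_radial: float = _ANI1X_RADIAL_RC
    Rc_angular: float = _ANI1X_ANGULAR_RC
    eta_R: float = _ANI1X_ETA_R
    radial_shifts: tuple[float, ...] = tuple(_default_radial_shifts())
    eta_A: float = _ANI1X_ETA_A
    zeta: float = _ANI1X_ZETA
    theta_shifts: tuple[float, ...] = (0.0, math.pi)
    angular_radial_shifts: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "radial_shifts", tuple(self.radial_shifts))
        object.__setattr__(self, "theta_shifts", tuple(self.theta_shifts))
        object.__setattr__(
            self, "angular_radial_shifts", tuple(self.angular_radial_shifts)
        )
        if not self.species:
            raise ValueError("species list must be non-empty")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if self.Rc_radial <= 0 or self.Rc_angular <= 0:
            raise ValueError("cutoffs must be positive")
        if not self.radial_shifts or not self.theta_shifts or not self.angular_radial_shifts:
            raise ValueError("shift lists must be non-empty")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")

    # -- layout helpers -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_radial_per_species(self) -> int:
        return len(self.radial_shifts)

    @property
    def n_angular_per_pair(self) -> int:
        return len(self.theta_shifts) * len(self.angular_radial_shifts)

    @property
    def radial_length(self) -> int:
        return self.n_species * self.n_radial_per_species

    @property
    def angular_length(self) -> int:
        n = self.n_species
        return n * (n + 1) // 2 * self.n_angular_per_pair

    def species_index(self, label: str) -> int:
        try:
            return self.species.index(label)
        except ValueError:
            raise KeyError(f"species {label!r} not in AEVParams.species") from None

    def pair_index(self, a: int, b: int) -> int:
        """Index of the unordered species pair block (a_idx <= b_idx)."""
        if a > b:
            a, b = b, a
        n = self.n_species
        # pairs (0,0)..(0,n-1), (1,1)..(1,n-1), ...
        return a * n - a * (a - 1) // 2 + (b - a)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(self.species)
        d["radial_shifts"] = list(self.radial_shifts)
        d["theta_shifts"] = list(self.theta_shifts)
        d["angular_radial_shifts"] = list(self.angular_radial_shifts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AEVParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AEVParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "AEVParams":
        return cls.from_dict(json.loads(s))


@dataclass
class AEVMatrix:
    """Per-atom feature vectors, row-aligned with the system's atoms."""

    values: np.ndarray  # (N, L)
    params: AEVParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("AEVMatrix.values must be 2-D")
        if self.values.shape[1] != aev_length(self.params):
            raise ValueError(
                f"row length {self.values.shape[1]} does not match layout "
                f"{aev_length(self.params)}"
            )

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")


def aev_length(params: AEVParams) -> int:
    """Total per-atom feature length for the given parameter set."""
    return params.radial_length + params.angular_length


def cutoff(Rij, Rc: float):
    """Cosine cutoff: 1 at R=0, 0 at and beyond R=Rc; scalar or array."""
    R = np.asarray(Rij, dtype=np.float64)
    if np.any(R < 0):
        raise ValueError("distances must be non-negative")
    if Rc <= 0:
        raise ValueError("cutoff radius must be positive")
    out = np.where(R <= Rc, 0.5 * (np.cos(np.pi * R / Rc) + 1.0), 0.0)
    return out if out.ndim else float(out)


def cutoff_derivative(Rij, Rc: float):
    """d f_c / dR; zero beyond the cutoff."""
    R = np.asarray(Rij, dtype=np.float64)
    out = np.where(R <= Rc, -0.5 * np.pi / Rc * np.sin(np.pi * R / Rc), 0.0)
    return out if out.ndim else float(out)


def _species_indices(system, params: AEVParams) -> np.ndarray:
    idx = np.empty(len(system.elements), dtype=np.intp)
    for i, el in enumerate(system.elements):
        idx[i] = params.species_index(el)
    return idx


def _pair_lists(coords: np.ndarray, rc: float):
    """Indices (i, j), i != j, with R_ij <= rc, plus distances and vectors."""
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    mask = (dist <= rc) & ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(mask)
    return ii, jj, dist, diff


def radial_terms(system, i: int, params: AEVParams) -> np.ndarray:
    """Radial part of atom ``i``'s AEV (length n_species * n_radial_shifts)."""
    aevs = compute_aevs(system, params)
    return aevs.values[i, : params.radial_length].copy()


def angular_terms(system, i: int, params: AEVParams) -> np.ndarray:
    """Angular part of atom ``i``'s AEV."""
    aevs = compute_aevs(system, params)
    return aevs.values[i, params.radial_length :].copy()


def compute_aevs(system, params: AEVParams) -> AEVMatrix:
    """Compute the AEV of every atom in ``system``.

    Depends only on interatomic distances, included angles and species,
    hence is invariant under rigid transforms, reflections, and exchange
    of same-species atoms.
    """
    coords = np.asarray(system.coords, dtype=np.float64)
    n = coords.shape[0]
    sp = _species_indices(system, params)
    L = aev_length(params)
    out = np.zeros((n, L))
    if n == 0:
        return AEVMatrix(out, params)

    n_rad = params.n_radial_per_species
    rs = np.asarray(params.radial_shifts)

    # ---- radial part ----
    ii, jj, dist, _ = _pair_lists(coords, params.Rc_radial)
    if ii.size:
        r = dist[ii, jj]
        if np.any(r == 0.0):
            raise ValueError("coincident atoms (zero interatomic distance)")
        fc = cutoff(r, params.Rc_radial)
        terms = np.exp(-params.eta_R * (r[:, None] - rs[None, :]) ** 2) * fc[:, None]
        cols = sp[jj][:, None] * n_rad + np.arange(n_rad)[None, :]
        np.add.at(out, (ii[:, None], cols), terms)

    # ---- angular part ----
    trip = _triples(coords, params.Rc_angular)
    if trip is not None:
        ti, tj, tk, r1, r2, cos_t = trip
        ang = _angular_term_values(r1, r2, cos_t, params)  # (T, n_ang)
        pair_idx = np.empty(ti.shape, dtype=np.intp)
        for t in range(ti.size):
            pair_idx[t] = params.pair_index(sp[tj[t]], sp[tk[t]])
        n_ang = params.n_angular_per_pair
        cols = (
            params.radial_length
            + pair_idx[:, None] * n_ang
            + np.arange(n_ang)[None, :]
        )
        np.add.at(out, (ti[:, None], cols), ang)

    return AEVMatrix(out, params)


def _triples(coords: np.ndarray, rc: float):
    """Unordered neighbour pairs (j < k in enumeration order) around each centre.

    Returns centre/neighbour indices, the two distances and cos(theta).
    """
    n = coords.shape[0]
    if n < 3:
        return None
    diff = coords[:, None, :] - coords[None, :, :]  # diff[i, j] = r_i - r_j
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    mask = (dist <= rc) & ~np.eye(n, dtype=bool)
    ti_l, tj_l, tk_l = [], [], []
    for i in range(n):
        nb = np.nonzero(mask[i])[0]
        if nb.size < 2:
            continue
        a, b = np.triu_indices(nb.size, k=1)
        ti_l.append(np.full(a.size, i, dtype=np.intp))
        tj_l.append(nb[a])
        tk_l.append(nb[b])
    if not ti_l:
        return None
    ti = np.concatenate(ti_l)
    tj = np.concatenate(tj_l)
    tk = np.concatenate(tk_l)
    v1 = coords[tj] - coords[ti]
    v2 = coords[tk] - coords[ti]
    r1 = dist[ti, tj]
    r2 = dist[ti, tk]
    if np.any(r1 == 0.0) or np.any(r2 == 0.0):
        raise ValueError("coincident atoms: angle undefined")
    cos_t = np.einsum("ij,ij->i", v1, v2) / (r1 * r2)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    return ti, tj, tk, r1, r2, cos_t


def _angular_term_values(r1, r2, cos_t, params: AEVParams) -> np.ndarray:
    """Angular summands for each triple; columns iterate theta (outer), R_s (inner)."""
    theta = np.arccos(cos_t)
    fc = cutoff(r1, params.Rc_angular) * cutoff(r2, params.Rc_angular)
    ravg = 0.5 * (r1 + r2)
    ths = np.asarray(params.theta_shifts)
    ars = np.asarray(params.angular_radial_shifts)
    angfac = (1.0 + np.cos(theta[:, None] - ths[None, :])) ** params.zeta  # (T, n_th)
    radfac = np.exp(-params.eta_A * (ravg[:, None] - ars[None, :]) ** 2)  # (T, n_rs)
    pre = 2.0 ** (1.0 - params.zeta)
    vals = pre * angfac[:, :, None] * radfac[:, None, :] * fc[:, None, None]
    return vals.reshape(r1.shape[0], -1)


def aev_backward(system, params: AEVParams, grad_out: np.ndarray) -> np.ndarray:
    """Back-propagate d(scalar)/d(AEV) to Cartesian coordinates.

    ``grad_out`` has shape (N, L); returns (N, 3) with
    ``g[a] = sum_{i,l} grad_out[i, l] * d AEV[i, l] / d coords[a]``.
    Used for end-to-end coordinate gradients of model predictions.
    """
    coords = np.asarray(system.coords, dtype=np.float64)
    n = coords.shape[0]
    sp = _species_indices(system, params)
    grad_out = np.asarray(grad_out, dtype=np.float64)
    if grad_out.shape != (n, aev_length(params)):
        raise ValueError("grad_out shape mismatch")
    gcoords = np.zeros((n, 3))

    n_rad = params.n_radial_per_species
    rs = np.asarray(params.radial_shifts)

    # ---- radial ----
    ii, jj, dist, diff = _pair_lists(coords, params.Rc_radial)
    if ii.size:
        r = dist[ii, jj]
        if np.any(r == 0.0):
            raise ValueError("coincident atoms (zero interatomic distance)")
        fc = cutoff(r, params.Rc_radial)
        dfc = cutoff_derivative(r, params.Rc_radial)
        gauss = np.exp(-params.eta_R * (r[:, None] - rs[None, :]) ** 2)
        # d term / dR
        dterm = gauss * (
            -2.0 * params.eta_R * (r[:, None] - rs[None, :]) * fc[:, None]
            + dfc[:, None]
        )
        cols = sp[jj][:, None] * n_rad + np.arange(n_rad)[None, :]
        g = grad_out[ii[:, None], cols]  # (P, n_rad)
        dR = np.sum(g * dterm, axis=1)  # (P,)
        unit = diff[ii, jj] / r[:, None]  # d R_ij / d x_i
        np.add.at(gcoords, ii, dR[:, None] * unit)
        np.add.at(gcoords, jj, -dR[:, None] * unit)

    # ---- angular ----
    trip = _triples(coords, params.Rc_angular)
    if trip is not None:
        ti, tj, tk, r1, r2, cos_t = trip
        v1 = coords[tj] - coords[ti]
        v2 = coords[tk] - coords[ti]
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
        rc = params.Rc_angular
        fc1, fc2 = cutoff(r1, rc), cutoff(r2, rc)
        dfc1, dfc2 = cutoff_derivative(r1, rc), cutoff_derivative(r2, rc)
        ravg = 0.5 * (r1 + r2)
        ths = np.asarray(params.theta_shifts)
        ars = np.asarray(params.angular_radial_shifts)
        zeta = params.zeta
        pre = 2.0 ** (1.0 - zeta)

        angfac = (1.0 + np.cos(theta[:, None] - ths[None, :])) ** zeta
        # d/d theta of (1 + cos(theta - ths))^zeta
        dang_dtheta = (
            -zeta
            * (1.0 + np.cos(theta[:, None] - ths[None, :])) ** (zeta - 1.0)
            * np.sin(theta[:, None] - ths[None, :])
        )
        radfac = np.exp(-params.eta_A * (ravg[:, None] - ars[None, :]) ** 2)
        drad_dravg = radfac * (-2.0 * params.eta_A * (ravg[:, None] - ars[None, :]))

        pair_idx = np.empty(ti.shape, dtype=np.intp)
        for t in range(ti.size):
            pair_idx[t] = params.pair_index(sp[tj[t]], sp[tk[t]])
        n_ang = params.n_angular_per_pair
        cols = (
            params.radial_length
            + pair_idx[:, None] * n_ang
            + np.arange(n_ang)[None, :]
        )
        g = grad_out[ti[:, None], cols].reshape(ti.size, len(ths), len(ars))

        fcprod = (fc1 * fc2)[:, None, None]
        # partials of the summand wrt theta, ravg, r1, r2
        d_theta = np.sum(
            g * pre * dang_dtheta[:, :, None] * radfac[:, None, :] * fcprod,
            axis=(1, 2),
        )
        d_ravg = np.sum(
            g * pre * angfac[:, :, None] * drad_dravg[:, None, :] * fcprod,
            axis=(1, 2),
        )
        base = np.sum(g * pre * angfac[:, :, None] * radfac[:, None, :], axis=(1, 2))
        d_r1 = 0.5 * d_ravg + base * dfc1 * fc2
        d_r2 = 0.5 * d_ravg + base * fc1 * dfc2

        u1 = v1 / r1[:, None]  # d r1 / d x_j
        u2 = v2 / r2[:, None]
        np.add.at(gcoords, tj, d_r1[:, None] * u1)
        np.add.at(gcoords, tk, d_r2[:, None] * u2)
        np.add.at(gcoords, ti, -(d_r1[:, None] * u1 + d_r2[:, None] * u2))

        # d theta / d x via d cos(theta): dtheta/dcos = -1/sin(theta)
        # guard: at theta = 0 or pi, sin -> 0; d_theta also -> 0 for the
        # restricted theta shifts {0, pi}, so the ratio is taken safely.
        safe_sin = np.where(sin_t < 1e-12, 1.0, sin_t)
        d_cos = np.where(sin_t < 1e-12, 0.0, -d_theta / safe_sin)
        inv_r1r2 = 1.0 / (r1 * r2)
        dcos_dxj = v2 * inv_r1r2[:, None] - cos_t[:, None] * v1 / (r1**2)[:, None]
        dcos_dxk = v1 * inv_r1r2[:, None] - cos_t[:, None] * v2 / (r2**2)[:, None]
        np.add.at(gcoords, tj, d_cos[:, None] * dcos_dxj)
        np.add.at(gcoords, tk, d_cos[:, None] * dcos_dxk)
        np.add.at(gcoords, ti, -d_cos[:, None] * (dcos_dxj + dcos_dxk))

    return gcoords
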