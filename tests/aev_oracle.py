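"""Naive reference implementation of the symmetry functions.

Deliberately independent of :mod:`aevnet.aev`: plain Python loops over
all pairs and all ordered neighbour pairs, transcribed directly from the
defining formulas. Used only to cross-check the vectorized featurizer.
"""

import math

import numpy as np


def oracle_cutoff(r, rc):
    if r > rc:
        return 0.0
    return 0.5 * (math.cos(math.pi * r / rc) + 1.0)


def oracle_aev_row(system, i, params):
    coords = np.asarray(system.coords, float)
    elements = list(system.elements)
    n = len(elements)
    sp_index = {s: k for k, s in enumerate(params.species)}
    ns = len(params.species)

    radial = [0.0] * (ns * len(params.radial_shifts))
    for j in range(n):
        if j == i:
            continue
        rij = math.dist(coords[i], coords[j])
        if rij > params.Rc_radial:
            continue
        a = sp_index[elements[j]]
        for m, rs in enumerate(params.radial_shifts):
            radial[a * len(params.radial_shifts) + m] += (
                math.exp(-params.eta_R * (rij - rs) ** 2)
                * oracle_cutoff(rij, params.Rc_radial)
            )

    # unordered species-pair blocks, lexicographic (a <= b)
    pairs = [(a, b) for a in range(ns) for b in range(a, ns)]
    pair_pos = {p: k for k, p in enumerate(pairs)}
    n_ang = len(params.theta_shifts) * len(params.angular_radial_shifts)
    angular = [0.0] * (len(pairs) * n_ang)
    for j in range(n):
        for k in range(j + 1, n):  # each unordered neighbour pair once
            if j == i or k == i:
                continue
            rij = math.dist(coords[i], coords[j])
            rik = math.dist(coords[i], coords[k])
            if rij > params.Rc_angular or rik > params.Rc_angular:
                continue
            v1 = coords[j] - coords[i]
            v2 = coords[k] - coords[i]
            cos_t = float(np.dot(v1, v2)) / (rij * rik)
            cos_t = max(-1.0, min(1.0, cos_t))
            theta = math.acos(cos_t)
            a, b = sorted((sp_index[elements[j]], sp_index[elements[k]]))
            block = pair_pos[(a, b)]
            col = 0
            for ts in params.theta_shifts:
                for rs in params.angular_radial_shifts:
                    val = (
                        2.0 ** (1.0 - params.zeta)
                        * (1.0 + math.cos(theta - ts)) ** params.zeta
                        * math.exp(-params.eta_A * ((rij + rik) / 2.0 - rs) ** 2)
                        * oracle_cutoff(rij, params.Rc_angular)
                        * oracle_cutoff(rik, params.Rc_angular)
                    )
                    angular[block * n_ang + col] += val
                    col += 1
    return np.array(radial + angular)


def oracle_aevs(system, params):
    return np.array([
        oracle_aev_row(system, i, params) for i in range(len(system.elements))
    ])
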