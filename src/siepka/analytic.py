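"""Closed-form reference energies for validating the Poisson solver.

These are textbook results for charges inside a spherical low-dielectric
cavity embedded in a high-dielectric continuum; the grid solver is checked
against them in the test suite and the acceptance script.
"""
from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

from .electrostatics import COULOMB_K

__all__ = ["born_energy", "kirkwood_energy"]


def born_energy(q: float, radius: float, eps_in: float, eps_out: float) -> float:
    """Born solvation energy (kcal/mol) of a point charge centred in a
    sphere: ``-(k q² / 2a)(1/eps_in − 1/eps_out)``."""
    return -COULOMB_K * q * q / (2.0 * radius) * (1.0 / eps_in - 1.0 / eps_out)


def kirkwood_energy(coords, charges, radius: float, eps_in: float,
                    eps_out: float, lmax: int = 30) -> float:
    """Reaction-field energy (kcal/mol) of point charges inside a spherical
    cavity, from the Kirkwood multipole expansion truncated at ``lmax``.

    ``W = (k/2) Σ_l B_l Σ_ij q_i q_j r_i^l r_j^l P_l(cos γ_ij)`` with
    ``B_l = (l+1)(eps_in − eps_out) / (eps_in [l eps_in + (l+1) eps_out] a^{2l+1})``.
    The l = 0 term reduces to the Born expression.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    r = np.linalg.norm(coords, axis=1)
    if np.any(r >= radius):
        raise ValueError("all charges must lie strictly inside the cavity")
    # cos of the angle between every pair of position vectors
    with np.errstate(invalid="ignore"):
        unit = np.where(r[:, None] > 0, coords / np.maximum(r, 1e-12)[:, None], 0.0)
    cosg = np.clip(unit @ unit.T, -1.0, 1.0)
    # charges at the centre interact isotropically (P_l terms vanish for l>0)
    at_center = r < 1e-12
    cosg[at_center, :] = 1.0
    cosg[:, at_center] = 1.0

    qq = np.outer(charges, charges)
    w = 0.0
    for l in range(lmax + 1):
        b_l = ((l + 1) * (eps_in - eps_out)
               / (eps_in * (l * eps_in + (l + 1) * eps_out) * radius ** (2 * l + 1)))
        rl = r ** l
        w += b_l * float(np.sum(qq * np.outer(rl, rl) * eval_legendre(l, cosg)))
    return 0.5 * COULOMB_K * w
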