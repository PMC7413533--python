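"""Accelerated-MD dual-boost mathematics.

Accelerated MD adds a boost potential dV(r) to the system potential V(r)
whenever V(r) falls below an energy threshold E_thresh, which raises basins
and flattens barriers while leaving the surface above the threshold
untouched:

    V*(r) = V(r)                       for V(r) >= E_thresh
    V*(r) = V(r) + dV(r)               for V(r) <  E_thresh
    dV(r) = (E_thresh - V(r))^2 / (E_thresh - V(r) + alpha)

``alpha`` (> 0) controls how aggressively the surface is flattened: on the
boosted branch V* approaches the asymptote E_thresh - alpha as V -> -inf.
Raising E_thresh or lowering alpha both enhance sampling.

The dual-boost protocol applies one such boost to the total potential
energy and a second, independent one to the dihedral term, with parameters
derived from conventional-MD energy averages and system size:

    E_threshP = <E_tot> + 0.16 kcal/mol * N_atoms
    alpha_P   = 0.16 kcal/mol * N_atoms
    E_threshD = <E_dih> + 4 kcal/mol * N_residues
    alpha_D   = 4/5 kcal/mol * N_residues

These are pure scalar/array functions; the package does not integrate
all-atom equations of motion (the synthetic dimer simulator applies the
same boost formulas to its double-well energy term for demonstrations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KB


@dataclass(frozen=True)
class BoostParameters:
    """Dual-boost thresholds and acceleration parameters, kcal/mol."""

    E_threshP: float
    alpha_P: float
    E_threshD: float
    alpha_D: float

    def __post_init__(self):
        if self.alpha_P <= 0 or self.alpha_D <= 0:
            raise ValueError("acceleration parameters must be positive")


@dataclass(frozen=True)
class EnergyAverages:
    """Conventional-MD energy averages and system size."""

    E_tot_avg: float  # kcal/mol
    E_dih_avg: float  # kcal/mol
    n_atoms: int
    n_residues: int

    def __post_init__(self):
        if self.n_atoms < 1 or self.n_residues < 1:
            raise ValueError("atom and residue counts must be >= 1")


def dual_boost_parameters(av: EnergyAverages) -> BoostParameters:
    """Dual-boost parameters from cMD averages and system size."""
    alpha_p = 0.16 * av.n_atoms
    alpha_d = (4.0 / 5.0) * av.n_residues
    return BoostParameters(
        E_threshP=av.E_tot_avg + 0.16 * av.n_atoms,
        alpha_P=alpha_p,
        E_threshD=av.E_dih_avg + 4.0 * av.n_residues,
        alpha_D=alpha_d,
    )


def boost_potential(V, E_thresh: float, alpha: float):
    """Boost energy dV added below the threshold; 0 at or above it.

    Accepts scalars or arrays (kcal/mol).  Always >= 0, continuous at
    V = E_thresh, and non-increasing in V on the boosted branch.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    V = np.asarray(V, dtype=float)
    gap = E_thresh - V
    with np.errstate(invalid="ignore", divide="ignore"):
        dv = np.where(gap > 0, gap * gap / (gap + alpha), 0.0)
    if dv.ndim == 0:
        return float(dv)
    return dv


def modified_potential(V, E_thresh: float, alpha: float):
    """The boosted potential V* = V + dV (kcal/mol).

    Equal to V at and above the threshold; strictly increasing in V
    everywhere (conformational energy order is preserved) and bounded
    above by E_thresh on the boosted branch.
    """
    V = np.asarray(V, dtype=float)
    out = V + boost_potential(V, E_thresh, alpha)
    if out.ndim == 0:
        return float(out)
    return out


def boost_force_scale(V, E_thresh: float, alpha: float):
    """dV*/dV: the factor by which forces are scaled on the boosted branch.

    Equals alpha^2 / (E_thresh - V + alpha)^2 below the threshold and 1 at
    or above it; always in (0, 1].
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    V = np.asarray(V, dtype=float)
    gap = E_thresh - V
    scale = np.where(gap > 0, (alpha / (gap + alpha)) ** 2, 1.0)
    if scale.ndim == 0:
        return float(scale)
    return scale


def reweight_frames(deltaV_series, temperature: float = 300.0) -> np.ndarray:
    """Exponential frame weights exp(dV_i / kBT), normalized to sum 1.

    Optional: the landscape module histograms boosted frames directly by
    default and only applies these weights on request.
    """
    dv = np.asarray(deltaV_series, dtype=float)
    if dv.ndim != 1 or dv.size < 1:
        raise ValueError("deltaV_series must be a non-empty 1-D array")
    if not np.all(np.isfinite(dv)):
        raise ValueError("deltaV_series must be finite")
    kt = KB * temperature
    w = np.exp((dv - dv.max()) / kt)
    return w / w.sum()
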