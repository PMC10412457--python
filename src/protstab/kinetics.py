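"""Closed-form proteolysis kinetics and the two-state K50 <-> ΔG mapping.

A protein challenged with protease at concentration ``E`` (μM) is cleaved with
single-turnover kinetics, ``k_obs = k_max * E / (E + K50)``, where ``K50`` is
the protease concentration giving half-maximal cleavage rate.  Folded and
unfolded states have separate K50 values: a universal folded-state ``K50_F``
(cleavage only in constant tag regions) and a sequence-specific unfolded-state
``K50_U``.  Under rapid equilibrium of folding and enzyme binding the observed
K50 is the population-weighted harmonic mixture

    1 / K50 = f_U / K50_U + (1 - f_U) / K50_F,

with ``f_U = 1 / (1 + exp(ΔG / RT))`` the equilibrium unfolded fraction.
Inverting this relation converts a measured K50 into an absolute unfolding
free energy ΔG (kcal/mol, positive = stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

# Assay dynamic range: ΔG estimates outside are censored to the bound.
DG_CLIP_LO = -1.0
DG_CLIP_HI = 5.0

CENSOR_NONE = "none"
CENSOR_BELOW = "below_range"
CENSOR_ABOVE = "above_range"


@dataclass(frozen=True)
class ProteolysisParams:
    """Global kinetic parameters for one protease.

    Parameters
    ----------
    k_max : float
        Maximal (saturating) cleavage rate, min^-1.
    t_digest : float
        Digestion time, min (5 min in the standard assay).
    RT : float
        Thermal energy, kcal/mol (0.593 at 298 K).
    K50_F : float
        Universal folded-state K50, μM (cleavage of the constant tag).
    """

    k_max: float = 1.0
    t_digest: float = 5.0
    RT: float = 0.593
    K50_F: float = 500.0

    def __post_init__(self) -> None:
        for name in ("k_max", "t_digest", "RT", "K50_F"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")


def k_obs(E_conc, K50, k_max=1.0):
    """Single-turnover cleavage rate k_max * E / (E + K50), min^-1."""
    E_conc = np.asarray(E_conc, dtype=float)
    K50 = np.asarray(K50, dtype=float)
    if np.any(K50 <= 0):
        raise ValueError("K50 must be positive")
    if np.any(np.asarray(k_max) <= 0):
        raise ValueError("k_max must be positive")
    if np.any(E_conc < 0):
        raise ValueError("protease concentration must be >= 0")
    return k_max * E_conc / (E_conc + K50)


def survival_fraction(E_conc, K50, params: ProteolysisParams):
    """Fraction of substrate left uncleaved after the digestion time."""
    return np.exp(-k_obs(E_conc, K50, params.k_max) * params.t_digest)


def f_unfolded(dG, RT: float = 0.593):
    """Equilibrium unfolded fraction 1 / (1 + exp(ΔG / RT))."""
    if RT <= 0:
        raise ValueError("RT must be positive")
    return expit(-np.asarray(dG, dtype=float) / RT)


def effective_K50(dG, K50_U, params: ProteolysisParams):
    """Observed K50 for a sequence with stability ΔG and unfolded-state K50_U.

    Harmonic mixing of state susceptibilities:
    ``1/K50 = f_U/K50_U + (1 - f_U)/K50_F``.  Strictly increasing in ΔG,
    bounded by (K50_U, K50_F).
    """
    K50_U = np.asarray(K50_U, dtype=float)
    if np.any(K50_U <= 0) or np.any(K50_U >= params.K50_F):
        raise ValueError("model requires 0 < K50_U < K50_F")
    fU = f_unfolded(dG, params.RT)
    return 1.0 / (fU / K50_U + (1.0 - fU) / params.K50_F)


def deltaG_from_K50(K50, K50_U, params: ProteolysisParams):
    """Invert :func:`effective_K50`: ΔG from an observed K50.

    Returns -inf where ``K50 <= K50_U`` (fully unfolded / below range) and
    +inf where ``K50 >= K50_F`` (above range); these propagate as flags, never
    silent NaN.  Use :func:`clip_dG` to map them onto the assay's dynamic
    range with censoring annotations.
    """
    K50 = np.asarray(K50, dtype=float)
    K50_U = np.asarray(K50_U, dtype=float)
    if np.any(K50 <= 0):
        raise ValueError("K50 must be positive")
    if np.any(K50_U <= 0) or np.any(K50_U >= params.K50_F):
        raise ValueError("model requires 0 < K50_U < K50_F")
    with np.errstate(divide="ignore", invalid="ignore"):
        fU = (1.0 / K50 - 1.0 / params.K50_F) / (1.0 / K50_U - 1.0 / params.K50_F)
        dG = params.RT * (np.log1p(-fU) - np.log(fU))
    dG = np.where(K50 <= K50_U, -np.inf, dG)
    dG = np.where(K50 >= params.K50_F, np.inf, dG)
    if dG.ndim == 0:
        return float(dG)
    return dG


def clip_dG(dG, lo: float = DG_CLIP_LO, hi: float = DG_CLIP_HI):
    """Clip ΔG estimates to the assay's dynamic range [lo, hi].

    Returns ``(clipped, censor)`` where censor marks values (including ±inf
    range flags) that fell outside the range.
    """
    dG = np.asarray(dG, dtype=float)
    clipped = np.clip(dG, lo, hi)
    censor = np.full(dG.shape, CENSOR_NONE, dtype=object)
    censor[dG < lo] = CENSOR_BELOW
    censor[dG > hi] = CENSOR_ABOVE
    if clipped.ndim == 0:
        return float(clipped), str(censor[()])
    return clipped, censor
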