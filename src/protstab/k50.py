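"""Per-sequence K50 inference from counts across the protease dilution series.

The count model: each sequence i enters selection at (unknown) library
fraction f_i; at condition c (effective protease concentration E_c) a fraction
``S_i(c) = exp(-k_max t E_c / (E_c + K50_i))`` survives, and reads are sampled
multinomially from the renormalized surviving pool, so the expected fraction
is ``f_i S_i(c) / Z_c`` with ``Z_c = sum_j f_j S_j(c)``.  The per-condition
normalizer Z_c couples all sequences; it is re-estimated from the current fits
in an EM-style alternation.  With a Poisson approximation to the multinomial,
the pre-selection fraction f_i profiles out in closed form, so the profile
log-likelihood over a log10 K50 grid is a single matrix product:

    ll[i, g] = sum_c n_ic log(S(c, g) / Z_c) - T_i log(N_pre + sum_c N_c S(c, g) / Z_c)

with T_i the sequence's total reads across pre and post conditions.  Point
estimates are the refined grid MAP; 95% intervals are grid-posterior quantiles
under a uniform prior on log10 K50 spanning the concentration series ± 2
decades, with censoring flagged when an interval touches a prior bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable
from .kinetics import CENSOR_ABOVE, CENSOR_BELOW, CENSOR_NONE, ProteolysisParams

CENSOR_NO_ESTIMATE = "no_estimate"
CENSOR_FIT_FAILURE = "fit_failure"


@dataclass
class K50Result:
    """Estimates plus the fitted per-condition normalizers and grid."""

    estimates: pd.DataFrame
    normalizers: pd.Series  # Z_c per post-selection condition key
    grid: np.ndarray
    pre_depth: float
    condition_keys: list[str] = field(default_factory=list)


def _survival_grid(conc_uM: np.ndarray, grid: np.ndarray, params: ProteolysisParams) -> np.ndarray:
    """S[c, g] = survival at concentration c for K50 = 10**grid[g]."""
    K50 = 10.0 ** grid[None, :]
    E = conc_uM[:, None]
    return np.exp(-params.k_max * params.t_digest * E / (E + K50))


def _profile_loglik(n_post: np.ndarray, N_post: np.ndarray, n_pre: np.ndarray,
                    N_pre: float, Z: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Poisson profile log-likelihood over a shared survival grid.

    n_post: (n, C) counts, N_post: (C,) depths, Z: (C,) normalizers,
    S: (C, G) survival; the pre-selection fraction is profiled out.
    """
    logS_over_Z = np.log(S) - np.log(Z)[:, None]
    A = N_pre + (N_post / Z) @ S  # (G,)
    T = n_pre + n_post.sum(axis=1)
    return n_post @ logS_over_Z - np.outer(T, np.log(A))


def _refine_map(grid: np.ndarray, ll_row: np.ndarray) -> float:
    j = int(np.argmax(ll_row))
    if j == 0 or j == len(grid) - 1:
        return float(grid[j])
    denom = ll_row[j - 1] - 2.0 * ll_row[j] + ll_row[j + 1]
    if denom >= 0:
        return float(grid[j])
    step = grid[1] - grid[0]
    return float(grid[j] + 0.5 * step * (ll_row[j - 1] - ll_row[j + 1]) / denom)


def _posterior_summary(grid: np.ndarray, ll: np.ndarray):
    """Vectorized posterior mean/sd and 95% interval per row of ll.

    ``grid`` may be shared (1D) or per-row (same shape as ll)."""
    X = np.broadcast_to(grid, ll.shape)
    w = np.exp(ll - ll.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    mean = np.sum(w * X, axis=1)
    sd = np.sqrt(np.maximum(np.sum(w * X**2, axis=1) - mean**2, 0.0))
    cdf = np.cumsum(w, axis=1)
    lo = np.empty(len(ll))
    hi = np.empty(len(ll))
    for i in range(len(ll)):
        lo[i] = np.interp(0.025, cdf[i], X[i])
        hi[i] = np.interp(0.975, cdf[i], X[i])
    return mean, sd, lo, hi


def _local_grids(point: np.ndarray, sd: np.ndarray, bounds: tuple[float, float],
                 step: float, n_points: int = 101) -> np.ndarray:
    """Per-sequence fine grids around the MAP (posteriors are often narrower
    than the coarse grid step, which would distort quantile intervals)."""
    half = np.maximum(4.0 * sd, 2.0 * step)
    lo = np.clip(point - half, bounds[0], bounds[1])
    hi = np.clip(point + half, bounds[0], bounds[1])
    t = np.linspace(0.0, 1.0, n_points)
    return lo[:, None] + (hi - lo)[:, None] * t[None, :]


def infer_K50(table: CountTable, protease: str, params: ProteolysisParams,
              pseudocount: float = 0.5, grid_points: int = 501, prior_pad: float = 2.0,
              em_iters: int = 100, em_tol: float = 1e-6,
              conc_multipliers: dict[str, float] | None = None,
              replicate: int | None = None) -> K50Result:
    """Infer log10 K50 (point, 95% interval, censor flag) for every sequence.

    Pools all post-selection conditions of ``protease`` (optionally one
    replicate).  Requires a pre-selection column for the protease and at least
    three nonzero protease concentrations.
    """
    pre = table.select(protease=protease, round="pre")
    post = table.select(protease=protease, round="post", replicate=replicate)
    if pre.counts.shape[1] == 0:
        raise ValueError(f"no pre-selection condition for {protease!r}")
    conc = np.array([c.conc_uM for c in post.conditions], dtype=float)
    if conc_multipliers:
        conc = conc * np.array([conc_multipliers.get(c.key, 1.0) for c in post.conditions])
    if (conc > 0).sum() < 3:
        raise ValueError("need at least 3 protease concentrations")

    n_pre = pre.counts.sum(axis=1).to_numpy(dtype=float)
    N_pre = float(n_pre.sum())
    n_post = post.counts.to_numpy(dtype=float)
    N_post = n_post.sum(axis=0)

    nz = conc[conc > 0]
    grid = np.linspace(np.log10(nz.min()) - prior_pad,
                       np.log10(nz.max()) + prior_pad, grid_points)
    S = _survival_grid(conc, grid, params)  # (C, G)

    # initial guesses: plug-in pre-fractions, survival from enrichment ratios
    f0 = (n_pre + pseudocount) / (N_pre + pseudocount * len(n_pre))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ((n_post + 0.5) / np.maximum(N_post, 1.0)) / f0[:, None]
    scale = np.maximum(np.quantile(ratio, 0.9, axis=0), 1e-12)
    S0 = np.clip(ratio / scale, 1e-9, 1.0)

    T = n_pre + n_post.sum(axis=1)
    kt = params.k_max * params.t_digest

    def run_em(S_init: np.ndarray):
        f = f0
        Z = np.maximum(f @ S_init, 1e-12)
        ll = None
        for _ in range(max(em_iters, 1)):
            ll = _profile_loglik(n_post, N_post, n_pre, N_pre, Z, S)
            k50_map = 10.0 ** np.array([_refine_map(grid, row) for row in ll])
            S_map = np.exp(-kt * conc[None, :] / (conc[None, :] + k50_map[:, None]))
            A_i = N_pre + S_map @ (N_post / Z)
            f_new = T / np.maximum(A_i, 1e-300)
            f_new /= f_new.sum()
            Z_new = np.maximum(f_new @ S_map, 1e-12)
            converged = np.max(np.abs(np.log(Z_new) - np.log(Z))) < em_tol
            Z, f = Z_new, f_new
            if converged:
                break
        ll = _profile_loglik(n_post, N_post, n_pre, N_pre, Z, S)
        return Z, ll, float(ll.max(axis=1).sum())

    # The joint (Z, K50) likelihood has near-degenerate optima related by a
    # one-dilution-step ladder translation when the pool lacks fully
    # resistant sequences; start the alternation from step-shifted initial
    # survivals as well and keep the highest-likelihood fixed point.
    lower = np.full(len(conc), -1, dtype=int)  # next lower-concentration cond
    for c in range(len(conc)):
        below = np.flatnonzero((conc < conc[c]) & (conc > 0))
        if conc[c] > 0 and len(below):
            lower[c] = below[np.argmax(conc[below])]
    S_up = S0.copy()      # as if every K50 were one step higher
    S_down = S0.copy()    # one step lower
    for c in range(len(conc)):
        if conc[c] == 0:
            continue
        S_up[:, c] = S0[:, lower[c]] if lower[c] >= 0 else 1.0
        src = np.flatnonzero(lower == c)
        S_down[:, c] = S0[:, src[0]] if len(src) else S0[:, c] ** 3
    Z, ll, best = None, None, -np.inf
    for S_init in (S0, S_up, S_down):
        Z_c, ll_c, total = run_em(S_init)
        if total > best:
            Z, ll, best = Z_c, ll_c, total

    point = np.array([_refine_map(grid, row) for row in ll])
    _, sd0, _, _ = _posterior_summary(grid, ll)
    step = grid[1] - grid[0]

    # second pass on per-sequence fine grids: the coarse step can exceed the
    # posterior width at high depth, which would distort quantile intervals
    X = _local_grids(point, sd0, (grid[0], grid[-1]), step)
    lo = np.empty(len(point))
    hi = np.empty(len(point))
    sd = np.empty(len(point))
    for start in range(0, len(point), 1000):
        idx = slice(start, min(start + 1000, len(point)))
        K50f = 10.0 ** X[idx]  # (m, L)
        Sf = np.exp(-kt * conc[None, :, None] /
                    (conc[None, :, None] + K50f[:, None, :]))  # (m, C, L)
        llf = np.einsum("mc,mcl->ml", n_post[idx], np.log(Sf) - np.log(Z)[None, :, None])
        Af = N_pre + np.einsum("c,mcl->ml", N_post / Z, Sf)
        llf -= T[idx, None] * np.log(Af)
        _, sd[idx], lo[idx], hi[idx] = _posterior_summary(X[idx], llf)

    censor = np.full(len(point), CENSOR_NONE, dtype=object)
    above = hi >= grid[-1] - step
    below = lo <= grid[0] + step
    censor[above] = CENSOR_ABOVE
    censor[below] = CENSOR_BELOW
    point[above] = grid[-1]
    point[below] = grid[0]
    censor[n_pre <= 0] = CENSOR_NO_ESTIMATE
    censor[(n_post.sum(axis=1) <= 0) & (n_pre > 0)] = CENSOR_FIT_FAILURE
    bad = np.isin(censor, [CENSOR_NO_ESTIMATE, CENSOR_FIT_FAILURE])
    point[bad] = np.nan

    est = pd.DataFrame({
        "log10_K50": point, "lo95": lo, "hi95": hi, "sd": sd,
        "censor": censor, "n_pre_counts": n_pre,
    }, index=table.seq_ids)
    est.index.name = "seq_id"
    return K50Result(est, pd.Series(Z, index=[c.key for c in post.conditions]),
                     grid, N_pre, [c.key for c in post.conditions])


@dataclass
class CalibrationResult:
    """Per-condition effective concentration multipliers (reference = 1)."""

    reference: str
    factor: float
    multipliers: dict[str, float]


def calibrate_concentrations(est_ref: pd.DataFrame, est_other: pd.DataFrame,
                             other_keys: list[str] | None = None,
                             reference: str = "ref",
                             min_shared: int = 50) -> CalibrationResult:
    """Calibrate effective protease concentration from overlapping sequences.

    If the other condition set's true concentrations are ``m x`` nominal, its
    fitted log10 K50 values (in nominal units) sit ``-log10 m`` below the
    reference; the recovered multiplier is ``10**(-median difference)``.
    Applying it (via ``conc_multipliers`` in :func:`infer_K50`) aligns the two
    estimate sets and never increases their median absolute disagreement.
    """
    both = est_ref.join(est_other, lsuffix="_ref", rsuffix="_oth", how="inner")
    ok = (both["censor_ref"] == CENSOR_NONE) & (both["censor_oth"] == CENSOR_NONE)
    shared = both[ok]
    if len(shared) < min_shared:
        warnings.warn(f"only {len(shared)} shared uncensored sequences "
                      f"(< {min_shared}); returning identity calibration")
        factor = 1.0
    else:
        delta = float(np.median(shared["log10_K50_oth"] - shared["log10_K50_ref"]))
        factor = 10.0 ** (-delta)
    mult = {k: factor for k in (other_keys or [])}
    return CalibrationResult(reference=reference, factor=factor, multipliers=mult)


def replicate_correlation(est1: pd.DataFrame, est2: pd.DataFrame,
                          max_ci_width: float = 0.5):
    """Pearson R of replicate log10 K50 after confidence/dynamic-range filtering.

    Retained sequences are uncensored in both replicates with 95% interval
    width <= ``max_ci_width`` log10 units; returns (R, retained fraction).
    """
    both = est1.join(est2, lsuffix="_1", rsuffix="_2", how="inner")
    keep = (
        (both["censor_1"] == CENSOR_NONE) & (both["censor_2"] == CENSOR_NONE)
        & ((both["hi95_1"] - both["lo95_1"]) <= max_ci_width)
        & ((both["hi95_2"] - both["lo95_2"]) <= max_ci_width)
    )
    retained = both[keep]
    if len(retained) < 3:
        raise ValueError("fewer than 3 sequence pairs retained by the filter")
    r = float(np.corrcoef(retained["log10_K50_1"], retained["log10_K50_2"])[0, 1])
    return r, len(retained) / len(both)
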