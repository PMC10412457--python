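"""Downstream statistics on quality-filtered stability data.

Per-site PCA of amino-acid stability profiles, two-way additive models and
thermodynamic couplings for double-mutant grids (with bootstrap
uncertainties), a wild-type amino-acid classifier (shared monotone weighting
of ΔG plus per-amino-acid offsets), functional-site calls from conservation
vs. stability, the stabilizing-mutation census, side-chain cone contact
counts on structures, and before/after design evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .kinetics import clip_dG
from .unfolded import AA_ALPHABET

NON_CYS = [a for a in AA_ALPHABET if a != "C"]
NONPOLAR = frozenset("AVLIMFWY")


# ---------------------------------------------------------------------------
# Site PCA


@dataclass
class PCAResult:
    components: np.ndarray          # (n_components, 20) loadings
    variance_fractions: np.ndarray
    scores: np.ndarray              # (n_sites, n_components)
    site_means: np.ndarray
    n_sites: int


def pca_fit(profiles, clip: bool = True) -> PCAResult:
    """PCA of site stability profiles (sites x 20 amino acids).

    Values are clipped to the assay dynamic range, then each site's mean over
    the 20 amino acids is subtracted before the decomposition; sites with any
    missing ΔG are dropped.  Centering removes the all-ones direction, so the
    rank is at most 19.
    """
    X = np.asarray(pd.DataFrame(profiles), dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 20:
        raise ValueError("need at least 20 complete sites")
    if clip:
        X, _ = clip_dG(X)
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    if np.allclose(Xc - Xc.mean(axis=0), 0.0):
        raise ValueError("all site profiles identical: zero variance between sites")
    pca = PCA(n_components=min(19, Xc.shape[0] - 1))
    scores = pca.fit_transform(Xc)
    return PCAResult(pca.components_, pca.explained_variance_ratio_, scores,
                     means, X.shape[0])


def wt_advantage(profiles, wt_labels, k: int):
    """Median wild-type stability advantage and its rank-k reconstruction.

    The full statistic is the median over sites of the mean ΔΔG (variant minus
    wild type, positive = stabilizing) of the 19 alternative amino acids —
    negative values mean the wild type is typically more stable.  The
    reconstructed statistic recomputes this after projecting the site-centered
    profiles onto the first k principal directions (k = 0 gives exactly 0,
    full rank reproduces the full statistic).
    """
    X = np.asarray(pd.DataFrame(profiles), dtype=float)
    wt_idx = np.asarray([AA_ALPHABET.index(a) if isinstance(a, str) else int(a)
                         for a in wt_labels])
    keep = ~np.isnan(X).any(axis=1)
    X, wt_idx = X[keep], wt_idx[keep]
    X, _ = clip_dG(X)
    Xc = X - X.mean(axis=1, keepdims=True)

    def statistic(M):
        wt_vals = M[np.arange(len(M)), wt_idx]
        ddg = M - wt_vals[:, None]
        mean_alt = (ddg.sum(axis=1) - 0.0) / (M.shape[1] - 1)  # wt term is 0
        return float(np.median(mean_alt))

    full = statistic(Xc)
    if k <= 0:
        return full, 0.0
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k, len(s))
    recon = (U[:, :k] * s[:k]) @ Vt[:k]
    return full, statistic(recon)


# ---------------------------------------------------------------------------
# Thermodynamic couplings (two-way additive model on 20 x 20 grids)


@dataclass
class CouplingFit:
    grand_mean: float
    row_effects: pd.Series
    col_effects: pd.Series
    fitted: pd.DataFrame
    coupling: pd.DataFrame   # observed - additive fit; NaN at missing cells
    n_cells: int
    bootstrap_sd: pd.DataFrame | None = None


def _additive_lstsq(obs: np.ndarray):
    """Minimum-norm least squares of mu + alpha_i + beta_j on observed cells."""
    R, C = obs.shape
    ii, jj = np.nonzero(~np.isnan(obs))
    y = obs[ii, jj]
    X = np.zeros((len(y), 1 + R + C))
    X[:, 0] = 1.0
    X[np.arange(len(y)), 1 + ii] = 1.0
    X[np.arange(len(y)), 1 + R + jj] = 1.0
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu, alpha, beta = coef[0], coef[1:1 + R], coef[1 + R:]
    fitted = mu + alpha[:, None] + beta[None, :]
    fitted[~np.isin(np.arange(R), ii), :] = np.nan
    fitted[:, ~np.isin(np.arange(C), jj)] = np.nan
    return mu, alpha, beta, fitted


def fit_additive_pair(grid, min_cells: int = 100, clip: bool = True) -> CouplingFit:
    """Fit the 40-parameter additive model to a 20x20 double-mutant ΔG table.

    The coupling is observed minus fitted; on a complete table it equals the
    classical two-way interaction residual.  Censored/missing cells are
    excluded; a fully missing row or column leaves its parameter undefined and
    its couplings missing.
    """
    table = grid.table if hasattr(grid, "table") else pd.DataFrame(grid)
    obs = table.to_numpy(dtype=float)
    if clip:
        clipped, _ = clip_dG(obs)
        obs = np.where(np.isnan(obs), np.nan, clipped)
    n_cells = int((~np.isnan(obs)).sum())
    if n_cells < min_cells:
        raise ValueError(f"only {n_cells} non-missing cells (< {min_cells})")
    mu, alpha, beta, fitted = _additive_lstsq(obs)
    # report the sum-to-zero gauge
    a_def = np.unique(np.nonzero(~np.isnan(obs))[0])
    b_def = np.unique(np.nonzero(~np.isnan(obs))[1])
    a_mean, b_mean = alpha[a_def].mean(), beta[b_def].mean()
    row = pd.Series(alpha - a_mean, index=table.index)
    col = pd.Series(beta - b_mean, index=table.columns)
    row[~np.isin(np.arange(len(row)), a_def)] = np.nan
    col[~np.isin(np.arange(len(col)), b_def)] = np.nan
    coupling = pd.DataFrame(obs - fitted, index=table.index, columns=table.columns)
    return CouplingFit(float(mu + a_mean + b_mean), row, col,
                       pd.DataFrame(fitted, index=table.index, columns=table.columns),
                       coupling, n_cells)


def bootstrap_coupling(grid, n_boot: int = 1000, seed: int = 0,
                       clip: bool = True) -> pd.DataFrame:
    """Bootstrap s.d. of each cell's coupling (resampling the observed cells
    of the double-mutant grid with replacement and refitting the additive
    model).  Deterministic given the seed."""
    table = grid.table if hasattr(grid, "table") else pd.DataFrame(grid)
    obs = table.to_numpy(dtype=float)
    if clip:
        clipped, _ = clip_dG(obs)
        obs = np.where(np.isnan(obs), np.nan, clipped)
    R, C = obs.shape
    ii, jj = np.nonzero(~np.isnan(obs))
    y = obs[ii, jj]
    m = len(y)
    X = np.zeros((m, 1 + R + C))
    X[:, 0] = 1.0
    X[np.arange(m), 1 + ii] = 1.0
    X[np.arange(m), 1 + R + jj] = 1.0
    rng = np.random.default_rng(seed)
    samples = np.empty((n_boot, m))
    for b in range(n_boot):
        w = rng.multinomial(m, np.full(m, 1.0 / m)).astype(float)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        fitted_cells = coef[0] + coef[1 + ii] + coef[1 + R + jj]
        samples[b] = y - fitted_cells
    sd_cells = samples.std(axis=0)  # population sd: a single resample gives 0
    out = np.full((R, C), np.nan)
    out[ii, jj] = sd_cells
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def triplet_coupling(pair_grids: dict[str, dict], n_boot: int = 200,
                     seed: int = 0) -> pd.DataFrame:
    """Compare wild-type-pair couplings across backgrounds for triplet scans.

    ``pair_grids`` maps a pair label to ``{background: PairGrid}`` (typically
    'wt' and 'ala').  Each grid is modelled independently with the 40
    additive parameters; the third-order signature is the wild-type cell's
    coupling in the wild-type background minus in the substituted background.
    Pairs missing a background are skipped.
    """
    rows = []
    for label, grids in pair_grids.items():
        if len(grids) < 2:
            continue
        bgs = sorted(grids, key=lambda b: b != "wt")  # wt first
        rec = {"pair": label}
        couplings = {}
        for bg in bgs[:2]:
            grid = grids[bg]
            fit = fit_additive_pair(grid)
            sd = bootstrap_coupling(grid, n_boot=n_boot, seed=seed)
            ai, aj = grid.wt_pair
            couplings[bg] = float(fit.coupling.loc[ai, aj])
            rec[f"coupling_{bg}"] = couplings[bg]
            rec[f"sd_{bg}"] = float(sd.loc[ai, aj])
        rec["signature"] = couplings[bgs[0]] - couplings[bgs[1]]
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wild-type amino-acid classifier


class WildTypeClassifier(BaseEstimator, ClassifierMixin):
    """Predict the wild-type amino acid at a site from variant stabilities.

    ``P(a | site) = softmax_a(ln2 * (g(ΔG_a) + o_a))`` over the 19 non-Cys
    amino acids: a shared non-decreasing piecewise-linear weighting function
    ``g`` (log2 probability units, knots every ``knot_spacing`` kcal/mol on
    the assay range) converts stability into likelihood; per-amino-acid
    offsets ``o_a`` (log2, Val anchored at 0) capture stability-independent
    preferences.  Fitting maximizes the summed log-probability of the observed
    wild types; monotonicity is enforced by optimizing nonnegative knot
    increments.
    """

    def __init__(self, knot_spacing: float = 0.5, dG_range: tuple = (-1.0, 5.0),
                 anchor_aa: str = "V", smoothing: float = 1.0, max_iter: int = 1000):
        self.knot_spacing = knot_spacing
        self.dG_range = dG_range
        self.anchor_aa = anchor_aa
        # curvature penalty on g's knot increments: damps wiggles where the
        # data are sparse without biasing any constant slope
        self.smoothing = smoothing
        self.max_iter = max_iter

    def _ramp_features(self, X):
        """Φ[s, a, k]: fraction of knot interval k traversed by X[s, a]."""
        knots = self.knots_
        h = np.diff(knots)
        Xc = np.clip(X, knots[0], knots[-1])
        return np.clip((Xc[..., None] - knots[:-1]) / h, 0.0, 1.0)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 19:
            raise ValueError("X must be (n_sites, 19) ΔG over non-Cys amino acids")
        if X.shape[0] < 2:
            raise ValueError("degenerate problem: need at least 2 sites")
        y = np.asarray([NON_CYS.index(a) if isinstance(a, str) else int(a)
                        for a in y])
        X, _ = clip_dG(X)
        lo, hi = self.dG_range
        self.knots_ = np.arange(lo, hi + 0.5 * self.knot_spacing, self.knot_spacing)
        K = len(self.knots_) - 1
        anchor = NON_CYS.index(self.anchor_aa)
        free = [i for i in range(19) if i != anchor]
        Phi = self._ramp_features(X)  # (n, 19, K)
        n = len(X)
        Y = np.zeros((n, 19))
        Y[np.arange(n), y] = 1.0
        ln2 = np.log(2.0)
        history: list[float] = []

        def unpack(theta):
            delta = theta[:K]
            offsets = np.zeros(19)
            offsets[free] = theta[K:]
            return delta, offsets

        def objective(theta):
            delta, offsets = unpack(theta)
            g = Phi @ delta  # (n, 19)
            logits = ln2 * (g + offsets)
            logits -= logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            P = expl / expl.sum(axis=1, keepdims=True)
            nll = -np.sum(logits[np.arange(n), y] - np.log(expl.sum(axis=1))) / n
            G = (P - Y) / n  # d nll / d logits / ln2 ... (chain below)
            grad_delta = ln2 * np.einsum("na,nak->k", G, Phi)
            grad_off = ln2 * G.sum(axis=0)
            d2 = np.diff(delta)
            nll += self.smoothing * float(d2 @ d2) / max(K - 1, 1)
            grad_pen = np.zeros(K)
            grad_pen[:-1] -= 2.0 * d2
            grad_pen[1:] += 2.0 * d2
            grad_delta = grad_delta + self.smoothing * grad_pen / max(K - 1, 1)
            history.append(nll)
            return nll, np.concatenate([grad_delta, grad_off[free]])

        theta0 = np.zeros(K + 18)
        bounds = [(0.0, None)] * K + [(None, None)] * 18
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": self.max_iter})
        delta, offsets = unpack(res.x)
        self.increments_ = delta
        self.g_values_ = np.concatenate([[0.0], np.cumsum(delta)])
        self.offsets_ = pd.Series(offsets, index=NON_CYS)
        self.classes_ = np.array(NON_CYS)
        self.nll_history_ = np.array(history)
        self.n_iter_ = res.nit
        return self

    def weighting_function(self, dG):
        """g(ΔG) in log2 units (g at the lower knot fixed to 0)."""
        check_is_fitted(self, "increments_")
        Phi = self._ramp_features(np.asarray(dG, dtype=float))
        return Phi @ self.increments_

    def mean_slope(self, lo: float = 1.5, hi: float = 4.0) -> float:
        """Average slope of g (log2 per kcal/mol) on [lo, hi]."""
        g = self.weighting_function(np.array([lo, hi]))
        return float((g[1] - g[0]) / (hi - lo))

    def predict_proba(self, X):
        check_is_fitted(self, "offsets_")
        X, _ = clip_dG(np.asarray(X, dtype=float))
        logits = np.log(2.0) * (self.weighting_function(X) + self.offsets_.to_numpy())
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_classifier(X, y, **kwargs) -> WildTypeClassifier:
    """Thin wrapper: fit a :class:`WildTypeClassifier` on site ΔG profiles."""
    return WildTypeClassifier(**kwargs).fit(X, y)


def classifier_metrics(proba: np.ndarray, y) -> dict:
    """Sequence recovery (argmax = wild type; ties resolve to the
    lexicographically first amino acid) and base-2 perplexity."""
    y = np.asarray([NON_CYS.index(a) if isinstance(a, str) else int(a) for a in y])
    proba = np.asarray(proba, dtype=float)
    recovery = float(np.mean(np.argmax(proba, axis=1) == y))
    logp = np.log2(np.maximum(proba[np.arange(len(y)), y], 1e-300))
    return {"recovery": recovery, "perplexity": float(2.0 ** (-np.mean(logp)))}


def null_model_proba(y, n_sites: int | None = None) -> np.ndarray:
    """The frequency-only null model: every site gets the empirical
    amino-acid frequencies as its probability vector."""
    y = np.asarray([NON_CYS.index(a) if isinstance(a, str) else int(a) for a in y])
    freqs = np.bincount(y, minlength=19) / len(y)
    return np.tile(freqs, ((n_sites or len(y)), 1))


def offset_ratio(offsets, aa1: str, aa2: str) -> float:
    """Probability fold-ratio of aa1 over aa2 at equal stability, 2**(o1-o2)."""
    if hasattr(offsets, "offsets_"):
        offsets = offsets.offsets_
    offsets = dict(offsets)
    for aa in (aa1, aa2):
        if aa not in offsets:
            raise ValueError(f"unknown amino acid {aa!r}")
    return float(2.0 ** (offsets[aa1] - offsets[aa2]))


# ---------------------------------------------------------------------------
# Functional-site classification


def normalize_conservation(scores: pd.DataFrame, domain_col: str = "domain",
                           score_col: str = "score") -> pd.Series:
    """Standardize per-site conservation scores within each domain and flip
    the sign so positive = sensitive to mutations (per-domain mean 0, sd 1)."""
    out = pd.Series(np.nan, index=scores.index)
    for _, grp in scores.groupby(domain_col):
        if len(grp) < 3:
            raise ValueError("need at least 3 sites per domain")
        x = grp[score_col].to_numpy(dtype=float)
        sd = x.std()  # population sd
        if sd == 0:
            raise ValueError("zero-variance domain")
        out[grp.index] = -(x - x.mean()) / sd
    return out


def mean_site_ddG(profile: pd.DataFrame, wt_aa: pd.Series,
                  mode: str = "all_subs") -> pd.Series:
    """Per-site mean ΔΔG of substitutions (all non-wild-type amino acids, or
    only nonpolar ones), from a sites x 20 ΔG profile table."""
    if mode not in ("all_subs", "nonpolar_only"):
        raise ValueError("mode must be 'all_subs' or 'nonpolar_only'")
    vals, _ = clip_dG(profile.to_numpy(dtype=float))
    out = []
    for i, site in enumerate(profile.index):
        wt = wt_aa.loc[site]
        cols = [a for a in profile.columns
                if a != wt and (mode == "all_subs" or a in NONPOLAR)]
        idx = [profile.columns.get_loc(a) for a in cols]
        out.append(np.nanmean(vals[i, idx]) - vals[i, profile.columns.get_loc(wt)])
    return pd.Series(out, index=profile.index)


def classify_functional(mean_ddG, conservation, c_thresh: float = 1.0,
                        d_thresh: float = -0.5) -> pd.Series:
    """Functional sites: sensitive to mutation (normalized conservation >=
    c_thresh) yet unimportant for stability (mean ΔΔG >= d_thresh).  Sites
    missing either score are unclassified (NA)."""
    mean_ddG = pd.Series(mean_ddG)
    conservation = pd.Series(np.asarray(conservation, dtype=float),
                             index=mean_ddG.index)
    out = pd.array((conservation >= c_thresh) & (mean_ddG >= d_thresh),
                   dtype="boolean")
    out[mean_ddG.isna().to_numpy() | conservation.isna().to_numpy()] = pd.NA
    return pd.Series(out, index=mean_ddG.index)


# ---------------------------------------------------------------------------
# Stabilizing-mutation census


def _mutation_category(row) -> str:
    if row["type"] == "ins":
        return "insertion"
    if row["type"] == "del":
        return "deletion"
    a = "NP" if row["wt_aa"] in NONPOLAR else "P"
    b = "NP" if row["mut_aa"] in NONPOLAR else "P"
    return f"{a}->{b}"


def stabilizing_census(variants: pd.DataFrame, threshold: float = 1.0,
                       ddg_col: str = "ddG", class_col: str | None = None) -> dict:
    """Count stabilizing mutations (ΔΔG strictly > threshold) by category.

    Entries censored at the lower clip bound carry an upper-bound ΔΔG and can
    never exceed the threshold; entries censored at the upper bound carry a
    lower bound and count whenever that bound already exceeds it — so the
    strict comparison on tabulated values handles both.
    """
    df = variants[variants["type"] != "wt"].copy()
    df = df[df[ddg_col].notna()]
    stab = df[df[ddg_col] > threshold]
    result = {
        "n_total": int(len(df)),
        "n_stabilizing": int(len(stab)),
        "fraction": float(len(stab) / len(df)) if len(df) else 0.0,
        "by_category": stab.apply(_mutation_category, axis=1).value_counts().to_dict()
        if len(stab) else {},
    }
    if class_col and class_col in df:
        result["by_class"] = stab[class_col].value_counts().to_dict()
    return result


# ---------------------------------------------------------------------------
# Structure: side-chain cone contacts


CONE_MODES = {
    "burial_CA": lambda res: [res["CA"]] if "CA" in res else [],
    "sidechain_CB": lambda res: [res["CB"]] if "CB" in res else [],
    "aromatic_CE2": lambda res: [res["CE2"]]
    if res.get_resname() in ("PHE", "TYR", "TRP") and "CE2" in res else [],
    "acidic_OE1_OD1": lambda res: (
        [res["OE1"]] if res.get_resname() == "GLU" and "OE1" in res else
        [res["OD1"]] if res.get_resname() == "ASP" and "OD1" in res else []),
    "basic_NZ_NE": lambda res: (
        [res["NZ"]] if res.get_resname() == "LYS" and "NZ" in res else
        [res["NE"]] if res.get_resname() == "ARG" and "NE" in res else []),
}


def virtual_cbeta(residue) -> np.ndarray:
    """Ideal-geometry Cβ built from backbone N, Cα, C (for glycine)."""
    n = residue["N"].coord.astype(float)
    ca = residue["CA"].coord.astype(float)
    c = residue["C"].coord.astype(float)
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def cone_contacts(entity, focal_residue, mode: str = "burial_CA",
                  radius: float = 9.0, cos_half_angle: float = 0.5):
    """Count target atoms inside a 9 Å cone projected from the focal residue's
    Cβ along its Cα→Cβ vector (60° half-angle by default); the focal residue
    itself is excluded.  Returns NaN with a warning if the focal residue lacks
    the required backbone atoms."""
    if mode not in CONE_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    res = focal_residue
    try:
        ca = res["CA"].coord.astype(float)
        cb = (virtual_cbeta(res) if res.get_resname() == "GLY" or "CB" not in res
              else res["CB"].coord.astype(float))
    except KeyError:
        warnings.warn(f"residue {res} lacks backbone atoms; skipped")
        return float("nan")
    axis = cb - ca
    norm = np.linalg.norm(axis)
    if norm == 0:
        warnings.warn("degenerate Cα-Cβ axis; skipped")
        return float("nan")
    axis /= norm
    count = 0
    for other in entity.get_residues():
        if other is res:
            continue
        for atom in CONE_MODES[mode](other):
            v = atom.coord.astype(float) - cb
            d = np.linalg.norm(v)
            if 0 < d <= radius and (v @ axis) / d >= cos_half_angle:
                count += 1
    return count


# ---------------------------------------------------------------------------
# Design evaluation


def design_delta(wt_dG, redesign_dG):
    """Per-domain stability change after redesign plus summary statistics.

    Inputs are mappings/Series of domain id → ΔG; unpaired entries are skipped
    (their count is reported)."""
    wt = pd.Series(wt_dG, dtype=float)
    rd = pd.Series(redesign_dG, dtype=float)
    shared = wt.index.intersection(rd.index)
    delta = (rd[shared] - wt[shared]).dropna()
    summary = {
        "mean": float(delta.mean()) if len(delta) else float("nan"),
        "sd": float(delta.std(ddof=1)) if len(delta) > 1 else float("nan"),
        "fraction_gt_1": float((delta > 1.0).mean()) if len(delta) else float("nan"),
        "n": int(len(delta)),
        "n_skipped": int(len(wt) + len(rd) - 2 * len(delta)),
    }
    return delta, summary
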