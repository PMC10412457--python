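"""Unfolded-state susceptibility model: a cleavage-site PSSM predicting K50,U.

Fully unfolded chains are cleaved at every protease target residue (trypsin:
K/R; chymotrypsin: aromatic/bulky F/Y/W/L/M).  Each candidate site contributes
a rate on the 1/μM scale that is log-additive over a sequence window around
the scissile bond; site rates add, so

    1 / K50_U = sum_sites 10 ** (a0 + sum_off w[off, aa(site + off)]).

More cut sites mean a lower K50,U.  The weights are trained by least squares
on scrambled (assumed fully unfolded) sequences whose measured K50 equals
their K50,U.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
BOUNDARY = "^"  # dedicated symbol for window offsets outside the sequence
N_SYMBOLS = len(AA_ALPHABET) + 1

DEFAULT_TARGETS = {
    "trypsin": frozenset("KR"),
    "chymotrypsin": frozenset("FYWLM"),
}


def _encode_sites(sequences, targets, window):
    """Collect target sites and their window contexts across sequences.

    Returns (seq_idx, positions, ctx) where ctx[s, j] is the symbol index at
    offset window[j] from site s (boundary symbol outside the sequence).
    """
    offsets = np.arange(window[0], window[1] + 1)
    seq_idx, positions, ctx_rows = [], [], []
    for i, seq in enumerate(sequences):
        seq = str(seq).upper()
        codes = []
        for aa in seq:
            if aa not in AA_INDEX:
                raise ValueError(f"non-standard residue {aa!r} in sequence {i}")
            codes.append(AA_INDEX[aa])
        codes = np.asarray(codes, dtype=np.int64)
        sites = np.flatnonzero(np.isin(codes, [AA_INDEX[a] for a in targets]))
        for p in sites:
            pos = p + offsets
            row = np.where((pos < 0) | (pos >= len(codes)), N_SYMBOLS - 1,
                           codes[np.clip(pos, 0, len(codes) - 1)])
            ctx_rows.append(row)
            seq_idx.append(i)
            positions.append(p)
    if ctx_rows:
        ctx = np.vstack(ctx_rows)
    else:
        ctx = np.zeros((0, len(offsets)), dtype=np.int64)
    return np.asarray(seq_idx), np.asarray(positions), ctx


class CleavagePSSM(BaseEstimator, RegressorMixin):
    """Position-specific scoring matrix for unfolded-state protease susceptibility.

    Parameters
    ----------
    protease : str
        'trypsin' or 'chymotrypsin' (selects the default target-residue set).
    target_residues : iterable of str, optional
        Override the P1 target set.
    window : (int, int)
        Inclusive offset range around the scissile P1 residue (offset 0).
    ridge : float
        L2 penalty on the weight matrix (the intercept a0 is unpenalized).
    validation_fraction : float
        Held-out fraction used to report ``heldout_r_`` after fitting.
    random_state : int
        Seed for the train/validation split.

    Attributes
    ----------
    a0_ : float
        Intercept, log10 of a single site's rate contribution (1/μM scale).
    weights_ : ndarray of shape (n_offsets, 21)
        Log10-additive weights per offset and symbol (last column = boundary).
    heldout_r_ : float
        Pearson r of predictions on the held-out split (NaN if none held out).
    """

    def __init__(self, protease="trypsin", target_residues=None, window=(-4, 3),
                 ridge=1e-3, max_iter=500, validation_fraction=0.1, random_state=0):
        self.protease = protease
        self.target_residues = target_residues
        self.window = window
        self.ridge = ridge
        self.max_iter = max_iter
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _targets(self):
        if self.target_residues is not None:
            return frozenset(str(a).upper() for a in self.target_residues)
        try:
            return DEFAULT_TARGETS[self.protease]
        except KeyError:
            raise ValueError(f"unknown protease {self.protease!r}; pass target_residues")

    def fit(self, X, y):
        """Fit on sequences X with measured log10 K50 values y (scrambles)."""
        sequences = list(X)
        y = np.asarray(y, dtype=float)
        if len(sequences) != len(y):
            raise ValueError("X and y length mismatch")
        if len(set(sequences)) < 2:
            raise ValueError("degenerate design: training sequences are all identical")
        lo, hi = self.window
        if not (lo <= 0 <= hi):
            raise ValueError("window must contain offset 0 (the P1 residue)")

        rng = np.random.default_rng(self.random_state)
        n = len(sequences)
        n_val = int(round(self.validation_fraction * n))
        perm = rng.permutation(n)
        val_idx = set(perm[:n_val].tolist())
        train = [i for i in range(n) if i not in val_idx]

        self.a0_, self.weights_ = self._fit_weights(
            [sequences[i] for i in train], y[train])

        if n_val >= 3:
            pred = self.predict([sequences[i] for i in sorted(val_idx)])
            truth = y[sorted(val_idx)]
            ok = np.isfinite(pred)
            self.heldout_r_ = float(np.corrcoef(pred[ok], truth[ok])[0, 1])
        else:
            self.heldout_r_ = float("nan")
        return self

    def _fit_weights(self, sequences, y):
        targets = self._targets()
        lo, hi = self.window
        n_off = hi - lo + 1
        seq_idx, _, ctx = _encode_sites(sequences, targets, self.window)
        n = len(sequences)
        has_site = np.zeros(n, dtype=bool)
        has_site[seq_idx] = True
        if not has_site.all():
            warnings.warn(f"{int((~has_site).sum())} training sequences have no "
                          "target site and are excluded from the fit")
            keep = np.flatnonzero(has_site)
            remap = -np.ones(n, dtype=np.int64)
            remap[keep] = np.arange(len(keep))
            seq_idx = remap[seq_idx]
            y = y[keep]
            n = len(keep)
        if n < 3:
            raise ValueError("too few usable training sequences")

        observed = np.zeros((n_off, N_SYMBOLS), dtype=bool)
        for j in range(n_off):
            observed[j, np.unique(ctx[:, j])] = True
        if not observed.all():
            warnings.warn("some (offset, symbol) combinations were never observed; "
                          "their weights are fixed at 0")

        off_base = np.arange(n_off) * N_SYMBOLS
        flat_ctx = ctx + off_base  # (n_sites, n_off) indices into W.ravel()
        ln10 = np.log(10.0)

        def objective(theta):
            a0, w = theta[0], theta[1:]
            log_r = a0 + w[flat_ctx].sum(axis=1)
            log_r = np.clip(log_r, -30, 30)
            r = 10.0 ** log_r
            R = np.bincount(seq_idx, weights=r, minlength=n)
            pred = -np.log10(R)
            resid = pred - y
            loss = float(resid @ resid) / n + self.ridge * float(w @ w)
            # d pred_i / d a0 = -1 ; d pred_i / d w[k] = -(sum over its sites of r * 1[ctx uses k]) / R_i
            coef = (2.0 / n) * resid  # d loss / d pred
            site_coef = -coef[seq_idx] * r / R[seq_idx]
            grad = np.zeros_like(theta)
            grad[0] = site_coef.sum()
            gw = np.zeros(n_off * N_SYMBOLS)
            for j in range(n_off):
                np.add.at(gw, flat_ctx[:, j], site_coef)
            grad[1:] = gw + 2.0 * self.ridge * w
            return loss, grad

        theta0 = np.zeros(1 + n_off * N_SYMBOLS)
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter})
        a0 = float(res.x[0])
        W = res.x[1:].reshape(n_off, N_SYMBOLS)
        W[~observed] = 0.0
        return a0, W

    def site_susceptibilities(self, seq: str) -> np.ndarray:
        """Per-position rate contributions (1/μM); nonzero only at target residues."""
        check_is_fitted(self, "weights_")
        targets = self._targets()
        seq_idx, positions, ctx = _encode_sites([seq], targets, self.window)
        out = np.zeros(len(str(seq)))
        if len(positions) == 0:
            return out
        off_base = np.arange(ctx.shape[1]) * N_SYMBOLS
        log_r = self.a0_ + self.weights_.ravel()[ctx + off_base].sum(axis=1)
        out[positions] = 10.0 ** log_r
        return out

    def predict_K50U(self, X):
        """K50,U per sequence (μM) and a resistant mask (no target sites)."""
        check_is_fitted(self, "weights_")
        X = list(X)
        seq_idx, _, ctx = _encode_sites(X, self._targets(), self.window)
        totals = np.zeros(len(X))
        if len(seq_idx):
            off_base = np.arange(ctx.shape[1]) * N_SYMBOLS
            log_r = self.a0_ + self.weights_.ravel()[ctx + off_base].sum(axis=1)
            totals = np.bincount(seq_idx, weights=10.0 ** log_r, minlength=len(X))
        resistant = totals == 0
        with np.errstate(divide="ignore"):
            k50u = np.where(resistant, np.inf, 1.0 / np.where(resistant, 1.0, totals))
        return k50u, resistant

    def predict(self, X):
        """Predicted log10 K50,U per sequence (+inf where resistant)."""
        k50u, _ = self.predict_K50U(X)
        with np.errstate(divide="ignore"):
            return np.log10(k50u)

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "weights_")
        payload = {
            "protease": self.protease,
            "target_residues": sorted(self._targets()),
            "window": list(self.window),
            "a0": self.a0_,
            "symbols": AA_ALPHABET + BOUNDARY,
            "weights": self.weights_.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CleavagePSSM":
        payload = json.loads(Path(path).read_text())
        model = cls(protease=payload["protease"],
                    target_residues=payload["target_residues"],
                    window=tuple(payload["window"]))
        model.a0_ = float(payload["a0"])
        model.weights_ = np.asarray(payload["weights"], dtype=float)
        model.heldout_r_ = float("nan")
        return model


def fit_pssm(sequences, log10_k50, protease: str, **kwargs) -> CleavagePSSM:
    """Fit a :class:`CleavagePSSM` on scramble measurements (thin wrapper)."""
    return CleavagePSSM(protease=protease, **kwargs).fit(sequences, log10_k50)
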