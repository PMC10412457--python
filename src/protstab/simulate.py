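"""Synthetic libraries and forward simulation of the proteolysis selection.

Everything downstream of the wet lab is testable against this module: it
generates mutational-scan libraries with known per-variant stabilities (a
low-rank site x amino-acid factor model mimicking burial/helix propensity),
scrambled fully-unfolded sequences with known K50,U from a generating PSSM,
20x20 double-mutant grids with planted thermodynamic couplings, and sequencing
count tables produced by Dirichlet pre-selection fractions, single-turnover
cleavage survival across the threefold dilution series (11 concentrations +
no-protease control; replicate 1 max 25 μM, replicate 2 max 25·√3 ≈ 43.3 μM)
and multinomial read sampling at configurable depth.  All randomness flows
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import Condition, CountTable, ROUND_POST, ROUND_PRE
from .kinetics import ProteolysisParams, effective_K50, f_unfolded
from .unfolded import AA_ALPHABET, CleavagePSSM, N_SYMBOLS

PROTEASES = ("trypsin", "chymotrypsin")

# one fixed codon per amino acid (counting is exact-match, no optimization)
CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}

# Kyte-Doolittle hydropathy and (negated) Pace-Scholtz helix penalty, in
# AA_ALPHABET order; used as the default stability factor loadings.
_KD = dict(A=1.8, C=2.5, D=-3.5, E=-3.5, F=2.8, G=-0.4, H=-3.2, I=4.5, K=-3.9,
           L=3.8, M=1.9, N=-3.5, P=-1.6, Q=-3.5, R=-4.5, S=-0.8, T=-0.7,
           V=4.2, W=-0.9, Y=-1.3)
_HELIX = dict(A=0.0, C=0.68, D=0.69, E=0.40, F=0.54, G=1.0, H=0.61, I=0.41,
              K=0.26, L=0.21, M=0.24, N=0.65, P=3.16, Q=0.39, R=0.21, S=0.50,
              T=0.66, V=0.61, W=0.49, Y=0.53)


def _unit(vals: dict) -> np.ndarray:
    v = np.array([vals[a] for a in AA_ALPHABET], dtype=float)
    v = v - v.mean()
    return v / v.std()


DEFAULT_LOADINGS = np.vstack([_unit(_KD), _unit({a: -_HELIX[a] for a in AA_ALPHABET})])

# amino-acid-specific log2 offsets (stability-independent usage preferences),
# Val anchored at 0, Cys never sampled as wild type
DEFAULT_OFFSETS = {
    "E": 1.5, "D": 1.2, "K": 1.0, "Q": 0.6, "A": 0.5, "N": 0.5, "R": 0.5,
    "S": 0.4, "T": 0.3, "G": 0.2, "V": 0.0, "L": -0.1, "I": -0.2, "H": -0.3,
    "P": -0.5, "M": -1.5, "Y": -1.8, "F": -2.0, "W": -3.5,
}
DEFAULT_SLOPE = 3.2  # log2 probability units per kcal/mol (~9.2-fold per kcal)


def to_nucleotide(aa_seq: str) -> str:
    return "".join(CODON[a] for a in aa_seq)


def condition_grid(protease: str, replicate: int = 1, max_conc: float | None = None,
                   n_conc: int = 11, dilution: float = 3.0,
                   include_pre: bool = True) -> list[Condition]:
    """The standard dilution series: n_conc threefold dilutions + no-protease
    control (+ the pre-selection reference).  Replicate 1 tops out at 25 μM,
    replicate 2 at 25·dilution**0.5 (43.3 μM for the threefold series)."""
    if max_conc is None:
        max_conc = 25.0 * dilution ** 0.5 if replicate == 2 else 25.0
    concs = [max_conc / dilution ** i for i in range(n_conc)]
    out = []
    if include_pre:
        out.append(Condition(protease, replicate, 0.0, ROUND_PRE))
    out.append(Condition(protease, replicate, 0.0, ROUND_POST))  # no-protease control
    out.extend(Condition(protease, replicate, c, ROUND_POST) for c in sorted(concs))
    return out


def default_generating_pssm(protease: str, seed: int = 0,
                            weight_sd: float = 0.15) -> CleavagePSSM:
    """A known ground-truth PSSM used to assign K50,U to synthetic sequences."""
    rng = np.random.default_rng(seed + {"trypsin": 11, "chymotrypsin": 13}[protease])
    model = CleavagePSSM(protease=protease)
    # typical unfolded 50-mers end up with K50,U of order 0.02-0.1 μM, keeping
    # the usable ΔG window (RT·ln(K50F/K50U)) comfortably above the clip range
    model.a0_ = 0.6
    model.weights_ = rng.normal(0.0, weight_sd, size=(8, N_SYMBOLS))
    model.heldout_r_ = float("nan")
    return model


def gen_scrambles(n: int, seed: int = 0, length: int = 50,
                  source_sequences=None,
                  pssms: dict[str, CleavagePSSM] | None = None) -> pd.DataFrame:
    """Scrambled (fully unfolded) sequences with ground-truth K50,U.

    If ``source_sequences`` is given, each output is a residue shuffle of one
    of them (composition preserved exactly); otherwise sequences are uniform
    random over the 20 amino acids.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if pssms is None:
        pssms = {p: default_generating_pssm(p, seed) for p in PROTEASES}
    aas = np.array(list(AA_ALPHABET))
    seqs = []
    for i in range(n):
        if source_sequences is not None:
            src = list(str(source_sequences[i % len(source_sequences)]))
            rng.shuffle(src)
            seqs.append("".join(src))
        else:
            seqs.append("".join(rng.choice(aas, size=length)))
    df = pd.DataFrame({"seq_id": [f"scramble_{i}" for i in range(n)], "aa_seq": seqs})
    df["true_dG"] = -np.inf  # fully unfolded
    for p, model in pssms.items():
        k50u, _ = model.predict_K50U(seqs)
        df[f"true_K50U_{p}"] = k50u
        with np.errstate(divide="ignore"):
            df[f"true_log10_K50U_{p}"] = np.log10(k50u)
    return df.set_index("seq_id")


def variant_name(wt_id: str, site: int, wt_aa: str, mut_aa: str) -> str:
    return f"{wt_id}|{site}|{wt_aa}|{mut_aa}"


def parse_variant_name(name: str) -> dict:
    """Parse 'wtid|site|wt_aa|mut_aa' headers (mut 'wtN' = synonymous wild
    type, 'del' = deletion, 'insG'/'insA' = insertion, else substitution)."""
    wt_id, site, wt_aa, mut_aa = name.split("|")
    if mut_aa.startswith("wt"):
        vtype = "wt"
    elif mut_aa == "del":
        vtype = "del"
    elif mut_aa.startswith("ins"):
        vtype = "ins"
    else:
        vtype = "sub"
    return {"wt_id": wt_id, "site": int(site), "wt_aa": wt_aa,
            "mut_aa": mut_aa, "type": vtype}


@dataclass
class SyntheticLibrary:
    """A mutational-scan library with full ground truth."""

    variants: pd.DataFrame          # per-variant annotation, sequence, truth
    wildtypes: pd.DataFrame         # per-domain wild-type truth
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)  # site x 20 true ΔG
    loadings: np.ndarray | None = None
    slope: float = DEFAULT_SLOPE
    offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))


def gen_library(n_domains: int = 8, length_range: tuple[int, int] = (40, 72),
                n_factors: int = 2, factor_scale: float = 0.9,
                profile_noise: float = 0.15, wt_dG_range: tuple[float, float] = (1.5, 4.0),
                slope: float = DEFAULT_SLOPE, offsets: dict[str, float] | None = None,
                include_indels: bool = True, n_wt_codon_variants: int = 3,
                pssms: dict[str, CleavagePSSM] | None = None,
                params: dict[str, ProteolysisParams] | None = None,
                compute_k50: bool = True,
                seed: int = 0) -> SyntheticLibrary:
    """Generate domains, their site x amino-acid ΔG landscapes and all variants.

    Per site, the 20-amino-acid stability profile is a rank-``n_factors``
    factor model (default loadings: hydropathy and helix propensity) plus
    Gaussian noise; wild-type residues are sampled from the softmax of
    ``slope · ΔG + offset`` over the 19 non-Cys amino acids, i.e. from a known
    wild-type classifier model.  Variant ΔG values are wild-type ΔG plus the
    profile difference at the mutated site; deletions and Gly/Ala insertions
    are mildly destabilizing.  True K50,U (per protease) comes from the
    generating PSSMs and true K50 from the two-state kinetic model.
    """
    lo, hi = length_range
    if not (3 <= lo <= hi):
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    offsets = dict(DEFAULT_OFFSETS if offsets is None else offsets)
    if pssms is None:
        pssms = {p: default_generating_pssm(p, seed) for p in PROTEASES}
    if params is None:
        params = {p: ProteolysisParams() for p in PROTEASES}
    loadings = DEFAULT_LOADINGS[:n_factors] if n_factors <= 2 else np.vstack(
        [DEFAULT_LOADINGS, rng.normal(0, 1, size=(n_factors - 2, 20))])

    aa_arr = np.array(list(AA_ALPHABET))
    non_cys = [a for a in AA_ALPHABET if a != "C"]
    off_vec = np.array([offsets[a] for a in non_cys])

    wt_rows, var_rows, profiles = [], [], {}
    for d in range(n_domains):
        wt_id = f"dom{d:03d}"
        L = int(rng.integers(lo, hi + 1))
        z = rng.normal(0.0, 1.0, size=(L, len(loadings)))
        phi = factor_scale * (z @ loadings) + rng.normal(0.0, profile_noise, size=(L, 20))
        wt_dG = float(rng.uniform(*wt_dG_range))

        # wild type sampled from the known classifier model (19 non-Cys aa)
        phi_nc = phi[:, [AA_ALPHABET.index(a) for a in non_cys]]
        logits = slope * phi_nc + off_vec
        w = 2.0 ** (logits - logits.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        wt_idx = np.array([rng.choice(len(non_cys), p=w[s]) for s in range(L)])
        wt_seq = "".join(non_cys[i] for i in wt_idx)
        wt_phi = phi[np.arange(L), [AA_ALPHABET.index(a) for a in wt_seq]]

        # site x 20 realized variant ΔG (the wild-type column equals wt_dG)
        prof = wt_dG + phi - wt_phi[:, None]
        profiles[wt_id] = pd.DataFrame(prof, columns=list(AA_ALPHABET),
                                       index=pd.RangeIndex(1, L + 1, name="site"))
        wt_rows.append({"wt_id": wt_id, "aa_seq": wt_seq, "true_dG": wt_dG, "length": L})

        for k in range(n_wt_codon_variants):
            var_rows.append({"name": variant_name(wt_id, 0, "_", f"wt{k}"),
                             "wt_id": wt_id, "type": "wt", "site": 0, "wt_aa": "_",
                             "mut_aa": f"wt{k}", "aa_seq": wt_seq, "true_dG": wt_dG})
        for s in range(L):
            wt_aa = wt_seq[s]
            for j, aa in enumerate(aa_arr):
                if aa == wt_aa:
                    continue
                var_rows.append({
                    "name": variant_name(wt_id, s + 1, wt_aa, aa), "wt_id": wt_id,
                    "type": "sub", "site": s + 1, "wt_aa": wt_aa, "mut_aa": aa,
                    "aa_seq": wt_seq[:s] + aa + wt_seq[s + 1:],
                    "true_dG": float(prof[s, j]),
                })
            if include_indels:
                var_rows.append({
                    "name": variant_name(wt_id, s + 1, wt_aa, "del"), "wt_id": wt_id,
                    "type": "del", "site": s + 1, "wt_aa": wt_aa, "mut_aa": "del",
                    "aa_seq": wt_seq[:s] + wt_seq[s + 1:],
                    "true_dG": wt_dG - abs(rng.normal(1.2, 0.6)),
                })
                for ins in "GA":
                    var_rows.append({
                        "name": variant_name(wt_id, s + 1, wt_aa, f"ins{ins}"),
                        "wt_id": wt_id, "type": "ins", "site": s + 1, "wt_aa": wt_aa,
                        "mut_aa": f"ins{ins}",
                        "aa_seq": wt_seq[:s + 1] + ins + wt_seq[s + 1:],
                        "true_dG": wt_dG - abs(rng.normal(0.9, 0.5)),
                    })

    variants = pd.DataFrame(var_rows).set_index("name")
    wildtypes = pd.DataFrame(wt_rows).set_index("wt_id")
    if not compute_k50:
        return SyntheticLibrary(variants, wildtypes, profiles, loadings, slope, offsets)
    for p, model in pssms.items():
        k50u, _ = model.predict_K50U(variants["aa_seq"].tolist())
        variants[f"true_K50U_{p}"] = k50u
        finite = np.isfinite(k50u)
        dg = variants["true_dG"].to_numpy()
        k50 = np.empty(len(variants))
        k50[finite] = effective_K50(dg[finite], k50u[finite], params[p])
        # unfolded-state-resistant variants are still cleaved from the folded
        # state (the constant tag), so their true K50 is K50_F / (1 - f_U)
        fU = f_unfolded(dg[~finite], params[p].RT)
        k50[~finite] = params[p].K50_F / np.maximum(1.0 - fU, 1e-12)
        variants[f"true_K50_{p}"] = k50
    return SyntheticLibrary(variants, wildtypes, profiles, loadings, slope, offsets)


def simulate_experiment(truth: pd.DataFrame, conditions: list[Condition],
                        depth: int = 1_000_000, seed: int = 0,
                        dirichlet_alpha: float = 50.0,
                        conc_errors: dict[str, float] | None = None,
                        params: dict[str, ProteolysisParams] | None = None,
                        expected: bool = False) -> CountTable:
    """Simulate sequencing counts for a library across selection conditions.

    ``truth`` is indexed by seq_id with a ``true_K50_<protease>`` column per
    protease (μM) and optionally ``floor_K50_<protease>`` adding folded-state
    cleavage with its own K50 (a rate floor independent of stability).
    Pre-selection fractions are Dirichlet; reads are multinomial at ``depth``
    per condition (or exact expected counts when ``expected``).
    ``conc_errors`` maps condition keys to hidden concentration factors for
    calibration tests.
    """
    if not any(c.round == ROUND_PRE for c in conditions):
        raise ValueError("conditions must include a pre-selection reference")
    if params is None:
        params = {p: ProteolysisParams() for p in PROTEASES}
    rng = np.random.default_rng(seed)
    n = len(truth)
    f_pre = (np.full(n, 1.0 / n) if expected
             else rng.dirichlet(np.full(n, dirichlet_alpha)))

    cols = {}
    for cond in conditions:
        if cond.round == ROUND_PRE:
            p_vec = f_pre
        else:
            E = cond.conc_uM * (conc_errors or {}).get(cond.key, 1.0)
            pp = params[cond.protease]
            k50 = truth[f"true_K50_{cond.protease}"].to_numpy(dtype=float)
            k = pp.k_max * E / (E + k50)
            floor_col = f"floor_K50_{cond.protease}"
            if floor_col in truth:
                fl = truth[floor_col].to_numpy(dtype=float)
                extra = np.where(np.isfinite(fl), pp.k_max * E / (E + fl), 0.0)
                k = k + extra
            S = np.exp(-k * pp.t_digest)
            w = f_pre * S
            p_vec = w / w.sum()
        if expected:
            cols[cond.key] = depth * p_vec
        else:
            cols[cond.key] = rng.multinomial(depth, p_vec)
    df = pd.DataFrame(cols, index=truth.index)
    df.index.name = "seq_id"
    return CountTable(df, conditions)


@dataclass
class PairGrid:
    """A 20 x 20 double-mutant ΔG table at two sites of one domain."""

    domain_id: str
    site_i: int
    site_j: int
    table: pd.DataFrame  # index/columns = amino acids at site i / site j
    wt_pair: tuple[str, str]
    background: str = "wt"


def gen_pair_grids(n_pairs: int = 3, coupling_spec: dict | None = None,
                   noise: float = 0.1, seed: int = 0,
                   backgrounds: tuple[str, ...] = ("wt",),
                   effect_sd: float = 0.8, mean_dG: float = 2.5):
    """Double-mutant grids: additive row/column effects + planted couplings.

    ``coupling_spec`` maps ``(aa_i, aa_j)`` to a coupling value, or to a dict
    ``{background: value}`` for background-dependent (third-order) couplings.
    Returns ``(grids, truth)`` where truth records the planted additive parts
    and coupling matrix per grid.
    """
    rng = np.random.default_rng(seed)
    aas = list(AA_ALPHABET)
    grids, truth = [], []
    for k in range(n_pairs):
        alpha = rng.normal(0.0, effect_sd, 20)
        beta = rng.normal(0.0, effect_sd, 20)
        mu = rng.normal(mean_dG, 0.4)
        wt_pair = (aas[rng.integers(20)], aas[rng.integers(20)])
        for bg in backgrounds:
            C = np.zeros((20, 20))
            for (ai, aj), val in (coupling_spec or {}).items():
                v = val.get(bg, 0.0) if isinstance(val, dict) else val
                C[aas.index(ai), aas.index(aj)] = v
            eps = rng.normal(0.0, noise, size=(20, 20)) if noise > 0 else 0.0
            tab = mu + alpha[:, None] + beta[None, :] + C + eps
            grids.append(PairGrid(f"pairdom{k:02d}", 1, 2,
                                  pd.DataFrame(tab, index=aas, columns=aas),
                                  wt_pair, bg))
            truth.append({"domain_id": f"pairdom{k:02d}", "background": bg,
                          "mu": mu, "alpha": alpha.copy(), "beta": beta.copy(),
                          "coupling": C})
    return grids, truth


def gen_classifier_sites(n_sites: int = 5000, slope: float = DEFAULT_SLOPE,
                         offsets: dict[str, float] | None = None,
                         dG_mean: float = 2.5, dG_sd: float = 1.2,
                         seed: int = 0):
    """Independent site profiles + wild types from a known classifier model.

    Returns ``(X, y)``: X the (n_sites, 19) ΔG matrix over non-Cys amino acids
    (clipped to the assay range) and y the sampled wild-type indices.
    """
    rng = np.random.default_rng(seed)
    offsets = dict(DEFAULT_OFFSETS if offsets is None else offsets)
    non_cys = [a for a in AA_ALPHABET if a != "C"]
    off_vec = np.array([offsets[a] for a in non_cys])
    X = np.clip(rng.normal(dG_mean, dG_sd, size=(n_sites, 19)), -1.0, 5.0)
    logits = slope * X + off_vec
    w = 2.0 ** (logits - logits.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(19, p=w[s]) for s in range(n_sites)])
    return X, y
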