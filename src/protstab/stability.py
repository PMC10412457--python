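"""K50 → ΔG conversion, joint two-protease fits, ΔΔG, and quality filtering.

Stage 1 (measurement level): every estimate carries a 95% interval; estimates
whose interval is wider than 0.5 kcal/mol are flagged low-confidence, and
estimates whose interval lies fully outside the assay's −1..5 kcal/mol dynamic
range are censored to the bound ('<−1' / '>5').

Stage 2 (scan level): each whole mutational scan is assigned to exactly one of
twelve groups.  G0 passes all filters with wild-type ΔG ≤ 4.75 kcal/mol (so
stabilizing mutations are resolvable); G1 passes but is too stable for that;
G2–G11 fail a filter (poor expression, unstable wild type, inconsistent or
poorly correlated trypsin/chymotrypsin ΔG, bad slope or intercept, too many
stabilizing mutants, multiple cysteines, evidence of folded-state cleavage).

Stage 3 (mutant level): within G0/G1 scans, individual mutants that introduce
new cleavage sites into poorly structured regions (apparent destabilization)
or cysteines into poorly structured regions (apparent stabilization through
cross-linking) are blanked in the '_ML' output columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable
from .k50 import (K50Result, _local_grids, _posterior_summary, _refine_map,
                  infer_K50)
from .kinetics import (CENSOR_ABOVE, CENSOR_BELOW, CENSOR_NONE, DG_CLIP_HI,
                       DG_CLIP_LO, ProteolysisParams, clip_dG, deltaG_from_K50,
                       effective_K50, f_unfolded)
from .unfolded import DEFAULT_TARGETS

LOW_CONFIDENCE_WIDTH = 0.5  # kcal/mol, 95% interval width


# ---------------------------------------------------------------------------
# ΔG fitting


def _dG_from_k50_estimates(est: pd.DataFrame, K50U: np.ndarray,
                           params: ProteolysisParams) -> pd.DataFrame:
    """Transform per-protease K50 estimates (log10) into ΔG with intervals."""
    out = pd.DataFrame(index=est.index)
    usable = np.isfinite(K50U) & (K50U > 0) & (K50U < params.K50_F)
    for col, src in (("dG", "log10_K50"), ("dG_lo", "lo95"), ("dG_hi", "hi95")):
        vals = np.full(len(est), np.nan)
        finite_pt = est[src].notna().to_numpy() & usable
        if finite_pt.any():
            vals[finite_pt] = deltaG_from_K50(
                10.0 ** est[src].to_numpy()[finite_pt], K50U[finite_pt], params)
        out[col] = vals
    censor = est["censor"].copy()
    censor[(out["dG"] == -np.inf).to_numpy()] = CENSOR_BELOW
    censor[(out["dG"] == np.inf).to_numpy()] = CENSOR_ABOVE
    censor[~usable] = "resistant"
    out["censor"] = censor
    return out


def fit_dG(table: CountTable, K50U: dict[str, pd.Series],
           params: dict[str, ProteolysisParams],
           dG_grid: np.ndarray | None = None, chunk: int = 256,
           k50_kwargs: dict | None = None):
    """Per-protease and joint ΔG for every sequence in the library.

    ``K50U`` maps protease → per-sequence unfolded-state K50 (μM; inf/NaN =
    unfolded-state resistant, that protease is dropped for that sequence).
    The joint fit maximizes the product of the proteases' count likelihoods
    over one shared ΔG, with each protease's K50 tied to ΔG through the
    two-state model; sequences usable with only one protease fall back to a
    single-protease fit, flagged in ``fit_mode``.

    Returns ``(df, k50_results)``.
    """
    if dG_grid is None:
        dG_grid = np.linspace(-6.0, 10.0, 481)
    proteases = list(params)
    k50_results: dict[str, K50Result] = {}
    df = pd.DataFrame(index=table.seq_ids)
    for p in proteases:
        res = infer_K50(table, p, params[p], **(k50_kwargs or {}))
        k50_results[p] = res
        ku = K50U[p].reindex(table.seq_ids).to_numpy(dtype=float)
        sub = _dG_from_k50_estimates(res.estimates, ku, params[p])
        df[f"log10_K50_{p}"] = res.estimates["log10_K50"]
        df[f"K50_censor_{p}"] = res.estimates["censor"]
        df[f"dG_{p}"], _ = clip_dG(sub["dG"].to_numpy())
        df[f"dG_{p}"] = np.where(sub["dG"].isna(), np.nan, df[f"dG_{p}"])
        df[f"dG_{p}_lo"] = sub["dG_lo"]
        df[f"dG_{p}_hi"] = sub["dG_hi"]
        df[f"dG_{p}_censor"] = sub["censor"]
        df[f"n_pre_counts_{p}"] = res.estimates["n_pre_counts"]

    # joint grid fit
    n = len(table.seq_ids)
    usable = {}
    blocks = {}
    T = np.zeros(n)
    for p in proteases:
        post = table.select(protease=p, round="post")
        pre = table.select(protease=p, round="pre")
        n_post = post.counts.to_numpy(dtype=float)
        n_pre = pre.counts.sum(axis=1).to_numpy(dtype=float)
        ku = K50U[p].reindex(table.seq_ids).to_numpy(dtype=float)
        ok = np.isfinite(ku) & (ku > 0) & (ku < params[p].K50_F)
        usable[p] = ok
        # resistant sequences contribute nothing to the joint fit for p
        T[ok] += n_pre[ok] + n_post[ok].sum(axis=1)
        blocks[p] = {
            "n_post": n_post, "N_post": n_post.sum(axis=0),
            "N_pre": float(n_pre.sum()),
            "Z": k50_results[p].normalizers.to_numpy(),
            "conc": np.array([c.conc_uM for c in post.conditions]),
            "ku": ku, "ok": ok,
        }

    def joint_ll(X2d: np.ndarray) -> np.ndarray:
        """Profile log-likelihood at per-row ΔG grids X2d (n, L)."""
        ll = np.zeros_like(X2d)
        A = np.zeros_like(X2d)
        for p in proteases:
            b = blocks[p]
            kt = params[p].k_max * params[p].t_digest
            A[b["ok"]] += b["N_pre"]
            for start in range(0, n, chunk):
                idx = np.arange(start, min(start + chunk, n))
                sel = idx[b["ok"][idx]]
                if len(sel) == 0:
                    continue
                fU = f_unfolded(X2d[sel], params[p].RT)  # (m, L)
                K50 = 1.0 / (fU / b["ku"][sel, None] + (1.0 - fU) / params[p].K50_F)
                conc = b["conc"]
                S = np.exp(-kt * conc[None, :, None] /
                           (conc[None, :, None] + K50[:, None, :]))  # (m, C, L)
                ll[sel] += np.einsum("mc,mcl->ml", b["n_post"][sel],
                                     np.log(S) - np.log(b["Z"])[None, :, None])
                A[sel] += np.einsum("c,mcl->ml", b["N_post"] / b["Z"], S)
        return ll - T[:, None] * np.log(np.maximum(A, 1e-300))

    ll = joint_ll(np.broadcast_to(dG_grid, (n, len(dG_grid))))
    any_usable = np.logical_or.reduce([usable[p] for p in proteases])
    point = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    rows = np.flatnonzero(any_usable)
    if len(rows):
        pts = np.array([_refine_map(dG_grid, ll[i]) for i in rows])
        _, sd0, _, _ = _posterior_summary(dG_grid, ll[rows])
        # fine local pass: intervals can be narrower than the coarse grid step
        step = dG_grid[1] - dG_grid[0]
        Xf = np.broadcast_to(dG_grid, (n, len(dG_grid))).copy()
        Xf[rows] = _local_grids(pts, sd0, (dG_grid[0], dG_grid[-1]), step,
                                n_points=len(dG_grid))
        llf = joint_ll(Xf)
        _, sd_r, lo_r, hi_r = _posterior_summary(Xf[rows], llf[rows])
        point[rows], sd[rows], lo[rows], hi[rows] = pts, sd_r, lo_r, hi_r

    censor = np.full(n, CENSOR_NONE, dtype=object)
    censor[~any_usable] = "resistant"
    censor[(hi < DG_CLIP_LO)] = CENSOR_BELOW
    censor[(lo > DG_CLIP_HI)] = CENSOR_ABOVE
    modes = []
    for i in range(n):
        used = [p for p in proteases if usable[p][i]]
        modes.append("joint" if len(used) > 1 else (f"{used[0]}_only" if used else "none"))

    clipped, _ = clip_dG(point)
    df["dG"] = np.where(np.isnan(point), np.nan, clipped)
    df["dG_raw"] = point
    df["dG_lo"] = lo
    df["dG_hi"] = hi
    df["dG_sd"] = sd
    df["dG_censor"] = censor
    df["dG_width"] = hi - lo
    df["low_confidence"] = (hi - lo) > LOW_CONFIDENCE_WIDTH
    df["fit_mode"] = modes
    return df, k50_results


def fit_joint_dG(table: CountTable, K50U_t, K50U_c,
                 params_t: ProteolysisParams, params_c: ProteolysisParams, **kw):
    """Convenience wrapper around :func:`fit_dG` for the two standard proteases."""
    df, _ = fit_dG(table, {"trypsin": pd.Series(K50U_t, index=table.seq_ids),
                           "chymotrypsin": pd.Series(K50U_c, index=table.seq_ids)},
                   {"trypsin": params_t, "chymotrypsin": params_c}, **kw)
    return df


# ---------------------------------------------------------------------------
# Domain scans: ΔΔG, trypsin/chymotrypsin consistency, group classification


@dataclass
class GroupThresholds:
    """Scan-classification thresholds (only the G1 cut and the 0.5 kcal/mol CI
    flag are canonical; the rest reproduce the decision structure and are
    configurable)."""

    g2_min_pre_counts: float = 20.0
    g3_min_wt_dG: float = 0.25
    g4_max_wt_dG_gap: float = 1.0
    g5_min_r: float = 0.8
    g6_slope_range: tuple[float, float] = (0.8, 1.25)
    g7_max_stabilizing_frac: float = 0.10
    g10_max_intercept: float = 0.75
    g11_jump: float = 0.5 * 0.593 * np.log(10.0)  # ΔG-equivalent of 0.5 log10 K50 units
    g11_min_variants: int = 5
    g1_wt_dG: float = 4.75
    cys_whitelist: tuple[str, ...] = ()
    low_variance_sd: float = 0.3
    rule1_ddG: float = -0.5
    rule2_ddG: float = 0.5


@dataclass
class DomainScan:
    """One wild-type background's mutational scan with fitted estimates."""

    wt_id: str
    wt_seq: str
    data: pd.DataFrame
    group: str | None = None
    stats: dict = field(default_factory=dict)


def build_scan(wt_id: str, wt_seq: str, annotations: pd.DataFrame,
               estimates: pd.DataFrame) -> DomainScan:
    """Join variant annotations (type/site/wt_aa/mut_aa) with ΔG estimates."""
    rows = annotations[annotations["wt_id"] == wt_id]
    data = rows.join(estimates, how="inner")
    return DomainScan(wt_id, wt_seq, data.copy())


def wild_type_dG(scan: DomainScan, column: str = "dG") -> float:
    """Wild-type ΔG = median over synonymous wild-type variants (clipped)."""
    wt = scan.data[scan.data["type"] == "wt"]
    if len(wt) == 0:
        raise ValueError(f"scan {scan.wt_id} has no wild-type variants")
    vals = wt[column].dropna().to_numpy()
    if len(vals) == 0:
        return float("nan")
    clipped, _ = clip_dG(vals)
    return float(np.median(clipped))


def compute_ddG(scan: DomainScan, columns=("dG", "dG_trypsin", "dG_chymotrypsin")) -> DomainScan:
    """ΔΔG = clipped variant ΔG − clipped wild-type ΔG (positive = stabilizing).

    Variants censored at the upper clip bound get a 'lower_bound' ΔΔG flag
    (their true ΔΔG is at least the tabulated value); lower-censored ones get
    'upper_bound'.
    """
    for col in columns:
        if col not in scan.data:
            continue
        wt = wild_type_dG(scan, col)
        clipped, _ = clip_dG(scan.data[col].to_numpy(dtype=float))
        suffix = col.removeprefix("dG")
        scan.data[f"ddG{suffix}"] = clipped - wt
        scan.stats[f"wt_dG{suffix}"] = wt
    cens = scan.data.get("dG_censor")
    if cens is not None:
        flag = np.full(len(scan.data), "none", dtype=object)
        flag[(cens == CENSOR_ABOVE).to_numpy()] = "lower_bound"
        flag[(cens == CENSOR_BELOW).to_numpy()] = "upper_bound"
        scan.data["ddG_bound"] = flag
    return scan


def _reliable_mask(data: pd.DataFrame) -> pd.Series:
    ok = pd.Series(True, index=data.index)
    for p in ("trypsin", "chymotrypsin"):
        ok &= data[f"dG_{p}_censor"] == CENSOR_NONE
        ok &= (data[f"dG_{p}_hi"] - data[f"dG_{p}_lo"]) <= LOW_CONFIDENCE_WIDTH
    return ok


def tc_consistency(scan: DomainScan, min_pairs: int = 10):
    """(Pearson r, OLS slope, intercept) of chymotrypsin ΔG on trypsin ΔG over
    reliable (uncensored, narrow-interval) variants."""
    ok = _reliable_mask(scan.data)
    x = scan.data.loc[ok, "dG_trypsin"].to_numpy(dtype=float)
    y = scan.data.loc[ok, "dG_chymotrypsin"].to_numpy(dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if len(x) < min_pairs:
        scan.stats.update(tc_r=np.nan, tc_slope=np.nan, tc_intercept=np.nan,
                          tc_n=len(x))
        return np.nan, np.nan, np.nan
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    scan.stats.update(tc_r=r, tc_slope=float(slope),
                      tc_intercept=float(intercept), tc_n=int(len(x)))
    return r, float(slope), float(intercept)


def _cut_site_jump(scan: DomainScan, thresholds: GroupThresholds) -> float:
    """Largest per-site median jump in apparent ΔΔG for one protease when a
    wild-type cut site of that protease is mutated away (folded-state
    cleavage signature)."""
    targets = DEFAULT_TARGETS
    all_targets = targets["trypsin"] | targets["chymotrypsin"]
    subs = scan.data[scan.data["type"] == "sub"]
    best = -np.inf
    for p, other in (("trypsin", "chymotrypsin"), ("chymotrypsin", "trypsin")):
        rows = subs[subs["wt_aa"].isin(targets[p])
                    & ~subs["mut_aa"].isin(all_targets)]
        for _, grp in rows.groupby("site"):
            jump = (grp[f"ddG_{p}"] - grp[f"ddG_{other}"]).dropna()
            if len(jump) >= thresholds.g11_min_variants:
                best = max(best, float(np.median(jump)))
    return best


def classify_domain(scan: DomainScan,
                    thresholds: GroupThresholds | None = None) -> str:
    """Assign the scan to its (single) quality group, first failing rule wins.

    Order: G2 (expression), G3 (too unstable), G4 (inconsistent wild-type ΔG),
    G5 (poor T–C correlation), G6 (poor slope), G9/G8 (multiple Cys), G7 (too
    many stabilizing mutants), G10 (poor intercept), G11 (folded-state
    cleavage signature), then G1/G0 by wild-type stability.
    """
    th = thresholds or GroupThresholds()
    if "ddG" not in scan.data:
        compute_ddG(scan)
    if "tc_r" not in scan.stats:
        tc_consistency(scan)

    wt_rows = scan.data[scan.data["type"] == "wt"]
    pre_cols = [c for c in scan.data.columns if c.startswith("n_pre_counts")]
    pre_counts = float(wt_rows[pre_cols].median().min()) if len(wt_rows) else 0.0
    wt_dG = scan.stats.get("wt_dG", wild_type_dG(scan))
    wt_t = scan.stats.get("wt_dG_trypsin", wild_type_dG(scan, "dG_trypsin"))
    wt_c = scan.stats.get("wt_dG_chymotrypsin", wild_type_dG(scan, "dG_chymotrypsin"))
    r, slope, intercept = (scan.stats["tc_r"], scan.stats["tc_slope"],
                           scan.stats["tc_intercept"])
    ddG = scan.data.loc[scan.data["type"] != "wt", "ddG"].dropna()
    stab_frac = float((ddG > 1.0).mean()) if len(ddG) else 0.0
    n_cys = scan.wt_seq.count("C")
    scan.stats.update(wt_pre_counts=pre_counts, stabilizing_frac=stab_frac,
                      n_cys=n_cys)

    if pre_counts < th.g2_min_pre_counts:
        group = "G2"
    elif np.isfinite(wt_dG) and wt_dG < th.g3_min_wt_dG:
        group = "G3"
    elif np.isfinite(wt_t) and np.isfinite(wt_c) and abs(wt_t - wt_c) > th.g4_max_wt_dG_gap:
        group = "G4"
    elif np.isnan(r):
        group = "unclassifiable"
    elif r < th.g5_min_r:
        group = "G5"
    elif not (th.g6_slope_range[0] <= slope <= th.g6_slope_range[1]):
        group = "G6"
    elif n_cys > 1:
        group = "G8" if scan.wt_id in th.cys_whitelist else "G9"
    elif stab_frac > th.g7_max_stabilizing_frac:
        group = "G7"
    elif abs(intercept) > th.g10_max_intercept:
        group = "G10"
    elif _cut_site_jump(scan, th) > th.g11_jump:
        group = "G11"
    elif wt_dG > th.g1_wt_dG:
        group = "G1"
    else:
        group = "G0"
    scan.group = group
    return group


# ---------------------------------------------------------------------------
# Stage 3: mutant-level filtering


def filter_mutants(scan: DomainScan,
                   thresholds: GroupThresholds | None = None) -> DomainScan:
    """Flag individual mutants that can disrupt the assay.

    Rule 1: a substitution creating a new cleavage site for a protease, in a
    poorly structured region (low ΔG variance across rule-exempt amino acids
    at the site), with apparent destabilization in that protease.  Rule 2: a
    Cys substitution in a poorly structured region with apparent stabilization
    (disulfide retention of the cDNA).  Site variance is computed over
    substitutions that can never match either rule, so the filter is
    idempotent.  Flags go into a boolean ``filtered`` column.
    """
    th = thresholds or GroupThresholds()
    if "ddG" not in scan.data:
        compute_ddG(scan)
    targets = DEFAULT_TARGETS
    all_targets = targets["trypsin"] | targets["chymotrypsin"]
    data = scan.data
    subs = data["type"] == "sub"
    exempt = subs & ~data["mut_aa"].isin(all_targets | {"C"})

    site_sd = (data.loc[exempt].groupby("site")["dG"].std())
    sd_of = data["site"].map(site_sd)
    low_var = sd_of < th.low_variance_sd

    filtered = pd.Series(False, index=data.index)
    reason = pd.Series("", index=data.index, dtype=object)
    for p in ("trypsin", "chymotrypsin"):
        new_site = (subs & data["mut_aa"].isin(targets[p])
                    & ~data["wt_aa"].isin(targets[p]))
        hit = new_site & low_var & (data[f"ddG_{p}"] < th.rule1_ddG)
        filtered |= hit.fillna(False)
        reason[hit.fillna(False)] = f"new_{p}_site"
    cys_hit = subs & (data["mut_aa"] == "C") & low_var & (data["ddG"] > th.rule2_ddG)
    filtered |= cys_hit.fillna(False)
    reason[cys_hit.fillna(False)] = "cys_stabilizing"

    data["filtered"] = filtered
    data["filter_reason"] = reason
    return scan


# ---------------------------------------------------------------------------
# Dataset assembly


def _fmt_ml(value, censor, filtered) -> str:
    if filtered or pd.isna(value):
        return "–"
    if censor == CENSOR_BELOW:
        return "<-1"
    if censor == CENSOR_ABOVE:
        return ">5"
    return f"{value:.2f}"


def assemble_dataset(scans: list[DomainScan]):
    """Assemble the quality-filtered library tables.

    Returns ``(dataset2, dataset3)``: dataset2 holds all G0+G1 variants with
    ΔG; dataset3 the G0 variants with ΔΔG (only there are stabilizing
    mutations resolvable).  '_ML' columns blank filtered/low-quality entries
    with '–' and mark out-of-range estimates '<-1' / '>5'.
    """
    rows2, rows3 = [], []
    for scan in scans:
        if scan.group is None:
            raise ValueError(f"scan {scan.wt_id} has not been classified")
        if scan.group not in ("G0", "G1"):
            continue
        if "filtered" not in scan.data:
            filter_mutants(scan)
        for name, row in scan.data.iterrows():
            rec = {
                "name": name, "wt_id": scan.wt_id, "aa_seq": row["aa_seq"],
                "log10_K50_trypsin": row.get("log10_K50_trypsin"),
                "log10_K50_chymotrypsin": row.get("log10_K50_chymotrypsin"),
                "dG": row["dG"],
                "dG_ML": _fmt_ml(row["dG"], row.get("dG_censor"), row["filtered"]),
                "group_label": scan.group,
            }
            rows2.append(rec)
            if scan.group == "G0":
                rec3 = dict(rec)
                rec3["ddG"] = row.get("ddG")
                rec3["ddG_ML"] = _fmt_ml(row.get("ddG"), row.get("dG_censor"),
                                         row["filtered"])
                rows3.append(rec3)
    cols2 = ["name", "wt_id", "aa_seq", "log10_K50_trypsin",
             "log10_K50_chymotrypsin", "dG", "dG_ML", "group_label"]
    dataset2 = pd.DataFrame(rows2, columns=cols2)
    dataset3 = pd.DataFrame(rows3, columns=cols2 + ["ddG", "ddG_ML"])
    return dataset2, dataset3
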