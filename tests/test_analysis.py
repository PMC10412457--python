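"""Site PCA, couplings, wild-type classifier, functional sites, census, cones."""

import numpy as np
import pandas as pd
import pytest

from protstab import simulate as sim
from protstab.analysis import (NON_CYS, WildTypeClassifier, bootstrap_coupling,
                               classifier_metrics, classify_functional,
                               cone_contacts, design_delta, fit_additive_pair,
                               mean_site_ddG, normalize_conservation,
                               null_model_proba, offset_ratio, pca_fit,
                               stabilizing_census, triplet_coupling,
                               virtual_cbeta, wt_advantage)
from protstab.unfolded import AA_ALPHABET


# ---------------------------------------------------------------------------
# PCA


def low_rank_profiles(n_sites=300, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    V = sim.DEFAULT_LOADINGS  # two orthogonal-ish loading vectors
    z = rng.normal(0, 1, size=(n_sites, 2))
    X = 2.5 + z @ V + rng.normal(0, noise, size=(n_sites, 20))
    return np.clip(X, -1, 5)


def test_pca_identical_profiles_rejected():
    X = np.tile(np.linspace(0, 2, 20), (50, 1))
    with pytest.raises(ValueError):
        pca_fit(X)


def test_pca_recovers_low_rank_structure():
    res = pca_fit(low_rank_profiles())
    assert res.variance_fractions[:2].sum() >= 0.95
    assert res.variance_fractions.sum() == pytest.approx(1.0)
    assert len(res.variance_fractions) <= 19  # site centering removes one dof
    # components orthonormal
    G = res.components @ res.components.T
    np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-10)


def test_pca_drops_incomplete_sites():
    X = low_rank_profiles(n_sites=60)
    X[3, 5] = np.nan
    res = pca_fit(X)
    assert res.n_sites == 59


def test_wt_advantage_limits():
    X = low_rank_profiles(n_sites=200, seed=1)
    rng = np.random.default_rng(2)
    wt = rng.integers(0, 20, 200)
    full, recon0 = wt_advantage(X, wt, k=0)
    assert recon0 == 0.0
    full19, recon19 = wt_advantage(X, wt, k=19)
    assert recon19 == pytest.approx(full19, abs=1e-10)
    assert full == full19


def test_wt_advantage_explained_fraction_grows_with_k():
    """Wild types drawn from a stability-driven model: the reconstructed
    advantage approaches the full advantage monotonically (on average)."""
    X = low_rank_profiles(n_sites=400, noise=0.3, seed=3)
    rng = np.random.default_rng(4)
    w = 2.0 ** (3.0 * X)
    w /= w.sum(axis=1, keepdims=True)
    wt = np.array([rng.choice(20, p=w[i]) for i in range(len(X))])
    full, _ = wt_advantage(X, wt, k=0)
    assert full < 0  # wild type typically more stable
    fracs = [wt_advantage(X, wt, k=k)[1] / full for k in (1, 2, 5, 19)]
    assert fracs[-1] == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(fracs) > -0.05)
    assert fracs[1] > 0.5  # two planted factors carry most of the advantage


# ---------------------------------------------------------------------------
# additive pair model and couplings


def test_additive_table_has_zero_couplings():
    grids, _ = sim.gen_pair_grids(1, noise=0.0, seed=5)
    fit = fit_additive_pair(grids[0])
    assert np.nanmax(np.abs(fit.coupling.to_numpy())) < 1e-10
    # fitted residuals orthogonal to row/column indicator space
    C = fit.coupling.to_numpy()
    assert np.allclose(C.sum(axis=0), 0, atol=1e-9)
    assert np.allclose(C.sum(axis=1), 0, atol=1e-9)


def test_single_cell_perturbation_two_way_residual():
    aas = list(AA_ALPHABET)
    # 3x3 complete additive table with +delta in one cell -> coupling 4*delta/9
    base = np.add.outer([0.0, 1.0, 2.0], [0.0, 0.5, 1.0]) + 2.0
    base[1, 2] += 0.9
    fit = fit_additive_pair(pd.DataFrame(base, index=aas[:3], columns=aas[:3]),
                            min_cells=9, clip=False)
    assert fit.coupling.iloc[1, 2] == pytest.approx(0.9 * 4 / 9)
    # 20x20 with +2 in one cell -> 2 * (19/20)^2
    tab = np.add.outer(np.linspace(0, 1.9, 20), np.linspace(0, 0.95, 20)) + 1.0
    tab[4, 7] += 2.0
    fit20 = fit_additive_pair(pd.DataFrame(tab, index=aas, columns=aas), clip=False)
    assert fit20.coupling.iloc[4, 7] == pytest.approx(2.0 * (19 / 20) ** 2)


def test_additive_fit_matches_statsmodels_ols_oracle():
    """Independent oracle: OLS with categorical row/column design, complete
    and incomplete random tables."""
    import statsmodels.api as sm
    rng = np.random.default_rng(6)
    aas = list(AA_ALPHABET)
    for trial in range(10):
        tab = rng.normal(2, 1, size=(20, 20)).clip(-1, 5)
        if trial % 2:
            mask = rng.random((20, 20)) < 0.15
            tab[mask] = np.nan
        fit = fit_additive_pair(pd.DataFrame(tab, index=aas, columns=aas),
                                clip=False)
        ii, jj = np.nonzero(~np.isnan(tab))
        # full-rank reference-category parametrization of the same model
        X = np.zeros((len(ii), 38))
        for k, (i, j) in enumerate(zip(ii, jj)):
            if i > 0:
                X[k, i - 1] = 1.0
            if j > 0:
                X[k, 19 + j - 1] = 1.0
        res = sm.OLS(tab[ii, jj], sm.add_constant(X)).fit()
        resid = np.full((20, 20), np.nan)
        resid[ii, jj] = res.resid
        np.testing.assert_allclose(fit.coupling.to_numpy()[ii, jj],
                                   resid[ii, jj], atol=1e-8)


def test_fit_additive_pair_requires_enough_cells():
    tab = np.full((20, 20), np.nan)
    tab[:5, :5] = 1.0
    with pytest.raises(ValueError):
        fit_additive_pair(pd.DataFrame(tab))


def test_missing_row_leaves_couplings_undefined():
    grids, _ = sim.gen_pair_grids(1, noise=0.05, seed=7)
    tab = grids[0].table.copy()
    tab.iloc[3, :] = np.nan
    fit = fit_additive_pair(tab)
    assert fit.coupling.iloc[3].isna().all()
    assert np.isnan(fit.row_effects.iloc[3])
    assert fit.coupling.iloc[4].notna().all()


def test_bootstrap_sd_noiseless_and_degenerate():
    grids, _ = sim.gen_pair_grids(1, noise=0.0, seed=8)
    sd = bootstrap_coupling(grids[0], n_boot=50, seed=0, clip=False)
    assert np.nanmax(sd.to_numpy()) < 1e-9
    sd1 = bootstrap_coupling(grids[0], n_boot=1, seed=0, clip=False)
    assert np.nanmax(sd1.to_numpy()) == 0.0


def test_bootstrap_sd_tracks_ls_theory():
    """With iid noise σ on a complete R x C table, the bootstrap spread of a
    cell's coupling reflects the additive fit's uncertainty there: the cell's
    own value is fixed, so sd ≈ σ·sqrt(1/R + 1/C - 1/(RC)) (the fitted-value
    leverage under LS theory)."""
    sigma = 0.25
    grids, _ = sim.gen_pair_grids(1, noise=sigma, seed=9)
    sd = bootstrap_coupling(grids[0], n_boot=300, seed=1, clip=False)
    analytic = sigma * np.sqrt(1 / 20 + 1 / 20 - 1 / 400)
    med = float(np.nanmedian(sd.to_numpy()))
    assert analytic * 0.7 <= med <= analytic * 1.3


def test_bootstrap_deterministic_given_seed():
    grids, _ = sim.gen_pair_grids(1, noise=0.1, seed=10)
    a = bootstrap_coupling(grids[0], n_boot=25, seed=3)
    b = bootstrap_coupling(grids[0], n_boot=25, seed=3)
    assert a.equals(b)


def test_triplet_coupling_background_signature():
    spec = {("A", "D"): {"wt": 1.5, "ala": 0.0}}
    grids, _ = sim.gen_pair_grids(1, coupling_spec=spec, noise=0.05, seed=11,
                                  backgrounds=("wt", "ala"))
    for g in grids:
        g.wt_pair = ("A", "D")
    table = triplet_coupling({"pair0": {g.background: g for g in grids}},
                             n_boot=50, seed=0)
    assert table.iloc[0]["signature"] == pytest.approx(1.5, abs=0.15)
    # identical backgrounds: signature ~ 0
    grids2, _ = sim.gen_pair_grids(1, coupling_spec={("A", "D"): 1.0},
                                   noise=0.05, seed=12, backgrounds=("wt", "ala"))
    for g in grids2:
        g.wt_pair = ("A", "D")
    t2 = triplet_coupling({"p": {g.background: g for g in grids2}}, n_boot=50, seed=0)
    assert abs(t2.iloc[0]["signature"]) < 0.15
    # missing background skipped
    t3 = triplet_coupling({"p": {"wt": grids2[0]}})
    assert t3.empty


# ---------------------------------------------------------------------------
# wild-type classifier


def test_classifier_equal_stabilities_reduce_to_frequency_model():
    rng = np.random.default_rng(13)
    n = 4000
    X = np.full((n, 19), 2.0)
    freqs = rng.dirichlet(np.full(19, 5.0))
    y = rng.choice(19, size=n, p=freqs)
    clf = WildTypeClassifier().fit(X, y)
    proba = clf.predict_proba(X[:1])[0]
    emp = np.bincount(y, minlength=19) / n
    np.testing.assert_allclose(proba, emp, atol=5e-3)


def test_classifier_parameter_recovery_small():
    X, y = sim.gen_classifier_sites(3000, seed=14)
    clf = WildTypeClassifier().fit(X, y)
    assert clf.mean_slope() == pytest.approx(sim.DEFAULT_SLOPE, rel=0.15)
    assert clf.offsets_["V"] == 0.0  # anchor
    errs = [abs(clf.offsets_[a] - sim.DEFAULT_OFFSETS[a]) for a in NON_CYS]
    assert np.mean(errs) < 0.35
    # probabilities sum to one per site
    P = clf.predict_proba(X[:50])
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    # monotone weighting function
    g = clf.weighting_function(np.linspace(-1, 5, 50))
    assert np.all(np.diff(g) >= -1e-12)


def test_classifier_degenerate_single_site():
    with pytest.raises(ValueError):
        WildTypeClassifier().fit(np.full((1, 19), 2.0), [0])


def test_classifier_metrics_limits():
    y = np.repeat(np.arange(19), 5)  # balanced wild types
    uniform = np.full((len(y), 19), 1 / 19)
    m = classifier_metrics(uniform, y)
    assert m["recovery"] == pytest.approx(1 / 19)
    assert m["perplexity"] == pytest.approx(19.0)
    point = np.zeros((len(y), 19))
    point[np.arange(len(y)), y] = 1.0
    m2 = classifier_metrics(point, y)
    assert m2 == {"recovery": 1.0, "perplexity": 1.0}


def test_null_model_perplexity_is_entropy_power():
    rng = np.random.default_rng(15)
    y = rng.choice(19, size=5000, p=rng.dirichlet(np.full(19, 2.0)))
    m = classifier_metrics(null_model_proba(y), y)
    freqs = np.bincount(y, minlength=19) / len(y)
    entropy_bits = -np.sum(freqs[freqs > 0] * np.log2(freqs[freqs > 0]))
    assert m["perplexity"] == pytest.approx(2.0 ** entropy_bits)


def test_offset_ratio_printed_values():
    offsets = {"E": 1.5, "W": -3.5, "V": 0.0}
    assert offset_ratio(offsets, "E", "W") == pytest.approx(32.0)
    assert offset_ratio(offsets, "V", "W") == pytest.approx(11.3137, abs=1e-3)
    assert offset_ratio(offsets, "E", "E") == 1.0
    with pytest.raises(ValueError):
        offset_ratio(offsets, "E", "X")


# ---------------------------------------------------------------------------
# conservation and functional sites


def test_normalize_conservation_zscore_and_flip():
    df = pd.DataFrame({"domain": ["d"] * 3, "score": [-2.0, 0.0, 2.0]})
    z = normalize_conservation(df)
    np.testing.assert_allclose(z, [1.2247, 0.0, -1.2247], atol=1e-4)
    # idempotent up to the sign flip
    df2 = pd.DataFrame({"domain": ["d"] * 3, "score": z})
    np.testing.assert_allclose(normalize_conservation(df2), -z, atol=1e-12)
    with pytest.raises(ValueError):
        normalize_conservation(pd.DataFrame({"domain": ["d"] * 3,
                                             "score": [1.0, 1.0, 1.0]}))
    with pytest.raises(ValueError):
        normalize_conservation(pd.DataFrame({"domain": ["d", "d"],
                                             "score": [0.0, 1.0]}))


def test_classify_functional_quadrants():
    ddg = pd.Series([-0.1, -2.5, -0.1, np.nan])
    cons = [2.0, 2.0, 0.2, 1.5]
    out = classify_functional(ddg, cons)
    assert out.tolist()[:3] == [True, False, False]
    assert pd.isna(out.iloc[3])


def test_classify_functional_recovers_planted_sites():
    rng = np.random.default_rng(16)
    n = 400
    functional = np.zeros(n, bool)
    functional[rng.choice(n, 40, replace=False)] = True
    cons = np.where(functional, rng.normal(2.0, 0.3, n), rng.normal(0, 0.5, n))
    ddg = np.where(functional, rng.normal(0.0, 0.2, n), rng.normal(-1.5, 0.6, n))
    out = classify_functional(pd.Series(ddg), cons)
    sens = (out[functional] == True).mean()  # noqa: E712
    assert sens >= 0.9


def test_mean_site_ddG_modes():
    prof = pd.DataFrame(2.0, index=[1, 2], columns=list(AA_ALPHABET))
    prof.loc[1, "W"] = 4.0
    wt = pd.Series({1: "A", 2: "G"})
    all_subs = mean_site_ddG(prof, wt, "all_subs")
    np_only = mean_site_ddG(prof, wt, "nonpolar_only")
    assert all_subs[2] == 0.0
    assert all_subs[1] == pytest.approx(2.0 / 19)
    assert np_only[1] == pytest.approx(2.0 / 7)  # W among 7 nonpolar non-wt
    with pytest.raises(ValueError):
        mean_site_ddG(prof, wt, "bogus")


# ---------------------------------------------------------------------------
# census and design evaluation


def test_stabilizing_census_strict_threshold():
    df = pd.DataFrame({
        "type": ["sub", "sub", "sub", "sub", "wt"],
        "wt_aa": ["A", "D", "L", "F", "_"],
        "mut_aa": ["K", "V", "E", "Y", "wt0"],
        "ddG": [1.2, 0.9, -2.0, 1.0, 0.0],
    })
    out = stabilizing_census(df)
    assert out["n_stabilizing"] == 1  # strict >1
    assert out["by_category"] == {"NP->P": 1}
    assert stabilizing_census(df.iloc[:0])["n_stabilizing"] == 0


def test_stabilizing_census_planted_fraction():
    rng = np.random.default_rng(17)
    n = 20000
    ddg = rng.normal(-0.6, 0.4, n)
    stab = rng.random(n) < 0.004
    ddg[stab] = rng.uniform(1.05, 2.0, stab.sum())
    ddg[~stab] = np.minimum(ddg[~stab], 0.99)
    df = pd.DataFrame({"type": "sub", "wt_aa": "A", "mut_aa": "K", "ddG": ddg})
    out = stabilizing_census(df)
    p = stab.mean()
    se = np.sqrt(p * (1 - p) / n)
    assert abs(out["fraction"] - p) <= 4 * se + 1e-12


def test_design_delta_arithmetic():
    wt = {"a": 2.0, "b": 1.0, "c": 3.0}
    rd = {"a": 3.0, "b": 3.5}
    delta, summary = design_delta(wt, rd)
    assert delta.to_dict() == {"a": 1.0, "b": 2.5}
    assert summary["mean"] == pytest.approx(1.75)
    assert summary["fraction_gt_1"] == 0.5
    assert summary["n_skipped"] == 1


# ---------------------------------------------------------------------------
# cone contacts on structures


def build_structure(atoms):
    """Minimal Bio.PDB structure from {(resname, resseq): {atom: coord}}."""
    from Bio.PDB.StructureBuilder import StructureBuilder
    sb = StructureBuilder()
    sb.init_structure("s")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for (resname, resseq), atom_map in atoms.items():
        sb.init_residue(resname, " ", resseq, " ")
        for name, coord in atom_map.items():
            sb.set_line_counter(resseq)
            sb.init_atom(name, np.array(coord, dtype=float), 0.0, 1.0, " ",
                         name, element=name[0])
    return sb.get_structure()


def focal_residue(structure, resseq=1):
    return [r for r in structure.get_residues() if r.id[1] == resseq][0]


def base_focal():
    # CA at origin, CB along +x: the cone points along +x
    return {("ALA", 1): {"N": (0, 1, 0), "CA": (0, 0, 0), "C": (1, 1, 0),
                         "CB": (1, 0, 0)}}


def test_cone_counts_on_axis_and_out_of_range():
    atoms = dict(base_focal())
    atoms[("ALA", 2)] = {"CB": (6, 0, 0), "CA": (6, 1, 0)}    # 5 Å from CB, on axis
    atoms[("ALA", 3)] = {"CB": (11.5, 0, 0), "CA": (11.5, 1, 0)}  # 10.5 Å: too far
    atoms[("ALA", 4)] = {"CB": (-2, 0, 0), "CA": (-2, 1, 0)}  # behind the cone
    s = build_structure(atoms)
    focal = focal_residue(s)
    assert cone_contacts(s, focal, "sidechain_CB") == 1
    assert cone_contacts(s, focal, "burial_CA") == 1


def test_cone_isolated_residue_zero_and_missing_atoms():
    s = build_structure(base_focal())
    assert cone_contacts(s, focal_residue(s), "burial_CA") == 0
    broken = build_structure({("ALA", 1): {"CA": (0, 0, 0)}})
    with pytest.warns(UserWarning):
        assert np.isnan(cone_contacts(broken, focal_residue(broken), "burial_CA"))


def test_cone_mode_specific_atoms():
    atoms = dict(base_focal())
    atoms[("PHE", 2)] = {"CE2": (5, 0, 0)}
    atoms[("GLU", 3)] = {"OE1": (4, 0.5, 0)}
    atoms[("ASP", 4)] = {"OD1": (4, -0.5, 0)}
    atoms[("LYS", 5)] = {"NZ": (3, 0, 0.5)}
    atoms[("ARG", 6)] = {"NE": (3, 0, -0.5)}
    atoms[("LEU", 7)] = {"CE2": (5, 1, 0)}  # CE2 only counts for F/Y/W
    s = build_structure(atoms)
    focal = focal_residue(s)
    assert cone_contacts(s, focal, "aromatic_CE2") == 1
    assert cone_contacts(s, focal, "acidic_OE1_OD1") == 2
    assert cone_contacts(s, focal, "basic_NZ_NE") == 2
    with pytest.raises(ValueError):
        cone_contacts(s, focal, "nope")


def test_cone_rigid_motion_invariance():
    rng = np.random.default_rng(18)
    atoms = dict(base_focal())
    for i in range(2, 12):
        atoms[("ALA", i)] = {"CB": tuple(rng.normal(0, 5, 3)),
                             "CA": tuple(rng.normal(0, 5, 3))}
    s1 = build_structure(atoms)
    c1 = cone_contacts(s1, focal_residue(s1), "sidechain_CB")
    # random rotation + translation
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(0, 10, 3)
    rotated = {key: {n: tuple(q @ np.array(c) + t) for n, c in am.items()}
               for key, am in atoms.items()}
    s2 = build_structure(rotated)
    assert cone_contacts(s2, focal_residue(s2), "sidechain_CB") == c1


def test_glycine_virtual_cbeta_geometry():
    atoms = {("GLY", 1): {"N": (0, 1.46, 0), "CA": (0.0, 0.0, 0.0),
                          "C": (1.42, -0.55, 0)}}
    s = build_structure(atoms)
    res = focal_residue(s)
    cb = virtual_cbeta(res)
    # ideal Cβ sits ~1.5 Å from Cα, off the backbone plane
    assert np.linalg.norm(cb) == pytest.approx(1.53, abs=0.15)
    assert abs(cb[2]) > 0.5
    atoms[("ALA", 2)] = {"CB": tuple(cb + 3.0 * cb / np.linalg.norm(cb)),
                         "CA": (5, 5, 5)}
    s2 = build_structure(atoms)
    assert cone_contacts(s2, focal_residue(s2), "sidechain_CB") == 1
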