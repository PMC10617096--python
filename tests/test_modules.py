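"""Spearman correlation, k-means modules, the hypergeometric test and the
module-to-module map."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom as scipy_hypergeom
from scipy.stats import pearsonr, rankdata

from cropmap.effects import EffectMatrix, RegulationPair
from cropmap.modules import (
    ModuleAssignment,
    ModuleEdge,
    build_module_map,
    correlate_spearman,
    export_edges,
    hypergeom_pvalue,
    kmeans_modules,
    read_edges,
)


def _em(mat, targets=None, features=None):
    mat = np.asarray(mat, dtype=float)
    targets = targets or [f"T{i}" for i in range(mat.shape[0])]
    features = features or [f"R{i}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=targets, columns=features)
    return EffectMatrix(effect=df, pvalue=pd.DataFrame(0.5, index=targets, columns=features))


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def test_duplicated_row_correlates_perfectly():
    e = _em([[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 2, 2]])
    c = correlate_spearman(e, axis="targets")
    assert c.iloc[0, 1] == pytest.approx(1.0)


def test_negated_row_correlates_minus_one():
    e = _em([[1, 2, 3, 4], [-1, -2, -3, -4], [4, 1, 2, 2]])
    c = correlate_spearman(e, axis="targets")
    assert c.iloc[0, 1] == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson():
    rng = np.random.default_rng(4)
    e = _em(rng.random((5, 8)))
    c = correlate_spearman(e, axis="targets")
    X = e.effect.to_numpy()
    for i in range(5):
        for j in range(5):
            expected = pearsonr(rankdata(X[i]), rankdata(X[j])).statistic
            assert c.iloc[i, j] == pytest.approx(expected, abs=1e-12)


def test_constant_profile_gets_zero_with_warning():
    e = _em([[1, 1, 1, 1], [1, 2, 3, 4], [4, 1, 2, 2]])
    with pytest.warns(UserWarning, match="constant"):
        c = correlate_spearman(e, axis="targets")
    assert c.iloc[0, 1] == 0.0
    assert c.iloc[0, 0] == 1.0  # diagonal stays 1


def test_correlation_symmetric_unit_diagonal():
    rng = np.random.default_rng(8)
    e = _em(rng.random((6, 5)))
    c = correlate_spearman(e, axis="features")
    assert np.allclose(c.to_numpy(), c.to_numpy().T)
    assert np.allclose(np.diag(c.to_numpy()), 1.0)


# ---------------------------------------------------------------------------
# k-means modules
# ---------------------------------------------------------------------------


def _block_correlation(n_a, n_b, within=0.9, between=-0.5):
    n = n_a + n_b
    c = np.full((n, n), between)
    c[:n_a, :n_a] = within
    c[n_a:, n_a:] = within
    np.fill_diagonal(c, 1.0)
    labels = [f"L{i}" for i in range(n)]
    return pd.DataFrame(c, index=labels, columns=labels)


def test_kmeans_separable_blocks_partition_perfectly():
    c = _block_correlation(4, 5)
    ma = kmeans_modules(c, k=2, seed=0)
    mods = [ma.assignment[f"L{i}"] for i in range(9)]
    assert len(set(mods[:4])) == 1 and len(set(mods[4:])) == 1
    assert mods[0] != mods[4]


def test_kmeans_k_equals_labels_gives_singletons():
    c = _block_correlation(3, 3)
    ma = kmeans_modules(c, k=6, seed=0)
    assert sorted(ma.assignment.values()) == [1, 2, 3, 4, 5, 6]
    assert ma.inertia == pytest.approx(0.0)


def test_kmeans_deterministic_under_seed():
    rng = np.random.default_rng(3)
    X = rng.random((10, 10))
    c = pd.DataFrame((X + X.T) / 2, index=[f"L{i}" for i in range(10)], columns=[f"L{i}" for i in range(10)])
    a = kmeans_modules(c, k=3, seed=7)
    b = kmeans_modules(c, k=3, seed=7)
    assert a.assignment == b.assignment


def test_kmeans_recovers_planted_programs_across_seeds():
    from sklearn.metrics import adjusted_rand_score

    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        c = _block_correlation(5, 6)
        noise = rng.normal(0, 0.05, c.shape)
        cn = pd.DataFrame(
            np.clip((noise + noise.T) / 2 + c.to_numpy(), -1, 1),
            index=c.index, columns=c.columns,
        )
        ma = kmeans_modules(cn, k=2, seed=seed)
        got = [ma.assignment[l] for l in c.index]
        truth = [0] * 5 + [1] * 6
        hits += adjusted_rand_score(truth, got) >= 0.9
    assert hits >= 18


def test_kmeans_rejects_bad_k():
    c = _block_correlation(2, 2)
    with pytest.raises(ValueError):
        kmeans_modules(c, k=1, seed=0)
    with pytest.raises(ValueError):
        kmeans_modules(c, k=5, seed=0)


# ---------------------------------------------------------------------------
# Hypergeometric test
# ---------------------------------------------------------------------------


def brute_force_hypergeom(N, K_P, K_R, k, tail):
    """Exhaustive enumeration over all C(N, K_R) draws."""
    pop = range(N)
    from_pi = set(range(K_P))
    count_eq = count_ge = total = 0
    for draw in itertools.combinations(pop, K_R):
        x = len(from_pi.intersection(draw))
        total += 1
        count_eq += x == k
        count_ge += x >= k
    return (count_eq if tail == "pmf" else count_ge) / total


def test_forced_draw_pmf_is_one():
    assert hypergeom_pvalue(10, 10, 4, 4, tail="pmf") == pytest.approx(1.0)


def test_empty_module_pmf_at_zero_is_one():
    assert hypergeom_pvalue(10, 0, 4, 0, tail="pmf") == pytest.approx(1.0)


def test_hypergeom_matches_exhaustive_enumeration():
    cases = [(20, 8, 5, 4), (12, 5, 6, 2), (15, 7, 4, 0), (10, 3, 7, 3)]
    for N, K_P, K_R, k in cases:
        for tail in ("pmf", "upper"):
            got = hypergeom_pvalue(N, K_P, K_R, k, tail=tail)
            expected = brute_force_hypergeom(N, K_P, K_R, k, tail)
            assert got == pytest.approx(expected, rel=1e-12)


def test_hypergeom_matches_scipy_cross_check():
    rng = np.random.default_rng(0)
    for _ in range(100):
        N = int(rng.integers(2, 2000))
        K_P = int(rng.integers(0, N + 1))
        K_R = int(rng.integers(0, N + 1))
        lo, hi = max(0, K_P + K_R - N), min(K_P, K_R)
        k = int(rng.integers(lo, hi + 1))
        assert hypergeom_pvalue(N, K_P, K_R, k, "pmf") == pytest.approx(
            scipy_hypergeom.pmf(k, N, K_P, K_R), rel=1e-9, abs=1e-300
        )
        assert hypergeom_pvalue(N, K_P, K_R, k, "upper") == pytest.approx(
            scipy_hypergeom.sf(k - 1, N, K_P, K_R), rel=1e-9, abs=1e-300
        )


def test_pmf_sums_to_one_over_support():
    rng = np.random.default_rng(1)
    for _ in range(100):
        N = int(rng.integers(1, 60))
        K_P = int(rng.integers(0, N + 1))
        K_R = int(rng.integers(0, N + 1))
        lo, hi = max(0, K_P + K_R - N), min(K_P, K_R)
        s = sum(hypergeom_pvalue(N, K_P, K_R, k, "pmf") for k in range(lo, hi + 1))
        assert s == pytest.approx(1.0, rel=1e-10)


def test_hypergeom_rejects_invalid_input():
    with pytest.raises(ValueError):
        hypergeom_pvalue(10, 11, 4, 2)
    with pytest.raises(ValueError):
        hypergeom_pvalue(10, 4, 4, 5)


# ---------------------------------------------------------------------------
# Module map
# ---------------------------------------------------------------------------


def _pair(t, f, sign, eff, p=0.01):
    return RegulationPair(t, f, sign, eff, p)


def test_concentrated_regulations_yield_single_edge():
    # P1's activating regulations all land in R-module 1 while P2's land in
    # R-module 2, so the (P1, R1) cell is maximally enriched
    pm = ModuleAssignment({"T1": 1, "T2": 1, "T3": 2}, k=2, seed=0, inertia=0.0)
    rm = ModuleAssignment({"R1": 1, "R2": 1, "R3": 2, "R4": 2}, k=2, seed=0, inertia=0.0)
    pairs = [
        _pair("T1", "R1", "activating", 0.5),
        _pair("T1", "R2", "activating", 0.4),
        _pair("T2", "R1", "activating", 0.3),
        _pair("T2", "R2", "activating", 0.2),
        _pair("T3", "R3", "activating", 0.3),
        _pair("T3", "R4", "activating", 0.3),
        _pair("T3", "R3", "repressive", -0.5),
    ]
    edges = build_module_map(pairs, pm, rm, alpha=0.25, tail="pmf")
    act = [e for e in edges if e.sign_class == "activating"]
    assert any(e.from_module == 1 and e.to_module == 1 for e in act)
    # p for the (P1,R1) cell equals the enumeration oracle: N=6, K_P=4, K_R=4, k=4
    e11 = next(e for e in act if e.from_module == 1 and e.to_module == 1)
    assert e11.pvalue == pytest.approx(brute_force_hypergeom(6, 4, 4, 4, "pmf"), rel=1e-12)


def test_empty_pair_list_gives_empty_map():
    pm = ModuleAssignment({"T1": 1}, k=2, seed=0, inertia=0.0)
    rm = ModuleAssignment({"R1": 1}, k=2, seed=0, inertia=0.0)
    assert build_module_map([], pm, rm) == []


def test_unknown_target_rejected():
    pm = ModuleAssignment({"T1": 1, "T2": 2}, k=2, seed=0, inertia=0.0)
    rm = ModuleAssignment({"R1": 1, "R2": 2}, k=2, seed=0, inertia=0.0)
    with pytest.raises(ValueError, match="missing"):
        build_module_map([_pair("TX", "R1", "activating", 0.1)], pm, rm)


def test_bh_adjustment_monotone_in_raw_pvalues():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    raw = np.sort(rng.random(30))
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    assert (np.diff(adj) >= -1e-12).all()
    assert adj.min() >= raw.min()


def test_null_module_map_controls_false_edges():
    """Random pairs + random modules: BH at 0.05 leaves essentially no edges."""
    total_edges = 0
    n_seeds = 50
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        targets = [f"T{i}" for i in range(12)]
        features = [f"R{i}" for i in range(15)]
        pairs = []
        for i in range(200):
            sign = "activating" if rng.random() < 0.5 else "repressive"
            eff = 0.1 if sign == "activating" else -0.1
            pairs.append(_pair(str(rng.choice(targets)), str(rng.choice(features)), sign, eff))
        pm = ModuleAssignment({t: int(x) for t, x in zip(targets, rng.integers(1, 5, 12))}, k=4, seed=0, inertia=0.0)
        rm = ModuleAssignment({f: int(x) for f, x in zip(features, rng.integers(1, 6, 15))}, k=5, seed=0, inertia=0.0)
        total_edges += len(build_module_map(pairs, pm, rm, alpha=0.05))
    # under the global null BH gives weak FWER control at alpha per seed
    expected = 0.05 * n_seeds
    bound = expected + 2 * np.sqrt(n_seeds * 0.05 * 0.95)
    assert total_edges <= bound


def test_planted_map_recovered_across_seeds(small_screen):
    """An activating perturbation->regulon module is found, without a
    repressive counterpart, for most seeds of the clustering."""
    pm = ModuleAssignment(
        {"T1": 1, "T2": 1, "T3": 1, "T4": 2, "T5": 2}, k=2, seed=0, inertia=0.0
    )
    rm = ModuleAssignment(
        {"R1": 1, "R2": 1, "R3": 1, "R4": 2, "R5": 2}, k=2, seed=0, inertia=0.0
    )
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        # planted program: every module-1 target activates every module-1 regulon
        pairs = [
            _pair(t, f, "activating", 0.5)
            for t in ("T1", "T2", "T3") for f in ("R1", "R2", "R3")
        ]
        # background activating and repressive pairs confined to module 2
        for _ in range(4):
            t = str(rng.choice(["T4", "T5"]))
            f = str(rng.choice(["R4", "R5"]))
            pairs.append(_pair(t, f, "activating", 0.2))
        for _ in range(3):
            t = str(rng.choice(["T4", "T5"]))
            f = str(rng.choice(["R4", "R5"]))
            pairs.append(_pair(t, f, "repressive", -0.2))
        pairs = list(dict.fromkeys(pairs))  # unique (target, feature, sign)
        edges = build_module_map(pairs, pm, rm, alpha=0.05)
        act = [e for e in edges if e.sign_class == "activating" and e.from_module == 1 and e.to_module == 1]
        rep = [e for e in edges if e.sign_class == "repressive" and e.from_module == 1 and e.to_module == 1]
        hits += bool(act) and not rep
    assert hits >= 18


# ---------------------------------------------------------------------------
# Edge export
# ---------------------------------------------------------------------------


def test_export_single_edge_single_row(tmp_path):
    e = ModuleEdge(1, 2, "activating", 0.001, 0.01)
    export_edges([e], tmp_path / "edges.tsv")
    df = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert len(df) == 1
    assert df.loc[0, "weight"] == pytest.approx(2.0)


def test_export_round_trip(tmp_path):
    edges = [
        ModuleEdge(1, 2, "activating", 0.001, 0.004),
        ModuleEdge(2, 1, "repressive", 0.002, 0.008),
    ]
    export_edges(edges, tmp_path / "edges.tsv")
    back = read_edges(tmp_path / "edges.tsv")
    assert back == sorted(edges, key=lambda e: (e.from_module, e.to_module, e.sign_class))


def test_export_sif_uses_sign_as_interaction(tmp_path):
    export_edges([ModuleEdge(1, 2, "repressive", 0.01, 0.02)], tmp_path / "e.sif", format="sif")
    assert (tmp_path / "e.sif").read_text() == "P1\trepressive\tR2\n"


def test_export_sorted_deterministically(tmp_path):
    rng = np.random.default_rng(0)
    edges = [
        ModuleEdge(int(rng.integers(1, 5)), int(rng.integers(1, 6)),
                   "activating" if rng.random() < 0.5 else "repressive",
                   float(rng.random() * 0.04), float(rng.random() * 0.04))
        for _ in range(100)
    ]
    export_edges(edges, tmp_path / "a.tsv")
    export_edges(list(reversed(edges)), tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
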