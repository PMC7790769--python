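"""Adjacency/TOM algebra, module detection, eigengenes, merging, traits."""

import numpy as np
import pandas as pd
import pytest

from circleaf import coexpr, express


def _samples(stages=("FL1", "FL2", "FL3", "FL4", "FL5"), reps=3):
    return [f"{st}-{r}" for st in stages for r in range(1, reps + 1)]


def _design(stages=("FL1", "FL2", "FL3", "FL4", "FL5"), reps=3):
    return express.make_design(
        {f"{st}-{r}": (st, r) for st in stages for r in range(1, reps + 1)}
    )


def test_combine_and_filter_drops_flat_and_zero_features():
    cols = _samples()
    varying = np.repeat([40.0, 20.0, 10.0, 5.0, 2.0], 3)  # CV ~ 0.9
    circ = pd.DataFrame({"varying": varying, "zero": np.zeros(15)}, index=cols).T
    mrna = pd.DataFrame({"constant": np.full(15, 5.0)}, index=cols).T
    out = coexpr.combine_and_filter(circ, mrna)
    assert list(out.index) == ["circ::varying"]  # constant (CV 0) and zero drop
    with pytest.raises(ValueError):
        coexpr.combine_and_filter(circ, mrna[cols[:10]])


def test_adjacency_powers_absolute_correlation():
    cols = _samples()
    x = np.arange(15, dtype=float)
    m = pd.DataFrame({"a": x, "b": -x + 100, "c": x * 2}, index=cols).T
    adj = coexpr.adjacency_matrix(m)
    assert np.allclose(np.diag(adj), 1.0)
    assert adj[0, 1] == pytest.approx(1.0)  # |-1|^5
    assert np.allclose(adj, adj.T)
    assert abs(abs(-0.5) ** 5 - 0.03125) < 1e-12  # the soft-threshold rule


def test_tom_two_node_and_identity():
    a = np.array([[1.0, 1.0], [1.0, 1.0]])
    tom = coexpr.topological_overlap(a)
    assert tom[0, 1] == pytest.approx(1.0)
    eye = coexpr.topological_overlap(np.eye(3))
    assert np.allclose(eye, np.eye(3))


def test_tom_matches_brute_force_triple_sum():
    rng = np.random.default_rng(1)
    n = 8
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    tom = coexpr.topological_overlap(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            expected = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
            assert tom[i, j] == pytest.approx(expected)
    assert ((tom >= 0) & (tom <= 1)).all()


def _latent_blocks(sizes, seed=0, noise=0.15):
    """Blocks around mutually uncorrelated latent profiles (between-block
    correlation ~ 0, within-block ~ 0.95)."""
    rng = np.random.default_rng(seed)
    latents = []
    for _ in sizes:
        v = rng.normal(0, 1, 15)
        for u in latents:  # orthogonalize against earlier latents
            v -= np.dot(v, u) / np.dot(u, u) * u
        latents.append(v / v.std())
    rows, ids = [], []
    for b, size in enumerate(sizes):
        for i in range(size):
            rows.append(latents[b] + rng.normal(0, noise, 15))
            ids.append(f"b{b}_f{i}")
    return pd.DataFrame(rows, index=ids, columns=_samples())


def _profile_blocks(sizes, seed=0, base_rate=40.0):
    """Poisson abundance blocks following stage profiles, as the planted
    synthetic study conditions produce them."""
    from circleaf.simdata import profile_multipliers

    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for b, (profile, size) in enumerate(sizes):
        lam = base_rate * np.repeat(profile_multipliers(profile, 5), 3)
        for i in range(size):
            rows.append(rng.poisson(lam).astype(float))
            ids.append(f"b{b}_{profile}_{i}")
    return pd.DataFrame(rows, index=ids, columns=_samples())


def test_two_planted_blocks_recovered():
    m = _latent_blocks([40, 40], seed=2)
    adj = coexpr.adjacency_matrix(m)
    tom = coexpr.topological_overlap(adj)
    modules = coexpr.detect_modules(tom, list(m.index))
    real = [mod for mod in modules if mod.label != coexpr.UNASSIGNED]
    assert len(real) == 2
    for mod in real:
        blocks = {x.split("_")[0] for x in mod.members}
        assert len(blocks) == 1  # module membership matches a planted block


def test_below_min_size_all_unassigned():
    m = _latent_blocks([10, 10], seed=3)
    tom = coexpr.topological_overlap(coexpr.adjacency_matrix(m))
    modules = coexpr.detect_modules(tom, list(m.index))
    assert len(modules) == 1 and modules[0].label == coexpr.UNASSIGNED


def test_partition_invariant_to_row_shuffling():
    m = _latent_blocks([35, 35], seed=4)
    perm = np.random.default_rng(5).permutation(len(m))
    shuffled = m.iloc[perm]
    mods_a = coexpr.detect_modules(
        coexpr.topological_overlap(coexpr.adjacency_matrix(m)), list(m.index)
    )
    mods_b = coexpr.detect_modules(
        coexpr.topological_overlap(coexpr.adjacency_matrix(shuffled)),
        list(shuffled.index),
    )
    parts_a = sorted(frozenset(mod.members) for mod in mods_a)
    parts_b = sorted(frozenset(mod.members) for mod in mods_b)
    assert parts_a == parts_b


def test_eigengene_identical_rows_and_sign():
    cols = _samples()
    profile = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3).repeat(1)
    profile = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 3)
    m = pd.DataFrame([profile, profile, profile], index=list("abc"), columns=cols)
    e = coexpr.module_eigengene(m)
    z = (profile - profile.mean()) / profile.std(ddof=1)
    assert np.allclose(np.abs(np.corrcoef(e, z)[0, 1]), 1.0)
    assert np.corrcoef(e, z)[0, 1] > 0  # oriented with the mean profile
    assert e.std(ddof=1) == pytest.approx(1.0)
    assert np.allclose(coexpr.module_eigengene(-m), -e)


def test_eigengene_matches_direct_eigendecomposition():
    m = _profile_blocks([("up", 3)], seed=6)
    e = coexpr.module_eigengene(m)
    z = ((m.T - m.mean(axis=1)) / m.std(axis=1, ddof=1)).T.to_numpy()
    cov = z @ z.T
    w, v = np.linalg.eigh(cov)
    lead = v[:, np.argmax(w)]
    recon = lead @ z  # first PC of the sample dimension
    assert abs(np.corrcoef(e, recon)[0, 1]) == pytest.approx(1.0)


def _designed_module_pair(target_cor, seed=7, size=10):
    """Two modules whose eigengenes correlate approximately target_cor."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, 1, 15)
    w = rng.normal(0, 1, 15)
    w -= np.dot(w, u) / np.dot(u, u) * u
    v = target_cor * u / u.std() + np.sqrt(1 - target_cor**2) * w / w.std()
    rows, ids = [], []
    for b, latent in enumerate((u, v)):
        for i in range(size):
            rows.append(latent / latent.std() + rng.normal(0, 0.02, 15))
            ids.append(f"m{b}_f{i}")
    m = pd.DataFrame(rows, index=ids, columns=_samples())
    modules = [
        coexpr.CoexModule("turquoise", ids[:size]),
        coexpr.CoexModule("blue", ids[size:]),
    ]
    return m, modules


def test_merge_close_modules_by_eigengene_similarity():
    # dissimilarity 1 - 0.9 = 0.1 < 0.217 -> merged
    m, modules = _designed_module_pair(0.9)
    merged = coexpr.merge_close_modules(modules, m)
    real = [mod for mod in merged if mod.label != coexpr.UNASSIGNED]
    assert len(real) == 1 and len(real[0].members) == 20
    # dissimilarity 1 - 0.5 = 0.5 > 0.217 -> kept apart
    m2, modules2 = _designed_module_pair(0.5)
    apart = coexpr.merge_close_modules(modules2, m2)
    assert len([mod for mod in apart if mod.label != coexpr.UNASSIGNED]) == 2
    single = coexpr.merge_close_modules(
        [coexpr.CoexModule("turquoise", list(m.index[:10]))], m
    )
    assert len([mod for mod in single if mod.label != coexpr.UNASSIGNED]) == 1


def test_trait_classification_of_indicator_and_monotone_eigengenes():
    design = _design()
    stages = ["FL1", "FL2", "FL3", "FL4", "FL5"]
    samples = _samples()
    ind = np.repeat([0.0, 0.0, 1.0, 0.0, 0.0], 3)
    mod = coexpr.CoexModule("blue", ["x"], eigengene=ind)
    coexpr.module_trait_correlation([mod], design, samples, stages)
    assert mod.classification == "turn-point"
    assert mod.stage_correlations["FL3"][0] == pytest.approx(1.0)
    up = coexpr.CoexModule("brown", ["y"], eigengene=np.repeat(np.arange(5.0), 3))
    coexpr.module_trait_correlation([up], design, samples, stages)
    assert up.classification == "continuous-up"
    down = coexpr.CoexModule("t", ["z"], eigengene=-np.repeat(np.arange(5.0), 3))
    coexpr.module_trait_correlation([down], design, samples, stages)
    assert down.classification == "continuous-down"


def test_full_wgcna_recovers_three_profile_blocks():
    m = _profile_blocks([("down", 40), ("up", 40), ("turnpoint", 40)], seed=8)
    design = _design()
    mods = coexpr.run_wgcna(m, design, ["FL1", "FL2", "FL3", "FL4", "FL5"])
    real = [mod for mod in mods if mod.label != coexpr.UNASSIGNED]
    assert len(real) >= 3
    label_map = {"down": "continuous-down", "up": "continuous-up",
                 "turnpoint": "turn-point"}
    matched = 0
    for mod in real:
        profiles = [x.split("_")[1] for x in mod.members]
        majority = max(set(profiles), key=profiles.count)
        if profiles.count(majority) / len(profiles) > 0.9:
            assert mod.classification == label_map[majority]
            matched += 1
    assert matched >= 3
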