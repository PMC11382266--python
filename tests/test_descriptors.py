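import numpy as np
import pandas as pd
import pytest

from surfclass import build_feature_table, descriptor_vector, group_report, prune_correlated
from surfclass.descriptors import (
    DEFAULT_REGISTRY,
    RESIDUE_CLASSES,
    DuplicateRowError,
    NoComparisonError,
    feature_columns,
)
from surfclass.secondary_structure import UndefinedCompositionError, assign_ss
from surfclass.surface_sasa import surface_profile
from surfclass.synthetic_data import AA_THREE, StructureSpec, make_structure


def _vector_from_codes(codes, flags, labels):
    """Build a minimal structure + profile + labels triple by hand."""
    from surfclass.structure_io import THREE_TO_ONE
    from surfclass.surface_sasa import ResidueSasa, SurfaceProfile

    one = "".join(THREE_TO_ONE[c] for c in codes)
    s = make_structure(StructureSpec(one, "extended", 0.0, 0))
    prof = SurfaceProfile(protein_id=s.protein_id)
    for i, (code, flag) in enumerate(zip(codes, flags)):
        prof.residues.append(
            ResidueSasa("A", i, code, 50.0, 100.0, 0.5 if flag else 0.1, flag)
        )
    ss = {("A", i): lab for i, lab in enumerate(labels)}
    return descriptor_vector(s, prof, ss)


def test_surface_composition_arithmetic():
    codes = ["GLU", "GLU", "CYS", "LEU"]
    v = _vector_from_codes(codes, [True] * 4, "CCCC")
    assert v["surf_GLU_pct"] == pytest.approx(50.0)
    assert v["surf_CYS_pct"] == pytest.approx(25.0)
    assert v["surf_LEU_pct"] == pytest.approx(25.0)
    others = [f"surf_{aa}_pct" for aa in AA_THREE if aa not in codes]
    assert all(v[c] == 0.0 for c in others)


def test_positive_surface_is_fully_hydrophilic():
    v = _vector_from_codes(["ARG", "HIS", "LYS"], [True] * 3, "CCC")
    assert v["surf_positive_pct"] == pytest.approx(100.0)
    assert v["surf_hydrophilic_pct"] == pytest.approx(100.0)
    assert v["surf_hydrophobic_pct"] == 0.0


def test_glycine_is_unclassified():
    v = _vector_from_codes(["GLY", "GLY", "GLY"], [True] * 3, "CCC")
    assert v["surf_GLY_pct"] == pytest.approx(100.0)
    for cls in ("positive", "negative", "polar_uncharged", "hydrophobic", "hydrophilic"):
        assert v[f"surf_{cls}_pct"] == 0.0


def test_surface_only_vs_overall_quantities():
    codes = ["GLU", "LEU", "LEU", "LEU"]
    v = _vector_from_codes(codes, [True, False, False, False], "HHHH")
    assert v["surf_GLU_pct"] == pytest.approx(100.0)  # only Glu on surface
    assert v["surface_ratio_pct"] == pytest.approx(25.0)
    assert v["overall_helix_pct"] == pytest.approx(100.0)
    assert v["surf_helix_pct"] == pytest.approx(100.0)


def test_no_surface_residues_is_undefined():
    with pytest.raises(UndefinedCompositionError):
        _vector_from_codes(["ALA", "ALA"], [False, False], "CC")


def test_residue_classes_partition_their_union():
    four = ["positive", "negative", "polar_uncharged", "hydrophobic"]
    union = set().union(*(RESIDUE_CLASSES[c] for c in four))
    assert sum(len(RESIDUE_CLASSES[c]) for c in four) == len(union)
    assert {"GLY", "PRO", "CYS"}.isdisjoint(union)
    assert RESIDUE_CLASSES["hydrophilic"] == (
        RESIDUE_CLASSES["positive"]
        | RESIDUE_CLASSES["negative"]
        | RESIDUE_CLASSES["polar_uncharged"]
    )


def test_feature_table_contract(mixed_structures):
    t = build_feature_table(mixed_structures)
    assert t.shape == (len(mixed_structures), len(DEFAULT_REGISTRY) + 1)
    assert not t.drop(columns="class").isna().any().any()
    aa_cols = [f"surf_{aa}_pct" for aa in AA_THREE]
    assert np.allclose(t[aa_cols].sum(axis=1), 100.0, atol=1e-6)
    assert np.allclose(
        t["surf_hydrophilic_pct"],
        t["surf_positive_pct"] + t["surf_negative_pct"] + t["surf_polar_uncharged_pct"],
    )


def test_feature_table_determinism_identical_structures():
    a = make_structure(StructureSpec("ACDEF", "helix", 0.0, 0))
    b = make_structure(StructureSpec("ACDEF", "helix", 0.0, 0))
    b.protein_id = "copy"
    t = build_feature_table([(a, "cytosol"), (b, "secreted")])
    assert np.allclose(t.drop(columns="class").iloc[0], t.drop(columns="class").iloc[1])


def test_duplicate_protein_id_rejected():
    a = make_structure(StructureSpec("ACDEF", "helix", 0.0, 0))
    b = make_structure(StructureSpec("ACDEF", "helix", 0.0, 0))
    with pytest.raises(DuplicateRowError):
        build_feature_table([(a, "cytosol"), (b, "secreted")])


# --- correlation pruning -------------------------------------------------


def _corr_table(seed=0, n=60):
    rng = np.random.default_rng(seed)
    f1 = rng.normal(size=n)
    t = pd.DataFrame(
        {
            "f1": f1,
            "f2": 2.0 * f1,
            "f3": rng.normal(size=n),
        }
    )
    t["class"] = rng.choice(["a", "b"], n)
    return t


def test_duplicated_feature_pruned_by_cumulative_r():
    t = _corr_table()
    pruned, removed = prune_correlated(t, 0.85)
    # brute-force cumulative |r| over the original features
    corr = t[["f1", "f2", "f3"]].corr().abs()
    np.fill_diagonal(corr.values, 0)
    cum = corr.sum()
    expected_victim = "f1" if cum["f1"] > cum["f2"] else "f2"
    if cum["f1"] == cum["f2"]:
        expected_victim = "f2"
    assert removed == [expected_victim]
    assert "f3" in pruned.columns
    assert "class" in pruned.columns


def test_uncorrelated_table_unchanged():
    rng = np.random.default_rng(5)
    t = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    t["class"] = "x"
    pruned, removed = prune_correlated(t, 0.85)
    assert removed == []
    assert list(pruned.columns) == list(t.columns)


def test_exactly_085_pair_is_kept():
    # construct two features with Pearson r exactly 0.85
    rng = np.random.default_rng(1)
    n = 200
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z -= z.mean()
    z -= x * (x @ z) / (x @ x)  # orthogonalize
    z /= z.std()
    r = 0.85
    y = r * x + np.sqrt(1 - r * r) * z
    t = pd.DataFrame({"x": x, "y": y})
    t["class"] = "c"
    assert abs(t[["x", "y"]].corr().iloc[0, 1]) == pytest.approx(0.85, abs=1e-12)
    pruned, removed = prune_correlated(t, 0.85)
    assert removed == []


def test_constant_column_removed_with_warning():
    t = _corr_table()
    t["flat"] = 3.14
    with pytest.warns(UserWarning, match="zero-variance"):
        pruned, removed = prune_correlated(t, 0.85)
    assert "flat" in removed
    assert "flat" not in pruned.columns


def test_pruning_is_idempotent_and_survivors_uncorrelated():
    rng = np.random.default_rng(9)
    base = rng.normal(size=(80, 3))
    mix = rng.normal(size=(3, 8))
    t = pd.DataFrame(base @ mix + 0.05 * rng.normal(size=(80, 8)),
                     columns=[f"g{i}" for i in range(8)])
    t["class"] = "c"
    pruned, removed = prune_correlated(t, 0.85)
    feats = feature_columns(pruned)
    corr = pruned[feats].corr().abs()
    np.fill_diagonal(corr.values, 0)
    assert corr.max().max() <= 0.85 + 1e-12
    again, removed2 = prune_correlated(pruned, 0.85)
    assert removed2 == []
    assert list(again.columns) == list(pruned.columns)


# --- group reports -------------------------------------------------------


def test_null_distribution_rarely_significant():
    rng = np.random.default_rng(42)
    hits = 0
    for _ in range(100):
        t = pd.DataFrame(
            {
                "d": rng.normal(size=60),
                "class": ["a"] * 30 + ["b"] * 30,
            }
        )
        p = group_report(t, "d").p_values[("a", "b")]
        hits += p <= 0.05
    assert hits <= 10  # expect p > 0.05 in >= 90% of null repeats


def test_strong_shift_is_extremely_significant():
    rng = np.random.default_rng(0)
    t = pd.DataFrame(
        {
            "d": np.concatenate([rng.normal(0, 1, 100), rng.normal(5, 1, 100)]),
            "class": ["a"] * 100 + ["b"] * 100,
        }
    )
    assert group_report(t, "d").p_values[("a", "b")] < 1e-10


def test_constant_descriptor_degenerate_p_one():
    t = pd.DataFrame({"d": [1.0] * 20, "class": ["a"] * 10 + ["b"] * 10})
    with pytest.warns(UserWarning, match="degenerate"):
        rep = group_report(t, "d")
    assert rep.p_values[("a", "b")] == 1.0


def test_single_class_is_no_comparison():
    t = pd.DataFrame({"d": np.arange(10.0), "class": ["a"] * 10})
    with pytest.raises(NoComparisonError):
        group_report(t, "d")


def test_histograms_share_binning():
    rng = np.random.default_rng(2)
    t = pd.DataFrame({"d": rng.normal(size=40), "class": ["a"] * 20 + ["b"] * 20})
    rep = group_report(t, "d", n_bins=10)
    assert len(rep.bins) == 11
    assert all(c.sum() == 20 for c in rep.counts.values())
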