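import numpy as np
import pytest

from mzpanel.annotation import (
    PROTON_MASS,
    annotate_table,
    expected_mz,
    intersect_common,
    match_features,
)
from mzpanel.io import FeatureRecord, FeatureTable, SampleRecord, feature_id_for
from mzpanel.library import CompoundLibrary, CompoundRecord
from mzpanel.selection import PanelDefinition

PANEL_MZ = {
    "FA 2-OH C16:0": (271.2266, "NEG"),
    "FA C18:0": (283.2629, "NEG"),
    "TUDCA": (498.2936, "NEG"),
    "PE ae C36:4": (722.5130, "NEG"),
    "PE aa C38:6": (762.5081, "NEG"),
    "LysoPC a C20:4": (544.3411, "POS"),
}


class TestExpectedMz:
    def test_deprotonated(self):
        assert expected_mz(272.235, "NEG") == pytest.approx(271.227724, abs=1e-6)

    def test_protonated(self):
        assert expected_mz(543.3325, "POS") == pytest.approx(544.339776, abs=1e-6)

    def test_proton_self_cancellation(self):
        assert expected_mz(PROTON_MASS + 1e-12, "NEG") == pytest.approx(0.0, abs=1e-9)

    def test_too_small_for_neg(self):
        with pytest.raises(ValueError):
            expected_mz(0.5, "NEG")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            expected_mz(100.0, "NEUTRAL")


class TestMatchFeatures:
    def test_confirmed_panel_all_match(self, panel_library):
        """All six published (m/z, mode) pairs match their masses within 0.01 Da."""
        feats = [
            FeatureRecord(feature_id_for(mz, mode), mz, mode)
            for mz, mode in PANEL_MZ.values()
        ]
        res = match_features(feats, panel_library, threshold=0.01)
        assert res.n_annotated == 6
        assert res.flagged == []
        assert {m.compound_name for m in res.primary} == set(PANEL_MZ)
        assert all(abs(m.mass_error) <= 0.0041 for m in res.primary)

    def test_out_of_threshold(self, panel_library):
        feats = [FeatureRecord("f", 271.25, "NEG")]
        res = match_features(feats, panel_library, threshold=0.01)
        assert res.n_annotated == 0

    def test_second_feature_flagged(self, panel_library):
        feats = [
            FeatureRecord("f1", 271.2277, "NEG"),
            FeatureRecord("f2", 271.2330, "NEG"),
        ]
        res = match_features(feats, panel_library, threshold=0.01)
        assert [m.feature_id for m in res.primary] == ["f1"]
        assert [m.feature_id for m in res.flagged] == ["f2"]
        assert res.flagged[0].rank == "secondary"

    def test_labels_use_mode_suffix(self, panel_library):
        feats = [FeatureRecord("f", 544.3411, "POS")]
        res = match_features(feats, panel_library, threshold=0.01)
        assert res.primary[0].label == "LysoPC a C20:4_P"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            match_features([FeatureRecord("f", 100.0, "NEG")], CompoundLibrary(records=[]), 0.01)

    def test_nonpositive_threshold_rejected(self, panel_library):
        with pytest.raises(ValueError):
            match_features([], panel_library, 0.0)


def _brute_force_assign(feats, comps, threshold):
    """Independent oracle: repeatedly pick the global min-|error| candidate."""
    cands = []
    for f in feats:
        for c in comps:
            err = f.mz - expected_mz(c.monoisotopic_mass, f.esi_mode)
            if abs(err) <= threshold:
                cands.append((abs(err), f.mz, c.name, f.feature_id, f.esi_mode))
    primary = []
    used_f, used_c = set(), set()
    while True:
        rest = [c for c in cands if c[3] not in used_f and (c[2], c[4]) not in used_c]
        if not rest:
            break
        best = min(rest)
        primary.append((best[3], best[2]))
        used_f.add(best[3])
        used_c.add((best[2], best[4]))
    return sorted(primary)


class TestGreedyProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        comps = [
            CompoundRecord(name=f"c{i}", monoisotopic_mass=float(m))
            for i, m in enumerate(rng.uniform(100, 130, 15))
        ]
        lib = CompoundLibrary(records=comps)
        feats = [
            FeatureRecord(f"f{i}", float(mz), "NEG")
            for i, mz in enumerate(rng.uniform(99, 130, 15))
        ]
        res = match_features(feats, lib, threshold=0.5)
        got = sorted((m.feature_id, m.compound_name) for m in res.primary)
        assert got == _brute_force_assign(feats, comps, 0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_exclusivity_and_threshold(self, seed):
        rng = np.random.default_rng(100 + seed)
        comps = [
            CompoundRecord(name=f"c{i}", monoisotopic_mass=float(m))
            for i, m in enumerate(rng.uniform(100, 110, 20))
        ]
        lib = CompoundLibrary(records=comps)
        feats = [
            FeatureRecord(f"f{i}", float(mz), "NEG")
            for i, mz in enumerate(rng.uniform(99, 109, 20))
        ]
        res = match_features(feats, lib, threshold=0.3)
        for m in res.primary + res.flagged:
            assert abs(m.mass_error) <= 0.3
        fids = [m.feature_id for m in res.primary]
        names = [(m.compound_name, m.esi_mode) for m in res.primary]
        assert len(fids) == len(set(fids))
        assert len(names) == len(set(names))

    @pytest.mark.parametrize("seed", range(4))
    def test_threshold_monotonicity(self, seed):
        """Candidate sets shrink with the threshold: every match found at a
        tight threshold is also in-threshold at a looser one."""
        rng = np.random.default_rng(200 + seed)
        comps = [
            CompoundRecord(name=f"c{i}", monoisotopic_mass=float(m))
            for i, m in enumerate(rng.uniform(100, 105, 10))
        ]
        lib = CompoundLibrary(records=comps)
        feats = [
            FeatureRecord(f"f{i}", float(mz), "NEG")
            for i, mz in enumerate(rng.uniform(99, 104, 10))
        ]

        def candset(res):
            return {(m.feature_id, m.compound_name) for m in res.primary + res.flagged}

        tight = candset(match_features(feats, lib, threshold=0.05))
        loose = candset(match_features(feats, lib, threshold=0.2))
        assert tight <= loose


def _table_with_library_features(library, n_noise, seed=0):
    rng = np.random.default_rng(seed)
    feats = []
    for c in library.matchable():
        mode = c.esi_mode or "NEG"
        mz = expected_mz(c.monoisotopic_mass, mode)
        feats.append(FeatureRecord(feature_id_for(mz, mode), mz, mode))
    targets = np.array([f.mz for f in feats])
    made = 0
    while made < n_noise:
        mz = float(rng.uniform(50, 1200))
        if np.min(np.abs(targets - mz)) < 0.05:
            continue
        feats.append(FeatureRecord(feature_id_for(mz, "NEG"), mz, "NEG"))
        made += 1
    samples = [SampleRecord(f"s{i}", "case" if i % 2 else "control") for i in range(4)]
    X = rng.uniform(1, 100, size=(4, len(feats)))
    return FeatureTable.from_records(samples, feats, X)


class TestAnnotateTable:
    def test_reduction_to_library_features(self, panel_library):
        """A 100-feature table with 6 library-derived features reduces to 6 columns."""
        table = _table_with_library_features(panel_library, n_noise=94)
        annotated, res = annotate_table(table, panel_library, threshold=0.01)
        assert annotated.n_features == 6
        assert res.n_input_features == 100
        assert set(annotated.features.index) == {
            "FA 2-OH C16:0_N", "FA C18:0_N", "TUDCA_N",
            "PE ae C36:4_N", "PE aa C38:6_N", "LysoPC a C20:4_P",
        }

    def test_abundances_preserved(self, panel_library):
        table = _table_with_library_features(panel_library, n_noise=10)
        annotated, res = annotate_table(table, panel_library, threshold=0.01)
        for m in res.primary:
            np.testing.assert_allclose(
                annotated.abundances[m.label], table.abundances[m.feature_id]
            )

    def test_no_matches_warns_and_empties(self, panel_library):
        samples = [SampleRecord("s1", "case"), SampleRecord("s2", "control")]
        feats = [FeatureRecord("f", 999.0, "NEG")]
        table = FeatureTable.from_records(samples, feats, np.ones((2, 1)))
        with pytest.warns(UserWarning, match="no features matched"):
            annotated, _ = annotate_table(table, panel_library, threshold=0.01)
        assert annotated.n_features == 0

    def test_idempotence(self, panel_library):
        table = _table_with_library_features(panel_library, n_noise=5)
        once, _ = annotate_table(table, panel_library, threshold=0.01)
        twice, _ = annotate_table(once, panel_library, threshold=0.01)
        assert twice.equals(once)


class TestIntersectCommon:
    def _annotated(self, labels):
        samples = [SampleRecord("s1", "case"), SampleRecord("s2", "control")]
        feats = [FeatureRecord(l, 100.0 + i, "NEG", l.rsplit("_", 1)[0]) for i, l in enumerate(labels)]
        return FeatureTable.from_records(samples, feats, np.ones((2, len(labels))))

    def test_ten_to_six_order_preserved(self):
        panel = PanelDefinition(labels=[f"m{i}_N" for i in range(10)], method="linear_svm")
        other = self._annotated(["m1_N", "m3_N", "m5_N", "m7_N", "m8_N", "m9_N"])
        with pytest.warns(UserWarning, match="dropped"):
            out = intersect_common(panel, other)
        assert out.labels == ["m1_N", "m3_N", "m5_N", "m7_N", "m8_N", "m9_N"]
        assert out.method == "linear_svm"

    def test_identity(self):
        panel = PanelDefinition(labels=["a_N", "b_N"], method="x", k=2)
        other = self._annotated(["b_N", "a_N"])
        assert intersect_common(panel, other).labels == ["a_N", "b_N"]

    def test_disjoint_warns_empty(self):
        panel = PanelDefinition(labels=["a_N"], method="x", k=1)
        other = self._annotated(["z_N"])
        with pytest.warns(UserWarning):
            out = intersect_common(panel, other)
        assert out.labels == []
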