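"""Cross-linking layer: filtering, peak acceptance, quantification, geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

from mlproteo.datamodel import StructureModel, ValidationError, XlThresholds
from mlproteo.xlink import (
    accept_peak,
    check_distance_restraint,
    filter_identifications,
    impute_minimum,
    normalize_to_reference,
    pca_scores,
    quantify_crosslink,
    replicate_pearson,
)


def _xls(rows):
    return pd.DataFrame(rows, columns=["xl_id", "pos_a", "pos_b", "ld_score",
                                       "peptide_len_a", "peptide_len_b",
                                       "library_rt"])


class TestIdentificationFilter:
    def test_strict_ld_and_length(self):
        df = _xls([
            ("boundary", 1, 5, 25.0, 9, 9, 30.0),   # ld not strictly above
            ("ok", 1, 5, 25.1, 5, 9, 30.0),
            ("short", 1, 5, 40.0, 4, 9, 30.0),
        ])
        kept = filter_identifications(df)
        assert list(kept["xl_id"]) == ["ok"]


def _run(light_areas, heavy_areas, apex_light=30.0, apex_heavy=30.0, snr=10.0):
    rows = []
    for i, a in enumerate(light_areas, start=1):
        rows.append(("xl", "WT", 1, "light", i, a, snr, apex_light))
    for i, a in enumerate(heavy_areas, start=1):
        rows.append(("xl", "WT", 1, "heavy", i, a, snr, apex_heavy))
    return pd.DataFrame(rows, columns=["xl_id", "condition", "replicate",
                                       "channel", "transition_index", "area",
                                       "snr", "apex_rt"])


class TestPeakAcceptance:
    def test_identical_patterns_at_library_rt_accepted(self):
        ok, reasons = accept_peak(_run([1, 2, 3, 4, 5, 6],
                                       [1, 2, 3, 4, 5, 6]), library_rt=30.0)
        assert ok and reasons == []

    def test_rt_beyond_two_minutes_rejected(self):
        ok, reasons = accept_peak(
            _run([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6],
                 apex_light=32.5, apex_heavy=32.5), library_rt=30.0)
        assert not ok and "rt_mismatch" in reasons

    def test_no_coelution_rejected(self):
        ok, reasons = accept_peak(
            _run([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6],
                 apex_light=29.8, apex_heavy=30.3), library_rt=30.0)
        assert not ok and "no_coelution" in reasons

    def test_anticorrelated_shape_rejected(self):
        light = [1, 2, 3, 4, 5, 6]
        heavy = light[::-1]
        # hand check: reversing a strictly increasing vector gives r = -1
        assert np.corrcoef(light, heavy)[0, 1] == pytest.approx(-1.0)
        ok, reasons = accept_peak(_run(light, heavy), library_rt=30.0)
        assert not ok and reasons == ["shape_mismatch"]

    def test_insufficient_transitions(self):
        ok, reasons = accept_peak(_run([1, 2], [1, 2]), library_rt=30.0)
        assert not ok and reasons == ["insufficient transitions"]

    def test_missing_channel_errors(self):
        run = _run([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValidationError):
            accept_peak(run[run["channel"] == "light"], library_rt=30.0)


class TestQuantification:
    def _areas(self, areas_snr):
        rows = []
        for i, (area, snr) in enumerate(areas_snr):
            channel = "light" if i < 6 else "heavy"
            rows.append(("xl", "WT", 1, channel, (i % 6) + 1, float(area),
                         float(snr), 30.0))
        return pd.DataFrame(rows, columns=["xl_id", "condition", "replicate",
                                           "channel", "transition_index",
                                           "area", "snr", "apex_rt"])

    def test_sum_of_twelve(self):
        m = self._areas([(a, 10) for a in range(1, 13)])
        assert quantify_crosslink(m) == 78.0

    def test_low_snr_transition_dropped(self):
        pairs = [(a, 10) for a in range(1, 12)] + [(12, 4)]
        assert quantify_crosslink(self._areas(pairs)) == 66.0

    def test_snr_boundary_inclusive(self):
        # "signal to noise ratio <5 were filtered out": snr exactly 5 stays
        assert quantify_crosslink(self._areas([(10, 5.0)] * 12)) == 120.0

    def test_all_low_snr_missing(self):
        assert np.isnan(quantify_crosslink(self._areas([(5, 1)] * 12)))

    def test_permutation_and_split_additivity(self):
        m = self._areas([(a, 10) for a in range(1, 13)])
        shuffled = m.sample(frac=1.0, random_state=1)
        assert quantify_crosslink(shuffled) == quantify_crosslink(m)
        # splitting one transition's area into two leaves the sum unchanged
        split = m.copy()
        split.loc[split.index[-1], "area"] = 6.0
        extra = split.iloc[[-1]].copy()
        extra["area"] = 6.0
        extra["transition_index"] = 5  # reuse another slot
        merged = pd.concat([split.iloc[:-1], split.iloc[[-1]], extra])
        assert quantify_crosslink(merged) == quantify_crosslink(m)


class TestNormalization:
    def _refs(self, v1, v2):
        return pd.DataFrame({
            "condition": ["WT", "WT"], "replicate": [1, 1],
            "intensity": [v1, v2],
        })

    def _abund(self, v):
        return pd.DataFrame({"xl_id": ["xl"], "condition": ["WT"],
                             "replicate": [1], "abundance": [v]})

    def test_mean_of_two_references(self):
        out = normalize_to_reference(self._abund(6.0), self._refs(2.0, 4.0))
        assert out["abundance"].iloc[0] == pytest.approx(2.0)

    def test_unit_references_identity(self):
        out = normalize_to_reference(self._abund(6.0), self._refs(1.0, 1.0))
        assert out["abundance"].iloc[0] == pytest.approx(6.0)

    def test_zero_reference_errors(self):
        with pytest.raises(ValidationError):
            normalize_to_reference(self._abund(6.0), self._refs(0.0, 4.0))

    def test_missing_run_errors(self):
        abund = pd.DataFrame({"xl_id": ["xl"], "condition": ["KR"],
                              "replicate": [2], "abundance": [6.0]})
        with pytest.raises(ValidationError, match="KR/2"):
            normalize_to_reference(abund, self._refs(2.0, 4.0))


class TestMinimumImputation:
    def test_identity_without_missing(self):
        m = pd.DataFrame([[4.0, 2.0], [8.0, 3.0]])
        pd.testing.assert_frame_equal(impute_minimum(m), m)

    def test_global_minimum_fills(self):
        m = pd.DataFrame([[4.0, np.nan], [8.0, 2.0]])
        assert impute_minimum(m).iloc[0, 1] == 2.0

    def test_all_missing_errors(self):
        with pytest.raises(ValidationError):
            impute_minimum(pd.DataFrame([[np.nan], [np.nan]]))


def _matrix(values, conditions):
    cols = pd.MultiIndex.from_tuples(conditions,
                                     names=["condition", "replicate"])
    return pd.DataFrame(values, columns=cols,
                        index=[f"XL{i}" for i in range(len(values))])


class TestReplicatePearson:
    def test_duplicated_replicate_r_one(self):
        m = _matrix([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]],
                    [("WT", 1), ("WT", 2)])
        corr, avg = replicate_pearson(m)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert avg["WT"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.random(6)
        m = _matrix(np.column_stack([v, 3 * v + 2]), [("WT", 1), ("WT", 2)])
        _, avg = replicate_pearson(m)
        assert avg["WT"] == pytest.approx(1.0)

    def test_hand_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 9.0])
        hand = (((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum()
                          * ((y - y.mean()) ** 2).sum()))
        m = _matrix(np.column_stack([x, y]), [("WT", 1), ("WT", 2)])
        corr, _ = replicate_pearson(m)
        assert corr.iloc[0, 1] == pytest.approx(hand, abs=1e-12)


class TestPca:
    def test_identical_samples_equal_scores(self):
        m = _matrix(2.0 ** np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]),
                    [("WT", 1), ("WT", 2)])
        scores, _ = pca_scores(m)
        assert scores["PC1"].iloc[0] == pytest.approx(scores["PC1"].iloc[1])

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(3)
        m = _matrix(2.0 ** rng.normal(15, 2, size=(10, 6)),
                    [("WT", 1), ("WT", 2), ("WT", 3),
                     ("KR", 1), ("KR", 2), ("KR", 3)])
        _, evr = pca_scores(m)
        assert evr.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        m = _matrix(2.0 ** rng.normal(15, 1, size=(3, 3)),
                    [("WT", 1), ("WT", 2), ("KR", 1)])
        scores, evr = pca_scores(m)
        x = np.log2(m.to_numpy()).T
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        oracle_scores = xc @ v
        for k in range(2):  # rank is n_samples - 1
            assert evr[k] == pytest.approx(w[k] / w.sum(), abs=1e-10)
            got = scores.iloc[:, k].to_numpy()
            want = oracle_scores[:, k]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(
                got, -want, atol=1e-8)

    def test_sample_reorder_invariance(self):
        rng = np.random.default_rng(5)
        m = _matrix(2.0 ** rng.normal(15, 1, size=(8, 4)),
                    [("WT", 1), ("WT", 2), ("KR", 1), ("KR", 2)])
        scores, _ = pca_scores(m)
        perm = [("KR", 2), ("WT", 1), ("KR", 1), ("WT", 2)]
        scores_p, _ = pca_scores(m[perm])
        for col in scores.index:
            assert scores_p.loc[col].to_numpy() == pytest.approx(
                scores.loc[col].to_numpy(), abs=1e-8)


def _line_structure(spacing=1.0, n=40, lo=1):
    residues = {
        i: ("LYS", (spacing * (i - lo), 0.0, 0.0))
        for i in range(lo, lo + n)
    }
    return StructureModel("A", residues, (lo, lo + n - 1))


class TestDistanceRestraint:
    def test_hand_distance_satisfied(self):
        s = _line_structure()
        status, d = check_distance_restraint(1, 11, s)
        assert d == pytest.approx(10.0)
        assert status == "satisfied"

    def test_boundary_inclusive_and_violation(self):
        s = StructureModel("A", {
            1: ("LYS", (0.0, 0.0, 0.0)),
            2: ("LYS", (30.0, 0.0, 0.0)),
            3: ("LYS", (30.1, 0.0, 0.0)),
        }, (1, 3))
        assert check_distance_restraint(1, 2, s)[0] == "satisfied"
        assert check_distance_restraint(1, 3, s)[0] == "violated"

    def test_outside_coverage_unmappable(self):
        s = StructureModel("A", {i: ("ALA", (float(i), 0.0, 0.0))
                                 for i in range(146, 553)}, (146, 552))
        status, d = check_distance_restraint(5, 200, s)
        assert status == "unmappable" and np.isnan(d)

    def test_symmetry(self):
        s = _line_structure()
        assert check_distance_restraint(3, 20, s) == check_distance_restraint(
            20, 3, s)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        s = _line_structure(spacing=2.9)
        pairs = [(1, 5), (1, 12), (3, 30), (10, 11)]
        baseline = [check_distance_restraint(a, b, s) for a, b in pairs]
        for _ in range(20):
            rot = special_ortho_group.rvs(3, random_state=rng)
            shift = rng.normal(0, 50, size=3)
            moved = StructureModel("A", {
                i: (name, tuple(rot @ np.array(xyz) + shift))
                for i, (name, xyz) in s.residues.items()
            }, s.covered_range)
            for (a, b), (status, d) in zip(pairs, baseline):
                s2, d2 = check_distance_restraint(a, b, moved)
                assert s2 == status
                assert d2 == pytest.approx(d, abs=1e-9)

    def test_numbering_offset(self):
        s = _line_structure(lo=101)
        status, d = check_distance_restraint(1, 11, s, offset=100)
        assert status == "satisfied" and d == pytest.approx(10.0)
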