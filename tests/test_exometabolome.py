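import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from nicheflow.exometabolome import (
    Annotation,
    IonTable,
    ProfileCall,
    annotate_ions,
    classify_profiles,
    cluster_profiles,
    differential_secretion,
    normalize_profiles,
    phase_fold_changes,
    read_ion_table,
    select_candidates,
    write_ion_table,
)
from nicheflow.model_io import MetaboliteRef
from nicheflow.synthetic_data import ProfileSimConfig, generate_exometabolome

TPS = np.array([0.0, 6.0, 12.0, 18.0, 24.0, 36.0])
BOUNDARY = 18.0


def make_table(rows: dict[str, list[float]], mz=None) -> IonTable:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=TPS)
    mz = mz or {k: 100.0 + i for i, k in enumerate(rows)}
    return IonTable(df, pd.Series(mz), BOUNDARY)


class TestPhaseFoldChanges:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([1, 2, 3, 4, 2, 1], (4, 4)),       # bell, amplitude 4
            ([1, 2, 3, 4, 4, 4], (4, 1)),       # monotone accumulating
            ([5, 5, 5, 5, 5, 5], (1, 1)),       # constant positive
        ],
    )
    def test_noise_free_geometry(self, series, expected):
        fa, fd, low = phase_fold_changes(np.array(series, float), TPS, BOUNDARY, 0.0)
        assert (fa, fd) == pytest.approx(expected)
        assert not low

    def test_all_zero_series_floors_at_one_and_flags(self):
        fa, fd, low = phase_fold_changes(np.zeros(6), TPS, BOUNDARY, epsilon=0.5)
        assert (fa, fd) == (1.0, 1.0)
        assert low

    def test_peak_restricted_to_conditioning_phase(self):
        # the late spike must not count as accumulation
        fa, _, _ = phase_fold_changes(
            np.array([1, 1, 1, 1, 9, 1.0]), TPS, BOUNDARY, 0.0
        )
        assert fa == pytest.approx(1.0)


class TestClassify:
    def test_inclusive_threshold_boundary_is_bell(self):
        # exactly 2-fold both ways: the threshold is inclusive
        table = make_table({"i": [10, 15, 20, 20, 15, 10]})
        (call,) = classify_profiles(table, threshold=2.0, epsilon=0.0)
        assert (call.fc_accum, call.fc_deplete) == (2.0, 2.0)
        assert call.archetype == "bell"

    def test_one_sided_fold_change_is_accumulating(self):
        table = make_table({"i": [10, 20, 30, 40, 30, 26]})
        (call,) = classify_profiles(table)
        assert call.archetype == "accumulating"

    def test_noise_free_synthetic_truth_recovered(self, noise_free_table):
        (table, truth), _ = noise_free_table
        calls = classify_profiles(table)
        assert all(c.archetype == truth[c.ion_id] for c in calls)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        table = make_table(
            {"bell": [10, 15, 40, 40, 20, 10], "flat": [30, 31, 30, 29, 30, 30]}
        )
        base = [c.archetype for c in classify_profiles(table)]
        scaled = [c.archetype for c in classify_profiles(table.scaled(scale))]
        assert base == scaled

    def test_accuracy_degrades_with_noise(self, reference):
        def accuracy(noise_sd):
            accs = []
            for seed in range(3):
                cfg = ProfileSimConfig(n_ions=200, noise_sd=noise_sd, seed=seed)
                table, truth = generate_exometabolome(cfg)
                calls = classify_profiles(table)
                accs.append(np.mean([c.archetype == truth[c.ion_id] for c in calls]))
            return np.mean(accs)

        a0, a_mid, a_hi = accuracy(0.0), accuracy(0.3), accuracy(0.8)
        assert a0 == 1.0
        assert a0 >= a_mid >= a_hi
        assert a_hi < 1.0


class TestAnnotation:
    def test_alanine_deprotonated_ion_annotated(self):
        # independent oracle: IUPAC atomic masses composed by hand
        m_ala = 3 * 12.0 + 7 * 1.0078250319 + 14.0030740052 + 2 * 15.9949146221
        mz_obs = m_ala - (1.0078250319 - 0.000548579909)
        table = make_table({"i": [1, 2, 3, 4, 2, 1]}, mz={"i": mz_obs})
        ref = [MetaboliteRef("ala", "L-Alanine", "C3H7NO2", 89.047678)]
        anns = annotate_ions(table, ref, tolerance=0.005)
        assert len(anns) == 1
        assert anns[0].metabolite_id == "ala"
        assert anns[0].adduct == "[M-H]-"
        assert abs(anns[0].mass_error) < 1e-4

    def test_outside_tolerance_not_annotated(self):
        ref = [MetaboliteRef("ala", "L-Alanine", "C3H7NO2", 89.047678)]
        table = make_table({"i": [1, 1, 1, 1, 1, 1]}, mz={"i": 88.040402 + 0.006})
        assert annotate_ions(table, ref, tolerance=0.005) == []

    def test_empty_reference_warns_and_returns_nothing(self, caplog):
        table = make_table({"i": [1, 1, 1, 1, 1, 1]})
        with caplog.at_level("WARNING"):
            assert annotate_ions(table, []) == []
        assert "empty metabolite reference" in caplog.text

    def test_shrinking_tolerance_never_adds_annotations(self, noise_free_table, reference):
        (table, _), _ = noise_free_table
        wide = {(a.ion_id, a.metabolite_id, a.adduct) for a in annotate_ions(table, reference, 0.005)}
        narrow = {(a.ion_id, a.metabolite_id, a.adduct) for a in annotate_ions(table, reference, 0.001)}
        assert narrow <= wide

    def test_ambiguous_ions_get_multiple_annotations(self):
        # leucine and isoleucine share a formula: same m/z, two annotations
        refs = [
            MetaboliteRef("leu", "L-Leucine", "C6H13NO2", 131.094629),
            MetaboliteRef("ile", "L-Isoleucine", "C6H13NO2", 131.094629),
        ]
        table = make_table({"i": [1, 1, 1, 1, 1, 1]}, mz={"i": 131.094629 - 1.007276})
        anns = annotate_ions(table, refs)
        assert {a.metabolite_id for a in anns} == {"leu", "ile"}


class TestNormalize:
    def test_none_is_identity(self):
        table = make_table({"i": [1, 2, 3, 4, 2, 1]})
        out = normalize_profiles(table, "none")
        pd.testing.assert_frame_equal(out.intensities, table.intensities)

    def test_culture_auc_linearity(self):
        table = make_table({"i": [1, 2, 3, 4, 2, 1]})
        dens = pd.Series(np.linspace(0.1, 1.0, 6), index=TPS)
        base = normalize_profiles(table, "culture-AUC", culture_density=dens)
        doubled = normalize_profiles(table.scaled(2.0), "culture-AUC", culture_density=dens)
        pd.testing.assert_frame_equal(doubled.intensities, base.intensities.mul(2.0))

    def test_equal_per_cell_secretion_normalizes_identically(self):
        # two replicates: culture 3x denser secretes 3x more of everything
        dens = pd.Series(np.linspace(0.1, 1.0, 6), index=TPS)
        t1 = make_table({"i": [1, 2, 3, 4, 2, 1]})
        t2 = t1.scaled(3.0)
        n1 = normalize_profiles(t1, "culture-AUC", culture_density=dens)
        n2 = normalize_profiles(t2, "culture-AUC", culture_density=dens.mul(3.0))
        assert np.allclose(n1.intensities, n2.intensities, atol=1e-9)

    def test_zero_auc_rejected(self):
        table = make_table({"i": [1, 2, 3, 4, 2, 1]})
        dens = pd.Series(np.zeros(6), index=TPS)
        with pytest.raises(ValueError, match="AUC"):
            normalize_profiles(table, "culture-AUC", culture_density=dens)


class TestClustering:
    def test_two_archetypes_recovered_exactly(self, reference):
        cfg = ProfileSimConfig(
            n_ions=60,
            archetype_fractions={"bell": 0.5, "flat": 0.0, "accumulating": 0.0, "depleting": 0.5},
            noise_sd=0.0,
            seed=2,
        )
        table, truth = generate_exometabolome(cfg)
        labels = cluster_profiles(table, k=2, seed=0)
        truth_codes = [truth[i] for i in labels.index]
        assert adjusted_rand_score(truth_codes, labels.to_numpy()) == 1.0

    def test_identical_profiles_warn_degenerate(self):
        table = make_table({"a": [1, 2, 3, 4, 2, 1], "b": [1, 2, 3, 4, 2, 1]})
        with pytest.warns(UserWarning, match="degenerate"):
            cluster_profiles(table, k=2, seed=0)

    def test_fixed_seed_reruns_identically(self, noise_free_table):
        (table, _), _ = noise_free_table
        a = cluster_profiles(table, k=4, seed=5)
        b = cluster_profiles(table, k=4, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_k_larger_than_n_ions_rejected(self):
        table = make_table({"a": [1, 2, 3, 4, 2, 1]})
        with pytest.raises(ValueError, match="exceeds"):
            cluster_profiles(table, k=2, seed=0)


class TestCandidates:
    def call(self, ion, arch):
        return ProfileCall(ion_id=ion, archetype=arch, fc_accum=4.0, fc_deplete=4.0)

    def ann(self, ion, met):
        return Annotation(ion_id=ion, metabolite_id=met, adduct="[M-H]-", mass_error=0.0)

    def test_no_bell_ions_gives_empty_candidates(self):
        calls = [self.call("i1", "flat"), self.call("i2", "accumulating")]
        df, unknowns = select_candidates(calls, [self.ann("i1", "ala")])
        assert df.empty and unknowns == []

    def test_annotated_and_unknown_bells_partitioned(self):
        calls = [self.call(f"i{k}", "bell") for k in range(5)]
        anns = [self.ann("i0", "ala"), self.ann("i1", "gln"), self.ann("i2", "ser")]
        df, unknowns = select_candidates(calls, anns)
        assert len(df) == 3
        assert unknowns == ["i3", "i4"]

    def test_count_matches_independent_refilter(self, noise_free_table, reference):
        (table, _), _ = noise_free_table
        calls = classify_profiles(table, threshold=2.0)
        anns = annotate_ions(table, reference, 0.005)
        df, unknowns = select_candidates(calls, anns)
        # independent re-filter straight off the raw table
        eps = table.epsilon()
        raw = table.intensities.to_numpy()
        cond = table.timepoints <= table.phase_boundary
        peak = raw[:, cond].max(axis=1)
        bell = ((peak + eps) / (raw[:, 0] + eps) >= 2) & ((peak + eps) / (raw[:, -1] + eps) >= 2)
        bell_ids = set(np.array(table.ion_ids)[bell])
        annotated = {a.ion_id for a in anns}
        assert set(df["ion_id"]) == bell_ids & annotated
        assert set(unknowns) == bell_ids - annotated

    def test_deterministic_in_inputs(self):
        calls = [self.call("i0", "bell")]
        anns = [self.ann("i0", "ala")]
        df1, _ = select_candidates(calls, anns)
        df2, _ = select_candidates(list(calls), list(anns))
        pd.testing.assert_frame_equal(df1, df2)


class TestDifferentialSecretion:
    def replicates(self, shift=0.0, seed=0, n_ions=100):
        rng = np.random.default_rng(seed)
        base = rng.uniform(50, 150, n_ions)

        def one(arm_shift):
            rows = {
                f"i{k}": base[k] * np.ones(len(TPS)) + rng.normal(0, 1, len(TPS))
                for k in range(n_ions)
            }
            t = make_table(rows)
            if arm_shift:
                t.intensities.iloc[0] += arm_shift
            return t

        ctrl = [one(0.0) for _ in range(3)]
        trt = [one(shift) for _ in range(3)]
        return ctrl, trt

    def test_identical_arms_no_discoveries(self):
        t = make_table({"i": [1, 2, 3, 4, 2, 1]})
        out = differential_secretion([t, t], [t, t])
        assert (out["q"] == 1.0).all()
        assert out["zero_variance"].all()

    def test_strongly_shifted_ion_is_top_discovery(self):
        ctrl, trt = self.replicates(shift=30.0, seed=4)  # ~30 sigma
        out = differential_secretion(ctrl, trt)
        assert out["q"].idxmin() == "i0"
        assert out.loc["i0", "q"] < 0.1

    def test_needs_two_replicates_per_arm(self):
        t = make_table({"i": [1, 2, 3, 4, 2, 1]})
        with pytest.raises(ValueError, match="replicates"):
            differential_secretion([t], [t, t])


def test_ion_table_round_trip(tmp_path, noise_free_table):
    (table, _), _ = noise_free_table
    p = tmp_path / "ions.tsv"
    write_ion_table(table, p)
    again = read_ion_table(p)
    assert again.phase_boundary == table.phase_boundary
    pd.testing.assert_frame_equal(again.intensities, table.intensities)
    pd.testing.assert_series_equal(again.mz, table.mz, check_names=False)
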