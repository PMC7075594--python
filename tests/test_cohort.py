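"""Synthetic cohort generator: determinism, coupling->PLI mapping, scores."""

import numpy as np
import pytest
from scipy import stats as spstats

import eegraph as eg
from conftest import make_pair_spec


class TestDeterminism:
    def test_same_spec_and_seed_give_identical_cohorts(self):
        spec = make_pair_spec({(0, 1): 0.6}, epochs=3, seed=7)
        a = eg.generate_cohort(spec)
        b = eg.generate_cohort(spec)
        assert [s.subject_id for s in a] == [s.subject_id for s in b]
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.recording.data, sb.recording.data)
            assert sa.cognitive_scores == sb.cognitive_scores

    def test_different_seeds_differ(self):
        a = eg.generate_cohort(make_pair_spec({(0, 1): 0.6}, epochs=2, seed=1))
        b = eg.generate_cohort(make_pair_spec({(0, 1): 0.6}, epochs=2, seed=2))
        assert not np.array_equal(a[0].recording.data, b[0].recording.data)


class TestCouplingToPli:
    def test_fully_coupled_pair_reaches_pli_one(self):
        # one pair at coupling 1, no independent component, no white noise:
        # the pair's phase difference is the constant pi/4 offset, so the
        # sign of the wrapped difference never changes.  Beta band: its
        # short envelope nulls keep the per-epoch analytic-phase estimate
        # accurate enough to recover the exact value.
        spec = make_pair_spec(
            {(0, 1): 1.0}, n_channels=3, band="beta", epochs=6,
            noise_sd=0.0, seed=7,
        )
        subj = eg.generate_cohort(spec)[0]
        cm = eg.subject_connectivity(subj.recording, eg.BAND_MAP["beta"])
        assert cm.values[0, 1] >= 0.999
        assert cm.values[0, 1] == cm.values.max()

    def test_fully_coupled_pair_dominates_in_slow_band(self):
        # same construction in the delta band: deep envelope nulls of slow
        # narrowband noise cost a few percent of estimation accuracy, but
        # the coupled pair still saturates far above everything else
        spec = make_pair_spec(
            {(0, 1): 1.0}, n_channels=3, epochs=6, noise_sd=0.0, seed=7
        )
        subj = eg.generate_cohort(spec)[0]
        cm = eg.subject_connectivity(subj.recording, eg.BAND_MAP["delta"])
        assert cm.values[0, 1] > 0.9
        assert cm.values[0, 1] == cm.values.max()

    def test_zero_coupling_gives_near_zero_pli(self):
        # beta band decorrelates fastest, so a long epoch pushes the
        # finite-sample bias of |mean sign| toward zero
        spec = make_pair_spec(
            {}, n_channels=3, band="beta", epochs=1, seed=3,
            epoch_length=30.0,
        )
        subj = eg.generate_cohort(spec)[0]
        cm = eg.subject_connectivity(subj.recording, eg.BAND_MAP["beta"])
        off = cm.values[np.triu_indices(3, 1)]
        assert np.all(off < 0.1)

    def test_mean_pli_nondecreasing_on_coupling_grid(self):
        # 3-point grid, one pair, replicate-averaged
        grid = [0.0, 0.5, 1.0]
        means = []
        for c in grid:
            vals = []
            for rep in range(12):
                spec = make_pair_spec(
                    {(0, 1): c}, n_channels=3, band="beta", epochs=4,
                    seed=100 + rep,
                )
                subj = eg.generate_cohort(spec)[0]
                cm = eg.subject_connectivity(subj.recording, eg.BAND_MAP["beta"])
                vals.append(cm.values[0, 1])
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
        assert means[2] - means[0] > 0.3  # the grid spans a real dynamic range

    def test_pli_rank_order_follows_coupling_rank_order(self):
        # all six pairs of a 4-channel set carry distinct couplings; the
        # replicate-averaged PLI estimates must rank in the same order
        couplings = {(0, 1): 0.9, (2, 3): 0.75, (0, 2): 0.6,
                     (1, 3): 0.45, (0, 3): 0.3, (1, 2): 0.15}
        requested = np.zeros((4, 4))
        for (i, j), c in couplings.items():
            requested[i, j] = requested[j, i] = c
        acc = np.zeros((4, 4))
        n_rep = 8
        for rep in range(n_rep):
            spec = make_pair_spec(
                couplings, n_channels=4, band="beta", epochs=8, seed=40 + rep
            )
            subj = eg.generate_cohort(spec)[0]
            acc += eg.subject_connectivity(
                subj.recording, eg.BAND_MAP["beta"]
            ).values
        iu = np.triu_indices(4, 1)
        rho = spstats.spearmanr(requested[iu], (acc / n_rep)[iu]).statistic
        assert rho > 0.9

    def test_patient_delta_contrast_lowers_global_pli(self):
        # patients = controls with couplings scaled by 0.7; the patient arm
        # must show lower global delta PLI in >= 90% of seeded replicates
        couplings = {(0, 1): 0.7, (2, 3): 0.7, (4, 5): 0.7, (6, 7): 0.7}
        patient_mat = np.full((8, 8), 0.1)
        np.fill_diagonal(patient_mat, 0.0)
        for (i, j), c in couplings.items():
            patient_mat[i, j] = patient_mat[j, i] = c * 0.7
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            spec = make_pair_spec(
                couplings, n_channels=8, epochs=4, floor=0.1,
                n_controls=5, n_patients=5, patient_mat=patient_mat,
                seed=600 + rep,
            )
            glob = {"control": [], "patient": []}
            for s in eg.generate_cohort(spec):
                cm = eg.subject_connectivity(s.recording, eg.BAND_MAP["delta"])
                glob[s.group].append(eg.global_average_pli(cm))
            wins += np.mean(glob["patient"]) < np.mean(glob["control"])
        assert wins >= 0.9 * n_rep


class TestCognitiveScores:
    def test_defaults_recover_group_distributions(self):
        spec = eg.CohortSpec()
        rng = np.random.default_rng(0)
        n = 10_000
        onb = np.array(
            [eg.generate_cognitive_scores(spec, "control", rng)["ONB"]
             for _ in range(n)]
        )
        assert abs(onb.mean() - 0.94) < 4 * 0.06 / np.sqrt(n)
        assert abs(onb.std() - 0.06) < 0.003
        ocl = np.array(
            [eg.generate_cognitive_scores(spec, "patient", rng)["OCL"]
             for _ in range(n)]
        )
        assert abs(ocl.mean() - 0.59) < 4 * 0.09 / np.sqrt(n)
        # distributional recovery: KS against the target normal law
        p = spstats.kstest(ocl, "norm", args=(0.59, 0.09)).pvalue
        assert p > 0.01

    def test_zero_sd_is_degenerate(self):
        spec = make_pair_spec({}, n_channels=4)
        spec.cognitive_distributions = {"control": {"X": (5.0, 0.0)}}
        rng = np.random.default_rng(0)
        draws = [
            eg.generate_cognitive_scores(spec, "control", rng)["X"]
            for _ in range(10)
        ]
        assert draws == [5.0] * 10

    def test_unknown_group_rejected(self):
        spec = make_pair_spec({}, n_channels=4)
        with pytest.raises(KeyError, match="nogroup"):
            eg.generate_cognitive_scores(
                spec, "nogroup", np.random.default_rng(0)
            )


class TestSpecValidation:
    def test_asymmetric_coupling_rejected(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = 0.5  # not mirrored
        with pytest.raises(ValueError, match="symmetric"):
            eg.CohortSpec(
                channel_labels=("a", "b", "c"),
                bands=(eg.BAND_MAP["delta"],),
                band_coupling={"control": {"delta": mat},
                               "patient": {"delta": mat}},
            )

    def test_non_integer_epoch_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            make_pair_spec({}, n_channels=3, epoch_length=0.3333)

    def test_out_of_range_coupling_rejected(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            eg.CohortSpec(
                channel_labels=("a", "b", "c"),
                bands=(eg.BAND_MAP["delta"],),
                band_coupling={"control": {"delta": mat},
                               "patient": {"delta": mat}},
            )

    def test_epoch_range_draws_within_bounds(self):
        spec = make_pair_spec(
            {}, n_channels=3, epochs=(2, 5), n_controls=6, seed=2
        )
        counts = {s.recording.n_epochs for s in eg.generate_cohort(spec)}
        assert counts <= {2, 3, 4, 5} and len(counts) > 1


def test_write_cohort_roundtrip(tmp_path):
    spec = make_pair_spec({(0, 1): 0.5}, epochs=2, n_controls=2, n_patients=1)
    subjects = eg.generate_cohort(spec)
    manifest = eg.write_cohort(subjects, tmp_path)
    rows = eg.read_cohort_manifest(manifest)
    assert [r["subject_id"] for r in rows] == [s.subject_id for s in subjects]
    assert [r["group"] for r in rows] == ["control", "control", "patient"]
    back = eg.read_recording(rows[0]["path"])
    np.testing.assert_array_equal(back.data, subjects[0].recording.data)
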