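"""Synthetic cohort generator: determinism, design constants, recoverability."""

import json

import numpy as np
import pytest

from strokeconn import synthdata as sd
from strokeconn.atlas import pair_compartment
from strokeconn.motion import compute_fd
from strokeconn.connectivity import fisher_z


def small_config(tmp_seed=0, **overrides):
    defaults = dict(
        n_controls=2,
        n_stroke_sensorimotor=2,
        n_stroke_motor=1,
        n_rois=10,
        n_frames=40,
        grid_shape=(14, 14, 14),
        n_sessions=3,
        hypo_connections=[(0, 1, -0.5)],
        hyper_connections=[(2, 4, 0.5)],
        seed=tmp_seed,
    )
    defaults.update(overrides)
    return sd.CohortConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_rois", 0),
            ("tr", -1.0),
            ("spike_rate_patients", 1.5),
            ("noise_sd", -0.1),
            ("seed", -3),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            small_config(**{field: value})

    def test_connection_indices_validated(self):
        with pytest.raises(ValueError, match="hypo_connections"):
            small_config(hypo_connections=[(0, 0, -0.5)])
        with pytest.raises(ValueError, match="hyper_connections"):
            small_config(hyper_connections=[(0, 99, 0.5)])

    def test_default_sets_match_study_counts(self):
        cfg = sd.CohortConfig()
        by_comp = {}
        for (i, j, dz), cls in [(c, "hypo") for c in cfg.hypo_connections] + [
            (c, "hyper") for c in cfg.hyper_connections
        ]:
            comp = sd._canonical_compartment(i, j, cfg.n_rois)
            by_comp[(cls, comp)] = by_comp.get((cls, comp), 0) + 1
            assert (dz < 0) == (cls == "hypo")
        assert by_comp == sd.DEFAULT_SET_COUNTS


class TestRealignment:
    def test_no_spikes_stay_below_threshold(self):
        df = sd.generate_realignment(250, 0.0, seed=0)
        assert compute_fd(df).max() < 0.5

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="n_frames"):
            sd.generate_realignment(1, 0.1)

    def test_exceedance_rate_matches_spike_rate(self):
        # Monte-Carlo over 100 seeds at the patient spike rate
        fracs = [
            (compute_fd(sd.generate_realignment(250, 0.35, seed=s)) > 0.5).mean()
            for s in range(100)
        ]
        assert abs(np.mean(fracs) - 0.35) < 0.05

    def test_deterministic_given_seed(self):
        a = sd.generate_realignment(100, 0.2, seed=5)
        b = sd.generate_realignment(100, 0.2, seed=5)
        assert a.equals(b)


class TestTemplates:
    def test_sample_correlation_converges_to_template(self):
        z = sd.build_z_template(6, 0.1, [(0, 1, 0.5)])
        series = sd.sample_roi_signals(z, 40000, np.random.default_rng(0))
        r = np.corrcoef(series, rowvar=False)
        assert r[0, 1] == pytest.approx(np.tanh(0.6), abs=0.02)
        assert r[2, 3] == pytest.approx(np.tanh(0.1), abs=0.02)

    def test_template_correlation_is_positive_definite(self):
        z = sd.build_z_template(20, 0.1, [(0, 1, -3.0), (2, 3, 3.0)])
        r = sd.template_correlation(z)
        w = np.linalg.eigvalsh(r)
        assert w.min() > 0
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    cfg = small_config(tmp_seed=3)
    truth = sd.generate_cohort(cfg, out)
    return cfg, truth, out


class TestGeneratedCohort:
    def test_bold_file_count(self, cohort):
        cfg, truth, out = cohort
        bolds = sorted(out.glob("*/*/bold.nii.gz"))
        # 2 controls x 1 session + 3 stroke x 3 sessions = 11
        assert len(bolds) == 11

    def test_ground_truth_roundtrip(self, cohort):
        cfg, truth, out = cohort
        loaded = sd.GroundTruth.load(out / "ground_truth.json")
        assert loaded.to_dict() == truth.to_dict()

    def test_lesion_confined_to_one_hemisphere(self, cohort):
        import nibabel as nib

        cfg, truth, out = cohort
        from strokeconn.atlas import load_atlas

        atlas = load_atlas(out / "atlas.nii.gz", out / "atlas_labels.json")
        for sub in truth.subjects:
            if sub.group != "stroke":
                continue
            lesion = np.asarray(
                nib.load(str(out / sub.subject_id / "lesion.nii.gz")).dataobj
            ).astype(bool)
            other = "left" if sub.lesion_side == "right" else "right"
            for lab in atlas.labels:
                if lab.hemisphere == other:
                    assert not (lesion & (atlas.label_volume == lab.id)).any()

    def test_spike_frames_match_realignment(self, cohort):
        cfg, truth, out = cohort
        from strokeconn.motion import read_realignment

        sub = truth.subjects[-1]
        ses = sub.sessions[0]
        fd = compute_fd(read_realignment(out / sub.subject_id / ses / "realignment.tsv"))
        assert sorted(np.flatnonzero(fd > 0.5).tolist()) == sorted(
            sub.spike_frames[ses]
        )

    def test_determinism_same_seed_same_cohort(self, cohort, tmp_path):
        import nibabel as nib

        cfg, truth, out = cohort
        truth2 = sd.generate_cohort(small_config(tmp_seed=3), tmp_path / "again")
        assert truth.to_dict() == truth2.to_dict()
        a = np.asarray(nib.load(str(out / "strk-01" / "T2" / "bold.nii.gz")).dataobj)
        b = np.asarray(
            nib.load(str(tmp_path / "again" / "strk-01" / "T2" / "bold.nii.gz")).dataobj
        )
        np.testing.assert_array_equal(a, b)

    def test_phenotype_rows_cover_all_sessions(self, cohort):
        import pandas as pd

        cfg, truth, out = cohort
        pheno = pd.read_csv(out / "phenotype.tsv", sep="\t")
        assert len(pheno) == 2 * 1 + 3 * 3
        assert set(pheno.columns) >= {
            "subject_id",
            "group",
            "arm",
            "lesion_side",
            "age",
            "session",
        }


def test_behaviour_change_tracks_true_index_change(tmp_path):
    """Regressing behavioural change on the true index change recovers the
    configured coupling coefficient at low noise."""
    import pandas as pd

    coupling = {"sulcs": sd.BehaviourCoupling("contra_hyper", 10.0, 0.3, 4.0, 2.0)}
    cfg = sd.CohortConfig(
        n_controls=0,
        n_stroke_sensorimotor=12,
        n_stroke_motor=12,
        n_rois=10,
        n_frames=20,
        grid_shape=(14, 14, 14),
        n_sessions=2,
        hypo_connections=[(0, 1, -0.5)],
        hyper_connections=[(2, 4, 0.5)],
        subject_shift_sd=0.3,
        behaviour_model=coupling,
        treatment_effects={
            "sensorimotor": {"T2": {}},
            "motor": {"T2": {"contra_hyper": 0.2}},
        },
        seed=9,
    )
    truth = sd.generate_cohort(cfg, tmp_path)
    pheno = pd.read_csv(tmp_path / "phenotype.tsv", sep="\t")
    wide = pheno.pivot_table(index="subject_id", columns="session", values="sulcs")
    x, y = [], []
    for sub in truth.subjects:
        x.append(sub.index_shifts["T2"]["contra_hyper"])
        y.append(wide.loc[sub.subject_id, "T2"] - wide.loc[sub.subject_id, "T1"])
    slope = np.polyfit(x, y, 1)[0]
    assert slope == pytest.approx(10.0, rel=0.2)
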