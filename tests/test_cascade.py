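"""Feature fusion, cascade fitting, and majority-vote semantics."""

import numpy as np
import pandas as pd
import pytest

from stenograde.cascade import CascadeModel, fuse, provenance
from stenograde.radiomics import feature_names


def indexed(n_patients, images_per_patient, n_cols, rng, prefix="original_glcm_F"):
    tuples = [
        (f"P{p:03d}", "V0", w)
        for p in range(n_patients)
        for w in range(images_per_patient)
    ]
    index = pd.MultiIndex.from_tuples(
        tuples, names=["patient_id", "vessel_id", "view_index"]
    )
    return pd.DataFrame(
        rng.normal(size=(len(tuples), n_cols)),
        index=index,
        columns=[f"{prefix}{k}" for k in range(n_cols)],
    )


class TestFuse:
    def test_full_roster_plus_latents_is_529_columns(self, rng):
        index = indexed(2, 2, 1, rng).index
        radiomic = pd.DataFrame(
            rng.normal(size=(4, 465)), index=index, columns=feature_names()
        )
        ae = pd.DataFrame(
            rng.normal(size=(4, 64)),
            index=radiomic.index,
            columns=[f"ae_{k}" for k in range(64)],
        )
        fused = fuse(radiomic, ae)
        assert fused.shape[1] == 529
        tags = provenance(fused.columns)
        assert (tags == "radiomic").sum() == 465 and (tags == "ae").sum() == 64

    def test_empty_frame_passes_through(self, rng):
        x = indexed(2, 2, 3, rng)
        assert fuse(x, pd.DataFrame()).equals(x)
        assert fuse(pd.DataFrame(), x).equals(x)

    def test_row_key_mismatch_lists_offenders(self, rng):
        a = indexed(2, 2, 3, rng)
        b = indexed(3, 2, 2, rng, prefix="ae_")
        with pytest.raises(ValueError, match="P002"):
            fuse(a, b)


class _FixedStage:
    """Stand-in stage returning scripted per-image positive probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, rows):
        return self.probs[: len(rows)]


def patient_rows(n_images):
    index = pd.MultiIndex.from_tuples(
        [("P001", "V0", w) for w in range(n_images)],
        names=["patient_id", "vessel_id", "view_index"],
    )
    return pd.DataFrame({"x": np.zeros(n_images)}, index=index)


def model_with(stage_a_probs, stage_b_probs):
    return CascadeModel(
        stage_a=_FixedStage(stage_a_probs), stage_b=_FixedStage(stage_b_probs)
    )


class TestMajorityVoting:
    def test_no_stenosis_majority_stops_the_cascade(self):
        # 13 of 21 images voted no-stenosis: final noCAD, stage B never runs
        probs_a = np.array([0.1] * 13 + [0.9] * 8)
        model = model_with(probs_a, np.full(21, 0.9))
        pred = model.predict_patient(patient_rows(21))
        assert pred.stage_a_votes == (13, 8)
        assert pred.final_label == "noCAD"
        assert pred.stage_b_votes is None

    def test_stenosis_majority_proceeds_to_severity_vote(self):
        # 13 of 17 voted stenosis, stage-B majority obstructive
        probs_a = np.array([0.9] * 13 + [0.1] * 4)
        probs_b = np.array([0.8] * 10 + [0.2] * 7)
        model = model_with(probs_a, probs_b)
        pred = model.predict_patient(patient_rows(17))
        assert pred.stage_a_votes == (4, 13)
        assert pred.stage_b_votes == (7, 10)
        assert pred.final_label == "obstructive"

    def test_stage_a_tie_breaks_toward_severity(self):
        probs_a = np.array([0.9, 0.9, 0.1, 0.1])  # 2-2 split
        model = model_with(probs_a, np.array([0.1, 0.1, 0.1, 0.9]))
        pred = model.predict_patient(patient_rows(4))
        assert pred.stage_b_votes is not None  # proceeded despite the tie
        assert pred.final_label == "nonobstructive"

    def test_stage_b_tie_breaks_to_obstructive(self):
        model = model_with(np.full(4, 0.9), np.array([0.9, 0.9, 0.1, 0.1]))
        pred = model.predict_patient(patient_rows(4))
        assert pred.final_label == "obstructive"

    def test_voting_invariant_to_image_order(self, rng):
        probs_a = rng.random(11)
        probs_b = rng.random(11)
        base = model_with(probs_a, probs_b).predict_patient(patient_rows(11))
        perm = rng.permutation(11)
        shuffled = model_with(probs_a[perm], probs_b[perm]).predict_patient(
            patient_rows(11)
        )
        assert base.final_label == shuffled.final_label
        assert base.stage_a_votes == shuffled.stage_a_votes

    def test_empty_patient_rejected(self):
        with pytest.raises(ValueError):
            model_with([0.5], [0.5]).predict_patient(patient_rows(0))


def separable_features(rng, per_class=6, images=4):
    """Three patient classes cleanly encoded in two feature dimensions."""
    frames = []
    labels = {}
    for k, label in enumerate(("noCAD", "nonobstructive", "obstructive")):
        for p in range(per_class):
            pid = f"P{k}{p:02d}"
            labels[pid] = label
            index = pd.MultiIndex.from_tuples(
                [(pid, "V0", w) for w in range(images)],
                names=["patient_id", "vessel_id", "view_index"],
            )
            x = rng.normal(0, 0.3, size=(images, 12))
            x[:, 0] += 3.0 * (k >= 1)  # disease marker
            x[:, 1] += 3.0 * (k == 2)  # severity marker
            frames.append(
                pd.DataFrame(
                    x, index=index, columns=[f"original_glcm_F{j}" for j in range(12)]
                )
            )
    return pd.concat(frames), pd.Series(labels)


class TestFit:
    def test_separable_cohort_reaches_perfect_training_accuracy(self, rng):
        features, labels = separable_features(rng)
        model = CascadeModel.fit(features, labels, seed=0, n_trees=50)
        pred = model.predict(features)
        assert all(pred.loc[p, "final_label"] == labels[p] for p in labels.index)

    def test_stage_b_trains_only_on_cad_patient_images(self, rng, monkeypatch):
        features, labels = separable_features(rng)
        captured = {}
        original = CascadeModel._fit_stage

        def spy(name, x, y, *args, **kwargs):
            captured[name] = x.index.get_level_values("patient_id").unique().tolist()
            return original(name, x, y, *args, **kwargs)

        monkeypatch.setattr(CascadeModel, "_fit_stage", staticmethod(spy))
        CascadeModel.fit(features, labels, seed=0, n_trees=20)
        no_cad = {p for p, l in labels.items() if l == "noCAD"}
        assert set(captured["a"]) == set(labels.index)
        assert set(captured["b"]) == set(labels.index) - no_cad

    def test_missing_class_rejected(self, rng):
        features, labels = separable_features(rng)
        only_cad = labels[labels != "noCAD"]
        mask = features.index.get_level_values("patient_id").isin(only_cad.index)
        with pytest.raises(ValueError, match="three classes"):
            CascadeModel.fit(features.loc[mask], only_cad, seed=0, n_trees=10)

    def test_no_cad_patient_never_gets_stage_b_votes(self, rng):
        features, labels = separable_features(rng)
        model = CascadeModel.fit(features, labels, seed=0, n_trees=50)
        pred = model.predict(features)
        for pid in labels[labels == "noCAD"].index:
            if pred.loc[pid, "final_label"] == "noCAD":
                assert np.isnan(pred.loc[pid, "stage_b_votes_obstructive"])
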