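"""Two-stage cascade classification with per-patient majority voting.

Images are classified individually; patients are graded by composing two
binary sub-tasks:

* **stage A** — no CAD vs. any CAD, trained on every training image;
* **stage B** — nonobstructive vs. obstructive, trained only on images of
  CAD patients.

At prediction time stage A classifies all of a patient's images. If the
majority says "no CAD" the patient is labeled noCAD and stage B never runs;
otherwise stage B classifies all images and its majority decides the grade.
Exact vote ties break toward the more severe outcome (proceed to stage B /
obstructive) — the clinically conservative convention.

Each stage owns its scaler, three-step feature selection, SMOTE balancing and
a 500-tree random forest (sqrt-p features per split), all fitted on training
rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

from .selection import (
    SelectionReport,
    apply_scaler,
    fit_scaler,
    select_features,
    smote_balance,
)
from .synthetic import CLASS_LABELS

__all__ = ["fuse", "CascadeStage", "CascadeModel", "PatientPrediction"]


def fuse(radiomic: pd.DataFrame, ae: pd.DataFrame) -> pd.DataFrame:
    """Column-wise merge of radiomic and AE feature matrices.

    Row keys (patient, vessel, view) must match exactly; an empty frame passes
    the other through unchanged. Column-name prefixes ('ae_' vs. radiomic
    image-type prefixes) carry the provenance tag.
    """
    if radiomic.empty:
        return ae.copy()
    if ae.empty:
        return radiomic.copy()
    left = set(map(tuple, radiomic.index))
    right = set(map(tuple, ae.index))
    if left != right:
        missing = sorted(left ^ right)[:10]
        raise ValueError(f"row-key mismatch between feature matrices: {missing}")
    return pd.concat([radiomic, ae.loc[radiomic.index]], axis=1)


def provenance(columns) -> pd.Series:
    """'ae' or 'radiomic' per column name."""
    return pd.Series(
        ["ae" if str(c).startswith("ae_") else "radiomic" for c in columns],
        index=list(columns),
    )


@dataclass
class CascadeStage:
    """One fitted binary sub-task: scaler + selected features + forest."""

    name: str
    scaler: StandardScaler
    report: SelectionReport
    forest: RandomForestClassifier

    @property
    def selected(self) -> list[str]:
        return self.report.kept_after_lasso

    def predict_proba(self, x: pd.DataFrame) -> np.ndarray:
        """P(positive class) per image; positive = CAD (A) / obstructive (B)."""
        scaled = apply_scaler(self.scaler, x)[self.selected]
        proba = self.forest.predict_proba(scaled.to_numpy())
        pos = list(self.forest.classes_).index(1)
        return proba[:, pos]


@dataclass
class PatientPrediction:
    """Votes and final grade for one patient."""

    patient_id: str
    stage_a_votes: tuple[int, int]  # (n_noCAD, n_CAD)
    stage_b_votes: tuple[int, int] | None  # (n_nonobstructive, n_obstructive)
    final_label: str
    per_image_labels: pd.Series


@dataclass
class CascadeModel:
    """The fitted two-stage cascade."""

    stage_a: CascadeStage
    stage_b: CascadeStage
    seed: int = 0
    vote_policy: str = "per-stage-majority"

    @classmethod
    def fit(
        cls,
        features: pd.DataFrame,
        patient_labels: pd.Series,
        seed: int = 0,
        n_trees: int = 500,
        rho_max: float = 0.95,
        alpha: float = 0.05,
        smote_k: int = 5,
    ) -> "CascadeModel":
        """Fit both stages on training images.

        ``features`` is indexed by (patient_id, vessel_id, view_index);
        ``patient_labels`` maps patient_id to one of the three class labels and
        is broadcast to images. All three classes must be present.
        """
        labels_img = pd.Series(
            features.index.get_level_values("patient_id").map(patient_labels),
            index=features.index,
        )
        if set(CLASS_LABELS) - set(labels_img):
            raise ValueError("training data must contain all three classes")

        y_a = (labels_img != "noCAD").astype(int).to_numpy()
        stage_a = cls._fit_stage(
            "a", features, y_a, seed, n_trees, rho_max, alpha, smote_k
        )

        cad_mask = (labels_img != "noCAD").to_numpy()
        x_b = features.loc[cad_mask]
        y_b = (labels_img[cad_mask] == "obstructive").astype(int).to_numpy()
        stage_b = cls._fit_stage(
            "b", x_b, y_b, seed + 1, n_trees, rho_max, alpha, smote_k
        )
        return cls(stage_a=stage_a, stage_b=stage_b, seed=seed)

    @staticmethod
    def _fit_stage(
        name: str,
        x: pd.DataFrame,
        y: np.ndarray,
        seed: int,
        n_trees: int,
        rho_max: float,
        alpha: float,
        smote_k: int,
    ) -> CascadeStage:
        scaler = fit_scaler(x)
        scaled = apply_scaler(scaler, x)
        report = select_features(
            scaled, y, task=name, rho_max=rho_max, alpha=alpha, seed=seed
        )
        sub = scaled[report.kept_after_lasso]
        x_bal, y_bal = smote_balance(sub, y, k_neighbors=smote_k, seed=seed)
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        ).fit(x_bal, y_bal)
        return CascadeStage(name=name, scaler=scaler, report=report, forest=forest)

    # -- prediction --------------------------------------------------------

    def predict_patient(self, patient_rows: pd.DataFrame) -> PatientPrediction:
        """Grade one patient from all of their images (majority per stage)."""
        if patient_rows.empty:
            raise ValueError("patient has no images")
        pid = str(patient_rows.index.get_level_values("patient_id")[0])
        p_a = self.stage_a.predict_proba(patient_rows)
        votes_a = (p_a >= 0.5).astype(int)
        n_cad = int(votes_a.sum())
        n_no = int(len(votes_a) - n_cad)
        per_image = pd.Series(
            np.where(votes_a == 1, "CAD", "noCAD"), index=patient_rows.index
        )
        if n_no > n_cad:  # strict majority needed to stop at noCAD
            return PatientPrediction(
                patient_id=pid,
                stage_a_votes=(n_no, n_cad),
                stage_b_votes=None,
                final_label="noCAD",
                per_image_labels=per_image,
            )
        p_b = self.stage_b.predict_proba(patient_rows)
        votes_b = (p_b >= 0.5).astype(int)
        n_obs = int(votes_b.sum())
        n_non = int(len(votes_b) - n_obs)
        final = "obstructive" if n_obs >= n_non else "nonobstructive"
        per_image = pd.Series(
            np.where(votes_b == 1, "obstructive", "nonobstructive"),
            index=patient_rows.index,
        )
        return PatientPrediction(
            patient_id=pid,
            stage_a_votes=(n_no, n_cad),
            stage_b_votes=(n_non, n_obs),
            final_label=final,
            per_image_labels=per_image,
        )

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-patient grades for a full feature matrix.

        Returns a frame indexed by patient_id with the final label, the vote
        counts, and chained pseudo-probabilities for the three classes
        (P(noCAD) = 1 - pA; P(nonobstructive) = pA (1 - pB); P(obstructive) =
        pA pB, with pA/pB the patient-mean stage scores) for ROC analysis.
        """
        records = []
        for pid, rows in features.groupby(level="patient_id", sort=True):
            pred = self.predict_patient(rows)
            p_a = float(self.stage_a.predict_proba(rows).mean())
            p_b = float(self.stage_b.predict_proba(rows).mean())
            records.append(
                {
                    "patient_id": pid,
                    "final_label": pred.final_label,
                    "stage_a_votes_noCAD": pred.stage_a_votes[0],
                    "stage_a_votes_CAD": pred.stage_a_votes[1],
                    "stage_b_votes_nonobstructive": (
                        pred.stage_b_votes[0] if pred.stage_b_votes else np.nan
                    ),
                    "stage_b_votes_obstructive": (
                        pred.stage_b_votes[1] if pred.stage_b_votes else np.nan
                    ),
                    "score_noCAD": 1.0 - p_a,
                    "score_nonobstructive": p_a * (1.0 - p_b),
                    "score_obstructive": p_a * p_b,
                }
            )
        return pd.DataFrame(records).set_index("patient_id")
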