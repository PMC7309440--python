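"""Human-readable reporting: per-patient decision-path explanations with
none/low/medium/high improvement buckets, and result tables.

The bucket labels are a communication device layered over the continuous
predicted improvement (more negative = more improvement); the edges are
configurable and default to within-cohort quartiles of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .shapley import TreeEnsemble, ensemble_from_lightgbm

BUCKET_LABELS = ("high", "medium", "low", "none")  # most to least improvement


def bucket_edges_from_predictions(predictions: np.ndarray) -> tuple[float, float, float]:
    """Default bucket edges: quartiles of the predicted improvement."""
    q1, q2, q3 = np.percentile(np.asarray(predictions, dtype=float), [25, 50, 75])
    return (float(q1), float(q2), float(q3))


def bucket_label(prediction: float, edges: Sequence[float]) -> str:
    """Map a predicted improvement to none/low/medium/high.

    ``edges`` are three ascending cut points; predictions at or below the
    lowest edge (most negative = most improvement) are "high".
    """
    if len(edges) != 3 or not all(edges[i] <= edges[i + 1] for i in range(2)):
        raise ValueError("edges must be three ascending cut points")
    idx = int(np.searchsorted(np.asarray(edges, dtype=float), prediction, side="left"))
    return BUCKET_LABELS[idx]


@dataclass
class PatientExplanation:
    subject_id: str
    symptom: int
    tree_index: int
    #: (feature name, threshold, direction, subject's value) per decision node
    path: list[tuple[str, float, str, float]]
    tree_prediction: float  # output of the displayed tree alone
    prediction: float  # full-ensemble prediction
    bucket: str

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "symptom": self.symptom,
            "tree_index": self.tree_index,
            "path": [
                {"feature": f, "threshold": t, "direction": d, "value": v}
                for f, t, d, v in self.path
            ],
            "tree_prediction": self.tree_prediction,
            "prediction": self.prediction,
            "bucket": self.bucket,
        }


def explain_patient(
    model,
    subject_row: pd.Series,
    bucket_edges: Sequence[float],
    symptom: int = 0,
    tree_index: int = 0,
) -> PatientExplanation:
    """Trace one subject through a designated tree of the ensemble.

    Left branches are taken when the feature value is at or below the
    decision boundary.  The bucket is assigned from the full-ensemble
    prediction under the configured edges.
    """
    ensemble = model if isinstance(model, TreeEnsemble) else ensemble_from_lightgbm(model)
    # the row must carry the model's features in training order (tree models
    # sanitise names internally, so alignment is positional)
    names = list(subject_row.index)
    if ensemble.feature_names and len(ensemble.feature_names) != len(names):
        raise KeyError(
            f"subject row has {len(names)} features, model expects "
            f"{len(ensemble.feature_names)}"
        )
    x = subject_row.to_numpy(dtype=float)
    tree = ensemble.trees[tree_index]
    raw_path = tree.decision_path(x)
    path = [(names[f], t, d, float(x[f])) for f, t, d in raw_path]
    leaf = tree.predict_one(x)
    pred = float(ensemble.predict(x[None, :])[0])
    return PatientExplanation(
        subject_id=str(subject_row.name),
        symptom=symptom,
        tree_index=tree_index,
        path=path,
        tree_prediction=float(leaf),
        prediction=pred,
        bucket=bucket_label(pred, bucket_edges),
    )


# ---------------------------------------------------------------------------
# Tables

def c_index_table(results: Sequence) -> pd.DataFrame:
    """Per-symptom discrimination table (symptom, C index, 95% CI)."""
    from .cohort import ITEM_NAMES

    rows = [
        {
            "item": r.symptom,
            "symptom": ITEM_NAMES[r.symptom - 1],
            "c_index": round(r.c, 3),
            "ci": f"{r.ci_low:.3f}-{r.ci_high:.3f}",
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def delta_c_table(deltas: dict[int, "object"]) -> pd.DataFrame:
    """Per-symptom paired C-index difference table."""
    from .cohort import ITEM_NAMES

    rows = [
        {
            "item": item,
            "symptom": ITEM_NAMES[item - 1],
            "delta_c": round(d.delta_c, 3),
            "ci": f"{d.ci_low:.3f} to {d.ci_high:.3f}",
            "significant": d.significant,
        }
        for item, d in sorted(deltas.items())
    ]
    return pd.DataFrame(rows)


def importance_table(percents: pd.Series, k: int = 3) -> pd.DataFrame:
    head = percents.head(k)
    return pd.DataFrame({"feature": head.index, "contribution_pct": head.round(1).values})
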