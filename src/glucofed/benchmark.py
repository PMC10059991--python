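"""Bundled per-subject benchmark scores for the statistics workflow.

These are the published weighted-F1 scores of the two competing training
regimes — federated grammatical evolution ("FLEA") versus fully
independent per-patient evolution ("non-FL") — evaluated as global models
on the twelve OhioT1DM subjects.  The raw CGM data set is
access-restricted and is not (and may not be) redistributed; only these
aggregate scores are shipped, as the worked input for the Quade
comparison protocol.

Layout: each regime contributes one selected global model.  Its score is
reported on the six learning subjects (559-591, the cross-evaluation row
of the selected model) and on six held-out subjects (540-596) that did
not participate in learning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import ResultMatrix

LEARNING_SUBJECTS = ["559", "563", "570", "575", "588", "591"]
HELDOUT_SUBJECTS = ["540", "544", "552", "567", "584", "596"]

#: Selected non-FL global model (model 570) on the six learning subjects.
NONFL_LEARNING_F1 = [0.7270, 0.7233, 0.8269, 0.6291, 0.7312, 0.6061]
#: Selected federated global model (model 575) on the six learning subjects.
FLEA_LEARNING_F1 = [0.7234, 0.7177, 0.8016, 0.6472, 0.7339, 0.6052]

#: The same two global models on the six held-out subjects.
NONFL_HELDOUT_F1 = [0.6075, 0.7024, 0.5748, 0.6193, 0.6504, 0.6524]
FLEA_HELDOUT_F1 = [0.6261, 0.7036, 0.6077, 0.6312, 0.6667, 0.6681]

#: Full cross-evaluation tables: row = model evolved for that subject,
#: column = subject whose test set it is scored on.
NONFL_CROSS_EVAL = pd.DataFrame(
    [
        [0.7006, 0.5731, 0.6803, 0.5878, 0.6823, 0.5486],
        [0.6820, 0.7072, 0.8294, 0.5679, 0.6975, 0.5635],
        [0.7270, 0.7233, 0.8269, 0.6291, 0.7312, 0.6061],
        [0.7052, 0.6726, 0.7657, 0.6423, 0.6935, 0.5866],
        [0.6466, 0.5395, 0.7167, 0.4996, 0.7310, 0.5134],
        [0.6577, 0.6913, 0.7579, 0.5637, 0.6761, 0.5796],
    ],
    index=[f"model {s}" for s in LEARNING_SUBJECTS],
    columns=LEARNING_SUBJECTS,
)

FLEA_CROSS_EVAL = pd.DataFrame(
    [
        [0.7304, 0.7210, 0.8047, 0.6337, 0.7320, 0.6015],
        [0.7278, 0.7141, 0.7947, 0.6113, 0.7193, 0.6043],
        [0.7194, 0.7312, 0.8314, 0.5986, 0.7235, 0.5952],
        [0.7234, 0.7177, 0.8016, 0.6472, 0.7339, 0.6052],
        [0.7260, 0.7287, 0.8206, 0.6230, 0.7216, 0.6020],
        [0.7260, 0.7214, 0.8180, 0.6199, 0.7291, 0.5932],
    ],
    index=[f"model {s}" for s in LEARNING_SUBJECTS],
    columns=LEARNING_SUBJECTS,
)

#: Held-out weighted precision/recall/F1/accuracy of the two global models
#: (two-decimal published rounding), per subject plus the average row.
HELDOUT_SCOREBOARD = pd.DataFrame(
    {
        "regime": ["flea"] * 6 + ["nonfl"] * 6,
        "subject": HELDOUT_SUBJECTS * 2,
        "precision": [0.64, 0.72, 0.65, 0.64, 0.69, 0.71,
                      0.62, 0.72, 0.62, 0.62, 0.67, 0.69],
        "recall": [0.63, 0.70, 0.60, 0.63, 0.67, 0.66,
                   0.61, 0.70, 0.58, 0.62, 0.66, 0.65],
        "f1": [0.63, 0.70, 0.61, 0.63, 0.67, 0.67,
               0.61, 0.70, 0.57, 0.62, 0.65, 0.65],
        "accuracy": [0.63, 0.70, 0.60, 0.63, 0.67, 0.66,
                     0.61, 0.70, 0.58, 0.62, 0.66, 0.65],
    }
)


def twelve_subject_matrix() -> ResultMatrix:
    """The 12 subjects x 2 regimes weighted-F1 table used for the Quade test.

    Column "FLEA" is its selected global model's score on all twelve
    subjects; column "non-FL" likewise for the independent regime.
    """
    flea = np.array(FLEA_LEARNING_F1 + FLEA_HELDOUT_F1)
    nonfl = np.array(NONFL_LEARNING_F1 + NONFL_HELDOUT_F1)
    return ResultMatrix(
        np.column_stack([flea, nonfl]),
        problems=LEARNING_SUBJECTS + HELDOUT_SUBJECTS,
        algorithms=["FLEA", "non-FL"],
    )
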