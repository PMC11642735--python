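"""Small bundled example datasets.

``AVIAN_ORDER_SCORES`` holds published per-order proxy scores for the
twelve well-sampled avian orders used when classifying clades by effective
population size: each order carries a range-size score, a trophic-level
score, and a body-mass score, each in {-1, 0, +1} (positive = smaller
populations).  Summing the three with :func:`karyorate.comparative.ne_index`
yields the order's population-size index and class.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["AVIAN_ORDER_SCORES", "avian_order_scores"]

#: order -> (range_score, trophic_score, mass_score)
AVIAN_ORDER_SCORES = {
    "Accipitriformes": (0, 1, 1),
    "Anseriformes": (-1, -1, 1),
    "Charadriiformes": (0, 1, 0),
    "Columbiformes": (0, -1, 0),
    "Galliformes": (1, -1, 1),
    "Gruiformes": (0, -1, 1),
    "Passeriformes": (0, 1, -1),
    "Pelecaniformes": (-1, 1, 1),
    "Piciformes": (0, 1, 0),
    "Psittaciformes": (1, -1, 0),
    "Strigiformes": (0, 1, 0),
    "Strisores": (0, 1, 0),
}


def avian_order_scores() -> pd.DataFrame:
    """The example per-order scores as a DataFrame."""
    return pd.DataFrame.from_dict(
        AVIAN_ORDER_SCORES, orient="index",
        columns=["range_score", "trophic_score", "mass_score"])
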