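"""Conditional expected values and the break-even-point statistic.

Expectations are probability-weighted averages of binding strength or
selective propensity over the combinations of a class ``k`` (and optionally
a subclass ``k_f``), with the probabilities renormalized within the cell so
they form a proper conditional distribution.

The break-even point (BEP) is the smallest degree ``k`` at which the
conditional probability of glioblastoma binding drops strictly below that of
either competing channel; the larger the BEP, the longer the nanoparticle
population stays tumor-directed as interactions stack up.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .affinity import CHANNEL_GCC, CHANNEL_NHC, CHANNEL_F, CHANNELS
from .enumeration import ProbabilityTable

KF_OVERALL = "overall"

_SP_COLUMN = {
    CHANNEL_GCC: "sp_gcc",
    CHANNEL_NHC: "sp_nhc",
    CHANNEL_F: "sp_f",
}


def expected_value(values: Sequence[float], probs: Sequence[float]) -> float:
    """Probability-weighted average; weights are renormalized to sum to 1."""
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if values.shape != probs.shape:
        raise ValueError("values and probs must have equal length")
    if (probs < 0).any():
        raise ValueError("probabilities must be >= 0")
    total = probs.sum()
    if total <= 0:
        raise ValueError("all probabilities are zero; expectation undefined")
    return float((values * probs).sum() / total)


def expectation_tables(
    ptable: ProbabilityTable, propensities: pd.DataFrame
) -> pd.DataFrame:
    """E(BST) and E(S_p) per (k, k_f, channel) and per-k overall.

    ``propensities`` is the per-(combination, k_f) frame from
    :func:`ccmen.propensity.propensity_frame`.  Each channel's expectation
    weights are that channel's probability rows renormalized within the
    (k, k_f) cell — or within the whole class for the ``"overall"`` rows.
    Cells carrying no probability mass are omitted.
    """
    frame = ptable.frame.merge(
        propensities[["codes", "kf", "sp_gcc", "sp_nhc", "sp_f"]],
        on=["codes", "kf"],
        how="left",
    )
    frame = frame[frame["p_abs"] > 0].copy()
    frame["sp"] = np.select(
        [frame["channel"] == ch for ch in CHANNELS],
        [frame[_SP_COLUMN[ch]] for ch in CHANNELS],
    )

    records = []
    for (k, kf, channel), cell in frame.groupby(["k", "kf", "channel"]):
        records.append(
            {
                "k": int(k),
                "kf": int(kf),
                "channel": channel,
                "e_bst": expected_value(cell["bst"], cell["p_abs"]),
                "e_sp": expected_value(cell["sp"], cell["p_abs"]),
            }
        )
    for (k, channel), cell in frame.groupby(["k", "channel"]):
        records.append(
            {
                "k": int(k),
                "kf": KF_OVERALL,
                "channel": channel,
                "e_bst": expected_value(cell["bst"], cell["p_abs"]),
                "e_sp": expected_value(cell["sp"], cell["p_abs"]),
            }
        )
    out = pd.DataFrame(records, columns=["k", "kf", "channel", "e_bst", "e_sp"])
    return out.reset_index(drop=True)


def break_even_point(dist: pd.DataFrame) -> int | None:
    """First degree where GCC's conditional probability loses the lead.

    ``dist`` is the per-k channel distribution from
    :func:`ccmen.enumeration.distribution_over_k`.  Returns the smallest k
    with CP(k, GCC) strictly below max(CP(k, NHC), CP(k, F)), or ``None``
    when the glioblastoma channel never falls behind.
    """
    for k in sorted(dist.index):
        row = dist.loc[k]
        if row[CHANNEL_GCC] < max(row[CHANNEL_NHC], row[CHANNEL_F]):
            return int(k)
    return None
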