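"""Selective-propensity geometry.

The three channel binding strengths of a configuration are read as a vector
``(BST_GCC, BST_NHC, BST_F)`` in a 3-D interaction space.  The selective
propensity toward a channel is the complement of the angle between that
vector and the channel's axis:

    S_p,T = 90 deg - arccos(BST_T / ||BST||)

so an axis-aligned vector scores 90 deg on its channel and 0 deg on the
others.  Because the squared direction cosines sum to one, at most one
channel can exceed 45 deg; a configuration with a channel strictly above
45 deg is classified toward it, otherwise it has no net directional
preference (NNDP).  The zero vector has undefined angles and is NNDP by
convention so that inert configurations never abort a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np
import pandas as pd

from .affinity import CHANNEL_GCC, CHANNEL_NHC, CHANNEL_F
from .enumeration import BSTVector

DIRECTION_NNDP = "NNDP"
DIRECTIONS = (CHANNEL_GCC, CHANNEL_NHC, CHANNEL_F, DIRECTION_NNDP)

#: default decision threshold, degrees
DEFAULT_THRESHOLD = 45.0


@dataclass(frozen=True)
class PropensityVector:
    """Per-channel selective propensities in degrees (NaN for a zero vector)."""

    sp_gcc: float
    sp_nhc: float
    sp_f: float

    @property
    def defined(self) -> bool:
        return not (isnan(self.sp_gcc) or isnan(self.sp_nhc) or isnan(self.sp_f))

    def channel(self, name: str) -> float:
        return {
            CHANNEL_GCC: self.sp_gcc,
            CHANNEL_NHC: self.sp_nhc,
            CHANNEL_F: self.sp_f,
        }[name]


def selective_propensity(bst: BSTVector) -> PropensityVector:
    """Selective propensities of one binding-strength vector."""
    v = bst.as_array()
    peak = float(v.max())
    if peak == 0.0:
        return PropensityVector(np.nan, np.nan, np.nan)
    u = v / peak  # angles are scale invariant; rescaling avoids under/overflow
    r = float(np.linalg.norm(u))
    sp = 90.0 - np.degrees(np.arccos(np.clip(u / r, -1.0, 1.0)))
    return PropensityVector(*map(float, sp))


def classify_direction(
    sp: PropensityVector, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """The unique channel strictly above the threshold, else NNDP."""
    if not sp.defined:
        return DIRECTION_NNDP
    winners = [
        ch
        for ch in (CHANNEL_GCC, CHANNEL_NHC, CHANNEL_F)
        if sp.channel(ch) > threshold
    ]
    if len(winners) > 1:  # impossible for threshold >= 45 (cos^2 identity)
        raise AssertionError(f"multiple channels above {threshold} deg: {winners}")
    return winners[0] if winners else DIRECTION_NNDP


def propensity_frame(
    triples: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Vectorized propensities + direction for a frame of BST triples.

    ``triples`` must carry columns ``bst_gcc``, ``bst_nhc``, ``bst_f`` (one
    row per (combination, k_f), see :func:`ccmen.enumeration.bst_triples`);
    the returned copy adds ``sp_gcc``, ``sp_nhc``, ``sp_f`` (NaN for zero
    vectors) and ``direction``.
    """
    out = triples.copy()
    v = out[["bst_gcc", "bst_nhc", "bst_f"]].to_numpy(dtype=float)
    peak = v.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(peak > 0, v / peak, np.nan)  # rescale against underflow
    r = np.linalg.norm(np.nan_to_num(u), axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = u / r
    sp = 90.0 - np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
    out["sp_gcc"], out["sp_nhc"], out["sp_f"] = sp[:, 0], sp[:, 1], sp[:, 2]

    filled = np.nan_to_num(sp, nan=-np.inf)
    best = filled.argmax(axis=1)
    direction = np.full(len(out), DIRECTION_NNDP, dtype=object)
    above = filled[np.arange(len(out)), best] > threshold
    channels = np.array([CHANNEL_GCC, CHANNEL_NHC, CHANNEL_F], dtype=object)
    direction[above] = channels[best[above]]
    out["direction"] = direction
    return out
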