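"""Population-level bookkeeping: fractions, odds ratios, culture modes.

Each (combination, k_f) subclass is classified toward GCC, NHC, F or NNDP by
its propensity geometry; the probability mass of all its configurations is
then pooled on that direction.  The headline prediction redistributes the
NNDP mass equally over the three real fates (an undirected particle ends up
somewhere), while intermediate outputs keep the raw NNDP share so the
bookkeeping stays auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from .affinity import (
    CBETable,
    CHANNEL_GCC,
    CHANNEL_NHC,
    CHANNEL_F,
    CHANNELS,
    zero_channel,
)
from .enumeration import (
    ProbabilityTable,
    bst_triples,
    class_probabilities,
    distribution_over_k,
    enumerate_configurations,
)
from .expectation import break_even_point, expectation_tables
from .propensity import DEFAULT_THRESHOLD, DIRECTION_NNDP, DIRECTIONS, propensity_frame

MODE_CULTURE_I = "culture_I"
MODE_CULTURE_II = "culture_II"
MODES = (MODE_CULTURE_I, MODE_CULTURE_II)


@dataclass(frozen=True)
class PopulationSummary:
    """Fractional directional preference of the exposed particle population.

    ``fractions`` holds the raw shares per direction (including NNDP);
    ``redistributed`` the headline shares after splitting NNDP equally.
    ``per_node`` is the (k, k_f, direction) mass table feeding the network
    plots; ``odds`` the per-channel odds ratios (may contain ``inf``/``nan``
    on degenerate fractions); ``bep`` the break-even point or ``None``.
    """

    mode: str
    threshold: float
    fractions: Mapping[str, float]
    redistributed: Mapping[str, float]
    per_node: pd.DataFrame
    odds: Mapping[str, float]
    bep: int | None

    @property
    def frac_gcc(self) -> float:
        return self.fractions[CHANNEL_GCC]

    @property
    def frac_nhc(self) -> float:
        return self.fractions[CHANNEL_NHC]

    @property
    def frac_f(self) -> float:
        return self.fractions[CHANNEL_F]

    @property
    def frac_nndp(self) -> float:
        return self.fractions[DIRECTION_NNDP]


@dataclass
class ModelRun:
    """Every intermediate table of one full model evaluation."""

    cbe: CBETable
    mode: str
    threshold: float
    ptable: ProbabilityTable
    propensities: pd.DataFrame  # per (combination, k_f): BST triple, S_p, direction
    distribution: pd.DataFrame  # per-k conditional channel probabilities + mass
    expectations: pd.DataFrame  # E(BST), E(S_p) per (k, kf, channel)
    summary: PopulationSummary


def population_fractions(
    ptable: ProbabilityTable,
    propensities: pd.DataFrame,
    mode: str = MODE_CULTURE_II,
    threshold: float = DEFAULT_THRESHOLD,
) -> PopulationSummary:
    """Pool probability mass by classified direction.

    ``propensities`` must carry ``codes``, ``kf`` and ``direction`` columns
    (see :func:`ccmen.propensity.propensity_frame`).
    """
    mass = (
        ptable.frame.groupby(["codes", "k", "kf"], as_index=False)["p_abs"]
        .sum()
        .merge(propensities[["codes", "kf", "direction"]], on=["codes", "kf"])
    )
    fractions = {d: 0.0 for d in DIRECTIONS}
    for direction, share in mass.groupby("direction")["p_abs"].sum().items():
        fractions[str(direction)] = float(share)

    per_node = (
        mass.groupby(["k", "kf", "direction"], as_index=False)["p_abs"]
        .sum()
        .rename(columns={"p_abs": "fraction"})
        .sort_values(["k", "kf", "direction"])
        .reset_index(drop=True)
    )

    odds = {ch: odds_ratio(fractions, ch) for ch in CHANNELS}
    dist = distribution_over_k(ptable)
    summary = PopulationSummary(
        mode=mode,
        threshold=threshold,
        fractions=fractions,
        redistributed={},
        per_node=per_node,
        odds=odds,
        bep=break_even_point(dist),
    )
    return replace(summary, redistributed=redistribute_nndp(summary).fractions)


def redistribute_nndp(summary: PopulationSummary) -> PopulationSummary:
    """Split the NNDP share equally over GCC, NHC and F.

    An undirected particle still binds one of the three fates eventually;
    lacking any preference its mass is apportioned uniformly.  Conserves the
    total.
    """
    share = summary.fractions[DIRECTION_NNDP] / 3.0
    fractions = {
        CHANNEL_GCC: summary.fractions[CHANNEL_GCC] + share,
        CHANNEL_NHC: summary.fractions[CHANNEL_NHC] + share,
        CHANNEL_F: summary.fractions[CHANNEL_F] + share,
        DIRECTION_NNDP: 0.0,
    }
    return replace(summary, fractions=fractions, redistributed=fractions)


def odds_ratio(fractions: Mapping[str, float] | PopulationSummary, channel: str) -> float:
    """Odds of the channel's fraction against the mean competing fraction.

    With ``f`` the channel's share of classified mass and ``g`` the mean of
    the two competing channels' shares, returns [f/(1-f)] / [g/(1-g)].
    Degenerate shares (0 or 1) yield ``inf`` or ``nan`` rather than raising,
    so zeroed channels do not abort a run.
    """
    if isinstance(fractions, PopulationSummary):
        fractions = fractions.fractions
    if channel not in CHANNELS:
        raise KeyError(f"unknown channel {channel!r}")
    others = [c for c in CHANNELS if c != channel]
    f = fractions[channel]
    g = (fractions[others[0]] + fractions[others[1]]) / 2.0

    def _odds(x: float) -> float:
        if x >= 1.0:
            return math.inf
        return x / (1.0 - x)

    of, og = _odds(f), _odds(g)
    if og == 0.0:
        return math.inf if of > 0 else math.nan
    if math.isinf(og):
        return math.nan if math.isinf(of) else 0.0
    return of / og


def evaluate(
    cbe: CBETable,
    mode: str = MODE_CULTURE_II,
    threshold: float = DEFAULT_THRESHOLD,
) -> ModelRun:
    """Run the full model on one CBE table: enumeration through summary."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not 0.0 < threshold < 90.0:
        raise ValueError(f"threshold must lie in (0, 90) degrees, got {threshold}")
    if mode == MODE_CULTURE_I:
        cbe = zero_channel(cbe, CHANNEL_NHC)
    n = cbe.n
    ptable = class_probabilities(enumerate_configurations(n), cbe)
    props = propensity_frame(bst_triples(n, cbe), threshold=threshold)
    dist = distribution_over_k(ptable)
    expectations = expectation_tables(ptable, props)
    summary = population_fractions(ptable, props, mode=mode, threshold=threshold)
    return ModelRun(
        cbe=cbe,
        mode=mode,
        threshold=threshold,
        ptable=ptable,
        propensities=props,
        distribution=dist,
        expectations=expectations,
        summary=summary,
    )


def run_culture_mode(
    cbe: CBETable,
    mode: str = MODE_CULTURE_II,
    threshold: float = DEFAULT_THRESHOLD,
) -> PopulationSummary:
    """Population summary under a culture mode.

    ``culture_I`` models a culture without normal cells by zeroing the NHC
    channel before enumeration; ``culture_II`` uses all three channels.
    """
    return evaluate(cbe, mode=mode, threshold=threshold).summary
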