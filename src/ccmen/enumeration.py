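"""Exhaustive enumeration of interaction classes and their probabilities.

A binding event engages ``k`` of the ``n`` nanoparticle surface proteins
simultaneously (the *degree of interaction*); of those, ``k_f`` are engaged
by soluble factors rather than a cell surface (the *degree of factor
interaction*).  Model assumptions:

1. a combination interacts with GCC only, GCC+F, NHC only, NHC+F or F only;
2. it can never touch GCC and NHC at once — the cell branch is exclusive;
3. at least one surface protein interacts;
4. ``k_f = k`` means no cell interaction at all (the F-only branch);
5. factor-factor interactions do not occur;
6. every other contact contributes no directional mass.

For each combination and each ``k_f`` the binding strength (BST) toward a
channel is averaged over the C(k, k_f) equally likely assignments of which
members bind factors; by exchangeability this equals the channel CBE sum
scaled by the cell share ``(k - k_f)/k`` (or the factor share ``k_f/k``).
Probability mass is taken proportional to BST: each configuration's branch
channel contributes its BST as weight, every configuration with ``k_f > 0``
additionally contributes its factor BST as F-channel weight, and the grand
total normalizes to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from math import comb
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .affinity import CBETable, CHANNEL_GCC, CHANNEL_NHC, CHANNEL_F, CHANNELS
from .errors import DegenerateModelError

BRANCH_GCC = CHANNEL_GCC
BRANCH_NHC = CHANNEL_NHC
BRANCH_F_ONLY = "F_only"

#: global normalization tolerance
NORMALIZATION_ATOL = 1e-9


@dataclass(frozen=True)
class Combination:
    """A set of receptor codes acting together in one binding event."""

    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes) or tuple(sorted(self.codes)) != self.codes:
            raise ValueError("codes must be sorted and distinct")
        if not self.codes or min(self.codes) < 1:
            raise ValueError("codes must be a nonempty subset of 1..n")

    @property
    def k(self) -> int:
        return len(self.codes)

    @property
    def label(self) -> str:
        """Receptor codes joined by '-', the Prot_comb convention."""
        return "-".join(str(c) for c in self.codes)


@dataclass(frozen=True)
class Configuration:
    """A combination with a factor-bound count and a cell branch."""

    codes: tuple[int, ...]
    k_f: int
    branch: str

    def __post_init__(self) -> None:
        k = len(self.codes)
        if not 0 <= self.k_f <= k:
            raise ValueError(f"k_f must lie in 0..{k}, got {self.k_f}")
        if self.branch == BRANCH_F_ONLY:
            if self.k_f != k:
                raise ValueError("F_only branch requires k_f == k")
        elif self.branch in (BRANCH_GCC, BRANCH_NHC):
            if self.k_f == k:
                raise ValueError("cell branches require k_f < k")
        else:
            raise ValueError(f"unknown branch {self.branch!r}")

    @property
    def k(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class BSTVector:
    """Binding strengths toward the three channels for one (combination, k_f)."""

    gcc: float
    nhc: float
    f: float

    def __post_init__(self) -> None:
        if min(self.gcc, self.nhc, self.f) < 0:
            raise ValueError("binding strengths must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.gcc, self.nhc, self.f], dtype=float)


def count_combinations(n: int, k: int) -> int:
    """Number of receptor combinations of degree ``k`` out of ``n``."""
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    return comb(n, k)


def count_configurations(n: int) -> int:
    """Total configuration count: sum over k of C(n,k) * (2k + 1)."""
    return sum(count_combinations(n, k) * (2 * k + 1) for k in range(1, n + 1))


def enumerate_configurations(n: int) -> Iterator[Configuration]:
    """Yield every configuration exactly once, in the fixed output order.

    Order: degree ``k`` ascending, combinations lexicographic by codes,
    ``k_f`` ascending; within a cell subclass the GCC branch precedes NHC.
    The F-only subclass (``k_f = k``) is emitted once, not per cell branch.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    for k in range(1, n + 1):
        for codes in _combinations(range(1, n + 1), k):
            for k_f in range(k + 1):
                if k_f == k:
                    yield Configuration(codes=codes, k_f=k_f, branch=BRANCH_F_ONLY)
                else:
                    yield Configuration(codes=codes, k_f=k_f, branch=BRANCH_GCC)
                    yield Configuration(codes=codes, k_f=k_f, branch=BRANCH_NHC)


def configuration_bst(config: Configuration, cbe: CBETable) -> BSTVector:
    """Assignment-averaged binding strengths of one configuration.

    Averaging the per-assignment channel sums over all C(k, k_f) factor
    assignments leaves each member cell-bound with probability
    ``(k - k_f)/k``, so the cell channels are the CBE sums scaled by that
    share and the factor channel by ``k_f/k``.  The full triple is returned
    regardless of branch; the branch only decides which entries carry
    probability mass.
    """
    k = config.k
    cell_share = (k - config.k_f) / k
    factor_share = config.k_f / k
    sum_gcc = sum(cbe.gcc[c] for c in config.codes)
    sum_nhc = sum(cbe.nhc[c] for c in config.codes)
    sum_f = sum(cbe.f[c] for c in config.codes)
    return BSTVector(
        gcc=cell_share * sum_gcc, nhc=cell_share * sum_nhc, f=factor_share * sum_f
    )


@dataclass
class ProbabilityTable:
    """All probability-carrying rows of the model plus the normalizer.

    ``frame`` has one row per (configuration, channel) weight: columns
    ``codes`` (tuple), ``k``, ``kf``, ``branch``, ``channel``, ``bst``
    (the channel binding strength), ``weight`` (unnormalized mass),
    ``p_abs`` (weight / Z) and ``cp_within_k`` (renormalized within each k).
    """

    frame: pd.DataFrame
    z: float
    n: int


def class_probabilities(
    configs: Iterable[Configuration], cbe: CBETable
) -> ProbabilityTable:
    """BST-proportional probability mass over every configuration.

    Raises :class:`DegenerateModelError` when no configuration carries any
    binding strength (all CBE zero), violating the at-least-one-interaction
    assumption.
    """
    rows: list[dict] = []
    for config in configs:
        bst = configuration_bst(config, cbe)
        base = {"codes": config.codes, "k": config.k, "kf": config.k_f,
                "branch": config.branch}
        if config.branch == BRANCH_F_ONLY:
            rows.append({**base, "channel": CHANNEL_F, "bst": bst.f})
        else:
            cell_bst = bst.gcc if config.branch == BRANCH_GCC else bst.nhc
            rows.append({**base, "channel": config.branch, "bst": cell_bst})
            if config.k_f > 0:
                rows.append({**base, "channel": CHANNEL_F, "bst": bst.f})
    frame = pd.DataFrame(rows)
    frame["weight"] = frame["bst"]
    z = float(frame["weight"].sum())
    if z <= 0:
        raise DegenerateModelError(
            "every conditional binding efficiency is zero; the model carries no mass"
        )
    frame["p_abs"] = frame["weight"] / z
    mass_k = frame.groupby("k")["p_abs"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["cp_within_k"] = np.where(mass_k > 0, frame["p_abs"] / mass_k, 0.0)
    n = int(frame["k"].max())
    return ProbabilityTable(frame=frame, z=z, n=n)


def bst_triples(n: int, cbe: CBETable) -> pd.DataFrame:
    """One row per (combination, k_f): the full BST triple.

    Shared by the propensity geometry and the BST output files; branch
    bookkeeping does not enter here because the triple is branch-independent.
    """
    rows = []
    for k in range(1, n + 1):
        for codes in _combinations(range(1, n + 1), k):
            sum_gcc = sum(cbe.gcc[c] for c in codes)
            sum_nhc = sum(cbe.nhc[c] for c in codes)
            sum_f = sum(cbe.f[c] for c in codes)
            for k_f in range(k + 1):
                cell = (k - k_f) / k
                fac = k_f / k
                rows.append(
                    {
                        "codes": codes,
                        "k": k,
                        "kf": k_f,
                        "bst_gcc": cell * sum_gcc,
                        "bst_nhc": cell * sum_nhc,
                        "bst_f": fac * sum_f,
                    }
                )
    return pd.DataFrame(rows)


def distribution_over_k(ptable: ProbabilityTable) -> pd.DataFrame:
    """Per-degree channel distribution.

    Returns a frame indexed by ``k`` with the conditional probabilities
    ``GCC``/``NHC``/``F`` (summing to 1 within each k) and the absolute
    per-degree mass in column ``mass``.
    """
    grouped = (
        ptable.frame.groupby(["k", "channel"])["p_abs"].sum().unstack(fill_value=0.0)
    )
    for channel in CHANNELS:
        if channel not in grouped.columns:
            grouped[channel] = 0.0
    grouped = grouped[list(CHANNELS)]
    grouped = grouped.reindex(range(1, ptable.n + 1), fill_value=0.0)
    mass = grouped.sum(axis=1)
    cond = grouped.div(mass.where(mass > 0), axis=0).fillna(0.0)
    cond["mass"] = mass
    cond.index.name = "k"
    return cond
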