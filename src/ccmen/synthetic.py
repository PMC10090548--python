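"""Synthetic model inputs.

The real binding-score matrices behind the published analysis live in an
external repository, so the pipeline is exercised on generated conditional
binding efficiencies with controllable directional structure: each channel's
per-receptor CBE is its level times multiplicative lognormal noise (affinity
and expression both act multiplicatively, and lognormal noise keeps CBEs
nonnegative).  The defaults encode the regime the model was built for —
homotypic tumor binding modestly stronger per receptor than cognate factor
sequestration, with the normal-cell channel an order of magnitude weaker —
see docs/methods.md for the rationale.

The verbatim published expression table (11 receptor/factor pairs) ships as
packaged data and is exposed via :func:`table1_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import CBETable
from .expression import ExpressionTable, table_from_frame


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic CBE table.

    ``gcc_bias``, ``nhc_level`` and ``factor_level`` are the expected CBE per
    receptor on each channel (arbitrary units — only ratios matter, since the
    probability model is scale invariant); ``noise_cv`` the coefficient of
    variation of the multiplicative lognormal noise.
    """

    n_receptors: int = 11
    gcc_bias: float = 1.63
    nhc_level: float = 0.1
    factor_level: float = 1.0
    noise_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptors < 1:
            raise ValueError("n_receptors must be >= 1")
        if min(self.gcc_bias, self.nhc_level, self.factor_level, self.noise_cv) < 0:
            raise ValueError("channel levels and noise_cv must be >= 0")


def generate_cbe_tables(spec: SyntheticSpec) -> CBETable:
    """Seeded synthetic CBE triples with expected channel means per the spec.

    With ``noise_cv == 0`` every receptor's triple equals
    (gcc_bias, nhc_level, factor_level) exactly; otherwise each entry is the
    level times a unit-mean lognormal draw with the requested coefficient of
    variation.  Identical specs produce bit-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_receptors
    levels = (spec.gcc_bias, spec.nhc_level, spec.factor_level)
    if spec.noise_cv == 0:
        draws = np.ones((3, n))
    else:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        draws = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=(3, n))
    channels = [
        {code: float(level * draws[i, code - 1]) for code in range(1, n + 1)}
        for i, level in enumerate(levels)
    ]
    return CBETable(gcc=channels[0], nhc=channels[1], f=channels[2])


def write_synthetic_inputs(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write cmcc.csv / cmnc.csv / cmf.csv (plus the expression
    fixture when the receptor count matches its 11 pairs)."""
    outdir = Path(outdir)
    cbe = generate_cbe_tables(spec)
    paths = cbe.write(outdir)
    fixture = table1_fixture()
    if spec.n_receptors == fixture.n:
        paths["expression.csv"] = fixture.write(outdir / "expression.csv")
    return paths


def table1_fixture() -> ExpressionTable:
    """The packaged published expression table (11 receptors, 11 factors)."""
    with resources.files("ccmen.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return table_from_frame(df)
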