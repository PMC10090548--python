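"""Conditional binding efficiencies (CBE).

An intrinsic binding score (BS, from protein-protein docking) between a
nanoparticle surface protein and a partner is conditioned on how strongly the
two partners are actually expressed:

    CBE = BS * min(NEX_ccmen, NEX_target) * min(FC_ccmen, FC_target)

i.e. the score is scaled by the lower of the two native expression levels and
the lower of the two glioblastoma fold changes — binding cannot be more
available than its scarcer partner.  Three CBE channels are kept per
receptor: toward glioblastoma cells (GCC, homotypic receptor-receptor
binding), toward normal healthy cells (NHC, same score but normal-side fold
change is 1 by construction), and toward the secreted factor ligand (F).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import StructureError
from .expression import ExpressionTable

CHANNEL_GCC = "GCC"
CHANNEL_NHC = "NHC"
CHANNEL_F = "F"
CHANNELS = (CHANNEL_GCC, CHANNEL_NHC, CHANNEL_F)

PAIRING_COGNATE = "cognate"
PAIRING_MAX = "max_over_factors"


def compute_cbe(
    bs: float,
    nex_ccmen: float,
    nex_target: float,
    fc_ccmen: float,
    fc_target: float,
) -> float:
    """Conditional binding efficiency of one score under two expression pairs."""
    for name, v in (
        ("bs", bs),
        ("nex_ccmen", nex_ccmen),
        ("nex_target", nex_target),
        ("fc_ccmen", fc_ccmen),
        ("fc_target", fc_target),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return bs * min(nex_ccmen, nex_target) * min(fc_ccmen, fc_target)


@dataclass(frozen=True)
class BindingScoreSet:
    """Intrinsic binding scores keyed by receptor code.

    ``cell``: homotypic receptor-vs-same-receptor score (nanoparticle coat
    against the identical protein on a target cell membrane).
    ``factor``: receptor-vs-factor scores keyed by (receptor code, factor
    code); the cognate pairing sits on the diagonal.
    """

    cell: Mapping[int, float]
    factor: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cell.values()) or any(
            v < 0 for v in self.factor.values()
        ):
            raise StructureError("binding scores must be >= 0")


@dataclass(frozen=True)
class CBETable:
    """Per-receptor conditional binding efficiencies for the three channels."""

    gcc: Mapping[int, float]
    nhc: Mapping[int, float]
    f: Mapping[int, float]

    def __post_init__(self) -> None:
        keys = set(self.gcc)
        if set(self.nhc) != keys or set(self.f) != keys:
            raise StructureError("the three CBE channels must share one receptor set")
        if not keys:
            raise StructureError("CBE table is empty")
        for channel in (self.gcc, self.nhc, self.f):
            if any(v < 0 for v in channel.values()):
                raise StructureError("CBE values must be >= 0")

    @property
    def n(self) -> int:
        return len(self.gcc)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(sorted(self.gcc))

    def channel(self, name: str) -> Mapping[int, float]:
        try:
            return {CHANNEL_GCC: self.gcc, CHANNEL_NHC: self.nhc, CHANNEL_F: self.f}[
                name
            ]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")

    def scaled(self, factor: float) -> "CBETable":
        """Every CBE multiplied by ``factor`` (used for invariance checks)."""
        return CBETable(
            gcc={c: v * factor for c, v in self.gcc.items()},
            nhc={c: v * factor for c, v in self.nhc.items()},
            f={c: v * factor for c, v in self.f.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        codes = self.codes
        return pd.DataFrame(
            {
                "code": codes,
                "cbe_gcc": [self.gcc[c] for c in codes],
                "cbe_nhc": [self.nhc[c] for c in codes],
                "cbe_f": [self.f[c] for c in codes],
            }
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three channels as cmcc.csv / cmnc.csv / cmf.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for fname, channel in (
            ("cmcc.csv", self.gcc),
            ("cmnc.csv", self.nhc),
            ("cmf.csv", self.f),
        ):
            path = outdir / fname
            pd.Series([channel[c] for c in self.codes], name="cbe").to_csv(
                path, index=False
            )
            paths[fname] = path
        return paths


def build_cbe_tables(
    bs: BindingScoreSet,
    expr_ccmen: ExpressionTable,
    expr_gcc: ExpressionTable | None = None,
    expr_nhc: ExpressionTable | None = None,
    expr_f: ExpressionTable | None = None,
    pairing: str = PAIRING_COGNATE,
) -> CBETable:
    """Derive the three CBE channels from binding scores and expression tables.

    The nanoparticle coat is extruded glioblastoma membrane, so by default
    the CCMEN side shares the GCC expression table.  The NHC channel uses the
    homotypic score with the normal-side fold change fixed at 1 (fold change
    is defined glioblastoma-vs-normal, making the normal cell the reference).
    The factor channel pairs each receptor with its cognate factor, or with
    the best-scoring factor when ``pairing="max_over_factors"``.
    """
    expr_gcc = expr_gcc or expr_ccmen
    expr_nhc = expr_nhc or expr_ccmen
    expr_f = expr_f or expr_ccmen
    if pairing not in (PAIRING_COGNATE, PAIRING_MAX):
        raise ValueError(f"unknown pairing mode {pairing!r}")

    gcc: dict[int, float] = {}
    nhc: dict[int, float] = {}
    fch: dict[int, float] = {}
    for rec in expr_ccmen.receptors:
        code = rec.code
        if code not in bs.cell:
            raise KeyError(f"no homotypic binding score for receptor code {code}")
        r_gcc = expr_gcc.receptor(code)
        r_nhc = expr_nhc.receptor(code)
        gcc[code] = compute_cbe(bs.cell[code], rec.nex, r_gcc.nex, rec.fc, r_gcc.fc)
        nhc[code] = compute_cbe(bs.cell[code], rec.nex, r_nhc.nex, rec.fc, 1.0)

        if pairing == PAIRING_COGNATE:
            fcode = expr_ccmen.cognate[code]
            if (code, fcode) not in bs.factor:
                raise KeyError(
                    f"no binding score for receptor {code} vs cognate factor {fcode}"
                )
            fac = expr_f.factor(fcode)
            fch[code] = compute_cbe(
                bs.factor[(code, fcode)], rec.nex, fac.nex, rec.fc, fac.fc
            )
        else:
            candidates = [
                compute_cbe(score, rec.nex, expr_f.factor(fcode).nex, rec.fc, expr_f.factor(fcode).fc)
                for (rcode, fcode), score in bs.factor.items()
                if rcode == code
            ]
            if not candidates:
                raise KeyError(f"no factor binding scores for receptor code {code}")
            fch[code] = max(candidates)
    return CBETable(gcc=gcc, nhc=nhc, f=fch)


def load_binding_scores(path: str | Path) -> BindingScoreSet:
    """Read a long-format score file: receptor_code,target_code,channel,score.

    ``channel`` is ``cell`` for homotypic receptor-receptor scores (the
    target code must equal the receptor code) or ``factor`` for
    receptor-vs-factor scores.
    """
    df = pd.read_csv(path)
    required = {"receptor_code", "target_code", "channel", "score"}
    missing = required - set(df.columns)
    if missing:
        raise StructureError(
            f"binding-score file {path} missing column(s): {sorted(missing)}"
        )
    cell: dict[int, float] = {}
    factor: dict[tuple[int, int], float] = {}
    for _, row in df.iterrows():
        rcode, tcode = int(row["receptor_code"]), int(row["target_code"])
        score = float(row["score"])
        if row["channel"] == "cell":
            if tcode != rcode:
                raise StructureError(
                    f"homotypic score rows must have target_code == receptor_code "
                    f"(got {rcode} vs {tcode})"
                )
            cell[rcode] = score
        elif row["channel"] == "factor":
            factor[(rcode, tcode)] = score
        else:
            raise StructureError(f"unknown score channel {row['channel']!r}")
    return BindingScoreSet(cell=cell, factor=factor)


def load_cbe_matrix(
    path: str | Path, reduce: str = "diagonal"
) -> dict[int, float]:
    """Load one CBE channel file (cmcc.csv / cmnc.csv / cmf.csv style).

    One row per receptor in code order.  A single-column file is read as the
    per-receptor CBE vector directly; an n-by-n file (receptor-by-factor) is
    reduced to a vector via its diagonal (cognate pairing, default) or its
    row maximum (``reduce="max"``).  A header row is optional.
    """
    df = pd.read_csv(path, header=None)
    # drop an optional header row (any non-numeric cell in the first row)
    first = df.iloc[0]
    if pd.to_numeric(first, errors="coerce").isna().any():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise StructureError(f"non-numeric CBE entry in {path}") from exc
    if (values < 0).any():
        raise StructureError(f"negative CBE entry in {path}")
    nrow, ncol = values.shape
    if ncol == 1:
        vec = values[:, 0]
    else:
        if ncol != nrow:
            raise StructureError(
                f"CBE matrix in {path} must be a column or square, got {values.shape}"
            )
        if reduce == "diagonal":
            vec = np.diag(values)
        elif reduce == "max":
            vec = values.max(axis=1)
        else:
            raise ValueError(f"unknown reduce mode {reduce!r}")
    return {code: float(v) for code, v in enumerate(vec, start=1)}


def load_cbe_tables(
    gcc_path: str | Path,
    nhc_path: str | Path,
    f_path: str | Path,
    reduce: str = "diagonal",
) -> CBETable:
    """Assemble a :class:`CBETable` from the three channel files."""
    gcc = load_cbe_matrix(gcc_path, reduce=reduce)
    nhc = load_cbe_matrix(nhc_path, reduce=reduce)
    f = load_cbe_matrix(f_path, reduce=reduce)
    if not (len(gcc) == len(nhc) == len(f)):
        raise StructureError(
            f"channel files disagree on receptor count: {len(gcc)}/{len(nhc)}/{len(f)}"
        )
    return CBETable(gcc=gcc, nhc=nhc, f=f)


def zero_channel(table: CBETable, channel: str) -> CBETable:
    """Return a copy with one channel replaced by all zeros.

    Zeroing the NHC channel reproduces a culture without normal cells
    (test-culture-I mode); the other channels are untouched.
    """
    zeros = {c: 0.0 for c in table.codes}
    if channel == CHANNEL_GCC:
        return replace(table, gcc=zeros)
    if channel == CHANNEL_NHC:
        return replace(table, nhc=zeros)
    if channel == CHANNEL_F:
        return replace(table, f=zeros)
    raise KeyError(f"unknown channel {channel!r}")
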