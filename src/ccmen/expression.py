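"""Surface-protein expression tables.

The model's expression inputs are a paired list of membrane receptors and
their secreted cognate factors (ligands), each with a native expression level
on normal brain tissue (``nex``, arbitrary units), an expression level
relative to a baseline gene (``rnx``), and a glioblastoma-vs-normal fold
change (``fc``).  The baseline is by convention the factor with the lowest
native expression, so that every ``rnx`` is a dimensionless ratio >= 1 apart
from the baseline itself (``rnx == 1``).

Receptor ``i`` and factor ``i`` share a numeric code (row order), encoding
the cognate receptor/ligand pairing (e.g. PDGFRA with PDGF); a different
pairing can be supplied explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError, StructureError

ROLE_RECEPTOR = "receptor"
ROLE_FACTOR = "factor"
ROLES = (ROLE_RECEPTOR, ROLE_FACTOR)

#: relative tolerance beyond which a supplied rnx is reported as inconsistent
RNX_WARN_RTOL = 0.01

_REQUIRED_COLUMNS = ("gene", "role", "nex", "fc")


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression entry.

    Parameters
    ----------
    gene : str
        Gene symbol.
    role : str
        Either ``"receptor"`` or ``"factor"``.
    code : int
        1-based numeric code (row order within the role).
    nex : float
        Native expression on normal tissue, arbitrary units (>= 0).
    rnx : float
        Expression relative to the baseline gene (nex / nex_baseline).
    fc : float
        Glioblastoma fold change versus normal tissue (> 0).
    """

    gene: str
    role: str
    code: int
    nex: float
    rnx: float
    fc: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise StructureError(f"unknown role {self.role!r} for gene {self.gene}")
        if not self.nex >= 0:
            raise StructureError(f"nex must be >= 0, got {self.nex} for {self.gene}")
        if not self.fc > 0:
            raise StructureError(f"fc must be > 0, got {self.fc} for {self.gene}")


@dataclass(frozen=True)
class ExpressionTable:
    """Paired receptor/factor expression table.

    ``cognate`` maps receptor code -> factor code and must be a bijection
    over ``1..n``; the default (row-order) pairing is the identity.
    """

    receptors: tuple[ExpressionRecord, ...]
    factors: tuple[ExpressionRecord, ...]
    baseline_gene: str
    cognate: Mapping[int, int]

    def __post_init__(self) -> None:
        if len(self.receptors) != len(self.factors):
            raise StructureError(
                f"receptor/factor count mismatch: {len(self.receptors)} vs {len(self.factors)}"
            )
        n = len(self.receptors)
        if n == 0:
            raise StructureError("expression table is empty")
        for records in (self.receptors, self.factors):
            codes = sorted(r.code for r in records)
            if codes != list(range(1, n + 1)):
                raise StructureError(f"codes must be 1..{n} without gaps, got {codes}")
        if sorted(self.cognate) != list(range(1, n + 1)) or sorted(
            self.cognate.values()
        ) != list(range(1, n + 1)):
            raise StructureError("cognate pairing must be a bijection over codes 1..n")

    @property
    def n(self) -> int:
        return len(self.receptors)

    def receptor(self, code: int) -> ExpressionRecord:
        for r in self.receptors:
            if r.code == code:
                return r
        raise KeyError(f"no receptor with code {code}")

    def factor(self, code: int) -> ExpressionRecord:
        for r in self.factors:
            if r.code == code:
                return r
        raise KeyError(f"no factor with code {code}")

    def record(self, gene: str) -> ExpressionRecord:
        for r in (*self.receptors, *self.factors):
            if r.gene == gene:
                return r
        raise KeyError(f"no gene {gene!r} in table")

    def cognate_factor(self, receptor_code: int) -> ExpressionRecord:
        return self.factor(self.cognate[receptor_code])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "role": r.role,
                "code": r.code,
                "nex": r.nex,
                "rnx": r.rnx,
                "fc": r.fc,
            }
            for r in (*self.receptors, *self.factors)
        ]
        return pd.DataFrame(rows, columns=["gene", "role", "code", "nex", "rnx", "fc"])

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def _default_baseline(factors: Sequence[ExpressionRecord]) -> ExpressionRecord:
    return min(factors, key=lambda r: r.nex)


def compute_relative_expression(
    table: ExpressionTable, baseline_gene: str | None = None
) -> ExpressionTable:
    """Recompute every record's ``rnx`` as ``nex / nex(baseline)``.

    The default baseline is the factor with minimum native expression.
    Idempotent: re-running with the same baseline is a no-op.
    """
    if baseline_gene is None:
        baseline_gene = _default_baseline(table.factors).gene
    base = table.record(baseline_gene)  # KeyError if unknown
    if base.nex == 0:
        raise ZeroDivisionError(
            f"baseline gene {baseline_gene!r} has zero native expression"
        )
    receptors = tuple(replace(r, rnx=r.nex / base.nex) for r in table.receptors)
    factors = tuple(replace(r, rnx=r.nex / base.nex) for r in table.factors)
    return replace(
        table, receptors=receptors, factors=factors, baseline_gene=baseline_gene
    )


def table_from_frame(
    df: pd.DataFrame,
    baseline_gene: str | None = None,
    cognate: Mapping[int, int] | None = None,
) -> ExpressionTable:
    """Build a validated :class:`ExpressionTable` from a dataframe.

    ``rnx`` is always recomputed from ``nex``; if the frame carries an ``rnx``
    column that disagrees by more than 1% relative, a warning is emitted (the
    recomputed value wins — printed tables are typically rounded at the last
    digit).
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    def _records(role: str) -> tuple[ExpressionRecord, ...]:
        sub = df[df["role"] == role]
        out = []
        for i, (_, row) in enumerate(sub.iterrows(), start=1):
            try:
                nex = float(row["nex"])
                fc = float(row["fc"])
            except (TypeError, ValueError) as exc:
                raise StructureError(
                    f"non-numeric nex/fc for gene {row['gene']!r}"
                ) from exc
            code = int(row["code"]) if "code" in df.columns else i
            out.append(
                ExpressionRecord(
                    gene=str(row["gene"]), role=role, code=code, nex=nex, rnx=1.0, fc=fc
                )
            )
        return tuple(out)

    receptors = _records(ROLE_RECEPTOR)
    factors = _records(ROLE_FACTOR)
    if not factors:
        raise StructureError("table contains no factor rows")
    n = len(receptors)
    cognate = dict(cognate) if cognate is not None else {c: c for c in range(1, n + 1)}
    table = ExpressionTable(
        receptors=receptors,
        factors=factors,
        baseline_gene="",
        cognate=cognate,
    )
    table = compute_relative_expression(table, baseline_gene)

    if "rnx" in df.columns:
        supplied = {
            str(row["gene"]): float(row["rnx"])
            for _, row in df.iterrows()
            if pd.notna(row["rnx"])
        }
        for rec in (*table.receptors, *table.factors):
            given = supplied.get(rec.gene)
            if given is None or rec.rnx == 0:
                continue
            if abs(given - rec.rnx) > RNX_WARN_RTOL * abs(rec.rnx):
                warnings.warn(
                    f"supplied rnx {given} for {rec.gene} disagrees with recomputed "
                    f"{rec.rnx:.4g} by more than {RNX_WARN_RTOL:.0%}; using the "
                    "recomputed value",
                    stacklevel=2,
                )
    return table


def load_expression_table(
    path: str | Path,
    baseline_gene: str | None = None,
    cognate: Mapping[int, int] | None = None,
) -> ExpressionTable:
    """Load a comma-separated expression file (columns gene,role,nex,fc[,code,rnx])."""
    df = pd.read_csv(path)
    return table_from_frame(df, baseline_gene=baseline_gene, cognate=cognate)
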