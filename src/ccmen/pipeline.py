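"""End-to-end orchestration and the tabular output families.

One run turns a CBE table (loaded from the three channel files, or derived
from binding scores plus expression tables) into the full set of
comma-separated output families:

``BST_<k>_<CH>.csv``
    binding strength per combination (rows, ``Prot_comb`` = receptor codes
    joined by ``-``) and factor degree (columns ``BST@kf=N``);
``P_<k>_<CH>.csv``
    absolute binding probabilities in the same layout (``P@kf=N``);
``SP_<k>_<CH>.csv``
    selective propensities in degrees, plus the row mean (``Sp_avg``);
``BST@k_interactions.csv`` / ``P@K_interactions.csv`` / ``SP@K_interactions.csv``
    per-degree channel totals, rows GCC, NHC, F (for SP, the propensity of
    the per-degree aggregate BST vector);
``EBST_<k>_<CH>.csv`` / ``ESP_<k>_<CH>.csv``
    conditional expected binding strength / propensity per subclass, with the
    class-wide value in the ``*_Overall`` column;
``EBST_k_interactions.csv`` / ``ESP_k_interactions.csv``
    class-wide expectations, rows GCC, NHC, F;
``summary.json``
    fractions (raw and NNDP-redistributed), odds ratios, BEP and the per-node
    table, at full precision.

CSV floats are written at six significant digits; iteration order is fixed,
so re-running on identical inputs reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import (
    CBETable,
    CHANNELS,
    CHANNEL_F,
    CHANNEL_GCC,
    CHANNEL_NHC,
    build_cbe_tables,
    load_binding_scores,
    load_cbe_tables,
    PAIRING_COGNATE,
)
from .enumeration import count_configurations
from .errors import ConfigError
from .expectation import KF_OVERALL
from .expression import load_expression_table
from .population import ModelRun, MODE_CULTURE_II, MODES, evaluate
from .propensity import DEFAULT_THRESHOLD

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

_SP_COLUMN = {CHANNEL_GCC: "sp_gcc", CHANNEL_NHC: "sp_nhc", CHANNEL_F: "sp_f"}
_BST_COLUMN = {CHANNEL_GCC: "bst_gcc", CHANNEL_NHC: "bst_nhc", CHANNEL_F: "bst_f"}


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs of one pipeline run.

    Exactly one CBE source must be supplied: either the three channel files
    (``cbe_gcc``/``cbe_nhc``/``cbe_f``) or a binding-score file plus an
    expression table (``bs`` + ``expression``).
    """

    outdir: Path
    cbe_gcc: Path | None = None
    cbe_nhc: Path | None = None
    cbe_f: Path | None = None
    bs: Path | None = None
    expression: Path | None = None
    mode: str = MODE_CULTURE_II
    threshold: float = DEFAULT_THRESHOLD
    pairing: str = PAIRING_COGNATE
    baseline_gene: str | None = None

    def __post_init__(self) -> None:
        cbe_given = [self.cbe_gcc, self.cbe_nhc, self.cbe_f]
        has_cbe = all(p is not None for p in cbe_given)
        if any(p is not None for p in cbe_given) and not has_cbe:
            raise ConfigError("all three CBE channel files must be given together")
        has_bs = self.bs is not None and self.expression is not None
        if has_cbe == has_bs:
            raise ConfigError(
                "supply exactly one CBE source: the three channel files, or a "
                "binding-score file plus an expression table"
            )
        if not 0.0 < self.threshold < 90.0:
            raise ConfigError(
                f"threshold must lie in (0, 90) degrees, got {self.threshold}"
            )
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")


def resolve_cbe(config: RunConfig) -> CBETable:
    """Load or derive the CBE table a config points at."""
    if config.cbe_gcc is not None:
        return load_cbe_tables(config.cbe_gcc, config.cbe_nhc, config.cbe_f)
    scores = load_binding_scores(config.bs)
    expr = load_expression_table(config.expression, baseline_gene=config.baseline_gene)
    return build_cbe_tables(scores, expr, pairing=config.pairing)


def run_pipeline(config: RunConfig) -> ModelRun:
    """Execute the model and write every output family under ``config.outdir``."""
    cbe = resolve_cbe(config)
    run = evaluate(cbe, mode=config.mode, threshold=config.threshold)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_outputs(run, outdir)
    logger.info(
        "n=%d receptors, %d configurations, BEP=%s",
        cbe.n,
        count_configurations(cbe.n),
        run.summary.bep,
    )
    return run


# ---------------------------------------------------------------------------
# output writers


def _prot_comb(codes: tuple[int, ...]) -> str:
    return "-".join(str(c) for c in codes)


def _kf_range(channel: str, k: int) -> range:
    # cell channels carry mass for kf < k, the factor channel for kf > 0
    return range(0, k) if channel in (CHANNEL_GCC, CHANNEL_NHC) else range(1, k + 1)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def write_outputs(run: ModelRun, outdir: Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _register(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = outdir / name
        _write(df, path, index=index)
        paths[name] = path

    n = run.cbe.n
    props = run.propensities
    pframe = run.ptable.frame

    # probability mass per (combination, kf, channel), branches pooled
    pmass = pframe.groupby(["codes", "k", "kf", "channel"], as_index=False)[
        "p_abs"
    ].sum()
    props = props.assign(label=props["codes"].map(_prot_comb))
    pmass = pmass.assign(label=pmass["codes"].map(_prot_comb))

    for k in range(1, n + 1):
        sub = props[props["k"] == k]
        ordered = sorted({c for c in sub["codes"]})
        label_index = [_prot_comb(c) for c in ordered]
        for channel in CHANNELS:
            kfs = list(_kf_range(channel, k))

            bst_wide = sub.pivot(index="label", columns="kf", values=_BST_COLUMN[channel])
            bst_wide = bst_wide.reindex(index=label_index, columns=kfs)
            bst_wide.columns = [f"BST@kf={kf}" for kf in kfs]
            bst_wide.index.name = "Prot_comb"
            _register(f"BST_{k}_{channel}.csv", bst_wide, index=True)

            pm = pmass[(pmass["k"] == k) & (pmass["channel"] == channel)]
            p_wide = (
                pm.pivot(index="label", columns="kf", values="p_abs")
                .reindex(index=label_index, columns=kfs)
                .fillna(0.0)
            )
            p_wide.columns = [f"P@kf={kf}" for kf in kfs]
            p_wide.index.name = "Prot_comb"
            _register(f"P_{k}_{channel}.csv", p_wide, index=True)

            sp_kfs = list(range(0, k + 1))
            sp_wide = sub.pivot(index="label", columns="kf", values=_SP_COLUMN[channel])
            sp_wide = sp_wide.reindex(index=label_index, columns=sp_kfs)
            sp_wide.insert(0, "Sp_avg", sp_wide.mean(axis=1))
            sp_wide.columns = ["Sp_avg"] + [f"Sp@kf={kf}" for kf in sp_kfs]
            sp_wide.index.name = "Prot_comb"
            _register(f"SP_{k}_{channel}.csv", sp_wide, index=True)

    # per-degree channel totals, rows GCC / NHC / F
    k_cols = [f"k={k}" for k in range(1, n + 1)]
    bst_tot = (
        pframe.groupby(["channel", "k"])["bst"].sum().unstack(fill_value=0.0)
    ).reindex(index=list(CHANNELS), columns=range(1, n + 1), fill_value=0.0)
    bst_tot.columns = k_cols
    bst_tot.index.name = "channel"
    _register("BST@k_interactions.csv", bst_tot, index=True)

    p_tot = (
        pframe.groupby(["channel", "k"])["p_abs"].sum().unstack(fill_value=0.0)
    ).reindex(index=list(CHANNELS), columns=range(1, n + 1), fill_value=0.0)
    p_tot.columns = k_cols
    p_tot.index.name = "channel"
    _register("P@K_interactions.csv", p_tot, index=True)

    # propensity of the per-degree aggregate BST vector
    agg = bst_tot.to_numpy(dtype=float)  # rows GCC, NHC, F
    norms = np.linalg.norm(agg, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp_tot = 90.0 - np.degrees(np.arccos(np.clip(agg / norms, -1.0, 1.0)))
    sp_tot_df = pd.DataFrame(sp_tot, index=list(CHANNELS), columns=k_cols)
    sp_tot_df.index.name = "channel"
    _register("SP@K_interactions.csv", sp_tot_df, index=True)

    # expectations
    exp = run.expectations
    subclass = exp[exp["kf"] != KF_OVERALL]
    overall = exp[exp["kf"] == KF_OVERALL].set_index(["k", "channel"])
    for prefix, value_col, head in (
        ("EBST", "e_bst", "EBST"),
        ("ESP", "e_sp", "SP"),
    ):
        for k in range(1, n + 1):
            for channel in CHANNELS:
                cell = subclass[
                    (subclass["k"] == k) & (subclass["channel"] == channel)
                ]
                row: dict[str, float] = {}
                if (k, channel) in overall.index:
                    row[f"{head}_Overall"] = overall.loc[(k, channel), value_col]
                for _, r in cell.sort_values("kf").iterrows():
                    row[f"{head}@kf={int(r['kf'])}"] = r[value_col]
                if not row:
                    continue
                _register(
                    f"{prefix}_{k}_{channel}.csv", pd.DataFrame([row]), index=False
                )
        tot = (
            overall[value_col]
            .unstack(level="k")
            .reindex(index=list(CHANNELS), columns=range(1, n + 1))
        )
        tot.columns = k_cols
        tot.index.name = "channel"
        _register(f"{prefix}_k_interactions.csv", tot, index=True)

    # headline summary
    summary = run.summary
    per_node = summary.per_node.copy()
    payload = {
        "mode": summary.mode,
        "threshold_degrees": summary.threshold,
        "n_receptors": n,
        "n_configurations": count_configurations(n),
        "fractions_raw": dict(summary.fractions),
        "fractions_redistributed": dict(summary.redistributed),
        "odds_ratios": {
            ch: (None if not np.isfinite(v) else v) for ch, v in summary.odds.items()
        },
        "bep": summary.bep,
        "per_k": {
            str(k): {
                "cp_gcc": float(row[CHANNEL_GCC]),
                "cp_nhc": float(row[CHANNEL_NHC]),
                "cp_f": float(row[CHANNEL_F]),
                "mass": float(row["mass"]),
            }
            for k, row in run.distribution.iterrows()
        },
        "per_node": per_node.to_dict(orient="records"),
    }
    path = outdir / "summary.json"
    path.write_text(
        json.dumps(
            payload,
            indent=2,
            sort_keys=True,
            default=lambda o: o.item() if hasattr(o, "item") else str(o),
        )
        + "\n"
    )
    paths["summary.json"] = path
    return paths


# ---------------------------------------------------------------------------
# readers (round-trip support)


def read_combination_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-combination family file (BST_/P_/SP_/EBST_/ESP_ prefix)."""
    df = pd.read_csv(path)
    if "Prot_comb" in df.columns:
        df["codes"] = df["Prot_comb"].map(
            lambda s: tuple(int(c) for c in str(s).split("-"))
        )
    return df


def read_interactions_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-degree channel-totals file (rows GCC, NHC, F)."""
    return pd.read_csv(path, index_col="channel")


def read_summary(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
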