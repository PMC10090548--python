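"""Best-effort graphical summaries of a model run.

Three figures: the per-degree channel probability profile, a 3-D quiver of
per-receptor selective propensities, and a Kamada-Kawai network of the
class/subclass fractional populations (node size proportional to the mass a
(k, k_f) node carries, labelled "odds ratio / fraction").  Rendering is
never allowed to fail a run — any exception degrades to a warning.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .affinity import CHANNELS, CHANNEL_GCC
from .enumeration import BSTVector
from .population import ModelRun
from .propensity import DIRECTION_NNDP

logger = logging.getLogger(__name__)


def render_plots(run: ModelRun, outdir: str | Path) -> list[Path]:
    """Write the three figures under ``outdir``; returns the files created."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, fn in (
        ("distribution_per_k.png", _plot_distribution),
        ("propensity_quiver.png", _plot_quiver),
        ("population_network.png", _plot_network),
    ):
        path = outdir / name
        try:
            fn(run, path)
            written.append(path)
        except Exception as exc:  # noqa: BLE001 - plots are best-effort
            warnings.warn(f"could not render {name}: {exc}", stacklevel=2)
    return written


def _plot_distribution(run: ModelRun, path: Path) -> None:
    dist = run.distribution
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6))
    ax1.bar(dist.index, dist["mass"], color="0.6")
    ax1.set_xlabel("degree of interaction k")
    ax1.set_ylabel("absolute probability mass")
    ax1.set_title("mass per degree")
    for channel in CHANNELS:
        ax2.plot(dist.index, dist[channel], marker="o", label=channel)
    if run.summary.bep is not None:
        ax2.axvline(run.summary.bep, ls="--", color="r", label=f"BEP k={run.summary.bep}")
    ax2.set_xlabel("degree of interaction k")
    ax2.set_ylabel("conditional probability CP$_k$")
    ax2.legend(fontsize=8)
    ax2.set_title("channel share per degree")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_quiver(run: ModelRun, path: Path) -> None:
    cbe = run.cbe
    fig = plt.figure(figsize=(5, 4.5))
    ax = fig.add_subplot(projection="3d")
    for i, code in enumerate(cbe.codes):
        vec = BSTVector(gcc=cbe.gcc[code], nhc=cbe.nhc[code], f=cbe.f[code])
        v = vec.as_array()
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        v = v / norm
        ax.quiver(0, 0, 0, *v, length=1.0, arrow_length_ratio=0.15)
        ax.text(*(v * 1.05), s=str(code), fontsize=7)
    ax.set_xlabel("GCC")
    ax.set_ylabel("NHC")
    ax.set_zlabel("F")
    ax.set_title("per-receptor propensity directions")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_network(run: ModelRun, path: Path, channel: str = CHANNEL_GCC) -> None:
    per_node = run.summary.per_node
    per_node = per_node[per_node["direction"] != DIRECTION_NNDP]
    g = nx.Graph()
    g.add_node("root")
    sizes = {"root": 100.0}
    labels = {"root": "CCMEN"}
    odds = run.summary.odds.get(channel, float("nan"))
    for k, chunk in per_node.groupby("k"):
        k_node = f"k={k}"
        g.add_edge("root", k_node)
        sizes[k_node] = float(chunk["fraction"].sum())
        labels[k_node] = k_node
        for _, row in chunk.iterrows():
            leaf = f"k={k},kf={row['kf']}:{row['direction']}"
            g.add_edge(k_node, leaf)
            sizes[leaf] = float(row["fraction"])
            labels[leaf] = f"{odds:.2g}/{row['fraction']:.3g}"
    pos = nx.kamada_kawai_layout(g)
    fig, ax = plt.subplots(figsize=(7, 6))
    node_sizes = [40 + 4000 * sizes.get(nd, 0.0) for nd in g.nodes]
    nx.draw_networkx(
        g, pos=pos, ax=ax, with_labels=False, node_size=node_sizes, node_color="#88b"
    )
    nx.draw_networkx_labels(g, pos=pos, labels=labels, font_size=6, ax=ax)
    ax.set_title("class/subclass fractional population")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
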