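"""Naive full-materialization reference implementation.

Everything here is computed the slow, explicit way — exhaustive enumeration
of factor assignments within every subclass, plain dict/loop bookkeeping, no
shared code with the package — so it can serve as an independent oracle for
the streaming engine on small receptor counts.
"""

import itertools
import math

GCC, NHC, F, NNDP = "GCC", "NHC", "F", "NNDP"


def oracle_bst(codes, kf, gcc, nhc, f):
    """Assignment-averaged BST triple by explicit enumeration."""
    gs, ns, fs = [], [], []
    for bound in itertools.combinations(codes, kf):
        cell = [m for m in codes if m not in bound]
        gs.append(sum(gcc[m] for m in cell))
        ns.append(sum(nhc[m] for m in cell))
        fs.append(sum(f[m] for m in bound))
    m = len(gs)
    return (sum(gs) / m, sum(ns) / m, sum(fs) / m)


def oracle_propensity(triple):
    """(sp_gcc, sp_nhc, sp_f) in degrees, or None for the zero vector."""
    r = math.sqrt(sum(v * v for v in triple))
    if r == 0:
        return None
    return tuple(90.0 - math.degrees(math.acos(max(-1.0, min(1.0, v / r)))) for v in triple)


def oracle_direction(triple, threshold=45.0):
    sp = oracle_propensity(triple)
    if sp is None:
        return NNDP
    winners = [ch for ch, v in zip((GCC, NHC, F), sp) if v > threshold]
    assert len(winners) <= 1
    return winners[0] if winners else NNDP


def oracle_evaluate(gcc, nhc, f, threshold=45.0, zero_nhc=False):
    """Full model evaluation by brute force.

    Returns a dict with per-row weights, conditional distributions,
    propensities, directions, fractions, BEP and expectations.
    """
    if zero_nhc:
        nhc = {c: 0.0 for c in nhc}
    codes_all = sorted(gcc)
    n = len(codes_all)

    rows = []  # (codes, kf, branch, channel, bst)
    triples = {}
    for k in range(1, n + 1):
        for codes in itertools.combinations(codes_all, k):
            for kf in range(0, k + 1):
                triple = oracle_bst(codes, kf, gcc, nhc, f)
                triples[(codes, kf)] = triple
                bg, bn, bf = triple
                if kf == k:
                    rows.append((codes, kf, "F_only", F, bf))
                else:
                    rows.append((codes, kf, GCC, GCC, bg))
                    if kf > 0:
                        rows.append((codes, kf, GCC, F, bf))
                    rows.append((codes, kf, NHC, NHC, bn))
                    if kf > 0:
                        rows.append((codes, kf, NHC, F, bf))

    z = sum(r[4] for r in rows)
    assert z > 0, "degenerate model"
    probs = [r[4] / z for r in rows]

    # per-degree conditional channel distribution
    mass_k = {k: 0.0 for k in range(1, n + 1)}
    chan_k = {(k, ch): 0.0 for k in range(1, n + 1) for ch in (GCC, NHC, F)}
    for (codes, kf, branch, channel, bst), p in zip(rows, probs):
        k = len(codes)
        mass_k[k] += p
        chan_k[(k, channel)] += p
    cp = {
        (k, ch): (chan_k[(k, ch)] / mass_k[k] if mass_k[k] > 0 else 0.0)
        for k in range(1, n + 1)
        for ch in (GCC, NHC, F)
    }

    bep = None
    for k in range(1, n + 1):
        if cp[(k, GCC)] < max(cp[(k, NHC)], cp[(k, F)]):
            bep = k
            break

    directions = {key: oracle_direction(t, threshold) for key, t in triples.items()}
    fractions = {d: 0.0 for d in (GCC, NHC, F, NNDP)}
    node_mass = {}
    for (codes, kf, branch, channel, bst), p in zip(rows, probs):
        node_mass[(codes, kf)] = node_mass.get((codes, kf), 0.0) + p
    for key, mass in node_mass.items():
        fractions[directions[key]] += mass

    sps = {key: oracle_propensity(t) for key, t in triples.items()}

    # expectations per (k, kf, channel) and per (k, channel)
    sp_index = {GCC: 0, NHC: 1, F: 2}
    cells = {}
    for (codes, kf, branch, channel, bst), p in zip(rows, probs):
        if p <= 0:
            continue
        k = len(codes)
        sp_val = sps[(codes, kf)][sp_index[channel]]
        for key in ((k, kf, channel), (k, "overall", channel)):
            tot, wb, ws = cells.get(key, (0.0, 0.0, 0.0))
            cells[key] = (tot + p, wb + p * bst, ws + p * sp_val)
    expectations = {
        key: (wb / tot, ws / tot) for key, (tot, wb, ws) in cells.items()
    }

    return {
        "rows": rows,
        "probs": probs,
        "z": z,
        "cp": cp,
        "mass_k": mass_k,
        "bep": bep,
        "triples": triples,
        "sps": sps,
        "directions": directions,
        "fractions": fractions,
        "expectations": expectations,
    }
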