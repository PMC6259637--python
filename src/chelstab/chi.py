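"""Valence connectivity indices on vertex-weighted molecular graphs.

The n-th order valence connectivity index is

    chi_v(n) = sum over all simple paths of n edges of
               1 / sqrt(prod of the valence deltas of the path's vertices)

with the Kier-Hall valence delta of a vertex

    delta_v = (Zv - H) / (Z - Zv - 1)

where Zv is the valence-electron count of the neutral atom, Z the atomic
number and H the number of attached hydrogens.  For second-row atoms the
denominator is 1, so delta reduces to Zv - H (primary..quaternary C give
1..4, O in OH gives 5, N in NH2 gives 3).  For the first-row transition
metals the neutral-atom d+s electron count is used (e.g. Ni: 10/17).

By default the fractional metal deltas are truncated to three decimal
places before use.  Descriptor programs carry vertex weights at fixed
precision, and the published reference indices for these complexes are
reproduced to half a unit in their last printed digit only under this
convention; exact rational deltas (``delta_decimals=None``) agree with
it to about 1e-3 on these graphs.  Integer deltas (C, N, O) are
unaffected either way.

Each undirected path is counted exactly once; paths are stored with the
lexicographically smaller endpoint first so listings are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .fixtures import LIGANDS, METALS, amino_acid_spec, metal_spec
from .graphs import build_complex

__all__ = [
    "valence_delta",
    "graph_deltas",
    "enumerate_paths",
    "PathSet",
    "chi_v",
    "chi_table",
    "chi_table_frame",
]

MAX_ORDER = 10

#: Vertex weights are truncated to this many decimals before the path sum;
#: ``None`` selects exact rational deltas.
DEFAULT_DELTA_DECIMALS: int | None = 3


def valence_delta(
    Zv: int, Z: int, nH: int, decimals: int | None = DEFAULT_DELTA_DECIMALS
) -> float:
    """Kier-Hall valence delta (Zv - nH) / (Z - Zv - 1) of one vertex.

    ``decimals`` truncates the quotient to fixed precision (the default
    convention, see module docstring); pass ``None`` for the exact value.
    """
    num = Zv - nH
    den = Z - Zv - 1
    if den == 0:
        den = 1  # second-row atoms C, N, O
    if num <= 0 or den <= 0:
        raise ValueError(
            f"unsupported vertex: Zv={Zv}, Z={Z}, nH={nH} gives "
            f"nonpositive delta {num}/{den}"
        )
    delta = num / den
    if decimals is not None:
        scale = 10**decimals
        delta = math.floor(delta * scale) / scale
    return delta


def graph_deltas(
    g: nx.Graph, decimals: int | None = DEFAULT_DELTA_DECIMALS
) -> dict:
    """Valence delta of every vertex of a weighted complex graph."""
    return {
        node: valence_delta(d["Zv"], d["Z"], d["nH"], decimals)
        for node, d in g.nodes(data=True)
    }


@dataclass(frozen=True)
class PathSet:
    """All simple paths of a fixed edge count, each counted once.

    Paths are tuples of vertex labels in canonical orientation (the
    orientation whose vertex sequence compares lexicographically smaller).
    """

    order: int
    paths: frozenset[tuple]

    def __len__(self) -> int:
        return len(self.paths)

    def sorted(self) -> list[tuple]:
        return sorted(self.paths, key=lambda p: tuple(map(str, p)))


def enumerate_paths(g: nx.Graph, n: int) -> PathSet:
    """Enumerate every simple path of exactly ``n`` edges in ``g``.

    Depth-first extension from every start vertex; the canonical
    orientation de-duplicates the two traversal directions.  Exhaustive
    and exact — complex graphs here have at most ~20 vertices.
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"path order must be a positive integer, got {n!r}")
    if n > MAX_ORDER:
        raise ValueError(f"path order {n} exceeds supported maximum {MAX_ORDER}")
    found: set[tuple] = set()

    def extend(path: list, seen: set) -> None:
        if len(path) == n + 1:
            rev = tuple(reversed(path))
            tup = tuple(path)
            found.add(min(tup, rev, key=lambda p: tuple(map(str, p))))
            return
        for nbr in g.neighbors(path[-1]):
            if nbr not in seen:
                path.append(nbr)
                seen.add(nbr)
                extend(path, seen)
                seen.remove(nbr)
                path.pop()

    for start in g.nodes():
        extend([start], {start})
    return PathSet(order=n, paths=frozenset(found))


def chi_v(
    g: nx.Graph, n: int = 3,
    delta_decimals: int | None = DEFAULT_DELTA_DECIMALS,
) -> float:
    """n-th order valence connectivity index of a weighted graph."""
    deltas = graph_deltas(g, delta_decimals)
    total = 0.0
    for path in enumerate_paths(g, n).sorted():
        prod = 1.0
        for node in path:
            prod *= deltas[node]
        total += 1.0 / math.sqrt(prod)
    return total


def path_contributions(
    g: nx.Graph, n: int = 3,
    delta_decimals: int | None = DEFAULT_DELTA_DECIMALS,
) -> list[tuple[tuple, float]]:
    """Per-path terms of chi_v, in canonical path order (for audit output)."""
    deltas = graph_deltas(g, delta_decimals)
    out = []
    for path in enumerate_paths(g, n).sorted():
        prod = 1.0
        for node in path:
            prod *= deltas[node]
        out.append((path, 1.0 / math.sqrt(prod)))
    return out


def chi_table(
    metals: Iterable[str] | None = None,
    ligands: Iterable[str] | None = None,
    n: int = 3,
    delta_decimals: int | None = DEFAULT_DELTA_DECIMALS,
) -> dict[tuple[str, str, str], float]:
    """chi_v for the full metal x ligand x {mono, bis} cross product.

    Includes pairs without experimental constants (the Ni complexes are
    always needed: they are the normalization reference of the model).
    Keys are ``(metal, ligand, species)``.
    """
    metals = list(metals) if metals is not None else list(METALS)
    ligands = list(ligands) if ligands is not None else list(LIGANDS)
    table: dict[tuple[str, str, str], float] = {}
    for m in metals:
        spec_m = metal_spec(m)
        for lig in ligands:
            spec_l = amino_acid_spec(lig)
            for species in ("mono", "bis"):
                table[(m, lig, species)] = chi_v(
                    build_complex(spec_m, spec_l, species), n, delta_decimals
                )
    return table


def chi_table_frame(table: Mapping[tuple[str, str, str], float]) -> pd.DataFrame:
    """Wide DataFrame view of a chi table: one row per (metal, ligand)."""
    pairs = sorted({(m, l) for m, l, _ in table}, key=_pair_key)
    return pd.DataFrame(
        {
            "metal": [m for m, _ in pairs],
            "ligand": [l for _, l in pairs],
            "chi_mono": [table[(m, l, "mono")] for m, l in pairs],
            "chi_bis": [table[(m, l, "bis")] for m, l in pairs],
        }
    )


def _pair_key(pair: Sequence[str]) -> tuple[int, int]:
    metal_order = list(METALS)
    return (LIGANDS.index(pair[1]), metal_order.index(pair[0]))
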