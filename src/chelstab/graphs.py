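"""Vertex-weighted heavy-atom graphs of metal(II) amino-acid aqua complexes.

A complex is modelled as a simple undirected graph over heavy atoms only;
hydrogens are implicit (each vertex carries an attached-H count).  The
metal in a mono-complex MB is tetracoordinate: bonded to the amino N, one
carboxylate O of the chelate ring, and two water oxygens.  In a
bis-complex MB2 it is hexacoordinate: two N,O-chelating ligands plus two
waters.  Bond orders and formal charges are ignored — connectivity
indices are defined on the simple graph, and coordination bonds are
ordinary edges.

Graphs are :class:`networkx.Graph` instances whose nodes are string
labels in a fixed canonical order (metal first, then each ligand's atoms
backbone-to-side-chain, waters last) and carry the attributes
``element``, ``Z``, ``Zv`` and ``nH``.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .fixtures import AminoAcidSpec, MetalSpec, amino_acid_spec, metal_spec

__all__ = [
    "build_mono_complex",
    "build_bis_complex",
    "build_complex",
    "validate_graph",
    "write_adjacency",
    "read_adjacency",
]

# Second-row elements appearing in the ligands and waters: (Z, Zv).
_ORGANIC = {"C": (6, 4), "N": (7, 5), "O": (8, 6)}


def _add_atom(g: nx.Graph, name: str, element: str, nH: int,
              Z: int | None = None, Zv: int | None = None) -> None:
    if Z is None:
        Z, Zv = _ORGANIC[element]
    g.add_node(name, element=element, Z=Z, Zv=Zv, nH=nH)


def _add_ligand(g: nx.Graph, spec: AminoAcidSpec, idx: int) -> tuple[str, str]:
    """Add one bound amino-acid residue; returns its (N, carboxylate O) nodes."""
    suffix = str(idx)
    n, ca, c = "N" + suffix, "CA" + suffix, "C" + suffix
    o_coord, o_carbonyl = "O" + suffix, "OX" + suffix
    _add_atom(g, n, "N", nH=2)
    _add_atom(g, ca, "C", nH=spec.ca_nH)
    _add_atom(g, c, "C", nH=0)
    _add_atom(g, o_coord, "O", nH=0)
    _add_atom(g, o_carbonyl, "O", nH=0)
    g.add_edges_from([(n, ca), (ca, c), (c, o_coord), (c, o_carbonyl)])
    for atom, nh, parent in spec.side_chain:
        node = atom + suffix
        _add_atom(g, node, "C", nH=nh)
        g.add_edge(node, parent + suffix)
    return n, o_coord


def build_complex(metal: MetalSpec | str, ligand: AminoAcidSpec | str,
                  species: str) -> nx.Graph:
    """Build the aqua-complex graph for ``species`` in {"mono", "bis"}.

    The mono complex closes one five-membered chelate ring
    M-N-CA-C-O and the bis complex two; two water oxygens (nH=2) fill
    the remaining coordination sites in both.
    """
    if isinstance(metal, str):
        metal = metal_spec(metal)
    if isinstance(ligand, str):
        ligand = amino_acid_spec(ligand)
    if species not in ("mono", "bis"):
        raise ValueError(f"species must be 'mono' or 'bis', got {species!r}")

    g = nx.Graph()
    _add_atom(g, "M", metal.symbol, nH=0, Z=metal.Z, Zv=metal.Zv)
    n_ligands = 1 if species == "mono" else 2
    for i in range(1, n_ligands + 1):
        n_node, o_node = _add_ligand(g, ligand, i)
        g.add_edges_from([("M", n_node), ("M", o_node)])
    for w in ("W1", "W2"):
        _add_atom(g, w, "O", nH=2)
        g.add_edge("M", w)
    g.graph["label"] = f"{metal.symbol}({ligand.name.capitalize()}) {species}"
    g.graph["species"] = species
    return g


def build_mono_complex(metal: MetalSpec | str, ligand: AminoAcidSpec | str) -> nx.Graph:
    """Tetracoordinate MB aqua complex (one chelate ring, two waters)."""
    return build_complex(metal, ligand, "mono")


def build_bis_complex(metal: MetalSpec | str, ligand: AminoAcidSpec | str) -> nx.Graph:
    """Hexacoordinate MB2 aqua complex (two chelate rings, two waters)."""
    return build_complex(metal, ligand, "bis")


def validate_graph(g: nx.Graph) -> list[str]:
    """Check structural invariants; returns a list of violation messages.

    An empty list means the graph is a well-formed complex graph:
    undirected simple graph, connected, no self-loops, every vertex
    weighted, metal degree matching its species label when present.
    """
    violations: list[str] = []
    if g.number_of_nodes() == 0:
        return ["graph is empty"]
    for node, data in g.nodes(data=True):
        for key in ("element", "Z", "Zv", "nH"):
            if key not in data:
                violations.append(f"vertex {node} missing attribute {key}")
        nh = data.get("nH")
        zv = data.get("Zv")
        if nh is not None and nh < 0:
            violations.append(f"vertex {node} has negative nH")
        if nh is not None and zv is not None and nh > zv:
            violations.append(f"vertex {node} has nH > Zv")
    if nx.number_of_selfloops(g) > 0:
        violations.append("graph has self-loops")
    if not nx.is_connected(g):
        violations.append("graph is not connected")
    species = g.graph.get("species")
    if species is not None and "M" in g:
        expected = {"mono": 4, "bis": 6}[species]
        if g.degree("M") != expected:
            violations.append(
                f"metal degree {g.degree('M')} != {expected} for {species} complex"
            )
    return violations


def write_adjacency(g: nx.Graph, path: str | Path) -> None:
    """Write a graph in the plain-text adjacency-list dialect.

    Format: one header line ``#vertices id element nH`` introducing the
    vertex block (``id element Z Zv nH`` per line, in canonical order),
    then one ``i j`` line per edge using the vertex ids.
    """
    nodes = list(g.nodes())
    index = {node: i for i, node in enumerate(nodes)}
    lines = ["#vertices id element nH"]
    for node in nodes:
        d = g.nodes[node]
        lines.append(f"{index[node]} {d['element']} {d['Z']} {d['Zv']} {d['nH']}")
    lines.append("#edges")
    for u, v in g.edges():
        i, j = sorted((index[u], index[v]))
        lines.append(f"{i} {j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency(path: str | Path) -> nx.Graph:
    """Read a graph written by :func:`write_adjacency`."""
    g = nx.Graph()
    section = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#vertices"):
            section = "vertices"
            continue
        if line.startswith("#edges"):
            section = "edges"
            continue
        parts = line.split()
        if section == "vertices":
            idx, element, Z, Zv, nH = parts
            g.add_node(int(idx), element=element, Z=int(Z), Zv=int(Zv), nH=int(nH))
        elif section == "edges":
            g.add_edge(int(parts[0]), int(parts[1]))
        else:
            raise ValueError(f"line outside any section: {line!r}")
    return g
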