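"""Directed gene-interaction networks and the metagene extension.

A gene network is a directed graph over gene identifiers: an edge
``g_i -> g_j`` means gene *i* regulates (activates or inhibits) gene *j*.
The *extended* network adds a hypothetical *metagene* ``g0`` representing
the external perturbation, with an edge to every real gene: the perturbation
can in principle touch any gene directly, so ``g0`` is an incoming neighbour
of every gene.

Edge signs (activation ``+1`` / inhibition ``-1``), when present in the
input, are stored but ignored by the MRF prior, whose feature functions
depend only on adjacency; only the sigmoid expression simulator consumes
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Default reserved identifier for the metagene.
METAGENE = "__g0__"

_SIGN_TOKENS = {"+": 1, "-": -1, "1": 1, "-1": -1, "+1": 1}


class NetworkError(ValueError):
    """Invalid network structure or lookup."""


@dataclass
class GeneNetwork:
    """A directed gene-interaction network.

    Parameters
    ----------
    genes
        Ordered gene identifiers.
    edges
        Set of ``(source, target)`` pairs; no self-loops.
    signs
        Optional ``{(source, target): +1|-1}`` activation/inhibition map for
        a subset of edges.
    """

    genes: list[str]
    edges: set[tuple[str, str]]
    signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise NetworkError("duplicate gene identifiers")
        for u, v in self.edges:
            if u == v:
                raise NetworkError(f"self-loop on gene {u!r}")
            if u not in gene_set or v not in gene_set:
                raise NetworkError(f"edge ({u!r}, {v!r}) references unknown gene")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def has_edge(self, source: str, target: str) -> bool:
        """Adjacency indicator ``W_ij``: True iff ``source -> target`` exists."""
        return (source, target) in self.edges

    def incoming(self, gene: str) -> set[str]:
        if gene not in set(self.genes):
            raise NetworkError(f"unknown gene {gene!r}")
        return {u for (u, v) in self.edges if v == gene}

    def outgoing(self, gene: str) -> set[str]:
        if gene not in set(self.genes):
            raise NetworkError(f"unknown gene {gene!r}")
        return {v for (u, v) in self.edges if u == gene}


@dataclass
class ExtendedGeneNetwork:
    """A :class:`GeneNetwork` plus the metagene and its edges.

    The metagene sits at index 0 of :attr:`genes`; it has an outgoing edge to
    every real gene and no incoming edges.
    """

    base: GeneNetwork
    metagene: str = METAGENE

    def __post_init__(self) -> None:
        if self.metagene in set(self.base.genes):
            raise NetworkError(
                f"gene named like the metagene sentinel {self.metagene!r}; "
                "choose a different sentinel"
            )

    @property
    def genes(self) -> list[str]:
        """Metagene followed by the real genes, in base order."""
        return [self.metagene] + self.base.genes

    @property
    def edges(self) -> set[tuple[str, str]]:
        meta = {(self.metagene, g) for g in self.base.genes}
        return self.base.edges | meta

    def has_edge(self, source: str, target: str) -> bool:
        if source == self.metagene:
            return target in set(self.base.genes)
        return self.base.has_edge(source, target)

    def neighbors(self, gene: str, direction: str) -> set[str]:
        """Incoming or outgoing neighbours of *gene* in the extended network."""
        if direction not in ("incoming", "outgoing"):
            raise ValueError(f"direction must be 'incoming'|'outgoing', got {direction!r}")
        if gene == self.metagene:
            return set(self.base.genes) if direction == "outgoing" else set()
        if direction == "incoming":
            return self.base.incoming(gene) | {self.metagene}
        return self.base.outgoing(gene)


def neighbors(net: ExtendedGeneNetwork, gene: str, direction: str) -> set[str]:
    """Functional alias for :meth:`ExtendedGeneNetwork.neighbors`."""
    return net.neighbors(gene, direction)


def extend_with_metagene(net: GeneNetwork, sentinel: str = METAGENE) -> ExtendedGeneNetwork:
    """Attach the metagene to every gene of *net*."""
    return ExtendedGeneNetwork(base=net, metagene=sentinel)


def load_edge_list(
    path,
    dialect: str = "edgelist",
    ordering: str = "lexicographic",
) -> GeneNetwork:
    """Load a directed network from a whitespace/TAB edge list.

    ``dialect='edgelist'`` expects ``source target [sign]`` lines with sign in
    ``{+, -, 1, -1}``; ``dialect='sif'`` expects ``source relation target``.
    Lines starting with ``#`` are comments.  Duplicate edges are collapsed,
    self-loops dropped with a warning.  ``ordering`` controls the gene order:
    ``'lexicographic'`` (default, reproducible) or ``'first-seen'``.
    """
    if dialect not in ("edgelist", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if ordering not in ("lexicographic", "first-seen"):
        raise ValueError(f"unknown ordering {ordering!r}")

    edges: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], int] = {}
    seen: list[str] = []
    seen_set: set[str] = set()

    def note(g: str) -> None:
        if g not in seen_set:
            seen_set.add(g)
            seen.append(g)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 columns, got {len(parts)}")
            if dialect == "sif":
                if len(parts) < 3:
                    raise ValueError(f"{path}: line {lineno}: SIF needs 3 columns")
                src, _, tgt = parts[0], parts[1], parts[2]
                sign = None
            else:
                src, tgt = parts[0], parts[1]
                sign = None
                if len(parts) >= 3:
                    token = parts[2]
                    if token not in _SIGN_TOKENS:
                        raise ValueError(
                            f"{path}: line {lineno}: bad sign token {token!r} "
                            f"(expected one of {sorted(_SIGN_TOKENS)})"
                        )
                    sign = _SIGN_TOKENS[token]
            if src == tgt:
                logger.warning("%s: line %d: dropping self-loop on %r", path, lineno, src)
                note(src)
                continue
            note(src)
            note(tgt)
            edges.add((src, tgt))
            if sign is not None:
                signs[(src, tgt)] = sign

    genes = sorted(seen) if ordering == "lexicographic" else seen
    return GeneNetwork(genes=genes, edges=edges, signs=signs)


def write_edge_list(net: GeneNetwork, path) -> None:
    """Write the network as a TSV edge list (signs preserved where known)."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            sign = net.signs.get((u, v))
            if sign is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{sign:+d}\n")
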