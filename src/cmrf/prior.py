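"""Markov-random-field prior over gene interaction variables.

Hidden-variable hierarchy
-------------------------
Each gene carries a binary state per group: ``S_A, S_B`` (1 = differentially
expressed, DE; 0 = equally expressed, EE).  The pair is encoded as a
*regulation* value ``Z in {1..4}``::

    (S_A, S_B):  (1,1)->1   (1,0)->2   (0,1)->3   (0,0)->4

``Z in {2,3}`` means the gene is differentially regulated (DR), ``{1,4}``
equally regulated (ER).  Every network edge ``g_i -> g_j`` carries an
*interaction* variable ``X_ij = 4*(Z_i - 1) + Z_j in {1..16}``.

The MRF is defined over the interaction variables: ``X_ij`` and ``X_pj`` are
neighbours when ``g_p -> g_i`` is an edge (they share the target subscript),
and ``X_ij`` and ``X_ik`` are neighbours when ``g_j -> g_k`` is an edge
(shared source subscript).  A neighbour's gene pair need not itself be a
network edge; such *virtual* neighbours still take a well-defined value
derived from the current ``Z`` vector and enter feature evaluation.

Seven feature functions weight the prior (coefficients ``gamma_1..gamma_7``):

* ``F1 = [X=2]``, ``F2 = [X=3]`` — the gene pair's target is DR via this edge;
* ``F3 = [X not in {2,3}]`` — everything else;
* ``F4`` — count of left neighbours ``X_pj`` equal to ``X_ij`` (the incoming
  regulators of ``g_i`` agree with it, i.e. ``Z_p = Z_i``);
* ``F5`` — count of right neighbours ``X_ik`` equal to ``X_ij``
  (``Z_k = Z_j``);
* ``F6 = [Z_i in {1,4}]``, ``F7 = [Z_j in {1,4}]`` — either endpoint is ER,
  expressing the belief that most genes respond alike in the two groups.

Only the nodewise conditional prior is ever evaluated (pseudo-likelihood);
the global partition function is never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ExtendedGeneNetwork

N_FEATURES = 7

# Regulation components of each interaction value t = 1..16 (index t-1).
ZI_OF_X = np.repeat(np.arange(1, 5), 4)  # left component Z_i
ZJ_OF_X = np.tile(np.arange(1, 5), 4)  # right component Z_j

# Unary feature columns F1, F2, F3, F6, F7 over t = 1..16 (Table rows).
_T = np.arange(1, 17)
F1_TABLE = (_T == 2).astype(float)
F2_TABLE = (_T == 3).astype(float)
F3_TABLE = 1.0 - F1_TABLE - F2_TABLE
F6_TABLE = np.isin(ZI_OF_X, (1, 4)).astype(float)
F7_TABLE = np.isin(ZJ_OF_X, (1, 4)).astype(float)


def encode_regulation(sA: int, sB: int) -> int:
    """Map a gene's per-group DE states to its regulation value Z."""
    if sA not in (0, 1) or sB not in (0, 1):
        raise ValueError(f"states must be binary, got ({sA}, {sB})")
    return 1 + 2 * (1 - sA) + (1 - sB)


def decode_regulation(z: int) -> tuple[int, int]:
    """Inverse of :func:`encode_regulation`."""
    if z not in (1, 2, 3, 4):
        raise ValueError(f"Z must be in 1..4, got {z}")
    return (1 - (z - 1) // 2, 1 - (z - 1) % 2)


def encode_interaction(zi: int, zj: int) -> int:
    """``X_ij = 4*(Z_i - 1) + Z_j``."""
    if zi not in (1, 2, 3, 4) or zj not in (1, 2, 3, 4):
        raise ValueError(f"Z values must be in 1..4, got ({zi}, {zj})")
    return 4 * (zi - 1) + zj


def decode_interaction(x: int) -> tuple[int, int]:
    """Inverse of :func:`encode_interaction`."""
    if not 1 <= x <= 16:
        raise ValueError(f"X must be in 1..16, got {x}")
    return (int(ZI_OF_X[x - 1]), int(ZJ_OF_X[x - 1]))


def eval_features(x: int, left_nbrs, right_nbrs) -> np.ndarray:
    """Feature vector ``(F1..F7)`` of a node with value *x*.

    *left_nbrs* / *right_nbrs* are the current values of the node's left
    (``X_pj``) and right (``X_ik``) neighbours, virtual ones included.
    """
    if not 1 <= x <= 16:
        raise ValueError(f"X must be in 1..16, got {x}")
    left = np.asarray(left_nbrs, dtype=int)
    right = np.asarray(right_nbrs, dtype=int)
    return np.array(
        [
            F1_TABLE[x - 1],
            F2_TABLE[x - 1],
            F3_TABLE[x - 1],
            float((left == x).sum()),
            float((right == x).sum()),
            F6_TABLE[x - 1],
            F7_TABLE[x - 1],
        ]
    )


def feature_matrix(left_nbrs, right_nbrs) -> np.ndarray:
    """(16, 7) matrix of feature vectors for every candidate value t = 1..16."""
    left = np.asarray(left_nbrs, dtype=int)
    right = np.asarray(right_nbrs, dtype=int)
    f4 = np.bincount(left - 1, minlength=16)[:16].astype(float) if left.size else np.zeros(16)
    f5 = np.bincount(right - 1, minlength=16)[:16].astype(float) if right.size else np.zeros(16)
    return np.column_stack([F1_TABLE, F2_TABLE, F3_TABLE, f4, f5, F6_TABLE, F7_TABLE])


def conditional_prior(gamma, left_nbrs, right_nbrs) -> np.ndarray:
    """Conditional prior ``p(X_ij = t | neighbours, gamma)`` over t = 1..16.

    Computed in log space with max-subtraction; always sums to one.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (N_FEATURES,):
        raise ValueError(f"gamma must have shape ({N_FEATURES},)")
    scores = feature_matrix(left_nbrs, right_nbrs) @ gamma
    scores -= scores.max()
    w = np.exp(scores)
    return w / w.sum()


@dataclass
class PriorParams:
    """Feature coefficients ``gamma_1..gamma_7`` of the MRF prior."""

    gamma: np.ndarray = field(default_factory=lambda: np.zeros(N_FEATURES))

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (N_FEATURES,):
            raise ValueError(f"gamma must have {N_FEATURES} entries")
        if not np.isfinite(self.gamma).all():
            raise ValueError("gamma must be finite")


class InteractionGraph:
    """MRF over the interaction variables of an extended gene network.

    One node per directed edge of the extended network (metagene edges
    included).  Genes are indexed with the metagene at 0; nodes store the
    integer gene pair ``(src, tgt)``.  For each node the *left* neighbour
    sources (incoming neighbours of ``src``) and *right* neighbour targets
    (outgoing neighbours of ``tgt``) are precomputed; their interaction
    values — whether or not the pair is a real edge — are derived from a
    current ``Z`` vector at evaluation time.
    """

    def __init__(self, net: ExtendedGeneNetwork):
        self.net = net
        self.genes: list[str] = net.genes  # metagene first
        self.gene_index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        gi = self.gene_index

        in_nbrs: list[list[int]] = [[] for _ in self.genes]
        out_nbrs: list[list[int]] = [[] for _ in self.genes]
        pairs: list[tuple[int, int]] = []
        for u, v in sorted(net.base.edges):
            iu, iv = gi[u], gi[v]
            in_nbrs[iv].append(iu)
            out_nbrs[iu].append(iv)
            pairs.append((iu, iv))
        for g in net.base.genes:  # metagene edges
            in_nbrs[gi[g]].append(0)
            out_nbrs[0].append(gi[g])
            pairs.append((0, gi[g]))
        pairs.sort()

        self.src = np.array([p for p, _ in pairs], dtype=int)
        self.tgt = np.array([q for _, q in pairs], dtype=int)
        self.node_index: dict[tuple[int, int], int] = {p: n for n, p in enumerate(pairs)}
        self.in_nbrs = [np.array(sorted(x), dtype=int) for x in in_nbrs]
        self.out_nbrs = [np.array(sorted(x), dtype=int) for x in out_nbrs]
        # left/right neighbour gene indices per node
        self.left_src = [self.in_nbrs[s] for s in self.src]
        self.right_tgt = [self.out_nbrs[t] for t in self.tgt]
        self.is_metagene_node = self.src == 0

    @property
    def n_nodes(self) -> int:
        return len(self.src)

    def node_of(self, source: str, target: str) -> int:
        key = (self.gene_index[source], self.gene_index[target])
        if key not in self.node_index:
            raise KeyError(f"({source!r}, {target!r}) is not a network edge")
        return self.node_index[key]

    def neighbor_pairs(self, n: int) -> list[tuple[int, int]]:
        """Gene-index pairs of all MRF neighbours of node *n*, virtual included."""
        j = int(self.tgt[n])
        i = int(self.src[n])
        return [(int(p), j) for p in self.left_src[n]] + [(i, int(k)) for k in self.right_tgt[n]]

    def mrf_edges(self) -> set[tuple[int, int]]:
        """MRF edges between *real* nodes, as sorted node-index pairs."""
        edges: set[tuple[int, int]] = set()
        for n in range(self.n_nodes):
            for pair in self.neighbor_pairs(n):
                m = self.node_index.get(pair)
                if m is not None and m != n:
                    edges.add((min(n, m), max(n, m)))
        return edges

    def node_values(self, Z: np.ndarray) -> np.ndarray:
        """Interaction value of every node under the per-gene ``Z`` vector."""
        return 4 * (Z[self.src] - 1) + Z[self.tgt]

    def neighbor_values(self, n: int, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Current values of node *n*'s left and right neighbours under ``Z``."""
        j = self.tgt[n]
        i = self.src[n]
        left = 4 * (Z[self.left_src[n]] - 1) + Z[j]
        right = 4 * (Z[i] - 1) + Z[self.right_tgt[n]]
        return left, right

    def dump_tsv(self, Z: np.ndarray, path) -> None:
        """Debug dump: one row per node with its assignment and neighbours."""
        vals = self.node_values(Z)
        with open(path, "w") as fh:
            fh.write("source\ttarget\tX\tneighbors\n")
            for n in range(self.n_nodes):
                nbrs = ";".join(
                    f"{self.genes[p]}->{self.genes[q]}" for p, q in self.neighbor_pairs(n)
                )
                fh.write(
                    f"{self.genes[self.src[n]]}\t{self.genes[self.tgt[n]]}\t{vals[n]}\t{nbrs}\n"
                )


def build_interaction_graph(net: ExtendedGeneNetwork) -> InteractionGraph:
    """Construct the MRF over interaction variables for *net*."""
    return InteractionGraph(net)
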