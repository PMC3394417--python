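"""Semi-synthetic perturbation-experiment generators with ground truth.

Three building blocks emulate the benchmark designs used to evaluate the
model:

* a Gaussian *control emulator*: per-gene mean and sd drawn uniformly, then
  i.i.d. normal samples — a stand-in for a real control expression matrix;
* *mean-shift* two-group data: affected genes keep their control variance
  but move their non-control mean by ``±d_p`` (primary) or ``±d_s``
  (secondary) gene sds, where the affected sets are planted by a breadth
  first search over the network that labels each visited gene secondary
  with probability ``1 - (1-q)^eta`` (``eta`` = its DE incoming neighbours);
* *sigmoid propagation*: a primary perturbation of relative size
  ``deviation`` spreads through the signed network via a steep sigmoid
  transfer, producing attenuated secondary shifts.

Two-group truth follows the three-set scheme: one affected set is planted
in both groups (equally regulated), the other two in exactly one group each
(differentially regulated); their primaries are the PDR gold standard.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GroupData, TwoGroupExpressionData
from .network import GeneNetwork

DEFAULT_N_SAMPLES = 155  # control-cohort scale of the emulated radiation study
DEFAULT_MU_RANGE = (100.0, 1000.0)
DEFAULT_SIGMA_RANGE = (50.0, 250.0)
DEFAULT_Q = 0.4


@dataclass
class SigmoidParams:
    """Propagation constants of the sigmoid simulator.

    alpha scales the transfer output; beta is the sigmoid steepness; k_ac /
    k_in weight activating / inhibiting inputs; h is the response threshold
    (also the per-hop attenuation of the normalized change).
    """

    alpha: float = 1.0
    beta: float = 0.01
    k_ac: float = 1.0
    k_in: float = 1.0
    h: float = 0.1

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "k_ac", "k_in", "h"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class TruthLabels:
    """Planted per-gene roles and the derived PDR/SDR/ER gene sets."""

    role_A: dict[str, str]  # gene -> primary | secondary | unaffected
    role_B: dict[str, str]
    pdr: set[str] = field(default_factory=set)
    sdr: set[str] = field(default_factory=set)
    er_affected: set[str] = field(default_factory=set)

    def affected(self, group: str) -> set[str]:
        roles = self.role_A if group == "A" else self.role_B
        return {g for g, r in roles.items() if r != "unaffected"}

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.role_A)
        flag = [
            "PDR" if g in self.pdr else "SDR" if g in self.sdr else "ER"
            for g in genes
        ]
        return pd.DataFrame(
            {
                "role_A": [self.role_A[g] for g in genes],
                "role_B": [self.role_B[g] for g in genes],
                "class": flag,
            },
            index=pd.Index(genes, name="gene"),
        )


def generate_control(
    genes,
    n_samples: int = DEFAULT_N_SAMPLES,
    mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    rng=None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Emulated control matrix plus the per-gene ``(mu_i, sigma_i)`` used.

    *genes* may be a list of identifiers or an integer count.
    """
    rng = np.random.default_rng(rng)
    if isinstance(genes, int):
        genes = [f"g{i + 1}" for i in range(genes)]
    m = len(genes)
    if m < 1 or n_samples < 1:
        raise ValueError("need at least one gene and one sample")
    lo, hi = mu_range
    slo, shi = sigma_range
    if not (lo <= hi and 0 < slo <= shi):
        raise ValueError("invalid mu_range or sigma_range")
    mu = rng.uniform(lo, hi, size=m)
    sigma = rng.uniform(slo, shi, size=m)
    values = rng.normal(mu[:, None], sigma[:, None], size=(m, n_samples))
    df = pd.DataFrame(
        values,
        index=pd.Index(genes, name="gene"),
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
    return df, mu, sigma


def secondary_probability(q: float, eta: int) -> float:
    """Probability ``1 - (1-q)^eta`` that a visited gene turns secondary DE.

    ``eta`` is the gene's current number of DE incoming neighbours; with no
    DE regulator the gene cannot be secondarily affected.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    return 1.0 - (1.0 - q) ** eta


def select_affected_sets(
    network: GeneNetwork,
    n_primary: int,
    q: float = DEFAULT_Q,
    rng=None,
    exclude: set[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Plant one affected set: primaries plus BFS-propagated secondaries.

    Repeats until *n_primary* primaries are placed: a random unlabelled gene
    becomes primary DE, then its outgoing neighbours are traversed breadth
    first; each visited unlabelled gene turns secondary DE with probability
    ``1 - (1-q)^eta`` where ``eta`` is its current number of DE incoming
    neighbours.  Only DE genes propagate further.  Genes in *exclude* are
    never labelled (used to keep multiple sets disjoint).
    """
    rng = np.random.default_rng(rng)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    exclude = set(exclude or ())
    available = [g for g in network.genes if g not in exclude]
    if n_primary > len(available):
        raise ValueError(f"n_primary={n_primary} exceeds available genes ({len(available)})")

    out_nbrs = {g: sorted(network.outgoing(g)) for g in network.genes}
    in_nbrs = {g: network.incoming(g) for g in network.genes}
    primaries: set[str] = set()
    secondaries: set[str] = set()
    labelled = set(exclude)

    while len(primaries) < n_primary:
        pool = [g for g in network.genes if g not in labelled]
        if not pool:
            raise ValueError("ran out of unlabelled genes while placing primaries")
        root = pool[rng.integers(len(pool))]
        primaries.add(root)
        labelled.add(root)
        de_here = primaries | secondaries
        queue = deque(out_nbrs[root])
        visited = {root}
        while queue:
            g = queue.popleft()
            if g in visited:
                continue
            visited.add(g)
            if g in labelled:
                continue
            eta = len(in_nbrs[g] & de_here)
            if eta and rng.random() < secondary_probability(q, eta):
                secondaries.add(g)
                labelled.add(g)
                de_here.add(g)
                queue.extend(out_nbrs[g])
    return primaries, secondaries


def build_two_group_truth(
    network: GeneNetwork,
    set_sizes: tuple[int, int, int],
    q: float = DEFAULT_Q,
    rng=None,
) -> TruthLabels:
    """Plant the three-set two-group design and derive PDR/SDR/ER labels.

    ``set_sizes`` gives the primary count of each of the three disjoint
    affected sets: set 1 is applied to both groups (equally regulated), set
    2 to group A only, set 3 to group B only.  PDR = primaries of sets 2
    and 3; SDR = their secondaries.
    """
    rng = np.random.default_rng(rng)
    exclude: set[str] = set()
    sets = []
    for size in set_sizes:
        if size == 0:
            sets.append((set(), set()))
            continue
        prim, sec = select_affected_sets(network, size, q=q, rng=rng, exclude=exclude)
        sets.append((prim, sec))
        exclude |= prim | sec

    (p1, s1), (p2, s2), (p3, s3) = sets
    role_A = {g: "unaffected" for g in network.genes}
    role_B = {g: "unaffected" for g in network.genes}
    for g in p1 | p2:
        role_A[g] = "primary"
    for g in s1 | s2:
        role_A[g] = "secondary"
    for g in p1 | p3:
        role_B[g] = "primary"
    for g in s1 | s3:
        role_B[g] = "secondary"
    return TruthLabels(
        role_A=role_A,
        role_B=role_B,
        pdr=p2 | p3,
        sdr=s2 | s3,
        er_affected=p1 | s1,
    )


def generate_two_group(
    controlA: pd.DataFrame,
    controlB: pd.DataFrame,
    labels: TruthLabels,
    d_p: float,
    d_s: float,
    rng=None,
) -> TwoGroupExpressionData:
    """Mean-shift non-control data for both groups from planted labels.

    Per gene and group: estimate ``(mu_i, sigma_i)`` from the control row;
    sample the non-control row from ``N(mu_i + shift, sigma_i^2)`` with
    ``shift = ±d_p sigma_i`` (primary), ``±d_s sigma_i`` (secondary) or 0
    (unaffected); the sign is drawn once per gene per group.  The control
    matrices pass through unchanged.
    """
    rng = np.random.default_rng(rng)
    if not d_p > d_s > 0:
        raise ValueError(f"need d_p > d_s > 0, got d_p={d_p}, d_s={d_s}")
    groups = {}
    for grp, control in (("A", controlA), ("B", controlB)):
        roles = labels.role_A if grp == "A" else labels.role_B
        missing = set(control.index) - set(roles)
        if missing:
            raise ValueError(f"labels missing for genes {sorted(missing)[:5]}...")
        mu = control.mean(axis=1).to_numpy()
        sigma = control.std(axis=1, ddof=1).to_numpy()
        size = np.array(
            [d_p if roles[g] == "primary" else d_s if roles[g] == "secondary" else 0.0
             for g in control.index]
        )
        sign = rng.choice([-1.0, 1.0], size=len(mu))
        shift = sign * size * sigma
        n = control.shape[1]
        non = rng.normal((mu + shift)[:, None], sigma[:, None], size=(len(mu), n))
        noncontrol = pd.DataFrame(non, index=control.index, columns=control.columns)
        groups[grp] = GroupData(control=control, noncontrol=noncontrol)
    return TwoGroupExpressionData(groupA=groups["A"], groupB=groups["B"])


def sigmoid_propagate(
    control: pd.DataFrame,
    primary_set: set[str],
    deviation: float,
    params: SigmoidParams | None = None,
    network: GeneNetwork | None = None,
    sign: int = 1,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Propagate a primary perturbation through the network (sigmoid transfer).

    Primary genes change by ``deviation`` times their control mean.  The
    normalized change ``delta`` of every other gene is iterated to a fixed
    point of ``delta_i = sign(u) * alpha * g(|u|) * max(|u| - h, 0)`` with
    ``u = k_ac * sum(activator deltas) - k_in * sum(inhibitor deltas)`` and
    ``g(v) = (S(v) - S(0)) / (1 - S(0))``, ``S(v) = 1/(1 + exp(-(v-h)/beta))``;
    unsigned edges count as activating, deltas are clipped to [-1, 1].  The
    returned matrix is the control plus each gene's change times its control
    mean; genes unreachable from the primaries are returned unchanged.
    """
    params = params or SigmoidParams()
    if network is None:
        raise ValueError("a network is required for propagation")
    if not 0 < deviation <= 1:
        raise ValueError("deviation must be in (0, 1]")
    unknown = primary_set - set(control.index)
    if unknown:
        raise ValueError(f"primary genes not in control matrix: {sorted(unknown)[:5]}")

    genes = list(control.index)
    idx = {g: i for i, g in enumerate(genes)}
    m = len(genes)
    acts: list[list[int]] = [[] for _ in range(m)]
    inhs: list[list[int]] = [[] for _ in range(m)]
    for (u, v) in network.edges:
        if u in idx and v in idx:
            (inhs if network.signs.get((u, v), 1) < 0 else acts)[idx[v]].append(idx[u])

    s0 = 1.0 / (1.0 + np.exp(params.h / params.beta))

    def transfer(u: np.ndarray) -> np.ndarray:
        au = np.abs(u)
        sig = 1.0 / (1.0 + np.exp(-(au - params.h) / params.beta))
        g = (sig - s0) / (1.0 - s0)
        return np.clip(np.sign(u) * params.alpha * g * np.maximum(au - params.h, 0.0), -1.0, 1.0)

    delta = np.zeros(m)
    primary_idx = np.array([idx[g] for g in primary_set], dtype=int)
    if primary_idx.size:
        delta[primary_idx] = sign * deviation
    free = np.array([i for i in range(m) if genes[i] not in primary_set], dtype=int)
    for _ in range(max_iter):
        u = np.array(
            [
                params.k_ac * delta[acts[i]].sum() - params.k_in * delta[inhs[i]].sum()
                for i in free
            ]
        )
        new = transfer(u)
        step = np.max(np.abs(new - delta[free])) if free.size else 0.0
        delta[free] = 0.5 * delta[free] + 0.5 * new  # damped update, same fixed point
        if step < tol:
            break
    else:
        raise RuntimeError(
            f"sigmoid propagation did not converge in {max_iter} iterations "
            f"(last step {step:.2e})"
        )
    x = control.mean(axis=1).to_numpy()
    return control.add(delta * x, axis=0)


def simulate_dataset_shift(
    network: GeneNetwork,
    set_sizes: tuple[int, int, int],
    d_p: float,
    d_s: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    q: float = DEFAULT_Q,
    mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    rng=None,
) -> tuple[TwoGroupExpressionData, TruthLabels]:
    """Full mean-shift benchmark: emulated control + planted labels + shifts.

    One emulated control matrix serves both groups, mirroring benchmark
    designs that reuse a single real control cohort; the non-control
    matrices are sampled independently per group.
    """
    rng = np.random.default_rng(rng)
    labels = build_two_group_truth(network, set_sizes, q=q, rng=rng)
    ctrl, _, _ = generate_control(network.genes, n_samples, mu_range, sigma_range, rng)
    data = generate_two_group(ctrl, ctrl, labels, d_p, d_s, rng)
    return data, labels


def simulate_dataset_sigmoid(
    network: GeneNetwork,
    set_sizes: tuple[int, int, int],
    deviation: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    q: float = DEFAULT_Q,
    params: SigmoidParams | None = None,
    mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    rng=None,
) -> tuple[TwoGroupExpressionData, TruthLabels]:
    """Full sigmoid benchmark: per-group primaries perturb the control matrix.

    One emulated control matrix serves both groups (mirroring designs that
    reuse a single real control cohort); each group's non-control matrix is
    that control with its own propagated change added — the perturbation
    acts on the measured data, so unaffected genes are identical between
    control and non-control.
    """
    rng = np.random.default_rng(rng)
    labels = build_two_group_truth(network, set_sizes, q=q, rng=rng)
    prim_a = {g for g, r in labels.role_A.items() if r == "primary"}
    prim_b = {g for g, r in labels.role_B.items() if r == "primary"}
    ctrl, _, _ = generate_control(network.genes, n_samples, mu_range, sigma_range, rng)
    groups = {}
    for grp, prim in (("A", prim_a), ("B", prim_b)):
        non = sigmoid_propagate(ctrl, prim, deviation, params, network)
        groups[grp] = GroupData(control=ctrl, noncontrol=non)
    return (
        TwoGroupExpressionData(groupA=groups["A"], groupB=groups["B"]),
        labels,
    )


def dp_grid() -> list[float]:
    """The primary-shift grid of the significance experiment: 0.1..3.0."""
    return [round(0.1 * k, 1) for k in range(1, 31)]


def ds_for_dp(d_p: float) -> float:
    """Secondary shift paired with a primary shift: ``1`` above 1.1, else ``d_p/2``."""
    return 1.0 if d_p > 1.1 else 0.5 * d_p


def random_scale_free_network(n_genes: int, rng=None) -> GeneNetwork:
    """A random directed scale-free gene network (no self-loops, deduplicated)."""
    import networkx as nx

    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    g = nx.scale_free_graph(n_genes, seed=seed)
    edges = {
        (f"g{u + 1}", f"g{v + 1}")
        for u, v in g.edges()
        if u != v
    }
    genes = [f"g{i + 1}" for i in range(n_genes)]
    return GeneNetwork(genes=genes, edges=edges)
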