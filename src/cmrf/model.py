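"""CMRF model: fitting the MRF prior and Gaussian likelihood to data.

:class:`CMRF` couples two-group expression data with a gene network and
fits, by alternating optimization:

1. initial per-gene DE states from two-sample t tests;
2. likelihood hyperparameters ``theta_Y = (mu0, sigma, tau)`` by
   differential evolution (DE), maximizing the data likelihood over the
   interaction-variable assignment;
3. prior coefficients ``theta_X = (gamma_1..gamma_7)`` by DE, maximizing the
   pseudo-prior (product of nodewise conditional priors);
4. a single iterated-conditional-modes (ICM) sweep over the per-gene state
   pairs ``(S_A, S_B)``, each gene set to the choice maximizing the sum of
   normalized posterior factors of every interaction variable its state
   touches;
5. repeat 2-4 until no state flips and the parameters stop moving.

``fit()`` returns a :class:`CMRFResults` carrying states, regulation and
interaction assignments, fitted parameters, the per-cycle objective trace
and ranking/diagnostic methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sp_stats

from .data import TwoGroupExpressionData, restrict_to_network
from .likelihood import ExpressionSuffStats, GeneLikCache, LikelihoodParams
from .network import METAGENE, ExtendedGeneNetwork, GeneNetwork, extend_with_metagene
from .prior import (
    N_FEATURES,
    F1_TABLE,
    F2_TABLE,
    F3_TABLE,
    F6_TABLE,
    F7_TABLE,
    ZI_OF_X,
    ZJ_OF_X,
    InteractionGraph,
    PriorParams,
)

logger = logging.getLogger(__name__)

_UNARY = np.column_stack([F1_TABLE, F2_TABLE, F3_TABLE, F6_TABLE, F7_TABLE])
_UNARY_IDX = np.array([0, 1, 2, 5, 6])  # gamma coordinates of the unary features
_CANDIDATE_STATES = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass
class FitConfig:
    """Tunable settings of the CMRF fit.

    ttest_alpha
        Significance level of the initializing two-sample t tests.
    de_pop, de_maxiter, de_crossover, de_weight
        Differential-evolution settings (rand/1/bin): target population size,
        generations, crossover rate CR and differential weight F.
    gamma_bounds
        Box bounds applied to every feature coefficient.
    theta_y_bounds
        Optional ``[(mu0_lo, mu0_hi), (sigma_lo, sigma_hi), (tau_lo,
        tau_hi)]`` override; by default ``mu0`` is bounded by the data
        range and ``sigma``/``tau`` by ``[1e-3, 10]`` times the pooled sd.
    fixed_gamma
        Optional ``{coefficient_number: value}`` (1-based, e.g. ``{6: 0.0,
        7: 0.0}``) holding chosen coefficients fixed instead of estimating
        them — the remedy for small datasets where the equal-regulation
        prior would otherwise swamp the data.
    max_cycles, tol
        Outer-loop cap and relative parameter-movement tolerance.
    seed
        Master RNG seed; every stochastic subroutine derives from it.
    """

    ttest_alpha: float = 0.05
    de_pop: int = 40
    de_maxiter: int = 100
    de_crossover: float = 0.9
    de_weight: float = 0.8
    gamma_bounds: tuple[float, float] = (-10.0, 10.0)
    theta_y_bounds: list[tuple[float, float]] | None = None
    fixed_gamma: dict[int, float] = field(default_factory=dict)
    max_cycles: int = 20
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ttest_alpha < 1.0:
            raise ValueError("ttest_alpha must be in (0, 1)")
        lo, hi = self.gamma_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("gamma_bounds must be finite with lower < upper")
        for k in self.fixed_gamma:
            if k not in range(1, N_FEATURES + 1):
                raise ValueError(f"fixed_gamma keys must be 1..{N_FEATURES}, got {k}")


def de_optimize(objective, bounds, config: FitConfig, seed: int) -> np.ndarray:
    """Maximize *objective* over box *bounds* with differential evolution.

    Deterministic given *seed*; raises if the optimum is non-finite.
    """
    ndim = len(bounds)
    popsize = max(5, math.ceil(config.de_pop / ndim))
    result = optimize.differential_evolution(
        lambda v: -objective(v),
        bounds,
        strategy="rand1bin",
        maxiter=config.de_maxiter,
        popsize=popsize,
        mutation=config.de_weight,
        recombination=config.de_crossover,
        rng=np.random.default_rng(seed),
        polish=True,
        tol=1e-8,
    )
    if not np.isfinite(result.fun):
        raise RuntimeError("objective is -inf over the entire search region")
    return np.asarray(result.x, dtype=float)


def init_states(data: TwoGroupExpressionData, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Initial DE states from per-gene two-sample t tests (control vs non-control).

    Returns ``(S_A, S_B)`` over ``[metagene] + genes`` (index 0 is the
    metagene, forced DE).  A gene is DE in a group iff its p-value is below
    *alpha*.
    """
    out = []
    for grp in ("A", "B"):
        gd = data.group(grp)
        ctrl = gd.control.to_numpy(dtype=float)
        non = gd.noncontrol.to_numpy(dtype=float)
        if ctrl.shape[1] < 2 or non.shape[1] < 2:
            raise ValueError(
                f"group {grp}: need >=2 control and >=2 non-control samples per gene"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sp_stats.ttest_ind(ctrl, non, axis=1)
            p = np.asarray(res.pvalue, dtype=float)
        diff = ctrl.mean(axis=1) - non.mean(axis=1)
        # degenerate zero-variance rows: identical means -> no evidence (p=1),
        # different means -> unambiguous shift (p=0)
        p = np.where(np.isnan(p), np.where(diff == 0.0, 1.0, 0.0), p)
        out.append(np.concatenate([[1], (p < alpha).astype(int)]))
    return out[0], out[1]


def states_to_Z(S_A: np.ndarray, S_B: np.ndarray) -> np.ndarray:
    """Vectorized regulation encoding ``Z = 1 + 2*(1-S_A) + (1-S_B)``."""
    return 1 + 2 * (1 - S_A) + (1 - S_B)


class CMRF:
    """Comparative MRF model of differential regulation.

    Parameters
    ----------
    data
        Two-group control/non-control expression data.
    network
        Directed gene-interaction network.  Genes without expression data
        are dropped from the network; expression of genes outside the
        network is ignored (both with a logged count).
    config
        Fit settings; defaults are used when omitted.
    metagene
        Sentinel identifier for the perturbation metagene.
    """

    def __init__(
        self,
        data: TwoGroupExpressionData,
        network: GeneNetwork,
        config: FitConfig | None = None,
        metagene: str = METAGENE,
    ):
        self.config = config or FitConfig()
        data = restrict_to_network(data, network)
        keep = set(data.genes)
        dropped = [g for g in network.genes if g not in keep]
        if dropped:
            logger.info("dropping %d network genes without expression data", len(dropped))
        subnet = GeneNetwork(
            genes=[g for g in network.genes if g in keep],
            edges={(u, v) for (u, v) in network.edges if u in keep and v in keep},
            signs={e: s for e, s in network.signs.items() if e[0] in keep and e[1] in keep},
        )
        self.network: ExtendedGeneNetwork = extend_with_metagene(subnet, metagene)
        self.graph = InteractionGraph(self.network)
        self.data = _align(data, self.graph.genes[1:])
        self.stats = ExpressionSuffStats(self.data, self.graph.genes, metagene)
        self._prepare_structures()

    @classmethod
    def from_files(cls, network_path, pathA_ctrl, pathA_non, pathB_ctrl, pathB_non, **kw):
        from .data import read_expression
        from .network import load_edge_list

        net = load_edge_list(network_path, dialect=kw.pop("dialect", "edgelist"))
        data = read_expression(pathA_ctrl, pathA_non, pathB_ctrl, pathB_non)
        return cls(data, net, **kw)

    # -- precomputed structure ------------------------------------------------

    def _prepare_structures(self) -> None:
        g = self.graph
        m = len(g.genes)
        self.degree = np.bincount(g.src, minlength=m) + np.bincount(g.tgt, minlength=m)
        # dependency closure per real gene: every node whose posterior factor
        # involves the gene's state, directly (endpoint) or through a
        # neighbour value
        nodes_by_src: list[list[int]] = [[] for _ in range(m)]
        nodes_by_tgt: list[list[int]] = [[] for _ in range(m)]
        for n in range(g.n_nodes):
            nodes_by_src[g.src[n]].append(n)
            nodes_by_tgt[g.tgt[n]].append(n)
        self.dep_nodes: list[np.ndarray] = [np.empty(0, dtype=int)]
        for i in range(1, m):
            dep: set[int] = set(nodes_by_src[i]) | set(nodes_by_tgt[i])
            for r in g.out_nbrs[i]:  # i is a left-neighbour source of X_r*
                dep.update(nodes_by_src[r])
            for t in g.in_nbrs[i]:  # i is a right-neighbour target of X_*t
                dep.update(nodes_by_tgt[t])
            self.dep_nodes.append(np.fromiter(sorted(dep), dtype=int))

    # -- likelihood-side objective -------------------------------------------

    def _theta_y_bounds(self) -> list[tuple[float, float]]:
        if self.config.theta_y_bounds is not None:
            bounds = [tuple(b) for b in self.config.theta_y_bounds]
            if len(bounds) != 3 or any(not lo < hi for lo, hi in bounds):
                raise ValueError("theta_y_bounds must be three (lower < upper) pairs")
            return bounds
        vals = np.hstack(
            [
                self.data.group(g).control.to_numpy().ravel()
                for g in ("A", "B")
            ]
            + [
                self.data.group(g).noncontrol.to_numpy().ravel()
                for g in ("A", "B")
            ]
        )
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            hi = lo + 1.0
        sd = float(vals.std())
        if sd <= 0:
            sd = 1.0
        return [(lo, hi), (1e-3 * sd, 10.0 * sd), (1e-3 * sd, 10.0 * sd)]

    def data_loglik(self, Z: np.ndarray, params: LikelihoodParams) -> float:
        """Sum over MRF nodes of ``log p(Y_i, Y_j | X_ij)`` for the ``Z``-derived assignment.

        Equals the degree-weighted sum of per-gene regulation log-likelihoods.
        """
        cache = GeneLikCache(self.stats, params)
        per_gene = cache.logZ[np.arange(len(Z)), Z - 1]
        per_gene = per_gene[1:]  # metagene contributes log 1 = 0
        return float((self.degree[1:] * per_gene).sum())

    def fit_theta_Y(self, Z: np.ndarray, seed: int) -> LikelihoodParams:
        """DE-maximize the data likelihood over ``(mu0, sigma, tau)``."""
        bounds = self._theta_y_bounds()
        deg = self.degree[1:].astype(float)
        stats = self.stats
        S_A = np.isin(Z, (1, 2))[1:]
        S_B = np.isin(Z, (1, 3))[1:]

        pieces = {}
        for grp in ("A", "B"):
            pieces[grp] = tuple(
                (n, m[1:], s[1:])
                for (n, m, s) in (
                    stats.stats[(grp, "control")],
                    stats.stats[(grp, "noncontrol")],
                    stats.stats[(grp, "pooled")],
                )
            )

        from .likelihood import marginal_loglik_stats

        def objective(v):
            mu0, sigma, tau = v
            params = LikelihoodParams(mu0=mu0, sigma=sigma, tau=tau)
            total = 0.0
            for grp, de_mask in (("A", S_A), ("B", S_B)):
                (nc, mc, sc), (nn, mn, sn), (np_, mp, sp) = pieces[grp]
                de = marginal_loglik_stats(nc, mc, sc, params) + marginal_loglik_stats(
                    nn, mn, sn, params
                )
                ee = marginal_loglik_stats(np_, mp, sp, params)
                total += float((deg * np.where(de_mask, de, ee)).sum())
            return total

        mu0, sigma, tau = de_optimize(objective, bounds, self.config, seed)
        return LikelihoodParams(mu0=float(mu0), sigma=float(sigma), tau=float(tau))

    # -- prior-side objective -------------------------------------------------

    def _prior_features(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-node F4/F5 candidate columns and observed values under ``Z``."""
        g = self.graph
        n_nodes = g.n_nodes
        f4 = np.zeros((n_nodes, 16))
        f5 = np.zeros((n_nodes, 16))
        for n in range(n_nodes):
            left, right = g.neighbor_values(n, Z)
            if left.size:
                f4[n] = np.bincount(left - 1, minlength=16)[:16]
            if right.size:
                f5[n] = np.bincount(right - 1, minlength=16)[:16]
        x_obs = g.node_values(Z)
        return f4, f5, x_obs

    def prior_pseudologlik(self, Z: np.ndarray, gamma: np.ndarray) -> float:
        """Sum over nodes of the log conditional prior of the current value."""
        f4, f5, x_obs = self._prior_features(Z)
        return _prior_score(gamma, f4, f5, x_obs, self.graph.is_metagene_node)

    def fit_theta_X(self, Z: np.ndarray, seed: int) -> PriorParams:
        """DE-maximize the pseudo-prior over the free feature coefficients.

        Metagene-edge nodes are normalized over their admissible candidate
        set {1..4} (the metagene is DE by construction, so values implying
        anything else cannot occur and must not shape the conditional).
        """
        f4, f5, x_obs = self._prior_features(Z)
        meta = self.graph.is_metagene_node
        fixed = {k - 1: v for k, v in self.config.fixed_gamma.items()}
        free = [k for k in range(N_FEATURES) if k not in fixed]
        if not free:
            gamma = np.array([fixed[k] for k in range(N_FEATURES)])
            return PriorParams(gamma=gamma)

        def assemble(vfree):
            gamma = np.empty(N_FEATURES)
            gamma[free] = vfree
            for k, v in fixed.items():
                gamma[k] = v
            return gamma

        def objective(vfree):
            return _prior_score(assemble(vfree), f4, f5, x_obs, meta)

        bounds = [self.config.gamma_bounds] * len(free)
        best = de_optimize(objective, bounds, self.config, seed)
        return PriorParams(gamma=assemble(best))

    # -- ICM -------------------------------------------------------------------

    def _node_log_posterior(
        self, n: int, Z: np.ndarray, gamma: np.ndarray, ll16: np.ndarray
    ) -> float:
        """Log posterior factor ``log F_ij`` of node *n* under ``Z``.

        ``F_ij = p(Y_i, Y_j | X_ij) * p(X_ij | neighbours)`` with the
        conditional prior normalized over the 16 candidate values; summed
        over all nodes this is the objective the alternating optimization
        maximizes (steps 2 and 3 each maximize one of its two terms).
        ``ll16`` is the precomputed (n_nodes, 16) likelihood table.
        """
        g = self.graph
        left, right = g.neighbor_values(n, Z)
        wp = _UNARY @ gamma[_UNARY_IDX]
        if left.size:
            wp = wp + gamma[3] * np.bincount(left - 1, minlength=16)[:16]
        if right.size:
            wp = wp + gamma[4] * np.bincount(right - 1, minlength=16)[:16]
        if g.is_metagene_node[n]:
            wp = wp[:4]  # only Z_0 = 1 values are admissible
        x = 4 * (Z[g.src[n]] - 1) + Z[g.tgt[n]]
        m = wp.max()
        log_prior = wp[x - 1] - m - np.log(np.exp(wp - m).sum())
        return float(ll16[n, x - 1] + log_prior)

    def pseudo_loglik(self, Z: np.ndarray, gamma: np.ndarray, cache: GeneLikCache) -> float:
        """Full pseudo-log-likelihood: sum of log F_ij over every node."""
        ll16 = self._likelihood_table(cache)
        return sum(
            self._node_log_posterior(n, Z, gamma, ll16) for n in range(self.graph.n_nodes)
        )

    def _likelihood_table(self, cache: GeneLikCache) -> np.ndarray:
        g = self.graph
        return cache.logZ[g.src][:, ZI_OF_X - 1] + cache.logZ[g.tgt][:, ZJ_OF_X - 1]

    def icm_sweep(
        self,
        S_A: np.ndarray,
        S_B: np.ndarray,
        gamma: np.ndarray,
        cache: GeneLikCache,
    ) -> tuple[np.ndarray, np.ndarray, int]:
        """One ICM sweep over all real genes; ties keep the current state.

        For each gene the four ``(S_A, S_B)`` choices are scored by the sum
        of log posterior factors over every node whose factor depends on the
        gene's state; the argmax is kept.  The full pseudo-log-likelihood is
        non-decreasing across the sweep.
        """
        S_A = S_A.copy()
        S_B = S_B.copy()
        Z = states_to_Z(S_A, S_B)
        ll16 = self._likelihood_table(cache)
        flips = 0
        for i in range(1, len(Z)):
            dep = self.dep_nodes[i]
            if dep.size == 0:
                continue
            cur = (int(S_A[i]), int(S_B[i]))
            best_state, best_score = cur, None
            for cand in _CANDIDATE_STATES:
                Z[i] = 1 + 2 * (1 - cand[0]) + (1 - cand[1])
                score = sum(self._node_log_posterior(n, Z, gamma, ll16) for n in dep)
                if cand == cur:
                    cur_score = score
                if best_score is None or score > best_score + 1e-12:
                    # strict improvement over the incumbent; evaluation order
                    # puts no candidate before (1,1), ties resolved below
                    best_state, best_score = cand, score
            # tie toward the current state
            if abs(best_score - cur_score) <= 1e-12:
                best_state = cur
            if best_state != cur:
                flips += 1
            S_A[i], S_B[i] = best_state
            Z[i] = 1 + 2 * (1 - best_state[0]) + (1 - best_state[1])
        return S_A, S_B, flips

    # -- outer loop --------------------------------------------------------------

    def fit(self) -> "CMRFResults":
        """Run the full alternating optimization and return the results."""
        cfg = self.config
        S_A, S_B = init_states(self.data, cfg.ttest_alpha)
        Z = states_to_Z(S_A, S_B)
        seed_y = (cfg.seed * 1000003 + 1) % (2**31)
        seed_x = (cfg.seed * 1000003 + 2) % (2**31)

        trace: list[float] = []
        prev_vec: np.ndarray | None = None
        converged = False
        theta_y = None
        prior = None
        cache = None
        n_cycles = 0
        for cycle in range(1, cfg.max_cycles + 1):
            n_cycles = cycle
            theta_y = self.fit_theta_Y(Z, seed_y)
            cache = GeneLikCache(self.stats, theta_y)
            prior = self.fit_theta_X(Z, seed_x)
            S_A, S_B, flips = self.icm_sweep(S_A, S_B, prior.gamma, cache)
            Z = states_to_Z(S_A, S_B)
            obj = self.pseudo_loglik(Z, prior.gamma, cache)
            trace.append(obj)
            vec = np.concatenate([[theta_y.mu0, theta_y.sigma, theta_y.tau], prior.gamma])
            moved = (
                np.inf
                if prev_vec is None
                else float(np.max(np.abs(vec - prev_vec) / (1.0 + np.abs(prev_vec))))
            )
            prev_vec = vec
            logger.info("cycle %d: objective %.4f, %d state flips", cycle, obj, flips)
            if flips == 0 and moved < cfg.tol:
                converged = True
                break
        if not converged:
            logger.warning("fit did not converge within %d cycles", cfg.max_cycles)

        return CMRFResults(
            model=self,
            S_A=S_A,
            S_B=S_B,
            Z=Z,
            X=self.graph.node_values(Z),
            prior_params=prior,
            lik_params=theta_y,
            cache=cache,
            trace=trace,
            converged=converged,
            n_cycles=n_cycles,
        )


def _prior_score(
    gamma: np.ndarray,
    f4: np.ndarray,
    f5: np.ndarray,
    x_obs: np.ndarray,
    is_metagene: np.ndarray | None = None,
) -> float:
    w = (_UNARY @ gamma[_UNARY_IDX])[None, :] + gamma[3] * f4 + gamma[4] * f5
    if is_metagene is not None:
        w = w.copy()
        w[is_metagene, 4:] = -np.inf  # metagene edges: only Z_0 = 1 candidates
    m = w.max(axis=1)
    lse = m + np.log(np.exp(w - m[:, None]).sum(axis=1))
    return float((w[np.arange(len(x_obs)), x_obs - 1] - lse).sum())


def _align(data: TwoGroupExpressionData, order: list[str]) -> TwoGroupExpressionData:
    from .data import GroupData

    return TwoGroupExpressionData(
        groupA=GroupData(data.groupA.control.loc[order], data.groupA.noncontrol.loc[order]),
        groupB=GroupData(data.groupB.control.loc[order], data.groupB.noncontrol.loc[order]),
    )


class CMRFResults:
    """Fitted CMRF state: assignments, parameters, diagnostics, rankings."""

    def __init__(
        self,
        model: CMRF,
        S_A: np.ndarray,
        S_B: np.ndarray,
        Z: np.ndarray,
        X: np.ndarray,
        prior_params: PriorParams,
        lik_params: LikelihoodParams,
        cache: GeneLikCache,
        trace: list[float],
        converged: bool,
        n_cycles: int,
    ):
        self.model = model
        self.S_A = S_A
        self.S_B = S_B
        self.Z = Z
        self.X = X
        self.prior_params = prior_params
        self.lik_params = lik_params
        self.cache = cache
        self.trace = trace
        self.converged = converged
        self.n_cycles = n_cycles

    @property
    def genes(self) -> list[str]:
        """Gene identifiers (metagene first)."""
        return self.model.graph.genes

    def states_frame(self) -> pd.DataFrame:
        """Per-gene states, regulation value and regulation class (real genes)."""
        genes = self.genes[1:]
        z = self.Z[1:]
        return pd.DataFrame(
            {
                "S_A": self.S_A[1:],
                "S_B": self.S_B[1:],
                "Z": z,
                "regulation": np.where(np.isin(z, (2, 3)), "DR", "ER"),
            },
            index=pd.Index(genes, name="gene"),
        )

    def dr_genes(self) -> list[str]:
        """Differentially regulated genes (Z in {2, 3})."""
        return [g for g, z in zip(self.genes[1:], self.Z[1:]) if z in (2, 3)]

    def posterior_interaction(self, geneI: str, geneJ: str) -> np.ndarray:
        """Posterior distribution of ``X_ij`` over t = 1..16 (sums to one).

        Combines the likelihood table with the conditional prior at the
        fitted state; metagene edges carry mass only on t in {1..4}.
        """
        g = self.model.graph
        n = g.node_of(geneI, geneJ)
        ll16 = self.model._likelihood_table(self.cache)
        left, right = g.neighbor_values(n, self.Z)
        gamma = self.prior_params.gamma
        w = _UNARY @ gamma[_UNARY_IDX] + ll16[n]
        if left.size:
            w = w + gamma[3] * np.bincount(left - 1, minlength=16)[:16]
        if right.size:
            w = w + gamma[4] * np.bincount(right - 1, minlength=16)[:16]
        m = w.max()
        p = np.exp(w - m)
        return p / p.sum()

    def loglik_Z_gene(self, gene: str, zval: int) -> float:
        """Cached ``log L_Z(gene, zval)`` under the fitted parameters."""
        idx = self.model.graph.gene_index[gene]
        if zval not in (1, 2, 3, 4):
            raise ValueError(f"Z must be in 1..4, got {zval}")
        return float(self.cache.logZ[idx, zval - 1])

    def reverse_loglik(self, gene: str) -> float:
        """Reverse-hypothesis log-likelihood LL of a DR gene.

        For a gene that is DE in A and EE in B (Z=2) this is the likelihood
        of the opposite assignment (Z=3), and vice versa; lower values mean
        stronger differential regulation.
        """
        idx = self.model.graph.gene_index[gene]
        z = int(self.Z[idx])
        if z not in (2, 3):
            raise ValueError(f"gene {gene!r} is not differentially regulated (Z={z})")
        return float(self.cache.logZ[idx, (3 if z == 2 else 2) - 1])

    def summary(self) -> str:
        """Human-readable fit summary."""
        z = self.Z[1:]
        counts = {v: int((z == v).sum()) for v in (1, 2, 3, 4)}
        gamma = self.prior_params.gamma
        lines = [
            "CMRF fit summary",
            "=" * 44,
            f"genes: {len(z)}   interactions: {self.model.graph.n_nodes}"
            f" (incl. {int(self.model.graph.is_metagene_node.sum())} metagene edges)",
            f"cycles: {self.n_cycles}   converged: {self.converged}",
            f"pseudo-log-likelihood: {self.trace[-1]:.4f}" if self.trace else "",
            "-" * 44,
            "theta_Y:  mu0 = {:.4g}   sigma = {:.4g}   tau = {:.4g}".format(
                self.lik_params.mu0, self.lik_params.sigma, self.lik_params.tau
            ),
            "theta_X:  " + "  ".join(f"g{k + 1}={gamma[k]:+.3f}" for k in range(N_FEATURES)),
            "-" * 44,
            "regulation:  DE/DE (Z=1): {1}   DR A-only (Z=2): {2}   "
            "DR B-only (Z=3): {3}   EE/EE (Z=4): {4}".format(None, *[counts[v] for v in (1, 2, 3, 4)]),
            f"DR genes: {len(self.dr_genes())}",
        ]
        return "\n".join(line for line in lines if line)
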