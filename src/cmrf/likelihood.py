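"""Hierarchical Gaussian marginal likelihood of expression measurements.

Measurements of one gene in one sample set are modelled as i.i.d. Gaussian
with a latent set mean ``mu`` and a global measurement sd ``sigma``; ``mu``
itself is drawn from a genome-wide Gaussian with mean ``mu0`` and sd ``tau``.
Integrating ``mu`` out gives the marginal likelihood

    L(z | mu0, sigma^2, tau^2) = integral prod_i N(z_i | mu, sigma^2)
                                          N(mu | mu0, tau^2) dmu,

evaluated in closed form (log space).  With ``n = |z|``, sample mean
``zbar``, centred sum of squares ``sse`` and ``d = zbar - mu0``:

    log L = -(n/2) log(2 pi) - (n-1) log sigma - 0.5 log(sigma^2 + n tau^2)
            - 0.5 [ sse / sigma^2  +  n d^2 / (sigma^2 + n tau^2) ]

A gene that is differentially expressed (DE) in a group has independent set
means for its control and non-control measurements: its likelihood is the
product of the two marginals.  An equally expressed (EE) gene shares one
mean: the pooled measurements get a single marginal.  The metagene, which
represents the perturbation and is DE by definition, has likelihood one for
the DE state and zero (``-inf`` in log space) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TwoGroupExpressionData
from .network import METAGENE
from .prior import decode_interaction

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LikelihoodParams:
    """Global expression-model hyperparameters ``theta_Y = (mu0, sigma, tau)``.

    mu0
        Genome-wide mean expression.
    sigma
        Within-set measurement standard deviation (> 0).
    tau
        Standard deviation of a set's latent mean around ``mu0`` (>= 0;
        ``tau = 0`` collapses the hierarchy to a fixed mean ``mu0``).
    """

    mu0: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu0) and np.isfinite(self.sigma) and np.isfinite(self.tau)):
            raise ValueError("likelihood parameters must be finite")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


def marginal_loglik_stats(n, mean, sse, params: LikelihoodParams):
    """Closed-form marginal log-likelihood from sufficient statistics.

    Vectorized over ``mean`` / ``sse``; ``n`` is the (scalar or array) sample
    count.
    """
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sse = np.asarray(sse, dtype=float)
    var = params.sigma**2
    denom = var + n * params.tau**2
    d = mean - params.mu0
    return (
        -0.5 * n * _LOG2PI
        - (n - 1.0) * np.log(params.sigma)
        - 0.5 * np.log(denom)
        - 0.5 * (sse / var + n * d * d / denom)
    )


def marginal_loglik(z, params: LikelihoodParams) -> float:
    """Marginal log-likelihood of the measurement vector *z*."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("z must be a non-empty 1-D vector")
    n = z.size
    mean = z.mean()
    sse = float(((z - mean) ** 2).sum())
    return float(marginal_loglik_stats(n, mean, sse, params))


def _set_stats(matrix: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """(n, per-gene mean, per-gene centred SS) of a genes x samples matrix."""
    n = matrix.shape[1]
    mean = matrix.mean(axis=1)
    sse = ((matrix - mean[:, None]) ** 2).sum(axis=1)
    return n, mean, sse


class ExpressionSuffStats:
    """Per-gene sufficient statistics of the four matrices plus pooled sets.

    Rows are aligned to the extended gene order (metagene at index 0, with
    NaN statistics: its likelihood is fixed by convention, never computed).
    """

    def __init__(self, data: TwoGroupExpressionData, genes: list[str], metagene: str = METAGENE):
        order = [g for g in genes if g != metagene]
        if order != data.genes:
            data = _reindex(data, order)
        self.genes = [metagene] + order
        self.metagene = metagene
        self.stats: dict[tuple[str, str], tuple[int, np.ndarray, np.ndarray]] = {}
        for grp in ("A", "B"):
            gd = data.group(grp)
            ctrl = gd.control.to_numpy(dtype=float)
            non = gd.noncontrol.to_numpy(dtype=float)
            pad = lambda t: (t[0], _pad_nan(t[1]), _pad_nan(t[2]))  # noqa: E731
            self.stats[(grp, "control")] = pad(_set_stats(ctrl))
            self.stats[(grp, "noncontrol")] = pad(_set_stats(non))
            self.stats[(grp, "pooled")] = pad(_set_stats(np.hstack([ctrl, non])))

    @property
    def n_genes(self) -> int:
        """Number of genes including the metagene."""
        return len(self.genes)


def _pad_nan(arr: np.ndarray) -> np.ndarray:
    return np.concatenate([[np.nan], arr])


def _reindex(data: TwoGroupExpressionData, order: list[str]) -> TwoGroupExpressionData:
    from .data import GroupData

    return TwoGroupExpressionData(
        groupA=GroupData(data.groupA.control.loc[order], data.groupA.noncontrol.loc[order]),
        groupB=GroupData(data.groupB.control.loc[order], data.groupB.noncontrol.loc[order]),
    )


class GeneLikCache:
    """Per-gene log-likelihoods of the DE and EE states under fixed params.

    ``logZ`` is an ``(n_genes, 4)`` matrix: column ``z-1`` holds
    ``log L_Z(gene, z)``.  Row 0 is the metagene: ``[0, -inf, -inf, -inf]``
    (it is DE in both groups by convention).
    """

    def __init__(self, stats: ExpressionSuffStats, params: LikelihoodParams):
        self.params = params
        self.genes = stats.genes
        de = {}
        ee = {}
        for grp in ("A", "B"):
            n_c, m_c, s_c = stats.stats[(grp, "control")]
            n_n, m_n, s_n = stats.stats[(grp, "noncontrol")]
            n_p, m_p, s_p = stats.stats[(grp, "pooled")]
            de[grp] = marginal_loglik_stats(n_c, m_c, s_c, params) + marginal_loglik_stats(
                n_n, m_n, s_n, params
            )
            ee[grp] = marginal_loglik_stats(n_p, m_p, s_p, params)
            de[grp][0] = 0.0  # metagene convention: L_DE = 1
            ee[grp][0] = -np.inf  # L_EE = 0
        self.logDE = de
        self.logEE = ee
        self.logZ = np.column_stack(
            [
                de["A"] + de["B"],
                de["A"] + ee["B"],
                ee["A"] + de["B"],
                ee["A"] + ee["B"],
            ]
        )
        # -inf + inf cannot arise (logDE is finite for real genes), but be safe:
        self.logZ[0] = [0.0, -np.inf, -np.inf, -np.inf]

    def loglik_X(self, i: int, j: int, x: int) -> float:
        """``log p(Y_i, Y_j | X_ij = x)`` via the pairwise factorization."""
        zi, zj = decode_interaction(x)
        return float(self.logZ[i, zi - 1] + self.logZ[j, zj - 1])

    def loglik_X16(self, i: int, j: int) -> np.ndarray:
        """Vector of ``log p(Y_i, Y_j | X_ij = t)`` over t = 1..16."""
        from .prior import ZI_OF_X, ZJ_OF_X

        return self.logZ[i, ZI_OF_X - 1] + self.logZ[j, ZJ_OF_X - 1]


# ---------------------------------------------------------------------------
# Name-keyed convenience wrappers (thin layer over the cached fast path).
# ---------------------------------------------------------------------------


def _gene_vectors(data: TwoGroupExpressionData, gene: str, group: str):
    gd = data.group(group)
    if gene not in gd.control.index:
        raise KeyError(f"unknown gene {gene!r}")
    return (
        gd.control.loc[gene].to_numpy(dtype=float),
        gd.noncontrol.loc[gene].to_numpy(dtype=float),
    )


def loglik_state(
    data: TwoGroupExpressionData,
    gene: str,
    group: str,
    state: str,
    params: LikelihoodParams,
    metagene: str = METAGENE,
) -> float:
    """Log-likelihood of a gene being DE or EE in one group."""
    if state not in ("DE", "EE"):
        raise ValueError(f"state must be 'DE' or 'EE', got {state!r}")
    if gene == metagene:
        return 0.0 if state == "DE" else -np.inf
    y, y2 = _gene_vectors(data, gene, group)
    if state == "DE":
        return marginal_loglik(y, params) + marginal_loglik(y2, params)
    return marginal_loglik(np.concatenate([y, y2]), params)


def loglik_Z(
    data: TwoGroupExpressionData,
    gene: str,
    zval: int,
    params: LikelihoodParams,
    metagene: str = METAGENE,
) -> float:
    """Log-likelihood of a gene's regulation value Z in {1..4}."""
    if zval not in (1, 2, 3, 4):
        raise ValueError(f"Z must be in 1..4, got {zval}")
    if gene == metagene:
        return 0.0 if zval == 1 else -np.inf
    state_a = "DE" if zval in (1, 2) else "EE"
    state_b = "DE" if zval in (1, 3) else "EE"
    return loglik_state(data, gene, "A", state_a, params) + loglik_state(
        data, gene, "B", state_b, params
    )


def loglik_X(
    data: TwoGroupExpressionData,
    geneI: str,
    geneJ: str,
    xval: int,
    params: LikelihoodParams,
    metagene: str = METAGENE,
) -> float:
    """Log-likelihood of an edge's interaction value X in {1..16}."""
    zi, zj = decode_interaction(xval)
    return loglik_Z(data, geneI, zi, params, metagene) + loglik_Z(
        data, geneJ, zj, params, metagene
    )
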