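"""Rankings, baselines and significance analyses on top of a fitted model.

The fitted model labels genes differentially regulated (DR); candidate
*primarily* differentially regulated (PDR) genes are obtained by ordering
the DR genes, by default by the reverse-hypothesis log-likelihood ``LL_i``
(the likelihood of the opposite group assignment of the gene's DE state —
the worse the reverse hypothesis fits, the stronger the differential
regulation).  A per-group t-test ranking and the unified-rank merge provide
the single-group baseline, and a group-shuffling permutation test provides
a null for the DR count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .data import GroupData, TwoGroupExpressionData
from .model import CMRF, CMRFResults, FitConfig
from .network import GeneNetwork


@dataclass
class RankedGeneList:
    """An ordered gene list with scores and their meaning.

    ``semantics`` is one of ``reverse-LL`` (ascending: lower = stronger
    PDR), ``metagene-likelihood`` (descending), ``p-value`` (ascending) or
    ``unified-rank`` (merge position).
    """

    genes: list[str]
    scores: list[float]
    semantics: str

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranking contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.genes) + 1),
                "gene": self.genes,
                "score": self.scores,
                "semantics": [self.semantics] * len(self.genes),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def posterior_interaction(fit: CMRFResults, geneI: str, geneJ: str) -> np.ndarray:
    """Posterior distribution of the edge's interaction variable (16-vector)."""
    return fit.posterior_interaction(geneI, geneJ)


def reverse_loglik(fit: CMRFResults, gene: str) -> float:
    """Reverse-hypothesis log-likelihood ``LL_i`` of a DR gene."""
    return fit.reverse_loglik(gene)


def rank_pdr(fit: CMRFResults, method: str = "reverse_ll") -> RankedGeneList:
    """Rank the fitted model's DR genes as PDR candidates.

    ``method='reverse_ll'`` (default) sorts by increasing reverse-hypothesis
    log-likelihood; ``method='metagene_lik'`` by decreasing likelihood of
    the gene's metagene interaction at its fitted value.  Ties break by
    gene order.  An empty list is a valid outcome (no DR genes found).
    """
    dr = fit.dr_genes()
    if method == "reverse_ll":
        scores = [fit.reverse_loglik(g) for g in dr]
        order = np.argsort(scores, kind="stable")
        return RankedGeneList(
            genes=[dr[i] for i in order],
            scores=[scores[i] for i in order],
            semantics="reverse-LL",
        )
    if method == "metagene_lik":
        scores = [fit.loglik_Z_gene(g, int(fit.Z[fit.model.graph.gene_index[g]])) for g in dr]
        order = np.argsort([-s for s in scores], kind="stable")
        return RankedGeneList(
            genes=[dr[i] for i in order],
            scores=[scores[i] for i in order],
            semantics="metagene-likelihood",
        )
    raise ValueError(f"unknown method {method!r}")


def ttest_rank(group: GroupData) -> RankedGeneList:
    """Per-gene two-sample t-test ranking of one group (ascending p-value)."""
    ctrl = group.control.to_numpy(dtype=float)
    non = group.noncontrol.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.asarray(sp_stats.ttest_ind(ctrl, non, axis=1).pvalue, dtype=float)
    diff = ctrl.mean(axis=1) - non.mean(axis=1)
    p = np.where(np.isnan(p), np.where(diff == 0.0, 1.0, 0.0), p)
    genes = list(group.control.index)
    order = np.argsort(p, kind="stable")  # ties keep gene order
    return RankedGeneList(
        genes=[genes[i] for i in order],
        scores=[float(p[i]) for i in order],
        semantics="p-value",
    )


def unified_rank(rank_A: RankedGeneList, rank_B: RankedGeneList) -> RankedGeneList:
    """Merge two single-group rankings into one DR candidate ranking.

    Scanning both lists position by position, a gene entering the top-k of
    *both* lists (the equally-regulated intersection ``Lambda_k``) is
    excluded; at each position k, group A's candidate is appended before
    group B's.  Scores are the merge positions.
    """
    a, b = rank_A.genes, rank_B.genes
    omega = min(len(a), len(b))
    out: list[str] = []
    seen: set[str] = set()
    set_a: set[str] = set()
    set_b: set[str] = set()
    for k in range(omega):
        set_a.add(a[k])
        set_b.add(b[k])
        lam = set_a & set_b
        for cand in (a[k], b[k]):
            if cand not in lam and cand not in seen:
                out.append(cand)
                seen.add(cand)
    return RankedGeneList(
        genes=out,
        scores=[float(r + 1) for r in range(len(out))],
        semantics="unified-rank",
    )


def sensitivity_at_k(ranking: RankedGeneList, truth: set[str], k: int) -> float:
    """Fraction of true genes recovered in the top *k* of the ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not truth:
        raise ValueError("truth set is empty")
    return len(set(ranking.top(k)) & truth) / len(truth)


def permutation_test(
    data: TwoGroupExpressionData,
    network: GeneNetwork,
    config: FitConfig | None = None,
    n_perm: int = 40,
    rng=None,
) -> list[int]:
    """Group-shuffling null: DR-gene count of the model on permuted data.

    For each permutation, samples are reassigned between groups A and B at
    the sample level — control columns shuffled with control columns,
    non-control with non-control — preserving per-group sample counts; the
    model is refit and its DR count recorded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    counts = []
    for _ in range(n_perm):
        shuffled = _shuffle_groups(data, rng)
        cfg = config or FitConfig()
        fit = CMRF(shuffled, network, config=cfg).fit()
        counts.append(len(fit.dr_genes()))
    return counts


def _shuffle_groups(data: TwoGroupExpressionData, rng) -> TwoGroupExpressionData:
    groups = {}
    parts = {}
    for kind in ("control", "noncontrol"):
        mat_a = getattr(data.groupA, kind)
        mat_b = getattr(data.groupB, kind)
        pooled = pd.concat([mat_a, mat_b], axis=1)
        perm = rng.permutation(pooled.shape[1])
        n_a = mat_a.shape[1]
        new_a = pooled.iloc[:, perm[:n_a]]
        new_b = pooled.iloc[:, perm[n_a:]]
        parts[kind] = (new_a, new_b)
    groups["A"] = GroupData(control=parts["control"][0], noncontrol=parts["noncontrol"][0])
    groups["B"] = GroupData(control=parts["control"][1], noncontrol=parts["noncontrol"][1])
    return TwoGroupExpressionData(groupA=groups["A"], groupB=groups["B"])


def significance_table(
    network: GeneNetwork,
    set_sizes: tuple[int, int, int],
    dp_values,
    n_samples: int = 155,
    config: FitConfig | None = None,
    rng=None,
    **generator_kw,
) -> pd.DataFrame:
    """Reverse-LL of planted DR genes across a grid of primary shifts.

    The planted gene sets and the emulated control matrix are drawn once
    and shared across the whole grid (the experiment varies only the shift
    size); for every ``d_p`` (with the paired secondary shift) fresh
    non-control matrices are generated, the model fitted, and the
    reverse-hypothesis log-likelihood of every *planted* DR gene computed
    under its planted direction (DE in A only -> likelihood of the B-only
    assignment, and vice versa).  Long-format output: columns ``d_p``,
    ``gene``, ``class``, ``LL``.
    """
    from .simulate import (
        DEFAULT_MU_RANGE,
        DEFAULT_Q,
        DEFAULT_SIGMA_RANGE,
        build_two_group_truth,
        ds_for_dp,
        generate_control,
        generate_two_group,
    )

    rng = np.random.default_rng(rng)
    q = generator_kw.pop("q", DEFAULT_Q)
    mu_range = generator_kw.pop("mu_range", DEFAULT_MU_RANGE)
    sigma_range = generator_kw.pop("sigma_range", DEFAULT_SIGMA_RANGE)
    if generator_kw:
        raise TypeError(f"unknown generator options: {sorted(generator_kw)}")
    labels = build_two_group_truth(network, set_sizes, q=q, rng=rng)
    ctrl, _, _ = generate_control(network.genes, n_samples, mu_range, sigma_range, rng)
    rows = []
    for d_p in dp_values:
        d_s = ds_for_dp(d_p)
        data = generate_two_group(ctrl, ctrl, labels, d_p, d_s, rng)
        cfg = config or FitConfig()
        fit = CMRF(data, network, config=cfg).fit()
        gi = fit.model.graph.gene_index
        for gene in sorted(labels.pdr | labels.sdr):
            planted_z = 2 if labels.role_A[gene] != "unaffected" else 3
            ll = float(fit.cache.logZ[gi[gene], (3 if planted_z == 2 else 2) - 1])
            rows.append(
                {
                    "d_p": d_p,
                    "gene": gene,
                    "class": "PDR" if gene in labels.pdr else "SDR",
                    "LL": ll,
                }
            )
    return pd.DataFrame(rows)
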