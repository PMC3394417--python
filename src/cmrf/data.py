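"""Two-group control / non-control expression data.

The model compares two sample groups (``A`` and ``B``), each measured before
(control) and after (non-control) an external perturbation.  All four
matrices are genes x samples over a shared gene index.  Multi-timepoint
series are collapsed to a single non-control matrix by taking, per gene, the
post-perturbation timepoint whose mean deviates most from the control mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GeneNetwork

logger = logging.getLogger(__name__)


class DataError(ValueError):
    pass


@dataclass
class GroupData:
    """Control and non-control matrices (genes x samples) for one group."""

    control: pd.DataFrame
    noncontrol: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.control.index.equals(self.noncontrol.index):
            raise DataError("control and non-control matrices must share the gene index")
        for name, df in (("control", self.control), ("noncontrol", self.noncontrol)):
            arr = df.to_numpy(dtype=float)
            if not np.isfinite(arr).all():
                r, c = np.argwhere(~np.isfinite(arr))[0]
                raise DataError(
                    f"non-finite value in {name} matrix at gene {df.index[r]!r}, "
                    f"column {df.columns[c]!r}"
                )

    @property
    def n_control(self) -> int:
        return self.control.shape[1]

    @property
    def n_noncontrol(self) -> int:
        return self.noncontrol.shape[1]


@dataclass
class TwoGroupExpressionData:
    """The four expression matrices of a two-group perturbation experiment."""

    groupA: GroupData
    groupB: GroupData

    def __post_init__(self) -> None:
        if not self.groupA.control.index.equals(self.groupB.control.index):
            raise DataError("group A and group B must share the gene index")
        if len(self.genes) < 1:
            raise DataError("need at least one gene")

    @property
    def genes(self) -> list[str]:
        return list(self.groupA.control.index)

    @property
    def n_genes(self) -> int:
        return len(self.groupA.control.index)

    def group(self, which: str) -> GroupData:
        if which == "A":
            return self.groupA
        if which == "B":
            return self.groupB
        raise ValueError(f"group must be 'A' or 'B', got {which!r}")


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if arr.dtype == object or not np.isfinite(arr.astype(float, copy=False)).all():
        df_num = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(~np.isfinite(df_num.to_numpy(dtype=float)))
        if len(bad):
            r, c = bad[0]
            raise DataError(
                f"{path}: non-numeric or missing value at gene {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        df = df_num
    return df.astype(float)


def read_expression(pathA_ctrl, pathA_non, pathB_ctrl, pathB_non) -> TwoGroupExpressionData:
    """Read the four TSV matrices and align them on the common gene set.

    Genes missing from any file are dropped (count logged); the surviving
    order follows the group-A control file.
    """
    a_c = _read_matrix(pathA_ctrl)
    a_n = _read_matrix(pathA_non)
    b_c = _read_matrix(pathB_ctrl)
    b_n = _read_matrix(pathB_non)
    common = set(a_c.index) & set(a_n.index) & set(b_c.index) & set(b_n.index)
    if not common:
        raise DataError("no genes shared across the four expression files")
    order = [g for g in a_c.index if g in common]
    dropped = len(set(a_c.index) | set(a_n.index) | set(b_c.index) | set(b_n.index)) - len(order)
    if dropped:
        logger.warning("dropped %d genes missing from at least one matrix", dropped)
    return TwoGroupExpressionData(
        groupA=GroupData(a_c.loc[order], a_n.loc[order]),
        groupB=GroupData(b_c.loc[order], b_n.loc[order]),
    )


def collapse_time_series(control: pd.DataFrame, post_timepoints: list[pd.DataFrame]) -> GroupData:
    """Collapse a post-perturbation time series into one non-control matrix.

    For each gene, choose the timepoint whose mean expression deviates most
    (in absolute value) from the control mean; ties break toward the earliest
    timepoint.  Different genes may pick different timepoints.
    """
    if not post_timepoints:
        raise DataError("need at least one post-perturbation timepoint")
    for t, df in enumerate(post_timepoints):
        if not df.index.equals(control.index):
            raise DataError(f"timepoint {t} does not share the control gene index")
    ctrl_mean = control.mean(axis=1).to_numpy()
    # genes x timepoints matrix of |mean_t - mean_control|
    deltas = np.column_stack(
        [np.abs(df.mean(axis=1).to_numpy() - ctrl_mean) for df in post_timepoints]
    )
    chosen = np.argmax(deltas, axis=1)  # argmax returns the first (earliest) maximum
    rows = [post_timepoints[t].iloc[[i]] for i, t in enumerate(chosen)]
    noncontrol = pd.concat(rows)
    noncontrol.index = control.index
    return GroupData(control=control, noncontrol=noncontrol)


def restrict_to_network(data: TwoGroupExpressionData, net: GeneNetwork) -> TwoGroupExpressionData:
    """Keep only genes present in the network, preserving data order."""
    keep = [g for g in data.genes if g in set(net.genes)]
    if not keep:
        raise DataError("no overlap between expression genes and network genes")
    return TwoGroupExpressionData(
        groupA=GroupData(data.groupA.control.loc[keep], data.groupA.noncontrol.loc[keep]),
        groupB=GroupData(data.groupB.control.loc[keep], data.groupB.noncontrol.loc[keep]),
    )


def write_expression(data: TwoGroupExpressionData, prefix) -> list[str]:
    """Write the four matrices as TSVs ``{prefix}_{A|B}_{control|noncontrol}.tsv``."""
    paths = []
    for grp in ("A", "B"):
        gd = data.group(grp)
        for name, df in (("control", gd.control), ("noncontrol", gd.noncontrol)):
            path = f"{prefix}_{grp}_{name}.tsv"
            df.to_csv(path, sep="\t", index_label="gene")
            paths.append(path)
    return paths
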