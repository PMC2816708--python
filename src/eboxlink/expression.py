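"""Differential-expression calling and two-cell-line cross-comparison.

The filter cascade for a two-condition comparison with replicates:

* two-sample t-test per gene (pooled variance by default, df = n1 + n2 - 2);
* Benjamini-Hochberg FDR adjustment across genes;
* a gene is called differentially expressed iff |linear fold change| >= 1.2
  AND raw p <= 0.01 AND BH q <= 0.05.

Fold changes are displayed in the signed-reciprocal microarray convention:
ratios below 1 are reported as the negative reciprocal (0.61 -> -1.64), so
|reported fold change| >= 1 always.

``cross_compare`` decomposes the DE calls of two cell lines into exclusive,
shared, co-up, co-down, and opposite-direction gene sets; by construction
|shared| = |co_up| + |co_down| + |opposite|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import ValidationError

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "treated")


def _split_conditions(conditions) -> tuple[np.ndarray, np.ndarray]:
    cond = np.asarray(conditions)
    bad = set(cond) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition label(s) {sorted(bad)}")
    ctrl = np.nonzero(cond == "control")[0]
    trt = np.nonzero(cond == "treated")[0]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValidationError("need >= 2 replicates per condition for a t-test")
    return ctrl, trt


def read_expression_tsv(path) -> tuple[pd.DataFrame, list[str]]:
    """Read a genes x samples log2 matrix; condition = sample-label prefix.

    Sample labels are expected as "<condition>_<replicate>", e.g.
    control_1, treated_3.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    conditions = [c.split("_")[0] for c in df.columns]
    _split_conditions(conditions)
    return df, conditions


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def ttest_per_gene(
    matrix: pd.DataFrame, conditions, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sided two-sample t-test per gene (treated vs control).

    Returns a frame indexed by gene with columns (t, p_raw).  Genes with
    zero within-group variance and zero mean difference get t=0, p=1;
    zero variance with a nonzero difference yields p=0.
    """
    ctrl, trt = _split_conditions(conditions)
    x = matrix.values[:, trt]
    y = matrix.values[:, ctrl]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    diff = x.mean(axis=1) - y.mean(axis=1)
    degenerate = ~np.isfinite(t)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff == 0), 0.0, t)
        p = np.where(degenerate & (diff == 0), 1.0, p)
        t = np.where(~np.isfinite(t) & (diff != 0), np.sign(diff) * np.inf, t)
        p = np.where(np.isfinite(p), p, 0.0)
    return pd.DataFrame({"t": t, "p_raw": p}, index=matrix.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Linear fold change in the signed-reciprocal display convention."""
    fc = 2.0 ** np.abs(log2fc)
    return np.where(log2fc >= 0, fc, -fc)


def call_de(
    matrix: pd.DataFrame,
    conditions,
    fc_min: float = 1.2,
    p_raw_max: float = 0.01,
    q_max: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Apply the full filter cascade; returns the per-gene DE table.

    Columns: log2fc, fold_change (signed-reciprocal), t, p_raw, q_bh,
    direction ("up" / "down" / "ns").
    """
    if fc_min < 1:
        raise ValidationError("fc_min must be >= 1 (linear fold-change scale)")
    if not (0 < p_raw_max <= 1 and 0 < q_max <= 1):
        raise ValidationError("p_raw_max and q_max must be in (0, 1]")
    ctrl, trt = _split_conditions(conditions)
    tt = ttest_per_gene(matrix, conditions, equal_var=equal_var)
    log2fc = matrix.values[:, trt].mean(axis=1) - matrix.values[:, ctrl].mean(axis=1)
    q = bh_adjust(tt["p_raw"].values)
    passes = (
        (2.0 ** np.abs(log2fc) >= fc_min)
        & (tt["p_raw"].values <= p_raw_max)
        & (q <= q_max)
    )
    direction = np.where(~passes, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": signed_fold_change(log2fc),
            "t": tt["t"].values,
            "p_raw": tt["p_raw"].values,
            "q_bh": q,
            "direction": direction,
        },
        index=matrix.index.rename("gene_id"),
    )


def median_center(ratios: pd.DataFrame) -> pd.DataFrame:
    """Center each gene's ratios to median 0 across analyses.

    Genes with no observed values are dropped with a warning.
    """
    all_missing = ratios.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d gene(s) with no observations", int(all_missing.sum()))
        ratios = ratios.loc[~all_missing]
    return ratios.sub(ratios.median(axis=1), axis=0)


def f_test_screen(matrix: pd.DataFrame, group_labels) -> pd.DataFrame:
    """One-way F-test across >= 2 experimental groups, with BH adjustment.

    A screening device for "significant anywhere across the groups" gene
    sets; the original study's multi-group statistic is not documented, so
    this is offered as an explicit, flag-gated stand-in.
    """
    labels = np.asarray(group_labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    groups = [matrix.values[:, labels == u] for u in uniq]
    if any(g.shape[1] < 2 for g in groups):
        raise ValidationError("need >= 2 replicates per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {"F": f, "p_raw": p, "q_bh": bh_adjust(p)}, index=matrix.index
    )


@dataclass(frozen=True)
class CrossComparison:
    """Two-cell-line decomposition of DE gene sets."""

    exclusive_a: frozenset
    exclusive_b: frozenset
    shared: frozenset
    co_up: frozenset
    co_down: frozenset
    opposite: frozenset

    def __post_init__(self):
        assert self.shared == self.co_up | self.co_down | self.opposite
        assert not (self.co_up & self.co_down)
        assert not (self.opposite & (self.co_up | self.co_down))

    @property
    def co_regulated(self) -> frozenset:
        return self.co_up | self.co_down

    def counts(self) -> dict[str, int]:
        return {
            "exclusive_a": len(self.exclusive_a),
            "exclusive_b": len(self.exclusive_b),
            "shared": len(self.shared),
            "co_up": len(self.co_up),
            "co_down": len(self.co_down),
            "co_regulated": len(self.co_regulated),
            "opposite": len(self.opposite),
        }

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        for cat in ("exclusive_a", "exclusive_b", "co_up", "co_down", "opposite"):
            for g in sorted(getattr(self, cat)):
                rows.append({"gene_id": g, "category": cat})
        return pd.DataFrame(rows, columns=["gene_id", "category"])

    def summary(self) -> str:
        c = self.counts()
        return (
            f"exclusive A: {c['exclusive_a']}  exclusive B: {c['exclusive_b']}  "
            f"shared: {c['shared']} = co-regulated {c['co_regulated']} "
            f"(up {c['co_up']}, down {c['co_down']}) + opposite {c['opposite']}"
        )


def de_sets(de_table: pd.DataFrame) -> tuple[set, set]:
    """(up, down) gene-id sets from a DE table."""
    up = set(de_table.index[de_table["direction"] == "up"])
    down = set(de_table.index[de_table["direction"] == "down"])
    return up, down


def cross_compare(de_a: pd.DataFrame, de_b: pd.DataFrame) -> CrossComparison:
    """Decompose two DE tables sharing a gene-id namespace."""
    up_a, down_a = de_sets(de_a)
    up_b, down_b = de_sets(de_b)
    a, b = up_a | down_a, up_b | down_b
    shared = a & b
    co_up = up_a & up_b
    co_down = down_a & down_b
    opposite = (up_a & down_b) | (down_a & up_b)
    return CrossComparison(
        exclusive_a=frozenset(a - b),
        exclusive_b=frozenset(b - a),
        shared=frozenset(shared),
        co_up=frozenset(co_up),
        co_down=frozenset(co_down),
        opposite=frozenset(opposite),
    )
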