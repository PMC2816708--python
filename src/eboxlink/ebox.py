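"""Canonical E-box (CACGTG) content and positional distribution.

Characterizes where perfect-match canonical E-boxes sit relative to the TSS
in wide promoter windows (3,000 bp upstream to 500 bp downstream), how many
each promoter carries, and whether up- and down-regulated gene groups differ
in per-promoter E-box counts (Fisher exact test on a >=k / <k split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError
from .motifs import scan_consensus
from .promoters import PromoterRecord

logger = logging.getLogger(__name__)

CANONICAL_EBOX = "CACGTG"
DEFAULT_WINDOW = (-3000, 500)
DEFAULT_BIN_WIDTH = 50


@dataclass(frozen=True)
class PositionalProfile:
    """TSS-relative site offsets with a normalized positional density.

    ``density`` is a histogram-based probability density over ``bin_edges``
    (bp); it integrates to 1 whenever any offsets are present.
    """

    offsets: np.ndarray
    window: tuple[int, int]
    group_label: str
    bin_width: int = DEFAULT_BIN_WIDTH
    bin_edges: np.ndarray = field(init=False, repr=False)
    density: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        offsets = np.asarray(self.offsets, dtype=float)
        lo, hi = self.window
        if offsets.size and (offsets.min() < lo or offsets.max() >= hi):
            raise ValidationError(
                f"{self.group_label}: offsets outside window {self.window}"
            )
        edges = np.arange(lo, hi + self.bin_width, self.bin_width, dtype=float)
        if offsets.size:
            density, _ = np.histogram(offsets, bins=edges, density=True)
        else:
            density = np.zeros(len(edges) - 1)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", density)

    @property
    def mode_bin_center(self) -> float | None:
        """Center of the highest-density bin (None when empty)."""
        if not self.offsets.size:
            return None
        i = int(self.density.argmax())
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2)

    def kde(self, grid: np.ndarray | None = None):
        """Gaussian kernel density (Silverman bandwidth) for plotting."""
        if self.offsets.size < 2:
            raise ValidationError("need >= 2 offsets for a kernel density")
        kde = stats.gaussian_kde(self.offsets, bw_method="silverman")
        if grid is None:
            grid = np.linspace(self.window[0], self.window[1], 701)
        return grid, kde(grid)


@dataclass(frozen=True)
class CountDistribution:
    """Per-promoter E-box counts for one gene group."""

    counts: pd.Series  # gene_id -> count
    group_label: str

    @property
    def total_sites(self) -> int:
        return int(self.counts.sum())

    def n_with_at_least(self, k: int) -> int:
        return int((self.counts >= k).sum())


def ebox_profile(
    promoters: list[PromoterRecord],
    groups: dict[str, str] | None = None,
    pattern: str = CANONICAL_EBOX,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> tuple[dict[str, PositionalProfile], dict[str, CountDistribution]]:
    """Positional profiles and count distributions per gene group.

    ``groups`` maps gene ids to "up" or "down"; profiles are produced for
    "all" plus each present group.  Scanning is exact-match on both strands
    (for the palindromic canonical E-box this double-counts nothing).
    Genes listed in ``groups`` but absent from the promoter set are skipped
    with a logged count.
    """
    window = (
        -max(p.window_up for p in promoters),
        max(p.window_down for p in promoters),
    ) if promoters else DEFAULT_WINDOW
    by_gene = {p.gene_id: p for p in promoters}
    groups = dict(groups or {})
    missing = sorted(set(groups) - set(by_gene))
    if missing:
        logger.warning("%d grouped gene(s) absent from promoter set (skipped): %s",
                       len(missing), missing[:10])
        for g in missing:
            groups.pop(g)

    offsets_by_label: dict[str, list[int]] = {"all": []}
    counts_by_label: dict[str, dict[str, int]] = {"all": {}}
    for label in sorted(set(groups.values())):
        offsets_by_label[label] = []
        counts_by_label[label] = {}
    for p in promoters:
        hits = scan_consensus(p, pattern, strands="both")
        offs = [h.offset for h in hits]
        labels = ["all"] + ([groups[p.gene_id]] if p.gene_id in groups else [])
        for label in labels:
            offsets_by_label[label].extend(offs)
            counts_by_label[label][p.gene_id] = len(offs)

    profiles = {
        label: PositionalProfile(np.array(v, dtype=float), window, label, bin_width)
        for label, v in offsets_by_label.items()
    }
    counts = {
        label: CountDistribution(
            pd.Series(v, dtype=int).sort_index(), label
        )
        for label, v in counts_by_label.items()
    }
    return profiles, counts


@dataclass(frozen=True)
class CountComparison:
    """Fisher exact comparison of >=k vs <k E-box promoters across groups."""

    table: np.ndarray  # rows: >=k, <k ; columns: up, down
    k: int
    odds_ratio: float
    p_value: float


def compare_count_distributions(
    counts_up: CountDistribution, counts_down: CountDistribution, k: int = 2
) -> CountComparison:
    """Two-sided Fisher exact test on the 2x2 table {>=k, <k} x {up, down}."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if counts_up.counts.empty or counts_down.counts.empty:
        raise ValidationError("both groups must be non-empty")
    a = counts_up.n_with_at_least(k)
    b = counts_down.n_with_at_least(k)
    c = len(counts_up.counts) - a
    d = len(counts_down.counts) - b
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return CountComparison(table, k, float(odds), float(p))


def profiles_to_frame(profiles: dict[str, PositionalProfile]) -> pd.DataFrame:
    rows = [
        {"offset": int(o), "group": label}
        for label, prof in profiles.items()
        for o in prof.offsets
    ]
    return pd.DataFrame(rows, columns=["offset", "group"])


def plot_profiles(profiles: dict[str, PositionalProfile], path) -> None:
    """Write a density plot of the positional profiles (one line per group)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"all": "black", "up": "red", "down": "blue"}
    for label, prof in profiles.items():
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        ax.plot(centers, prof.density, label=label, color=colors.get(label))
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
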