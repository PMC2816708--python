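"""Motif over-representation against an expected-frequency background.

For each matrix the observed number of hit instances in a foreground
promoter set is compared with the rate expected from a background promoter
collection scanned with the same parameters.  The observed count is modelled
as Binomial(g * W, r / W) where g is the number of foreground promoters,
W the number of scanned windows per promoter and r the expected hit rate per
promoter; the reported probability is the exact upper tail P(X >= n).

The per-matrix "significance" score is a Bonferroni-style transform,

    significance = -log10(probability * n_matrices_tested)

so positive values indicate results that stay significant after correcting
for the number of matrices interrogated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError
from .motifs import BackgroundModel, MotifMatrix, ScanParams, count_feature_hits
from .promoters import PromoterRecord

logger = logging.getLogger(__name__)

#: significance cap used when probability underflows to exactly 0
MAX_SIGNIFICANCE = 350.0


@dataclass(frozen=True)
class ExpectedFreq:
    """Expected hit instances per promoter for one matrix."""

    matrix_id: str
    rate: float
    window_bp: float
    source_label: str = ""

    def __post_init__(self):
        if self.rate < 0:
            raise ValidationError(f"{self.matrix_id}: rate must be >= 0")

    def scaled_rate(self, foreground_window_bp: float) -> float:
        """Per-bp rescaling of the rate to a different window length."""
        if self.window_bp <= 0:
            raise ValidationError(f"{self.matrix_id}: window_bp must be > 0 to rescale")
        return self.rate * foreground_window_bp / self.window_bp


def estimate_expected_freq(
    background_promoters: list[PromoterRecord],
    matrices: list[MotifMatrix],
    bg: BackgroundModel,
    params: ScanParams = ScanParams(),
    source_label: str = "background promoters",
) -> list[ExpectedFreq]:
    """Scan a background promoter collection and record per-matrix hit rates.

    rate = total hit instances / number of background promoters; the mean
    window length is stored so rates can be rescaled per-bp when foreground
    windows differ in size.
    """
    if not background_promoters:
        raise ValidationError("background promoter set is empty")
    counts = count_feature_hits(background_promoters, matrices, bg, params)
    g = len(background_promoters)
    mean_bp = float(np.mean([len(p.seq) for p in background_promoters]))
    return [
        ExpectedFreq(row.matrix_id, row.n / g, mean_bp, source_label)
        for row in counts.itertuples(index=False)
    ]


def expected_freq_frame(table: list[ExpectedFreq]) -> pd.DataFrame:
    return pd.DataFrame(
        [e.__dict__ for e in table],
        columns=["matrix_id", "rate", "window_bp", "source_label"],
    )


def binomial_overrep(
    n: int, g: int, rate: float, windows_per_promoter: int
) -> float:
    """Upper-tail probability P(X >= n) of seeing n or more hit instances.

    X ~ Binomial(g * windows_per_promoter, rate / windows_per_promoter),
    evaluated exactly; for more than 1e6 trials a Poisson tail with
    lambda = g * rate is used instead.
    """
    if n < 0 or g < 1 or windows_per_promoter < 1:
        raise ValidationError("need n >= 0, g >= 1, windows_per_promoter >= 1")
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if n == 0:
        return 1.0
    p_window = rate / windows_per_promoter
    if p_window > 1:
        raise ValidationError(
            f"rate {rate} implies per-window probability {p_window:.3g} > 1"
        )
    trials = g * windows_per_promoter
    if trials <= 1_000_000:
        return float(stats.binom.sf(n - 1, trials, p_window))
    logger.debug("binomial_overrep: %d trials, using Poisson tail", trials)
    return float(stats.poisson.sf(n - 1, g * rate))


def significance_score(probability: float, n_matrices_tested: int) -> float:
    """Bonferroni-corrected -log10 score; positive iff corrected p < 1."""
    if n_matrices_tested < 1:
        raise ValidationError("n_matrices_tested must be >= 1")
    if not 0 <= probability <= 1:
        raise ValidationError(f"probability {probability} outside [0, 1]")
    if probability == 0:
        logger.warning("probability underflowed to 0; capping significance at %s",
                       MAX_SIGNIFICANCE)
        return MAX_SIGNIFICANCE
    return -math.log10(probability * n_matrices_tested)


def enrich_table(
    foreground_promoters: list[PromoterRecord],
    matrices: list[MotifMatrix],
    expected: list[ExpectedFreq],
    bg: BackgroundModel,
    params: ScanParams = ScanParams(),
    p_significant: float = 0.05,
) -> pd.DataFrame:
    """Per-matrix over-representation table, sorted by significance.

    Columns mirror the classic over-representation report: matrix_id, n
    (hit instances), genes_hit, probability (binomial upper tail),
    significance, and an ``overrepresented`` flag for probability below
    ``p_significant``.
    """
    if not matrices:
        return pd.DataFrame(
            columns=["matrix_id", "n", "genes_hit", "probability",
                     "significance", "overrepresented"]
        )
    exp_by_id = {e.matrix_id: e for e in expected}
    missing = sorted({m.matrix_id for m in matrices} - set(exp_by_id))
    if missing:
        raise ValidationError(f"matrices missing from expected-frequency table: {missing}")
    counts = count_feature_hits(foreground_promoters, matrices, bg, params)
    g = len(foreground_promoters)
    fg_bp = float(np.mean([len(p.seq) for p in foreground_promoters])) if g else 0.0
    widths = {m.matrix_id: m.width for m in matrices}
    n_tested = len(matrices)
    rows = []
    for row in counts.itertuples(index=False):
        e = exp_by_id[row.matrix_id]
        rate = e.scaled_rate(fg_bp) if g and abs(e.window_bp - fg_bp) > 0.5 else e.rate
        w = widths[row.matrix_id]
        n_windows = max(int(fg_bp) - w + 1, 1)
        if params.strands == "both":
            n_windows *= 2
        prob = binomial_overrep(row.n, max(g, 1), rate, n_windows) if g else 1.0
        rows.append(
            {
                "matrix_id": row.matrix_id,
                "n": row.n,
                "genes_hit": row.genes_hit,
                "probability": prob,
                "significance": significance_score(prob, n_tested),
                "overrepresented": prob < p_significant,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["significance", "matrix_id"], ascending=[False, True]
    ).reset_index(drop=True)
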