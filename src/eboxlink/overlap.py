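"""Gene-set overlap enrichment of a clustered target catalog.

Given a responsive gene set (e.g. rapamycin-modulated genes) and a catalog
of target genes grouped into temporal-response clusters, compute the
observed overlap, the overlap expected under independence over a declared
universe (the hypergeometric mean |responsive| * |scope| / |universe|), and
a 1-df goodness-of-fit chi-square of observed vs expected within the
responsive set.  Overlaps are additionally split by the direction of the
responsive genes, with a two-sided binomial sign test on the up/down split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from ._util import ValidationError

logger = logging.getLogger(__name__)

TOTAL_SCOPE = "total"


def dedup_to_genes(probes, probe_to_gene: dict[str, str]) -> set[str]:
    """Collapse a probe list to unique gene ids via a mapping table.

    A gene with several probes counts once, so intersections with target
    catalogs are not overestimated.  Unmapped probes are dropped (logged).
    """
    genes = set()
    dropped = 0
    for p in probes:
        g = probe_to_gene.get(p)
        if g is None:
            dropped += 1
        else:
            genes.add(g)
    if dropped:
        logger.info("dedup_to_genes: dropped %d unmapped probe(s)", dropped)
    return genes


@dataclass(frozen=True)
class TargetCatalog:
    """Disjoint target-gene clusters over a declared universe."""

    clusters: tuple[tuple[str, frozenset], ...]
    universe: frozenset

    def __post_init__(self):
        seen: set = set()
        for cid, members in self.clusters:
            if not members <= self.universe:
                raise ValidationError(f"cluster {cid!r} not contained in universe")
            if seen & members:
                raise ValidationError(f"cluster {cid!r} overlaps an earlier cluster")
            seen |= members
        object.__setattr__(self, "clusters", tuple(
            (cid, frozenset(m)) for cid, m in self.clusters
        ))
        object.__setattr__(self, "universe", frozenset(self.universe))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, universe) -> "TargetCatalog":
        """Build from a (gene_id, cluster_id) table, preserving cluster order."""
        clusters = [
            (str(cid), frozenset(sub["gene_id"]))
            for cid, sub in df.groupby("cluster_id", sort=True)
        ]
        return cls(tuple(clusters), frozenset(universe))

    @property
    def all_targets(self) -> frozenset:
        out: set = set()
        for _, m in self.clusters:
            out |= m
        return frozenset(out)

    def scope_set(self, scope: str) -> frozenset:
        if scope == TOTAL_SCOPE:
            return self.all_targets
        for cid, m in self.clusters:
            if cid == scope:
                return m
        raise KeyError(scope)


def expected_overlap(responsive, catalog: TargetCatalog, scope: str = TOTAL_SCOPE) -> float:
    """Independence expectation |responsive ∩ U| * |scope| / |U|.

    Responsive genes outside the universe are dropped (logged).
    """
    if not catalog.universe:
        raise ValidationError("catalog universe is empty")
    responsive = set(responsive)
    inside = responsive & catalog.universe
    if len(inside) < len(responsive):
        logger.info("expected_overlap: %d responsive gene(s) outside universe dropped",
                    len(responsive) - len(inside))
    return len(inside) * len(catalog.scope_set(scope)) / len(catalog.universe)


def chisq_observed_vs_expected(
    observed: float, expected: float, total_responsive: float
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of a target / non-target split.

    chi2 = (o - e)^2 / e + ((t - o) - (t - e))^2 / (t - e), upper-tail p at
    1 df, no continuity correction.
    """
    if not 0 < expected < total_responsive:
        raise ValidationError(
            f"need 0 < expected < total (got e={expected}, t={total_responsive})"
        )
    chi2 = (observed - expected) ** 2 / expected + (
        (total_responsive - observed) - (total_responsive - expected)
    ) ** 2 / (total_responsive - expected)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def sign_test(n_up: int, n_down: int) -> float:
    """Two-sided binomial sign test on an up/down direction split."""
    n = n_up + n_down
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_up, n, 0.5).pvalue)


@dataclass(frozen=True)
class OverlapResult:
    """Observed-vs-expected outcome for one scope (total or one cluster)."""

    scope: str
    observed: int
    expected: float
    chi2: float
    p: float
    up_in_overlap: int
    down_in_overlap: int
    sign_p: float

    def __post_init__(self):
        if self.up_in_overlap + self.down_in_overlap not in (0, self.observed):
            raise ValidationError(f"{self.scope}: direction split does not sum to observed")


def overlap_analysis(
    responsive_directions: dict[str, str],
    catalog: TargetCatalog,
    control_catalogs: dict[str, TargetCatalog] | None = None,
) -> dict[str, list[OverlapResult]]:
    """Full overlap analysis for a catalog and optional control catalogs.

    ``responsive_directions`` maps responsive gene ids to "up"/"down" (any
    other value contributes to the overlap but not to the direction split).
    Returns a mapping catalog-label -> [total result, per-cluster results].
    The primary catalog is keyed "catalog".
    """
    results: dict[str, list[OverlapResult]] = {}
    catalogs = {"catalog": catalog, **(control_catalogs or {})}
    for label, cat in catalogs.items():
        responsive = set(responsive_directions) & cat.universe
        total = len(responsive)
        per_catalog: list[OverlapResult] = []
        for scope in [TOTAL_SCOPE] + [cid for cid, _ in cat.clusters]:
            scope_set = cat.scope_set(scope)
            if not scope_set <= cat.universe or not scope_set:
                logger.warning("scope %r empty or outside universe; skipped", scope)
                continue
            ov = responsive & scope_set
            expected = expected_overlap(responsive, cat, scope)
            if not 0 < expected < total:
                logger.warning("scope %r: degenerate expectation (e=%.3g, t=%d); skipped",
                               scope, expected, total)
                continue
            chi2, p = chisq_observed_vs_expected(len(ov), expected, total)
            n_up = sum(1 for g in ov if responsive_directions.get(g) == "up")
            n_down = sum(1 for g in ov if responsive_directions.get(g) == "down")
            per_catalog.append(
                OverlapResult(scope, len(ov), expected, chi2, p, n_up, n_down,
                              sign_test(n_up, n_down))
            )
        results[label] = per_catalog
    return results


def overlap_frame(results: dict[str, list[OverlapResult]]) -> pd.DataFrame:
    rows = [
        {"catalog": label, **r.__dict__}
        for label, rs in results.items()
        for r in rs
    ]
    return pd.DataFrame(
        rows,
        columns=["catalog", "scope", "observed", "expected", "chi2", "p",
                 "up_in_overlap", "down_in_overlap", "sign_p"],
    )
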