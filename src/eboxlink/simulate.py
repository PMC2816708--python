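"""Synthetic data with planted ground truth for every pipeline stage.

Generators emulate the study conditions the pipeline was designed for:
two-condition triplicate expression matrices with planted log2 fold changes,
promoter sequences with planted motif instances whose positions are biased
toward the TSS (the empirically observed concentration of canonical E-boxes
within ~100 bp upstream of the start site), clustered target catalogs with
planted overlap enrichment, and pathway catalogs with planted enrichment.

Every generator is a pure function of its parameters and an explicit seed
(one fresh numpy Generator per call, no global state); identical inputs give
byte-identical outputs.  Background sequence is i.i.d. over the supplied
base frequencies (order-0), matching the order-0 expected-frequency model
used by the downstream scanners.  Planted motif instances overwrite bases in
place rather than inserting, so coordinates never shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import DNA_BASES, IUPAC_CODES, ValidationError, check_probability_vector, revcomp
from .motifs import MotifMatrix
from .overlap import TargetCatalog
from .pathways import PathwaySet
from .promoters import PromoterRecord

DEFAULT_CLUSTER_SIZES = (1712, 1643, 616, 178, 30)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(length: int, bg_freqs=(0.25, 0.25, 0.25, 0.25),
                    rng: np.random.Generator | None = None) -> str:
    """An i.i.d. DNA string over the given base frequencies."""
    bg = check_probability_vector(bg_freqs, "bg_freqs")
    rng = rng if rng is not None else np.random.default_rng()
    codes = rng.choice(4, size=length, p=bg)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


@dataclass
class SimTruth:
    """Planted ground truth, re-derivable from the emitted files."""

    planted_motif_positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    overlap_genes: list[str] = field(default_factory=list)
    enriched_pathways: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_motif_positions": self.planted_motif_positions,
                    "de_genes": self.de_genes,
                    "overlap_genes": self.overlap_genes,
                    "enriched_pathways": self.enriched_pathways,
                },
                fh, indent=1,
            )


@dataclass(frozen=True)
class PositionalModel:
    """Positional law for planted motif offsets (TSS-relative, bp)."""

    mode: str = "tss_peaked"  # "uniform" | "tss_peaked" | "fixed"
    peak_offset: int = -50
    spread: float = 30.0

    def __post_init__(self):
        if self.mode not in ("uniform", "tss_peaked", "fixed"):
            raise ValidationError("mode must be 'uniform', 'tss_peaked' or 'fixed'")
        if self.spread <= 0:
            raise ValidationError("spread must be > 0")


def gen_genome_and_tss(
    n_genes: int,
    chrom_len: int = 500_000,
    strand_fraction: float = 0.5,
    bg_freqs=(0.25, 0.25, 0.25, 0.25),
    seed: int | None = None,
    margin_up: int = 3000,
    margin_down: int = 500,
    chrom: str = "chr1",
) -> tuple[dict[str, str], pd.DataFrame]:
    """One i.i.d.-background chromosome plus a TSS table.

    TSS positions are sampled without collision inside margins wide enough
    that every gene admits the -margin_up/+margin_down window on either
    strand.  Returns (genome dict, TSS table with gene_id/chrom/tss/strand).
    """
    bg = check_probability_vector(bg_freqs, "bg_freqs")
    if n_genes < 0 or chrom_len < 1:
        raise ValidationError("n_genes >= 0 and chrom_len >= 1 required")
    rng = np.random.default_rng(seed)
    genome = {chrom: random_sequence(chrom_len, bg, rng)}
    margin = max(margin_up, margin_down)
    lo, hi = margin, chrom_len - margin - 1
    capacity = max(hi - lo + 1, 0)
    if n_genes > capacity:
        raise ValidationError(
            f"cannot place {n_genes} genes: only {capacity} admissible positions "
            f"in a {chrom_len} bp chromosome with {margin} bp margins"
        )
    if n_genes == 0:
        tss = pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"])
        return genome, tss
    positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_genes, replace=False))
    strands = np.where(rng.random(n_genes) < strand_fraction, "+", "-")
    width = len(str(n_genes))
    tss = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(n_genes)],
            "chrom": chrom,
            "tss": positions,
            "strand": strands,
        }
    )
    return genome, tss


def _sample_site(motif, rng: np.random.Generator) -> str:
    """Concrete site string from a consensus (IUPAC) or a MotifMatrix."""
    if isinstance(motif, MotifMatrix):
        return "".join(
            DNA_BASES[rng.choice(4, p=row)] for row in motif.freqs
        )
    site = []
    for c in str(motif).upper():
        choices = sorted(IUPAC_CODES[c])
        site.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0])
    return "".join(site)


def plant_motifs(
    promoters: list[PromoterRecord],
    motif,
    foreground_rate: float = 1.0,
    positional_model: PositionalModel = PositionalModel(),
    seed: int | None = None,
    both_strands: bool = True,
    max_retries: int = 100,
) -> tuple[list[PromoterRecord], SimTruth]:
    """Overwrite a motif instance into a fraction of promoters.

    A fraction ``foreground_rate`` of promoters (sampled without
    replacement) receives one planted instance at an offset drawn from the
    positional model; offsets falling outside the admissible range are
    resampled up to ``max_retries`` times before failing.  The truth records
    each planted (promoter, TSS-relative offset of the site's first base,
    strand).
    """
    if not 0 <= foreground_rate <= 1:
        raise ValidationError("foreground_rate must be in [0, 1]")
    width = motif.width if isinstance(motif, MotifMatrix) else len(str(motif))
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    out = list(promoters)
    n_plant = int(round(foreground_rate * len(promoters)))
    if n_plant == 0:
        return out, truth
    chosen = rng.choice(len(promoters), size=n_plant, replace=False)
    for idx in sorted(chosen):
        p = promoters[idx]
        if width > len(p.seq):
            raise ValidationError(f"{p.gene_id}: motif wider than promoter window")
        off0 = p.tss_offset_of_first_base
        lo, hi = off0, off0 + len(p.seq) - width  # admissible first-base offsets
        for attempt in range(max_retries):
            if positional_model.mode == "uniform":
                offset = int(rng.integers(lo, hi + 1))
            elif positional_model.mode == "fixed":
                offset = positional_model.peak_offset
            else:
                offset = int(round(rng.normal(positional_model.peak_offset,
                                              positional_model.spread)))
            if lo <= offset <= hi:
                break
        else:
            raise ValidationError(
                f"{p.gene_id}: no in-window offset found in {max_retries} draws"
            )
        strand = "+" if not both_strands or rng.random() < 0.5 else "-"
        site = _sample_site(motif, rng)
        written = site if strand == "+" else revcomp(site)
        i = offset - off0
        new_seq = p.seq[:i] + written + p.seq[i + width:]
        out[idx] = PromoterRecord(p.gene_id, p.window_up, p.window_down,
                                  new_seq, p.tss_offset_of_first_base)
        truth.planted_motif_positions.setdefault(p.gene_id, []).append((offset, strand))
    return out, truth


def gen_expression(
    universe: list[str],
    n_reps: int = 3,
    de_fraction: float = 0.05,
    lfc_magnitude: float = 1.0,
    noise_sd: float = 0.25,
    seed: int | None = None,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-condition log2 expression matrix with planted fold changes.

    Defaults reflect the emulated study design: three biological replicates
    per condition and a 2-fold (1 log2 unit) planted effect in a small
    fraction of genes, on top of replicate noise of 0.25 log2 units.
    Columns are labelled control_1..n, treated_1..n.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2 (t-test undefined otherwise)")
    if not 0 <= de_fraction <= 1:
        raise ValidationError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(universe)
    m = len(genes)
    baseline = rng.normal(baseline_mean, baseline_sd, size=m)
    values = np.repeat(baseline[:, None], 2 * n_reps, axis=1)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=(m, 2 * n_reps))
    truth = SimTruth()
    n_de = int(round(de_fraction * m))
    if n_de:
        de_idx = np.sort(rng.choice(m, size=n_de, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_de)
        values[de_idx, n_reps:] += (signs * lfc_magnitude)[:, None]
        truth.de_genes = {genes[i]: float(s * lfc_magnitude)
                          for i, s in zip(de_idx, signs)}
    cols = [f"control_{r + 1}" for r in range(n_reps)] + [
        f"treated_{r + 1}" for r in range(n_reps)
    ]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols)
    return df, truth


def gen_target_catalog(
    universe: list[str],
    cluster_sizes=DEFAULT_CLUSTER_SIZES,
    responsive_set=(),
    enrichment_factor: float = 1.0,
    seed: int | None = None,
) -> tuple[TargetCatalog, SimTruth]:
    """Disjoint target clusters with tunable overlap enrichment.

    Cluster members are sampled without replacement, cluster by cluster in
    the given order, with genes in ``responsive_set`` weighted by
    ``enrichment_factor`` relative to baseline (0 excludes them; 1 is the
    independence null).  Default cluster sizes mirror the five usable
    temporal-response clusters of the emulated c-Myc target catalog.
    """
    universe = list(universe)
    n = len(universe)
    sizes = [int(s) for s in cluster_sizes]
    if any(s < 1 for s in sizes):
        raise ValidationError("cluster sizes must be >= 1")
    if sum(sizes) > n:
        raise ValidationError(f"cluster sizes sum to {sum(sizes)} > universe {n}")
    if enrichment_factor < 0:
        raise ValidationError("enrichment_factor must be >= 0")
    responsive = set(responsive_set)
    rng = np.random.default_rng(seed)
    weights = np.array([enrichment_factor if g in responsive else 1.0 for g in universe])
    # feasibility: the most-weighted gene's inclusion probability in the
    # largest cluster must not exceed 1 under the renormalized weights
    if weights.sum() <= 0:
        raise ValidationError("all sampling weights are zero")
    max_p = weights.max() / weights.sum() * max(sizes)
    if max_p > 1 + 1e-12:
        raise ValidationError(
            f"infeasible enrichment: implied membership probability {max_p:.3g} > 1"
        )
    available = np.ones(n, dtype=bool)
    clusters = []
    for ci, size in enumerate(sizes, start=1):
        idx_avail = np.nonzero(available)[0]
        w = weights[idx_avail]
        if (w > 0).sum() < size:
            raise ValidationError(
                f"cluster {ci}: only {(w > 0).sum()} genes with positive weight left"
            )
        p = w / w.sum()
        chosen = rng.choice(idx_avail, size=size, replace=False, p=p)
        available[chosen] = False
        clusters.append(
            (f"cluster{ci}", frozenset(universe[i] for i in chosen))
        )
    catalog = TargetCatalog(tuple(clusters), frozenset(universe))
    truth = SimTruth(
        overlap_genes=sorted(responsive & set().union(*(m for _, m in clusters)))
    )
    return catalog, truth


def gen_pathways(
    universe: list[str],
    n_pathways: int = 50,
    size_range: tuple[int, int] = (10, 100),
    enriched_pathway_count: int = 0,
    sig_set=(),
    enrichment_weight: float = 4.0,
    seed: int | None = None,
) -> tuple[list[PathwaySet], SimTruth]:
    """Pathway catalog drawn from the universe, some enriched for sig_set.

    The first ``enriched_pathway_count`` pathways oversample genes in
    ``sig_set`` by ``enrichment_weight``; the rest sample uniformly.
    """
    universe = list(universe)
    n = len(universe)
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 1:
        raise ValidationError("pathway sizes must be >= 1")
    if hi > n:
        raise ValidationError(f"size_range upper bound {hi} exceeds universe size {n}")
    if lo > hi:
        raise ValidationError("size_range must be (low, high) with low <= high")
    if enriched_pathway_count > n_pathways:
        raise ValidationError("enriched_pathway_count exceeds n_pathways")
    sig = set(sig_set)
    rng = np.random.default_rng(seed)
    w_enriched = np.array([enrichment_weight if g in sig else 1.0 for g in universe])
    w_enriched = w_enriched / w_enriched.sum()
    truth = SimTruth()
    out = []
    width = len(str(max(n_pathways, 1)))
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < enriched_pathway_count
        p = w_enriched if enriched else None
        members = rng.choice(n, size=size, replace=False, p=p)
        pid = f"pw{i + 1:0{width}d}"
        desc = "planted-enriched" if enriched else "null"
        out.append(PathwaySet(pid, desc, frozenset(universe[j] for j in members)))
        if enriched:
            truth.enriched_pathways.append(pid)
    return out, truth
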