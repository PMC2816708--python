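"""Motif matrix parsing and promoter scanning.

Two scanning modes are provided:

* exact consensus matching against an IUPAC pattern (used for the canonical
  E-box CACGTG), and
* position-weight-matrix (PWM) scanning with an order-0 background model and
  a prior on site occurrence, in the style of MotifScanner.

The PWM hit rule: a length-w window ``x`` is a hit iff the log-odds

    log P(x | motif) - log P(x | background)  >  log((1 - prior) / prior)

i.e. iff the posterior odds of "motif" versus "background" exceed 1 when each
window carries prior probability ``prior`` of being a site.  The default
prior of 0.1 matches the setting used for promoter scans of
rapamycin-co-regulated genes.  Both strands are scanned by default; windows
containing N are skipped (and tallied); overlapping hits are all reported.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from ._util import (
    DNA_BASES,
    IUPAC_CODES,
    ParseError,
    ValidationError,
    check_probability_vector,
    encode_seq,
    revcomp,
)
from .promoters import PromoterRecord

logger = logging.getLogger(__name__)

UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class BackgroundModel:
    """Order-0 background: genome-wide/base-composition probabilities."""

    base_freqs: np.ndarray
    source_label: str = "uniform"

    def __post_init__(self):
        freqs = check_probability_vector(self.base_freqs, "background base_freqs")
        if np.any(freqs <= 0):
            raise ValidationError("background frequencies must all be > 0")
        object.__setattr__(self, "base_freqs", freqs)

    @classmethod
    def from_sequences(cls, seqs, source_label: str = "estimated") -> "BackgroundModel":
        """Estimate base frequencies by direct counting over sequences."""
        counts = np.zeros(4)
        for s in seqs:
            enc = encode_seq(s if isinstance(s, str) else s.seq)
            counts += np.bincount(enc[enc < 4], minlength=4)
        if counts.sum() == 0:
            raise ValidationError("no ACGT bases to estimate background from")
        return cls(counts / counts.sum(), source_label)


@dataclass(frozen=True)
class ScanParams:
    """Scanning knobs: site prior and strand handling."""

    prior: float = 0.1
    strands: str = "both"  # "both" | "forward"

    def __post_init__(self):
        if not 0 < self.prior < 1:
            raise ValidationError(f"prior must be in (0, 1), got {self.prior}")
        if self.strands not in ("both", "forward"):
            raise ValidationError("strands must be 'both' or 'forward'")

    @property
    def threshold(self) -> float:
        """Log-odds hit threshold log((1-prior)/prior), natural log."""
        return math.log((1.0 - self.prior) / self.prior)


@dataclass(frozen=True)
class MotifMatrix:
    """A position frequency matrix over (A, C, G, T).

    ``freqs`` rows are per-position base probabilities after pseudocount
    regularization; each row sums to 1.
    """

    matrix_id: str
    freqs: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4 or freqs.shape[0] < 1:
            raise ValidationError(f"{self.matrix_id}: freqs must be (width, 4), width >= 1")
        if np.any(np.abs(freqs.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError(f"{self.matrix_id}: rows must sum to 1")
        object.__setattr__(self, "freqs", freqs)

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(DNA_BASES[i] for i in self.freqs.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        matrix_id: str,
        counts,
        pseudocount: float = 0.01,
        bg: np.ndarray | None = None,
    ) -> "MotifMatrix":
        """Convert a count matrix to frequencies.

        The pseudocount mass is distributed proportionally to the background
        base frequencies: freq[i, b] = (count[i, b] + pc * bg[b]) / (row_total + pc).
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValidationError(f"{matrix_id}: counts must be (width, 4)")
        if np.any(counts < 0):
            raise ValidationError(f"{matrix_id}: negative counts")
        bgv = UNIFORM_BG if bg is None else check_probability_vector(bg, "bg")
        row_tot = counts.sum(axis=1, keepdims=True)
        freqs = (counts + pseudocount * bgv) / (row_tot + pseudocount)
        return cls(matrix_id, freqs, pseudocount)

    @classmethod
    def from_consensus(
        cls, matrix_id: str, consensus: str, pseudocount: float = 1e-6
    ) -> "MotifMatrix":
        """Near-point-mass matrix on a concrete consensus (degenerate PWM)."""
        counts = np.zeros((len(consensus), 4))
        for i, c in enumerate(consensus.upper()):
            for b in IUPAC_CODES[c]:
                counts[i, DNA_BASES.index(b)] = 1.0 / len(IUPAC_CODES[c])
        return cls.from_counts(matrix_id, counts, pseudocount)

    def log_odds(self, bg: BackgroundModel) -> np.ndarray:
        """(width, 4) natural-log odds table log(freq / bg)."""
        if np.any(bg.base_freqs <= 0):
            raise ValidationError("background frequency of zero: log-odds undefined")
        with np.errstate(divide="ignore"):
            return np.log(self.freqs) - np.log(bg.base_freqs)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence in a promoter.

    ``offset`` is the TSS-relative position of the site's first base in
    gene-strand orientation; ``strand`` is the hit strand relative to the
    promoter orientation; ``site_seq`` reads in the hit's own orientation
    (the reverse complement of the window for - hits).
    """

    gene_id: str
    matrix_id: str
    offset: int
    strand: str
    site_seq: str
    score: float


# ---------------------------------------------------------------------------
# matrix-file parsing (TRANSFAC flat and JASPAR), delegating to Bio.motifs


_TRANSFAC_ROW = re.compile(r"^\d\d\s")


def _validate_transfac_rows(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if _TRANSFAC_ROW.match(line):
            fields = line.split()
            # position, four counts, optional consensus letter
            if len(fields) not in (5, 6):
                raise ParseError(
                    f"line {lineno}: expected 4 count columns, got {len(fields) - 1}"
                )


def parse_transfac(text: str, pseudocount: float = 0.01, bg=None) -> list[MotifMatrix]:
    """Parse TRANSFAC flat-format count matrices into MotifMatrix objects.

    Matrix ids join the AC and ID fields as in "M00119-V$MAX_01"; counts are
    converted to frequencies with the background-weighted pseudocount.
    """
    if not text.strip():
        return []
    _validate_transfac_rows(text)
    try:
        records = bio_motifs.parse(StringIO(text), "transfac")
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise ParseError(f"TRANSFAC parse failure: {exc}") from exc
    out = []
    for m in records:
        ac = m.get("AC")
        mid = m.get("ID") or m.name
        matrix_id = f"{ac}-{mid}" if ac and mid else (ac or mid or "unnamed")
        counts = np.array([[m.counts[b][i] for b in DNA_BASES] for i in range(m.length)])
        out.append(MotifMatrix.from_counts(matrix_id, counts, pseudocount, bg))
    return out


def parse_jaspar_pfm(text: str, pseudocount: float = 0.01, bg=None) -> list[MotifMatrix]:
    """Parse JASPAR PFM records (">id name" header + four base rows)."""
    if not text.strip():
        return []
    try:
        records = bio_motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"JASPAR parse failure: {exc}") from exc
    out = []
    for m in records:
        matrix_id = m.matrix_id or m.name or "unnamed"
        counts = np.array([[m.counts[b][i] for b in DNA_BASES] for i in range(m.length)])
        out.append(MotifMatrix.from_counts(matrix_id, counts, pseudocount, bg))
    return out


# ---------------------------------------------------------------------------
# scanning


def _iupac_pattern_ok(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise ValidationError("empty pattern")
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValidationError(f"invalid IUPAC letter(s) {sorted(bad)} in pattern")
    return pattern


def _consensus_positions(seq: str, pattern: str) -> list[int]:
    """0-based start positions where ``pattern`` (IUPAC) exactly matches.

    Windows containing any character outside ACGT (including N) never match.
    """
    w = len(pattern)
    sets = [IUPAC_CODES[c] for c in pattern]
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if all(b in s and b in "ACGT" for b, s in zip(window, sets)):
            hits.append(i)
    return hits


def scan_consensus(
    promoter: PromoterRecord, pattern: str, strands: str = "both"
) -> list[MotifHit]:
    """Exact-match scan for an IUPAC consensus pattern.

    Minus-strand hits are reported at the offset of the site's first base in
    promoter orientation.  For self-reverse-complementary patterns (such as
    the canonical E-box CACGTG) the two strands yield the same position set
    and hits are deduplicated to the forward report.
    """
    pattern = _iupac_pattern_ok(pattern)
    seq = promoter.seq.upper()
    hits = [
        MotifHit(promoter.gene_id, pattern, promoter.offset_of(i), "+",
                 seq[i : i + len(pattern)], 0.0)
        for i in _consensus_positions(seq, pattern)
    ]
    if strands == "both":
        rc = revcomp(pattern)
        palindromic = rc == pattern
        if not palindromic:
            for i in _consensus_positions(seq, rc):
                hits.append(
                    MotifHit(promoter.gene_id, pattern, promoter.offset_of(i), "-",
                             revcomp(seq[i : i + len(pattern)]), 0.0)
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _window_scores(enc: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window log-odds scores plus validity mask (no N in window)."""
    w = lo.shape[0]
    n_win = len(enc) - w + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    # pad the table so code 4 (N) scores 0 but is masked invalid
    lo_pad = np.hstack([lo, np.zeros((w, 1))])
    for j in range(w):
        col = enc[j : j + n_win]
        scores += lo_pad[j, col]
        valid &= col < 4
    return scores, valid


def scan_pwm(
    promoter: PromoterRecord,
    matrix: MotifMatrix,
    bg: BackgroundModel,
    params: ScanParams = ScanParams(),
) -> list[MotifHit]:
    """PWM scan under the posterior-odds hit rule (see module docstring).

    Minus-strand windows are scored by reverse complementing the window
    against the same matrix; windows containing N are skipped and tallied in
    the debug log.
    """
    if len(promoter.seq) < matrix.width:
        return []
    enc = encode_seq(promoter.seq.upper())
    lo = matrix.log_odds(bg)
    thr = params.threshold
    hits: list[MotifHit] = []
    fwd_scores, valid = _window_scores(enc, lo)
    n_skipped = int((~valid).sum())
    w = matrix.width
    for i in np.nonzero(valid & (fwd_scores > thr))[0]:
        hits.append(
            MotifHit(promoter.gene_id, matrix.matrix_id, promoter.offset_of(int(i)),
                     "+", promoter.seq[i : i + w], float(fwd_scores[i]))
        )
    # scoring revcomp(window) against M == scoring window against M with
    # rows reversed and columns complement-swapped; for a strand-symmetric
    # (palindromic) matrix the two passes coincide, so the minus pass is
    # skipped to avoid double-reporting the same site
    lo_rc = lo[::-1, ::-1]
    if params.strands == "both" and not np.allclose(lo, lo_rc):
        rev_scores, valid_r = _window_scores(enc, lo_rc)
        for i in np.nonzero(valid_r & (rev_scores > thr))[0]:
            hits.append(
                MotifHit(promoter.gene_id, matrix.matrix_id, promoter.offset_of(int(i)),
                         "-", revcomp(promoter.seq[i : i + w]), float(rev_scores[i]))
            )
    if n_skipped:
        logger.debug("%s/%s: skipped %d windows containing N",
                     promoter.gene_id, matrix.matrix_id, n_skipped)
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def count_feature_hits(
    promoters: list[PromoterRecord],
    matrices: list[MotifMatrix],
    bg: BackgroundModel,
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """Per-matrix hit tally across a promoter set.

    ``n`` counts hit *instances* (a promoter may contribute several),
    ``genes_hit`` counts promoters with at least one hit.  Rows are ordered
    by matrix_id for determinism.
    """
    rows = []
    for m in sorted(matrices, key=lambda m: m.matrix_id):
        n = 0
        genes = 0
        for p in promoters:
            k = len(scan_pwm(p, m, bg, params))
            n += k
            genes += k > 0
        rows.append({"matrix_id": m.matrix_id, "n": n, "genes_hit": genes})
    return pd.DataFrame(rows, columns=["matrix_id", "n", "genes_hit"])


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    cols = ["gene_id", "matrix_id", "offset", "strand", "site_seq", "score"]
    return pd.DataFrame([h.__dict__ for h in hits], columns=cols)
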