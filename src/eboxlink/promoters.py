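"""Genome/TSS I/O and strand-aware promoter window extraction.

Two window presets are used throughout the pipeline: the proximal-promoter
preset (1,000 bp upstream, 200 bp downstream of the TSS) used for motif
over-representation, and the wide preset (3,000 bp upstream, 500 bp
downstream) used for E-box positional analysis.

Coordinate conventions
----------------------
Genomic coordinates are 0-based, half-open (BED native). The TSS base itself
is the first *downstream* base: a window of ``window_up`` upstream and
``window_down`` downstream bases has length exactly ``window_up +
window_down`` when unclipped.  Promoter sequences are always oriented
5'->3' on the gene's strand; offsets are signed bp relative to the TSS
(upstream negative, TSS = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import IUPAC_CODES, ParseError, ValidationError, revcomp

logger = logging.getLogger(__name__)

#: (window_up, window_down) presets.
PROXIMAL_WINDOW = (1000, 200)
WIDE_WINDOW = (3000, 500)


@dataclass(frozen=True)
class PromoterRecord:
    """A strand-resolved promoter window anchored at a TSS.

    ``seq`` is oriented 5'->3' on the gene's strand; position ``i`` of the
    sequence lies at TSS offset ``tss_offset_of_first_base + i``.
    """

    gene_id: str
    window_up: int
    window_down: int
    seq: str
    tss_offset_of_first_base: int

    def __post_init__(self):
        if len(self.seq) > self.window_up + self.window_down:
            raise ValidationError(
                f"{self.gene_id}: sequence longer than window "
                f"({len(self.seq)} > {self.window_up + self.window_down})"
            )

    def offset_of(self, index: int) -> int:
        """TSS-relative offset of sequence position ``index``."""
        return self.tss_offset_of_first_base + index

    @property
    def clipped(self) -> bool:
        return len(self.seq) < self.window_up + self.window_down


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: upper-case sequence}``.

    Raises on duplicate record names and on non-IUPAC characters.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate sequence name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set(IUPAC_CODES)
        if bad:
            raise ParseError(
                f"record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED6 TSS annotation into columns (gene_id, chrom, tss, strand).

    For + strand genes the TSS is ``start``; for - strand genes it is
    ``end - 1`` (the 0-based position of the transcription-start base).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ParseError(
            f"invalid strand value(s) {sorted(df.loc[bad_strand, 'strand'].unique())}"
        )
    if (df["start"] >= df["end"]).any():
        rows = df.index[df["start"] >= df["end"]].tolist()
        raise ParseError(f"start >= end at row(s) {rows}")
    if df["gene_id"].duplicated().any():
        dups = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ParseError(f"duplicate gene ids {dups}")
    tss = df["start"].where(df["strand"] == "+", df["end"] - 1)
    return pd.DataFrame(
        {"gene_id": df["gene_id"], "chrom": df["chrom"], "tss": tss, "strand": df["strand"]}
    )


def write_tss_bed(tss_table: pd.DataFrame, path) -> None:
    """Write the (gene_id, chrom, tss, strand) table back to single-base BED6."""
    t = tss_table
    # single-base interval covering the TSS base under the read_tss_bed convention
    bed = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["tss"],
            "end": t["tss"] + 1,
            "name": t["gene_id"],
            "score": 0,
            "strand": t["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def extract_promoters(
    genome: dict[str, str],
    tss_table: pd.DataFrame,
    window_up: int,
    window_down: int,
    clip: bool = False,
) -> list[PromoterRecord]:
    """Extract strand-aware promoter windows around each TSS.

    + strand: genomic interval [tss - window_up, tss + window_down);
    - strand: [tss - window_down + 1, tss + window_up + 1), reverse
    complemented so the result reads 5'->3' on the gene strand.

    With ``clip=False`` a window extending past a chromosome end raises a
    boundary error listing the offending gene ids; with ``clip=True`` the
    window is truncated and ``tss_offset_of_first_base`` reflects the bases
    actually present.
    """
    if window_up < 0 or window_down < 0:
        raise ValidationError("window_up and window_down must be >= 0")
    out: list[PromoterRecord] = []
    out_of_bounds: list[str] = []
    for row in tss_table.itertuples(index=False):
        chrom_seq = genome[row.chrom]
        L = len(chrom_seq)
        if not 0 <= row.tss < L:
            raise ValidationError(f"{row.gene_id}: TSS {row.tss} outside chromosome {row.chrom}")
        if row.strand == "+":
            a, b = row.tss - window_up, row.tss + window_down
        else:
            a, b = row.tss - window_down + 1, row.tss + window_up + 1
        if (a < 0 or b > L) and not clip:
            out_of_bounds.append(row.gene_id)
            continue
        a_c, b_c = max(a, 0), min(b, L)
        raw = chrom_seq[a_c:b_c] if b_c > a_c else ""
        if row.strand == "+":
            eff_up = row.tss - a_c
            seq = raw
        else:
            eff_up = b_c - (row.tss + 1)
            seq = revcomp(raw)
        out.append(
            PromoterRecord(
                gene_id=row.gene_id,
                window_up=window_up,
                window_down=window_down,
                seq=seq,
                tss_offset_of_first_base=-eff_up,
            )
        )
    if out_of_bounds:
        raise ValidationError(
            f"promoter window outside chromosome for gene(s) {out_of_bounds}; "
            "pass clip=True to truncate"
        )
    return out


def write_promoter_fasta(promoters: list[PromoterRecord], path) -> None:
    """Write promoters as FASTA with headers gene_id|offset|window_up|window_down."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f">{p.gene_id}|{p.tss_offset_of_first_base}|{p.window_up}|{p.window_down}\n"
            )
            for i in range(0, len(p.seq), 70):
                fh.write(p.seq[i : i + 70] + "\n")


def read_promoter_fasta(path) -> list[PromoterRecord]:
    out = []
    for name, seq in read_fasta(path).items():
        parts = name.split("|")
        if len(parts) != 4:
            raise ParseError(f"promoter header {name!r} lacks gene_id|offset|up|down fields")
        gene_id, off, up, down = parts
        out.append(PromoterRecord(gene_id, int(up), int(down), seq, int(off)))
    return out
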