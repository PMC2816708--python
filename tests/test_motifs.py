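"""Matrix parsing and scanning: exact oracles and invariance properties."""

import math

import numpy as np
import pytest

from eboxlink import (
    MotifMatrix,
    ParseError,
    ScanParams,
    count_feature_hits,
    parse_jaspar_pfm,
    parse_transfac,
    scan_consensus,
    scan_pwm,
)
from eboxlink._util import revcomp
from tests.conftest import make_promoter

TRANSFAC_BLOCK = """\
AC  M00001
XX
ID  V$TEST_01
XX
P0      A      C      G      T
01      8      0      0      0
02      0      8      0      0
03      0      0      8      0
04      0      0      0      8
05      8      0      0      0
06      0      8      0      0
XX
//
"""


class TestParsers:
    def test_transfac_consensus_recoverable(self):
        (m,) = parse_transfac(TRANSFAC_BLOCK, pseudocount=0.0)
        assert m.matrix_id == "M00001-V$TEST_01"
        assert m.consensus == "ACGTAC"

    def test_pseudocount_distributed_by_background(self):
        (m,) = parse_transfac(TRANSFAC_BLOCK, pseudocount=0.01)
        # counts (8,0,0,0): freq A = (8 + 0.01*0.25) / (8 + 0.01)
        assert m.freqs[0, 0] == pytest.approx((8 + 0.0025) / 8.01, rel=1e-12)
        assert m.freqs[0, 1] == pytest.approx(0.0025 / 8.01, rel=1e-12)

    def test_empty_input(self):
        assert parse_transfac("") == []
        assert parse_jaspar_pfm("  \n") == []

    def test_ragged_row_reports_line_number(self):
        bad = TRANSFAC_BLOCK.replace("03      0      0      8      0", "03      0      8")
        with pytest.raises(ParseError, match="line 8"):
            parse_transfac(bad)

    def test_jaspar_pfm(self):
        text = (
            ">MA0001.1 TEST\n"
            "A [ 0  5  0 ]\n"
            "C [ 5  0  0 ]\n"
            "G [ 0  0  5 ]\n"
            "T [ 0  0  0 ]\n"
        )
        (m,) = parse_jaspar_pfm(text, pseudocount=0.0)
        assert m.consensus == "CAG"
        assert m.matrix_id == "MA0001.1"


class TestScanConsensus:
    def test_canonical_ebox_found_in_known_site(self):
        p = make_promoter("TAATCACGTGATTG")
        hits = scan_consensus(p, "CACGTG")
        assert [(h.offset, h.strand) for h in hits] == [(4, "+")]
        assert hits[0].site_seq == "CACGTG"

    def test_non_canonical_site_not_matched(self):
        # contains CACATG (one mismatch from canonical) only
        assert scan_consensus(make_promoter("CACCACATGGGA"), "CACGTG") == []

    def test_palindrome_strand_invariance(self):
        p = make_promoter("GGCACGTGTTCACGTGAA")
        fwd = scan_consensus(p, "CACGTG", strands="forward")
        both = scan_consensus(p, "CACGTG", strands="both")
        assert [(h.offset, h.strand) for h in fwd] == [(h.offset, h.strand) for h in both]
        assert len(both) == 2

    def test_non_palindromic_minus_strand_reported(self):
        # GAATTC-free case: pattern CCCGTA, revcomp TACGGG present on fwd text
        p = make_promoter("AATACGGGTT")
        hits = scan_consensus(p, "CCCGTA", strands="both")
        assert [(h.offset, h.strand) for h in hits] == [(2, "-")]
        assert hits[0].site_seq == "CCCGTA"

    def test_window_with_n_never_matches(self):
        assert scan_consensus(make_promoter("CACNTG"), "CACNTG") == []

    def test_invalid_iupac_letter(self):
        with pytest.raises(Exception, match="IUPAC"):
            scan_consensus(make_promoter("ACGT"), "AZ")


def brute_force_pwm_hits(promoter, matrix, bg, params):
    """Independent per-window log-odds enumeration (plain Python)."""
    thr = math.log((1 - params.prior) / params.prior)
    w = matrix.width
    hits = []
    strands = ["+"] if params.strands == "forward" else ["+", "-"]
    lo = np.log(matrix.freqs) - np.log(bg.base_freqs)
    palindromic = np.allclose(lo, lo[::-1, ::-1])
    for i in range(len(promoter.seq) - w + 1):
        window = promoter.seq[i : i + w]
        if any(c not in "ACGT" for c in window):
            continue
        for strand in strands:
            if strand == "-" and palindromic:
                continue
            site = window if strand == "+" else revcomp(window)
            score = sum(
                math.log(matrix.freqs[j, "ACGT".index(c)] / bg.base_freqs["ACGT".index(c)])
                for j, c in enumerate(site)
            )
            if score > thr:
                hits.append((promoter.offset_of(i), strand, round(score, 9)))
    return sorted(hits)


class TestScanPwm:
    def test_degenerate_pwm_equals_consensus_scan(self, uniform_bg, scan_params, ebox_matrix):
        p = make_promoter("TTCACGTGCCACGTGA" * 3)
        pwm_hits = {(h.offset, h.strand) for h in scan_pwm(p, ebox_matrix, uniform_bg, scan_params)}
        cons_hits = {(h.offset, h.strand) for h in scan_consensus(p, "CACGTG")}
        assert pwm_hits == cons_hits

    def test_threshold_beyond_max_score_gives_no_hits(self, uniform_bg, ebox_matrix):
        # prior so small that log((1-prior)/prior) exceeds the max attainable score
        max_score = float(np.log(ebox_matrix.freqs.max(axis=1) / 0.25).sum())
        prior = 1.0 / (1.0 + math.exp(max_score + 1))
        params = ScanParams(prior=prior)
        p = make_promoter("CACGTG" * 10)
        assert scan_pwm(p, ebox_matrix, uniform_bg, params) == []

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_bruteforce_enumeration(self, seed, uniform_bg, scan_params):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 10, size=(7, 4))
        m = MotifMatrix.from_counts("rand", counts + 1, pseudocount=0.5)
        seq = "".join("ACGTN"[b] for b in rng.choice(5, p=[0.24] * 4 + [0.04], size=400))
        p = make_promoter(seq, window_up=200, window_down=200, offset=-200)
        got = sorted(
            (h.offset, h.strand, round(h.score, 9))
            for h in scan_pwm(p, m, uniform_bg, scan_params)
        )
        assert got == brute_force_pwm_hits(p, m, uniform_bg, scan_params)

    def test_prior_monotonicity(self, uniform_bg):
        rng = np.random.default_rng(5)
        m = MotifMatrix.from_counts("rand", rng.integers(1, 9, size=(6, 4)), 0.1)
        p = make_promoter("".join("ACGT"[b] for b in rng.integers(0, 4, 500)))
        previous: set = set()
        for prior in (0.001, 0.01, 0.1, 0.5, 0.9):
            hits = {(h.offset, h.strand) for h in scan_pwm(p, m, uniform_bg, ScanParams(prior=prior))}
            assert previous <= hits  # raising the prior only grows the hit set
            previous = hits

    def test_prepended_bases_leave_genomic_positions_unchanged(self, uniform_bg, scan_params, ebox_matrix):
        p = make_promoter("AACACGTGTT", window_up=5, window_down=5, offset=-5)
        extended = make_promoter("GGGG" + p.seq, window_up=9, window_down=5, offset=-9)
        base = {(h.offset, h.strand) for h in scan_pwm(p, ebox_matrix, uniform_bg, scan_params)}
        ext = {(h.offset, h.strand) for h in scan_pwm(extended, ebox_matrix, uniform_bg, scan_params)}
        assert base <= ext


class TestCountFeatureHits:
    def test_instances_vs_genes(self, uniform_bg, scan_params, ebox_matrix):
        p = make_promoter("CACGTGAAAACACGTG")
        df = count_feature_hits([p], [ebox_matrix], uniform_bg, scan_params)
        assert df.loc[0, "n"] == 2
        assert df.loc[0, "genes_hit"] == 1

    def test_empty_promoter_set(self, uniform_bg, scan_params, ebox_matrix):
        df = count_feature_hits([], [ebox_matrix], uniform_bg, scan_params)
        assert list(df["n"]) == [0]

    def test_order_invariance_and_sorted_ids(self, uniform_bg, scan_params, random_promoters):
        ms = [
            MotifMatrix.from_consensus("B-EBOX", "CACGTG"),
            MotifMatrix.from_consensus("A-GC", "GGCGCC"),
        ]
        df1 = count_feature_hits(random_promoters, ms, uniform_bg, scan_params)
        df2 = count_feature_hits(random_promoters[::-1], ms[::-1], uniform_bg, scan_params)
        assert df1.equals(df2)
        assert list(df1["matrix_id"]) == ["A-GC", "B-EBOX"]
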