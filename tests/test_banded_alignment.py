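"""Guide bands and the quality-aware banded aligner."""

import numpy as np
import pytest

from smsmap.banded_alignment import (
    BandError,
    GuideBand,
    banded_align,
    build_guide_band,
    path_cost,
)
from smsmap.config import MapperConfig
from smsmap.refinement import SdpChain
from smsmap.seq_io import QualityArrays, SeqRecord

from conftest import full_dp_cost, random_seq


def full_band(R, l_C):
    return GuideBand(lo=np.zeros(R + 1, dtype=int), hi=np.full(R + 1, l_C))


def flat_qv(seq, ins=15, sub=20, dele=15, sub_alt=None, del_alt=None):
    n = len(seq)
    return QualityArrays(
        ins=[ins] * n, sub=[sub] * n, del_=[dele] * n,
        sub_alt=sub_alt or "N" * n, del_alt=del_alt or "N" * n,
    )


class TestGuideBand:
    def test_identity_chain_bands_follow_main_diagonal(self):
        cfg = MapperConfig(b_sdp=15, k_sdp=11)
        chain = SdpChain(matches=[(i, i) for i in range(30)], k=11)
        band = build_guide_band(chain, R=40, l_C=40, cfg=cfg)
        for i in range(41):
            assert band.lo[i] == max(i - 15, 0)
            assert band.hi[i] == min(i + 15, 40)

    def test_drift_widens_between_matches(self):
        cfg = MapperConfig(b_sdp=15, k_sdp=5)
        # two matches on diagonals 30 and 38 with a gap of rows between them
        chain = SdpChain(matches=[(0, 30), (20, 58)], k=5)
        band = build_guide_band(chain, R=40, l_C=110, cfg=cfg)
        # inter-match rows get half-width |38 - 30| + 15 = 23
        mid = 10
        assert band.lo[mid] <= mid + 30 - 23
        assert band.hi[mid] >= mid + 30 + 23
        # on-match rows keep the tight b_sdp half-width on their diagonal
        assert band.hi[3] >= 3 + 30 + 15 and band.lo[24] <= 24 + 38 - 15

    def test_empty_chain_full_band(self):
        band = build_guide_band(SdpChain(matches=[], k=11), R=50, l_C=50,
                                cfg=MapperConfig())
        assert band.lo.tolist() == [0] * 51
        assert band.hi.tolist() == [50] * 51

    def test_band_invariants_on_random_chains(self, rng):
        cfg = MapperConfig(b_sdp=5, k_sdp=4)
        for _ in range(20):
            rows = sorted(rng.choice(60, size=4, replace=False).tolist())
            matches = [(int(r), int(r + rng.integers(-8, 9))) for r in rows]
            matches = [(r, max(g, 0)) for r, g in matches]
            chain = SdpChain(matches=matches, k=4)
            band = build_guide_band(chain, R=70, l_C=90, cfg=cfg)
            assert np.all(band.hi >= band.lo)
            assert np.all(np.diff(band.lo) >= 0)
            assert np.all(np.diff(band.hi) >= 0)
            assert np.all(band.lo[1:] <= band.hi[:-1] + 1)


class TestAlignerExamples:
    def test_identity_costs_zero(self):
        cfg = MapperConfig()
        read = SeqRecord(id="r", seq="ACGTACGT")
        res = banded_align(read, "ACGTACGT", full_band(8, 8), cfg)
        assert res.cost == 0.0
        assert res.cigar == [("M", 8)]
        assert res.n_match == 8 and res.n_mismatch == 0

    def test_substitution_quality_discount(self):
        # mismatch at the last base, but the alternative call explains the
        # genome base: pay S_i = 5, not the mismatch prior
        cfg = MapperConfig()
        qv = flat_qv("ACGA", sub=5, sub_alt="NNNT")
        read = SeqRecord(id="r", seq="ACGA", qv=qv)
        res = banded_align(read, "ACGT", full_band(4, 4), cfg)
        assert res.cost == 5.0
        assert res.cigar == [("M", 4)]

    def test_flat_deletion_prior(self):
        cfg = MapperConfig()
        read = SeqRecord(id="r", seq="ACGT")
        res = banded_align(read, "ACAGT", full_band(4, 5), cfg)
        assert res.cost == 15.0
        assert res.cigar == [("M", 2), ("D", 1), ("M", 2)]

    def test_insertion_quality_used(self):
        cfg = MapperConfig()
        qv = flat_qv("ACXGT".replace("X", "A"), ins=7)
        read = SeqRecord(id="r", seq="ACAGT", qv=qv)
        res = banded_align(read, "ACGT", full_band(5, 4), cfg)
        assert res.cost == 7.0
        assert res.n_ins == 1

    def test_free_interval_ends(self):
        # read aligns in the middle of a longer interval at zero cost
        cfg = MapperConfig()
        read = SeqRecord(id="r", seq="CGTA")
        res = banded_align(read, "AAACGTAAA", full_band(4, 9), cfg)
        assert res.cost == 0.0
        assert res.ref_start == 3 and res.ref_end == 7

    def test_degenerate_band_still_yields_a_read_global_path(self):
        # a one-column band admits only the all-insertion path: the read is
        # consumed entirely by insertions (global in the read, free ends)
        cfg = MapperConfig()
        read = SeqRecord(id="r", seq="ACGT")
        band = GuideBand(lo=np.zeros(5, dtype=int), hi=np.zeros(5, dtype=int))
        res = banded_align(read, "TTTT", band, cfg)
        assert res.cigar == [("I", 4)]
        assert res.cost == 4 * cfg.flat_insertion

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            GuideBand(lo=np.array([0, 2]), hi=np.array([3, 1]))  # empty row
        with pytest.raises(ValueError):
            GuideBand(lo=np.array([2, 0]), hi=np.array([3, 3]))  # lo decreases
        with pytest.raises(ValueError):
            GuideBand(lo=np.array([0, 5]), hi=np.array([3, 8]))  # gap between rows


class TestAlignerProperties:
    def test_full_band_equals_full_dp_oracle(self, rng):
        """With an all-admissible band the banded cost equals an independent
        full-matrix recurrence, with and without quality tracks."""
        cfg = MapperConfig()
        for trial in range(60):
            R = int(rng.integers(5, 80))
            L = int(rng.integers(5, 80))
            read_seq = random_seq(rng, R)
            interval = random_seq(rng, L)
            qv = None
            if trial % 2:
                qv = QualityArrays(
                    ins=rng.integers(2, 30, R).tolist(),
                    sub=rng.integers(2, 30, R).tolist(),
                    del_=rng.integers(2, 30, R).tolist(),
                    sub_alt=random_seq(rng, R),
                    del_alt=random_seq(rng, R),
                )
            read = SeqRecord(id="r", seq=read_seq, qv=qv)
            res = banded_align(read, interval, full_band(R, L), cfg)
            assert res.cost == full_dp_cost(read, interval, cfg)
            assert path_cost(res, read, interval, cfg) == res.cost

    def test_cigar_consumes_read_and_reference(self, rng):
        cfg = MapperConfig()
        read = SeqRecord(id="r", seq=random_seq(rng, 40))
        interval = random_seq(rng, 50)
        res = banded_align(read, interval, full_band(40, 50), cfg)
        consumed_read = sum(n for op, n in res.cigar if op in "MI")
        consumed_ref = sum(n for op, n in res.cigar if op in "MD")
        assert consumed_read == 40
        assert consumed_ref == res.ref_end - res.ref_start

    def test_cost_invariant_under_joint_reverse_complement(self, rng):
        """Reverse-complementing read and interval together (QV tracks
        reversed, alternative calls complemented) preserves the optimal
        cost.  The deletion track must be position-uniform for exact
        symmetry, since a deletion consumes no read base and its quality is
        indexed by the adjacent read row."""
        from smsmap.seq_io import revcomp

        cfg = MapperConfig()
        for _ in range(10):
            R, L = int(rng.integers(10, 50)), int(rng.integers(10, 50))
            read = SeqRecord(
                id="r", seq=random_seq(rng, R),
                qv=QualityArrays(
                    ins=rng.integers(2, 30, R).tolist(),
                    sub=rng.integers(2, 30, R).tolist(),
                    del_=[9] * R,
                    sub_alt=random_seq(rng, R),
                    del_alt="A" * R,
                ),
            )
            interval = random_seq(rng, L)
            fwd = banded_align(read, interval, full_band(R, L), cfg)
            rc_read = read.reverse_complement()
            rev = banded_align(rc_read, revcomp(interval), full_band(R, L), cfg)
            assert fwd.cost == rev.cost

    def test_flat_mode_cost_invariant_under_reverse_complement(self, rng):
        from smsmap.seq_io import revcomp

        cfg = MapperConfig()
        for _ in range(10):
            R, L = int(rng.integers(10, 60)), int(rng.integers(10, 60))
            read = SeqRecord(id="r", seq=random_seq(rng, R))
            interval = random_seq(rng, L)
            fwd = banded_align(read, interval, full_band(R, L), cfg)
            rev = banded_align(
                read.reverse_complement(), revcomp(interval), full_band(R, L), cfg
            )
            assert fwd.cost == rev.cost

    def test_narrow_band_matches_oracle_when_it_contains_the_path(self, rng):
        """A band built from the identity SDP chain still recovers the
        optimal alignment of a lightly corrupted read."""
        cfg = MapperConfig()
        base = random_seq(rng, 60)
        noisy = "".join(
            c if rng.random() > 0.05 else "ACGT"[rng.integers(4)] for c in base
        )
        read = SeqRecord(id="r", seq=noisy)
        from smsmap.refinement import sdp_refine

        chain = sdp_refine(noisy, base, MapperConfig(k_sdp=8))
        band = build_guide_band(chain, len(noisy), len(base), cfg)
        res = banded_align(read, base, band, cfg)
        assert res.cost == full_dp_cost(read, base, cfg)
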