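import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrpipe.errors import EmptyOverlapError, FormatError, ValidationError
from mrpipe.sumstats_io import (
    CANONICAL_COLUMNS,
    GwasPanel,
    align_alleles,
    complement,
    harmonise,
    is_palindromic,
    read_sumstats,
    write_sumstats,
)

from conftest import make_panel, make_record


def _write_file(tmp_path, rows, name="panel.tsv"):
    path = tmp_path / name
    lines = ["\t".join(CANONICAL_COLUMNS)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


GOOD_ROWS = [
    ("rs1", "1", 1000, "A", "G", 0.3, 0.10, 0.02, 1e-9, 10000),
    ("rs2", "1", 2000, "T", "C", 0.4, -0.05, 0.01, 1e-6, 10000),
    ("rs3", "2", 3000, "G", "A", 0.2, 0.02, 0.015, 0.4, 10000),
]


class TestReadWrite:
    def test_identity_read(self, tmp_path):
        panel = read_sumstats(_write_file(tmp_path, GOOD_ROWS), trait_id="t")
        assert len(panel) == 3
        assert panel.snp_ids == ("rs1", "rs2", "rs3")
        assert panel.records[1].beta == -0.05

    def test_strict_rejects_zero_se_naming_row(self, tmp_path):
        rows = list(GOOD_ROWS)
        rows[1] = ("rs2", "1", 2000, "T", "C", 0.4, -0.05, 0.0, 1e-6, 10000)
        with pytest.raises(ValidationError, match="row 2"):
            read_sumstats(_write_file(tmp_path, rows), trait_id="t")

    def test_non_strict_skips_and_reports(self, tmp_path):
        rows = list(GOOD_ROWS)
        rows[0] = ("rs1", "1", 1000, "A", "G", 1.3, 0.10, 0.02, 1e-9, 10000)
        panel = read_sumstats(_write_file(tmp_path, rows), trait_id="t", strict=False)
        assert len(panel) == 2
        assert any("rs1" in d for d in panel.diagnostics)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(FormatError, match="missing required column"):
            read_sumstats(path, trait_id="t")

    def test_round_trip_identity(self, tmp_path):
        panel = read_sumstats(_write_file(tmp_path, GOOD_ROWS), trait_id="t")
        path2 = write_sumstats(panel, tmp_path / "copy.tsv")
        again = read_sumstats(path2, trait_id="t")
        assert again.records == panel.records

    def test_round_trip_full_precision(self, tmp_path):
        beta = 0.123456789012345678
        panel = make_panel([make_record(beta=beta)])
        again = read_sumstats(write_sumstats(panel, tmp_path / "p.tsv"), trait_id="t")
        assert again.records[0].beta == beta

    def test_one_record_panel_two_lines(self, tmp_path):
        path = write_sumstats(make_panel([make_record()]), tmp_path / "p.tsv")
        assert len(path.read_text().strip().split("\n")) == 2

    def test_missing_eaf_round_trips_as_nan(self, tmp_path):
        panel = make_panel([make_record(eaf=float("nan"))])
        again = read_sumstats(write_sumstats(panel, tmp_path / "p.tsv"), trait_id="t")
        assert math.isnan(again.records[0].eaf)

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValidationError, match="empty"):
            GwasPanel(trait_id="t", trait_type="continuous", records=(), sample_size=10)

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_panel([make_record(), make_record()])


class TestHarmonise:
    def _pair(self, exp_kw, out_kw):
        e = make_panel([make_record(**exp_kw)], trait_id="exp")
        o = make_panel([make_record(**out_kw)], trait_id="out")
        return e, o

    def test_identity_case(self):
        e, o = self._pair(dict(ea="A", oa="G", beta=0.10), dict(ea="A", oa="G", beta=0.05))
        h = harmonise(e, o)
        assert h.beta_out[0] == 0.05
        assert h.dropped == ()

    def test_swapped_alleles_flip_sign(self):
        e, o = self._pair(dict(ea="A", oa="G", beta=0.10), dict(ea="G", oa="A", beta=0.05))
        h = harmonise(e, o)
        assert h.beta_out[0] == -0.05

    def test_strand_complement_kept(self):
        e, o = self._pair(dict(ea="A", oa="G", beta=0.10), dict(ea="T", oa="C", beta=0.05))
        assert harmonise(e, o).beta_out[0] == 0.05

    def test_complement_swapped_flips_sign(self):
        e, o = self._pair(dict(ea="A", oa="G", beta=0.10), dict(ea="C", oa="T", beta=0.05))
        assert harmonise(e, o).beta_out[0] == -0.05

    def test_palindromic_mid_frequency_dropped(self):
        e, o = self._pair(
            dict(ea="A", oa="T", eaf=0.50), dict(ea="A", oa="T", eaf=0.50)
        )
        with pytest.raises(EmptyOverlapError):
            harmonise(e, o, palindrome_eaf_window=0.08)

    def test_palindromic_drop_reason_recorded(self):
        e = make_panel(
            [make_record("rs1", ea="A", oa="T", eaf=0.5), make_record("rs2", pos=2000)],
            trait_id="exp",
        )
        o = make_panel(
            [make_record("rs1", ea="A", oa="T", eaf=0.5), make_record("rs2", pos=2000)],
            trait_id="out",
        )
        h = harmonise(e, o)
        assert ("rs1", "palindromic_ambiguous") in h.dropped
        assert h.snp_ids == ("rs2",)

    def test_palindromic_concordant_frequency_kept(self):
        e, o = self._pair(
            dict(ea="A", oa="T", eaf=0.2, beta=0.1), dict(ea="A", oa="T", eaf=0.25, beta=0.05)
        )
        h = harmonise(e, o)
        assert h.beta_out[0] == 0.05

    def test_palindromic_discordant_frequency_dropped(self):
        e, o = self._pair(
            dict(ea="C", oa="G", eaf=0.2), dict(ea="C", oa="G", eaf=0.8)
        )
        with pytest.raises(EmptyOverlapError):
            harmonise(e, o)

    def test_allele_mismatch_reason(self):
        e = make_panel(
            [make_record("rs1", ea="A", oa="G"), make_record("rs2", pos=2000)],
            trait_id="exp",
        )
        o = make_panel(
            [make_record("rs1", ea="A", oa="C"), make_record("rs2", pos=2000)],
            trait_id="out",
        )
        assert ("rs1", "allele_mismatch") in harmonise(e, o).dropped

    def test_missing_in_outcome(self):
        e = make_panel(
            [make_record("rs1"), make_record("rs2", pos=2000)], trait_id="exp"
        )
        o = make_panel([make_record("rs1")], trait_id="out")
        h = harmonise(e, o)
        assert ("rs2", "missing_in_outcome") in h.dropped

    def test_zero_overlap_raises(self):
        e = make_panel([make_record("rs1")], trait_id="exp")
        o = make_panel([make_record("rs9")], trait_id="out")
        with pytest.raises(EmptyOverlapError):
            harmonise(e, o)

    def test_missing_eaf_drops_palindromic_only(self):
        nan = float("nan")
        e = make_panel(
            [make_record("rs1", ea="A", oa="T", eaf=nan),
             make_record("rs2", pos=2000, eaf=nan)],
            trait_id="exp",
        )
        o = make_panel(
            [make_record("rs1", ea="A", oa="T", eaf=nan),
             make_record("rs2", pos=2000, eaf=nan)],
            trait_id="out",
        )
        h = harmonise(e, o)
        assert h.snp_ids == ("rs2",)
        assert ("rs1", "palindromic_ambiguous") in h.dropped


def _hset_to_panels(hset):
    """Re-express a HarmonisedSet as two panels with synthetic A/G alleles."""
    exp, out = [], []
    for i, s in enumerate(hset.snp_ids):
        common = dict(snp_id=s, chrom="1", pos=1000 * (i + 1),
                      ea="A", oa="G", eaf=float(hset.eaf[i]))
        exp.append(make_record(beta=float(hset.beta_exp[i]), se=float(hset.se_exp[i]),
                               pval=0.5, n=int(hset.n_exp[i]), **common))
        out.append(make_record(beta=float(hset.beta_out[i]), se=float(hset.se_out[i]),
                               pval=0.5, n=int(hset.n_out[i]), **common))
    return make_panel(exp, trait_id="exp"), make_panel(out, trait_id="out")


class TestHarmoniseProperties:
    def test_idempotent(self, clean_triplet):
        h1 = harmonise(clean_triplet.exposure, clean_triplet.outcome)
        e2, o2 = _hset_to_panels(h1)
        h2 = harmonise(e2, o2)
        np.testing.assert_array_equal(h1.beta_out, h2.beta_out)
        np.testing.assert_array_equal(h1.beta_exp, h2.beta_exp)
        assert h1.snp_ids == h2.snp_ids

    def test_orientation_invariance(self, clean_triplet):
        exp, out = clean_triplet.exposure, clean_triplet.outcome
        flipped = make_panel(
            [make_record(r.snp_id, r.chrom, r.pos, ea=r.other_allele,
                         oa=r.effect_allele, eaf=1.0 - r.eaf, beta=-r.beta,
                         se=r.se, pval=r.pval, n=r.n) for r in out],
            trait_id="out", sample_size=out.sample_size,
        )
        h1 = harmonise(exp, out)
        h2 = harmonise(exp, flipped)
        assert h1.snp_ids == h2.snp_ids
        np.testing.assert_array_equal(h1.beta_out, h2.beta_out)

    def test_abs_beta_out_preserved(self, clean_triplet):
        h = harmonise(clean_triplet.exposure, clean_triplet.outcome)
        by_id = {r.snp_id: r for r in clean_triplet.outcome}
        for s, b in zip(h.snp_ids, h.beta_out):
            assert abs(b) == abs(by_id[s].beta)


@given(
    pair=st.sampled_from([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]),
    swap=st.booleans(),
    strand=st.booleans(),
)
def test_align_alleles_recovers_orientation(pair, swap, strand):
    """Any swap/strand rewriting of a non-palindromic record is reversible."""
    ea, oa = pair
    a, b = (complement(ea), complement(oa)) if strand else (ea, oa)
    expected = 1
    if swap:
        a, b = b, a
        expected = -1
    sign, reason = align_alleles(ea, oa, 0.3, a, b, 0.3 if not swap else 0.7)
    assert reason is None
    assert sign == expected


def test_is_palindromic():
    assert is_palindromic("A", "T") and is_palindromic("C", "G")
    assert not is_palindromic("A", "G")
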