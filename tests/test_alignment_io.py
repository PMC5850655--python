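import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from substab import (
    Alignment,
    AlignmentShapeError,
    MissingTaxonError,
    ValidationError,
    read_alignment,
    restrict_alignment,
    write_alignment,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestReading:
    def test_fasta_parse(self, tmp_path):
        p = _write(tmp_path / "a.fasta",
                   ">s1 extra words\nACGTACGTAC\n>s2\nacgtacgtac\n"
                   ">s3\nACGT-CGTAC\n>s4\nACGUACGUAC\n")
        aln = read_alignment(p, "fasta")
        assert aln.n_taxa == 4 and aln.n_sites == 10
        assert aln.taxa[0] == "s1"            # name ends at whitespace
        assert aln.rows[1] == "ACGTACGTAC"    # lowercase normalised
        assert aln.rows[3] == "ACGTACGTAC"    # U -> T

    def test_phylip_parse_and_wrapped_rows(self, tmp_path):
        p = _write(tmp_path / "a.phy",
                   "4 8\ns1 ACGTACGT\ns2 ACGT\nACGT\ns3 AAAAAAAA\n"
                   "s4 TTTTTTTT\n")
        aln = read_alignment(p, "phylip")
        assert aln.n_taxa == 4 and aln.n_sites == 8
        assert aln.rows[1] == "ACGTACGT"

    def test_auto_sniff(self, tmp_path):
        fa = _write(tmp_path / "x", ">a\nACGT\n>b\nACGT\n>c\nACGT\n>d\nACGT\n")
        ph = _write(tmp_path / "y", "4 4\na ACGT\nb ACGT\nc ACGT\nd ACGT\n")
        assert read_alignment(fa).n_sites == 4
        assert read_alignment(ph).n_sites == 4

    def test_unequal_lengths_names_offender(self, tmp_path):
        p = _write(tmp_path / "bad.fasta",
                   ">a\nACGTACGTAC\n>b\nACGTACGTA\n")
        with pytest.raises(AlignmentShapeError, match="b"):
            read_alignment(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = _write(tmp_path / "dup.fasta", ">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_alignment(p)

    def test_unknown_character_located(self, tmp_path):
        p = _write(tmp_path / "chr.fasta", ">a\nACGT\n>b\nACXT\n")
        with pytest.raises(ValidationError, match=r"'X'.*position 3"):
            read_alignment(p)


@pytest.mark.parametrize("fmt", ["fasta", "phylip"])
def test_round_trip(tmp_path, fmt):
    aln = Alignment(("alpha", "beta", "gamma", "delta"),
                    ("ACGT-N", "RYSWKM", "ACGTAC", "BDHVAC"))
    path = tmp_path / f"rt.{fmt}"
    write_alignment(aln, path, fmt)
    back = read_alignment(path, fmt)
    assert back.taxa == aln.taxa
    assert back.rows == aln.rows
    assert back.n_sites == aln.n_sites


class TestRestrict:
    def test_reorders_rows(self, quartet_alignment):
        sub = restrict_alignment(quartet_alignment, ["C", "A"])
        assert sub.taxa == ("C", "A")
        assert sub.rows[0] == quartet_alignment.rows[2]
        assert sub.n_sites == quartet_alignment.n_sites

    def test_identity(self, quartet_alignment):
        same = restrict_alignment(quartet_alignment, quartet_alignment.taxa)
        assert same == quartet_alignment

    def test_missing_taxon_named(self, quartet_alignment):
        with pytest.raises(MissingTaxonError, match="seqX"):
            restrict_alignment(quartet_alignment, ["A", "seqX"])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(data=hst.data())
    def test_restriction_composes(self, data):
        aln = Alignment(
            ("w", "x", "y", "z", "q"),
            ("ACGTAC", "ACGTAG", "TCGTAC", "ACGAAC", "ACCTAC"),
        )
        names = list(aln.taxa)
        s = data.draw(hst.permutations(names))
        k = data.draw(hst.integers(min_value=1, max_value=len(s)))
        t = s[:k]
        via_s = restrict_alignment(restrict_alignment(aln, s), t)
        direct = restrict_alignment(aln, t)
        assert via_s == direct
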