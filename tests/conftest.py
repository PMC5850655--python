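import numpy as np
import pytest

from substab import (
    Alignment,
    caterpillar_tree,
    simulate_alignment,
    write_alignment,
)


@pytest.fixture
def quartet_alignment():
    """Four sequences whose every informative column supports AB|CD."""
    return Alignment(
        ("A", "B", "C", "D"),
        (
            "AAAAAAAAAACCCC",
            "AAAAAAAAAACCCG",
            "TTTTTTTTTTCCCC",
            "TTTTTTTTTTCCCG",
        ),
    )


@pytest.fixture
def gap_fixture(tmp_path):
    """Simulated high-signal alignment with injected gaps and ambiguities."""
    tree = caterpillar_tree(8, internal_len=0.08, terminal_len=0.05)
    aln = simulate_alignment(tree, 3000, seed=7)
    rows = [list(r) for r in aln.rows]
    # gap a stretch of one row, pepper ambiguity codes into two others
    for c in range(10, 40):
        rows[2][c] = "-"
    for c in range(100, 110):
        rows[5][c] = "N"
    for c in range(200, 205):
        rows[0][c] = "R"
    dirty = Alignment(aln.taxa, tuple("".join(r) for r in rows))
    path = tmp_path / "gapped.fasta"
    write_alignment(dirty, path)
    return path, dirty, tree


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
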