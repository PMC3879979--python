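import pytest

from strandbalance import GeneAlignment, Phylogeny


@pytest.fixture
def quartet_tree() -> Phylogeny:
    """Balanced rooted quartet ((A,B),(C,D))."""
    return Phylogeny.from_newick("((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);")


@pytest.fixture
def ladder5_tree() -> Phylogeny:
    """Default 5-strain pectinate tree."""
    return Phylogeny.ladder(("S1", "S2", "S3", "S4", "S5"), branch_length=0.01)


def make_alignment(
    focal: dict[str, str],
    outgroups: dict[str, str] | None = None,
    gene_id: str = "g1",
    strand: str = "leading",
) -> GeneAlignment:
    rows = dict(focal)
    rows.update(outgroups or {})
    return GeneAlignment(
        gene_id=gene_id,
        rows=rows,
        focal_labels=tuple(focal),
        strand=strand,
    )


@pytest.fixture
def make_aln():
    return make_alignment
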