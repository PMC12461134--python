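import pytest

from thermadapt.io import AlignedOrthogroup, TaxonLabel

FOUR_TAXA_ROLES = {
    "fg1": "foreground",
    "fg2": "foreground",
    "bg1": "background",
    "bg2": "background",
}


@pytest.fixture
def four_taxa_roles():
    return dict(FOUR_TAXA_ROLES)


@pytest.fixture
def taxon_labels():
    return (
        TaxonLabel("fg1", "S. droebachiensis", "arctic", "foreground"),
        TaxonLabel("fg2", "S. pallidus", "arctic", "foreground"),
        TaxonLabel("bg1", "S. droebachiensis", "subarctic", "background"),
        TaxonLabel("bg2", "S. pallidus", "subarctic", "background"),
    )


def make_alignment(columns, og_id="OG0000", taxa=("fg1", "fg2", "bg1", "bg2")):
    """Build an AlignedOrthogroup from per-column residue strings.

    Each element of *columns* is a string giving one residue per taxon,
    in the order of *taxa*; e.g. "TTSS" puts T in both foreground and S
    in both background taxa.
    """
    seqs = {
        taxon: "".join(col[i] for col in columns)
        for i, taxon in enumerate(taxa)
    }
    return AlignedOrthogroup(og_id, seqs)


@pytest.fixture
def make_aln():
    return make_alignment
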