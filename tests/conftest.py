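import pytest

from smirnaforge import homology as hom
from smirnaforge import preprocess as pre
from smirnaforge import synthetic as syn


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale synthetic bundle: 2 scaffolds x 20 kb, 6 planted hairpins
    (3 conserved), depth 20, 10% contaminants, no sequencing errors."""
    scaffolds, truth = syn.make_genome(
        seed=101, n_scaffolds=2, scaffold_length=20_000, n_hairpins=6,
    )
    contaminants = syn.make_contaminants(102)
    known = syn.make_known_reference(truth, n_conserved=3, max_divergence=2, seed=103)
    reads = syn.make_reads(
        truth, scaffolds, depth_per_locus=20, contaminant_fraction=0.1,
        contaminants=contaminants, error_rate=0.0, seed=104,
    )
    return {
        "scaffolds": scaffolds,
        "truth": truth,
        "contaminants": contaminants,
        "known": known,
        "reads": reads,
    }


@pytest.fixture(scope="session")
def small_tags(small_bundle):
    """Preprocessed unique tags of the small bundle (full filter cascade)."""
    recs = [pre.ReadRecord(r, s) for r, s in small_bundle["reads"]]
    tags = pre.collapse(pre.clean_reads(recs))
    kept, _ = pre.filter_ncrna(tags, dict(small_bundle["contaminants"]))
    return pre.size_select(kept)


@pytest.fixture(scope="session")
def small_known_ref(small_bundle):
    return [hom.KnownMiRNA.from_header(n, s) for n, s in small_bundle["known"]]
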