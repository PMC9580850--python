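import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from bsjprimer.filtering import DesignResources
from bsjprimer.fixtures import FixtureSpec, make_reference_bundle
from bsjprimer.reference_io import (
    load_genome,
    load_snp_track,
    load_transcriptome,
    parse_circ_list,
    parse_exon_annotation,
)
from bsjprimer.template_builder import Template


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return make_reference_bundle(FixtureSpec(seed=1), outdir)


@pytest.fixture(scope="session")
def genome(bundle):
    return load_genome(bundle["genome"])


@pytest.fixture(scope="session")
def transcripts(bundle):
    return parse_exon_annotation(bundle["gtf"])


@pytest.fixture(scope="session")
def snp_track(bundle):
    return load_snp_track(bundle["snps"])


@pytest.fixture(scope="session")
def transcriptome(bundle):
    return load_transcriptome(bundle["transcriptome"])


@pytest.fixture(scope="session")
def circs(bundle):
    return {c.id: c for c in parse_circ_list(bundle["circs"])}


@pytest.fixture()
def resources(genome, transcripts, snp_track, transcriptome):
    return DesignResources(genome, transcripts, snp_track, transcriptome)


def make_template(sequence: str, junction_index: int, circ_id: str = "toy",
                  chrom: str = "c1", offset: int = 0) -> Template:
    """Bare template over a literal sequence with an identity genome map."""
    n = len(sequence)
    return Template(
        circ_id=circ_id,
        sequence=sequence,
        junction_index=junction_index,
        flank_left=junction_index,
        flank_right=n - junction_index,
        spliced=False,
        genome_map=[(chrom, offset + i, "+") for i in range(n)],
    )


@pytest.fixture()
def template_factory():
    return make_template
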