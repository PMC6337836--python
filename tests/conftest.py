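import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pstmap.annotate import parse_gff3
from pstmap.sixframe import six_frame_translate
from pstmap.synthdata import SynthConfig, simulate, write_annotation_gff3
from pstmap.tagmap import map_psts


@pytest.fixture(scope="session")
def small_sim():
    """A small clean simulated proteogenome shared across tests."""
    return simulate(SynthConfig(n_genes=6, seed=11))


@pytest.fixture(scope="session")
def small_segments(small_sim):
    return [s for c in small_sim.contigs for s in six_frame_translate(c)]


@pytest.fixture(scope="session")
def small_hits(small_sim, small_segments):
    return map_psts(small_sim.psts, small_segments)


@pytest.fixture(scope="session")
def small_annotation(small_sim, tmp_path_factory):
    path = tmp_path_factory.mktemp("ann") / "annotation.gff3"
    write_annotation_gff3(small_sim.genes, path)
    return parse_gff3(path)
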