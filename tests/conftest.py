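import io

import numpy as np
import pytest

from structprobe import ScoreStore, ScoreTrack
from structprobe.simulate import StructureMask


@pytest.fixture
def hairpin():
    """35-nt stem-loop mask: 15 paired, 5-nt unpaired loop, 15 paired."""
    return StructureMask.hairpin(stem=15, loop=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_store(*tracks: ScoreTrack) -> ScoreStore:
    store = ScoreStore()
    for t in tracks:
        store.add_track(t)
    return store


@pytest.fixture
def small_store():
    """One dsss dataset: scores 1.0, 2.0, 3.0 at chr1:10-13 on +."""
    track = ScoreTrack(chrom="chr1", strand="+", method="dsss",
                       scores=np.array([1.0, 2.0, 3.0]), offset=10)
    return make_store(track)


def tsv_of(store: ScoreStore) -> str:
    buf = io.StringIO()
    store.export_tsv(buf)
    return buf.getvalue()
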