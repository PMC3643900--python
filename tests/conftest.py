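import numpy as np
import pytest

from paleorrna.consensus import Contig, Placement
from paleorrna.preprocess import Read


@pytest.fixture
def make_read():
    """Build a read with uniform quality unless given explicitly."""

    def _make(rid, seq, quality=30, emulsion_set="ES1"):
        qual = [quality] * len(seq) if isinstance(quality, int) else list(quality)
        return Read(rid, seq, qual, emulsion_set=emulsion_set)

    return _make


@pytest.fixture
def gapless_contig():
    """Construct a Contig directly from a consensus string and gapless read
    placements ``(read_id, sequence, offset, orientation)``.

    Bases are as placed (i.e. already reverse-complemented for '-'); the
    orientation only controls the scanning direction of the skip rule.
    """

    def _make(consensus, reads):
        ncol = len(consensus)
        placements = []
        coverage = np.zeros(ncol, dtype=int)
        for rid, seq, off, orient in reads:
            events = [("M", off + i, b) for i, b in enumerate(seq)]
            placements.append(Placement(rid, orient, off, events))
            coverage[off:off + len(seq)] += 1
        quality = np.full(ncol, 30)
        return Contig("test", "", "", list(consensus), coverage, quality,
                      placements)

    return _make
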