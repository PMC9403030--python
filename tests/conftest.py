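import numpy as np
import pytest

from foldspec.io import AnchorRecord, GeneModel, bin_contact_map, build_contact_map


@pytest.fixture
def gene200():
    return GeneModel("g", 200, cds=((20, 170),), utr5=((0, 20),), utr3=((170, 200),))


@pytest.fixture
def gene400():
    return GeneModel("g", 400, cds=((40, 340),), utr5=((0, 40),), utr3=((340, 400),))


def random_records(rng, gene, n_reads, max_weight=1):
    """Random intramolecular reads on one gene (helper, not a fixture)."""
    recs = []
    while len(recs) < n_reads:
        i, j = rng.integers(0, gene.length, size=2)
        if i == j:
            continue
        w = 1 if max_weight == 1 else int(rng.integers(1, max_weight + 1))
        recs.append(AnchorRecord(gene.gene_id, int(i), int(j), w))
    return recs


def binned_map(records, gene, halfwidth=10):
    return bin_contact_map(build_contact_map(records, gene), halfwidth)


def brute_force_mstar(cmap, halfwidth):
    """Independent naive window-sum oracle over unordered observed pairs."""
    out = np.zeros(cmap.n_pairs)
    pairs = list(zip(cmap.pair_i, cmap.pair_j, cmap.mnorm))
    for k, (i, j) in enumerate(zip(cmap.pair_i, cmap.pair_j)):
        total = 0.0
        for a, b, w in pairs:
            in_fwd = abs(a - i) <= halfwidth and abs(b - j) <= halfwidth
            in_rev = abs(b - i) <= halfwidth and abs(a - j) <= halfwidth
            if in_fwd or in_rev:
                total += w
        out[k] = total
    return out
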