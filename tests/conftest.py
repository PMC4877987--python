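import collections

import pytest

from covbin.synthetic import simulate_community
from covbin.tnf import CANONICAL_KMERS

COMMUNITY_SEED = 7


@pytest.fixture(scope="session")
def community():
    """The default four-genome community with planted contaminants."""
    return simulate_community(seed=COMMUNITY_SEED)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the default community (shared, ~30 s)."""
    from covbin.pipeline import run_demo

    outdir = tmp_path_factory.mktemp("demo")
    return run_demo(outdir, seed=COMMUNITY_SEED)


def naive_tnf(sequence):
    """Dictionary-based canonical 4-mer counter, independent of the
    vectorized implementation."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts = collections.Counter()
    for i in range(len(sequence) - 3):
        k = sequence[i:i + 4].upper()
        if any(c not in comp for c in k):
            continue
        rc = "".join(comp[c] for c in reversed(k))
        counts[min(k, rc)] += 1
    total = sum(counts.values())
    return [counts.get(k, 0) / total for k in CANONICAL_KMERS]


def majority_genome(bin_, truth):
    cnt = collections.Counter(truth[s] for s in bin_.scaffold_ids)
    return cnt.most_common(1)[0][0]


def precision_recall(bin_, truth, lengths, genome, min_len=5000):
    big = {s for s in bin_.scaffold_ids if lengths[s] >= min_len}
    target = {s for s, g in truth.items()
              if g == genome and lengths[s] >= min_len}
    tp = len(big & target)
    return (tp / len(big) if big else 0.0,
            tp / len(target) if target else 0.0)
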