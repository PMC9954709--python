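import numpy as np
import pytest

from wgdctdna.cn_profile import CNProfile, CNSegment


def profile_from_states(states, sample_id="S1", chromosome="1"):
    """Build a single-chromosome profile from (length, major, minor) triples."""
    segments, pos = [], 0
    for length, major, minor in states:
        segments.append(CNSegment(chromosome, pos, pos + length, major, minor))
        pos += length
    return CNProfile(sample_id=sample_id, segments=segments)


def brute_force_stats(profile, include_sex_chromosomes=False):
    """Per-base oracle for the three WGD statistics on small integer profiles."""
    cn, mcn_hits, loh_hits = [], 0, 0
    for seg in profile.included_segments(include_sex_chromosomes):
        for _ in range(seg.start, seg.end):
            cn.append(seg.major_cn + seg.minor_cn)
            mcn_hits += seg.major_cn >= 2
            loh_hits += seg.minor_cn == 0
    n = len(cn)
    return mcn_hits / n, sum(cn) / n, loh_hits / n


def random_profile(rng, max_coord=200, max_segments=8, sample_id="R"):
    """Random small integer-coordinate profile (autosomes only)."""
    n_seg = int(rng.integers(1, max_segments + 1))
    cuts = np.sort(rng.choice(np.arange(1, max_coord), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [max_coord]])
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        minor = int(rng.integers(0, 3))
        major = int(rng.integers(max(minor, 1), 5))
        # genome-wide disjoint intervals stay disjoint within any chromosome
        segments.append(CNSegment(str(rng.integers(1, 23)), int(lo), int(hi), major, minor))
    return CNProfile(sample_id=sample_id, segments=segments)


@pytest.fixture
def rng():
    return np.random.default_rng(20230701)
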