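import random

import pytest

from mitoprofile.genome_model import load_reference_annotation
from mitoprofile.synthetic_data import generate_mitogenome


@pytest.fixture(scope="session")
def ref_annotation():
    """The bundled reference organization table (38 features, 16,141 bp)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def synth():
    """One default synthetic mitogenome shared across modules (seed 1)."""
    return generate_mitogenome(seed=1)


def random_annotation(rng: random.Random, n_features: int = 20,
                      min_len: int = 20, gap_range=(-8, 26)):
    """Random circular annotation with planted signed gaps.

    Feature lengths >= ``min_len`` and |overlap| <= 8 guarantee that overlap
    regions of distinct consecutive pairs are disjoint, so position-wise
    coverage counts form an independent oracle for the geometry totals.
    Returns (annotation, planted_gaps) where ``planted_gaps[i]`` is the gap
    *after* feature i (the last one wraps to feature 0).
    """
    from mitoprofile.genome_model import GeneFeature, GenomeAnnotation, PCG

    lengths = [rng.randint(min_len, min_len + 200) for _ in range(n_features)]
    gaps = [rng.randint(*gap_range) for _ in range(n_features)]
    genome_length = sum(lengths) + sum(gaps)
    assert genome_length > 0
    feats = []
    pos = 1
    for i, ln in enumerate(lengths):
        start = (pos - 1) % genome_length + 1
        end = (pos + ln - 2) % genome_length + 1
        feats.append(GeneFeature(name=f"g{i}", kind=PCG,
                                 strand=rng.choice("JN"),
                                 start=start, end=end))
        pos += ln + gaps[i]
    return (GenomeAnnotation(features=tuple(feats),
                             genome_length=genome_length), gaps)


def coverage_oracle(annotation):
    """Brute-force per-position coverage counts over the circle.

    Returns (uncovered bp, multiply-covered bp) — equal to the spacer and
    overlap totals whenever overlaps of distinct pairs do not stack.
    """
    from mitoprofile.genome_model import feature_length

    n = annotation.genome_length
    cov = [0] * n
    for f in annotation.features:
        ln = feature_length(f, n)
        for k in range(ln):
            cov[(f.start - 1 + k) % n] += 1
    return sum(1 for c in cov if c == 0), sum(c - 1 for c in cov if c > 1)
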