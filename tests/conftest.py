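import random

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popgenscan.alignment import CodingAlignment, build_site_masks

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_alignment(ingroup, outgroup, exons=(), gene_id="test"):
    ids = tuple(f"hap{i}" for i in range(len(ingroup)))
    return CodingAlignment(gene_id=gene_id, ingroup_ids=ids,
                           ingroup=tuple(ingroup), outgroup_id="out",
                           outgroup=outgroup, exons=tuple(exons))


def random_alignment(rng: random.Random, n=None, L=None, with_missing=True,
                     coding=False):
    """Small random alignment: shared ancestral string plus scattered changes."""
    n = n or rng.randint(3, 8)
    L = L or rng.randrange(30, 121, 3)
    anc = [rng.choice("ACGT") for _ in range(L)]
    seqs = []
    for _ in range(n + 1):                       # last one is the outgroup
        s = list(anc)
        for _ in range(rng.randint(0, L // 4)):
            c = rng.randrange(L)
            s[c] = rng.choice("ACGT")
        if with_missing:
            for _ in range(rng.randint(0, 3)):
                s[rng.randrange(L)] = rng.choice("N-")
        seqs.append("".join(s))
    exons = ((0, L),) if coding else ()
    return make_alignment(seqs[:n], seqs[n], exons=exons)


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def small_gene():
    """Deterministic small synthetic gene with masks."""
    from popgenscan.synthetic import SyntheticGeneConfig, generate_gene
    cfg = SyntheticGeneConfig(gene_id="fixture_gene", n=12, L=600,
                              exons=((60, 540),), seed=11)
    aln, truth = generate_gene(cfg)
    return aln, build_site_masks(aln), truth
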