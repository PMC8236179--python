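"""Shared fixtures: synthetic study systems at two sizes.

The standard system (50 genomes, 2% mutations) is the package's default
study conditions and backs the end-to-end recovery checks; the small
system keeps bootstrap and CLI tests fast.
"""

import numpy as np
import pytest

import repliclass as rc


@pytest.fixture(scope="session")
def standard_fixture():
    """Default synthetic system: database, genomes, truth table."""
    return rc.make_fixture(rc.FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def trained(standard_fixture):
    """Full shred -> balance -> split -> featurize -> train run."""
    database, genomes, _ = standard_fixture
    return rc.run_train(genomes, database, seed=11)


@pytest.fixture(scope="session")
def small_fixture():
    """A miniature system for bootstrap and CLI tests."""
    spec = rc.FixtureSpec(
        n_db_plasmids=12,
        n_genomes=12,
        chromosome_length=(8_000, 12_000),
        plasmid_length=(1_000, 3_000),
        plasmids_per_genome=(1, 2),
        mutation_rate=0.02,
        seed=5,
    )
    return rc.make_fixture(spec)


@pytest.fixture(scope="session")
def small_dist():
    return rc.SizeDistribution(bins=((50, 1000, 0.5), (1000, 2000, 0.5)))


@pytest.fixture(scope="session")
def small_split(small_fixture, small_dist):
    """Shredded, balanced and genome-split contigs of the small system."""
    database, genomes, _ = small_fixture
    rng = np.random.default_rng(99)
    contigs_by_genome = {}
    for gid in sorted(genomes):
        shredded = []
        for replicon in genomes[gid]:
            shredded.extend(
                rc.shred_replicon(
                    replicon, small_dist, seed=int(rng.integers(0, 2**31 - 1))
                )
            )
        contigs_by_genome[gid] = shredded
    train_ids, test_ids = rc.split_genomes(sorted(genomes), seed=3)
    train = [c for g in train_ids for c in contigs_by_genome[g]]
    test = [c for g in test_ids for c in contigs_by_genome[g]]
    return database, train, test


def mk_hit(query_id="q1", qs=0, qe=100, subject_id="s1", evalue=1e-10, **kw):
    defaults = dict(
        percent_identity=98.0,
        alignment_length=qe - qs,
        subject_start=0,
        subject_end=qe - qs,
        strand="+",
        bitscore=50.0,
    )
    defaults.update(kw)
    return rc.Hit(
        query_id=query_id, subject_id=subject_id,
        query_start=qs, query_end=qe, evalue=evalue, **defaults,
    )
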