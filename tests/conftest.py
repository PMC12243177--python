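import numpy as np
import pytest

from tiscaller.records import ChimericRead, SoftClipRecord, TdnaConstruct


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def construct(rng):
    """A 500-bp random construct with borders at its ends."""
    return TdnaConstruct("vec1", random_dna(rng, 500))


def make_clip_record(
    read_id="r1",
    replicate_id="repA",
    chrom="chr1",
    aligned_start=1000,
    aligned_end=1059,
    clip_side="right",
    clip_seq="A" * 40,
    read_seq=None,
    genome_match_len=60,
    aligned_seq=None,
):
    clip_len = len(clip_seq)
    aligned_seq = aligned_seq if aligned_seq is not None else "C" * genome_match_len
    read_seq = read_seq if read_seq is not None else (
        aligned_seq + clip_seq if clip_side == "right" else clip_seq + aligned_seq
    )
    return SoftClipRecord(
        read_id=read_id,
        replicate_id=replicate_id,
        chrom=chrom,
        aligned_start=aligned_start,
        aligned_end=aligned_end,
        clip_side=clip_side,
        clip_seq=clip_seq,
        clip_quals="I" * clip_len,
        clip_len=clip_len,
        read_len=len(read_seq),
        genome_match_len=genome_match_len,
        aligned_seq=aligned_seq,
        read_seq=read_seq,
    )


def make_chimeric(
    read_id="c1",
    replicate_id="repA",
    chrom="chr1",
    junction=5000,
    config="R",
    orientation="+",
    genome_seg_len=75,
    tdna_seg_len=75,
    full_seq=None,
    construct_id="vec1",
    t_junction=1,
):
    if full_seq is None:
        full_seq = "A" * genome_seg_len + "G" * tdna_seg_len
    return ChimericRead(
        read_id=read_id,
        replicate_id=replicate_id,
        chrom=chrom,
        junction=junction,
        config=config,
        orientation=orientation,
        construct_id=construct_id,
        t_junction=t_junction,
        genome_seg_len=genome_seg_len,
        tdna_seg_len=tdna_seg_len,
        full_seq=full_seq,
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A shared synthetic dataset: 100-kb genome, 2 insertions (one per
    orientation), 150-bp error-free single-end reads, 2 replicates."""
    from tiscaller.simulate import make_fixture

    out = tmp_path_factory.mktemp("simdata")
    return make_fixture(str(out), seed=7)


@pytest.fixture(scope="session")
def wildtype_dir(tmp_path_factory):
    """Same generator, zero insertions (negative control)."""
    from tiscaller.simulate import make_fixture

    out = tmp_path_factory.mktemp("simdata_wt")
    return make_fixture(str(out), seed=7, n_insertions=0)
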