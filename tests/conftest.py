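import numpy as np
import pytest

from mitopop.seq_io import AlignmentMatrix, PopulationMap, SequenceRecord

# Four 10 bp sequences with two polymorphic sites (positions 5 and 10):
# s1/s2 differ at site 5, s3=s4 differ from s2 at site 10.
TOY4_SEQS = {
    "s1": "ACGTACGTAC",
    "s2": "ACGTGCGTAC",
    "s3": "ACGTGCGTAT",
    "s4": "ACGTGCGTAT",
}


@pytest.fixture
def toy4_records():
    return [SequenceRecord(k, v) for k, v in TOY4_SEQS.items()]


@pytest.fixture
def toy4_alignment(toy4_records):
    return AlignmentMatrix.from_records(toy4_records)


@pytest.fixture
def toy4_popmap():
    pops = {"s1": "X", "s2": "X", "s3": "Y", "s4": "Y"}
    return PopulationMap(dict(pops), dict(pops), {s: "G" for s in pops})


@pytest.fixture
def toy4_files(tmp_path):
    fasta = tmp_path / "toy4.fasta"
    fasta.write_text("".join(f">{k}\n{v}\n" for k, v in TOY4_SEQS.items()))
    popmap = tmp_path / "toy4.popmap.tsv"
    lines = ["sample_id\tsubpopulation\tpopulation\tgroup"]
    for s in TOY4_SEQS:
        pop = "X" if s in ("s1", "s2") else "Y"
        lines.append(f"{s}\t{pop}\t{pop}\tG")
    popmap.write_text("\n".join(lines) + "\n")
    return fasta, popmap


def random_alignment(rng, n=None, L=None, k_variants=3):
    """Small random {A,C,G,T} alignment for oracle-equivalence checks."""
    n = n or int(rng.integers(4, 21))
    L = L or int(rng.integers(5, 51))
    bases = np.array(list("ACGT"))
    # draw from a few template haplotypes plus noise so duplicates occur
    templates = bases[rng.integers(0, 4, size=(k_variants, L))]
    rows = templates[rng.integers(0, k_variants, size=n)].copy()
    noise = rng.random(rows.shape) < 0.05
    rows[noise] = bases[rng.integers(0, 4, size=int(noise.sum()))]
    ids = [f"t{i}" for i in range(n)]
    return AlignmentMatrix(ids, rows)


def random_popmap(rng, ids, n_pops=2):
    labels = [f"P{i}" for i in range(n_pops)]
    # guarantee at least two members per population
    assign = list(np.repeat(labels, 2))
    assign += [labels[int(rng.integers(n_pops))] for _ in range(len(ids) - len(assign))]
    rng.shuffle(assign)
    pops = dict(zip(ids, assign))
    return PopulationMap(dict(pops), dict(pops), {s: "G" for s in ids})
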