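import numpy as np
import pytest

import superbarcode as sb


@pytest.fixture(scope="session")
def truth() -> sb.TruthSet:
    """Default synthetic species set (4 species x 2 samples, 15 kb)."""
    return sb.simulate_species_set(sb.SimulationScenario(seed=11))


@pytest.fixture(scope="session")
def labels(truth) -> sb.SpeciesLabeling:
    return truth.labels


def make_alignment(rows: dict[str, str]) -> sb.Alignment:
    return sb.Alignment([sb.SequenceRecord(k, v) for k, v in rows.items()])


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_quadripartite(
    rng: np.random.Generator, lsc: int, ir: int, ssc: int
) -> sb.SequenceRecord:
    """A circular genome with a planted IR pair whose boundaries cannot
    extend by chance (flanking bases chosen non-complementary)."""
    lsc_seq = "A" + random_dna(rng, lsc - 2) + "A"
    ssc_seq = "A" + random_dna(rng, ssc - 2) + "A"
    ir_seq = random_dna(rng, ir)
    seq = lsc_seq + ir_seq + ssc_seq + sb.reverse_complement(ir_seq)
    return sb.SequenceRecord("planted", seq, circular=True)
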