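import numpy as np
import pytest

from aidsig.io import MutationRecord, attach_neighborhoods
from aidsig.motifs import default_catalog
from aidsig.simulate import SyntheticTruth, generate_mutations, generate_reference


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_record(neighborhood, center_index, pos, alt=None, chrom="chr1", sample="S1"):
    """Build a MutationRecord around an explicit neighborhood window."""
    ref = neighborhood[center_index]
    if alt is None:
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    return MutationRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        sample_id=sample,
        neighborhood=neighborhood,
        center_index=center_index,
    )


@pytest.fixture()
def toy_wrc_dataset():
    """Four 8 nt windows with hand-counted WRC/GYW occupancy.

    Valid (full-context, un-mutated) positions per window are indices 2..5
    minus the center (4).  Hand counts, per window:
      AATACGTT  center C hit (TAC);  motif among {2,3,5} = {5: GTT} -> 1/3
      TTGACGTT  center miss;         motif {5: GTT}                 -> 1/3
      AGTACGAT  center C hit (TAC);  motif positions {1,4}, none valid -> 0/3
      TTTTATTT  center miss;         no occurrence                  -> 0/3
    Totals: n=4, k=2, motif_positions=2, total_positions=12.
    """
    windows = ["AATACGTT", "TTGACGTT", "AGTACGAT", "TTTTATTT"]
    return [
        make_record(w, 4, pos=100 + 200 * i) for i, w in enumerate(windows)
    ]


@pytest.fixture(scope="session")
def enriched_dataset():
    """Mutations with a planted WRCG multiplier, shared across tests."""
    truth = SyntheticTruth(genome_length=60_000, n_mutations=800, theta={"WRCG": 4.0})
    rng = np.random.default_rng(7)
    reference = generate_reference(truth, rng)
    muts = generate_mutations(reference, truth, rng)
    muts = attach_neighborhoods(muts, {"chr1": reference})
    return reference, muts
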