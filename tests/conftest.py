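import pytest

from coevokit.io import AlignedFamily, FamilyRecord, PairingRow, PairingTable
from coevokit.synthetic import SimConfig, simulate_bundle


def make_family(name, seqs, organisms=None):
    """Tiny helper: seqs is {seq_id: residues}."""
    organisms = organisms or {}
    return AlignedFamily(
        name,
        [FamilyRecord(sid, organisms.get(sid, sid), s) for sid, s in seqs.items()],
    )


@pytest.fixture(scope="session")
def coevolving_bundle():
    """One mid-sized simulated dataset with planted coupling, shared by tests."""
    cfg = SimConfig(
        n_organisms=20,
        rate_correlation=0.8,
        coupled_pairs=[(10, 15), (50, 60), (90, 100)],
        compensation_prob=1.0,
        marker_length=600,
        duplications=[("org03", "A"), ("org03", "B")],
        seed=11,
    )
    return simulate_bundle(cfg)


@pytest.fixture
def toy_pairing():
    return PairingTable(
        [
            PairingRow("sp1", "a1", "b1"),
            PairingRow("sp2", "a2", "b2"),
            PairingRow("sp3", "a3", "b3"),
        ]
    )
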