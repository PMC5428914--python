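import datetime

import pytest

from careseq import (
    Contact,
    EdgeType,
    InfoEdge,
    Provider,
    ProviderLevel,
    build_sequence,
)

DAY0 = datetime.date(2020, 1, 6)


def make_contact(
    cid,
    day,
    level=ProviderLevel.GP,
    provider_id=None,
    patient_id="pt1",
    specialty="",
    reasons=(),
):
    return Contact(
        contact_id=cid,
        patient_id=patient_id,
        timestamp=DAY0 + datetime.timedelta(days=day),
        provider=Provider(provider_id or f"{level.name.lower()}1", level, specialty),
        reasons=list(reasons),
    )


@pytest.fixture
def gp_chain():
    """Three GP contacts 28 days apart, fully chained by follow-up summons."""
    contacts = [make_contact(f"c{i}", 28 * i) for i in range(3)]
    edges = [
        InfoEdge("c0", "c1", EdgeType.FOLLOWUP),
        InfoEdge("c1", "c2", EdgeType.FOLLOWUP),
    ]
    return build_sequence("pt1", contacts, edges)


@pytest.fixture
def two_thread_seq():
    """Two loosely connected threads of care.

    An orthopedist strand (regular visits O1, O2, with a referral onward to
    physiotherapy P1) and an unconnected family-physician strand (G1, G2):
    five contacts, three edges, two threads.
    """
    ortho = ProviderLevel.AMBULATORY_SPECIALIST
    contacts = [
        make_contact("O1", 0, ortho, "ortho1", specialty="orthopedics"),
        make_contact("G1", 5),
        make_contact("O2", 30, ortho, "ortho1", specialty="orthopedics"),
        make_contact("P1", 40, ProviderLevel.ALLIED_HEALTH, "physio1",
                     specialty="physiotherapy"),
        make_contact("G2", 60),
    ]
    edges = [
        InfoEdge("O1", "O2", EdgeType.FOLLOWUP),
        InfoEdge("O2", "P1", EdgeType.REFERRAL),
        InfoEdge("G1", "G2", EdgeType.FOLLOWUP),
    ]
    return build_sequence("pt1", contacts, edges)
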