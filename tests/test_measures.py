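import datetime

import pytest
from hypothesis import given, settings, strategies as st

from careseq import (
    EdgeType,
    InfoEdge,
    ProviderLevel,
    build_sequence,
    continuity_of_information,
    count_providers,
    information_threads,
    intervisit_intervals,
    summarize_sequence,
)

from conftest import DAY0, make_contact
from test_model import timeforward_sequences


# ---------------------------------------------------------------------------
# Independent oracles: a brute-force in-degree scan for continuity and a
# union-find over edge endpoints for threads.  Kept free of any careseq
# graph machinery.

def brute_continuity(seq):
    n = len(seq.contacts)
    if n < 2:
        return None
    informed = sum(
        1
        for c in seq.contacts
        if any(e.dst_contact_id == c.contact_id for e in seq.edges)
    )
    return informed / (n - 1)


def brute_threads(seq):
    parent = {c.contact_id: c.contact_id for c in seq.contacts}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in seq.edges:
        parent[find(e.src_contact_id)] = find(e.dst_contact_id)
    groups = {}
    for c in seq.contacts:
        groups.setdefault(find(c.contact_id), set()).add(c.contact_id)
    return {frozenset(g) for g in groups.values()}


class TestIntervals:
    def test_monthly_monitoring_gaps(self, gp_chain):
        assert intervisit_intervals(gp_chain) == [28, 28]

    def test_single_contact_has_no_interval(self):
        seq = build_sequence("pt1", [make_contact("c0", 0)])
        assert intervisit_intervals(seq) == []

    def test_level_filter_drops_other_levels(self):
        seq = build_sequence(
            "pt1",
            [
                make_contact("c0", 0),
                make_contact("c1", 10, ProviderLevel.AMBULATORY_SPECIALIST),
                make_contact("c2", 35),
            ],
        )
        assert intervisit_intervals(seq, level_filter=ProviderLevel.GP) == [35]
        assert intervisit_intervals(seq) == [10, 25]

    @settings(max_examples=150, derandomize=True)
    @given(timeforward_sequences())
    def test_gaps_are_nonnegative_and_conserve_span(self, seq):
        gaps = intervisit_intervals(seq)
        assert all(g >= 0 for g in gaps)
        span = (seq.contacts[-1].timestamp - seq.contacts[0].timestamp).days
        assert sum(gaps) == span


class TestProviders:
    def test_single_provider(self, gp_chain):
        assert count_providers(gp_chain) == (1, 1)

    def test_serial_specialists(self):
        # A GP plus four distinct ambulatory specialists visited serially.
        spec = ProviderLevel.AMBULATORY_SPECIALIST
        seq = build_sequence(
            "pt1",
            [
                make_contact("c0", 0, provider_id="gp1"),
                make_contact("c1", 10, spec, "cardio1"),
                make_contact("c2", 40, spec, "angio1"),
                make_contact("c3", 70, spec, "uro1"),
                make_contact("c4", 100, spec, "onco1"),
            ],
        )
        assert count_providers(seq) == (5, 2)


class TestContinuity:
    def test_fully_chained(self):
        contacts = [make_contact(f"c{i}", 10 * i) for i in range(4)]
        edges = [
            InfoEdge(f"c{i}", f"c{i+1}", EdgeType.FOLLOWUP) for i in range(3)
        ]
        assert continuity_of_information(build_sequence("pt1", contacts, edges)) == 1.0

    def test_fully_fragmented(self):
        contacts = [make_contact(f"c{i}", 10 * i) for i in range(4)]
        assert continuity_of_information(build_sequence("pt1", contacts)) == 0.0

    def test_partial_fan_out(self):
        contacts = [make_contact(f"c{i}", 10 * i) for i in range(5)]
        edges = [
            InfoEdge("c0", "c1", EdgeType.REFERRAL),
            InfoEdge("c0", "c2", EdgeType.REFERRAL),
        ]
        assert continuity_of_information(build_sequence("pt1", contacts, edges)) == 0.5

    def test_singleton_is_missing(self):
        seq = build_sequence("pt1", [make_contact("c0", 0)])
        assert continuity_of_information(seq) is None

    def test_parallel_edges_count_once(self):
        contacts = [make_contact("c0", 0), make_contact("c1", 10)]
        edges = [
            InfoEdge("c0", "c1", EdgeType.REFERRAL),
            InfoEdge("c0", "c1", EdgeType.FOLLOWUP),
        ]
        assert continuity_of_information(build_sequence("pt1", contacts, edges)) == 1.0


class TestThreads:
    def test_chain_is_one_thread(self, gp_chain):
        assert information_threads(gp_chain) == [["c0", "c1", "c2"]]

    def test_loosely_connected_strands(self, two_thread_seq):
        threads = information_threads(two_thread_seq)
        assert [set(t) for t in threads] == [{"O1", "O2", "P1"}, {"G1", "G2"}]

    def test_no_edges_gives_singletons(self):
        seq = build_sequence("pt1", [make_contact(f"c{i}", i) for i in range(3)])
        assert information_threads(seq) == [["c0"], ["c1"], ["c2"]]


class TestOracleEquivalence:
    """The shipped graph computations agree exactly with brute force."""

    @settings(max_examples=300, derandomize=True)
    @given(timeforward_sequences())
    def test_continuity_matches_indegree_scan(self, seq):
        assert continuity_of_information(seq) == brute_continuity(seq)

    @settings(max_examples=300, derandomize=True)
    @given(timeforward_sequences())
    def test_threads_match_union_find(self, seq):
        assert {frozenset(t) for t in information_threads(seq)} == brute_threads(seq)


@settings(max_examples=150, derandomize=True)
@given(timeforward_sequences(), st.data())
def test_adding_an_edge_never_hurts_connectivity(seq, data):
    """Monotonicity: a new legal edge never lowers continuity or splits threads."""
    if len(seq.contacts) < 2:
        return
    pairs = [
        (a.contact_id, b.contact_id)
        for i, a in enumerate(seq.contacts)
        for b in seq.contacts[i + 1 :]
    ]
    src, dst = data.draw(st.sampled_from(pairs))
    edge_type = data.draw(st.sampled_from(list(EdgeType)))
    bigger = build_sequence(
        seq.patient_id, seq.contacts, seq.edges + [InfoEdge(src, dst, edge_type)]
    )
    assert continuity_of_information(bigger) >= continuity_of_information(seq)
    assert len(information_threads(bigger)) <= len(information_threads(seq))


@settings(max_examples=200, derandomize=True)
@given(timeforward_sequences())
def test_full_continuity_implies_one_thread(seq):
    if continuity_of_information(seq) == 1.0:
        assert len(information_threads(seq)) == 1


class TestSummarize:
    def test_singleton_summary(self):
        seq = build_sequence("pt1", [make_contact("c0", 0)])
        s = summarize_sequence(seq)
        assert s.n_contacts == 1
        assert s.mean_interval_days is None
        assert s.continuity is None
        assert s.n_threads == 1
        assert s.largest_thread_fraction == 1.0

    def test_chained_monitoring_year(self):
        contacts = [make_contact(f"c{i:02d}", 28 * i) for i in range(13)]
        edges = [
            InfoEdge(f"c{i:02d}", f"c{i+1:02d}", EdgeType.FOLLOWUP) for i in range(12)
        ]
        s = summarize_sequence(build_sequence("pt1", contacts, edges))
        assert s.observation_days == 337
        assert s.contacts_per_year == pytest.approx(13 * 365 / 337)
        assert s.continuity == 1.0
        assert s.n_threads == 1
        assert s.mean_interval_days == 28
        assert s.mean_interval_days_gp == 28

    def test_two_thread_fixture_summary(self, two_thread_seq):
        s = summarize_sequence(two_thread_seq)
        assert s.continuity == pytest.approx(0.75)
        assert s.n_threads == 2
        assert s.largest_thread_fraction == pytest.approx(0.6)
        assert s.n_providers == 3
        assert s.n_provider_levels == 3
        assert s.edge_counts[EdgeType.FOLLOWUP] == 2
        assert s.edge_counts[EdgeType.REFERRAL] == 1
        assert s.edge_counts[EdgeType.REPORT] == 0

    def test_explicit_window_restricts_contacts(self, two_thread_seq):
        s = summarize_sequence(
            two_thread_seq, (DAY0, DAY0 + datetime.timedelta(days=31))
        )
        assert s.n_contacts == 3  # O1, G1, O2
        assert s.observation_days == 31
        assert s.edge_counts[EdgeType.FOLLOWUP] == 1  # only O1->O2 survives

    def test_inverted_window_rejected(self, gp_chain):
        with pytest.raises(ValueError, match="inverted"):
            summarize_sequence(gp_chain, (DAY0, DAY0 - datetime.timedelta(days=1)))

    @settings(max_examples=100, derandomize=True)
    @given(timeforward_sequences())
    def test_summary_invariants(self, seq):
        s = summarize_sequence(seq)
        assert 1 <= s.n_threads <= s.n_contacts
        assert (s.continuity is None) == (s.n_contacts == 1)
        assert s.largest_thread_fraction >= 1 / s.n_contacts
        assert sum(s.edge_counts.values()) == len(seq.edges)
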