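"""Caller unit tests, including exact equivalence with a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitwin.dmr import call_iidmrs, compute_deltas, count_dmr_probes
from epitwin.types import DeltaTrack, MethylationMatrix, ProbeRecord

from conftest import make_matrix


def track(rows, **kw):
    """rows: (chrom, pos, delta) tuples, probe ids auto-assigned."""
    return DeltaTrack(
        probe_ids=np.array([f"p{i}" for i in range(len(rows))], dtype=object),
        chromosomes=np.array([r[0] for r in rows], dtype=object),
        positions=np.array([r[1] for r in rows], dtype=np.int64),
        deltas=np.array([r[2] for r in rows], dtype=float),
        **kw,
    )


def brute_force_calls(t, min_delta=0.05, min_probes=2, max_gap=500):
    """Enumerate every candidate probe run and test the definition directly."""
    d, chrom, pos = t.deltas, t.chromosomes, t.positions
    n = len(d)

    def qual(i):
        return not np.isnan(d[i]) and abs(d[i]) >= min_delta

    def linked(i, j):
        # consecutive probes i < j extendable into one run
        return (
            qual(i) and qual(j)
            and chrom[i] == chrom[j]
            and pos[j] - pos[i] <= max_gap
            and np.sign(d[i]) == np.sign(d[j])
        )

    runs = []
    for i in range(n):
        for j in range(i + min_probes - 1, n):
            if not all(qual(k) for k in range(i, j + 1)):
                continue
            if not all(linked(k, k + 1) for k in range(i, j)):
                continue
            left_ext = i > 0 and linked(i - 1, i)
            right_ext = j < n - 1 and linked(j, j + 1)
            if not left_ext and not right_ext:
                runs.append((i, j))
    return [
        (
            str(chrom[i]), int(pos[i]), int(pos[j]) + 2,
            tuple(str(t.probe_ids[k]) for k in range(i, j + 1)),
            "gain" if d[i] > 0 else "loss",
        )
        for i, j in runs
    ]


def call_tuples(calls):
    return [
        (c.chromosome, c.start, c.end, c.probe_ids, c.direction) for c in calls
    ]


class TestComputeDeltas:
    manifest = [ProbeRecord("cgA", "chr1", 100), ProbeRecord("cgB", "chr1", 300)]

    def test_difference_and_missingness(self):
        m = make_matrix(["cgA", "cgB"], {"a": [0.80, np.nan], "b": [0.70, 0.5]})
        t = compute_deltas(m, "a", "b", self.manifest)
        assert t.deltas[0] == pytest.approx(0.10)
        assert np.isnan(t.deltas[1])

    def test_self_comparison_is_zero(self):
        m = make_matrix(["cgA", "cgB"], {"a": [0.3, 0.9]})
        t = compute_deltas(m, "a", "a", self.manifest)
        assert np.all(t.deltas == 0)

    def test_unknown_sample_raises(self):
        m = make_matrix(["cgA"], {"a": [0.3]})
        with pytest.raises(KeyError):
            compute_deltas(m, "a", "zzz", self.manifest[:1])


class TestCallRules:
    def test_gap_isolates_third_probe(self):
        t = track([("chr1", 100, 0.08), ("chr1", 400, 0.06), ("chr1", 2000, 0.20)])
        calls = call_iidmrs(t)
        assert call_tuples(calls) == [
            ("chr1", 100, 402, ("p0", "p1"), "gain")
        ]

    def test_sign_change_blocks_call(self):
        t = track([("chr1", 100, 0.08), ("chr1", 300, -0.06)])
        assert call_iidmrs(t) == []

    def test_missing_probe_breaks_run(self):
        t = track(
            [("chr1", 100, 0.08), ("chr1", 200, np.nan), ("chr1", 300, 0.08)]
        )
        assert call_iidmrs(t) == []

    def test_chromosome_change_breaks_run(self):
        t = track([("chr1", 100, 0.08), ("chr2", 150, 0.08)])
        assert call_iidmrs(t) == []

    def test_zero_track_zero_calls(self):
        t = track([("chr1", 100 * i, 0.0) for i in range(1, 20)])
        assert call_iidmrs(t) == []

    def test_threshold_is_inclusive(self):
        t = track([("chr1", 100, 0.05), ("chr1", 200, 0.05)])
        assert len(call_iidmrs(t, min_delta=0.05)) == 1

    def test_unsorted_input_rejected(self):
        t = track([("chr1", 300, 0.08), ("chr1", 100, 0.08)])
        with pytest.raises(ValueError, match="sorted"):
            call_iidmrs(t)


def random_track(rng, n):
    chroms = np.sort(rng.choice(["chr1", "chr2"], size=n))
    pos = np.sort(rng.integers(0, 3000, size=n))
    # re-sort within chromosome
    order = np.lexsort((pos, chroms))
    deltas = rng.uniform(-0.3, 0.3, size=n)
    deltas[rng.random(n) < 0.15] = np.nan
    return DeltaTrack(
        probe_ids=np.array([f"p{i}" for i in range(n)], dtype=object),
        chromosomes=chroms[order],
        positions=pos[order],
        deltas=deltas,
    )


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            t = random_track(rng, int(rng.integers(5, 120)))
            got = call_tuples(call_iidmrs(t))
            expected = brute_force_calls(t)
            assert got == expected

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            t = random_track(rng, 80)
            flipped = DeltaTrack(
                t.probe_ids, t.chromosomes, t.positions, -t.deltas
            )
            a = call_iidmrs(t)
            b = call_iidmrs(flipped)
            assert [(c.start, c.end, c.probe_ids) for c in a] == [
                (c.start, c.end, c.probe_ids) for c in b
            ]
            assert all(
                x.direction != y.direction for x, y in zip(a, b)
            )

    def test_monotonicity_in_min_delta_and_max_gap(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            t = random_track(rng, 80)
            loose = call_tuples(call_iidmrs(t, min_delta=0.05, max_gap=500))
            for strict_calls in (
                call_iidmrs(t, min_delta=0.10, max_gap=500),
                call_iidmrs(t, min_delta=0.05, max_gap=200),
            ):
                loose_probes = {p for c in loose for p in c[3]}
                for c in strict_calls:
                    assert set(c.probe_ids) <= loose_probes

    def test_distant_probe_does_not_perturb_existing_calls(self):
        t = track([("chr1", 100, 0.08), ("chr1", 300, 0.08)])
        augmented = track(
            [("chr1", 100, 0.08), ("chr1", 300, 0.08), ("chr1", 9000, 0.2)]
        )
        assert call_tuples(call_iidmrs(t)) == [
            c for c in call_tuples(call_iidmrs(augmented)) if c[1] == 100
        ]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    deltas=st.lists(
        st.one_of(st.none(), st.floats(-0.4, 0.4, allow_nan=False)),
        min_size=2, max_size=40,
    ),
    gaps=st.lists(st.integers(1, 900), min_size=40, max_size=40),
)
def test_caller_equals_oracle_on_generated_tracks(deltas, gaps):
    """Property: calls always match brute-force enumeration of the rule."""
    n = len(deltas)
    pos = np.cumsum(gaps[:n]).astype(np.int64)
    t = DeltaTrack(
        probe_ids=np.array([f"p{i}" for i in range(n)], dtype=object),
        chromosomes=np.array(["chr1"] * n, dtype=object),
        positions=pos,
        deltas=np.array([np.nan if d is None else d for d in deltas]),
    )
    assert call_tuples(call_iidmrs(t)) == brute_force_calls(t)


class TestCounting:
    def test_empty(self):
        assert count_dmr_probes([]) == {"n_calls": 0, "n_probes": 0}

    def test_feature_breakdown(self):
        t = track([("chr1", 100, 0.1), ("chr1", 200, 0.1), ("chr1", 300, 0.1)])
        calls = call_iidmrs(t)
        manifest = [
            ProbeRecord(f"p{i}", "chr1", 100 * (i + 1), feature_class="promoter")
            for i in range(3)
        ]
        counts = count_dmr_probes(calls, manifest)
        assert counts == {
            "n_calls": 1, "n_probes": 3, "per_feature": {"promoter": 3},
        }
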