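"""Occupancy accumulation, observation traces, and expected bulk counts."""

import numpy as np
import pytest

from cosolvmap import (
    COM,
    GridSpec,
    ProbeAtom,
    ProbeTopology,
    SnapshotSet,
    accumulate,
    expected_count,
)
from cosolvmap.density import ObservationTrace, TRACE_OOB


@pytest.fixture
def two_methyl_probe():
    return ProbeTopology(
        "dimethyl",
        [
            ProbeAtom("M1", 12.0, 1.7, "hydrophobic"),
            ProbeAtom("M2", 12.0, 1.7, "hydrophobic"),
            ProbeAtom("O", 16.0, 1.52, "polar"),
        ],
    )


def _random_snapshots(top, n_frames, n_instances, lo=-2.0, hi=7.0, seed=0):
    rng = np.random.default_rng(seed)
    return SnapshotSet(
        top, rng.uniform(lo, hi, size=(n_frames, n_instances, top.n_atoms, 3))
    )


class TestAccumulate:
    def test_two_pooled_atoms_in_one_voxel(self, two_methyl_probe, small_spec):
        coords = np.zeros((1, 1, 3, 3))
        coords[0, 0] = [[1.1, 1.1, 1.1], [1.2, 1.3, 1.4], [4.0, 4.0, 4.0]]
        snaps = SnapshotSet(two_methyl_probe, coords)
        cg, trace = accumulate(snaps, two_methyl_probe, "hydrophobic", small_spec)
        assert cg.counts[2, 2, 2] == 2
        assert cg.total == 2
        assert cg.multiplicity == 2
        assert len(trace) == 2

    def test_count_conservation(self, two_methyl_probe):
        spec = GridSpec((0, 0, 0), 0.5, (8, 8, 8))  # grid smaller than the box
        snaps = _random_snapshots(two_methyl_probe, 20, 7, seed=2)
        for group, mult in [("hydrophobic", 2), ("polar", 1), (COM, 1)]:
            cg, _ = accumulate(snaps, two_methyl_probe, group, spec)
            assert cg.total + cg.out_of_bounds == 20 * 7 * mult

    def test_order_independence(self, two_methyl_probe, small_spec):
        snaps = _random_snapshots(two_methyl_probe, 15, 4, seed=3)
        cg, _ = accumulate(snaps, two_methyl_probe, "hydrophobic", small_spec)
        perm = np.random.default_rng(4).permutation(15)
        shuffled = SnapshotSet(two_methyl_probe, snaps.coords[perm])
        cg2, _ = accumulate(shuffled, two_methyl_probe, "hydrophobic", small_spec)
        np.testing.assert_array_equal(cg.counts, cg2.counts)
        assert cg.out_of_bounds == cg2.out_of_bounds

    def test_matches_brute_force_tally(self, two_methyl_probe, small_spec):
        """Scripted placement pattern vs an independent per-point tally."""
        snaps = _random_snapshots(two_methyl_probe, 100, 3, lo=-1.0, hi=6.0, seed=7)
        cg, trace = accumulate(snaps, two_methyl_probe, "hydrophobic", small_spec)

        brute = np.zeros(small_spec.shape, dtype=int)
        oob = 0
        records = set()
        for f in range(100):
            for i in range(3):
                com = snaps.coords[f, i].mean(axis=0)  # not used for counts
                for ai in (0, 1):  # the two methyl atoms
                    p = snaps.coords[f, i, ai]
                    idx = tuple(int(np.floor(c / 0.5)) for c in p)
                    if all(0 <= k < 10 for k in idx):
                        brute[idx] += 1
                        records.add((f, i, ai))
                    else:
                        oob += 1
        np.testing.assert_array_equal(cg.counts, brute)
        assert cg.out_of_bounds == oob
        assert {(f, i, a) for f, i, a in zip(trace.frame, trace.instance, trace.atom)} == records

    def test_trace_links_atom_to_same_instance_com(self, two_methyl_probe, small_spec):
        snaps = _random_snapshots(two_methyl_probe, 5, 3, lo=0.5, hi=4.0, seed=8)
        _, trace = accumulate(snaps, two_methyl_probe, "polar", small_spec)
        com = snaps.com()
        for k in range(len(trace)):
            f, i = trace.frame[k], trace.instance[k]
            u = small_spec.voxel_index(com[f, i])
            expected = TRACE_OOB if not u else small_spec.ravel(np.array(u))
            assert trace.com_voxel[k] == expected

    def test_com_group_uses_com(self, two_methyl_probe, small_spec):
        snaps = _random_snapshots(two_methyl_probe, 4, 2, lo=0.5, hi=4.0, seed=9)
        cg, trace = accumulate(snaps, two_methyl_probe, COM, small_spec)
        assert cg.multiplicity == 1
        assert cg.total == len(trace) == 8
        assert np.array_equal(trace.atom_voxel, trace.com_voxel)

    def test_atom_subset_restriction(self, two_methyl_probe, small_spec):
        snaps = _random_snapshots(two_methyl_probe, 6, 2, seed=10)
        cg, _ = accumulate(
            snaps, two_methyl_probe, "hydrophobic", small_spec, atoms=["M1"]
        )
        assert cg.multiplicity == 1
        with pytest.raises(KeyError):
            accumulate(snaps, two_methyl_probe, "hydrophobic", small_spec, atoms=["O"])

    def test_empty_snapshots_rejected(self, two_methyl_probe, small_spec):
        with pytest.raises(ValueError):
            SnapshotSet(two_methyl_probe, np.empty((0, 1, 3, 3)))

    def test_unknown_chemotype_rejected(self, two_methyl_probe, small_spec):
        snaps = _random_snapshots(two_methyl_probe, 2, 1)
        with pytest.raises(KeyError):
            accumulate(snaps, two_methyl_probe, "aromatic", small_spec)

    def test_trace_csv_round_trip(self, two_methyl_probe, small_spec, tmp_path):
        snaps = _random_snapshots(two_methyl_probe, 5, 2, seed=11)
        _, trace = accumulate(snaps, two_methyl_probe, "hydrophobic", small_spec)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = ObservationTrace.from_csv(path, small_spec)
        for col in ("frame", "instance", "atom", "atom_voxel", "com_voxel"):
            np.testing.assert_array_equal(getattr(back, col), getattr(trace, col))


class TestExpectedCount:
    def test_direct_product(self, small_spec):
        n0, meta = expected_count(
            small_spec, n_frames=1000, multiplicity=1, bulk_number_density=0.002
        )
        assert n0 == pytest.approx(0.002 * 0.125 * 1000)
        assert meta["mode"] == "supplied_density"

    def test_multiplicity_linearity(self, small_spec):
        n1, _ = expected_count(small_spec, 500, 1, bulk_number_density=0.003)
        n2, _ = expected_count(small_spec, 500, 2, bulk_number_density=0.003)
        assert n2 == pytest.approx(2 * n1)

    def test_bulk_region_estimate(self, two_methyl_probe, small_spec):
        snaps = _random_snapshots(two_methyl_probe, 50, 4, lo=0.0, hi=5.0, seed=12)
        cg, _ = accumulate(snaps, two_methyl_probe, "polar", small_spec)
        region = np.ones(small_spec.shape, dtype=bool)
        n0, meta = expected_count(
            small_spec, 50, 1, counts=cg, bulk_region=region
        )
        assert n0 == pytest.approx(cg.counts.mean())
        assert meta["mode"] == "estimated_from_region"

    def test_empty_bulk_region_rejected(self, two_methyl_probe, small_spec):
        snaps = _random_snapshots(two_methyl_probe, 5, 2, seed=13)
        cg, _ = accumulate(snaps, two_methyl_probe, "polar", small_spec)
        with pytest.raises(ValueError, match="empty"):
            expected_count(
                small_spec, 5, 1, counts=cg,
                bulk_region=np.zeros(small_spec.shape, dtype=bool),
            )

    def test_uniform_monte_carlo_mean(self):
        """Uniform placements: mean voxel count matches rho*V*F within 3 SE."""
        top = ProbeTopology("one", [ProbeAtom("A", 12.0, 1.7, "a")])
        spec = GridSpec((0, 0, 0), 0.5, (10, 10, 10))  # exactly the 5 Å box
        M, F = 30, 400
        rng = np.random.default_rng(99)
        snaps = SnapshotSet(top, rng.uniform(0, 5.0, size=(F, M, 1, 3)))
        cg, _ = accumulate(snaps, top, "a", spec)
        expected = (M / 125.0) * 0.125 * F  # rho * voxel volume * frames
        total = F * M
        # counts are multinomial over 1000 voxels; SE of the grand mean
        se = np.sqrt(total * (1 / 1000) * (1 - 1 / 1000)) / 1000
        assert abs(cg.counts.mean() - expected) < 3 * se
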