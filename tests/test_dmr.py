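import itertools
import re

import numpy as np
import pandas as pd
import pytest

from hepmeth import dmr as dmr_mod
from hepmeth.diff import CpGCallSet

from conftest import make_diff, make_manifest


def run_oracle(chroms, positions, deltas, min_run, delta_min):
    """Independent maximal-run enumeration: sort by (chrom, pos), classify
    each probe as +1/-1/0, and emit consecutive constant nonzero groups."""
    def chrom_key(c):
        m = re.fullmatch(r"chr(\d+)", c)
        return (0, int(m.group(1))) if m else (1, c)

    order = sorted(range(len(deltas)), key=lambda i: (chrom_key(chroms[i]), positions[i]))
    states = []
    for i in order:
        d = deltas[i]
        s = 0 if abs(d) <= delta_min else (1 if d > 0 else -1)
        states.append((chroms[i], s, i))
    runs = []
    for (chrom, s), grp in itertools.groupby(states, key=lambda t: (t[0], t[1])):
        idxs = [t[2] for t in grp]
        if s != 0 and len(idxs) >= min_run:
            runs.append((chrom, s, tuple(idxs)))
    return runs


def random_instance(rng, n):
    """Random per-probe deltas on a 1-3 chromosome manifest."""
    n_chrom = int(rng.integers(1, 4))
    chroms = sorted(rng.integers(1, n_chrom + 1, n))
    positions, cursor, last_c = [], 0, None
    for c in chroms:
        if c != last_c:
            cursor, last_c = 0, c
        cursor += int(rng.integers(50, 2000))
        positions.append(cursor)
    chrom_names = [f"chr{c}" for c in chroms]
    # mix of null, boundary, and strong shifts, with sticky stretches
    deltas = rng.choice([-0.3, -0.15, -0.1, 0.0, 0.1, 0.15, 0.3], size=n)
    sticky = rng.random(n) < 0.7
    for i in range(1, n):
        if sticky[i]:
            deltas[i] = deltas[i - 1]
    probes = [f"p{i}" for i in range(n)]
    manifest = make_manifest(
        [
            (p, c, pos, "+", "", "Intergenic", "OpenSea")
            for p, c, pos in zip(probes, chrom_names, positions)
        ]
    )
    return manifest, make_diff(probes, deltas), chrom_names, positions, deltas


def assert_matches_oracle(manifest, diff_table, chroms, positions, deltas, min_run=4, delta_min=0.1):
    found = dmr_mod.find_dmrs(diff_table, manifest, min_run=min_run, delta_min=delta_min)
    probes = list(diff_table.index)
    expected = run_oracle(chroms, positions, deltas, min_run, delta_min)
    assert len(found) == len(expected)
    for got, (chrom, sign, idxs) in zip(found, expected):
        assert got.chromosome == chrom
        assert got.direction == ("hyper" if sign > 0 else "hypo")
        assert got.probe_ids == tuple(probes[i] for i in idxs)
        assert got.n_cpgs == len(idxs)
        assert got.start == positions[idxs[0]] and got.end == positions[idxs[-1]]


class TestFindDmrs:
    def test_no_shift_no_dmrs(self):
        manifest, diff_table, *_ = random_instance(np.random.default_rng(0), 50)
        diff_table["delta_beta"] = 0.0
        assert dmr_mod.find_dmrs(diff_table, manifest) == []

    def test_ten_or_more_consecutive_rule(self):
        """A run of 12 shifted probes is one DMR; 9 is below threshold."""
        for n_shift, expect in [(12, 1), (9, 0)]:
            n = n_shift + 2
            deltas = [0.0] + [0.2] * n_shift + [0.0]
            probes = [f"p{i}" for i in range(n)]
            positions = [100 * (i + 1) for i in range(n)]
            manifest = make_manifest(
                [(p, "chr1", pos, "+", "", "Intergenic", "OpenSea") for p, pos in zip(probes, positions)]
            )
            found = dmr_mod.find_dmrs(make_diff(probes, deltas), manifest, min_run=10, delta_min=0.1)
            assert len(found) == expect
            if expect:
                (d,) = found
                assert d.n_cpgs == 12
                assert d.direction == "hyper"
                assert (d.start, d.end) == (200, 1300)
                assert d.length_bp == 1101

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(10, 1000))
        manifest, diff_table, chroms, positions, deltas = random_instance(rng, n)
        assert_matches_oracle(manifest, diff_table, chroms, positions, deltas)

    def test_runs_broken_at_chromosome_boundary(self):
        probes = [f"p{i}" for i in range(12)]
        chroms = ["chr1"] * 6 + ["chr2"] * 6
        positions = [100 * (i + 1) for i in range(6)] * 2
        manifest = make_manifest(
            [(p, c, pos, "+", "", "Intergenic", "OpenSea") for p, c, pos in zip(probes, chroms, positions)]
        )
        found = dmr_mod.find_dmrs(make_diff(probes, [0.3] * 12), manifest, min_run=5, delta_min=0.1)
        assert [d.chromosome for d in found] == ["chr1", "chr2"]
        assert all(d.n_cpgs == 6 for d in found)

    def test_min_run_monotonicity(self):
        rng = np.random.default_rng(17)
        manifest, diff_table, *_ = random_instance(rng, 400)
        counts = [
            len(dmr_mod.find_dmrs(diff_table, manifest, min_run=k, delta_min=0.1))
            for k in (2, 4, 8, 16)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_max_gap_breaks_runs(self):
        probes = [f"p{i}" for i in range(10)]
        positions = [100, 200, 300, 400, 500, 50_000, 50_100, 50_200, 50_300, 50_400]
        manifest = make_manifest(
            [(p, "chr1", pos, "+", "", "Intergenic", "OpenSea") for p, pos in zip(probes, positions)]
        )
        table = make_diff(probes, [0.3] * 10)
        assert len(dmr_mod.find_dmrs(table, manifest, min_run=5, delta_min=0.1)) == 1
        assert len(dmr_mod.find_dmrs(table, manifest, min_run=5, delta_min=0.1, max_gap=1000)) == 2

    def test_min_run_below_two_rejected(self):
        manifest, diff_table, *_ = random_instance(np.random.default_rng(2), 20)
        with pytest.raises(ValueError):
            dmr_mod.find_dmrs(diff_table, manifest, min_run=1)


class TestSummaries:
    def _dmr(self, direction, start, end, n_cpgs=10, probes=()):
        return dmr_mod.DMR("chr1", start, end, n_cpgs, direction, 0.2, tuple(probes))

    def test_empty_summary_is_zero(self):
        s = dmr_mod.summarize_dmrs([])
        assert s.count == {"hyper": 0, "hypo": 0}
        assert s.mean_length_bp == {"hyper": 0.0, "hypo": 0.0}
        assert s.total_cpgs == {"hyper": 0, "hypo": 0}

    def test_mean_length_arithmetic(self):
        dmrs = [self._dmr("hyper", 1, 5_000), self._dmr("hyper", 1, 15_000)]
        s = dmr_mod.summarize_dmrs(dmrs)
        assert s.count["hyper"] == 2
        assert s.mean_length_bp["hyper"] == 10_000.0

    def test_summary_consistent_with_list(self, recovery_sim):
        from hepmeth import diff as diff_mod

        manifest, design, cohort = recovery_sim
        sheet = cohort.sheet
        table = diff_mod.compare_groups(
            cohort.beta,
            list(sheet.index[sheet["tissue_class"] == "normal"]),
            list(sheet.index[sheet["tissue_class"] == "HCC"]),
        )
        dmrs = dmr_mod.find_dmrs(table, manifest, min_run=10, delta_min=0.1)
        s = dmr_mod.summarize_dmrs(dmrs)
        for direction in ("hyper", "hypo"):
            members = [d for d in dmrs if d.direction == direction]
            assert s.count[direction] == len(members)
            assert s.total_cpgs[direction] == sum(d.n_cpgs for d in members)
            if members:
                assert s.mean_length_bp[direction] == pytest.approx(
                    np.mean([d.length_bp for d in members])
                )

    def test_fraction_of_calls_in_dmrs(self):
        dmrs = [self._dmr("hyper", 1, 100, probes=["a", "b", "c", "d"])]
        calls = CpGCallSet(
            "x",
            frozenset({"a", "b", "c", "d", "e", "f", "g", "h"}),
            frozenset({"y", "z"}),
            0.05,
            0.1,
        )
        assert dmr_mod.fraction_of_calls_in_dmrs(calls, dmrs) == pytest.approx(0.4)
        with pytest.warns(UserWarning):
            assert dmr_mod.fraction_of_calls_in_dmrs(
                CpGCallSet("e", frozenset(), frozenset(), 0.05, 0.1), dmrs
            ) == 0.0
        assert dmr_mod.fraction_of_calls_in_dmrs(calls, []) == 0.0

    def test_direction_matters_for_membership(self):
        dmrs = [self._dmr("hypo", 1, 100, probes=["a"])]
        calls = CpGCallSet("x", frozenset({"a"}), frozenset(), 0.05, 0.1)
        assert dmr_mod.fraction_of_calls_in_dmrs(calls, dmrs) == 0.0

    def test_shared_probes(self):
        a = [self._dmr("hyper", 1, 100, probes=["a", "b", "c"])]
        b = [self._dmr("hyper", 1, 100, probes=["b", "c", "d"])]
        assert dmr_mod.shared_dmr_probes(a, b)["hyper"] == {"b", "c"}
        assert dmr_mod.shared_dmr_probes(a, [])["hyper"] == set()
        assert dmr_mod.shared_dmr_probes(a, a)["hyper"] == {"a", "b", "c"}

    def test_bed_export_convention(self, tmp_path):
        d = self._dmr("hyper", 1_000, 2_000, probes=["a"])
        out = tmp_path / "d.bed"
        dmr_mod.dmrs_to_bed([d], out)
        assert out.read_text().splitlines()[0] == "chr1\t999\t2000\thyper\t200\t."
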