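"""Plant-like site calling, counting, motif grouping."""

import itertools

import numpy as np
import pytest

from holotools.alignment_prep import ColumnMap, filter_gap_columns, group_profile
from holotools.convergence import (
    PlantLikeSiteCall,
    call_plant_like_sites,
    count_plant_like_sites,
    group_motifs,
)
from holotools.seq_io import AMINO_ACIDS, GroupAssignment, ProteinAlignment


def build_case(animal_cols, bas_cols, cas_cols):
    """Alignment from per-group column strings; animals get round-robin clades."""
    n_animal, n_bas, n_cas = map(len, (animal_cols[0], bas_cols[0], cas_cols[0]))
    ids, rows, assignment = [], [], {}
    clades = ("non_bilaterian", "protostome", "deuterostome")
    for i in range(n_animal):
        sid = f"animal_{i}"
        ids.append(sid)
        rows.append("".join(col[i] for col in animal_cols))
        assignment[sid] = ("animal_LAS", clades[i % 3])
    for prefix, group, cols, n in (
        ("bas", "plant_BAS", bas_cols, n_bas),
        ("cas", "plant_CAS", cas_cols, n_cas),
    ):
        for i in range(n):
            sid = f"{prefix}_{i}"
            ids.append(sid)
            rows.append("".join(col[i] for col in cols))
            assignment[sid] = (group, "none")
    aln = ProteinAlignment(ids=tuple(ids), rows=tuple(rows))
    groups = GroupAssignment(assignment)
    profiles = {
        g: group_profile(aln, groups, functional_group=g)
        for g in ("animal_LAS", "plant_BAS", "plant_CAS")
    }
    cmap = ColumnMap(tuple(range(aln.length)))
    return aln, cmap, profiles


def run_calls(aln, cmap, profiles, focal="animal_0", **kwargs):
    return call_plant_like_sites(
        focal, aln, cmap,
        profiles["animal_LAS"], profiles["plant_BAS"], profiles["plant_CAS"],
        **kwargs,
    )


class TestThresholdLogic:
    def test_rare_in_animals_common_in_bas_is_called(self):
        # focal 'A' at 1/20 in animals, 16/20 in BAS, absent in CAS
        aln, cmap, profiles = build_case(
            ["A" + "L" * 19], ["A" * 16 + "G" * 4], ["G" * 20]
        )
        calls = run_calls(aln, cmap, profiles)
        assert len(calls) == 1 and calls[0].is_plant_like

    def test_animal_frequency_exactly_20_percent_not_called(self):
        aln, cmap, profiles = build_case(["ALLLL"], ["A" * 20], ["G" * 20])
        calls = run_calls(aln, cmap, profiles)
        assert calls[0].freq_animal_las == pytest.approx(0.2)
        assert not calls[0].is_plant_like

    def test_plant_frequency_exactly_55_percent_not_called(self):
        aln, cmap, profiles = build_case(
            ["A" + "L" * 19], ["A" * 11 + "G" * 9], ["G" * 20]
        )
        calls = run_calls(aln, cmap, profiles)
        assert calls[0].freq_plant_bas == pytest.approx(0.55)
        assert not calls[0].is_plant_like

    def test_cas_alone_suffices(self):
        aln, cmap, profiles = build_case(
            ["A" + "L" * 19], ["G" * 20], ["A" * 12 + "G" * 8]
        )
        assert run_calls(aln, cmap, profiles)[0].is_plant_like

    def test_focal_gap_column_skipped(self):
        # column 0: focal has '-', column 1: focal has 'L'
        aln, cmap, profiles = build_case(
            animal_cols=["-A", "LL"], bas_cols=["AA", "AA"], cas_cols=["GG", "GG"]
        )
        calls = run_calls(aln, cmap, profiles)
        assert [c.filtered_column for c in calls] == [1]

    def test_unknown_focal_id_is_error(self):
        aln, cmap, profiles = build_case(["ALLLLL"], ["A" * 8], ["G" * 8])
        with pytest.raises(KeyError):
            run_calls(aln, cmap, profiles, focal="nope")

    def test_count(self):
        calls = [
            PlantLikeSiteCall(i, i, "A", 0.1, 0.8, 0.1, flag)
            for i, flag in enumerate([True, False, True, True, False])
        ]
        assert count_plant_like_sites(calls) == 3


class TestProperties:
    def test_order_invariance(self, msa_filtered):
        filtered, cmap, groups, profiles, truth = msa_filtered
        calls = run_calls(filtered, cmap, profiles, focal=truth.focal_id)
        perm = list(filtered.ids)[::-1]
        shuffled = filtered.subset(perm)
        profiles2 = {
            g: group_profile(shuffled, groups, functional_group=g)
            for g in ("animal_LAS", "plant_BAS", "plant_CAS")
        }
        calls2 = run_calls(shuffled, cmap, profiles2, focal=truth.focal_id)
        assert calls == calls2

    def test_threshold_monotonicity(self, msa_filtered):
        filtered, cmap, groups, profiles, truth = msa_filtered
        grid_animal = [0.10, 0.15, 0.20, 0.25, 0.30]
        grid_plant = [0.45, 0.50, 0.55, 0.60, 0.65]
        counts = {}
        for amax, pmin in itertools.product(grid_animal, grid_plant):
            calls = run_calls(
                filtered, cmap, profiles, focal=truth.focal_id,
                animal_max=amax, plant_min=pmin,
            )
            counts[(amax, pmin)] = count_plant_like_sites(calls)
        for (amax, pmin), n in counts.items():
            for amax2, pmin2 in counts:
                if amax2 <= amax and pmin2 >= pmin:
                    assert counts[(amax2, pmin2)] <= n

    def test_matches_brute_force_oracle_on_small_alignments(self):
        """Independent per-column recount on random <=6x10 alignments."""
        rng = np.random.default_rng(42)
        alphabet = list("AGLKST-X")
        clades = ("non_bilaterian", "protostome", "deuterostome")
        for _ in range(25):
            n_animal, n_bas, n_cas = 3, 2, 1
            length = int(rng.integers(1, 11))
            ids, rows, assignment = [], [], {}
            for i in range(n_animal):
                ids.append(f"a{i}")
                assignment[f"a{i}"] = ("animal_LAS", clades[i])
            for i in range(n_bas):
                ids.append(f"b{i}")
                assignment[f"b{i}"] = ("plant_BAS", "none")
            ids.append("c0")
            assignment["c0"] = ("plant_CAS", "none")
            for _ in ids:
                rows.append("".join(rng.choice(alphabet, size=length)))
            aln = ProteinAlignment(ids=tuple(ids), rows=tuple(rows))
            groups = GroupAssignment(assignment)
            profiles = {
                g: group_profile(aln, groups, functional_group=g)
                for g in ("animal_LAS", "plant_BAS", "plant_CAS")
            }
            cmap = ColumnMap(tuple(range(length)))
            calls = run_calls(aln, cmap, profiles, focal="a0")

            # oracle: recompute frequencies from scratch, column by column
            expected = []
            focal_row = rows[0]
            for col in range(length):
                res = focal_row[col]
                if res not in AMINO_ACIDS:
                    continue

                def freq(members):
                    chars = [rows[ids.index(m)][col] for m in members]
                    valid = [ch for ch in chars if ch in AMINO_ACIDS]
                    return (chars.count(res) / len(valid)) if valid else 0.0

                fa = freq(["a0", "a1", "a2"])
                fb = freq(["b0", "b1"])
                fc = freq(["c0"])
                expected.append((col, fa < 0.20 and (fb > 0.55 or fc > 0.55)))
            assert [(c.filtered_column, c.is_plant_like) for c in calls] == expected


class TestMotifs:
    def call(self, col, flag=True):
        return PlantLikeSiteCall(col, col, "A", 0.05, 0.8, 0.1, flag)

    def test_consecutive_columns_form_one_motif(self):
        motifs = group_motifs([self.call(c) for c in (10, 11, 12)])
        assert len(motifs) == 1
        assert motifs[0].length == 3
        assert (motifs[0].start_original, motifs[0].end_original) == (10, 12)

    def test_distant_singletons_discarded(self):
        assert group_motifs([self.call(10), self.call(20)]) == []

    def test_spacing_boundary(self):
        assert len(group_motifs([self.call(10), self.call(13)])) == 1
        assert group_motifs([self.call(10), self.call(14)]) == []

    def test_non_plant_like_calls_ignored(self):
        calls = [self.call(10), self.call(11, flag=False), self.call(12)]
        motifs = group_motifs(calls)
        assert len(motifs) == 1 and motifs[0].length == 2

    def test_empty_input(self):
        assert group_motifs([]) == []
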