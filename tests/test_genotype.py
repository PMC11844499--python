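import numpy as np
import pandas as pd
import pytest

from opscreen.genotype import (
    aggregate_reads,
    dominant_barcodes,
    genotype_cells,
    map_to_codebook,
)
from opscreen.io import Codebook, CodebookEntry, FormatError
from opscreen.simulate import default_codebook


def levenshtein_reference(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (independent oracle)."""
    m, n = len(a), len(b)
    d = np.arange(n + 1)
    for i in range(1, m + 1):
        prev, d[0] = d[0], i
        for j in range(1, n + 1):
            cur = min(d[j] + 1, d[j - 1] + 1,
                      prev + (a[i - 1] != b[j - 1]))
            prev, d[j] = d[j], cur
    return int(d[n])


def _reads(rows):
    return pd.DataFrame(rows, columns=["cell_label", "barcode",
                                       "spot_quality"])


class TestAggregateReads:
    def test_counts_per_cell(self):
        reads = _reads([(1, "X" * 0 + "GATAGGGCACAT", 0.9)] * 3
                       + [(1, "TAAAGCGTGGGC", 0.9)])
        out = aggregate_reads(reads)
        assert out.iloc[0]["count"] == 3 and out.iloc[1]["count"] == 1

    def test_quality_floor_discards_everything(self):
        reads = _reads([(1, "G" * 12, 0.2), (1, "G" * 12, 0.3)])
        assert len(aggregate_reads(reads, quality_min=0.5)) == 0

    def test_truncation_collapses_shared_prefixes(self):
        reads = _reads([(1, "GAAAAAAAAAAA", 1.0), (1, "GCCCCCCCCCCC", 1.0)])
        out = aggregate_reads(reads, read_length=1)
        assert len(out) == 1 and out.iloc[0]["count"] == 2

    def test_unassigned_and_uncalled_reads_dropped(self):
        reads = _reads([(0, "G" * 12, 1.0), (2, "", 1.0), (3, "G" * 12, 1.0)])
        out = aggregate_reads(reads)
        assert out.cell_label.tolist() == [3]


class TestDominantBarcodes:
    @pytest.mark.parametrize("counts,expected", [
        ({"A": 3, "B": 1}, ("A", 3, "B", 1, False)),
        ({"A": 2, "B": 2}, ("A", 2, "B", 2, True)),
        ({"A": 5}, ("A", 5, None, 0, False)),
        ({}, (None, 0, None, 0, False)),
    ])
    def test_selection_and_tie_rules(self, counts, expected):
        assert dominant_barcodes(counts) == expected


class TestMapToCodebook:
    def test_exact_match_and_miss(self):
        cb = default_codebook()
        entry = cb.entries[0]
        assert map_to_codebook(entry.barcode, cb) == entry.sgrna_id
        neighbour = "A" + entry.barcode[1:]
        if neighbour != entry.barcode:
            assert map_to_codebook(neighbour, cb) == "unmapped"

    def test_distance_zero_equals_set_membership(self, rng):
        """Levenshtein-0 mapping is exactly membership in the codebook."""
        cb = default_codebook()
        members = set(cb.barcodes())
        bases = np.array(list("GCAT"))
        for _ in range(300):
            bc = "".join(rng.choice(bases, 12))
            mapped = map_to_codebook(bc, cb) != "unmapped"
            assert mapped == (bc in members)

    def test_distance_one_agrees_with_brute_force(self, rng):
        cb = default_codebook()
        bases = np.array(list("GCAT"))
        for _ in range(100):
            bc = "".join(rng.choice(bases, 12))
            got = map_to_codebook(bc, cb, max_distance=1)
            dists = {e.sgrna_id: levenshtein_reference(bc, e.barcode)
                     for e in cb}
            best = min(dists.values())
            hits = [s for s, d in dists.items() if d == best]
            expected = hits[0] if (best <= 1 and len(hits) == 1) else "unmapped"
            assert got == expected

    def test_prefix_collision_is_error(self):
        cb = Codebook([
            CodebookEntry("a", "GAAAAAAAAAAA", "X", "targeting"),
            CodebookEntry("b", "GACCCCCCCCCC", "Y", "targeting"),
        ])
        with pytest.raises(FormatError, match="ambiguous at length 2"):
            map_to_codebook("GA", cb, read_length=2)


class TestGenotypeCells:
    def test_dominant_barcode_maps_to_true_sgrna(self):
        cb = default_codebook()
        e1, e2 = cb.entries[0], cb.entries[1]
        reads = _reads([(1, e1.barcode, 1.0)] * 3 + [(1, e2.barcode, 1.0)]
                       + [(2, e2.barcode, 1.0)] * 2)
        table, summary = genotype_cells(reads, 3, cb)
        t = table.set_index("cell_label")
        assert t.loc[1].mapped_sgrna_id == e1.sgrna_id
        assert t.loc[1].second_barcode == e2.barcode
        assert t.loc[2].mapped_sgrna_id == e2.sgrna_id
        assert t.loc[3].mapped_sgrna_id == "unmapped"
        assert summary["fraction_cells_with_reads"] == pytest.approx(2 / 3)
        assert summary["reads_per_cell_mean"] == pytest.approx(6 / 3)
        assert summary["fraction_reads_mapped"] == 1.0

    def test_zero_read_screen_summary_flags_undefined(self):
        table, summary = genotype_cells(_reads([]), 4, default_codebook())
        assert len(table) == 4
        assert summary["fraction_cells_with_reads"] == 0.0
        assert summary["fraction_reads_mapped"] == 0.0
        assert summary["fraction_reads_mapped_undefined"]

    def test_determinism(self):
        cb = default_codebook()
        reads = _reads([(1, cb.entries[0].barcode, 1.0),
                        (1, cb.entries[1].barcode, 1.0)])
        a, _ = genotype_cells(reads, 1, cb)
        b, _ = genotype_cells(reads, 1, cb)
        pd.testing.assert_frame_equal(a, b)
        # tie: lexicographic winner, flagged ambiguous
        assert a.iloc[0].ambiguous
        assert a.iloc[0].top_barcode == min(cb.entries[0].barcode,
                                            cb.entries[1].barcode)

    def test_accuracy_monotone_in_quality_threshold(self, noisy_screen):
        """Reads filtered at a higher quality floor genotype at least as
        accurately (screen-level property used for read QC)."""
        from opscreen.decode import decode_stack
        from opscreen.register import align_stack

        from conftest import match_spots_to_truth

        sim = noisy_screen
        rows = []
        for stack in sim.iss_stacks:
            aligned, sh = align_stack(stack)
            reads = decode_stack(aligned, shifts=sh)
            truth = sim.truth.spots[sim.truth.spots.fov_id == stack.fov.fov_id]
            for det_i, gt_i in match_spots_to_truth(reads, truth):
                r = reads.iloc[det_i]
                if r.consistent and isinstance(r.barcode, str) and r.barcode:
                    rows.append((r.spot_quality,
                                 r.barcode == truth.iloc[gt_i].barcode))
        df = pd.DataFrame(rows, columns=["q", "ok"])
        accs = [df[df.q >= t].ok.mean() for t in (0.0, 0.1, 0.2)]
        assert accs[0] <= accs[1] + 1e-12
        assert accs[1] <= accs[2] + 1e-12
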