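"""TG structure identification, prediction, regioisomer labeling.

The brute-force oracle here re-derives identification and prediction from
first principles with plain nested loops (its own interval, abundance and
ID-peak logic) so the library implementation is checked against an
independent path on randomized tables.
"""

import itertools
import random

import pytest

from tgmrm.identifier import (
    PeakRecord,
    PeakTableError,
    Thresholds,
    assign_regio_suffixes,
    export_assignments,
    identify_structures,
    parse_peak_table,
    predict_structures,
    read_assignments,
    relative_abundance,
    rt_overlap_fraction,
    summarize_regioisomers,
)
from tgmrm.lipid_model import BruttoTG, FattyAcyl, parse_fa_token

from conftest import make_peak


# ---------------------------------------------------------------------------
# Brute-force oracle (independent implementation)
# ---------------------------------------------------------------------------

def _oracle_rel_abundance(peaks):
    out = {}
    for p in peaks:
        group = [q.intensity for q in peaks if q.q1 == p.q1]
        top = max(group)
        out[p] = 100.0 * p.intensity / top if top > 0 else 0.0
    return out


def _oracle_id_peak(support):
    best = None
    for p in support:
        key = (p.intensity, p.rt_left, p.peak_letter)
        if best is None or key < (best.intensity, best.rt_left, best.peak_letter):
            best = p
    return best


def _oracle_check(support, rel, thresholds):
    left = max(p.rt_left for p in support)
    right = min(p.rt_right for p in support)
    if right <= left:
        return None
    idp = _oracle_id_peak(support)
    frac = 100.0 * (right - left) / (idp.rt_right - idp.rt_left)
    if frac < thresholds.min_rt_overlap:
        return None
    if rel[idp] < thresholds.min_relative_abundance:
        return None
    return idp, left, right


def _oracle_string(slots, chain_peaks, idp):
    letters = []
    for fa_key, is_pred in slots:
        if is_pred:
            letters.append("#")
        else:
            p = chain_peaks[fa_key]
            letters.append(p.peak_letter.upper() if p is idp else p.peak_letter)
    return "".join(letters)


def oracle_identify(peaks, fa_list, thresholds):
    """All fa_list chain triples, filtered by the stated rules."""
    rel = _oracle_rel_abundance(peaks)
    results = set()
    bruttos = {p.brutto for p in peaks}
    for brutto in bruttos:
        group = [p for p in peaks if p.brutto == brutto]
        for triple in itertools.combinations_with_replacement(
            sorted(fa_list, key=lambda f: f.key), 3
        ):
            if sum(f.carbons for f in triple) != brutto.total_carbons:
                continue
            if sum(f.double_bonds for f in triple) != brutto.total_double_bonds:
                continue
            distinct = sorted({f.key for f in triple})
            options = [
                [p for p in group if p.q3_fa.key == k] for k in distinct
            ]
            if any(not opts for opts in options):
                continue
            for choice in itertools.product(*options):
                verdict = _oracle_check(choice, rel, thresholds)
                if verdict is None:
                    continue
                idp = verdict[0]
                chain_peaks = dict(zip(distinct, choice))
                slots = sorted((f.key, False) for f in triple)
                name = "TG(" + "_".join(f"{c}:{d}" for (c, d), _ in slots) + ")"
                results.add((name, _oracle_string(slots, chain_peaks, idp)))
    return results


def oracle_predict(peaks, fa_list, thresholds):
    """All detected chain pairs completed from fa_list, same rules."""
    rel = _oracle_rel_abundance(peaks)
    allowed = {f.key: f for f in fa_list}
    results = set()
    for brutto in {p.brutto for p in peaks}:
        group = [p for p in peaks if p.brutto == brutto]
        detected = sorted({p.q3_fa.key for p in group})
        for k1, k2 in itertools.combinations_with_replacement(detected, 2):
            tc = brutto.total_carbons - k1[0] - k2[0]
            td = brutto.total_double_bonds - k1[1] - k2[1]
            if tc <= 0 or td < 0 or (tc, td) not in allowed:
                continue
            if k1 == k2:
                pairings = [(p, p) for p in group if p.q3_fa.key == k1]
            else:
                pairings = [
                    (p1, p2)
                    for p1 in group
                    if p1.q3_fa.key == k1
                    for p2 in group
                    if p2.q3_fa.key == k2
                ]
            for p1, p2 in pairings:
                support = list({p1, p2})
                left = max(p.rt_left for p in support)
                right = min(p.rt_right for p in support)
                if right <= left:
                    continue
                suppressed = any(
                    q.q3_fa.key == (tc, td)
                    and min(q.rt_right, right) > max(q.rt_left, left)
                    for q in group
                )
                if suppressed:
                    continue
                verdict = _oracle_check(support, rel, thresholds)
                if verdict is None:
                    continue
                idp = verdict[0]
                chain_peaks = {k1: p1, k2: p2}
                slots = sorted([(k1, False), (k2, False), ((tc, td), True)])
                name = "TG(" + "_".join(
                    f"{c}:{d}#" if is_pred else f"{c}:{d}"
                    for (c, d), is_pred in slots
                ) + ")"
                results.add((name, _oracle_string(slots, chain_peaks, idp)))
    return results


def random_table(rng, max_peaks=30):
    """A random small peak table: 1-2 bruttos, random channels and windows."""
    pool = [(12, 0), (14, 0), (14, 1), (16, 0), (16, 1), (18, 1), (18, 2)]
    peaks = []
    n_bruttos = rng.randint(1, 2)
    bruttos = rng.sample([(44, 1), (46, 1), (48, 2), (48, 3), (50, 2)], n_bruttos)
    budget = rng.randint(4, max_peaks)
    for bc, bd in bruttos:
        q1 = f"{bc}:{bd}"
        chains = rng.sample(pool, rng.randint(2, 5))
        for c, d in chains:
            for letter in "ab"[: rng.randint(1, 2)]:
                if len(peaks) >= budget:
                    break
                left = round(rng.uniform(0, 8), 2)
                width = round(rng.uniform(0.3, 3.0), 2)
                peaks.append(
                    make_peak(
                        f"{c}:{d}", letter, left, left + width,
                        round(rng.uniform(0, 100), 1),
                        brutto=(bc, bd), q1=q1,
                    )
                )
    return peaks


@pytest.fixture
def fa_pool():
    return [
        FattyAcyl(c, d)
        for c, d in [
            (12, 0), (14, 0), (14, 1), (16, 0), (16, 1),
            (18, 1), (18, 2), (20, 0), (20, 1), (22, 2),
        ]
    ]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

PEAK_HEADER = "name,brutto,q1,q3_fa,peak_id,rt_left,rt_right,intensity\n"


class TestParsePeakTable:
    def test_well_formed_rows(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            PEAK_HEADER
            + "x,TG(48:3),884.8,12:0,a,1.0,2.0,100\n"
            + "y,48:3,884.8,14:0,a,1.0,2.0,50\n"
            + "z,TG(48:3),884.8,14:0,b,3.0,4.0,25\n"
        )
        peaks = parse_peak_table(path)
        assert len(peaks) == 3
        assert peaks[0].brutto == BruttoTG(48, 3)
        assert peaks[2].peak_letter == "b"

    def test_degenerate_rt_interval_names_the_row(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(PEAK_HEADER + "x,TG(48:3),q,12:0,a,2.0,2.0,100\n")
        with pytest.raises(PeakTableError, match="line 2"):
            parse_peak_table(path)

    def test_negative_intensity_rejected(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(PEAK_HEADER + "x,TG(48:3),q,12:0,a,1.0,2.0,-5\n")
        with pytest.raises(PeakTableError, match="line 2"):
            parse_peak_table(path)

    def test_duplicate_channel_letter_rejected(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            PEAK_HEADER
            + "x,TG(48:3),q,12:0,a,1.0,2.0,100\n"
            + "y,TG(48:3),q,12:0,a,1.5,2.5,50\n"
        )
        with pytest.raises(PeakTableError, match="duplicate"):
            parse_peak_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text("name,brutto,q1,q3_fa,peak_id,rt_left,rt_right\n")
        with pytest.raises(PeakTableError, match="intensity"):
            parse_peak_table(path)


# ---------------------------------------------------------------------------
# Peak arithmetic
# ---------------------------------------------------------------------------

class TestRelativeAbundance:
    def test_single_group_scaled_to_max(self):
        peaks = [
            make_peak("12:0", "a", 1, 2, 200),
            make_peak("14:0", "a", 1, 2, 100),
            make_peak("16:0", "a", 1, 2, 50),
        ]
        rel = relative_abundance(peaks)
        assert [rel[p] for p in peaks] == [100.0, 50.0, 25.0]

    def test_single_peak_is_100(self):
        (p,) = peaks = [make_peak("12:0", "a", 1, 2, 7.3)]
        assert relative_abundance(peaks)[p] == 100.0

    def test_groups_normalized_independently(self):
        peaks = [
            make_peak("12:0", "a", 1, 2, 10, brutto=(44, 0), q1="A"),
            make_peak("14:0", "a", 1, 2, 40, brutto=(44, 0), q1="A"),
            make_peak("12:0", "a", 1, 2, 500, brutto=(48, 0), q1="B"),
            make_peak("14:0", "a", 1, 2, 125, brutto=(48, 0), q1="B"),
        ]
        rel = relative_abundance(peaks)
        # brute-force per-group maxima: A -> 40, B -> 500
        assert [rel[p] for p in peaks] == [25.0, 100.0, 100.0, 25.0]

    def test_all_zero_group_maps_to_zero(self):
        peaks = [make_peak("12:0", "a", 1, 2, 0.0), make_peak("14:0", "a", 1, 2, 0.0)]
        assert set(relative_abundance(peaks).values()) == {0.0}


class TestRtOverlap:
    def test_identical_intervals_full_overlap(self):
        peaks = [make_peak("12:0", "a", 1, 2, 10), make_peak("14:0", "a", 1, 2, 5)]
        assert rt_overlap_fraction(peaks, peaks[1]) == 100.0

    def test_disjoint_intervals_zero(self):
        peaks = [make_peak("12:0", "a", 1, 2, 10), make_peak("14:0", "a", 3, 4, 5)]
        assert rt_overlap_fraction(peaks, peaks[1]) == 0.0

    def test_touching_endpoints_count_as_zero(self):
        peaks = [make_peak("12:0", "a", 1, 2, 10), make_peak("14:0", "a", 2, 3, 5)]
        assert rt_overlap_fraction(peaks, peaks[1]) == 0.0

    def test_id_peak_span_is_denominator(self):
        # members [0,10] and [5,15]; ID peak [5,9] inside the intersection
        peaks = [
            make_peak("12:0", "a", 0, 10, 10),
            make_peak("14:0", "a", 5, 15, 20),
            make_peak("16:0", "a", 5, 9, 5),
        ]
        assert rt_overlap_fraction(peaks, peaks[2]) == 100.0

    def test_id_peak_must_be_member(self):
        peaks = [make_peak("12:0", "a", 1, 2, 10)]
        outsider = make_peak("14:0", "a", 1, 2, 5)
        with pytest.raises(ValueError):
            rt_overlap_fraction(peaks, outsider)


# ---------------------------------------------------------------------------
# Identification / prediction on the worked example
# ---------------------------------------------------------------------------

class TestWorkedExample:
    def test_identifications(self, fig2_peaks, fig2_fa_list):
        identified = identify_structures(fig2_peaks, fig2_fa_list)
        got = {(a.tg_name, a.assignment_string) for a in identified}
        assert got == {
            ("TG(12:0_18:1_18:2)", "aAa"),
            ("TG(14:0_16:0_18:3)", "aaA"),
            ("TG(14:0_16:0_18:3)", "bbB"),
            ("TG(14:0_16:0_18:3)", "cCc"),
        }

    def test_predictions(self, fig2_peaks, fig2_fa_list):
        predicted = predict_structures(fig2_peaks, fig2_fa_list)
        got = {(a.tg_name, a.assignment_string) for a in predicted}
        assert got == {
            ("TG(12:0_14:0_22:3#)", "aA#"),
            ("TG(12:0_16:0_20:3#)", "aA#"),
            ("TG(14:0_14:0_20:3#)", "AA#"),
            ("TG(14:0_14:0_20:3#)", "BB#"),
            ("TG(14:0_14:0_20:3#)", "CC#"),
            ("TG(14:0_16:1#_18:2)", "A#a"),
        }

    def test_sum_mismatch_excluded(self, fig2_fa_list):
        # 12:0 + 18:1 + 18:1 sums to 48:2, not the brutto 48:3
        peaks = [
            make_peak("12:0", "a", 1, 2, 100),
            make_peak("18:1", "a", 1, 2, 50),
        ]
        identified = identify_structures(peaks, fig2_fa_list)
        assert identified == []

    def test_disjoint_peaks_excluded(self, fig2_fa_list):
        peaks = [
            make_peak("12:0", "a", 1, 2, 100),
            make_peak("18:1", "a", 3, 4, 50),
            make_peak("18:2", "a", 5, 6, 60),
        ]
        assert identify_structures(peaks, fig2_fa_list) == []

    def test_prediction_guards(self, fig2_fa_list):
        # completing chain would need negative double bonds: no prediction
        peaks = [
            make_peak("14:1", "a", 1, 2, 10),
            make_peak("16:3", "a", 1, 2, 20),
        ]
        assert predict_structures(peaks, fig2_fa_list) == []
        # completing chains (17:3 and 14:3) absent from the FA list: no prediction
        peaks = [
            make_peak("14:0", "a", 1, 2, 10),
            make_peak("17:0", "a", 1, 2, 20),
        ]
        preds = predict_structures(peaks, fig2_fa_list)
        # only the 14:0+14:0 pair completes to a listed chain (20:3)
        assert {a.tg_name for a in preds} == {"TG(14:0_14:0_20:3#)"}

    def test_identified_and_predicted_disjoint(self, fig2_peaks, fig2_fa_list):
        identified = identify_structures(fig2_peaks, fig2_fa_list)
        predicted = predict_structures(fig2_peaks, fig2_fa_list)
        ids = {(a.brutto, a.chain_multiset, a.assignment_string.lower()) for a in identified}
        preds = {(a.brutto, a.chain_multiset, a.assignment_string.lower()) for a in predicted}
        assert not ids & preds

    def test_composition_conservation(self, fig2_peaks, fig2_fa_list):
        for a in identify_structures(fig2_peaks, fig2_fa_list):
            assert sum(fa.carbons for fa in a.chains) == a.brutto.total_carbons
            assert sum(fa.double_bonds for fa in a.chains) == a.brutto.total_double_bonds


class TestThresholds:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(min_relative_abundance=101)
        with pytest.raises(ValueError):
            Thresholds(min_rt_overlap=-1)

    def test_abundance_threshold_cuts_weak_id_peaks(self, fig2_peaks, fig2_fa_list):
        # the window-a 18:3 ID peak sits at 20% of the Q1 maximum
        th = Thresholds(min_relative_abundance=25.0)
        got = {
            (a.tg_name, a.assignment_string)
            for a in identify_structures(fig2_peaks, fig2_fa_list, th)
        }
        assert ("TG(14:0_16:0_18:3)", "aaA") not in got
        assert ("TG(12:0_18:1_18:2)", "aAa") in got

    def test_overlap_threshold_cuts_partial_overlaps(self, fig2_fa_list):
        peaks = [
            make_peak("12:0", "a", 1.0, 2.0, 100),
            make_peak("18:1", "a", 1.5, 2.5, 30),  # ID peak, 50% covered
            make_peak("18:2", "a", 1.0, 2.0, 60),
        ]
        assert identify_structures(peaks, fig2_fa_list, Thresholds(0, 75)) == []
        kept = identify_structures(peaks, fig2_fa_list, Thresholds(0, 50))
        assert [(a.tg_name, a.assignment_string) for a in kept] == [
            ("TG(12:0_18:1_18:2)", "aAa")
        ]

    @pytest.mark.parametrize("op", [identify_structures, predict_structures])
    def test_monotone_in_both_thresholds(self, fig2_peaks, fig2_fa_list, op):
        """Raising either threshold never adds assignments."""
        rng = random.Random(11)
        tables = [fig2_peaks] + [random_table(rng) for _ in range(15)]
        fa_list = fig2_fa_list
        for peaks in tables:
            if not peaks:
                continue
            prev = None
            for ab, ov in [(0, 0), (0, 40), (10, 40), (30, 75), (60, 90)]:
                got = {
                    (a.tg_name, a.assignment_string)
                    for a in op(peaks, fa_list, Thresholds(ab, ov))
                }
                if prev is not None:
                    assert got <= prev
                prev = got

    def test_hard_overlap_gate_at_zero_threshold(self, fig2_fa_list):
        """Even at 0% overlap, disjoint supporting peaks never match."""
        peaks = [
            make_peak("12:0", "a", 1, 2, 100),
            make_peak("18:1", "a", 2, 3, 30),  # touches, no interior overlap
            make_peak("18:2", "a", 1, 2, 60),
        ]
        assert identify_structures(peaks, fig2_fa_list, Thresholds(0, 0)) == []


class TestPermutationInvariance:
    @pytest.mark.parametrize("op", [identify_structures, predict_structures])
    def test_row_order_irrelevant(self, fig2_peaks, fig2_fa_list, op):
        base = [
            (a.tg_name, a.assignment_string) for a in op(fig2_peaks, fig2_fa_list)
        ]
        rng = random.Random(5)
        for _ in range(5):
            shuffled = fig2_peaks[:]
            rng.shuffle(shuffled)
            got = [(a.tg_name, a.assignment_string) for a in op(shuffled, fig2_fa_list)]
            assert got == base


class TestOracleEquivalence:
    def test_identify_matches_brute_force(self, fa_pool):
        rng = random.Random(1234)
        thresholds = [Thresholds(0, 75), Thresholds(0, 0), Thresholds(20, 50)]
        for i in range(120):
            peaks = random_table(rng)
            th = thresholds[i % len(thresholds)]
            got = {
                (a.tg_name, a.assignment_string)
                for a in identify_structures(peaks, fa_pool, th)
            }
            assert got == oracle_identify(peaks, fa_pool, th), f"table {i}"

    def test_predict_matches_brute_force(self, fa_pool):
        rng = random.Random(99)
        thresholds = [Thresholds(0, 75), Thresholds(0, 0), Thresholds(20, 50)]
        for i in range(120):
            peaks = random_table(rng)
            th = thresholds[i % len(thresholds)]
            got = {
                (a.tg_name, a.assignment_string)
                for a in predict_structures(peaks, fa_pool, th)
            }
            assert got == oracle_predict(peaks, fa_pool, th), f"table {i}"


# ---------------------------------------------------------------------------
# Regioisomers
# ---------------------------------------------------------------------------

class TestRegioisomers:
    def test_worked_example_suffixes_in_rt_order(self, fig2_peaks, fig2_fa_list):
        identified = identify_structures(fig2_peaks, fig2_fa_list)
        suffixed = [
            a
            for a in assign_regio_suffixes(identified)
            if a.chain_multiset == ((14, 0), (16, 0), (18, 3))
        ]
        assert [(a.assignment_string, a.regio_suffix) for a in suffixed] == [
            ("aaA", 1),
            ("bbB", 2),
            ("cCc", 3),
        ]

    def test_unique_composition_keeps_suffix_zero(self, fig2_peaks, fig2_fa_list):
        suffixed = assign_regio_suffixes(identify_structures(fig2_peaks, fig2_fa_list))
        (solo,) = [a for a in suffixed if a.chain_multiset == ((12, 0), (18, 1), (18, 2))]
        assert solo.regio_suffix == 0
        assert solo.display_name == "TG(12:0_18:1_18:2)"

    def test_numbering_invariant_under_permutation(self, fig2_peaks, fig2_fa_list):
        identified = identify_structures(fig2_peaks, fig2_fa_list)
        base = [
            (a.tg_name, a.assignment_string, a.regio_suffix)
            for a in assign_regio_suffixes(identified)
        ]
        rng = random.Random(3)
        for _ in range(5):
            shuffled = identified[:]
            rng.shuffle(shuffled)
            got = [
                (a.tg_name, a.assignment_string, a.regio_suffix)
                for a in assign_regio_suffixes(shuffled)
            ]
            assert got == base

    def test_summary_histogram(self, fig2_peaks, fig2_fa_list):
        identified = identify_structures(fig2_peaks, fig2_fa_list)
        predicted = predict_structures(fig2_peaks, fig2_fa_list)
        suffixed = assign_regio_suffixes(identified + predicted)
        hist = summarize_regioisomers(suffixed)
        # 4 singleton species; 14:0_16:0_18:3 and 14:0_14:0_20:3 have 3 variants
        assert hist == {1: 4, 3: 2}
        # conservation: sum(class * count) equals total assignments
        assert sum(k * v for k, v in hist.items()) == len(suffixed)

    def test_all_unique_input_in_class_one(self, fig2_fa_list):
        peaks = [
            make_peak("12:0", "a", 1, 2, 100),
            make_peak("18:1", "a", 1, 2, 30),
            make_peak("18:2", "a", 1, 2, 60),
        ]
        suffixed = assign_regio_suffixes(identify_structures(peaks, fig2_fa_list))
        assert summarize_regioisomers(suffixed) == {1: 1}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

class TestExport:
    def test_round_trip(self, tmp_path, fig2_peaks, fig2_fa_list):
        identified = identify_structures(fig2_peaks, fig2_fa_list)
        predicted = predict_structures(fig2_peaks, fig2_fa_list)
        suffixed = assign_regio_suffixes(identified + predicted)
        path = tmp_path / "assignments.csv"
        export_assignments(suffixed, path)
        back = read_assignments(path)
        assert [
            (r["tg_name"], r["status"], r["assignment"], r["regio_suffix"])
            for r in back
        ] == [
            (a.tg_name, a.status, a.assignment_string, a.regio_suffix)
            for a in suffixed
        ]
        for r, a in zip(back, suffixed):
            assert r["id_peak_letter"] == a.id_peak.peak_letter
            assert r["rt_left"] == a.id_peak.rt_left
            assert r["intensity"] == a.intensity
            assert r["relative_abundance_pct"] == round(a.relative_abundance_pct, 2)

    def test_percent_formatting_two_decimals(self, tmp_path, fig2_peaks, fig2_fa_list):
        identified = identify_structures(fig2_peaks, fig2_fa_list)
        path = tmp_path / "assignments.csv"
        export_assignments(identified, path)
        for line in path.read_text().splitlines()[1:]:
            pct = line.split(",")[8]
            assert len(pct.split(".")[1]) == 2

    def test_empty_export_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_assignments([], tmp_path / "x.csv")
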