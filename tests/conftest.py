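"""Shared fixtures: the worked TG(48:3) example table and small FA lists."""

import pytest

from tgmrm.identifier import PeakRecord
from tgmrm.lipid_model import BruttoTG, FattyAcyl, parse_fa_token


def make_peak(fa, letter, left, right, intensity, brutto=(48, 3), q1=None, name=None):
    b = BruttoTG(*brutto)
    return PeakRecord(
        name=name or f"{b.label}_{fa}",
        brutto=b,
        q1=q1 or b.label,
        q3_fa=parse_fa_token(fa),
        peak_letter=letter,
        rt_left=left,
        rt_right=right,
        intensity=intensity,
    )


@pytest.fixture
def fig2_peaks():
    """A TG(48:3) brutto group with three chromatographic windows.

    Window a (RT 1-2) carries co-eluting losses 12:0, 14:0, 16:0, 18:1,
    18:2, 18:3; windows b (3-4) and c (5-6) carry only 14:0, 16:0, 18:3.
    Intensities are arranged so the ID peaks land where the worked example
    expects: 18:1 lowest in the 12:0/18:1/18:2 triple, 18:3 lowest in
    windows a and b, 16:0 lowest in window c, and the 14:0 peaks weaker
    than the 12:0 and 18:2 peaks they pair with in predictions.
    """
    return [
        make_peak("12:0", "a", 1.0, 2.0, 100.0),
        make_peak("14:0", "a", 1.0, 2.0, 40.0),
        make_peak("16:0", "a", 1.0, 2.0, 50.0),
        make_peak("18:1", "a", 1.0, 2.0, 30.0),
        make_peak("18:2", "a", 1.0, 2.0, 60.0),
        make_peak("18:3", "a", 1.0, 2.0, 20.0),
        make_peak("14:0", "b", 3.0, 4.0, 70.0),
        make_peak("16:0", "b", 3.0, 4.0, 80.0),
        make_peak("18:3", "b", 3.0, 4.0, 35.0),
        make_peak("14:0", "c", 5.0, 6.0, 90.0),
        make_peak("16:0", "c", 5.0, 6.0, 25.0),
        make_peak("18:3", "c", 5.0, 6.0, 45.0),
    ]


@pytest.fixture
def fig2_fa_list():
    """FA list for the worked example, including the prediction-only chains
    16:1, 20:3 and 22:3 that have no acquired peaks."""
    return [
        parse_fa_token(s)
        for s in ["12:0", "14:0", "16:0", "16:1", "18:1", "18:2", "18:3", "20:3", "22:3"]
    ]


@pytest.fixture
def milk_fa18():
    """An 18-chain acquisition list where the 6 most abundant milk chains
    (14:0, 16:0, 16:1, 18:0, 18:1, 18:2) are flagged repeatable."""
    repeatable = {(14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2)}
    chains = [
        (4, 0), (6, 0), (8, 0), (10, 0), (12, 0), (14, 0), (14, 1), (15, 0),
        (16, 0), (16, 1), (17, 0), (18, 0), (18, 1), (18, 2), (18, 3),
        (20, 0), (20, 4), (22, 6),
    ]
    return [FattyAcyl(c, d, repeatable=(c, d) in repeatable) for c, d in chains]
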