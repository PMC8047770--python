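"""TG structure identification and prediction from processed MRM peak tables.

Input is the export of an upstream peak-picking/deconvolution step: one row
per chromatographic peak of one monitored transition, carrying the brutto
(sum-composition) label, the Q1 channel key, the neutral-loss chain (Q3), an
alphabetic peak letter distinguishing chromatographically separated peaks of
the same channel, the retention-time borders and an intensity.

Identification: within a brutto group, any multiset of three detected loss
chains whose carbon and double-bond totals match the brutto exactly, with
mutually overlapping peaks, confirms a TG structure.  A repeated chain is
served by a single physical peak (both losses co-elute by construction).
Prediction: two overlapping loss peaks plus the user FA list complete the
third chain arithmetically when its own loss peak was not acquired.

The ID peak of an assignment is the lowest-intensity distinct supporting
peak; its retention span is the denominator of the overlap test and its
intensity the reported (upper-bound) abundance.  Chromatographically
separated regioisomers of one chain multiset receive numeric suffixes.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .lipid_model import (
    BruttoTG,
    FattyAcyl,
    fa_lookup,
    parse_fa_token,
)

__all__ = [
    "PeakRecord",
    "Thresholds",
    "TGAssignment",
    "PeakTableError",
    "parse_peak_table",
    "validate_peaks",
    "relative_abundance",
    "rt_overlap_fraction",
    "identify_structures",
    "predict_structures",
    "assign_regio_suffixes",
    "summarize_regioisomers",
    "export_assignments",
    "read_assignments",
]


@dataclass(frozen=True, order=True)
class PeakRecord:
    """One chromatographic peak of one (Q1, Q3) transition."""

    name: str
    brutto: BruttoTG
    q1: str
    q3_fa: FattyAcyl
    peak_letter: str
    rt_left: float
    rt_right: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.rt_left < self.rt_right):
            raise ValueError(
                f"peak {self.name!r}: rt_left ({self.rt_left}) must be < "
                f"rt_right ({self.rt_right})"
            )
        if self.intensity < 0:
            raise ValueError(f"peak {self.name!r}: negative intensity {self.intensity}")
        if not (len(self.peak_letter) == 1 and "a" <= self.peak_letter <= "z"):
            raise ValueError(
                f"peak {self.name!r}: peak letter must be a single letter a-z, "
                f"got {self.peak_letter!r}"
            )

    @property
    def interval(self) -> tuple[float, float]:
        return (self.rt_left, self.rt_right)

    @property
    def width(self) -> float:
        return self.rt_right - self.rt_left


@dataclass(frozen=True)
class Thresholds:
    """User-settable filters, both percentages in [0, 100].

    ``min_relative_abundance`` cuts assignments whose ID peak falls below the
    given percent of the strongest peak sharing its Q1 channel.
    ``min_rt_overlap`` requires the common retention segment of the
    supporting peaks to cover at least this percent of the ID peak's span.
    Defaults are 0% abundance and 75% overlap.
    """

    min_relative_abundance: float = 0.0
    min_rt_overlap: float = 75.0

    def __post_init__(self) -> None:
        for name in ("min_relative_abundance", "min_rt_overlap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be within [0, 100], got {v}")


@dataclass(frozen=True)
class TGAssignment:
    """An identified or predicted TG structure.

    ``assignment_string`` has one character per chain in canonical name
    order: the lower-case letter of the supporting peak, capitalized at
    every position served by the ID peak, and ``#`` for a predicted chain
    with no acquired peak (so e.g. ``aAa``, ``AA#``).  Exactly one distinct
    upper-case letter appears.
    """

    chains: tuple[FattyAcyl, FattyAcyl, FattyAcyl]
    predicted_chain: Optional[FattyAcyl]
    assignment_string: str
    brutto: BruttoTG
    id_peak: PeakRecord
    relative_abundance_pct: float
    intensity: float
    status: str  # "identified" | "predicted"
    regio_suffix: int = 0

    @property
    def chain_multiset(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(fa.key for fa in self.chains))

    @property
    def tg_name(self) -> str:
        # position i is the predicted chain iff its assignment char is '#'
        tokens = [
            f"{fa}#" if self.assignment_string[i] == "#" else str(fa)
            for i, fa in enumerate(self.chains)
        ]
        return "TG(" + "_".join(tokens) + ")"

    @property
    def display_name(self) -> str:
        if self.regio_suffix:
            return f"{self.tg_name}[{self.regio_suffix}]"
        return self.tg_name


class PeakTableError(ValueError):
    """Raised when a peak table fails validation; message lists the rows."""


# ---------------------------------------------------------------------------
# Parsing & validation
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = [
    "name",
    "brutto",
    "q1",
    "q3_fa",
    "peak_id",
    "rt_left",
    "rt_right",
    "intensity",
]


def parse_peak_table(path) -> list[PeakRecord]:
    """Read and validate a processed peak table from delimited text.

    Header: ``name,brutto,q1,q3_fa,peak_id,rt_left,rt_right,intensity``
    (comma or tab, case-insensitive).  Malformed rows are reported together
    with their line numbers in a single :class:`PeakTableError`.
    """
    from .cli_io import read_delimited_lines

    rows = read_delimited_lines(path)
    if not rows:
        raise PeakTableError(f"{path}: empty peak table")
    _, header = rows[0]
    cols = [c.strip().lower() for c in header]
    missing = [c for c in _PEAK_COLUMNS if c not in cols]
    if missing:
        raise PeakTableError(f"{path}: missing columns {missing} in header {header}")
    idx = {c: cols.index(c) for c in _PEAK_COLUMNS}

    peaks: list[PeakRecord] = []
    errors: list[str] = []
    for line_no, row in rows[1:]:
        if len(row) < len(cols):
            errors.append(f"line {line_no}: expected {len(cols)} fields, got {len(row)}")
            continue
        try:
            peaks.append(
                PeakRecord(
                    name=row[idx["name"]].strip(),
                    brutto=BruttoTG.parse(row[idx["brutto"]]),
                    q1=row[idx["q1"]].strip(),
                    q3_fa=parse_fa_token(row[idx["q3_fa"]]),
                    peak_letter=row[idx["peak_id"]].strip(),
                    rt_left=float(row[idx["rt_left"]]),
                    rt_right=float(row[idx["rt_right"]]),
                    intensity=float(row[idx["intensity"]]),
                )
            )
        except ValueError as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise PeakTableError(f"{path}: invalid peak table:\n  " + "\n  ".join(errors))
    validate_peaks(peaks, source=str(path))
    return peaks


def validate_peaks(peaks: Sequence[PeakRecord], source: str = "peak table") -> None:
    """Check cross-row invariants: (q1, q3_fa, peak_letter) must be unique."""
    seen: dict[tuple, int] = {}
    dupes = []
    for i, p in enumerate(peaks):
        key = (p.q1, p.q3_fa.key, p.peak_letter)
        if key in seen:
            dupes.append(f"rows {seen[key] + 1} and {i + 1} share (q1={p.q1}, q3_fa={p.q3_fa}, peak={p.peak_letter})")
        else:
            seen[key] = i
    if dupes:
        raise PeakTableError(f"{source}: duplicate peak keys:\n  " + "\n  ".join(dupes))


# ---------------------------------------------------------------------------
# Peak arithmetic
# ---------------------------------------------------------------------------

def relative_abundance(peaks: Sequence[PeakRecord]) -> dict[PeakRecord, float]:
    """Percent intensity of each peak vs the maximum of its Q1 group.

    The group maximum maps to exactly 100.  A group whose intensities are all
    zero gets 0% throughout (such peaks survive only at threshold 0).
    """
    if not peaks:
        raise ValueError("no peaks given")
    groups: dict[str, list[PeakRecord]] = defaultdict(list)
    for p in peaks:
        groups[p.q1].append(p)
    out: dict[PeakRecord, float] = {}
    for members in groups.values():
        top = max(m.intensity for m in members)
        for m in members:
            out[m] = 100.0 * m.intensity / top if top > 0 else 0.0
    return out


def _common_segment(peaks: Iterable[PeakRecord]) -> tuple[float, float] | None:
    """Intersection of all peak intervals, or None if empty/zero-length.

    Touching endpoints do not count as overlap: the hard co-elution gate
    requires an intersection of positive length.
    """
    left = max(p.rt_left for p in peaks)
    right = min(p.rt_right for p in peaks)
    if right <= left:
        return None
    return (left, right)


def rt_overlap_fraction(
    member_peaks: Sequence[PeakRecord], id_peak: PeakRecord
) -> float:
    """Percent of the ID peak's span covered by the members' common segment.

    Returns 0 when the intervals have no positive-length intersection.
    """
    if id_peak not in member_peaks:
        raise ValueError("id_peak must be one of the member peaks")
    seg = _common_segment(member_peaks)
    if seg is None:
        return 0.0
    return 100.0 * (seg[1] - seg[0]) / id_peak.width


def _pick_id_peak(support: Sequence[PeakRecord]) -> PeakRecord:
    # lowest intensity; ties broken by earlier rt_left, then peak letter
    return min(support, key=lambda p: (p.intensity, p.rt_left, p.peak_letter))


# ---------------------------------------------------------------------------
# Identification & prediction
# ---------------------------------------------------------------------------

def _group_peaks(
    peaks: Sequence[PeakRecord],
) -> list[tuple[BruttoTG, dict[tuple[int, int], list[PeakRecord]]]]:
    """Group peaks by brutto, then by loss chain; deterministic order."""
    by_brutto: dict[BruttoTG, dict[tuple[int, int], list[PeakRecord]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for p in peaks:
        by_brutto[p.brutto][p.q3_fa.key].append(p)
    out = []
    for brutto in sorted(by_brutto):
        by_chain = by_brutto[brutto]
        for key in by_chain:
            by_chain[key].sort(key=lambda p: (p.rt_left, p.peak_letter))
        out.append((brutto, dict(sorted(by_chain.items()))))
    return out


def _make_assignment(
    chains: Sequence[FattyAcyl],
    chain_peaks: Mapping[tuple[int, int], PeakRecord],
    predicted: Optional[FattyAcyl],
    brutto: BruttoTG,
    rel: Mapping[PeakRecord, float],
) -> TGAssignment:
    """Assemble a TGAssignment from chosen supporting peaks.

    ``chains`` are the observed chains (2 or 3); ``predicted``, if given, is
    the arithmetically completed third chain.  The assignment string orders
    chains canonically, with a predicted chain sorting after an observed
    chain of equal (C, D).
    """
    support = sorted(set(chain_peaks.values()))
    id_peak = _pick_id_peak(support)
    # (chain, is_predicted) in canonical order
    slots = [(fa, False) for fa in chains]
    if predicted is not None:
        slots.append((predicted, True))
    slots.sort(key=lambda t: (t[0].key, t[1]))
    letters = []
    for fa, is_pred in slots:
        if is_pred:
            letters.append("#")
        else:
            peak = chain_peaks[fa.key]
            letters.append(
                peak.peak_letter.upper() if peak is id_peak else peak.peak_letter
            )
    return TGAssignment(
        chains=tuple(fa for fa, _ in slots),  # type: ignore[arg-type]
        predicted_chain=predicted,
        assignment_string="".join(letters),
        brutto=brutto,
        id_peak=id_peak,
        relative_abundance_pct=rel[id_peak],
        intensity=id_peak.intensity,
        status="predicted" if predicted is not None else "identified",
    )


def _passes(
    support: Sequence[PeakRecord],
    rel: Mapping[PeakRecord, float],
    thresholds: Thresholds,
) -> bool:
    seg = _common_segment(support)
    if seg is None:
        return False  # hard gate: peaks must overlap
    id_peak = _pick_id_peak(support)
    frac = 100.0 * (seg[1] - seg[0]) / id_peak.width
    if frac < thresholds.min_rt_overlap:
        return False
    if rel[id_peak] < thresholds.min_relative_abundance:
        return False
    return True


def identify_structures(
    peaks: Sequence[PeakRecord],
    fa_list: Sequence[FattyAcyl],
    thresholds: Thresholds = Thresholds(),
) -> list[TGAssignment]:
    """Confirm TG structures whose three loss peaks are all acquired.

    Within each brutto group, every multiset of three detected chains (each
    in the user FA list) is kept when the chain totals subtract the brutto to
    exactly zero in both carbons and double bonds, the distinct supporting
    peaks share a positive-length retention segment, that segment covers at
    least ``min_rt_overlap`` % of the ID peak's span, and the ID peak meets
    ``min_relative_abundance``.  A repeated chain is served by one physical
    peak.  Results are deduplicated on (name, assignment string) and are
    independent of input row order.
    """
    if not peaks:
        return []
    validate_peaks(peaks)
    allowed = fa_lookup(fa_list)
    rel = relative_abundance(peaks)
    out: dict[tuple[str, str], TGAssignment] = {}
    for brutto, by_chain in _group_peaks(peaks):
        chains = [
            allowed[key] for key in by_chain if key in allowed
        ]  # detected chains usable for identification
        for triple in itertools.combinations_with_replacement(chains, 3):
            if (
                sum(fa.carbons for fa in triple) != brutto.total_carbons
                or sum(fa.double_bonds for fa in triple) != brutto.total_double_bonds
            ):
                continue
            distinct = sorted({fa.key for fa in triple})
            for choice in itertools.product(*(by_chain[k] for k in distinct)):
                if not _passes(choice, rel, thresholds):
                    continue
                chain_peaks = dict(zip(distinct, choice))
                asn = _make_assignment(
                    triple, chain_peaks, None, brutto, rel
                )
                out.setdefault((asn.tg_name, asn.assignment_string), asn)
    return sorted(
        out.values(), key=lambda a: (a.chain_multiset, a.assignment_string)
    )


def predict_structures(
    peaks: Sequence[PeakRecord],
    fa_list: Sequence[FattyAcyl],
    thresholds: Thresholds = Thresholds(),
) -> list[TGAssignment]:
    """Predict TG structures from two acquired loss peaks plus the FA list.

    For each brutto group and each pair of detected chains with overlapping
    supporting peaks (a single peak serves both positions when the pair
    repeats one chain), the third chain is completed by subtraction from the
    brutto totals.  A prediction is emitted only when the completed chain has
    positive carbons and non-negative double bonds, is a member of the user
    FA list, and no acquired peak of that chain co-elutes with the pair in
    the same brutto group — otherwise the triple is a three-peak
    identification, not a prediction.  Thresholds apply as in
    :func:`identify_structures` with two-member support.
    """
    if not peaks:
        return []
    validate_peaks(peaks)
    allowed = fa_lookup(fa_list)
    rel = relative_abundance(peaks)
    out: dict[tuple[str, str], TGAssignment] = {}
    for brutto, by_chain in _group_peaks(peaks):
        detected = [parse_fa_token(f"{c}:{d}") for c, d in by_chain]
        for fa1, fa2 in itertools.combinations_with_replacement(detected, 2):
            third_c = brutto.total_carbons - fa1.carbons - fa2.carbons
            third_d = brutto.total_double_bonds - fa1.double_bonds - fa2.double_bonds
            if third_c <= 0 or third_d < 0 or third_d > third_c:
                continue
            third = allowed.get((third_c, third_d))
            if third is None:
                continue
            if fa1.key == fa2.key:
                pairings = [(p, p) for p in by_chain[fa1.key]]
            else:
                pairings = list(
                    itertools.product(by_chain[fa1.key], by_chain[fa2.key])
                )
            for p1, p2 in pairings:
                support = sorted({p1, p2})
                seg = _common_segment(support)
                if seg is None:
                    continue
                # suppression: an acquired peak of the completing chain that
                # co-elutes with the pair makes this a 3-peak identification
                third_peaks = by_chain.get(third.key, [])
                if any(
                    min(q.rt_right, seg[1]) > max(q.rt_left, seg[0])
                    for q in third_peaks
                ):
                    continue
                if not _passes(support, rel, thresholds):
                    continue
                chain_peaks = {fa1.key: p1, fa2.key: p2}
                asn = _make_assignment([fa1, fa2], chain_peaks, third, brutto, rel)
                out.setdefault((asn.tg_name, asn.assignment_string), asn)
    return sorted(
        out.values(), key=lambda a: (a.chain_multiset, a.assignment_string)
    )


# ---------------------------------------------------------------------------
# Regioisomers
# ---------------------------------------------------------------------------

def assign_regio_suffixes(assignments: Sequence[TGAssignment]) -> list[TGAssignment]:
    """Number chromatographically separated variants of one chain multiset.

    Assignments sharing a chain multiset but supported by different peak
    sets receive suffixes 1, 2, 3, ... ordered by ascending ID-peak
    ``rt_left`` (then peak letter, then assignment string, so the numbering
    is invariant under input permutation).  A multiset occurring once keeps
    suffix 0, meaning no suffix is printed.
    """
    groups: dict[tuple, list[TGAssignment]] = defaultdict(list)
    for a in assignments:
        groups[a.chain_multiset].append(a)
    suffixed: list[TGAssignment] = []
    for key in sorted(groups):
        members = sorted(
            groups[key],
            key=lambda a: (
                a.id_peak.rt_left,
                a.id_peak.peak_letter,
                a.assignment_string,
            ),
        )
        if len(members) == 1:
            suffixed.append(replace(members[0], regio_suffix=0))
        else:
            for i, a in enumerate(members, start=1):
                suffixed.append(replace(a, regio_suffix=i))
    suffixed.sort(key=lambda a: (a.chain_multiset, a.regio_suffix, a.assignment_string))
    return suffixed


def summarize_regioisomers(assignments: Sequence[TGAssignment]) -> dict[int, int]:
    """Histogram: number of chain multisets having exactly k chromatographic
    variants, for each k present."""
    sizes: dict[tuple, int] = defaultdict(int)
    for a in assignments:
        sizes[a.chain_multiset] += 1
    hist: dict[int, int] = defaultdict(int)
    for n in sizes.values():
        hist[n] += 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_ASSIGNMENT_HEADER = (
    "tg_name,status,assignment,regio_suffix,id_peak_q3_fa,id_peak_letter,"
    "rt_left,rt_right,relative_abundance_pct,intensity"
)


def export_assignments(assignments: Sequence[TGAssignment], path) -> str:
    """Write assignments as delimited text; atomic write-then-rename."""
    from .cli_io import atomic_write_text

    if not assignments:
        raise ValueError("nothing to export: empty assignment list")
    lines = [_ASSIGNMENT_HEADER]
    for a in assignments:
        lines.append(
            ",".join(
                [
                    a.tg_name,
                    a.status,
                    a.assignment_string,
                    str(a.regio_suffix),
                    str(a.id_peak.q3_fa),
                    a.id_peak.peak_letter,
                    repr(a.id_peak.rt_left),
                    repr(a.id_peak.rt_right),
                    f"{a.relative_abundance_pct:.2f}",
                    repr(a.intensity),
                ]
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")
    return str(path)


def read_assignments(path) -> list[dict]:
    """Read an assignment file back as a list of field dicts."""
    from .cli_io import read_delimited_lines

    rows = read_delimited_lines(path)
    if not rows or [c.strip().lower() for c in rows[0][1]][:2] != ["tg_name", "status"]:
        raise ValueError(f"{path}: not an assignments file (bad header)")
    out = []
    for line_no, row in rows[1:]:
        try:
            out.append(
                {
                    "tg_name": row[0],
                    "status": row[1],
                    "assignment": row[2],
                    "regio_suffix": int(row[3]),
                    "id_peak_q3_fa": row[4],
                    "id_peak_letter": row[5],
                    "rt_left": float(row[6]),
                    "rt_right": float(row[7]),
                    "relative_abundance_pct": float(row[8]),
                    "intensity": float(row[9]),
                }
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return out
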