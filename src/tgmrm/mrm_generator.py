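"""MRM acquisition-list design for targeted TG detection.

From an enumerated set of TG compositions this module derives the multiple
reaction monitoring (MRM) transition list — one (Q1, Q3) pair per composition
and constituent chain, where Q1 is the [M+NH4]+ precursor and Q3 the product
after neutral loss of that chain as RCOONH4 — plus the companion structure
table listing, for every composition, the transitions needed to confirm it.

Transitions are deduplicated on the (Q1, Q3) pair rounded to the working m/z
precision: isobaric compositions sharing a brutto level share Q1, and equal
losses then collapse to a single monitored channel, which is what shrinks the
acquisition method to a size a triple quadrupole can cycle through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .lipid_model import (
    BruttoTG,
    FattyAcyl,
    TGComposition,
    neutral_loss_mass,
    parse_fa_token,
    tg_ammonium_adduct_mz,
)

__all__ = [
    "MRMTransition",
    "StructureTableRow",
    "build_mrm_list",
    "build_structure_table",
    "export_mrm",
    "read_mrm_list",
    "read_structure_table",
    "DEFAULT_PRECISION",
]

# Unit-resolution triple-quadrupole practice: one decimal place.
DEFAULT_PRECISION = 1


@dataclass(frozen=True, order=True)
class MRMTransition:
    """One monitored (Q1, Q3) channel with the chain whose loss defines Q3."""

    q1_mz: float
    q3_mz: float
    loss_fa: FattyAcyl

    def __post_init__(self) -> None:
        if not (self.q1_mz > self.q3_mz > 0):
            raise ValueError(
                f"require q1 > q3 > 0, got Q1={self.q1_mz}, Q3={self.q3_mz}"
            )


@dataclass(frozen=True)
class StructureTableRow:
    """A TG composition with the 1-3 distinct transitions that confirm it."""

    composition: TGComposition
    brutto: BruttoTG
    transitions: tuple[MRMTransition, ...]

    def __post_init__(self) -> None:
        n_distinct = len(self.composition.distinct_chains)
        if len(self.transitions) != n_distinct:
            raise ValueError(
                f"{self.composition.name}: expected {n_distinct} transitions, "
                f"got {len(self.transitions)}"
            )


def _transitions_for(comp: TGComposition, precision: int) -> list[MRMTransition]:
    q1 = round(tg_ammonium_adduct_mz(comp), precision)
    out = []
    for fa in comp.distinct_chains:
        q3 = round(tg_ammonium_adduct_mz(comp) - neutral_loss_mass(fa), precision)
        out.append(MRMTransition(q1, q3, fa))
    return out


def build_mrm_list(
    comps: Sequence[TGComposition], precision: int = DEFAULT_PRECISION
) -> list[MRMTransition]:
    """Build the deduplicated MRM transition list for a composition set.

    For every composition and every distinct constituent chain the rounded
    (Q1, Q3) pair appears exactly once; the recorded ``loss_fa`` is that of
    the first contributing composition in canonical order (the physical
    method cannot distinguish isobaric losses).  Sorted by (Q1, Q3).
    """
    if not comps:
        raise ValueError("composition list is empty")
    ordered = sorted(comps, key=lambda c: tuple(fa.key for fa in c.chains))
    seen: dict[tuple[float, float], MRMTransition] = {}
    for comp in ordered:
        for tr in _transitions_for(comp, precision):
            seen.setdefault((tr.q1_mz, tr.q3_mz), tr)
    return sorted(seen.values(), key=lambda t: (t.q1_mz, t.q3_mz))


def build_structure_table(
    comps: Sequence[TGComposition], precision: int = DEFAULT_PRECISION
) -> list[StructureTableRow]:
    """One row per composition with its confirming transitions.

    The linked transitions are consistent with :func:`build_mrm_list`: every
    (Q1, Q3) pair referenced here is present in the deduplicated list.
    """
    if not comps:
        raise ValueError("composition list is empty")
    ordered = sorted(set(comps), key=lambda c: tuple(fa.key for fa in c.chains))
    rows = []
    for comp in ordered:
        rows.append(
            StructureTableRow(
                composition=comp,
                brutto=comp.brutto,
                transitions=tuple(_transitions_for(comp, precision)),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def _fmt(value: float, precision: int) -> str:
    return f"{value:.{precision}f}"


def export_mrm(
    transitions: Sequence[MRMTransition],
    rows: Sequence[StructureTableRow],
    out_prefix,
    precision: int = DEFAULT_PRECISION,
) -> tuple[str, str]:
    """Write ``<prefix>_mrm_list.csv`` and ``<prefix>_structures.csv``.

    m/z values are printed with fixed decimals at the working precision so
    the files round-trip bit-exactly through the readers.  Returns the two
    paths written.  Writes are atomic (write-then-rename).
    """
    from .cli_io import atomic_write_text

    if not transitions or not rows:
        raise ValueError("nothing to export: empty transition or structure list")
    prefix = str(out_prefix)
    mrm_path = prefix + "_mrm_list.csv"
    structure_path = prefix + "_structures.csv"

    lines = ["q1_mz,q3_mz,loss_fa,compound_group"]
    for tr in transitions:
        group = f"TG {_fmt(tr.q1_mz, precision)} loss {tr.loss_fa}"
        lines.append(
            f"{_fmt(tr.q1_mz, precision)},{_fmt(tr.q3_mz, precision)},{tr.loss_fa},{group}"
        )
    atomic_write_text(mrm_path, "\n".join(lines) + "\n")

    lines = ["tg_name,brutto,total_carbons,total_double_bonds,q1_mz,q3_fa_list"]
    for row in rows:
        fa_tokens = ";".join(str(tr.loss_fa) for tr in row.transitions)
        lines.append(
            ",".join(
                [
                    row.composition.name,
                    row.brutto.label,
                    str(row.brutto.total_carbons),
                    str(row.brutto.total_double_bonds),
                    _fmt(row.transitions[0].q1_mz, precision),
                    fa_tokens,
                ]
            )
        )
    atomic_write_text(structure_path, "\n".join(lines) + "\n")
    return mrm_path, structure_path


def read_mrm_list(path) -> list[MRMTransition]:
    """Read a transition list written by :func:`export_mrm`."""
    from .cli_io import read_delimited_lines

    rows = read_delimited_lines(path)
    if not rows or [c.strip().lower() for c in rows[0][1]][:3] != ["q1_mz", "q3_mz", "loss_fa"]:
        raise ValueError(f"{path}: not an MRM list file (bad header)")
    out = []
    for line_no, row in rows[1:]:
        try:
            out.append(
                MRMTransition(float(row[0]), float(row[1]), parse_fa_token(row[2]))
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return out


def read_structure_table(path) -> list[tuple[str, BruttoTG, float, list[FattyAcyl]]]:
    """Read a structure table written by :func:`export_mrm`.

    Returns (tg_name, brutto, q1_mz, loss chains) per row — enough to verify
    a round trip without re-deriving the composition objects.
    """
    from .cli_io import read_delimited_lines

    rows = read_delimited_lines(path)
    if not rows or [c.strip().lower() for c in rows[0][1]][:2] != ["tg_name", "brutto"]:
        raise ValueError(f"{path}: not a structure table file (bad header)")
    out = []
    for line_no, row in rows[1:]:
        try:
            out.append(
                (
                    row[0],
                    BruttoTG.parse(row[1]),
                    float(row[4]),
                    [parse_fa_token(tok) for tok in row[5].split(";")],
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return out
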