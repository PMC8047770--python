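"""Core lipid data types and combinatorics for triacylglycerol (TG) profiling.

A TG is a glycerol backbone esterified with three fatty acyl (FA) chains.
On a triple-quadrupole instrument TGs are monitored as ammonium adducts
[M+NH4]+ and fragmented by neutral loss of one acyl chain as its ammonium
salt (RCOONH4), leaving a diacylglycerol-like product ion.  This module
provides the chain/composition types, the monoisotopic mass arithmetic for
those adducts and losses, and the combinatorial enumeration of all chain
multisets that a user-supplied FA list can form.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from pyteomics import mass as _ptmass

__all__ = [
    "FattyAcyl",
    "TGComposition",
    "BruttoTG",
    "parse_fa_token",
    "fa_monoisotopic_mass",
    "neutral_loss_mass",
    "tg_neutral_mass",
    "tg_ammonium_adduct_mz",
    "brutto_ammonium_adduct_mz",
    "enumerate_tg",
    "read_fa_list",
]

# Monoisotopic masses of the fixed chemical pieces (Da).
MASS_H = _ptmass.calculate_mass(formula="H")
MASS_NH3 = _ptmass.calculate_mass(formula="NH3")
MASS_NH4 = _ptmass.calculate_mass(formula="NH4")
# Glycerol (C3H8O3) minus three waters: what the backbone contributes once
# all three acids are esterified.
MASS_GLYCEROL_BACKBONE = _ptmass.calculate_mass(formula="C3H2")

ReappearancePolicy = Literal["unrestricted", "restricted"]


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain, shorthand ``C:D`` (carbons : double bonds).

    ``carbons`` counts all acyl carbons including the carboxyl carbon.
    ``repeatable`` is an acquisition-design flag: may this chain occupy more
    than one of the three positions of a TG?  It does not take part in
    equality or ordering — chains are identified by (carbons, double_bonds).
    """

    carbons: int
    double_bonds: int
    repeatable: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.carbons, int) or not isinstance(self.double_bonds, int):
            raise TypeError("carbons and double_bonds must be integers")
        if self.carbons < 2:
            raise ValueError(
                f"invalid fatty acyl {self.carbons}:{self.double_bonds}: "
                "need at least 2 carbons"
            )
        if self.double_bonds < 0:
            raise ValueError(
                f"invalid fatty acyl {self.carbons}:{self.double_bonds}: "
                "negative double bond count"
            )
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"invalid fatty acyl {self.carbons}:{self.double_bonds}: "
                "more double bonds than carbons"
            )

    @property
    def key(self) -> tuple[int, int]:
        return (self.carbons, self.double_bonds)

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


_FA_TOKEN_RE = re.compile(r"^\s*(\d+):(\d+)\s*$")


def parse_fa_token(token: str, repeatable: bool = True) -> FattyAcyl:
    """Parse a ``C:D`` shorthand token into a :class:`FattyAcyl`."""
    m = _FA_TOKEN_RE.match(token)
    if not m:
        raise ValueError(f"cannot parse fatty acyl token {token!r} (expected 'C:D')")
    return FattyAcyl(int(m.group(1)), int(m.group(2)), repeatable=repeatable)


@dataclass(frozen=True, order=True)
class TGComposition:
    """An unordered multiset of exactly three fatty acyl chains.

    Chains are stored in canonical ascending (carbons, double_bonds) order so
    equality is independent of the order chains were supplied in.
    """

    chains: tuple[FattyAcyl, FattyAcyl, FattyAcyl]

    def __post_init__(self) -> None:
        if len(self.chains) != 3:
            raise ValueError(f"a TG has exactly 3 chains, got {len(self.chains)}")
        ordered = tuple(sorted(self.chains, key=lambda fa: fa.key))
        object.__setattr__(self, "chains", ordered)

    @classmethod
    def of(cls, *chains: FattyAcyl | str) -> "TGComposition":
        fas = tuple(
            parse_fa_token(c) if isinstance(c, str) else c for c in chains
        )
        return cls(fas)  # type: ignore[arg-type]

    @classmethod
    def parse(cls, text: str) -> "TGComposition":
        """Parse ``TG(12:0_18:1_18:2)`` (or the bare underscore form)."""
        body = text.strip()
        if body.upper().startswith("TG(") and body.endswith(")"):
            body = body[3:-1]
        tokens = body.split("_")
        if len(tokens) != 3:
            raise ValueError(f"cannot parse TG name {text!r}: need 3 chain tokens")
        return cls.of(*tokens)

    @property
    def total_carbons(self) -> int:
        return sum(fa.carbons for fa in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(fa.double_bonds for fa in self.chains)

    @property
    def brutto(self) -> "BruttoTG":
        return BruttoTG(self.total_carbons, self.total_double_bonds)

    @property
    def distinct_chains(self) -> tuple[FattyAcyl, ...]:
        seen: dict[tuple[int, int], FattyAcyl] = {}
        for fa in self.chains:
            seen.setdefault(fa.key, fa)
        return tuple(seen.values())

    @property
    def name(self) -> str:
        return "TG(" + "_".join(str(fa) for fa in self.chains) + ")"

    def __str__(self) -> str:
        return self.name


_BRUTTO_RE = re.compile(r"^\s*(?:TG\()?\s*(\d+):(\d+)\s*\)?\s*$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class BruttoTG:
    """Sum-composition ("brutto") annotation: total carbons and double bonds.

    ``TG(48:3)`` means 48 carbons and 3 double bonds summed over the three
    constituent chains; the individual chains are unresolved at this level.
    """

    total_carbons: int
    total_double_bonds: int

    def __post_init__(self) -> None:
        if self.total_carbons < 6:
            raise ValueError(
                f"brutto TG needs >= 6 carbons (3 chains of >= 2), got {self.total_carbons}"
            )
        if self.total_double_bonds < 0:
            raise ValueError("brutto double bond count cannot be negative")

    @classmethod
    def parse(cls, text: str) -> "BruttoTG":
        m = _BRUTTO_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse brutto label {text!r} (expected 'TG(C:D)' or 'C:D')")
        return cls(int(m.group(1)), int(m.group(2)))

    @property
    def label(self) -> str:
        return f"TG({self.total_carbons}:{self.total_double_bonds})"

    def __str__(self) -> str:
        return self.label


# ---------------------------------------------------------------------------
# Mass arithmetic
# ---------------------------------------------------------------------------

def fa_monoisotopic_mass(fa: FattyAcyl) -> float:
    """Monoisotopic mass of the free fatty acid C_c H_(2c-2d) O_2 in Da."""
    h = 2 * fa.carbons - 2 * fa.double_bonds
    return _ptmass.calculate_mass(formula=f"C{fa.carbons}H{h}O2")


def neutral_loss_mass(fa: FattyAcyl) -> float:
    """Mass of the neutral loss RCOONH4 (the acid's ammonium salt) in Da."""
    return fa_monoisotopic_mass(fa) + MASS_NH3


def tg_neutral_mass(comp: TGComposition) -> float:
    """Monoisotopic mass of the neutral TG: three acids condensed on glycerol."""
    return sum(fa_monoisotopic_mass(fa) for fa in comp.chains) + MASS_GLYCEROL_BACKBONE


def tg_ammonium_adduct_mz(comp: TGComposition) -> float:
    """m/z of the singly charged ammonium adduct [M+NH4]+ of a TG.

    The electron mass is ignored (< 0.0006 Da, below unit-resolution
    reporting precision on a triple quadrupole).
    """
    return tg_neutral_mass(comp) + MASS_NH4


def brutto_ammonium_adduct_mz(brutto: BruttoTG) -> float:
    """[M+NH4]+ m/z from a brutto label alone.

    The TG mass depends only on total carbons and double bonds, so any chain
    split of the same brutto shares one precursor m/z (the basis of Q1
    channel sharing).
    """
    c, d = brutto.total_carbons, brutto.total_double_bonds
    h = 2 * c - 2 * d  # sum over the three acids
    acids = _ptmass.calculate_mass(formula=f"C{c}H{h}O6")
    return acids + MASS_GLYCEROL_BACKBONE + MASS_NH4


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _check_fa_list(fa_list: Sequence[FattyAcyl]) -> list[FattyAcyl]:
    if not fa_list:
        raise ValueError("fatty acyl list is empty")
    seen: set[tuple[int, int]] = set()
    for fa in fa_list:
        if fa.key in seen:
            raise ValueError(f"duplicate fatty acyl entry {fa} in list")
        seen.add(fa.key)
    return sorted(fa_list, key=lambda fa: fa.key)


def enumerate_tg(
    fa_list: Sequence[FattyAcyl],
    policy: ReappearancePolicy = "unrestricted",
) -> list[TGComposition]:
    """Enumerate all TG compositions (chain multisets of size 3) from a FA list.

    With ``policy="unrestricted"`` every multiset is returned; for *n* chains
    that is (n^3 + 3n^2 + 2n)/6 compositions.  With ``policy="restricted"``
    the reappearance rule is applied: a composition may contain at most one
    chain position (counted with multiplicity) occupied by a non-repeatable
    chain, so only the designated abundant chains may fill two or three
    positions.  Output is deterministic: canonically sorted, no duplicates.
    """
    ordered = _check_fa_list(fa_list)
    if policy not in ("unrestricted", "restricted"):
        raise ValueError(f"unknown reappearance policy {policy!r}")
    comps: list[TGComposition] = []
    for triple in itertools.combinations_with_replacement(ordered, 3):
        if policy == "restricted":
            n_restricted = sum(1 for fa in triple if not fa.repeatable)
            if n_restricted > 1:
                continue
        comps.append(TGComposition(triple))
    comps.sort(key=lambda c: tuple(fa.key for fa in c.chains))
    return comps


def unrestricted_count(n: int) -> int:
    """Closed-form multiset count: (n^3 + 3n^2 + 2n) / 6."""
    return (n**3 + 3 * n**2 + 2 * n) // 6


# ---------------------------------------------------------------------------
# FA list file
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"true", "t", "yes", "y", "1"}
_FALSE_TOKENS = {"false", "f", "no", "n", "0"}


def _parse_bool(token: str, line_no: int) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise ValueError(f"line {line_no}: cannot parse boolean {token!r}")


def read_fa_list(path) -> list[FattyAcyl]:
    """Read a user FA list from delimited text.

    Expected header columns (case-insensitive): ``fa_carbons``,
    ``fa_double_bonds``, ``repeatable``.  Blank lines and lines starting
    with ``#`` are ignored; comma and tab delimiters are auto-detected.
    """
    from .cli_io import read_delimited_lines

    rows = read_delimited_lines(path)
    if not rows:
        raise ValueError(f"{path}: empty fatty acyl list file")
    header_no, header = rows[0]
    cols = [c.strip().lower() for c in header]
    required = ["fa_carbons", "fa_double_bonds", "repeatable"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} in header {header}")
    idx = {c: cols.index(c) for c in required}
    fas: list[FattyAcyl] = []
    for line_no, row in rows[1:]:
        if len(row) < len(cols):
            raise ValueError(f"{path}: line {line_no}: expected {len(cols)} fields, got {len(row)}")
        try:
            fa = FattyAcyl(
                int(row[idx["fa_carbons"]]),
                int(row[idx["fa_double_bonds"]]),
                repeatable=_parse_bool(row[idx["repeatable"]], line_no),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        fas.append(fa)
    _check_fa_list(fas)  # reject duplicates early, with a clear message
    return fas


def fa_lookup(fa_list: Iterable[FattyAcyl]) -> dict[tuple[int, int], FattyAcyl]:
    """Index a FA list by (carbons, double_bonds) for O(1) membership tests."""
    return {fa.key: fa for fa in fa_list}
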