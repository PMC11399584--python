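"""Lipid shorthand nomenclature: parsing, formatting, and omega-class assignment.

Implements the subset of LIPID MAPS shorthand used for routine plasma
lipidomics: a class token (``CE``, ``TG``, ``PC`` ...) followed by acyl chains
written ``carbons:double_bonds``, joined by ``_`` (sn-position unknown) or
``/`` (sn-position known).  ``O-`` marks an ether bond, ``P-`` a vinyl ether
(plasmalogen), and ``d`` a sphingoid base (``SM d18:1/16:0``).  A single
chain token for a multi-chain class (``TG 52:3``) is a sum composition —
the species level — where individual chains are unknown.

Deuterated internal-standard labels (``d31-LPC 16:0``) are stripped and kept
as a deuterium count so that standards can be referenced by name.

Omega (n-) classes cannot be read off shorthand names because double-bond
positions are not resolved by routine MS2; they are assigned from a lookup
table of the most abundant positional isomer per acyl, shipped as
``data/omega_lookup.csv`` and overridable by the user.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Chain",
    "LipidSpecies",
    "OmegaLookup",
    "LipidParseError",
    "parse_lipid_name",
    "format_lipid_name",
    "assign_omega",
    "CLASS_CHAIN_COUNT",
]

#: expected number of acyl/alkyl chains per supported lipid class
CLASS_CHAIN_COUNT: dict[str, int] = {
    "CE": 1, "LPC": 1, "LPE": 1, "FA": 1, "MG": 1,
    "PC": 2, "PE": 2, "PI": 2, "PS": 2, "PG": 2, "PA": 2, "DG": 2, "SM": 2,
    "TG": 3,
}

_BOND_PREFIXES = ("O-", "P-", "d")

SPECIES = "species"
MOLECULAR_SPECIES = "molecular_species"


class LipidParseError(ValueError):
    """Raised when a shorthand name cannot be parsed; carries the position."""

    def __init__(self, message: str, name: str, position: int = 0):
        super().__init__(f"{message} in {name!r} at position {position}")
        self.name = name
        self.position = position


@dataclass(frozen=True, order=True)
class Chain:
    """One fatty acyl/alkyl chain: carbons, double bonds, optional bond prefix."""

    carbons: int
    double_bonds: int
    bond_prefix: Optional[str] = None  # None | "O-" | "P-" | "d"

    def __post_init__(self):
        if self.carbons <= 0:
            raise ValueError(f"chain carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("chain double_bonds must be >= 0")
        if self.bond_prefix is not None and self.bond_prefix not in _BOND_PREFIXES:
            raise ValueError(f"unknown bond prefix {self.bond_prefix!r}")

    def __str__(self) -> str:
        prefix = self.bond_prefix or ""
        return f"{prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed shorthand lipid name.

    ``chains`` is empty at species (sum-composition) level, where only
    ``total_carbons``/``total_double_bonds`` are known.
    """

    raw_name: str
    lipid_class: str
    chains: tuple[Chain, ...]
    level: str  # SPECIES or MOLECULAR_SPECIES
    known_positions: bool = False  # '/' separator (sn positions known)
    deuterium: Optional[int] = None  # e.g. 31 for "d31-LPC 16:0"
    _sum_composition: Optional[tuple[int, int]] = None

    @property
    def total_carbons(self) -> int:
        if self.level == MOLECULAR_SPECIES:
            return sum(c.carbons for c in self.chains)
        return self._sum_composition[0]

    @property
    def total_double_bonds(self) -> int:
        if self.level == MOLECULAR_SPECIES:
            return sum(c.double_bonds for c in self.chains)
        return self._sum_composition[1]

    @property
    def subclass_key(self) -> str:
        """Class key including ether/plasmalogen subclass, e.g. ``PC O-``.

        Used to match features to class-specific internal standards and to
        build enrichment class sets (ether species count as their own
        subclass, as they are chemically distinct).
        """
        for c in self.chains:
            if c.bond_prefix == "O-":
                return f"{self.lipid_class} O-"
            if c.bond_prefix == "P-":
                return f"{self.lipid_class} P-"
        return self.lipid_class

    @property
    def is_labeled_standard(self) -> bool:
        return self.deuterium is not None


_LABEL_RE = re.compile(r"^d(\d+)-")
_CHAIN_RE = re.compile(r"^(O-|P-|d)?(\d+):(\d+)$")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepts ``CE 20:4``, ``TG 16:0_18:1_20:4``, ``PE P-16:0/22:6``,
    ``SM d18:1/16:0``, sum compositions such as ``TG 52:3``, the
    parenthesised variant ``PE (18:0/18:0)``, and deuterated-standard
    labels such as ``d31-LPC 16:0``.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name", name)
    raw = name
    work = name.strip()
    offset = len(name) - len(name.lstrip())

    deuterium = None
    m = _LABEL_RE.match(work)
    if m:
        deuterium = int(m.group(1))
        offset += m.end()
        work = work[m.end():]

    # class token: longest known class name at the start
    cls = None
    for cand in sorted(CLASS_CHAIN_COUNT, key=len, reverse=True):
        if work == cand or work.startswith(cand + " ") or work.startswith(cand + "("):
            cls = cand
            break
    if cls is None:
        raise LipidParseError("unknown lipid class token", raw, offset)
    rest = work[len(cls):].strip()
    offset += len(cls) + 1
    if rest.startswith("(") and rest.endswith(")"):
        rest = rest[1:-1].strip()
        offset += 1
    if not rest:
        raise LipidParseError("missing chain descriptor", raw, offset)

    known_positions = "/" in rest and "_" not in rest
    tokens = re.split(r"[_/]", rest)
    chains = []
    pos = offset
    for tok in tokens:
        cm = _CHAIN_RE.match(tok.strip())
        if not cm:
            raise LipidParseError(f"malformed chain {tok!r}", raw, pos)
        prefix, carbons, dbs = cm.group(1), int(cm.group(2)), int(cm.group(3))
        if carbons <= 0:
            raise LipidParseError(f"chain carbons must be positive in {tok!r}", raw, pos)
        chains.append(Chain(carbons, dbs, prefix))
        pos += len(tok) + 1

    expected = CLASS_CHAIN_COUNT[cls]
    if len(chains) == expected:
        return LipidSpecies(raw, cls, tuple(chains), MOLECULAR_SPECIES,
                            known_positions=known_positions, deuterium=deuterium)
    if len(chains) == 1 and expected > 1:
        ch = chains[0]
        if ch.bond_prefix in ("O-", "P-"):
            # sum composition of an ether subclass, e.g. "PC O-34:2"
            return LipidSpecies(raw, cls, (ch,), SPECIES, deuterium=deuterium,
                                _sum_composition=(ch.carbons, ch.double_bonds))
        return LipidSpecies(raw, cls, (), SPECIES, deuterium=deuterium,
                            _sum_composition=(ch.carbons, ch.double_bonds))
    raise LipidParseError(
        f"{cls} expects {expected} chains (or 1 for sum composition), got {len(chains)}",
        raw, offset)


def _chain_sort_key(c: Chain):
    # bond-prefixed (ether/sphingoid) chain conventionally written first
    return (c.bond_prefix is None, c.carbons, c.double_bonds)


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand text; ``parse(format(s))`` equals ``s`` up to raw_name."""
    label = f"d{species.deuterium}-" if species.deuterium is not None else ""
    if species.level == SPECIES:
        if species.chains:  # ether sum composition keeps its prefix
            body = str(species.chains[0])
        else:
            body = f"{species.total_carbons}:{species.total_double_bonds}"
        return f"{label}{species.lipid_class} {body}"
    if species.known_positions:
        chains = species.chains
        sep = "/"
    else:
        chains = tuple(sorted(species.chains, key=_chain_sort_key))
        sep = "_"
    return f"{label}{species.lipid_class} " + sep.join(str(c) for c in chains)


# ---------------------------------------------------------------------------
# omega classes

SATURATED_OTHER = "saturated/other"


@dataclass
class OmegaLookup:
    """Map (carbons, double_bonds) -> omega class of the most abundant isomer."""

    table: dict[tuple[int, int], str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "OmegaLookup":
        with resources.files("plasmaome.data").joinpath("omega_lookup.csv").open() as fh:
            return cls._from_rows(csv.DictReader(fh))

    @classmethod
    def from_csv(cls, path: str | Path) -> "OmegaLookup":
        with open(path, newline="") as fh:
            return cls._from_rows(csv.DictReader(fh))

    @classmethod
    def _from_rows(cls, rows: Iterable[dict]) -> "OmegaLookup":
        table = {}
        for row in rows:
            table[(int(row["carbons"]), int(row["double_bonds"]))] = row["omega_class"]
        return cls(table)

    def assign(self, chain: Chain | tuple[int, int], strict: bool = False) -> str:
        if isinstance(chain, Chain):
            key = (chain.carbons, chain.double_bonds)
        else:
            key = (int(chain[0]), int(chain[1]))
        if key in self.table:
            return self.table[key]
        if key[1] == 0:
            return SATURATED_OTHER
        if strict:
            raise KeyError(f"no omega-class entry for acyl {key[0]}:{key[1]}")
        return SATURATED_OTHER


def assign_omega(chain: Chain | tuple[int, int], lookup: OmegaLookup | None = None,
                 strict: bool = False) -> str:
    """Omega class of an acyl; defaults to the shipped lookup table."""
    if lookup is None:
        lookup = OmegaLookup.default()
    return lookup.assign(chain, strict=strict)
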