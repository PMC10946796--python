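"""LIPID MAPS-style shorthand notation parser.

Lipid names follow ``HeadGroup(Sn1/Sn2)`` with each acyl group written
``carbons:double_bonds`` — e.g. ``PC (18:0/18:3)`` is a phosphatidylcholine
with a saturated 18-carbon sn-1 chain and a tri-unsaturated 18-carbon sn-2
chain. When chain positions are unresolved the totals-only shorthand
``PC (36:3)`` is used. Also handled: ether lipids (``O-`` plasmanyl,
``P-`` plasmenyl), sphingoid bases (``SM (d34:1)``), lyso species (one
``0:0`` chain or an ``L`` headgroup) and per-chain deuterium labels
(``PC (15:0/18:1(d7))``). Whitespace around the parentheses is tolerated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class LipidParseError(ValueError):
    """Malformed shorthand name; carries the character position."""

    def __init__(self, message: str, name: str, position: int):
        super().__init__(f"{message} in {name!r} at position {position}")
        self.name = name
        self.position = position


@dataclass(frozen=True)
class AcylChain:
    carbons: int
    double_bonds: int
    ether: bool = False       # O- plasmanyl (alkyl) linkage
    plasmenyl: bool = False   # P- vinyl-ether linkage
    sphingoid: bool = False   # d-prefixed long-chain base
    deuterium: int = 0


@dataclass(frozen=True)
class ParsedLipid:
    name: str
    headgroup: str
    chains: tuple[AcylChain, ...]   # empty for totals-only shorthand
    total_carbons: int
    total_double_bonds: int
    totals_only: bool
    lyso: bool
    ether: bool
    plasmenyl: bool
    sphingoid: bool
    deuterium: int
    flags: tuple[str, ...] = field(default=())

    @property
    def odd_chain(self) -> bool:
        return self.total_carbons % 2 == 1


_NAME = re.compile(r"^\s*([A-Za-z][A-Za-z0-9]*)\s*\(\s*(.*?)\s*\)\s*$", re.S)
_CHAIN = re.compile(
    r"^(?P<link>[OP]-)?(?P<sphingo>[dt])?(?P<c>\d+):(?P<db>\d+)"
    r"(?:\s*\(\s*d(?P<deut>\d+)\s*\))?$"
)


def _parse_chain(text: str, name: str, offset: int) -> AcylChain:
    m = _CHAIN.match(text.strip())
    if m is None:
        raise LipidParseError(f"malformed acyl group {text.strip()!r}", name, offset)
    return AcylChain(
        carbons=int(m.group("c")),
        double_bonds=int(m.group("db")),
        ether=m.group("link") == "O-",
        plasmenyl=m.group("link") == "P-",
        sphingoid=m.group("sphingo") is not None,
        deuterium=int(m.group("deut") or 0),
    )


def parse_shorthand(name: str) -> ParsedLipid:
    """Parse a shorthand lipid name into headgroup, chains and totals.

    Raises :class:`LipidParseError` with the offending position on
    malformed input.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name", name, 0)
    m = _NAME.match(name)
    if m is None:
        raise LipidParseError("expected 'HeadGroup(chains)'", name, 0)
    headgroup, body = m.group(1), m.group(2)
    if not body:
        raise LipidParseError("empty chain specification", name, m.start(2))

    # chains separated by '/' (sn-resolved) or '_' (unresolved pairing)
    chains = tuple(
        _parse_chain(part, name, m.start(2))
        for part in re.split(r"[/_]", body)
    )
    total_c = sum(ch.carbons for ch in chains)
    total_db = sum(ch.double_bonds for ch in chains)
    totals_only = len(chains) == 1 and headgroup not in ("FA",) and not chains[0].sphingoid
    # a single d-prefixed chain (e.g. SM (d34:1)) is also a totals shorthand
    if len(chains) == 1 and chains[0].sphingoid:
        totals_only = True

    lyso = headgroup.startswith("L") or any(
        ch.carbons == 0 and ch.double_bonds == 0 for ch in chains
    )
    parsed = ParsedLipid(
        name=name,
        headgroup=headgroup,
        chains=() if totals_only else chains,
        total_carbons=total_c,
        total_double_bonds=total_db,
        totals_only=totals_only,
        lyso=lyso,
        ether=any(ch.ether for ch in chains),
        plasmenyl=any(ch.plasmenyl for ch in chains),
        sphingoid=any(ch.sphingoid for ch in chains),
        deuterium=sum(ch.deuterium for ch in chains),
    )
    return parsed
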