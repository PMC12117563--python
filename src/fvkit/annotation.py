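"""Antibody variable-domain detection, Martin-scheme renumbering and CDRs.

Numbering itself is delegated to a pluggable :class:`NumberingEngine`:
production use plugs in an adapter over ANARCI-style tabular output, while
tests and fixtures use the deterministic :class:`TableNumberingEngine`.
The module then maps engine results onto structure chains, trims constant
regions, and extracts complementarity-determining regions (CDRs).

Martin positions are ``(number, insertion_letter)`` pairs; insertion
letters order lexically within a number ('' < 'A' < 'B' ...), which is the
convention ANARCI emits for the Martin/Chothia family of schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from .model import Chain, Residue, ResidueId, StructureModel

__all__ = [
    "MartinPosition",
    "CdrDefinition",
    "KABAT_STYLE_CDRS",
    "DomainHit",
    "NumberingEngine",
    "TableNumberingEngine",
    "parse_anarci_table",
    "NumberedDomain",
    "detect_domains",
    "classify_format",
    "renumber_to_martin",
    "cdr_residues",
    "NumberingInconsistency",
]

log = logging.getLogger(__name__)

#: Martin position: (number, insertion letter or "").
MartinPosition = tuple[int, str]


class NumberingInconsistency(ValueError):
    """Engine numbering refers to residues absent from the chain."""


@dataclass(frozen=True)
class CdrDefinition:
    """CDR intervals as closed Martin-number ranges per domain type.

    The default follows Kabat-style loop definitions on Martin numbering
    (L1 24-34, L2 50-56, L3 89-97; H1 31-35, H2 50-65, H3 95-102); a
    position belongs to a CDR when its number falls in the interval,
    insertion letters included.
    """

    vh: tuple[tuple[int, int], ...] = ((31, 35), (50, 65), (95, 102))
    vl: tuple[tuple[int, int], ...] = ((24, 34), (50, 56), (89, 97))

    def spans(self, domain_type: str) -> tuple[tuple[int, int], ...]:
        if domain_type == "VH":
            return self.vh
        if domain_type == "VL":
            return self.vl
        raise ValueError(f"unknown domain type {domain_type!r}")

    def cdr_index(self, domain_type: str, pos: MartinPosition) -> Optional[int]:
        """0-based CDR index containing ``pos``, or None (framework)."""
        for i, (lo, hi) in enumerate(self.spans(domain_type)):
            if lo <= pos[0] <= hi:
                return i
        return None


KABAT_STYLE_CDRS = CdrDefinition()


@dataclass(frozen=True)
class DomainHit:
    """One engine result: a variable domain found within a sequence.

    ``start`` indexes the first numbered residue in the query sequence;
    ``positions`` gives the Martin position of each consecutive residue
    from there.
    """

    domain_type: str            # "VH" | "VL"
    start: int
    positions: tuple[MartinPosition, ...]

    def __post_init__(self) -> None:
        if self.domain_type not in ("VH", "VL"):
            raise ValueError(f"domain_type must be VH or VL, got {self.domain_type!r}")
        if list(self.positions) != sorted(self.positions):
            raise ValueError("engine numbering must be monotone in sequence order")

    @property
    def end(self) -> int:
        return self.start + len(self.positions)


class NumberingEngine(Protocol):
    """Contract for antibody numbering backends."""

    def number(self, sequence: str) -> list[DomainHit]:
        """Return every VH/VL domain found in ``sequence`` (may be empty)."""
        ...


class TableNumberingEngine:
    """Deterministic engine backed by a table of known domain sequences.

    Each registered entry maps an exact domain subsequence to its
    domain type and Martin positions; :meth:`number` reports every
    non-overlapping occurrence of a registered subsequence in the query,
    in order of appearance.  This is the backend used by the synthetic
    fixtures, decoupling tests from any external numbering binary.
    """

    def __init__(self) -> None:
        self._table: dict[str, tuple[str, tuple[MartinPosition, ...]]] = {}

    def register(self, sequence: str, domain_type: str,
                 positions: Sequence[MartinPosition]) -> None:
        if len(sequence) != len(positions):
            raise ValueError("sequence and positions lengths differ")
        self._table[sequence] = (domain_type, tuple((int(n), str(i)) for n, i in positions))

    def number(self, sequence: str) -> list[DomainHit]:
        hits: list[DomainHit] = []
        # longest registered sequences first so a fragment never shadows
        # the full domain it is contained in
        for domseq in sorted(self._table, key=len, reverse=True):
            dtype, positions = self._table[domseq]
            start = 0
            while True:
                idx = sequence.find(domseq, start)
                if idx < 0:
                    break
                if not any(idx < h.end and h.start < idx + len(domseq) for h in hits):
                    hits.append(DomainHit(dtype, idx, positions))
                start = idx + 1
        hits.sort(key=lambda h: h.start)
        return hits


def parse_anarci_table(text: str) -> tuple[str, tuple[MartinPosition, str]]:
    """Parse ANARCI-style tabular numbering lines.

    Lines look like ``H 92   C`` (chain type, position with optional
    insertion letter, one-letter residue); '-' residues (gaps) are skipped.
    Returns (domain_type, ((number, ins), aa) pairs) suitable for
    registering with :class:`TableNumberingEngine`.
    """
    dtype = None
    numbered: list[tuple[MartinPosition, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "//")):
            continue
        parts = line.split()
        if len(parts) < 3:
            continue
        ctype, pos, aa = parts[0], parts[1], parts[-1]
        if aa == "-":
            continue
        dt = {"H": "VH", "K": "VL", "L": "VL"}.get(ctype.upper())
        if dt is None:
            continue
        if dtype is None:
            dtype = dt
        elif dt != dtype:
            raise ValueError("mixed chain types in one numbering table")
        if pos[-1].isalpha():
            num, ins = int(pos[:-1]), pos[-1].upper()
        else:
            num, ins = int(pos), ""
        numbered.append(((num, ins), aa.upper()))
    if dtype is None or not numbered:
        raise ValueError("no numbered residues found")
    return dtype, tuple(numbered)


@dataclass
class NumberedDomain:
    """A VH or VL region of one chain with its Martin-number mapping.

    ``number_map`` is an ordered, injective mapping from original residue
    ids to Martin positions; ``cdr_spans`` holds the three CDR intervals
    in force for this domain.
    """

    chain_id: str
    domain_type: str
    number_map: dict[ResidueId, MartinPosition]
    cdr_spans: tuple[tuple[int, int], ...]
    cdrs: CdrDefinition = field(default=KABAT_STYLE_CDRS, repr=False)

    def __post_init__(self) -> None:
        if len(self.cdr_spans) != 3:
            raise ValueError("a variable domain has exactly 3 CDRs")
        vals = list(self.number_map.values())
        if len(set(vals)) != len(vals):
            raise ValueError("number_map must be injective")
        if vals != sorted(vals):
            raise ValueError("number_map must be order-preserving")

    def martin_of(self, rid: ResidueId) -> Optional[MartinPosition]:
        return self.number_map.get(rid)

    def original_of(self, pos: MartinPosition) -> Optional[ResidueId]:
        for rid, p in self.number_map.items():
            if p == pos:
                return rid
        return None

    def cdr_positions(self) -> list[MartinPosition]:
        return [p for p in self.number_map.values()
                if any(lo <= p[0] <= hi for lo, hi in self.cdr_spans)]


def detect_domains(model: StructureModel, engine: NumberingEngine,
                   cdrs: CdrDefinition = KABAT_STYLE_CDRS) -> list[NumberedDomain]:
    """Run the numbering engine over every chain and map hits to residues.

    A chain yielding one VH and one VL hit is an scFv candidate; chains
    with no hit are antigen candidates.  Engine failures on a chain are
    logged and the chain skipped.
    """
    domains: list[NumberedDomain] = []
    for chain in model.chains:
        seq = chain.sequence()
        try:
            hits = engine.number(seq)
        except Exception as exc:  # engine is third-party code
            log.warning("numbering engine failed on chain %s: %s",
                        chain.chain_id, exc)
            continue
        for hit in hits:
            if hit.end > len(chain.residues):
                log.warning("chain %s: hit extends past chain end, skipped",
                            chain.chain_id)
                continue
            nmap = {
                chain.residues[hit.start + i].rid: pos
                for i, pos in enumerate(hit.positions)
            }
            domains.append(NumberedDomain(
                chain.chain_id, hit.domain_type, nmap,
                cdrs.spans(hit.domain_type), cdrs))
    return domains


def classify_format(domains_by_chain: dict[str, list[NumberedDomain]]) -> str:
    """Classify an antibody unit's format from its per-chain domain lists.

    Returns one of ``paired``, ``heavy_only``, ``light_only``, ``scfv`` or
    ``unusual``.  A chain carrying two domains of the same type (e.g. a
    dual-variable-domain construct) makes the unit ``unusual``; unusual
    units are excluded from pipeline output.  The result is invariant
    under chain-order permutation.
    """
    has_vh_chain = has_vl_chain = False
    scfv = False
    for domains in domains_by_chain.values():
        types = sorted(d.domain_type for d in domains)
        if len(types) > 2:
            return "unusual"
        if len(types) == 2:
            if types[0] == types[1]:
                return "unusual"
            scfv = True
        elif types == ["VH"]:
            has_vh_chain = True
        elif types == ["VL"]:
            has_vl_chain = True
    if scfv:
        if has_vh_chain or has_vl_chain:
            return "unusual"
        return "scfv"
    if has_vh_chain and has_vl_chain:
        return "paired"
    if has_vh_chain:
        return "heavy_only"
    if has_vl_chain:
        return "light_only"
    return "unusual"


def renumber_to_martin(chain: Chain, domain: NumberedDomain) -> Chain:
    """Return the variable region of ``chain`` renumbered to Martin positions.

    Residues outside ``domain.number_map`` (constant regions, scFv linkers)
    are trimmed; the rest carry their Martin number and insertion letter.
    """
    out: list[Residue] = []
    seen = 0
    for res in chain:
        pos = domain.number_map.get(res.rid)
        if pos is None:
            continue
        seen += 1
        num, ins = pos
        out.append(Residue(res.res_name, num, ins,
                           [a.copy() for a in res.atoms]))
    if seen != len(domain.number_map):
        missing = set(domain.number_map) - {r.rid for r in chain}
        raise NumberingInconsistency(
            f"chain {chain.chain_id}: number_map references absent residues "
            f"{sorted(missing)}")
    return Chain(chain.chain_id, out)


def cdr_residues(domain: NumberedDomain, chain: Chain) -> list[Residue]:
    """Residues of a Martin-renumbered chain lying in any CDR span."""
    out = []
    for res in chain:
        if any(lo <= res.seq_number <= hi for lo, hi in domain.cdr_spans):
            out.append(res)
    return out
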