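"""Integrin subunit vocabulary and the canonical heterodimer pairing table.

Integrins are adhesion receptors assembled from one alpha and one beta
subunit.  In humans, 18 alpha and 8 beta subunit genes combine into exactly
24 permitted alpha-beta heterodimers; the pairing repertoire is fixed and
well established (beta1 pairs 12 alphas, beta2 pairs 4, beta3 pairs 2,
beta4/beta5/beta6/beta8 pair 1 each, beta7 pairs 2).  Co-expression of two
complementary subunit genes in a single cell is read here as a *potential*
heterodimer: no activation state, ligand binding or protein-level assembly
is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import FrozenSet, Iterable, Set, Tuple

__all__ = [
    "SubunitGene",
    "PairingTable",
    "HeterodimerCall",
    "ALPHA_GENES",
    "BETA_GENES",
    "SUBUNIT_SHORT_NAMES",
    "normalize_symbol",
    "build_pairing_table",
    "infer_heterodimers",
    "load_pairing_table",
    "save_pairing_table",
]


class UnknownSubunitError(ValueError):
    """Raised when a gene symbol is not a recognised integrin subunit gene."""


#: Conventional short names for every human integrin subunit gene.
#: ITGA2B is the platelet subunit alpha-IIb, written "a2b" here because gene
#: symbols in expression matrices frequently appear as ITGA2b.
SUBUNIT_SHORT_NAMES = {
    # alpha chain
    "ITGA1": "a1", "ITGA2": "a2", "ITGA2B": "a2b", "ITGA3": "a3",
    "ITGA4": "a4", "ITGA5": "a5", "ITGA6": "a6", "ITGA7": "a7",
    "ITGA8": "a8", "ITGA9": "a9", "ITGA10": "a10", "ITGA11": "a11",
    "ITGAD": "aD", "ITGAE": "aE", "ITGAL": "aL", "ITGAM": "aM",
    "ITGAV": "aV", "ITGAX": "aX",
    # beta chain
    "ITGB1": "b1", "ITGB2": "b2", "ITGB3": "b3", "ITGB4": "b4",
    "ITGB5": "b5", "ITGB6": "b6", "ITGB7": "b7", "ITGB8": "b8",
}

ALPHA_GENES: FrozenSet[str] = frozenset(
    g for g in SUBUNIT_SHORT_NAMES if g.startswith("ITGA")
)
BETA_GENES: FrozenSet[str] = frozenset(
    g for g in SUBUNIT_SHORT_NAMES if g.startswith("ITGB")
)

# Canonical alpha partners per beta subunit; 24 pairs in total.
_BETA_PARTNERS = {
    "ITGB1": ("ITGA1", "ITGA2", "ITGA3", "ITGA4", "ITGA5", "ITGA6",
              "ITGA7", "ITGA8", "ITGA9", "ITGA10", "ITGA11", "ITGAV"),
    "ITGB2": ("ITGAL", "ITGAM", "ITGAX", "ITGAD"),
    "ITGB3": ("ITGA2B", "ITGAV"),
    "ITGB4": ("ITGA6",),
    "ITGB5": ("ITGAV",),
    "ITGB6": ("ITGAV",),
    "ITGB7": ("ITGA4", "ITGAE"),
    "ITGB8": ("ITGAV",),
}


@dataclass(frozen=True)
class SubunitGene:
    """A single integrin subunit gene.

    Attributes
    ----------
    symbol : HGNC-style gene symbol, e.g. ``ITGA6`` or ``ITGB4``.
    chain : ``"alpha"`` or ``"beta"``, derived from the symbol.
    short_name : conventional subunit name (``a6``, ``b4``, ``a2b`` ...).
    """

    symbol: str
    chain: str = field(init=False)
    short_name: str = field(init=False)

    def __post_init__(self) -> None:
        symbol = normalize_symbol(self.symbol)
        object.__setattr__(self, "symbol", symbol)
        object.__setattr__(
            self, "chain", "alpha" if symbol in ALPHA_GENES else "beta"
        )
        object.__setattr__(self, "short_name", SUBUNIT_SHORT_NAMES[symbol])


def normalize_symbol(symbol: str) -> str:
    """Normalise an integrin gene symbol (case-insensitive, ``ITGA2b`` -> ``ITGA2B``).

    Raises
    ------
    UnknownSubunitError
        If the symbol is not one of the 26 integrin subunit genes.
    """
    candidate = symbol.strip().upper()
    if candidate not in SUBUNIT_SHORT_NAMES:
        raise UnknownSubunitError(
            f"{symbol!r} is not a recognised integrin subunit gene"
        )
    return candidate


def is_subunit_gene(symbol: str) -> bool:
    """True if ``symbol`` names an integrin subunit gene (case-insensitive)."""
    return symbol.strip().upper() in SUBUNIT_SHORT_NAMES


@dataclass(frozen=True)
class PairingTable:
    """The permitted alpha-beta heterodimer repertoire.

    ``pairs`` holds ``(alpha_symbol, beta_symbol)`` tuples; the canonical
    human table has exactly 24 entries.
    """

    pairs: FrozenSet[Tuple[str, str]]

    def __post_init__(self) -> None:
        for alpha, beta in self.pairs:
            if alpha not in ALPHA_GENES or beta not in BETA_GENES:
                raise ValueError(
                    f"invalid pair ({alpha}, {beta}): members must be one "
                    "alpha and one beta subunit gene"
                )

    def partners_of(self, symbol: str) -> Set[str]:
        """All permitted partners of one subunit gene."""
        symbol = normalize_symbol(symbol)
        out = set()
        for alpha, beta in self.pairs:
            if alpha == symbol:
                out.add(beta)
            elif beta == symbol:
                out.add(alpha)
        return out

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def build_pairing_table() -> PairingTable:
    """Return the canonical 24-pair human integrin pairing table.

    Stable across calls; per-beta alpha partner counts are
    b1:12, b2:4, b3:2, b4:1, b5:1, b6:1, b7:2, b8:1.
    """
    pairs = frozenset(
        (alpha, beta)
        for beta, alphas in _BETA_PARTNERS.items()
        for alpha in alphas
    )
    return PairingTable(pairs=pairs)


@dataclass(frozen=True)
class HeterodimerCall:
    """Per-cell inference result.

    ``dimers`` is the set of permitted (alpha, beta) pairs whose two genes
    are both expressed; ``unpaired`` the expressed subunit genes taking part
    in no inferred dimer.  One subunit may appear in several dimers (ITGB1
    with several alpha partners, ITGAV with several betas).
    """

    dimers: FrozenSet[Tuple[str, str]]
    unpaired: FrozenSet[str]

    @property
    def n_dimers(self) -> int:
        return len(self.dimers)

    @property
    def expressed(self) -> FrozenSet[str]:
        members = {g for pair in self.dimers for g in pair}
        return frozenset(members | self.unpaired)

    def dimer_names(self) -> list[str]:
        """Conventional names, e.g. ``['a6b1', 'a6b4']``, sorted."""
        return sorted(
            SUBUNIT_SHORT_NAMES[a] + SUBUNIT_SHORT_NAMES[b]
            for a, b in self.dimers
        )


def infer_heterodimers(
    expressed: Iterable[str], table: PairingTable | None = None
) -> HeterodimerCall:
    """Infer a cell's potential heterodimers from its expressed subunit genes.

    Parameters
    ----------
    expressed : iterable of integrin subunit gene symbols (any case).
    table : pairing table; the canonical 24-pair table by default.

    Returns
    -------
    HeterodimerCall with every permitted pair whose two members are both in
    ``expressed``, plus the expressed genes left in no pair.

    Raises
    ------
    UnknownSubunitError
        On any symbol that is not an integrin subunit gene; the offending
        symbol is named in the message.
    """
    if table is None:
        table = build_pairing_table()
    genes = {normalize_symbol(s) for s in expressed}
    dimers = frozenset(
        (a, b) for a, b in table.pairs if a in genes and b in genes
    )
    in_dimer = {g for pair in dimers for g in pair}
    return HeterodimerCall(dimers=dimers, unpaired=frozenset(genes - in_dimer))


def save_pairing_table(table: PairingTable, path: str | Path) -> None:
    """Write a pairing table as two-column TSV (alpha, beta), sorted."""
    lines = ["alpha\tbeta"]
    lines += [f"{a}\t{b}" for a, b in sorted(table.pairs)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_pairing_table(path: str | Path | None = None) -> PairingTable:
    """Read a pairing table from two-column TSV.

    With no path, loads the table bundled as package data (identical to
    :func:`build_pairing_table`).
    """
    if path is None:
        ref = resources.files("ctcintegrins").joinpath("data/integrin_pairs.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    pairs = set()
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or (i == 0 and line.lower().startswith("alpha")):
            continue
        alpha, beta = line.split("\t")
        pairs.add((normalize_symbol(alpha), normalize_symbol(beta)))
    return PairingTable(pairs=frozenset(pairs))
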