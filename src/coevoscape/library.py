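"""Library schemes, degenerate-codon expansion and selection count tables.

A library-on-library selection randomizes a fixed set of surface positions on
two protein chains (here called A and B) with a restricted amino-acid alphabet
encoded by a degenerate codon.  This module defines the scheme describing that
layout, expands degenerate codons into their DNA and protein alphabets,
computes theoretical library diversities, and reads/writes the per-round
paired-sequence read-count tables that every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
import yaml
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "LibraryScheme",
    "LibrarySequence",
    "SelectionDataset",
    "CodonExpansion",
    "expand_degenerate_codon",
    "theoretical_diversity",
    "default_scheme",
    "load_counts",
    "write_counts",
    "load_scheme",
    "write_scheme",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]


class CodonExpansion(NamedTuple):
    """Expansion of a degenerate codon into DNA codons and amino acids."""

    codons: frozenset
    amino_acids: frozenset
    stop_codons: frozenset
    codon_count: int
    aa_count: int


def expand_degenerate_codon(code: str) -> CodonExpansion:
    """Expand a 3-letter IUPAC degenerate codon.

    Returns the set of concrete DNA codons (Cartesian product of the symbol
    expansions), the amino acids they encode under the standard genetic code,
    and any stop codons (reported separately, never silently dropped).

    >>> expand_degenerate_codon("DTS").aa_count
    5
    """
    code = code.upper()
    if len(code) != 3:
        raise ValueError(f"degenerate codon must have 3 symbols, got {code!r}")
    expansions = []
    for symbol in code:
        bases = ambiguous_dna_values.get(symbol)
        if bases is None or symbol not in "ACGTUWSMKRYBDHVN":
            raise ValueError(f"invalid IUPAC nucleotide symbol {symbol!r} in {code!r}")
        expansions.append(bases.replace("U", "T"))
    codons = frozenset(
        a + b + c for a in expansions[0] for b in expansions[1] for c in expansions[2]
    )
    stops = frozenset(c for c in codons if c in _STANDARD_TABLE.stop_codons)
    aas = frozenset(_STANDARD_TABLE.forward_table[c] for c in codons - stops)
    return CodonExpansion(codons, aas, stops, len(codons), len(aas))


@dataclass(frozen=True)
class LibraryScheme:
    """Randomized-position layout of a two-chain library.

    Positions use the structure's 1-based residue numbering; the concatenated
    sequence order is chain A positions ascending followed by chain B
    positions ascending.
    """

    chain_a_positions: tuple
    chain_b_positions: tuple
    degenerate_codon: str = "DTS"
    alphabet: tuple = ()

    def __post_init__(self):
        a = tuple(sorted(self.chain_a_positions))
        b = tuple(sorted(self.chain_b_positions))
        object.__setattr__(self, "chain_a_positions", a)
        object.__setattr__(self, "chain_b_positions", b)
        if not a or not b:
            raise ValueError("both chains need at least one randomized position")
        if set(a) & set(b):
            raise ValueError("chain A and chain B position lists must be disjoint")
        if not self.alphabet:
            exp = expand_degenerate_codon(self.degenerate_codon)
            object.__setattr__(self, "alphabet", tuple(sorted(exp.amino_acids)))
        else:
            object.__setattr__(self, "alphabet", tuple(sorted(set(self.alphabet))))

    @property
    def total_positions(self) -> int:
        return len(self.chain_a_positions) + len(self.chain_b_positions)

    @property
    def positions(self) -> tuple:
        """Concatenated position labels, chain A then chain B."""
        return self.chain_a_positions + self.chain_b_positions

    @property
    def n_letters(self) -> int:
        return len(self.alphabet)

    def chain_of_index(self, i: int) -> str:
        """Chain ('A' or 'B') owning concatenated-sequence index ``i``."""
        if not 0 <= i < self.total_positions:
            raise IndexError(f"position index {i} out of range")
        return "A" if i < len(self.chain_a_positions) else "B"

    def validate(self, chain_a: str, chain_b: str) -> None:
        if len(chain_a) != len(self.chain_a_positions):
            raise ValueError(
                f"chain A sequence {chain_a!r} has length {len(chain_a)}, "
                f"expected {len(self.chain_a_positions)}"
            )
        if len(chain_b) != len(self.chain_b_positions):
            raise ValueError(
                f"chain B sequence {chain_b!r} has length {len(chain_b)}, "
                f"expected {len(self.chain_b_positions)}"
            )
        allowed = set(self.alphabet)
        for seq in (chain_a, chain_b):
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"sequence {seq!r} contains letters {sorted(bad)} outside "
                    f"the scheme alphabet {self.alphabet}"
                )

    def split(self, concatenated: str):
        """Split a concatenated sequence back into (chain_a, chain_b)."""
        na = len(self.chain_a_positions)
        if len(concatenated) != self.total_positions:
            raise ValueError(
                f"sequence length {len(concatenated)} != {self.total_positions}"
            )
        return concatenated[:na], concatenated[na:]


@dataclass(frozen=True)
class LibrarySequence:
    """A validated paired library sequence."""

    chain_a: str
    chain_b: str
    scheme: LibraryScheme

    def __post_init__(self):
        self.scheme.validate(self.chain_a, self.chain_b)

    @property
    def concatenated(self) -> str:
        return self.chain_a + self.chain_b


class Diversity(NamedTuple):
    nucleotide: int
    protein: int


def theoretical_diversity(scheme: LibraryScheme) -> Diversity:
    """Theoretical diversity of the library at the DNA and protein level.

    nucleotide = codon_count ** total_positions,
    protein = aa_count ** total_positions.  The default 11-position DTS
    library gives 6**11 = 362,797,056 DNA variants and 5**11 = 48,828,125
    protein variants.
    """
    exp = expand_degenerate_codon(scheme.degenerate_codon)
    n = scheme.total_positions
    return Diversity(exp.codon_count**n, exp.aa_count**n)


def default_scheme() -> LibraryScheme:
    """The 11-position DTS scheme: A(8,11,14,15,45) x B(29,30,33,43,44,47)."""
    return LibraryScheme(
        chain_a_positions=(8, 11, 14, 15, 45),
        chain_b_positions=(29, 30, 33, 43, 44, 47),
        degenerate_codon="DTS",
    )


@dataclass
class SelectionDataset:
    """Per-round paired-sequence read counts from a multi-round selection.

    ``counts`` maps round label -> {(chain_a, chain_b): read count}; rounds
    are ordered (round 0 is the unselected input pool by convention).
    """

    scheme: LibraryScheme
    rounds: list
    counts: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.counts.keys()) != list(self.rounds):
            self.counts = {r: self.counts[r] for r in self.rounds}
        for r in self.rounds:
            for (a, b), c in self.counts[r].items():
                if c < 0:
                    raise ValueError(f"negative count for {(a, b)} in round {r}")
                self.scheme.validate(a, b)

    @property
    def totals(self) -> dict:
        return {r: sum(self.counts[r].values()) for r in self.rounds}

    @property
    def final_round(self) -> str:
        return self.rounds[-1]

    def sequences(self, round_label=None):
        """Unique (chain_a, chain_b) pairs in one round, or across all rounds."""
        if round_label is not None:
            return sorted(self.counts[round_label])
        seen = set()
        for r in self.rounds:
            seen.update(self.counts[r])
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r, a, b, c)
            for r in self.rounds
            for (a, b), c in sorted(self.counts[r].items())
        ]
        return pd.DataFrame(rows, columns=["round", "chain_a", "chain_b", "count"])


def load_counts(path, scheme: LibraryScheme) -> SelectionDataset:
    """Load a TSV count table (columns round/chain_a/chain_b/count).

    '#' comment lines are ignored; duplicate (round, sequence) rows are
    summed; round order follows first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chain_a": str, "chain_b": str})
    required = {"round", "chain_a", "chain_b", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns {sorted(missing)}")
    rounds = list(dict.fromkeys(df["round"].astype(str)))
    counts = {r: {} for r in rounds}
    cols = zip(df["round"].astype(str), df["chain_a"], df["chain_b"], df["count"])
    for i, (rnd, a, b, c) in enumerate(cols):
        c = int(c)
        if c < 0:
            raise ValueError(f"negative count at row {i} of {path}")
        try:
            scheme.validate(a, b)
        except ValueError as err:
            raise ValueError(f"row {i} of {path}: {err}") from err
        d = counts[rnd]
        d[(a, b)] = d.get((a, b), 0) + c
    return SelectionDataset(scheme=scheme, rounds=rounds, counts=counts)


def write_counts(dataset: SelectionDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def write_scheme(scheme: LibraryScheme, path) -> None:
    doc = {
        "chain_a_positions": list(scheme.chain_a_positions),
        "chain_b_positions": list(scheme.chain_b_positions),
        "degenerate_codon": scheme.degenerate_codon,
        "alphabet": "".join(scheme.alphabet),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scheme(path) -> LibraryScheme:
    doc = yaml.safe_load(Path(path).read_text())
    return LibraryScheme(
        chain_a_positions=tuple(doc["chain_a_positions"]),
        chain_b_positions=tuple(doc["chain_b_positions"]),
        degenerate_codon=doc.get("degenerate_codon", "DTS"),
        alphabet=tuple(doc.get("alphabet", "")),
    )
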