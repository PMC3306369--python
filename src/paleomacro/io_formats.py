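"""Readers and writers for the formats the pipeline touches.

Character data travel as NEXUS ``DATA``/``CHARACTERS`` blocks, trees as
newick, stratigraphic ranges and measurements as delimited tables, and
time bins as a small JSON list.  NEXUS and newick parsing is delegated to
:mod:`dendropy`; this module only converts between dendropy's containers
and the light domain types the analysis stages consume.

Conventions used throughout the package:

* ages are in Ma before present, so a *larger* number is *older*;
* a missing character cell is an empty state-set, distinct from every
  observed state;
* taxon labels are matched across files after trimming and normalising
  internal runs of whitespace/underscores to single spaces.
"""

from __future__ import annotations

import io
import json
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import pandas as pd

__all__ = [
    "CharacterMatrix",
    "TaxonRecord",
    "TimeBin",
    "ParseError",
    "normalize_label",
    "read_character_matrix",
    "write_character_matrix",
    "read_taxon_table",
    "write_taxon_table",
    "read_time_bins",
    "write_time_bins",
    "read_tree",
    "write_tree",
]


class ParseError(ValueError):
    """Raised when an input document cannot be interpreted."""


_WS_RUN = re.compile(r"[\s_]+")


def normalize_label(label: str) -> str:
    """Canonical form of a taxon label for cross-file matching."""
    return _WS_RUN.sub(" ", label.strip())


# ---------------------------------------------------------------------------
# Character matrices
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Taxa × discrete characters with missing and polymorphic cells.

    ``cells[i][j]`` is a frozenset of non-negative integer state codes for
    taxon ``i``, character ``j``; the empty set encodes a missing ("?")
    cell.  ``ordered_flags[j]`` marks additive (ordered) characters; the
    default is all-unordered.
    """

    taxa: list[str]
    cells: list[list[frozenset[int]]]
    ordered_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        n_char = self.n_characters
        for label, row in zip(self.taxa, self.cells):
            if len(row) != n_char:
                raise ValueError(
                    f"taxon {label!r} has {len(row)} cells, expected {n_char}"
                )
        if not self.ordered_flags:
            self.ordered_flags = [False] * n_char

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    @property
    def n_states(self) -> int:
        """Size of the observed state universe (max code + 1)."""
        top = -1
        for row in self.cells:
            for cell in row:
                if cell:
                    top = max(top, max(cell))
        return top + 1

    def row(self, taxon: str) -> list[frozenset[int]]:
        if taxon in self.taxa:
            return self.cells[self.taxa.index(taxon)]
        want = normalize_label(taxon)
        for i, t in enumerate(self.taxa):
            if normalize_label(t) == want:
                return self.cells[i]
        raise KeyError(f"taxon {taxon!r} not in matrix")

    def missing_count(self) -> int:
        return sum(1 for row in self.cells for cell in row if not cell)

    def subset(self, taxa: Sequence[str]) -> "CharacterMatrix":
        rows = [self.row(t) for t in taxa]
        return CharacterMatrix(list(taxa), [list(r) for r in rows],
                               list(self.ordered_flags))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa and self.cells == other.cells
                and self.ordered_flags == other.ordered_flags)


def read_character_matrix(text: str, gap_as_missing: bool = True) -> CharacterMatrix:
    """Parse a NEXUS ``DATA``/``CHARACTERS`` block into a CharacterMatrix.

    "?" maps to the missing cell; "-" (inapplicable) is treated as missing
    by default, or as a distinct extra state when ``gap_as_missing`` is
    False.  Polymorphisms written ``{01}`` or ``(01)`` become multi-element
    state-sets.
    """
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"could not parse NEXUS character matrix: {exc}") from exc

    taxa: list[str] = []
    cells: list[list[frozenset[int]]] = []
    gap_state: int | None = None
    if not gap_as_missing:
        # the gap state is appended to the universe after the digit states
        top = 0
        for vec in dmat.values():
            for st in vec:
                if st.symbol is not None and st.symbol.isdigit():
                    top = max(top, int(st.symbol))
                for ms in (st.member_states or ()):
                    if ms.symbol.isdigit():
                        top = max(top, int(ms.symbol))
        gap_state = top + 1

    for taxon in dmat.taxon_namespace:
        vec = dmat[taxon]
        row: list[frozenset[int]] = []
        for pos, st in enumerate(vec):
            sym = st.symbol
            if sym == "?":
                row.append(frozenset())
            elif sym == "-":
                row.append(frozenset() if gap_as_missing else frozenset({gap_state}))
            elif sym is not None and sym.isdigit():
                row.append(frozenset({int(sym)}))
            elif st.member_states:
                members = {int(ms.symbol) for ms in st.member_states
                           if ms.symbol.isdigit()}
                if not members:
                    raise ParseError(
                        f"uninterpretable cell for taxon {taxon.label!r} "
                        f"at character {pos + 1}"
                    )
                row.append(frozenset(members))
            else:
                raise ParseError(
                    f"uninterpretable symbol {sym!r} for taxon "
                    f"{taxon.label!r} at character {pos + 1}"
                )
        taxa.append(normalize_label(taxon.label))
        cells.append(row)

    return CharacterMatrix(taxa, cells)


def write_character_matrix(matrix: CharacterMatrix) -> str:
    """Serialise a CharacterMatrix as a NEXUS document.

    Missing cells are written "?", polymorphic cells as braced tokens;
    the output round-trips through :func:`read_character_matrix`.
    """
    n_states = max(matrix.n_states, 1)
    symbols = "".join(str(s) for s in range(n_states))
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
    out.write(f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    out.write("MATRIX\n")
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for label, row in zip(matrix.taxa, matrix.cells):
        quoted = f"'{label}'" if re.search(r"[\s(){}\[\];]", label) else label
        toks = []
        for cell in row:
            if not cell:
                toks.append("?")
            elif len(cell) == 1:
                toks.append(str(next(iter(cell))))
            else:
                toks.append("{" + "".join(str(s) for s in sorted(cell)) + "}")
        out.write(f"{quoted:<{width}}{''.join(toks)}\n")
    out.write(";\nEND;\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Taxon tables (stratigraphic ranges + measurements)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRecord:
    """One operational taxon: stratigraphic range plus size measurements.

    ``fad``/``lad`` are first/last appearance ages in Ma (fad >= lad).
    Lengths are in mm; ``None`` marks a measurement that was never taken,
    which is distinct from zero.
    """

    name: str
    fad: float
    lad: float
    trunk_length: float | None = None
    neck_length: float | None = None
    bin_label: str | None = None

    def __post_init__(self) -> None:
        if self.fad < self.lad:
            raise ValueError(
                f"{self.name}: FAD {self.fad} is younger than LAD {self.lad}"
            )
        for attr in ("trunk_length", "neck_length"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive, got {v}")


_REQUIRED_COLUMNS = ("name", "fad", "lad")


def read_taxon_table(text: str) -> list[TaxonRecord]:
    """Read a delimited taxon table (CSV or TSV) into TaxonRecords."""
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str,
                         skipinitialspace=True)
    except Exception as exc:
        raise ParseError(f"could not read taxon table: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"taxon table missing required column {col!r}")

    def num(row, col):
        if col not in df.columns:
            return None
        raw = row[col]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        raw = str(raw).strip()
        if not raw:
            return None
        try:
            return float(raw)
        except ValueError as exc:
            raise ParseError(
                f"non-numeric value {raw!r} in column {col!r}"
            ) from exc

    records = []
    for _, row in df.iterrows():
        bin_label = None
        if "bin_label" in df.columns:
            raw = row["bin_label"]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                raw = str(raw).strip()
                bin_label = raw or None
        fad, lad = num(row, "fad"), num(row, "lad")
        if fad is None or lad is None:
            raise ParseError(f"taxon {row['name']!r} lacks a numeric age")
        records.append(TaxonRecord(
            name=normalize_label(str(row["name"])),
            fad=fad,
            lad=lad,
            trunk_length=num(row, "trunk_length"),
            neck_length=num(row, "neck_length"),
            bin_label=bin_label,
        ))
    return records


def write_taxon_table(records: Sequence[TaxonRecord]) -> str:
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "fad": r.fad,
                "lad": r.lad,
                "trunk_length": r.trunk_length,
                "neck_length": r.neck_length,
                "bin_label": r.bin_label,
            }
            for r in records
        ],
        columns=["name", "fad", "lad", "trunk_length", "neck_length", "bin_label"],
    )
    return df.to_csv(index=False)


# ---------------------------------------------------------------------------
# Time bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeBin:
    """A stratigraphic interval, closed at the older bound."""

    label: str
    older_bound: float
    younger_bound: float

    def __post_init__(self) -> None:
        if self.older_bound <= self.younger_bound:
            raise ValueError(
                f"bin {self.label!r}: older bound {self.older_bound} must "
                f"exceed younger bound {self.younger_bound}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older_bound + self.younger_bound)


def _check_disjoint(bins: Sequence[TimeBin]) -> None:
    ordered = sorted(bins, key=lambda b: -b.older_bound)
    for a, b in zip(ordered, ordered[1:]):
        if b.older_bound > a.younger_bound:
            raise ValueError(f"bins {a.label!r} and {b.label!r} overlap")


def read_time_bins(text: str) -> list[TimeBin]:
    """Read a JSON list of {"label", "older_bound", "younger_bound"}."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid time-bin JSON: {exc}") from exc
    bins = [TimeBin(d["label"], float(d["older_bound"]),
                    float(d["younger_bound"])) for d in raw]
    _check_disjoint(bins)
    return bins


def write_time_bins(bins: Sequence[TimeBin]) -> str:
    return json.dumps(
        [
            {"label": b.label, "older_bound": b.older_bound,
             "younger_bound": b.younger_bound}
            for b in bins
        ],
        indent=2,
    )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(text: str) -> dendropy.Tree:
    """Parse a newick tree; labels are normalised for cross-file matching."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=False)
    except Exception as exc:
        raise ParseError(f"could not parse newick tree: {exc}") from exc
    for taxon in tree.taxon_namespace:
        taxon.label = normalize_label(taxon.label)
    return tree


def write_tree(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
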