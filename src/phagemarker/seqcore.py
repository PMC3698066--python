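"""Sequence records, alphabets and IUPAC degeneracy.

Foundations for the marker-gene toolkit: a light sequence record with a
declared alphabet (nucleotide or amino acid), FASTA and label-table I/O,
reverse complement, translation, and IUPAC-aware base matching used by the
degenerate-primer machinery.

Coordinates are 0-based half-open internally; anything reported to users
(primer positions, amplicon spans) is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino_acid"

#: IUPAC degeneracy sets. Maps each nucleotide code to the set of concrete
#: bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse map: concrete base set -> minimal IUPAC code.
SETS_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

CONCRETE_BASES = frozenset("ACGT")
DEGENERATE_BASES = frozenset(IUPAC_SETS) - CONCRETE_BASES
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for codon in standard_dna_table.stop_codons:
        table[codon] = "*"
    return table


class AlphabetError(ValueError):
    """Residues inconsistent with the declared alphabet."""


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass(frozen=True)
class SeqRecord:
    """One named sequence over a declared alphabet.

    ``degenerate=True`` permits IUPAC ambiguity codes in nucleotide records
    (used for primers and consensus strings); plain genomic records should
    leave it off so that stray ambiguity codes are caught on construction.
    """

    id: str
    residues: str
    alphabet: str = NUCLEOTIDE
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        if self.alphabet not in (NUCLEOTIDE, AMINO_ACID):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed: frozenset[str]
        if self.alphabet == NUCLEOTIDE:
            allowed = frozenset(IUPAC_SETS) if self.degenerate else CONCRETE_BASES | {"N"}
        else:
            allowed = AA_LETTERS
        bad = set(self.residues) - set(allowed)
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)} "
                f"for alphabet {self.alphabet}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize_residues(raw: str, alphabet: str) -> str:
    s = raw.upper()
    if alphabet == NUCLEOTIDE:
        s = s.replace("U", "T")
    return s


def read_fasta(
    path: str | Path,
    alphabet: str = NUCLEOTIDE,
    degenerate: bool = False,
) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Residues are uppercased, U is normalized to T (nucleotide), line wraps
    and blank lines are removed, and input order is preserved. Malformed
    headers and illegal residues raise :class:`FastaParseError` naming the
    line; duplicate ids raise :class:`ValueError`.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        residues = _normalize_residues("".join(chunks), alphabet)
        try:
            rec = SeqRecord(header, residues, alphabet=alphabet, degenerate=degenerate)
        except AlphabetError as exc:
            raise FastaParseError(f"{path}: near line {line_no}: {exc}") from exc
        except ValueError as exc:
            raise FastaParseError(f"{path}: near line {line_no}: {exc}") from exc
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
        header, chunks = None, []

    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i - 1)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError(f"{path}: line {i}: empty FASTA header")
                header_line = i
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: line {i}: sequence data before first '>' header"
                    )
                chunks.append(line)
        flush(header_line + 1)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping residues at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA (gaps permitted) as ``(ids, rows)``.

    Rows are uppercased plain strings; equal lengths are enforced.
    """
    ids: list[str] = []
    rows: list[str] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    ids.append(header)
                    rows.append("".join(chunks).upper())
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if header is not None:
        ids.append(header)
        rows.append("".join(chunks).upper())
    if rows and len({len(r) for r in rows}) != 1:
        raise FastaParseError(f"{path}: alignment rows have unequal lengths")
    return ids, rows


def write_alignment_fasta(
    ids: list[str], rows: list[str], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(ids, rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def revcomp(s: str) -> str:
    """IUPAC-aware reverse complement of a nucleotide string."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(s.upper()))
    except KeyError as exc:
        raise AlphabetError(f"not a nucleotide/IUPAC character: {exc.args[0]!r}") from exc


class TranslationError(ValueError):
    """Codon cannot be translated unambiguously."""


def translate(s: str, frame: int = 0) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Stops are rendered ``*`` and a trailing partial codon is dropped.
    Degenerate codons are accepted only when every expansion encodes the
    same amino acid (e.g. GCN -> A); otherwise :class:`TranslationError`.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    s = _normalize_residues(s, NUCLEOTIDE)
    if len(s) < 3 + frame:
        raise ValueError("sequence shorter than one codon in this frame")
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    out = []
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if all(c in CONCRETE_BASES for c in codon):
            out.append(_CODON_TABLE[codon])
            continue
        try:
            expansions = {
                _CODON_TABLE[a + b + c]
                for a in IUPAC_SETS[codon[0]]
                for b in IUPAC_SETS[codon[1]]
                for c in IUPAC_SETS[codon[2]]
            }
        except KeyError as exc:
            raise AlphabetError(f"invalid base {exc.args[0]!r} in codon {codon}") from exc
        if len(expansions) != 1:
            raise TranslationError(f"ambiguous codon {codon} at position {i + 1}")
        out.append(expansions.pop())
    return "".join(out)


def iupac_match(template_base: str, pattern_base: str, allow_template_n: bool = False) -> bool:
    """True iff a concrete template base falls in the degeneracy set of a
    (possibly degenerate) pattern base.

    A template ``N`` matches nothing by default — conservative behaviour for
    in-silico PCR on partially ambiguous templates — unless
    ``allow_template_n`` is set, in which case it matches any pattern.
    """
    template_base = template_base.upper()
    pattern_base = pattern_base.upper()
    if pattern_base not in IUPAC_SETS:
        raise AlphabetError(f"invalid pattern base {pattern_base!r}")
    if template_base == "N":
        return allow_template_n
    if template_base not in CONCRETE_BASES:
        raise AlphabetError(f"template base must be concrete ACGT (or N): {template_base!r}")
    return template_base in IUPAC_SETS[pattern_base]


def consensus_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of observed concrete bases."""
    key = frozenset(b.upper() for b in bases)
    bad = key - CONCRETE_BASES
    if bad:
        raise AlphabetError(f"consensus over non-concrete bases: {sorted(bad)}")
    return SETS_TO_IUPAC[key]


def degeneracy(code: str) -> int:
    """Number of concrete bases a single IUPAC code stands for."""
    return len(IUPAC_SETS[code.upper()])


@dataclass
class LabelTable:
    """Sequence-id to cluster/subcluster assignments (the ground truth).

    By community convention a subcluster name carries its cluster as a
    prefix (cluster A, subcluster A1); a violation is reported as a warning
    rather than an error, since label schemes vary between collections.
    """

    rows: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (cluster, sub) in self.rows.items():
            if sub and not sub.startswith(cluster):
                warnings.warn(
                    f"label {sid!r}: subcluster {sub!r} does not carry cluster "
                    f"{cluster!r} as a prefix",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, sid: str) -> bool:
        return sid in self.rows

    def cluster(self, sid: str) -> str:
        return self.rows[sid][0]

    def subcluster(self, sid: str) -> str:
        return self.rows[sid][1]

    def ids(self) -> list[str]:
        return list(self.rows)

    def groups(self, level: str) -> dict[str, list[str]]:
        """Map group name -> member ids at ``level`` ('cluster' or 'subcluster')."""
        idx = {"cluster": 0, "subcluster": 1}[level]
        out: dict[str, list[str]] = {}
        for sid, tup in self.rows.items():
            name = tup[idx]
            if name:
                out.setdefault(name, []).append(sid)
        return out

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, str]]) -> "LabelTable":
        rows: dict[str, tuple[str, str]] = {}
        for sid, cluster, sub in pairs:
            if sid in rows:
                raise ValueError(f"duplicate id in label table: {sid!r}")
            rows[sid] = (cluster, sub)
        return cls(rows)


def read_labels(path: str | Path) -> LabelTable:
    """Read a 2-3 column TSV with header ``id<TAB>cluster<TAB>subcluster``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = [c.lower() for c in df.columns]
    if "id" not in cols or "cluster" not in cols:
        raise ValueError(f"{path}: label table needs 'id' and 'cluster' columns")
    df.columns = cols
    if "subcluster" not in cols:
        df["subcluster"] = ""
    return LabelTable.from_pairs(
        (r.id, r.cluster, r.subcluster) for r in df.itertuples(index=False)
    )


def write_labels(table: LabelTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(sid, c, s) for sid, (c, s) in table.rows.items()],
        columns=["id", "cluster", "subcluster"],
    )
    df.to_csv(path, sep="\t", index=False)
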