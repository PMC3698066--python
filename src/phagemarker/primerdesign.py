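"""Degenerate primer design on conserved marker-gene regions, with
in-silico PCR validation.

Conserved windows are gap-free stretches of a subcluster alignment, 16-22
columns long, whose column-wise minimal IUPAC consensus has at most three
degenerate positions — degeneracy absorbs silent substitutions while
keeping primers synthesizable. Primer pairs are an upstream window
consensus (forward) and the reverse complement of a downstream window
consensus (reverse), constrained to a target amplicon-length range.
Amplicon lengths are 1-based inclusive of both primer footprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import pandas as pd

from .seqcore import (
    CONCRETE_BASES,
    SeqRecord,
    consensus_code,
    degeneracy,
    iupac_match,
    revcomp,
)


@dataclass
class ConservedWindow:
    """A gap-free conserved block of an alignment, in MSA coordinates."""

    msa_column_start: int  # 0-based
    length: int
    consensus: str
    degenerate_positions: int
    gap_free: bool = True

    def __post_init__(self) -> None:
        if len(self.consensus) != self.length:
            raise ValueError("consensus length mismatch")


@dataclass
class PrimerPair:
    group: str
    forward: str
    reverse: str  # reverse-complement orientation, as synthesised
    predicted_products: dict[str, list[int]] = field(default_factory=dict)
    forward_window_start: int = -1
    reverse_window_start: int = -1

    @property
    def total_degeneracy(self) -> int:
        """Product of per-base degeneracy set sizes over both primers."""
        return prod(degeneracy(c) for c in self.forward + self.reverse)


@dataclass
class Amplicon:
    """Predicted PCR product; coordinates 1-based inclusive on the plus
    strand, spanning both primer footprints."""

    template_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _column_consensus(rows: list[str], col: int) -> str | None:
    bases = {r[col] for r in rows}
    if "-" in bases:
        return None
    if not bases <= CONCRETE_BASES:
        return None  # ambiguous residue in an input row: unusable column
    return consensus_code(bases)


def find_conserved_windows(
    msa_rows: list[str],
    min_len: int = 16,
    max_len: int = 22,
    max_degenerate: int = 3,
) -> list[ConservedWindow]:
    """Every gap-free window of allowed length whose minimal IUPAC
    consensus has at most ``max_degenerate`` degenerate columns.

    Overlapping windows are allowed; results are ordered longest-first,
    then by start column.
    """
    if len(msa_rows) < 2:
        raise ValueError("need at least 2 alignment rows")
    ncol = len(msa_rows[0])
    if any(len(r) != ncol for r in msa_rows):
        raise ValueError("ragged alignment")

    cons: list[str | None] = [_column_consensus(msa_rows, c) for c in range(ncol)]
    windows: list[ConservedWindow] = []
    for length in range(max_len, min_len - 1, -1):
        for start in range(0, ncol - length + 1):
            block = cons[start : start + length]
            if any(c is None for c in block):
                continue
            consensus = "".join(block)  # type: ignore[arg-type]
            ndeg = sum(c not in CONCRETE_BASES for c in consensus)
            if ndeg <= max_degenerate:
                windows.append(ConservedWindow(start, length, consensus, ndeg))
    return windows


def design_primer_pairs(
    windows: list[ConservedWindow],
    msa_rows: list[str],
    product_range: tuple[int, int] = (150, 900),
    row_ids: list[str] | None = None,
    group: str = "",
    max_degeneracy_product: int = 64,
    max_candidates: int | None = 150,
) -> list[PrimerPair]:
    """Pair upstream and downstream conserved windows into PCR primer sets.

    A pair is kept when the predicted product length (residues between the
    forward window start and reverse window end, inclusive) lies inside
    ``product_range`` on every alignment row. Results are ranked by total
    degeneracy, then by product length.

    Highly conserved alignments yield thousands of overlapping windows;
    ``max_candidates`` keeps the pairing quadratic small by considering
    only the best windows (fewest degenerate positions, then longest) per
    orientation. Pass None to pair every window.
    """
    if row_ids is None:
        row_ids = [f"row{i + 1}" for i in range(len(msa_rows))]
    if len(row_ids) != len(msa_rows):
        raise ValueError("row_ids length mismatch")
    lo, hi = product_range

    ranked = sorted(
        windows, key=lambda w: (w.degenerate_positions, -w.length, w.msa_column_start)
    )
    if max_candidates is not None:
        ranked = ranked[:max_candidates]

    # prefix sums of non-gap residues per row: O(1) product-length queries
    prefixes = []
    for row in msa_rows:
        p = [0]
        for c in row:
            p.append(p[-1] + (c != "-"))
        prefixes.append(p)

    def spans(col_a: int, col_b: int) -> list[int]:
        return [p[col_b + 1] - p[col_a] for p in prefixes]

    pairs: list[PrimerPair] = []
    for fwd in ranked:
        fstart = fwd.msa_column_start
        fend = fstart + fwd.length - 1
        for rev in ranked:
            rstart = rev.msa_column_start
            rend = rstart + rev.length - 1
            if rstart <= fend:
                continue  # overlapping or upstream
            sp = spans(fstart, rend)
            if not all(lo <= s <= hi for s in sp):
                continue
            pair = PrimerPair(
                group=group,
                forward=fwd.consensus,
                reverse=revcomp(rev.consensus),
                predicted_products={sid: [s] for sid, s in zip(row_ids, sp)},
                forward_window_start=fstart,
                reverse_window_start=rstart,
            )
            if pair.total_degeneracy <= max_degeneracy_product:
                pairs.append(pair)
    pairs.sort(
        key=lambda p: (
            p.total_degeneracy,
            min(v[0] for v in p.predicted_products.values()),
            p.forward_window_start,
        )
    )
    return pairs


def _primer_sites(
    template: str, pattern: str, max_mismatch: int, allow_template_n: bool
) -> list[int]:
    """0-based start positions where ``pattern`` (IUPAC) matches the plus
    strand with at most ``max_mismatch`` non-matching positions."""
    sites = []
    k = len(pattern)
    for i in range(len(template) - k + 1):
        mism = 0
        for t, p in zip(template[i : i + k], pattern):
            if not iupac_match(t, p, allow_template_n=allow_template_n):
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            sites.append(i)
    return sites


def insilico_pcr(
    template: SeqRecord,
    pair: PrimerPair,
    max_mismatch: int = 0,
    max_product: int = 5000,
    allow_template_n: bool = False,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a nucleotide template.

    The forward primer is matched IUPAC-wise on the plus strand and the
    reverse primer as its reverse complement downstream; both template
    orientations are screened, so results are strand-symmetric. All
    compatible pairings up to ``max_product`` are reported, 1-based
    inclusive of both primer footprints.
    """
    if template.alphabet != "nucleotide":
        raise ValueError("PCR template must be nucleotide")
    seq = template.residues
    amplicons: set[tuple[int, int]] = set()
    for left, right in ((pair.forward, pair.reverse), (pair.reverse, pair.forward)):
        left_sites = _primer_sites(seq, left, max_mismatch, allow_template_n)
        right_sites = _primer_sites(seq, revcomp(right), max_mismatch, allow_template_n)
        for i in left_sites:
            for j in right_sites:
                end = j + len(right) - 1
                length = end - i + 1
                if length < len(left) + len(right) or length > max_product:
                    continue
                amplicons.add((i + 1, end + 1))
    return [
        Amplicon(template.id, start, end) for start, end in sorted(amplicons)
    ]


def cross_reactivity(
    templates: list[SeqRecord],
    pairs: list[PrimerPair],
    max_mismatch: int = 0,
    max_product: int = 5000,
) -> pd.DataFrame:
    """Amplicon counts for every (primer group, template): the in-silico
    analogue of testing each primer set against DNA of every subcluster.

    A specific primer set amplifies only templates of its own group, i.e.
    the matrix is block-diagonal with respect to group membership.
    """
    groups = [p.group for p in pairs]
    data = {}
    for rec in templates:
        data[rec.id] = [
            len(insilico_pcr(rec, p, max_mismatch=max_mismatch, max_product=max_product))
            for p in pairs
        ]
    return pd.DataFrame(data, index=groups)


def pairs_to_frame(pairs: list[PrimerPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        lengths = sorted({v for vals in p.predicted_products.values() for v in vals})
        rows.append(
            (p.group, p.forward, p.reverse, ";".join(map(str, lengths)))
        )
    return pd.DataFrame(
        rows, columns=["group", "forward", "reverse", "product_length"]
    )
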