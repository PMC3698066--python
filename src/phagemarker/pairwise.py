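"""Word-match dotplots, global alignment and small-scale progressive MSA.

The dotplot engine is the evidence source for single-gene cluster
classification: exact word matches between two sequences, summarised as the
fraction of the query's words found anywhere in the subject (``coverage``)
and as the longest uninterrupted diagonal run.

Global alignment follows the classic free-end-gap affine-gap recipe used
for marker-gene comparisons: match 5.0, mismatch -4.0, gap open 12, gap
extension 3 (a gap of length k costs ``open + (k-1) * extend``). It is
backed by Biopython's ``PairwiseAligner``; an independent dynamic-
programming oracle in the test-suite cross-checks the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .seqcore import NUCLEOTIDE, SeqRecord, revcomp


@dataclass
class ScoringParams:
    """Alignment scores: positives reward, penalties are magnitudes."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 12.0
    gap_extend: float = 3.0
    free_end_gaps: bool = True

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class DotplotParams:
    """Word length defaults mirror common dotplot practice: 10 for
    nucleotide, 3 for amino-acid comparisons."""

    word_length: int | None = None
    both_strands: bool = False

    def resolved_word_length(self, alphabet: str) -> int:
        if self.word_length is not None:
            return self.word_length
        return 10 if alphabet == NUCLEOTIDE else 3


@dataclass
class DotplotResult:
    """Hits are 0-based (posA, posB) word-start pairs on the plus strand."""

    hits: set[tuple[int, int]]
    coverage_a: float
    longest_diagonal_run: int
    word_length: int
    len_a: int
    len_b: int
    rc_hits: set[tuple[int, int]] = field(default_factory=set)


def _word_positions(s: str, w: int) -> dict[str, list[int]]:
    table: dict[str, list[int]] = {}
    for i in range(len(s) - w + 1):
        table.setdefault(s[i : i + w], []).append(i)
    return table


def dotplot(a: SeqRecord, b: SeqRecord, params: DotplotParams | None = None) -> DotplotResult:
    """All exact word matches between ``a`` and ``b``.

    ``coverage_a`` is the fraction of a's words that occur anywhere in b
    (either strand when ``both_strands``), the quantity used as the
    classifier's similarity score.
    """
    params = params or DotplotParams()
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    w = params.resolved_word_length(a.alphabet)
    if w < 1 or w > min(len(a), len(b)):
        raise ValueError(
            f"word_length {w} invalid for sequences of length {len(a)}, {len(b)}"
        )
    table = _word_positions(b.residues, w)
    rc_table: dict[str, list[int]] = {}
    if params.both_strands:
        if a.alphabet != NUCLEOTIDE:
            raise ValueError("both_strands only applies to nucleotide dotplots")
        rc_table = _word_positions(revcomp(b.residues), w)

    hits: set[tuple[int, int]] = set()
    rc_hits: set[tuple[int, int]] = set()
    n_words = len(a) - w + 1
    covered = 0
    for i in range(n_words):
        word = a.residues[i : i + w]
        found = False
        if word in table:
            found = True
            hits.update((i, j) for j in table[word])
        if rc_table and word in rc_table:
            found = True
            rc_hits.update((i, j) for j in rc_table[word])
        covered += found

    longest = 0
    by_diag: dict[int, list[int]] = {}
    for i, j in hits:
        by_diag.setdefault(j - i, []).append(i)
    for starts in by_diag.values():
        starts.sort()
        run = 1
        for prev, cur in zip(starts, starts[1:]):
            run = run + 1 if cur == prev + 1 else 1
            longest = max(longest, run)
        longest = max(longest, run if len(starts) > 1 else 1)
    if hits and longest == 0:
        longest = 1

    return DotplotResult(
        hits=hits,
        coverage_a=covered / n_words,
        longest_diagonal_run=longest,
        word_length=w,
        len_a=len(a),
        len_b=len(b),
        rc_hits=rc_hits,
    )


def write_dotplot_tsv(result: DotplotResult, a: SeqRecord, b: SeqRecord, path) -> None:
    """Hit list as TSV: 1-based posA, posB and the matched word."""
    with open(path, "w") as fh:
        fh.write("posA\tposB\tword\n")
        for i, j in sorted(result.hits):
            fh.write(f"{i + 1}\t{j + 1}\t{a.residues[i : i + result.word_length]}\n")


def plot_dotplot(result: DotplotResult, path, title: str | None = None) -> None:
    """Render the hit set as a dotplot raster (PNG or any matplotlib format)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if result.hits:
        xs, ys = zip(*sorted(result.hits))
        ax.plot(xs, ys, ".", markersize=1, color="black")
    if result.rc_hits:
        xs, ys = zip(*sorted(result.rc_hits))
        ax.plot(xs, [result.len_b - result.word_length - y for y in ys],
                ".", markersize=1, color="grey")
    ax.set_xlim(0, result.len_a)
    ax.set_ylim(result.len_b, 0)  # top-left origin, dotplot convention
    ax.set_xlabel("sequence A")
    ax.set_ylabel("sequence B")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def word_coverage(query: str, subject_words: set[str], w: int) -> float:
    """Coverage of ``query`` against a precomputed subject word set.

    Fast path used by the classifier when one query is screened against a
    whole reference panel.
    """
    n = len(query) - w + 1
    if n < 1:
        raise ValueError("query shorter than word length")
    return sum(query[i : i + w] in subject_words for i in range(n)) / n


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    pct_identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.free_end_gaps:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def percent_identity(
    row_a: str, row_b: str, exclude_end_overhangs: bool = True
) -> float:
    """Identity over aligned columns where at least one row has a residue.

    With ``exclude_end_overhangs`` the leading/trailing columns covered by
    only one of the two rows (free end gaps) drop out of the denominator.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    n = len(row_a)
    start, stop = 0, n
    if exclude_end_overhangs:
        def span(row: str) -> tuple[int, int]:
            stripped = row.strip("-")
            if not stripped:
                return 0, 0
            lead = len(row) - len(row.lstrip("-"))
            return lead, lead + len(stripped)

        a0, a1 = span(row_a)
        b0, b1 = span(row_b)
        start, stop = max(a0, b0), min(a1, b1)
        if start >= stop:
            return 0.0
    ident = denom = 0
    for ca, cb in zip(row_a[start:stop], row_b[start:stop]):
        if ca == "-" and cb == "-":
            continue
        denom += 1
        if ca == cb and ca != "-":
            ident += 1
    return 100.0 * ident / denom if denom else 0.0


def global_align(
    a: SeqRecord | str,
    b: SeqRecord | str,
    params: ScoringParams | None = None,
    alphabet: str = NUCLEOTIDE,
) -> AlignmentResult:
    """Optimal global alignment under affine gaps, end gaps free by default."""
    params = params or ScoringParams()
    if isinstance(a, SeqRecord) and isinstance(b, SeqRecord):
        if a.alphabet != b.alphabet:
            raise ValueError("alphabet mismatch")
        alphabet = a.alphabet
    sa = a.residues if isinstance(a, SeqRecord) else a
    sb = b.residues if isinstance(b, SeqRecord) else b

    if not sa or not sb:
        # all-gap alignment against the non-empty side
        other = sa or sb
        gaps = "-" * len(other)
        if params.free_end_gaps or not other:
            score = 0.0
        else:
            score = -(params.gap_open + params.gap_extend * (len(other) - 1))
        aligned_a = sa or gaps
        aligned_b = sb or gaps
        if not sa and not sb:
            aligned_a = aligned_b = ""
        return AlignmentResult(aligned_a, aligned_b, score, 0.0)

    aligner = _make_aligner(params)
    aln = aligner.align(sa, sb)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    pid = percent_identity(row_a, row_b, exclude_end_overhangs=params.free_end_gaps)
    return AlignmentResult(row_a, row_b, float(aln.score), pid)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile_column_score(col_a: list[str], col_b: list[str], params: ScoringParams) -> float:
    # mean pairwise substitution score; gap pairings contribute zero
    total = 0.0
    n = 0
    for ca in col_a:
        for cb in col_b:
            n += 1
            if ca == "-" or cb == "-":
                continue
            total += params.match if ca == cb else params.mismatch
    return total / n if n else 0.0


def _align_profiles(
    rows_a: list[str], rows_b: list[str], params: ScoringParams
) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) alignment of two fixed alignments.

    Gap of length k costs ``gap_open + (k-1) * gap_extend``; end gaps are
    free when the scoring parameters say so. Ties resolve diagonal > up
    (gap in B) > left (gap in A) for determinism.
    """
    cols_a = [[r[i] for r in rows_a] for i in range(len(rows_a[0]))]
    cols_b = [[r[i] for r in rows_b] for i in range(len(rows_b[0]))]
    n, m = len(cols_a), len(cols_b)
    go, ge = params.gap_open, params.gap_extend
    end_free = params.free_end_gaps
    neg = -np.inf

    M = np.full((n + 1, m + 1), neg)  # state 0: column vs column
    X = np.full((n + 1, m + 1), neg)  # state 1: consume A, gap in B ("up")
    Y = np.full((n + 1, m + 1), neg)  # state 2: consume B, gap in A ("left")
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if end_free else -(go + ge * (i - 1))
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if end_free else -(go + ge * (j - 1))
        ptr_y[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _profile_column_score(cols_a[i - 1], cols_b[j - 1], params)
            best, ptr = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, ptr = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, ptr = Y[i - 1, j - 1], 2
            M[i, j] = best + s
            ptr_m[i, j] = ptr

            # trailing gaps in B are free when j == m and end gaps are free
            co = 0.0 if (end_free and j == m) else go
            ce = 0.0 if (end_free and j == m) else ge
            open_x, ext_x = M[i - 1, j] - co, X[i - 1, j] - ce
            X[i, j], ptr_x[i, j] = (open_x, 0) if open_x >= ext_x else (ext_x, 1)

            co = 0.0 if (end_free and i == n) else go
            ce = 0.0 if (end_free and i == n) else ge
            open_y, ext_y = M[i, j - 1] - co, Y[i, j - 1] - ce
            Y[i, j], ptr_y[i, j] = (open_y, 0) if open_y >= ext_y else (ext_y, 2)

    state = 0
    if X[n, m] > M[n, m] or Y[n, m] > M[n, m]:
        state = 1 if X[n, m] >= Y[n, m] else 2
    i, j = n, m
    path: list[int] = []
    while i > 0 or j > 0:
        path.append(state)
        if state == 0:
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = int(ptr_x[i, j])
            i -= 1
        else:
            state = int(ptr_y[i, j])
            j -= 1
    path.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for step in path:
        if step in (0, 1):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if step in (0, 2):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def _drop_all_gap_columns(rows: list[str]) -> list[str]:
    keep = [i for i in range(len(rows[0])) if any(r[i] != "-" for r in rows)]
    return ["".join(r[i] for i in keep) for r in rows]


def msa(seqs: list[SeqRecord], params: ScoringParams | None = None) -> list[str]:
    """Progressive multiple alignment guided by a neighbor-joining tree.

    Pairwise identity distances feed an NJ guide tree; alignments are merged
    profile-against-profile at each internal node with the same scoring
    parameters as :func:`global_align`. This is a compact progressive
    aligner in the ClustalW mould, not a reimplementation of any particular
    tool; columns that are gap-only in every row are never emitted.
    """
    params = params or ScoringParams()
    if not seqs:
        raise ValueError("need at least one sequence")
    if len({s.alphabet for s in seqs}) != 1:
        raise ValueError("mixed alphabets in MSA input")
    if len(seqs) == 1:
        return [seqs[0].residues]
    if len(seqs) == 2:
        res = global_align(seqs[0], seqs[1], params)
        return _drop_all_gap_columns([res.aligned_a, res.aligned_b])

    from .phylo import DistanceMatrix, nj_tree

    n = len(seqs)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_align(seqs[i], seqs[j], params).pct_identity
            dmat[i, j] = dmat[j, i] = 1.0 - pid / 100.0
    labels = [s.id for s in seqs]
    guide = nj_tree(DistanceMatrix(labels, dmat))

    by_id = {s.id: s for s in seqs}

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            sid = node.taxon.label
            return [sid], [by_id[sid].residues]
        child_blocks = [merge(c) for c in node.child_nodes()]
        ids, rows = child_blocks[0]
        for more_ids, more_rows in child_blocks[1:]:
            rows, more = _align_profiles(rows, more_rows, params)
            rows = rows + more
            ids = ids + more_ids
        return ids, rows

    ids, rows = merge(guide.seed_node)
    rows = _drop_all_gap_columns(rows)
    # restore input order
    pos = {sid: k for k, sid in enumerate(ids)}
    return [rows[pos[s.id]] for s in seqs]


def identity_stats(msa_rows: list[str]) -> tuple[float, float]:
    """(% identical sites, % mean pairwise identity) for an alignment.

    Identical sites: columns where every row carries the same residue (no
    gaps), as a percent of all columns. Pairwise identity: mean over all
    row pairs of column identity, each pair scored over columns where at
    least one of the two rows has a residue.
    """
    if len(msa_rows) < 2:
        raise ValueError("need at least 2 rows")
    ncol = len(msa_rows[0])
    if any(len(r) != ncol for r in msa_rows):
        raise ValueError("ragged alignment")
    ident_cols = 0
    for i in range(ncol):
        col = {r[i] for r in msa_rows}
        if len(col) == 1 and "-" not in col:
            ident_cols += 1
    pct_ident_sites = 100.0 * ident_cols / ncol

    pids = []
    for i in range(len(msa_rows)):
        for j in range(i + 1, len(msa_rows)):
            pids.append(
                percent_identity(msa_rows[i], msa_rows[j], exclude_end_overhangs=False)
            )
    return pct_ident_sites, float(np.mean(pids))
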