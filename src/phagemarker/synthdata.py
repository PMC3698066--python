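"""Synthetic cluster-structured phage panels with a truth table.

The generator emulates the shape of a curated phage collection: clusters
of related genomes subdivided into tighter subclusters, each genome
carrying a long marker gene (a tape-measure-protein analogue) at a known
locus, with optional horizontal segment exchange ("mosaicism") between
clusters. Every downstream module — classification, primer design,
phylogenetics — is testable against the generator's truth table without
any external downloads.

Evolution is deliberately simple: independent random ancestors per cluster
(real clusters share little nucleotide similarity), uniform per-site
substitution (Jukes-Cantor-like), optional geometric-length indels
confined outside the marker locus so truth intervals stay exact, and
optional cross-cluster segment swaps that never touch the marker by
default (mirroring the hypothesized stability of tail-structure genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seqcore import LabelTable, SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SynthConfig:
    """Panel shape and divergence settings.

    Divergences are per-copy substitution probabilities: each subcluster
    ancestor diverges from its cluster ancestor at
    ``within_cluster_divergence``, each member from its subcluster ancestor
    at ``within_subcluster_divergence``. Defaults model a tight subcluster
    (~90% pairwise member identity) inside a loose cluster, marker genes of
    ~3 kb inside 20 kb genomes.
    """

    n_clusters: int = 5
    subclusters_per_cluster: int = 2
    members_per_subcluster: int = 4
    genome_length: int = 20000
    tmp_length: int = 3000
    within_subcluster_divergence: float = 0.05
    within_cluster_divergence: float = 0.20
    between_cluster_divergence: float | None = None  # None: independent ancestors
    indel_rate: float = 0.0
    mosaic_swap_rate: float = 0.0
    tmp_start: int | None = None  # 0-based; default genome_length // 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "subclusters_per_cluster", "members_per_subcluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.tmp_length < self.genome_length):
            raise ValueError("tmp_length must be positive and < genome_length")
        for name in (
            "within_subcluster_divergence",
            "within_cluster_divergence",
            "indel_rate",
            "mosaic_swap_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.within_subcluster_divergence > self.within_cluster_divergence:
            raise ValueError(
                "within_subcluster_divergence must not exceed within_cluster_divergence"
            )
        start = self.resolved_tmp_start()
        if start < 0 or start + self.tmp_length > self.genome_length:
            raise ValueError("marker locus does not fit in the genome")

    def resolved_tmp_start(self) -> int:
        return self.genome_length // 4 if self.tmp_start is None else self.tmp_start


@dataclass
class TruthRow:
    id: str
    cluster: str
    subcluster: str
    tmp_start: int  # 1-based inclusive
    tmp_end: int
    donors: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def __len__(self) -> int:
        return len(self.rows)

    def to_label_table(self) -> LabelTable:
        return LabelTable.from_pairs((r.id, r.cluster, r.subcluster) for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.id,
                    r.cluster,
                    r.subcluster,
                    r.tmp_start,
                    r.tmp_end,
                    ";".join(f"{d}:{s}-{e}" for d, s, e in r.donors),
                )
                for r in self.rows
            ],
            columns=["id", "cluster", "subcluster", "tmp_start", "tmp_end", "donors"],
        )

    def row(self, sid: str) -> TruthRow:
        for r in self.rows:
            if r.id == sid:
                return r
        raise KeyError(sid)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _substitute(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution to a uniformly chosen different base."""
    if rate == 0.0:
        return seq.copy()
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit))
        idx = {b: k for k, b in enumerate(_BASES)}
        cur = np.array([idx[b] for b in out[hit]])
        out[hit] = _BASES[(cur + shift) % 4]
    return out


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate == 0.0:
        return seq
    pieces: list[np.ndarray] = []
    i = 0
    n = len(seq)
    while i < n:
        if rng.random() < rate:
            length = rng.geometric(0.5)
            if rng.random() < 0.5:  # insertion before i
                pieces.append(rng.choice(_BASES, size=length))
                pieces.append(seq[i : i + 1])
                i += 1
            else:  # deletion of `length` sites
                i += length
        else:
            pieces.append(seq[i : i + 1])
            i += 1
    if not pieces:
        return seq[:0]
    return np.concatenate(pieces)


def diverge(
    s: SeqRecord | str,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    new_id: str | None = None,
) -> SeqRecord:
    """Return a mutated copy: uniform substitutions plus geometric indels.

    Deterministic given the seed; ``seed`` may also be a Generator when the
    caller manages the random stream.
    """
    if not (0.0 <= sub_rate < 1.0 and 0.0 <= indel_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sid = s.id if isinstance(s, SeqRecord) else "seq"
    seq = np.frombuffer((s.residues if isinstance(s, SeqRecord) else s).encode(), dtype="S1")
    out = _substitute(seq, sub_rate, rng)
    out = _apply_indels(out, indel_rate, rng)
    return SeqRecord(new_id or sid, out.tobytes().decode())


def _cluster_name(i: int) -> str:
    # A, B, ..., Z, AA, AB, ...
    name = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        name = chr(ord("A") + r) + name
    return name


def generate_panel(
    config: SynthConfig,
) -> tuple[list[SeqRecord], list[SeqRecord], TruthTable]:
    """Generate genomes, embedded marker genes, and the truth table.

    Per cluster a random ancestor (independent between clusters unless
    ``between_cluster_divergence`` is set, in which case all clusters
    derive from one shared root); per subcluster a diverged copy at the
    within-cluster rate; per member a diverged copy at the
    within-subcluster rate. Indels are confined outside the marker locus
    so that every truth interval extracts a marker of exactly
    ``tmp_length``. Byte-identical outputs for identical config and seed.
    """
    rng = np.random.default_rng(config.seed)
    t0 = config.resolved_tmp_start()
    tlen = config.tmp_length

    genomes: list[SeqRecord] = []
    tmp_genes: list[SeqRecord] = []
    rows: list[TruthRow] = []

    shared_root: np.ndarray | None = None
    if config.between_cluster_divergence is not None:
        shared_root = np.frombuffer(
            _random_seq(rng, config.genome_length).encode(), dtype="S1"
        )

    for ci in range(config.n_clusters):
        cname = _cluster_name(ci)
        if shared_root is not None:
            cluster_anc = _substitute(shared_root, config.between_cluster_divergence, rng)
        else:
            cluster_anc = np.frombuffer(
                _random_seq(rng, config.genome_length).encode(), dtype="S1"
            )
        for si in range(config.subclusters_per_cluster):
            sname = (
                cname
                if config.subclusters_per_cluster == 1
                else f"{cname}{si + 1}"
            )
            sub_anc = _substitute(cluster_anc, config.within_cluster_divergence, rng)
            for mi in range(config.members_per_subcluster):
                gid = f"{sname}_{mi + 1:02d}"
                member = _substitute(sub_anc, config.within_subcluster_divergence, rng)
                if config.indel_rate > 0:
                    left = _apply_indels(member[:t0], config.indel_rate, rng)
                    right = _apply_indels(member[t0 + tlen :], config.indel_rate, rng)
                    member = np.concatenate([left, member[t0 : t0 + tlen], right])
                    start0 = len(left)
                else:
                    start0 = t0
                seq = member.tobytes().decode()
                genomes.append(SeqRecord(gid, seq))
                tmp_genes.append(SeqRecord(gid, seq[start0 : start0 + tlen]))
                rows.append(
                    TruthRow(gid, cname, sname, start0 + 1, start0 + tlen)
                )

    truth = TruthTable(rows)
    if config.mosaic_swap_rate > 0:
        genomes, truth = mosaic_swap(
            genomes, truth, config.mosaic_swap_rate, rng=rng
        )
    return genomes, tmp_genes, truth


def mosaic_swap(
    genomes: list[SeqRecord],
    truth: TruthTable,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    span_range: tuple[float, float] = (0.05, 0.15),
    protect_tmp: bool = True,
) -> tuple[list[SeqRecord], TruthTable]:
    """Horizontal exchange: with probability ``rate`` per genome, replace a
    random segment with the homologous-position segment of a random
    other-cluster genome. The marker locus is protected by default; donor
    segments are recorded in the truth table (1-based inclusive).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    clusters = {r.id: r.cluster for r in truth.rows}
    if len(set(clusters.values())) < 2:
        raise ValueError("mosaic swaps need at least 2 clusters")
    originals = {g.id: g.residues for g in genomes}

    new_genomes: list[SeqRecord] = []
    new_rows: list[TruthRow] = []
    for g, row in zip(genomes, truth.rows):
        donors = list(row.donors)
        seq = g.residues
        if rng.random() < rate:
            others = [x for x in truth.rows if clusters[x.id] != row.cluster]
            donor = others[rng.integers(0, len(others))]
            glen = len(seq)
            span = int(glen * (span_range[0] + rng.random() * (span_range[1] - span_range[0])))
            span = max(1, min(span, glen))
            # rejection-sample a start outside the marker interval
            for _ in range(200):
                start = int(rng.integers(0, glen - span + 1))
                if not protect_tmp:
                    break
                if start + span <= row.tmp_start - 1 or start >= row.tmp_end:
                    break
            else:
                start = None
            if start is not None:
                donor_seq = originals[donor.id]
                end = min(start + span, len(donor_seq), glen)
                seq = seq[:start] + donor_seq[start:end] + seq[end:]
                donors.append((donor.id, start + 1, end))
        new_genomes.append(SeqRecord(g.id, seq))
        new_rows.append(replace(row, donors=donors))
    return new_genomes, TruthTable(new_rows)
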