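"""Single-gene cluster/subcluster prediction and recovery statistics.

The classifier operationalizes visual dotplot inspection: a query marker
gene is compared against every member of a labelled reference panel by
exact word coverage (the fraction of the query's words found in the
reference), and the call is the subcluster of the best-covered reference.
Queries whose best coverage falls below a threshold are left unassigned —
the behaviour of true singletons, which share only a small fraction of
marker-gene words with any assigned cluster. The default threshold of
0.25 separates singleton-level similarity (~10%) from genuine subcluster
membership while tolerating divergent members.

Recovery statistics use the normal-approximation (Wald) confidence
interval for proportions at alpha = 0.05, computed on the unrounded
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm

from .pairwise import DotplotParams, ScoringParams, global_align, word_coverage
from .seqcore import LabelTable, SeqRecord


@dataclass
class ReferencePanel:
    """Labelled marker-gene sequences: the classification ground truth."""

    records: list[SeqRecord]
    labels: LabelTable
    _word_sets: dict[int, dict[str, set[str]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty reference panel")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in panel")
        unlabelled = [i for i in ids if i not in self.labels]
        if unlabelled:
            raise ValueError(f"panel records without labels: {unlabelled[:5]}")
        clusters = {self.labels.cluster(i) for i in ids}
        if not clusters:
            raise ValueError("panel must carry at least one cluster")

    def word_sets(self, w: int) -> dict[str, set[str]]:
        """Per-record word sets at word length ``w`` (cached)."""
        if w not in self._word_sets:
            self._word_sets[w] = {
                r.id: {r.residues[i : i + w] for i in range(len(r) - w + 1)}
                for r in self.records
            }
        return self._word_sets[w]

    def record(self, sid: str) -> SeqRecord:
        for r in self.records:
            if r.id == sid:
                return r
        raise KeyError(sid)


@dataclass
class ClusterCall:
    query_id: str
    status: str  # "assigned" | "unassigned"
    cluster: str
    subcluster: str
    best_hit_id: str
    similarity: float
    runner_up_margin: float


def classify_gene(
    query: SeqRecord,
    panel: ReferencePanel,
    dp: DotplotParams | None = None,
    threshold: float = 0.25,
    exclude_ids: set[str] | None = None,
) -> ClusterCall:
    """Classify one marker gene against a labelled panel.

    Similarity to each reference is the dotplot word coverage of the query.
    Exact coverage ties are broken by global-alignment percent identity and
    then lexicographically by reference id, so calls are deterministic.
    ``exclude_ids`` supports leave-one-out evaluation.
    """
    dp = dp or DotplotParams()
    exclude_ids = exclude_ids or set()
    if query.alphabet != panel.records[0].alphabet:
        raise ValueError("query alphabet does not match panel")
    w = dp.resolved_word_length(query.alphabet)
    word_sets = panel.word_sets(w)

    scores: list[tuple[float, str]] = []
    for rec in panel.records:
        if rec.id in exclude_ids or rec.id == query.id:
            continue
        scores.append((word_coverage(query.residues, word_sets[rec.id], w), rec.id))
    if not scores:
        raise ValueError("no panel records left to compare against")

    best_cov = max(c for c, _ in scores)
    tied = sorted(sid for c, sid in scores if c == best_cov)
    if len(tied) > 1:
        sp = ScoringParams()
        pid_of = {
            sid: global_align(query, panel.record(sid), sp).pct_identity for sid in tied
        }
        tied.sort(key=lambda sid: (-pid_of[sid], sid))
    best_id = tied[0]
    others = [c for c, sid in scores if sid != best_id]
    margin = best_cov - max(others) if others else best_cov

    if best_cov < threshold:
        return ClusterCall(query.id, "unassigned", "", "", best_id, best_cov, margin)
    return ClusterCall(
        query.id,
        "assigned",
        panel.labels.cluster(best_id),
        panel.labels.subcluster(best_id),
        best_id,
        best_cov,
        margin,
    )


def classify_panel_loo(
    panel: ReferencePanel,
    dp: DotplotParams | None = None,
    threshold: float = 0.25,
) -> list[ClusterCall]:
    """Leave-one-out classification of every panel member against the rest."""
    return [
        classify_gene(rec, panel, dp=dp, threshold=threshold, exclude_ids={rec.id})
        for rec in panel.records
    ]


def proportion_ci(
    successes: int, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Wald confidence interval for a proportion, in percentage points.

    Returns ``(proportion_pct, halfwidth_pct)`` with the half-width
    ``z(1 - alpha/2) * sqrt(p(1-p)/n)`` computed on the unrounded p.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValueError("successes must lie in [0, n]")
    p = successes / n
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * (p * (1.0 - p) / n) ** 0.5
    return 100.0 * p, 100.0 * half


@dataclass
class RecoveryReport:
    n: int
    cluster_correct: int
    subcluster_correct: int
    cluster_accuracy_pct: float
    subcluster_accuracy_pct: float
    ci_halfwidth_pct: float
    misassigned_ids: list[str]

    def __post_init__(self) -> None:
        if not (self.subcluster_correct <= self.cluster_correct <= self.n):
            raise ValueError("inconsistent correct counts")


def evaluate_recovery(
    calls: list[ClusterCall], truth: LabelTable, alpha: float = 0.05
) -> RecoveryReport:
    """Score calls against truth labels at cluster and subcluster level.

    Unassigned calls count as incorrect. Accuracies are reported to one
    decimal; the confidence half-width is the Wald interval on the
    subcluster proportion.
    """
    seen: set[str] = set()
    for c in calls:
        if c.query_id in seen:
            raise ValueError(f"duplicate query id {c.query_id!r}")
        if c.query_id not in truth:
            raise ValueError(f"call for unknown id {c.query_id!r}")
        seen.add(c.query_id)

    n = len(calls)
    cluster_ok = subcluster_ok = 0
    wrong: list[str] = []
    for c in calls:
        tc, ts = truth.cluster(c.query_id), truth.subcluster(c.query_id)
        good_cluster = c.status == "assigned" and c.cluster == tc
        good_sub = good_cluster and c.subcluster == ts
        cluster_ok += good_cluster
        subcluster_ok += good_sub
        if not good_sub:
            wrong.append(c.query_id)

    cl_pct, _ = proportion_ci(cluster_ok, n, alpha)
    sub_pct, sub_half = proportion_ci(subcluster_ok, n, alpha)
    return RecoveryReport(
        n=n,
        cluster_correct=cluster_ok,
        subcluster_correct=subcluster_ok,
        cluster_accuracy_pct=round(cl_pct, 1),
        subcluster_accuracy_pct=round(sub_pct, 1),
        ci_halfwidth_pct=round(sub_half, 2),
        misassigned_ids=sorted(wrong),
    )


def calls_to_frame(calls: list[ClusterCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.query_id, c.status, c.cluster, c.subcluster, c.best_hit_id,
             round(c.similarity, 4), round(c.runner_up_margin, 4))
            for c in calls
        ],
        columns=[
            "query_id", "status", "cluster", "subcluster",
            "best_hit_id", "similarity", "runner_up_margin",
        ],
    )
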