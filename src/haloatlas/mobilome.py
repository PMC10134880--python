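"""Insertion-sequence mobilization quantification from long-read SV calls.

Long-read sequencing of Halobacterium salinarum strains yields structural
variant (SV) calls — insertions and deletions relative to the reference —
whose allele sequences can be matched against the genome's catalog of
insertion-sequence (IS) elements. An insertion carrying an IS sequence is a
new transposition; a deletion removing an IS copy present in the reference
is an excision.

The pipeline here:

1. assigns each SV to its best-matching IS element by local alignment,
   keeping only calls with >= 75% identity and >= 80% coverage of both the
   SV allele and the IS (thresholds relaxed from the classic 80-80-80
   homology rule to tolerate nanopore error rates);
2. collapses neighboring calls of the same class and element starting
   within 50 bp into clusters, each with a mean start and an occurrence
   count ``e``;
3. divides ``e`` by the local read coverage ``c`` (mean depth over a
   25-nt bidirectional flank) to classify each mobilization as rare
   (e/c <= 0.1), common (0.1 < e/c <= 0.5) or predominant (e/c > 0.5) in
   the sequenced population;
4. normalizes per-library cluster counts by aligned-read depth and compares
   strain means with 68% confidence intervals (mean +/- one standard
   error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from haloatlas.io import CoverageTrack, SvRecord

IDENTITY_MIN = 0.75
COVERAGE_MIN = 0.80


@dataclass
class MobilizationEvent:
    """One SV call matched (or not) against the IS catalog."""

    library_id: str
    replicon_id: str
    start: int  # 1-based, as read from the VCF
    sv_class: str  # insertion | excision
    element_id: str | None  # None when unassigned
    identity: float
    q_coverage: float
    s_coverage: float

    @property
    def assigned(self) -> bool:
        return self.element_id is not None


@dataclass
class EventCluster:
    """Neighboring same-class, same-element events collapsed together."""

    library_id: str
    replicon_id: str
    sv_class: str
    element_id: str
    mean_start: float
    e: int  # occurrence count (support index numerator)
    c: float = float("nan")  # local read coverage
    population_class: str | None = None

    @property
    def ratio(self) -> float:
        return self.e / self.c


@dataclass
class StrainComparison:
    """Two-strain comparison of normalized mobilization counts at 68% CI."""

    strains: tuple[str, str]
    values: dict[str, list[float]]
    means: dict[str, float]
    standard_errors: dict[str, float]
    ci: dict[str, tuple[float, float]]  # mean +/- one SE
    verdict: str  # different | not_different | insufficient_replicates


def _blast_like_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def assign_is(
    sv: SvRecord,
    is_catalog: Sequence[tuple[str, str]],
    identity_min: float = IDENTITY_MIN,
    coverage_min: float = COVERAGE_MIN,
) -> MobilizationEvent:
    """Match one SV allele sequence against the IS catalog.

    The best local-alignment hit (highest score, ties broken by higher
    identity then lexical element id) is kept only if it reaches
    ``identity_min`` identity over the aligned columns and ``coverage_min``
    coverage of both the SV sequence (query) and the IS element (subject);
    otherwise the event is left unassigned and is dropped from clustering.
    """
    if not is_catalog:
        raise ValueError("IS catalog is empty")
    if not sv.sequence:
        raise ValueError(f"SV at {sv.replicon_id}:{sv.pos} has an empty sequence")
    aligner = _blast_like_aligner()
    best = None  # (score, identity, element_id, q_cov, s_cov)
    for element_id, element_seq in is_catalog:
        alignments = aligner.align(sv.sequence, element_seq.upper())
        try:
            aln = alignments[0]
        except IndexError:
            continue
        counts = aln.counts()
        aligned_cols = counts.identities + counts.mismatches + counts.gaps
        if aligned_cols == 0:
            continue
        identity = counts.identities / aligned_cols
        q_blocks, s_blocks = aln.aligned
        if len(q_blocks) == 0:
            continue
        q_span = q_blocks[-1][1] - q_blocks[0][0]
        s_span = s_blocks[-1][1] - s_blocks[0][0]
        q_cov = q_span / len(sv.sequence)
        s_cov = s_span / len(element_seq)
        key = (aln.score, identity, element_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            key[0] == best[0] and key[1] == best[1] and element_id < best[2]
        ):
            best = (aln.score, identity, element_id, q_cov, s_cov)
    if best is None:
        return MobilizationEvent(
            library_id=sv.library_id, replicon_id=sv.replicon_id, start=sv.pos,
            sv_class=sv.sv_class, element_id=None,
            identity=0.0, q_coverage=0.0, s_coverage=0.0,
        )
    score, identity, element_id, q_cov, s_cov = best
    passes = identity >= identity_min and q_cov >= coverage_min and s_cov >= coverage_min
    return MobilizationEvent(
        library_id=sv.library_id,
        replicon_id=sv.replicon_id,
        start=sv.pos,
        sv_class=sv.sv_class,
        element_id=element_id if passes else None,
        identity=identity,
        q_coverage=q_cov,
        s_coverage=s_cov,
    )


def cluster_events(
    events: Sequence[MobilizationEvent], max_gap: int = 50
) -> list[EventCluster]:
    """Collapse assigned events into clusters by single-linkage chaining.

    Events are partitioned by (library, replicon, class, element) and
    sorted by start; an event joins the open cluster when its start lies
    within ``max_gap`` of the previously added event's start, otherwise it
    opens a new cluster. Equivalent to the transitive closure of the
    <= ``max_gap`` adjacency, hence invariant to input order. Unassigned
    events are ignored.
    """
    partitions: dict[tuple[str, str, str, str], list[MobilizationEvent]] = {}
    for ev in events:
        if not ev.assigned:
            continue
        key = (ev.library_id, ev.replicon_id, ev.sv_class, ev.element_id)
        partitions.setdefault(key, []).append(ev)
    clusters: list[EventCluster] = []
    for (library, replicon, sv_class, element), members in sorted(partitions.items()):
        members.sort(key=lambda ev: ev.start)
        chain: list[int] = [members[0].start]
        for ev in members[1:]:
            if ev.start - chain[-1] <= max_gap:
                chain.append(ev.start)
            else:
                clusters.append(
                    EventCluster(library, replicon, sv_class, element,
                                 mean_start=float(np.mean(chain)), e=len(chain))
                )
                chain = [ev.start]
        clusters.append(
            EventCluster(library, replicon, sv_class, element,
                         mean_start=float(np.mean(chain)), e=len(chain))
        )
    return clusters


def local_coverage(depth_track: CoverageTrack, position: int, flank: int = 25) -> float:
    """Mean per-base read depth over a bidirectional flank around a position.

    ``position`` is 0-based; the window spans ``[position - flank,
    position + flank]`` (2*flank + 1 positions), clipped at the track
    bounds. Zero coverage over the whole window is an error — a support
    index cannot be formed there.
    """
    lo = max(position - flank, depth_track.origin)
    hi = min(position + flank + 1, depth_track.end)
    if hi <= lo:
        raise ValueError(f"window around {position} lies outside the depth track")
    window = depth_track.values[lo - depth_track.origin : hi - depth_track.origin]
    c = float(window.mean())
    if c == 0:
        raise ValueError(f"zero local coverage around position {position}")
    return c


def classify_cluster(e: int, c: float) -> str:
    """Population class of a mobilization from its support index e/c.

    rare: e/c <= 0.1; common: 0.1 < e/c <= 0.5; predominant: e/c > 0.5
    (an SV that may be fixed in the population's genomes).
    """
    if c <= 0:
        raise ValueError("local coverage must be > 0")
    ratio = e / c
    if ratio <= 0.1:
        return "rare"
    if ratio <= 0.5:
        return "common"
    return "predominant"


def annotate_clusters(
    clusters: Sequence[EventCluster],
    depth_tracks: Mapping[tuple[str, str], CoverageTrack],
    flank: int = 25,
) -> list[EventCluster]:
    """Fill in local coverage ``c`` and the population class of each cluster.

    ``depth_tracks`` maps (library_id, replicon_id) to the library's read
    depth track; the cluster's mean start (1-based) is converted to the
    track's 0-based coordinates before windowing.
    """
    for cluster in clusters:
        track = depth_tracks[(cluster.library_id, cluster.replicon_id)]
        position = int(round(cluster.mean_start)) - 1
        cluster.c = local_coverage(track, position, flank=flank)
        cluster.population_class = classify_cluster(cluster.e, cluster.c)
    return list(clusters)


def normalize_counts(
    cluster_counts: Mapping[str, float], aligned_reads: Mapping[str, int]
) -> dict[str, float]:
    """Depth-normalize per-library cluster counts.

    Libraries are adjusted up to the most deeply sequenced one: the scale
    factor of library i is max_j(reads_j) / reads_i, so the reference
    library's count is unchanged and shallower libraries are scaled up.
    """
    if set(cluster_counts) - set(aligned_reads):
        raise ValueError("every library needs an aligned-read count")
    if any(aligned_reads[lib] <= 0 for lib in cluster_counts):
        raise ValueError("aligned read counts must be positive")
    max_reads = max(aligned_reads[lib] for lib in cluster_counts)
    return {
        lib: cluster_counts[lib] * max_reads / aligned_reads[lib]
        for lib in cluster_counts
    }


def compare_strains(values_by_strain: Mapping[str, Sequence[float]]) -> StrainComparison:
    """Compare mean normalized mobilization counts of two strains.

    The interval for each strain is mean +/- one standard error (a 68%
    confidence interval under normality); the strains are called
    ``different`` when the intervals are disjoint. With fewer than two
    replicates in either strain the verdict is ``insufficient_replicates``.
    """
    if len(values_by_strain) != 2:
        raise ValueError("exactly two strains are compared")
    strains = tuple(values_by_strain)
    values = {s: [float(v) for v in values_by_strain[s]] for s in strains}
    means = {s: float(np.mean(v)) for s, v in values.items()}
    if any(len(v) < 2 for v in values.values()):
        se = {s: float("nan") for s in strains}
        ci = {s: (float("nan"), float("nan")) for s in strains}
        return StrainComparison(strains, values, means, se, ci, "insufficient_replicates")
    se = {s: float(np.std(v, ddof=1) / np.sqrt(len(v))) for s, v in values.items()}
    ci = {s: (means[s] - se[s], means[s] + se[s]) for s in strains}
    a, b = strains
    disjoint = ci[a][1] < ci[b][0] or ci[b][1] < ci[a][0]
    return StrainComparison(
        strains, values, means, se, ci, "different" if disjoint else "not_different"
    )
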