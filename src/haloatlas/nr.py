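"""Nonredundant reference construction by greedy identity clustering.

Archaeal genomes such as Halobacterium salinarum NRC-1 carry quasi-identical
paralogs (mostly within plasmid repeats and multicopy insertion sequences),
and successive annotation efforts have produced overlapping locus-tag
namespaces. Collapsing coding sequences at >= 95% global amino-acid identity
and noncoding sequences at >= 99% global nucleotide identity yields a
nonredundant reference in which each cluster is represented by a single
entity, plus a dictionary mapping every member back to its representative.

Clustering is greedy and longest-first (the strategy of CD-HIT): sequences
are sorted by decreasing length (ties broken by id), and each sequence joins
the first existing cluster whose representative it matches at or above the
identity threshold, otherwise it founds a new cluster. The result is
deterministic and invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

NUCLEOTIDE_ALPHABET = frozenset("ACGTUN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU*")


@dataclass
class SequenceCluster:
    """One cluster of (quasi-)identical sequences.

    The representative is the longest member (ties broken by lexical id);
    every member's global identity to the representative is at least
    ``identity_threshold``.
    """

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identity_threshold: float = 0.95
    mode: str = "protein"


def _validate(seq: str, mode: str, name: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    alphabet = PROTEIN_ALPHABET if mode == "protein" else NUCLEOTIDE_ALPHABET
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"{name}: invalid {mode} characters {sorted(bad)}")
    return seq


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def global_identity(
    seq_a: str,
    seq_b: str,
    mode: str = "protein",
    denominator: str = "alignment",
) -> float:
    """Global (Needleman-Wunsch) identity between two sequences.

    Scoring is match +1, mismatch 0, linear gap -1. Identity is the number
    of identical aligned columns divided by the alignment length
    (``denominator="alignment"``) or by the shorter sequence length
    (``denominator="shorter"``, the CD-HIT convention).
    """
    if mode not in ("protein", "nucleotide"):
        raise ValueError(f"mode must be 'protein' or 'nucleotide', got {mode!r}")
    if denominator not in ("alignment", "shorter"):
        raise ValueError(f"unknown denominator {denominator!r}")
    seq_a = _validate(seq_a, mode, "seq_a")
    seq_b = _validate(seq_b, mode, "seq_b")
    alignment = _aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    denom = aln_len if denominator == "alignment" else min(len(seq_a), len(seq_b))
    return counts.identities / denom


def cluster_sequences(
    records: list[tuple[str, str]],
    identity_threshold: float,
    mode: str = "protein",
    denominator: str = "alignment",
) -> tuple[list[SequenceCluster], pd.DataFrame]:
    """Greedy longest-first clustering of sequences at a global identity
    threshold (inclusive).

    Returns the clusters and a two-column dictionary table mapping every
    member id to its representative id.
    """
    ids = [name for name, _ in records]
    if len(ids) != len(set(ids)):
        raise ValueError("sequence ids must be unique")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[SequenceCluster] = []
    representatives: list[str] = []  # sequences, parallel to clusters
    for name, seq in ordered:
        seq = _validate(seq, mode, name)
        placed = False
        for cluster, rep_seq in zip(clusters, representatives):
            if global_identity(rep_seq, seq, mode, denominator) >= identity_threshold:
                cluster.member_ids.append(name)
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(
                    representative_id=name,
                    member_ids=[name],
                    identity_threshold=identity_threshold,
                    mode=mode,
                )
            )
            representatives.append(seq)
    dictionary = pd.DataFrame(
        [
            {"member_id": member, "representative_id": cluster.representative_id}
            for cluster in clusters
            for member in cluster.member_ids
        ]
    ).set_index("member_id")
    return clusters, dictionary
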