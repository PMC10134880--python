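"""RIP-Seq binding-region detection from IP versus control coverage.

The caller works on per-nucleotide coverage tracks of an immunoprecipitated
(IP) library and a mock/control library. It computes a coordinate-wise
log2 fold change LFC[i] = log2((s_ip*ip[i] + q) / (s_ctrl*ctrl[i] + q)) and
reports maximal runs of at least ``min_run_length`` consecutive positions
with LFC at or above ``lfc_threshold`` as binding regions. Regions from
biological replicates are merged by interval union, regions are assigned to
annotated genes by strand-aware overlap, and the replicate agreement at the
gene level is scored with an intersection-enrichment test.

Two knobs the raw procedure leaves open are made explicit:

- ``pseudocount`` (default 1.0) is added to both numerator and denominator
  after scaling, keeping the LFC finite where the control has no coverage.
- ``library_scaling`` (default ``"total-count"``) rescales both libraries
  to the mean total of the pair, so unequal sequencing depth does not shift
  every coordinate's LFC; ``"none"`` disables it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from haloatlas.io import CoverageTrack, GeneRecord
from haloatlas.stats import HypergeomResult, hypergeom_enrichment


@dataclass
class LfcTrack:
    """Coordinate-wise log2(IP/control) values over one strand of a replicon."""

    replicon_id: str
    strand: str
    lfc: np.ndarray
    origin: int = 0
    pseudocount: float = 1.0
    scale_factors: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.lfc = np.asarray(self.lfc, dtype=float)
        if not np.all(np.isfinite(self.lfc)):
            raise ValueError("LFC track contains non-finite values")


@dataclass(frozen=True)
class BindingRegion:
    """A maximal run of consecutive above-threshold LFC positions."""

    replicon_id: str
    strand: str
    start: int
    end: int
    min_lfc_in_region: float
    replicate_support: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return self.end - self.start


def compute_lfc_track(
    ip: CoverageTrack,
    ctrl: CoverageTrack,
    pseudocount: float = 1.0,
    library_scaling: str = "total-count",
) -> LfcTrack:
    """Coordinate-wise log2 fold change of IP over control coverage."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if library_scaling not in ("none", "total-count"):
        raise ValueError(f"unknown library_scaling {library_scaling!r}")
    if (ip.replicon_id, ip.strand, ip.origin, len(ip)) != (
        ctrl.replicon_id,
        ctrl.strand,
        ctrl.origin,
        len(ctrl),
    ):
        raise ValueError("IP and control tracks must cover the same replicon/strand/extent")
    if library_scaling == "total-count":
        total_ip, total_ctrl = ip.values.sum(), ctrl.values.sum()
        target = (total_ip + total_ctrl) / 2
        s_ip = target / total_ip if total_ip > 0 else 1.0
        s_ctrl = target / total_ctrl if total_ctrl > 0 else 1.0
    else:
        s_ip = s_ctrl = 1.0
    lfc = np.log2((s_ip * ip.values + pseudocount) / (s_ctrl * ctrl.values + pseudocount))
    return LfcTrack(
        replicon_id=ip.replicon_id,
        strand=ip.strand,
        lfc=lfc,
        origin=ip.origin,
        pseudocount=pseudocount,
        scale_factors=(s_ip, s_ctrl),
    )


def call_binding_regions(
    track: LfcTrack,
    lfc_threshold: float = 1.0,
    min_run_length: int = 10,
    replicate_id: str | None = None,
) -> list[BindingRegion]:
    """Report maximal runs of >= ``min_run_length`` consecutive positions
    with LFC >= ``lfc_threshold``.

    The threshold is inclusive, runs are never joined across a single
    sub-threshold position, and regions are reported maximal (not trimmed
    or extended).
    """
    if lfc_threshold <= 0 or min_run_length <= 0:
        raise ValueError("thresholds must be positive")
    above = track.lfc >= lfc_threshold
    support = frozenset([replicate_id]) if replicate_id else frozenset()
    regions: list[BindingRegion] = []
    # boundaries of runs of True in the boolean mask
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        if run_end - run_start < min_run_length:
            continue
        regions.append(
            BindingRegion(
                replicon_id=track.replicon_id,
                strand=track.strand,
                start=track.origin + int(run_start),
                end=track.origin + int(run_end),
                min_lfc_in_region=float(track.lfc[run_start:run_end].min()),
                replicate_support=support,
            )
        )
    return regions


def merge_replicates(*region_lists: list[BindingRegion]) -> list[BindingRegion]:
    """Interval union of binding regions across replicates.

    Overlapping or book-ended intervals on the same (replicon, strand)
    coalesce; the replicate support of a merged interval is the union of the
    supports of its contributors. Idempotent and commutative.
    """
    pooled = [r for regions in region_lists for r in regions]
    by_key: dict[tuple[str, str], list[BindingRegion]] = {}
    for r in pooled:
        by_key.setdefault((r.replicon_id, r.strand), []).append(r)
    merged: list[BindingRegion] = []
    for (replicon, strand), regions in sorted(by_key.items()):
        regions.sort(key=lambda r: (r.start, r.end))
        current = regions[0]
        for nxt in regions[1:]:
            if nxt.start <= current.end:  # overlap or book-ended
                current = replace(
                    current,
                    end=max(current.end, nxt.end),
                    min_lfc_in_region=min(current.min_lfc_in_region, nxt.min_lfc_in_region),
                    replicate_support=current.replicate_support | nxt.replicate_support,
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    return merged


def assign_regions_to_genes(
    regions: list[BindingRegion],
    annotation: list[GeneRecord],
    min_overlap: int = 1,
    same_strand: bool = True,
) -> pd.DataFrame:
    """Flag each annotated gene as bound if at least one region overlaps it.

    A gene counts as bound when some region overlaps it by at least
    ``min_overlap`` nucleotides, by default on the same strand. Returns a
    table indexed by gene id with a boolean ``bound`` column and the
    supporting region intervals.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    rows = []
    for gene in annotation:
        supporting = []
        for region in regions:
            if region.replicon_id != gene.replicon_id:
                continue
            if same_strand and region.strand != gene.strand:
                continue
            overlap = min(region.end, gene.end) - max(region.start, gene.start)
            if overlap >= min_overlap:
                supporting.append(f"{region.start}-{region.end}({region.strand})")
        rows.append(
            {
                "gene_id": gene.gene_id,
                "bound": bool(supporting),
                "n_regions": len(supporting),
                "regions": ";".join(supporting),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def replicate_intersection_enrichment(
    genes_br1: set[str],
    genes_br2: set[str],
    universe_n: int,
) -> tuple[int, float, float, float]:
    """Enrichment of the gene-level agreement between two replicates.

    For bound-gene sets A and B inside a universe of ``universe_n`` genes,
    the expected intersection under independence is |A|*|B|/N. Returns
    ``(observed, expected, fold, p)`` where p is the upper-tail
    hypergeometric probability of an intersection at least as large.
    """
    if universe_n < max(len(genes_br1), len(genes_br2)):
        raise ValueError("universe smaller than one of the gene sets")
    observed = len(genes_br1 & genes_br2)
    expected = len(genes_br1) * len(genes_br2) / universe_n
    fold = observed / expected if expected > 0 else float("nan")
    res: HypergeomResult = hypergeom_enrichment(
        observed, len(genes_br1), len(genes_br2), universe_n
    )
    return observed, expected, fold, res.p_upper
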