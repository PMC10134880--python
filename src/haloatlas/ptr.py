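"""Inference of putatively post-transcriptionally regulated (PTR) genes.

Two complementary procedures flag genes whose protein output is discordant
with their mRNA levels:

1. **Absolute-abundance approach** — per physiological state, a gene is a
   candidate when its mRNA sits in the upper quintile of the cohort while
   its protein sits in the lower quintile of detected proteins
   (``candidate_detected``) or was never detected by the proteomic assay
   (``candidate_undetected``).

2. **Relative-abundance approach** — across state transitions, a gene is a
   candidate when its mRNA is significantly upregulated while its protein
   is significantly downregulated (|log2 fold change| >= 1 and adjusted
   p < 0.05 on both sides by default).

Undetected-protein candidates are filtered to remove genes whose lack of
detection is plausibly technical rather than regulatory: predicted
transmembrane proteins, proteins absent from the spectral assay library,
and proteins yielding no suitable tryptic peptide (length 7-30) on in
silico digestion. Every exclusion is logged with its reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class QuintileCall:
    """Per-gene, per-state classification by the absolute-abundance rule."""

    gene_id: str
    timepoint: str
    mrna_quintile: int  # 1 (lowest fifth) .. 5 (highest)
    protein_status: str  # "quintile 1".."quintile 5" | "undetected"
    category: str  # candidate_detected | candidate_undetected | none


@dataclass(frozen=True)
class TransitionCall:
    """Per-gene classification of one state transition by the relative rule."""

    gene_id: str
    transition: str
    mrna_lfc: float
    mrna_p: float
    protein_lfc: float
    protein_p: float
    category: str  # e.g. mrna_up_protein_down


@dataclass
class PtrCandidate:
    """A gene flagged PTR by either approach, with its evidence trail."""

    gene_id: str
    evidence: set[str] = field(default_factory=set)
    timepoints: set[str] = field(default_factory=set)
    transitions: set[str] = field(default_factory=set)


def quintile_thresholds(
    values: Sequence[float], detected_only: bool = True
) -> tuple[float, float]:
    """20th and 80th percentiles (linear interpolation) of a value cohort.

    With ``detected_only`` missing values are excluded before the
    percentiles are computed; at least 5 detected values are required.
    """
    arr = np.asarray(values, dtype=float)
    if detected_only:
        arr = arr[~np.isnan(arr)]
    if arr.size < 5:
        raise ValueError(f"need at least 5 detected values, got {arr.size}")
    return float(np.percentile(arr, 20)), float(np.percentile(arr, 80))


def _quintile_of(value: float, cohort: np.ndarray) -> int:
    """1-based quintile index of a value within its cohort (1 = lowest)."""
    edges = np.percentile(cohort, [20, 40, 60, 80])
    return int(np.searchsorted(edges, value, side="left")) + 1


def absolute_approach(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    candidates_only: bool = True,
) -> list[QuintileCall]:
    """Quintile-based PTR candidate calling, one call per gene and state.

    ``mrna`` and ``protein`` are genes-by-states tables on a common index;
    missing protein entries mean the gene's protein was undetected in that
    state. Boundary values are inclusive (mRNA >= q80, protein <= q20).
    With ``candidates_only`` only candidate calls are returned.
    """
    if list(mrna.columns) != list(protein.columns):
        raise ValueError("mRNA and protein tables must share state columns")
    calls: list[QuintileCall] = []
    for tp in mrna.columns:
        m = mrna[tp].astype(float)
        p = protein[tp].astype(float)
        m_cohort = m.dropna().to_numpy()
        _, m_q80 = quintile_thresholds(m_cohort, detected_only=False)
        p_detected = p.dropna().to_numpy()
        p_q20, _ = quintile_thresholds(p_detected, detected_only=False)
        for gene in mrna.index:
            m_val, p_val = m[gene], p[gene]
            if np.isnan(m_val):
                continue
            undetected = np.isnan(p_val)
            if undetected:
                protein_status = "undetected"
            else:
                protein_status = f"quintile {_quintile_of(p_val, p_detected)}"
            high_mrna = m_val >= m_q80
            if high_mrna and undetected:
                category = "candidate_undetected"
            elif high_mrna and p_val <= p_q20:
                category = "candidate_detected"
            else:
                category = "none"
            if candidates_only and category == "none":
                continue
            calls.append(
                QuintileCall(
                    gene_id=str(gene),
                    timepoint=str(tp),
                    mrna_quintile=_quintile_of(m_val, m_cohort),
                    protein_status=protein_status,
                    category=category,
                )
            )
    return calls


def tryptic_digest(
    protein_seq: str, min_len: int = 7, max_len: int = 30
) -> tuple[list[str], bool]:
    """In silico trypsin digestion with zero missed cleavages.

    Cleaves C-terminally of K or R except when the next residue is P.
    Returns the peptides and whether at least one has a length in
    ``[min_len, max_len]`` (i.e. is suitable for detection by targeted MS).
    """
    seq = protein_seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid amino-acid residues {sorted(bad)}")
    if not seq:
        raise ValueError("empty protein sequence")
    peptides = [p for p in re.split(r"(?<=[KR])(?!P)", seq) if p]
    suitable = any(min_len <= len(p) <= max_len for p in peptides)
    return peptides, suitable


def filter_undetected(
    candidates_undetected: Iterable[str],
    tm_probability: Mapping[str, float],
    in_assay_library: Iterable[str],
    protein_seqs: Mapping[str, str],
    tm_cutoff: float = 0.9,
    manual_exclusions: Iterable[str] = (),
) -> tuple[list[str], pd.DataFrame]:
    """Remove undetected-protein candidates whose missingness is likely
    technical.

    A candidate is excluded when its transmembrane-domain probability is at
    or above ``tm_cutoff``, when it is absent from the spectral assay
    library, when its in silico tryptic digest yields no suitable peptide,
    or when it appears on an explicit manual exclusion list (annotation
    mismatches curated by hand). Returns the retained genes and an
    exclusion log with one row per removed gene listing every triggered
    reason.
    """
    library = frozenset(in_assay_library)
    manual = frozenset(manual_exclusions)
    retained: list[str] = []
    log_rows = []
    for gene in candidates_undetected:
        reasons = []
        if tm_probability.get(gene, 0.0) >= tm_cutoff:
            reasons.append("transmembrane")
        if gene not in library:
            reasons.append("not_in_assay_library")
        if gene in protein_seqs:
            _, suitable = tryptic_digest(protein_seqs[gene])
            if not suitable:
                reasons.append("no_suitable_tryptic_peptide")
        if gene in manual:
            reasons.append("manual")
        if reasons:
            log_rows.append({"gene_id": gene, "reasons": ";".join(reasons)})
        else:
            retained.append(gene)
    log = pd.DataFrame(log_rows, columns=["gene_id", "reasons"])
    return retained, log


def _de_status(lfc: float, p: float, lfc_cut: float, p_cut: float) -> str:
    if np.isnan(lfc) or np.isnan(p) or abs(lfc) < lfc_cut or p >= p_cut:
        return "ns"
    return "up" if lfc > 0 else "down"


def relative_approach(
    mrna_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
    p_kind: str = "adjusted",
) -> list[TransitionCall]:
    """Classify genes per state transition by joint mRNA/protein DE status.

    ``mrna_de`` and ``protein_de`` carry one row per gene and transition
    with columns ``transition``, ``lfc`` and ``p`` / ``p_adj``. Each gene
    falls into one of nine categories ``mrna_{up,down,ns}_protein_{...}``;
    the PTR-relevant class is ``mrna_up_protein_down``. ``p_kind`` selects
    adjusted or raw p-values (array-based knockout contrasts use raw p).
    """
    if p_kind not in ("adjusted", "raw"):
        raise ValueError(f"p_kind must be 'adjusted' or 'raw', got {p_kind!r}")
    p_col = "p_adj" if p_kind == "adjusted" else "p"
    merged = mrna_de.reset_index().merge(
        protein_de.reset_index(),
        on=["gene_id", "transition"],
        suffixes=("_mrna", "_protein"),
        how="inner",
    )
    calls: list[TransitionCall] = []
    for row in merged.itertuples(index=False):
        m_lfc, m_p = getattr(row, "lfc_mrna"), getattr(row, f"{p_col}_mrna")
        p_lfc, p_p = getattr(row, "lfc_protein"), getattr(row, f"{p_col}_protein")
        category = (
            f"mrna_{_de_status(m_lfc, m_p, lfc_cut, p_cut)}"
            f"_protein_{_de_status(p_lfc, p_p, lfc_cut, p_cut)}"
        )
        calls.append(
            TransitionCall(
                gene_id=str(row.gene_id),
                transition=str(row.transition),
                mrna_lfc=float(m_lfc),
                mrna_p=float(m_p),
                protein_lfc=float(p_lfc),
                protein_p=float(p_p),
                category=category,
            )
        )
    return calls


def naive_de(
    table: pd.DataFrame,
    group_a_cols: Sequence[str],
    group_b_cols: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Simple per-gene differential test between two replicate groups.

    Welch's t-test on log2(value + pseudocount) with Benjamini-Hochberg
    adjustment; the log2 fold change is group B minus group A. Intended for
    exercising synthetic pipelines end to end, not as a replacement for a
    count- or intensity-aware DE model. Requires >= 2 replicates per group.
    """
    if len(group_a_cols) < 2 or len(group_b_cols) < 2:
        raise ValueError("need at least 2 replicates per group")
    a = np.log2(table[list(group_a_cols)].astype(float) + pseudocount)
    b = np.log2(table[list(group_b_cols)].astype(float) + pseudocount)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    p = pd.Series(p, index=table.index)
    # degenerate zero-variance genes: identical groups are null, shifted are not
    degenerate = p.isna()
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = 0.0
    out = pd.DataFrame({"lfc": lfc, "p": p})
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out.index.name = "gene_id"
    return out


def integrate_candidates(
    quintile_calls: Iterable[QuintileCall],
    transition_calls: Iterable[TransitionCall],
) -> list[PtrCandidate]:
    """Union of the two evidence streams into one PTR candidate per gene.

    Evidence tags are ``absolute_detected``, ``absolute_undetected`` and
    ``relative`` (the latter only for the mrna_up_protein_down class); a
    gene supported by both approaches carries multiple tags.
    """
    by_gene: dict[str, PtrCandidate] = {}

    def _get(gene_id: str) -> PtrCandidate:
        return by_gene.setdefault(gene_id, PtrCandidate(gene_id=gene_id))

    for call in quintile_calls:
        if call.category == "candidate_detected":
            cand = _get(call.gene_id)
            cand.evidence.add("absolute_detected")
            cand.timepoints.add(call.timepoint)
        elif call.category == "candidate_undetected":
            cand = _get(call.gene_id)
            cand.evidence.add("absolute_undetected")
            cand.timepoints.add(call.timepoint)
    for call in transition_calls:
        if call.category == "mrna_up_protein_down":
            cand = _get(call.gene_id)
            cand.evidence.add("relative")
            cand.transitions.add(call.transition)
    return sorted(by_gene.values(), key=lambda c: c.gene_id)


def candidates_to_table(candidates: Iterable[PtrCandidate]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "evidence": ";".join(sorted(c.evidence)),
            "timepoints": ";".join(sorted(c.timepoints)),
            "transitions": ";".join(sorted(c.transitions)),
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["gene_id", "evidence", "timepoints", "transitions"]).set_index(
        "gene_id"
    )
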