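"""Assembly of the per-gene multi-omics atlas.

The atlas integrates, for each nonredundant gene, protein intensities
(SWATH-MS), mRNA abundances (RNA-Seq TPM) and ribosome-protected fragment
abundances (Ribo-Seq TPM) across four growth phases, together with derived
quantities (translational efficiency TE = protein/mRNA, ribosome occupancy
RO = RPF/mRNA, codon adaptation index, GC-content deviation, mRNA
half-life) and per-gene regulatory feature flags.

Because the three layers are measured on incommensurate scales, each time
point's genes-by-layers matrix is quantile normalized before ratios are
formed. Replicate measurements are averaged first, so one column per layer
represents each physiological state. Missing protein values (genes never
detected by the proteomic assay) are excluded from rank computation and
restored as missing, never imputed into the statistics; an optional display
pseudocount exists purely for visualization exports.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "quantile_normalize",
    "average_replicates",
    "compute_te_ro",
    "lag_correlations",
    "synonymous_families",
    "compute_cai_weights",
    "compute_cai",
    "gc_content",
    "gc_deviation",
    "average_half_lives",
    "assemble_atlas",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across the columns of a genes-by-layers matrix.

    After normalization every column holds the same sorted values: the
    per-rank means of the column-sorted input. Ties within a column receive
    the mean of the reference values at their tied ranks. Missing entries
    are excluded from rank computation and restored as missing; columns with
    missing values are mapped through quantile interpolation against the
    common reference distribution.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to quantile normalize")
    values = matrix.to_numpy(dtype=float)
    n_rows = values.shape[0]
    if n_rows == 0:
        raise ValueError("empty matrix")
    grid = np.linspace(0.0, 1.0, n_rows)
    # reference distribution: mean across columns of each column's sorted
    # non-missing values, interpolated onto a common quantile grid
    per_column = []
    for j in range(values.shape[1]):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        if col.size == 0:
            raise ValueError(f"column {matrix.columns[j]!r} has no detected values")
        if col.size == 1:
            per_column.append(np.full(n_rows, col[0]))
        else:
            per_column.append(np.interp(grid, np.linspace(0.0, 1.0, col.size), col))
    reference = np.mean(per_column, axis=0)
    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        present = ~np.isnan(values[:, j])
        col = values[present, j]
        # average ranks handle ties as the mean of tied reference values
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(col.size)
        ranks[order] = np.arange(col.size, dtype=float)
        for value in np.unique(col):
            tied = col == value
            ranks[tied] = ranks[tied].mean()
        q = ranks / (col.size - 1) if col.size > 1 else np.full(col.size, 0.5)
        out[present, j] = np.interp(q, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def average_replicates(table: pd.DataFrame, sep: str = "_R") -> pd.DataFrame:
    """Average replicate columns named like ``TP1_R1``, ``TP1_R2`` into one
    column per condition (``TP1``). Missing replicate values are ignored in
    the mean; a condition missing in all replicates stays missing."""
    groups = table.columns.str.split(sep).str[0]
    return table.T.groupby(groups).mean().T


# ---------------------------------------------------------------------------
# derived per-gene quantities
# ---------------------------------------------------------------------------

def compute_te_ro(
    protein: pd.DataFrame,
    mrna: pd.DataFrame,
    rpf: pd.DataFrame,
    pseudocount: float = 1.0,
    log2: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translational efficiency and ribosome occupancy per gene per state.

    TE = protein / (mRNA + pseudocount); RO = RPF / (mRNA + pseudocount).
    The pseudocount on the mRNA denominator follows the atlas convention of
    reporting mRNA as TPM+1. Missing protein propagates to TE only. With
    ``log2=True`` both ratios are returned in log2 units.
    """
    denom = mrna + pseudocount
    te = protein / denom
    ro = rpf / denom
    if log2:
        with np.errstate(divide="ignore"):
            te = np.log2(te)
            ro = np.log2(ro)
    return te, ro


def lag_correlations(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    log_transform: bool = True,
    pseudocount: float = 1.0,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of protein levels at state j with mRNA levels at
    state i, for every i <= j (same-state diagonal plus all positive lags).

    Values are log10(v + pseudocount)-transformed by default; pairs with a
    missing member are dropped per cell. Cells with fewer than ``min_pairs``
    complete pairs are reported missing with a warning.
    """
    timepoints = list(mrna.columns)
    if list(protein.columns) != timepoints:
        raise ValueError("mRNA and protein tables must share time-point columns")
    m = np.log10(mrna + pseudocount) if log_transform else mrna.astype(float)
    p = np.log10(protein + pseudocount) if log_transform else protein.astype(float)
    out = pd.DataFrame(np.nan, index=timepoints, columns=timepoints)
    out.index.name = "mrna_tp"
    out.columns.name = "protein_tp"
    for i, tp_m in enumerate(timepoints):
        for j, tp_p in enumerate(timepoints):
            if i > j:
                continue
            paired = pd.concat([m[tp_m], p[tp_p]], axis=1).dropna()
            if len(paired) < min_pairs:
                warnings.warn(
                    f"fewer than {min_pairs} complete pairs for mRNA {tp_m} vs protein {tp_p}"
                )
                continue
            out.loc[tp_m, tp_p] = paired.iloc[:, 0].corr(paired.iloc[:, 1])
    return out


# ---------------------------------------------------------------------------
# codon adaptation index
# ---------------------------------------------------------------------------

def synonymous_families(table_id: int = 11) -> dict[str, list[str]]:
    """Synonymous codon families (amino acid -> codons), stops excluded.

    Defaults to the bacterial/archaeal genetic code (translation table 11).
    """
    table = unambiguous_dna_by_id[table_id]
    families: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    return {aa: sorted(codons) for aa, codons in families.items()}


def _codons(seq: str, name: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def compute_cai_weights(
    reference_cds: Iterable[tuple[str, str]],
    table_id: int = 11,
    zero_count: float = 0.5,
) -> dict[str, float]:
    """Relative adaptiveness w of each codon from a reference gene set.

    The reference is typically the coding sequences of the most abundant
    proteins (here the proteomic top 5%). Within each synonymous family,
    RSCU_c = count_c / mean(count in family) and w_c = RSCU_c / max RSCU
    in the family. Codons never seen in the reference receive a count of
    ``zero_count`` before RSCU is formed; single-codon families (Met, Trp
    in table 11) get w = 1; stop codons are excluded. A stop codon before
    the final position is an in-frame error naming the offending sequence.
    """
    families = synonymous_families(table_id)
    stops = set(unambiguous_dna_by_id[table_id].stop_codons)
    counts: Counter[str] = Counter()
    for name, seq in reference_cds:
        codons = _codons(seq, name)
        for i, codon in enumerate(codons):
            if codon in stops:
                if i != len(codons) - 1:
                    raise ValueError(f"{name}: premature stop codon {codon} at codon {i + 1}")
                continue
            counts[codon] += 1
    weights: dict[str, float] = {}
    for codons in families.values():
        if len(codons) == 1:
            weights[codons[0]] = 1.0
            continue
        family_counts = np.array(
            [counts[c] if counts[c] > 0 else zero_count for c in codons], dtype=float
        )
        max_count = family_counts.max()
        for codon, count in zip(codons, family_counts):
            weights[codon] = count / max_count
    return weights


def compute_cai(gene_cds: str, weights: Mapping[str, float], table_id: int = 11) -> float:
    """Codon adaptation index: geometric mean of the adaptiveness weights
    over a gene's non-stop codons. Invariant to codon order; equals 1 iff
    every codon is family-maximal."""
    stops = set(unambiguous_dna_by_id[table_id].stop_codons)
    codons = [c for c in _codons(gene_cds, "gene") if c not in stops]
    if not codons:
        raise ValueError("gene has no non-stop codons")
    log_sum = 0.0
    for codon in codons:
        if codon not in weights:
            raise ValueError(f"codon {codon} has no adaptiveness weight")
        log_sum += math.log(weights[codon])
    return math.exp(log_sum / len(codons))


# ---------------------------------------------------------------------------
# sequence composition and half-lives
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """Fraction of G+C in a nucleotide sequence."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_deviation(seqs: Iterable[tuple[str, str]]) -> pd.Series:
    """Per-gene GC content minus the cohort mean GC content."""
    gc = pd.Series({name: gc_content(seq) for name, seq in seqs}, dtype=float)
    return gc - gc.mean()


def average_half_lives(
    half_life: pd.Series, cluster_dictionary: pd.DataFrame
) -> pd.Series:
    """Collapse member-level mRNA half-lives (minutes) to per-representative
    means, using the nonredundant-transcriptome dictionary. Missing members
    are ignored rather than dropping the whole cluster."""
    rep = cluster_dictionary["representative_id"]
    joined = pd.DataFrame({"half_life": half_life}).join(rep, how="inner")
    return joined.groupby("representative_id")["half_life"].mean()


# ---------------------------------------------------------------------------
# atlas assembly
# ---------------------------------------------------------------------------

def assemble_atlas(
    protein: pd.DataFrame,
    mrna: pd.DataFrame,
    rpf: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    cds: Mapping[str, str] | None = None,
    half_life: pd.Series | None = None,
    cai_weights: Mapping[str, float] | None = None,
    te_ro_pseudocount: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Build the integrated per-gene atlas table.

    Inputs are replicate-level abundance tables (columns like ``TP1_R1``)
    or already-averaged per-state tables. Replicates are averaged, the
    genes-by-layers matrix of each state is quantile normalized, and log2
    TE/RO are derived. Feature flags, CAI, GC deviation and half-lives are
    joined where provided. One row per gene of the mRNA universe; fields a
    gene lacks stay missing. Re-assembly of the same inputs is idempotent.
    """
    layers = {"protein": protein, "mrna": mrna, "rpf": rpf}
    averaged: dict[str, pd.DataFrame] = {}
    for name, table in layers.items():
        table = table.reindex(mrna.index)
        if table.columns.str.contains("_R").any():
            table = average_replicates(table)
        averaged[name] = table
    timepoints = list(averaged["mrna"].columns)
    if normalize:
        for tp in timepoints:
            stacked = pd.DataFrame({name: averaged[name][tp] for name in layers})
            norm = quantile_normalize(stacked)
            for name in layers:
                averaged[name][tp] = norm[name]
    te, ro = compute_te_ro(
        averaged["protein"],
        averaged["mrna"],
        averaged["rpf"],
        pseudocount=te_ro_pseudocount,
        log2=True,
    )
    blocks = {
        "protein": averaged["protein"],
        "mrna": averaged["mrna"],
        "rpf": averaged["rpf"],
        "te": te,
        "ro": ro,
    }
    atlas = pd.concat(
        {name: block for name, block in blocks.items()}, axis=1
    )
    atlas.columns = [f"{layer}_{tp}" for layer, tp in atlas.columns]
    if flags is not None:
        atlas = atlas.join(flags)
    if cds is not None:
        atlas = atlas.join(gc_deviation(cds.items()).rename("gc_dev"))
        if cai_weights is None:
            cai_weights = compute_cai_weights(list(cds.items()))
        atlas = atlas.join(
            pd.Series(
                {g: compute_cai(s, cai_weights) for g, s in cds.items()}, name="cai"
            )
        )
    if half_life is not None:
        atlas = atlas.join(half_life.rename("half_life"))
    atlas.index.name = "gene_id"
    return atlas


def atlas_to_long(atlas: pd.DataFrame) -> pd.DataFrame:
    """Long-format export of the per-state atlas layers (one row per gene,
    layer and state), convenient for plotting and viewers."""
    layer_cols = [c for c in atlas.columns if "_TP" in c]
    long = atlas[layer_cols].reset_index().melt(id_vars="gene_id", var_name="key")
    long[["layer", "timepoint"]] = long["key"].str.rsplit("_", n=1, expand=True)
    return long.drop(columns="key")[["gene_id", "layer", "timepoint", "value"]]
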