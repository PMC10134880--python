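"""Synthetic-data generators with planted ground truth.

Every pipeline stage can be exercised without any external download: each
generator here emits inputs in the exact shapes the analysis modules
consume, together with a :class:`TruthTable` recording what was planted, so
recovery can be tested mechanically. All generators draw from a single
explicitly seeded pseudo-random stream (no global state); identical seeds
and parameters give byte-identical outputs.

Noise models are deliberately simple and standard: Poisson for sequencing
depth, log-normal for abundance measurements. With noise switched off,
planted signal is recoverable exactly by construction, which is what the
plant-recover test suites assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from haloatlas.io import CoverageTrack, SvRecord

DNA = np.array(list("ACGT"))


@dataclass
class TruthTable:
    """Ground truth planted by a generator, keyed for recovery tests."""

    kind: str  # binding_regions | ptr_genes | sv_clusters | feature_flags
    records: list[dict]
    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RIP-Seq coverage
# ---------------------------------------------------------------------------

def gen_coverage_pair(
    genome_len: int,
    n_regions: int,
    region_len_range: tuple[int, int] = (10, 200),
    enrichment_lfc: float = 2.0,
    base_depth: float = 20.0,
    noise_model: str = "poisson",
    seed: int = 0,
    replicon_id: str = "chrSIM",
    strand: str = "+",
    min_separation: int = 20,
    noise_seed: int | None = None,
) -> tuple[CoverageTrack, CoverageTrack, TruthTable]:
    """Simulate an IP/control coverage pair with planted enriched regions.

    The control is flat (or Poisson) around ``base_depth``; inside each of
    ``n_regions`` non-overlapping planted intervals the IP mean depth is
    multiplied by 2**``enrichment_lfc``. Planted intervals are separated by
    at least ``min_separation`` background positions so calls never merge.

    ``seed`` fixes the planted-region placement; ``noise_seed`` (default:
    same as ``seed``) independently drives the sampling noise, so
    biological replicates of one binding landscape are simulated by keeping
    ``seed`` fixed and varying ``noise_seed``.
    """
    if noise_model not in ("none", "poisson"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    lo, hi = region_len_range
    if lo < 1 or hi < lo:
        raise ValueError("region_len_range must satisfy 1 <= min <= max")
    if enrichment_lfc < 0:
        raise ValueError("enrichment_lfc must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_regions)
    slack = genome_len - int(lengths.sum()) - min_separation * (n_regions + 1)
    if n_regions > 0 and slack < 0:
        raise ValueError(
            f"cannot place {n_regions} non-overlapping regions in {genome_len} nt"
        )
    starts = []
    if n_regions > 0:
        cuts = np.sort(rng.integers(0, slack + 1, size=n_regions))
        offset = 0
        for i, length in enumerate(lengths):
            start = min_separation * (i + 1) + offset + int(cuts[i])
            starts.append(start)
            offset += int(length)
    noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
    if noise_model == "none":
        ctrl_values = np.full(genome_len, float(base_depth))
        ip_values = np.full(genome_len, float(base_depth))
        for start, length in zip(starts, lengths):
            ip_values[start : start + length] = base_depth * 2.0**enrichment_lfc
    else:
        ctrl_values = noise_rng.poisson(base_depth, genome_len).astype(float)
        ip_mean = np.full(genome_len, float(base_depth))
        for start, length in zip(starts, lengths):
            ip_mean[start : start + length] = base_depth * 2.0**enrichment_lfc
        ip_values = noise_rng.poisson(ip_mean).astype(float)
    records = [
        {"start": int(s), "end": int(s + l), "length": int(l), "lfc": float(enrichment_lfc)}
        for s, l in zip(starts, lengths)
    ]
    truth = TruthTable(
        kind="binding_regions",
        records=records,
        seed=seed,
        params={
            "genome_len": genome_len,
            "enrichment_lfc": enrichment_lfc,
            "base_depth": base_depth,
            "noise_model": noise_model,
        },
    )
    ip = CoverageTrack(replicon_id, strand, ip_values)
    ctrl = CoverageTrack(replicon_id, strand, ctrl_values)
    return ip, ctrl, truth


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------

def gen_abundance_tables(
    n_genes: int,
    n_timepoints: int = 4,
    n_reps: int = 3,
    planted_ptr_frac: float = 0.05,
    missing_protein_frac: float = 0.5,
    noise_sigma: float = 0.2,
    protein_scatter: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate protein/mRNA/RPF abundance tables over a growth time course.

    Background genes follow a log-linear protein-versus-mRNA relationship
    with log-normal measurement noise; RPF tracks mRNA up to a per-gene
    ribosome-occupancy shift. A ``planted_ptr_frac`` fraction of genes is
    planted as post-transcriptionally regulated: their mRNA lies above the
    cohort's 80th percentile at every state while their protein is either
    below the detected 20th percentile (class ``detected_low``) or missing
    altogether (class ``undetected``, a ``missing_protein_frac`` share of
    the planted set). With ``noise_sigma = protein_scatter = 0`` the
    planted set is exactly the set the quintile rule recovers.

    Columns are named ``TP{t}_R{r}``; values are linear-scale TPM /
    intensity; missing protein is NaN.
    """
    if not (0 <= planted_ptr_frac <= 1 and 0 <= missing_protein_frac <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    n_planted = int(round(planted_ptr_frac * n_genes))
    if 0 < planted_ptr_frac * n_genes < 1:
        raise ValueError(
            f"planted_ptr_frac={planted_ptr_frac} requests a fractional gene "
            f"({planted_ptr_frac * n_genes:.2f}); increase n_genes or the fraction"
        )
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    planted = sorted(rng.choice(n_genes, size=n_planted, replace=False).tolist())
    planted_set = set(planted)
    n_undetected = int(round(missing_protein_frac * n_planted))
    undetected = set(planted[:n_undetected])

    # per-gene baseline and per-gene-per-state biology (not noise)
    base_log_mrna = rng.normal(2.0, 0.5, size=n_genes)
    tp_shift = rng.normal(0.0, 0.2, size=(n_genes, n_timepoints))
    ro_shift = rng.normal(0.0, 0.15, size=n_genes)
    log_mrna = base_log_mrna[:, None] + tp_shift  # genes x TPs, log10

    background = [i for i in range(n_genes) if i not in planted_set]
    if background:
        bg_max = log_mrna[background].max(axis=0)
        bg_min = log_mrna[background].min(axis=0)
    else:
        bg_max = np.full(n_timepoints, 2.0)
        bg_min = np.full(n_timepoints, 2.0)
    for i in planted:
        log_mrna[i] = bg_max + 0.3  # above every background gene at every state

    # protein follows mRNA log-linearly for background genes
    log_protein = 3.0 + 1.0 * log_mrna + rng.normal(0.0, protein_scatter, log_mrna.shape)
    bg_prot_min = (3.0 + 1.0 * bg_min) - 3.0 * protein_scatter
    for i in planted:
        log_protein[i] = bg_prot_min - 0.3  # below every detected background protein
    log_rpf = log_mrna + ro_shift[:, None]

    columns = [f"TP{t + 1}_R{r + 1}" for t in range(n_timepoints) for r in range(n_reps)]

    def _expand(log_means: np.ndarray) -> pd.DataFrame:
        reps = np.repeat(log_means, n_reps, axis=1)
        noisy = reps + rng.normal(0.0, noise_sigma, reps.shape)
        return pd.DataFrame(10.0**noisy, index=genes, columns=columns)

    mrna = _expand(log_mrna)
    protein = _expand(log_protein)
    rpf = _expand(log_rpf)
    for i in undetected:
        protein.iloc[i, :] = np.nan

    records = [
        {
            "gene_id": genes[i],
            "ptr_class": "undetected" if i in undetected else "detected_low",
        }
        for i in planted
    ]
    truth = TruthTable(
        kind="ptr_genes",
        records=records,
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_timepoints": n_timepoints,
            "n_reps": n_reps,
            "noise_sigma": noise_sigma,
            "protein_scatter": protein_scatter,
        },
    )
    return protein, mrna, rpf, truth


# ---------------------------------------------------------------------------
# structural-variant calls
# ---------------------------------------------------------------------------

def random_is_catalog(
    n_elements: int = 3, length_range: tuple[int, int] = (600, 1400), seed: int = 0
) -> list[tuple[str, str]]:
    """A small random insertion-sequence catalog for simulations."""
    rng = np.random.default_rng(seed)
    catalog = []
    for i in range(n_elements):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(DNA, size=length))
        catalog.append((f"ISSIM{i + 1}", seq))
    return catalog


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of positions with other bases."""
    chars = np.array(list(seq))
    n_mut = int(round(divergence * len(chars)))
    sites = rng.choice(len(chars), size=n_mut, replace=False)
    for site in sites:
        options = DNA[DNA != chars[site]]
        chars[site] = rng.choice(options)
    return "".join(chars)


def gen_sv_calls(
    n_clusters: int,
    events_per_cluster_range: tuple[int, int] = (1, 20),
    coverage_per_library: float | Mapping[str, float] = 25.0,
    n_noise_events: int = 0,
    is_catalog: Sequence[tuple[str, str]] | None = None,
    jitter_bp: int = 10,
    seed: int = 0,
    libraries: Sequence[str] = ("lib1",),
    replicon_id: str = "chrSIM",
    cluster_spacing: int = 500,
    decoy_divergence: float = 0.35,
) -> tuple[dict[str, list[SvRecord]], dict[str, int], TruthTable]:
    """Simulate per-library SV call sets with planted mobilization clusters.

    Each planted cluster picks an IS element, an SV class and an occurrence
    count ``e``; its member calls start within ``jitter_bp`` of the cluster
    anchor (so single-linkage chaining at 50 bp recovers the cluster
    exactly) and carry a verbatim copy of the element sequence. Anchors of
    consecutive clusters are ``cluster_spacing`` apart, far beyond the
    chaining distance. ``n_noise_events`` decoys carry sequences diverged
    ``decoy_divergence`` below the identity threshold and should be left
    unassigned. Local read depth is uniform at ``coverage_per_library``,
    which together with ``e`` fixes each cluster's expected e/c class.
    """
    if jitter_bp > 50:
        raise ValueError("jitter_bp > 50 would break planted-cluster recoverability")
    if is_catalog is None:
        is_catalog = random_is_catalog(seed=seed)
    if isinstance(coverage_per_library, Mapping):
        coverage = {lib: float(coverage_per_library[lib]) for lib in libraries}
    else:
        coverage = {lib: float(coverage_per_library) for lib in libraries}
    rng = np.random.default_rng(seed)
    e_lo, e_hi = events_per_cluster_range
    records: dict[str, list[SvRecord]] = {lib: [] for lib in libraries}
    truth_records: list[dict] = []
    for ci in range(n_clusters):
        lib = libraries[ci % len(libraries)]
        element_id, element_seq = is_catalog[int(rng.integers(len(is_catalog)))]
        sv_class = "insertion" if rng.random() < 0.5 else "excision"
        e = int(rng.integers(e_lo, e_hi + 1))
        anchor = 1000 + ci * cluster_spacing
        if jitter_bp > 0:
            offsets = np.sort(rng.integers(0, jitter_bp + 1, size=e))
        else:
            offsets = np.zeros(e, dtype=int)
        starts = [anchor + int(o) for o in offsets]
        for start in starts:
            records[lib].append(
                SvRecord(
                    replicon_id=replicon_id,
                    pos=start,
                    sv_class=sv_class,
                    sequence=element_seq,
                    library_id=lib,
                )
            )
        c = coverage[lib]
        ratio = e / c
        pop_class = "rare" if ratio <= 0.1 else ("common" if ratio <= 0.5 else "predominant")
        truth_records.append(
            {
                "library_id": lib,
                "replicon_id": replicon_id,
                "element_id": element_id,
                "sv_class": sv_class,
                "mean_start": float(np.mean(starts)),
                "e": e,
                "c": c,
                "population_class": pop_class,
                "label": "planted",
            }
        )
    noise_region = 1000 + n_clusters * cluster_spacing + 1000
    for ni in range(n_noise_events):
        lib = libraries[int(rng.integers(len(libraries)))]
        element_id, element_seq = is_catalog[int(rng.integers(len(is_catalog)))]
        decoy_seq = _mutate(element_seq, decoy_divergence, rng)
        pos = noise_region + ni * cluster_spacing
        records[lib].append(
            SvRecord(
                replicon_id=replicon_id,
                pos=pos,
                sv_class="insertion" if rng.random() < 0.5 else "excision",
                sequence=decoy_seq,
                library_id=lib,
            )
        )
        truth_records.append(
            {
                "library_id": lib,
                "replicon_id": replicon_id,
                "element_id": None,
                "mean_start": float(pos),
                "label": "unassigned",
            }
        )
    aligned_reads = {
        lib: int(rng.integers(50_000, 150_000)) for lib in libraries
    }
    truth = TruthTable(
        kind="sv_clusters",
        records=truth_records,
        seed=seed,
        params={
            "n_clusters": n_clusters,
            "jitter_bp": jitter_bp,
            "coverage": coverage,
            "genome_len": noise_region + max(n_noise_events, 1) * cluster_spacing + 2000,
        },
    )
    return records, aligned_reads, truth


def uniform_depth_tracks(
    libraries: Sequence[str],
    coverage: Mapping[str, float],
    genome_len: int,
    replicon_id: str = "chrSIM",
) -> dict[tuple[str, str], CoverageTrack]:
    """Uniform per-library depth tracks matching :func:`gen_sv_calls` output."""
    return {
        (lib, replicon_id): CoverageTrack(
            replicon_id, "+", np.full(genome_len, float(coverage[lib]))
        )
        for lib in libraries
    }


# ---------------------------------------------------------------------------
# feature flags
# ---------------------------------------------------------------------------

def gen_feature_flags(
    gene_ids: Sequence[str],
    planted_set: Sequence[str],
    baseline_rates: Mapping[str, float],
    planted_enrichment_odds: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate binary regulatory feature flags with controlled enrichment.

    Each feature is drawn independently per gene as a Bernoulli with its
    baseline rate; inside ``planted_set`` the odds are multiplied by
    ``planted_enrichment_odds`` (1.0 means no enrichment; a rate of 0
    stays 0).
    """
    planted = set(planted_set)
    if not planted <= set(gene_ids):
        raise ValueError("planted_set must be a subset of gene_ids")
    if planted_enrichment_odds < 0:
        raise ValueError("planted_enrichment_odds must be >= 0")
    rng = np.random.default_rng(seed)
    flags = pd.DataFrame(index=list(gene_ids), dtype=bool)
    for feature, rate in baseline_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"baseline rate for {feature} outside [0, 1]")
        if rate in (0.0, 1.0):
            planted_rate = rate
        else:
            odds = rate / (1 - rate) * planted_enrichment_odds
            planted_rate = odds / (1 + odds)
        draws = rng.random(len(gene_ids))
        rates = np.array(
            [planted_rate if g in planted else rate for g in gene_ids]
        )
        flags[feature] = draws < rates
    truth = TruthTable(
        kind="feature_flags",
        records=[{"gene_id": g} for g in sorted(planted)],
        seed=seed,
        params={
            "baseline_rates": dict(baseline_rates),
            "planted_enrichment_odds": planted_enrichment_odds,
        },
    )
    return flags, truth
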