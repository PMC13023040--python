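"""Pooled-screen statistics linking gene knockouts to repair-outcome shifts.

Each library guide carries a knockout identity and a table of repair-outcome
counts at the secondary cut site.  For a given outcome pattern, every guide
is tested against the pooled non-targeting controls with Fisher's exact
test (both tails) plus a log2 fold change of outcome frequencies.  Guides
are then ranked globally in a direction-aware way, aggregated to gene level
with Robust Rank Aggregation (RRA) — the minimum over order statistics of
beta tail probabilities — and assigned empirical p-values from a permutation
null of i.i.d. uniform ranks.  Two target-site libraries are merged by
outcome-frequency-weighted effect sizes and Stouffer z-combination of the
one-tailed p-values; hits require |log2FC| > 0.5 and combined P < .05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import EDITED_PATTERNS

__all__ = [
    "GuideStat",
    "assign_reads_to_guides",
    "filter_guides",
    "guide_outcome_test",
    "guide_outcome_tests",
    "rank_guides_directional",
    "rra_gene_score",
    "permutation_pvalue",
    "permutation_pvalues",
    "gene_scores_for_pattern",
    "analyze_library",
    "integrate_libraries",
    "call_hits",
    "DEFAULT_LFC_THRESHOLD",
    "DEFAULT_P_THRESHOLD",
]

DEFAULT_MIN_READS = 10
DEFAULT_N_PERM = 20_000
DEFAULT_LFC_THRESHOLD = 0.5
DEFAULT_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class GuideStat:
    """Per-guide Fisher test result for one outcome pattern."""

    guide_id: str
    pattern: str
    log2fc: float
    p_left: float
    p_right: float


# ---------------------------------------------------------------------------
# Read -> guide assignment
# ---------------------------------------------------------------------------

def assign_reads_to_guides(
    reads: dict[str, str] | list[tuple[str, str]],
    manifest: pd.DataFrame,
) -> tuple[dict[str, list[str]], int]:
    """Assign reads to library guides by exact, position-anchored matching.

    ``manifest`` needs columns ``guide_id``, ``guide_sequence`` and
    ``guide_offset`` (0-based position of the guide within the read).  A
    read is assigned to guide g iff
    ``read[offset : offset+len(seq)] == seq`` with zero mismatches.

    Returns ``(assignments, n_unmatched)`` where assignments maps guide_id
    to the list of matching read names.

    Raises
    ------
    ValueError
        If the manifest contains duplicate guide sequences.
    """
    if manifest["guide_sequence"].duplicated().any():
        dup = manifest.loc[manifest["guide_sequence"].duplicated(), "guide_id"]
        raise ValueError(f"duplicate guide sequences in manifest: {list(dup)[:5]}")
    items = reads.items() if isinstance(reads, dict) else reads
    lookup = {
        (int(row.guide_offset), row.guide_sequence): row.guide_id
        for row in manifest.itertuples()
    }
    offsets = sorted({int(o) for o, _ in lookup})
    lengths = sorted({len(s) for _, s in lookup})
    assignments: dict[str, list[str]] = {g: [] for g in manifest["guide_id"]}
    unmatched = 0
    for name, seq in items:
        hit = None
        for off in offsets:
            for L in lengths:
                gid = lookup.get((off, seq[off:off + L]))
                if gid is not None:
                    hit = gid
                    break
            if hit:
                break
        if hit is None:
            unmatched += 1
        else:
            assignments[hit].append(name)
    return assignments, unmatched


def filter_guides(
    records: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop guides with too few reads or no detectable edited alleles.

    ``records`` is a wide table (one row per guide, one column per edited
    pattern, plus ``guide_id``/``gene``/``category``).  Guides with total
    edited reads <= ``min_reads``, or with zero edited reads, are excluded.
    Returns ``(kept, exclusion_log)``.
    """
    totals = records[list(EDITED_PATTERNS)].sum(axis=1)
    low = totals <= min_reads
    unedited = totals == 0
    drop = low | unedited
    log = records.loc[drop, ["guide_id"]].copy()
    log["total_edited_reads"] = totals[drop].to_numpy()
    log["reason"] = np.where(unedited[drop], "no_edited_reads", "low_reads")
    return records.loc[~drop].reset_index(drop=True), log.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Per-guide Fisher tests
# ---------------------------------------------------------------------------

def _log2fc(a: int, n1: int, c: int, n2: int) -> float:
    """log2 frequency ratio with Haldane +0.5 correction on zero cells."""
    if a == 0 or c == 0 or a == n1 or c == n2:
        f1 = (a + 0.5) / (n1 + 1.0)
        f2 = (c + 0.5) / (n2 + 1.0)
    else:
        f1 = a / n1
        f2 = c / n2
    return float(np.log2(f1 / f2))


def guide_outcome_test(
    pattern_count: int,
    total_count: int,
    control_pattern: int,
    control_total: int,
    guide_id: str = "",
    pattern: str = "",
) -> GuideStat:
    """Fisher's exact test of one guide's outcome frequency vs controls.

    The 2x2 table is ``[[a, n1-a], [c, n2-c]]`` with a = guide reads showing
    the pattern out of n1 edited reads, against the pooled non-targeting
    control counts (c of n2).  p_right is the enrichment tail
    P(X >= a), p_left the depletion tail P(X <= a), both from the exact
    hypergeometric distribution with N = n1+n2, K = a+c draws of size n1.
    """
    a, n1, c, n2 = pattern_count, total_count, control_pattern, control_total
    if n2 <= 0 or c < 0 or c > n2:
        raise ValueError("control pool is empty or inconsistent")
    if not (0 <= a <= n1):
        raise ValueError("guide counts inconsistent")
    N, K = n1 + n2, a + c
    p_right = float(stats.hypergeom.sf(a - 1, N, K, n1))
    p_left = float(stats.hypergeom.cdf(a, N, K, n1))
    return GuideStat(
        guide_id=guide_id, pattern=pattern,
        log2fc=_log2fc(a, n1, c, n2),
        p_left=min(p_left, 1.0), p_right=min(p_right, 1.0),
    )


def guide_outcome_tests(
    records: pd.DataFrame,
    pattern: str,
    control_pattern: int,
    control_total: int,
) -> pd.DataFrame:
    """Vectorized :func:`guide_outcome_test` over all guides for one pattern."""
    a = records[pattern].to_numpy(dtype=np.int64)
    n1 = records[list(EDITED_PATTERNS)].sum(axis=1).to_numpy(dtype=np.int64)
    c, n2 = control_pattern, control_total
    if n2 <= 0:
        raise ValueError("control pool is empty")
    N, K = n1 + n2, a + c
    p_right = stats.hypergeom.sf(a - 1, N, K, n1)
    p_left = stats.hypergeom.cdf(a, N, K, n1)
    zero = (a == 0) | (a == n1)  # c is scalar and shared
    if c == 0 or c == n2:
        zero = np.ones_like(zero)
    f1 = np.where(zero, (a + 0.5) / (n1 + 1.0), a / np.maximum(n1, 1))
    f2 = np.where(zero, (c + 0.5) / (n2 + 1.0), c / n2)
    out = records[["guide_id", "gene", "category"]].copy()
    out["pattern"] = pattern
    out["log2fc"] = np.log2(f1 / f2)
    out["p_left"] = np.minimum(p_left, 1.0)
    out["p_right"] = np.minimum(p_right, 1.0)
    return out


# ---------------------------------------------------------------------------
# Directional ranking and RRA
# ---------------------------------------------------------------------------

def rank_guides_directional(stats_df: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Globally rank guides for one pattern in a direction-aware order.

    ``direction`` names the gene's inferred role: a gene that *promotes* an
    outcome shows depletion of that outcome when knocked out, so for
    ``direction="promoting"`` guides with log2fc < 0 are
    direction-consistent and sort first, ascending by p_left; inconsistent
    guides are appended, sorted descending by p_left (penalized).
    ``direction="inhibiting"`` mirrors this with log2fc > 0 and p_right
    (knockout enriches the outcome).  Ties break by |log2fc| descending,
    then guide_id.  Adds a ``norm_rank`` column in (0, 1] (position / n).
    """
    if direction not in ("inhibiting", "promoting"):
        raise ValueError("direction must be 'inhibiting' or 'promoting'")
    df = stats_df.copy()
    if direction == "promoting":
        consistent = df["log2fc"].to_numpy() < 0
        p = df["p_left"].to_numpy()
    else:
        consistent = df["log2fc"].to_numpy() > 0
        p = df["p_right"].to_numpy()
    df["_cons"] = consistent
    df["_p"] = p
    # Consistent block: p ascending.  Inconsistent block: p descending,
    # encoded as -p so a single ascending sort key works.
    df["_key"] = np.where(consistent, p, -p)
    df = df.sort_values(
        by=["_cons", "_key", "log2fc", "guide_id"],
        ascending=[False, True, True, True],
        key=lambda col: -col.abs() if col.name == "log2fc" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    n = len(df)
    df["norm_rank"] = (np.arange(n) + 1) / n
    return df.drop(columns=["_cons", "_p", "_key"])


def rra_gene_score(ranks: np.ndarray) -> float:
    """Robust Rank Aggregation rho for one gene's guide ranks.

    With normalized ranks r_(1) <= ... <= r_(k), rho is the minimum over j
    of Beta(j, k-j+1).cdf(r_(j)) — the probability that the j-th smallest of
    k i.i.d. uniforms falls at or below r_(j).  Small rho means the gene's
    guides sit improbably high in the ranked list.
    """
    r = np.sort(np.asarray(ranks, dtype=float))
    k = r.size
    if k == 0:
        raise ValueError("need at least one rank")
    j = np.arange(1, k + 1)
    return float(np.min(stats.beta.cdf(r, j, k - j + 1)))


def _rra_rho_rows(rank_matrix: np.ndarray) -> np.ndarray:
    """Row-wise RRA rho for a (n, k) matrix of normalized ranks."""
    r = np.sort(rank_matrix, axis=1)
    k = r.shape[1]
    j = np.arange(1, k + 1)
    return stats.beta.cdf(r, j, k - j + 1).min(axis=1)


def permutation_pvalue(
    rho_observed: float,
    k: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical p-value of an RRA rho under the i.i.d.-uniform rank null.

    Each permutation draws k uniform(0, 1] ranks and recomputes rho; the
    p-value is ``(1 + #{rho_perm <= rho_obs}) / (n_perm + 1)``, which is
    never zero.
    """
    return float(
        permutation_pvalues(np.array([rho_observed]), k, n_perm, seed)[0]
    )


def permutation_pvalues(
    rho_observed: np.ndarray,
    k: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Vectorized permutation p-values sharing one simulated null for all genes."""
    rng = np.random.default_rng(seed)
    null = _rra_rho_rows(rng.random((n_perm, k)))
    null.sort()
    counts = np.searchsorted(null, np.asarray(rho_observed, dtype=float),
                             side="right")
    return (1.0 + counts) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Gene-level pipeline
# ---------------------------------------------------------------------------

def gene_scores_for_pattern(
    guide_stats: pd.DataFrame,
    direction: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Rank guides, aggregate to gene-level RRA scores, add permutation p.

    ``guide_stats`` is the output of :func:`guide_outcome_tests` for one
    pattern.  Non-targeting guides participate in the global ranking (they
    anchor the null) but receive no gene score.  The representative
    one-tailed p carried forward per gene is the best direction-consistent
    tail p among its guides, and the gene effect size is the mean guide
    log2fc.
    """
    ranked = rank_guides_directional(guide_stats, direction)
    targets = ranked[ranked["category"] != "nontarget"]
    tail = "p_left" if direction == "promoting" else "p_right"
    grouped = targets.groupby("gene", sort=True)
    genes = []
    rank_lists = []
    for gene, grp in grouped:
        genes.append({
            "gene": gene,
            "pattern": grp["pattern"].iloc[0],
            "direction": direction,
            "n_guides": len(grp),
            "log2fc": float(grp["log2fc"].mean()),
            "p_tail": float(grp[tail].min()),
        })
        rank_lists.append(grp["norm_rank"].to_numpy())
    out = pd.DataFrame(genes)
    out["rra_rho"] = [rra_gene_score(r) for r in rank_lists]
    # One shared null per guide-count k.
    rng = np.random.default_rng(seed)
    out["p_empirical"] = np.nan
    for k, idx in out.groupby("n_guides").groups.items():
        out.loc[idx, "p_empirical"] = permutation_pvalues(
            out.loc[idx, "rra_rho"].to_numpy(), int(k), n_perm, rng
        )
    return out.sort_values("rra_rho", kind="mergesort").reset_index(drop=True)


def analyze_library(
    records: pd.DataFrame,
    patterns: list[str] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full single-library analysis: filter, test, rank, RRA, permutation p.

    ``records`` is the wide per-guide count table (guide_id, gene, category,
    one column per edited pattern).  Returns ``(gene_scores, exclusions)``;
    gene_scores has one row per gene x pattern x direction and carries the
    pattern's library-wide outcome frequency (for integration weighting).
    """
    patterns = patterns or list(EDITED_PATTERNS)
    kept, excluded = filter_guides(records, min_reads)
    nt = kept[kept["category"] == "nontarget"]
    if nt.empty:
        raise ValueError("no non-targeting guides after filtering")
    nt_total = int(nt[list(EDITED_PATTERNS)].sum().sum())
    lib_total = int(kept[list(EDITED_PATTERNS)].sum().sum())
    rng = np.random.default_rng(seed)
    results = []
    for pattern in patterns:
        c = int(nt[pattern].sum())
        stats_df = guide_outcome_tests(kept, pattern, c, nt_total)
        lib_freq = float(kept[pattern].sum()) / lib_total
        for direction in ("promoting", "inhibiting"):
            scores = gene_scores_for_pattern(stats_df, direction, n_perm, rng)
            scores["pattern_frequency"] = lib_freq
            results.append(scores)
    return pd.concat(results, ignore_index=True), excluded


# ---------------------------------------------------------------------------
# Library integration and hit calling
# ---------------------------------------------------------------------------

_P_FLOOR = np.finfo(float).tiny


def integrate_libraries(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    weight_a: float | None = None,
    weight_b: float | None = None,
    p_col: str = "p_empirical",
) -> pd.DataFrame:
    """Merge two libraries' gene scores into combined effects and p-values.

    Only genes present in both libraries (per pattern and direction) are
    retained.  Effect sizes combine as a weighted mean; one-tailed p-values
    convert to z-scores, combine as ``(wA*zA + wB*zB)/sqrt(wA^2 + wB^2)``
    (Stouffer with weights) and back-transform.  Default weights are each
    library's overall frequency of the pattern.
    """
    keys = ["gene", "pattern", "direction"]
    merged = scores_a.merge(scores_b, on=keys, suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared genes between libraries")
    wa = merged["pattern_frequency_a"].to_numpy() if weight_a is None \
        else np.full(len(merged), float(weight_a))
    wb = merged["pattern_frequency_b"].to_numpy() if weight_b is None \
        else np.full(len(merged), float(weight_b))
    if np.any(wa <= 0) or np.any(wb <= 0):
        raise ValueError("weights must be positive")
    lfc = (wa * merged["log2fc_a"] + wb * merged["log2fc_b"]) / (wa + wb)
    pa = np.clip(merged[f"{p_col}_a"].to_numpy(), _P_FLOOR, 1.0)
    pb = np.clip(merged[f"{p_col}_b"].to_numpy(), _P_FLOOR, 1.0)
    za = stats.norm.isf(pa)
    zb = stats.norm.isf(pb)
    z = (wa * za + wb * zb) / np.sqrt(wa ** 2 + wb ** 2)
    out = merged[keys].copy()
    out["combined_log2fc"] = lfc
    out["z_combined"] = z
    out["p_combined"] = stats.norm.sf(z)
    out["rra_rho_a"] = merged["rra_rho_a"]
    out["rra_rho_b"] = merged["rra_rho_b"]
    out["p_a"] = pa
    out["p_b"] = pb
    return out


def call_hits(
    gene_scores: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_col: str = "combined_log2fc",
    p_col: str = "p_combined",
) -> pd.DataFrame:
    """Flag significant genes: |log2FC| > threshold AND p < threshold (strict)."""
    out = gene_scores.copy()
    out["is_hit"] = (
        (out[lfc_col].abs() > lfc_threshold) & (out[p_col] < p_threshold)
    )
    return out
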