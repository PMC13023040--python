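"""Synthetic data generation for every stage of the toolkit.

Three generators emulate the inputs a real experiment would produce:

* :func:`gen_target_locus` / :func:`gen_edited_reads` — an amplicon
  reference with planted microhomology sites and reads drawn from a
  specified outcome spectrum, each read name carrying its true pattern.
* :func:`gen_timecourse_counts` — binomially sampled editing time courses
  from known rate constants, with a time-varying pattern mixture in which
  1-bp insertions peak early and MH deletions accumulate late.
* :func:`gen_screen_dataset` — a pooled-screen guide manifest and
  guide x outcome count table at a GeCKOv2-like composition (full scale:
  19,050 genes x 6 guides, 1,864 miRNAs x 4 guides, 1,000 non-targeting)
  with multiplicative planted effects and a ground-truth table.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indel import (
    RepairEvent,
    TargetLocus,
    apply_events,
    detect_microhomology,
    left_normalize,
)
from .kinetics import DEFAULT_TIME_GRID_H, KineticParams, TimeCourse, simulate_repair_ode
from .patterns import EDITED_PATTERNS, UNEDITED

__all__ = [
    "SyntheticLocus",
    "SpectrumSpec",
    "ScreenSpec",
    "gen_target_locus",
    "gen_edited_reads",
    "gen_timecourse_counts",
    "default_pattern_mix",
    "gen_screen_dataset",
    "gen_screen_reads",
    "DEFAULT_BASELINE_PROBS",
]

_BASES = np.array(list("ACGT"))

# Baseline outcome probabilities loosely matching observed amplicon
# spectra: deletions dominant (~64%), most insertions 1 bp, mutations rare.
DEFAULT_BASELINE_PROBS: dict[str, float] = {
    "1bp Ins": 0.25,
    "Large Ins": 0.03,
    "MH Small Del": 0.22,
    "NonMH Small Del": 0.18,
    "MH Large Del": 0.12,
    "NonMH Large Del": 0.12,
    "Mut": 0.08,
}


@dataclass(frozen=True)
class SyntheticLocus:
    """A generated :class:`TargetLocus` plus its planted deletion sites."""

    locus: TargetLocus
    mh_sites: tuple[tuple[int, int, int], ...]  # (start, length, mh_len)


@dataclass
class SpectrumSpec:
    """Target outcome probabilities for read generation."""

    pattern_probs: dict[str, float]
    insertion_templated_fraction: float = 0.7
    error_rate: float = 0.0  # per-base substitution errors, off by default

    def __post_init__(self) -> None:
        total = sum(self.pattern_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern probabilities sum to {total}, not 1")
        unknown = set(self.pattern_probs) - set(EDITED_PATTERNS) - {UNEDITED}
        if unknown:
            raise ValueError(f"unknown patterns: {unknown}")


# ---------------------------------------------------------------------------
# Locus generation
# ---------------------------------------------------------------------------

#: Default planted deletions (relative to the cut site): one MMEJ-style
#: small deletion (4 bp, 2 bp MH) and one large (8 bp, 3 bp MH).
DEFAULT_MH_DESIGN: tuple[tuple[int, int, int], ...] = ((-2, 4, 2), (-4, 8, 3))


def gen_target_locus(
    length: int = 120,
    protospacer_start: int = 45,
    mh_design: tuple[tuple[int, int, int], ...] | None = DEFAULT_MH_DESIGN,
    seed: int = 0,
) -> SyntheticLocus:
    """Random amplicon with an NGG PAM and planted microhomology sites.

    ``mh_design`` lists deletions as ``(start_rel_cut, length, mh_len)``;
    each is planted so that, after left-normalization, the deletion has
    exactly the requested junction microhomology (verified with
    :func:`repairmap.indel.detect_microhomology`; incompatible designs
    raise after bounded retries).
    """
    protospacer_len = 20
    pam_start = protospacer_start + protospacer_len
    cut = pam_start - 3
    if length < pam_start + 3 + 10 or protospacer_start < 10:
        raise ValueError("amplicon too short for protospacer + PAM + flanks")
    mh_design = tuple(mh_design or ())
    sites = tuple((cut + rel, L, mh) for rel, L, mh in mh_design)
    for start, L, mh in sites:
        if start < 1 or start + L + mh >= length or mh >= L:
            raise ValueError(f"incompatible mh_design entry {(start, L, mh)}")

    rng = np.random.default_rng(seed)
    for _ in range(200):
        seq = rng.choice(_BASES, size=length).tolist()
        seq[pam_start + 1] = "G"
        seq[pam_start + 2] = "G"
        for start, L, mh in sites:
            # Copy the deleted prefix to just downstream of the deletion,
            # respecting PAM positions by copying backwards instead.
            for k in range(mh):
                src, dst = start + k, start + L + k
                if dst in (pam_start + 1, pam_start + 2):
                    seq[src] = seq[dst]
                else:
                    seq[dst] = seq[src]
        ref = "".join(seq)
        if _verify_design(ref, sites) and ref[pam_start + 1:pam_start + 3] == "GG":
            locus = TargetLocus(ref_seq=ref, protospacer_start=protospacer_start,
                                protospacer_len=protospacer_len,
                                pam_start=pam_start, pam_strand="+")
            return SyntheticLocus(locus=locus, mh_sites=sites)
    raise ValueError("could not satisfy mh_design; relax the design or reseed")


def _verify_design(ref: str, sites: tuple[tuple[int, int, int], ...]) -> bool:
    for start, L, mh in sites:
        ev = left_normalize(RepairEvent("deletion", start, L), ref)
        if ev.start != start:  # placement must already be canonical
            return False
        if detect_microhomology(ev, ref) != mh:
            return False
    return True


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _find_nonmh_deletion(
    ref: str, cut: int, lengths: range, rng: np.random.Generator,
    mh_max: int = 1,
) -> RepairEvent:
    """A deletion overlapping the cut whose normalized MH is <= mh_max."""
    candidates = []
    for L in lengths:
        for start in range(max(1, cut - L), min(cut + 1, len(ref) - L - 2)):
            ev = left_normalize(RepairEvent("deletion", start, L), ref)
            if detect_microhomology(ev, ref) <= mh_max:
                candidates.append(ev)
    if not candidates:
        raise ValueError("no non-MH deletion available at this locus")
    return candidates[rng.integers(len(candidates))]


def _events_for_pattern(
    pattern: str,
    syn: SyntheticLocus,
    spec: SpectrumSpec,
    rng: np.random.Generator,
) -> list[RepairEvent]:
    ref = syn.locus.ref_seq
    cut = syn.locus.cut_site
    if pattern == UNEDITED:
        return []
    if pattern in ("1bp Ins", "Large Ins"):
        # Retry until the insertion, once left-normalized, still anchors
        # inside the +-5 bp cut window (a templated copy of the flank
        # slides upstream by its own length, further if the repeat extends).
        for attempt in range(20):
            templated = (rng.random() < spec.insertion_templated_fraction
                         and attempt < 10)
            if pattern == "1bp Ins":
                if templated:
                    ins = ref[cut - 1]  # duplicates the base 5' of the cut
                else:
                    ins = rng.choice([b for b in "ACGT" if b != ref[cut - 1]])
            else:
                # <= 5 bp keeps a flank-templated copy inside the window
                L = int(rng.integers(2, 6))
                if templated:
                    ins = ref[cut - L:cut]
                else:
                    ins = "".join(rng.choice(_BASES, size=L))
                    if ins == ref[cut - L:cut] or ins == ref[cut:cut + L]:
                        ins = ("A" if ins[0] != "A" else "C") + ins[1:]
            ev = RepairEvent("insertion", cut, len(ins), ins)
            if left_normalize(ev, ref).start >= cut - 5:
                return [ev]
        raise ValueError(f"could not place a {pattern} insertion at this locus")
    if pattern in ("MH Small Del", "MH Large Del"):
        small = pattern == "MH Small Del"
        options = [s for s in syn.mh_sites
                   if (s[1] <= 5) == small and s[2] >= 2]
        if not options:
            raise ValueError(f"locus has no planted site for {pattern}")
        start, L, _ = options[rng.integers(len(options))]
        return [RepairEvent("deletion", start, L)]
    if pattern == "NonMH Small Del":
        return [_find_nonmh_deletion(ref, cut, range(1, 6), rng)]
    if pattern == "NonMH Large Del":
        return [_find_nonmh_deletion(ref, cut, range(6, 13), rng)]
    if pattern == "Mut":
        k = int(rng.integers(1, 4))
        positions = rng.choice(np.arange(cut - 4, cut + 4), size=k, replace=False)
        subs = []
        for pos in sorted(int(p) for p in positions):
            alt = rng.choice([b for b in "ACGT" if b != ref[pos]])
            subs.append((pos, ref[pos], alt))
        return [
            RepairEvent("substitution", pos, 1, sub_bases=((pos, r, a),))
            for pos, r, a in subs
        ]
    raise ValueError(f"unknown pattern {pattern!r}")


def gen_edited_reads(
    syn: SyntheticLocus,
    spec: SpectrumSpec,
    n_reads: int,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw reads from the spectrum; names carry the true pattern label.

    Returns ``(name, sequence)`` pairs with names like
    ``read_000017|truth=MH Small Del``.  Reads are error-free unless
    ``spec.error_rate`` > 0, in which case uniform substitution errors are
    added after the edit.
    """
    rng = np.random.default_rng(seed)
    patterns = list(spec.pattern_probs)
    probs = np.array([spec.pattern_probs[p] for p in patterns])
    draws = rng.choice(len(patterns), size=n_reads, p=probs)
    reads = []
    ref = syn.locus.ref_seq
    for i, d in enumerate(draws):
        pattern = patterns[d]
        events = _events_for_pattern(pattern, syn, spec, rng)
        seq = apply_events(ref, events)
        if spec.error_rate > 0:
            arr = list(seq)
            hits = np.nonzero(rng.random(len(arr)) < spec.error_rate)[0]
            for pos in hits:
                arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
            seq = "".join(arr)
        reads.append((f"read_{i:06d}|truth={pattern}", seq))
    return reads


# ---------------------------------------------------------------------------
# Time-course generation
# ---------------------------------------------------------------------------

def default_pattern_mix(t: float) -> dict[str, float]:
    """Time-varying pattern mixture: early 1-bp insertions, late MH deletions.

    At t -> 0 the mix is insertion-heavy (fast NHEJ); MH deletion weight
    rises with a ~24 h timescale (delayed MMEJ), echoing the observed
    3-6 h insertion peak and late-phase MH accumulation.
    """
    late = 1.0 - np.exp(-t / 24.0)
    w = {
        "1bp Ins": 0.40 * np.exp(-t / 18.0) + 0.12,
        "Large Ins": 0.04,
        "MH Small Del": 0.08 + 0.22 * late,
        "NonMH Small Del": 0.18,
        "MH Large Del": 0.04 + 0.12 * late,
        "NonMH Large Del": 0.06 + 0.06 * late,
        "Mut": 0.06,
    }
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def gen_timecourse_counts(
    params: KineticParams,
    times: np.ndarray | None = None,
    depth: int = 5_000,
    pattern_mix=default_pattern_mix,
    seed: int = 0,
) -> TimeCourse:
    """Sample an editing time course from known kinetics.

    The edited read count at each time is Binomial(depth, F(t)) with
    F(t) = f_max * e(t) from the ODE; edited reads split multinomially
    over patterns according to ``pattern_mix(t)``.
    """
    t = np.asarray(DEFAULT_TIME_GRID_H if times is None else times, dtype=float)
    rng = np.random.default_rng(seed)
    F = simulate_repair_ode(params, t)["F"].to_numpy()
    edited = rng.binomial(depth, F)
    counts = np.zeros((t.size, len(EDITED_PATTERNS)), dtype=int)
    for i, ti in enumerate(t):
        mix = pattern_mix(ti)
        p = np.array([mix[pat] for pat in EDITED_PATTERNS])
        counts[i] = rng.multinomial(edited[i], p)
    pattern_counts = pd.DataFrame(counts, index=pd.Index(t, name="time_h"),
                                  columns=list(EDITED_PATTERNS))
    return TimeCourse(
        times=t,
        edited_fraction=edited / depth,
        pattern_counts=pattern_counts,
        total_reads=np.full(t.size, depth),
    )


# ---------------------------------------------------------------------------
# Screen generation
# ---------------------------------------------------------------------------

@dataclass
class ScreenSpec:
    """Composition and effect structure of a synthetic pooled screen."""

    n_genes: int = 200
    guides_per_gene: int = 6
    n_mirna: int = 20
    guides_per_mirna: int = 4
    n_nontarget: int = 50
    mean_reads: float = 200.0  # negative-binomial mean per guide
    nb_dispersion: float = 10.0  # NB shape; larger = closer to Poisson
    baseline_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_PROBS))
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)

    @classmethod
    def full_scale(cls, **kwargs) -> "ScreenSpec":
        """The published GeCKOv2 composition (122,756 guides)."""
        return cls(n_genes=19_050, guides_per_gene=6,
                   n_mirna=1_864, guides_per_mirna=4,
                   n_nontarget=1_000, **kwargs)

    @property
    def n_guides(self) -> int:
        return (self.n_genes * self.guides_per_gene
                + self.n_mirna * self.guides_per_mirna
                + self.n_nontarget)


def _random_guide_seqs(n: int, rng: np.random.Generator, length: int = 20) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in batch:
            s = "".join(_BASES[row])
            if s not in seqs:
                seqs.add(s)
                out.append(s)
    return out


def gen_screen_manifest(spec: ScreenSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Guide manifest: guide_id, gene, category, guide_sequence, guide_offset."""
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    mirnas = [f"MIR{i:04d}" for i in range(spec.n_mirna)]
    rows_gene = {
        "guide_id": [f"{g}_sg{j + 1}" for g in genes
                     for j in range(spec.guides_per_gene)],
        "gene": [g for g in genes for _ in range(spec.guides_per_gene)],
        "category": "gene",
    }
    rows_mir = {
        "guide_id": [f"{m}_sg{j + 1}" for m in mirnas
                     for j in range(spec.guides_per_mirna)],
        "gene": [m for m in mirnas for _ in range(spec.guides_per_mirna)],
        "category": "miRNA",
    }
    rows_nt = {
        "guide_id": [f"NT_sg{j + 1}" for j in range(spec.n_nontarget)],
        "gene": [f"NT{j + 1:04d}" for j in range(spec.n_nontarget)],
        "category": "nontarget",
    }
    manifest = pd.concat(
        [pd.DataFrame(r) for r in (rows_gene, rows_mir, rows_nt)],
        ignore_index=True,
    )
    manifest["guide_sequence"] = _random_guide_seqs(len(manifest), rng)
    manifest["guide_offset"] = 0
    return manifest


def gen_screen_dataset(
    spec: ScreenSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (manifest, guide x outcome counts, truth table).

    Every guide draws its edited-read depth from a negative binomial
    (mean ``spec.mean_reads``) and splits it multinomially over the seven
    patterns.  Guides of a planted-effect gene use the baseline with that
    pattern's probability multiplied by the fold change and the remainder
    renormalized; non-targeting guides always use the baseline.
    """
    rng = np.random.default_rng(seed)
    manifest = gen_screen_manifest(spec, rng)
    n = len(manifest)
    r = spec.nb_dispersion
    p_nb = r / (r + spec.mean_reads)
    depths = rng.negative_binomial(r, p_nb, size=n)

    base = np.array([spec.baseline_probs[p] for p in EDITED_PATTERNS])
    base = base / base.sum()
    counts = np.empty((n, len(EDITED_PATTERNS)), dtype=int)

    effect_probs: dict[str, np.ndarray] = {}
    for gene, pattern, fold in spec.planted_effects:
        q = base.copy()
        j = EDITED_PATTERNS.index(pattern)
        q[j] = q[j] * fold
        others = [i for i in range(len(q)) if i != j]
        if q[j] >= 1.0:
            raise ValueError("planted effect pushes probability past 1")
        q[others] = q[others] * (1 - q[j]) / q[others].sum()
        effect_probs[gene] = q

    gene_col = manifest["gene"].to_numpy()
    planted_mask = np.isin(gene_col, list(effect_probs))
    idx_base = np.nonzero(~planted_mask)[0]
    # Vectorized multinomial via conditional binomials (fast at full scale).
    counts[idx_base] = _fast_multinomial(depths[idx_base], base, rng)
    for gene, q in effect_probs.items():
        idx = np.nonzero(gene_col == gene)[0]
        counts[idx] = np.array([rng.multinomial(d, q) for d in depths[idx]])

    records = manifest[["guide_id", "gene", "category"]].copy()
    for j, pat in enumerate(EDITED_PATTERNS):
        records[pat] = counts[:, j]
    truth = pd.DataFrame(spec.planted_effects,
                         columns=["gene", "pattern", "fold_change"])
    return manifest, records, truth


def _fast_multinomial(depths: np.ndarray, probs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Multinomial sampling with per-row totals via sequential binomials."""
    n = depths.astype(np.int64).copy()
    out = np.zeros((depths.size, probs.size), dtype=np.int64)
    remaining_p = 1.0
    for j in range(probs.size - 1):
        pj = probs[j] / remaining_p
        out[:, j] = rng.binomial(n, min(pj, 1.0))
        n -= out[:, j]
        remaining_p -= probs[j]
    out[:, -1] = n
    return out


def gen_screen_reads(
    manifest: pd.DataFrame,
    reads_per_guide: int,
    rng: np.random.Generator,
    read_length: int = 60,
) -> list[tuple[str, str]]:
    """Reads with the guide sequence at its manifest offset, for assignment tests."""
    reads = []
    for row in manifest.itertuples():
        filler_len = read_length - int(row.guide_offset) - len(row.guide_sequence)
        for i in range(reads_per_guide):
            prefix = "".join(rng.choice(_BASES, size=int(row.guide_offset)))
            filler = "".join(rng.choice(_BASES, size=max(filler_len, 0)))
            reads.append(
                (f"{row.guide_id}|read{i}", prefix + row.guide_sequence + filler)
            )
    return reads
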