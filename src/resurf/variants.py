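"""Variant representation, mutational-distance metrics, QC triage and
diversity-constrained panel selection for re-surfaced protein candidates.

Percent metrics follow the reporting convention of re-surfacing panels:
integer percentages rounded half-up, with the surface percentage using the
number of surface-exposed positions as its denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .sasa import DesignabilityMask

__all__ = [
    "VariantSequence",
    "VariantProfile",
    "QcRecord",
    "mutations_between",
    "mutation_profile",
    "validate_variant",
    "qc_triage",
    "propose_candidates",
    "select_diverse_subset",
    "exact_diverse_subset",
    "hamming_distance",
    "read_fasta",
    "write_fasta",
    "substitution_scorer",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class VariantSequence:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AA20 + "X")
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def mutations_between(wt: str, variant: str) -> list[tuple[int, str, str]]:
    """Substitutions as (1-based position, wt_aa, new_aa)."""
    if len(wt) != len(variant):
        raise ValueError(
            f"length mismatch: wt {len(wt)} vs variant {len(variant)}"
        )
    return [
        (i + 1, w, v)
        for i, (w, v) in enumerate(zip(wt.upper(), variant.upper()))
        if w != v
    ]


@dataclass
class VariantProfile:
    """Mutational-distance metrics for one variant (one monomer)."""

    variant_id: str
    n_mutations_total: int
    pct_total: int  # integer percent, half-up
    n_mutations_surface: int
    pct_surface: int
    similarity_total: float  # exact percent before rounding
    similarity_surface: float
    monomer_length: int
    n_surface_positions: int

    def as_row(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "n_mutations_total": self.n_mutations_total,
            "pct_total": self.pct_total,
            "n_mutations_surface": self.n_mutations_surface,
            "pct_surface": self.pct_surface,
            "similarity_total": round(self.similarity_total, 1),
            "similarity_surface": round(self.similarity_surface, 1),
        }


def mutation_profile(
    wt: str, variant: VariantSequence, mask: DesignabilityMask
) -> VariantProfile:
    """Mutational-distance metrics against the wild-type monomer.

    Total percent uses the monomer length as denominator; surface percent
    uses the number of surface-exposed positions.  Integer percents are
    rounded half-up; similarities are kept exact (100 − percent mutated).
    """
    muts = mutations_between(wt, variant.sequence)
    length = len(wt)
    surface = set(mask.surface_positions())
    n_surface = len(surface)
    n_surf_mut = sum(1 for pos, _, _ in muts if pos in surface)
    pct_total_exact = 100.0 * len(muts) / length
    pct_surf_exact = 100.0 * n_surf_mut / n_surface if n_surface else 0.0
    return VariantProfile(
        variant_id=variant.id,
        n_mutations_total=len(muts),
        pct_total=round_half_up(pct_total_exact),
        n_mutations_surface=n_surf_mut,
        pct_surface=round_half_up(pct_surf_exact),
        similarity_total=100.0 - pct_total_exact,
        similarity_surface=100.0 - pct_surf_exact,
        monomer_length=length,
        n_surface_positions=n_surface,
    )


def validate_variant(
    wt: str, variant: VariantSequence, mask: DesignabilityMask
) -> list[tuple[int, str, str]]:
    """Mutated positions that are not designable (empty list = compliant)."""
    designable = set(mask.designable_positions())
    return [
        (pos, w, v)
        for pos, w, v in mutations_between(wt, variant.sequence)
        if pos not in designable
    ]


# ---------------------------------------------------------------------------
# QC triage

@dataclass
class QcRecord:
    variant_id: str
    purity_sds_page: float  # percent
    sec_target_species: float  # percent
    yield_nmol: float
    relative_activity: float  # percent of WT
    endotoxin: float | None = None  # EU/mg, required for the in-vivo tier

    def __post_init__(self) -> None:
        for f in ("purity_sds_page", "sec_target_species", "yield_nmol",
                  "relative_activity"):
            v = getattr(self, f)
            if v is None:
                raise ValueError(f"{self.variant_id}: missing field {f!r}")
            if v < 0:
                raise ValueError(f"{self.variant_id}: {f} must be non-negative")


#: Selection thresholds: >90% purity, >90% SEC target species, >5 nmol
#: produced, >50% relative activity; in-vivo material additionally
#: requires <100 EU/mg endotoxin.
DEFAULT_QC_THRESHOLDS = {
    "purity_sds_page": 90.0,
    "sec_target_species": 90.0,
    "yield_nmol": 5.0,
    "relative_activity": 50.0,
    "endotoxin_max": 100.0,
}


def qc_triage(
    records: Sequence[QcRecord],
    thresholds: Mapping[str, float] | None = None,
    in_vivo_tier: bool = False,
) -> dict[str, tuple[bool, list[str]]]:
    """Pass/fail per variant with the failed criteria listed.

    All "greater than" criteria are strict, matching the stated selection
    rules; the endotoxin ceiling (strict "less than") only applies when
    ``in_vivo_tier`` is set.
    """
    th = dict(DEFAULT_QC_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    out: dict[str, tuple[bool, list[str]]] = {}
    for rec in records:
        reasons = []
        if not rec.purity_sds_page > th["purity_sds_page"]:
            reasons.append("purity_sds_page")
        if not rec.sec_target_species > th["sec_target_species"]:
            reasons.append("sec_target_species")
        if not rec.yield_nmol > th["yield_nmol"]:
            reasons.append("yield_nmol")
        if not rec.relative_activity > th["relative_activity"]:
            reasons.append("relative_activity")
        if in_vivo_tier:
            if rec.endotoxin is None:
                raise ValueError(
                    f"{rec.variant_id}: missing field 'endotoxin' for in-vivo tier"
                )
            if not rec.endotoxin < th["endotoxin_max"]:
                reasons.append("endotoxin")
        out[rec.variant_id] = (not reasons, reasons)
    return out


# ---------------------------------------------------------------------------
# Candidate proposal (surrogate scorer) and diversity selection

#: Residue types favoured on a re-engineered solvent-exposed surface:
#: polar and charged side chains keep solubility and avoid burying
#: hydrophobics on the outside of the fold.
SURFACE_COMPATIBLE = "DEKRNQSTHG"


def substitution_scorer(position: int, wt_aa: str) -> dict[str, float]:
    """Default surrogate scorer for proposing surface substitutions.

    A stand-in preference model: BLOSUM62 log-odds restricted to
    surface-compatible (polar/charged) residues, shifted to positive
    weights.  It is *not* a functional predictor — it only biases
    proposals toward chemically plausible surface residues.
    """
    blosum = _blosum62()
    scores = {}
    for aa in SURFACE_COMPATIBLE:
        if aa == wt_aa:
            continue
        scores[aa] = float(blosum[wt_aa][aa]) + 5.0  # shift: min BLOSUM62 is -4
    return scores


_BLOSUM62_CACHE = None


def _blosum62():
    global _BLOSUM62_CACHE
    if _BLOSUM62_CACHE is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62_CACHE = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62_CACHE


def propose_candidates(
    wt: str,
    mask: DesignabilityMask,
    n_candidates: int,
    mutation_range: tuple[int, int],
    rng_seed: int,
    scorer: Callable[[int, str], dict[str, float]] | None = None,
) -> list[VariantSequence]:
    """Propose variants mutated only at designable positions.

    Mutation counts are sampled uniformly within ``mutation_range``
    (inclusive); positions are drawn without replacement and the new
    residue at each position is drawn with probability proportional to the
    scorer's weight.  Deterministic for a fixed seed.
    """
    designable = mask.designable_positions()
    if not designable:
        raise ValueError("mask has no designable positions")
    lo, hi = mutation_range
    if lo < 0 or hi > len(designable) or lo > hi:
        raise ValueError(
            f"mutation_range {mutation_range} outside [0, {len(designable)}]"
        )
    scorer = scorer or substitution_scorer
    rng = np.random.default_rng(rng_seed)
    out: list[VariantSequence] = []
    for i in range(n_candidates):
        m = int(rng.integers(lo, hi + 1))
        positions = rng.choice(designable, size=m, replace=False)
        seq = list(wt)
        for pos in sorted(int(p) for p in positions):
            wt_aa = wt[pos - 1]
            weights = scorer(pos, wt_aa)
            weights.pop(wt_aa, None)
            aas = sorted(weights)
            p = np.array([max(weights[a], 0.0) for a in aas], dtype=float)
            if p.sum() <= 0 or not aas:
                continue
            seq[pos - 1] = str(rng.choice(aas, p=p / p.sum()))
        out.append(VariantSequence(id=f"cand_{i + 1}", sequence="".join(seq)))
    return out


def hamming_distance(
    a: str, b: str, positions: Sequence[int] | None = None
) -> int:
    """Hamming distance, optionally restricted to 1-based positions."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if positions is None:
        return sum(1 for x, y in zip(a, b) if x != y)
    return sum(1 for p in positions if a[p - 1] != b[p - 1])


def _pairwise(pool: Sequence[VariantSequence], positions) -> np.ndarray:
    n = len(pool)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming_distance(
                pool[i].sequence, pool[j].sequence, positions
            )
    return d


def select_diverse_subset(
    pool: Sequence[VariantSequence],
    k: int,
    wt: str,
    positions: Sequence[int] | None = None,
) -> list[VariantSequence]:
    """Greedy max–min diversity selection.

    Seeds with the pool member farthest from the wild type, then
    iteratively adds the candidate whose minimum Hamming distance (over
    ``positions``, typically the designable set) to the already-selected
    set is largest.  Ties break by pool order.  Guarantees at least half
    the optimal min-pairwise distance (classic dispersion bound).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not pool:
        raise ValueError("pool is empty")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    wt_dist = [hamming_distance(v.sequence, wt, positions) for v in pool]
    selected = [int(np.argmax(wt_dist))]
    d = _pairwise(pool, positions)
    while len(selected) < k:
        best, best_score = None, -1
        for i in range(len(pool)):
            if i in selected:
                continue
            score = min(d[i, j] for j in selected)
            if score > best_score:
                best, best_score = i, score
        selected.append(best)
    return [pool[i] for i in selected]


def exact_diverse_subset(
    pool: Sequence[VariantSequence],
    k: int,
    positions: Sequence[int] | None = None,
) -> tuple[list[VariantSequence], int]:
    """Exhaustive max–min subset (test oracle; pools up to ~12 only).

    Returns the subset maximising the minimum pairwise distance and that
    optimal distance.  For k=1 the distance is defined as +inf is not
    meaningful, so the first pool member is returned with distance 0.
    """
    if len(pool) > 12:
        raise ValueError("exact search is limited to pools of <= 12")
    if k <= 0 or k > len(pool):
        raise ValueError("invalid k")
    if k == 1:
        return [pool[0]], 0
    d = _pairwise(pool, positions)
    best_subset, best_val = None, -1
    for comb in itertools.combinations(range(len(pool)), k):
        val = min(d[i, j] for i, j in itertools.combinations(comb, 2))
        if val > best_val:
            best_subset, best_val = comb, val
    return [pool[i] for i in best_subset], int(best_val)


def min_pairwise_distance(
    subset: Sequence[VariantSequence], positions: Sequence[int] | None = None
) -> int:
    if len(subset) < 2:
        return 0
    d = _pairwise(subset, positions)
    iu = np.triu_indices(len(subset), 1)
    return int(d[iu].min())


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path) -> list[VariantSequence]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [VariantSequence(id=r.id, sequence=str(r.seq)) for r in records]


def write_fasta(variants: Sequence[VariantSequence], path: str | Path) -> None:
    lines = []
    for v in variants:
        lines.append(f">{v.id}")
        for i in range(0, len(v.sequence), 60):
            lines.append(v.sequence[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")
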