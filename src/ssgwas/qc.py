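"""Marker and sample quality control for SNP-chip genotypes.

Filter order is fixed and deliberate: (1) SNP call rate, (2) sample call
rate, (3) minor allele frequency, (4) monomorphic markers, (5) parent-
progeny Mendelian conflict rate.  Each step operates on the matrix
surviving the previous step, so MAF reflects the retained samples.  A
Mendelian conflict is an opposite-homozygote parent/offspring pair (codes
0 vs 2) at a marker where both are called; a genotyped pair whose conflict
rate exceeds the threshold flags the *offspring* for removal (the parent
may anchor other progeny).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, Pedigree

__all__ = [
    "QcThresholds",
    "QcResult",
    "allele_frequencies",
    "mendelian_conflicts",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Chip-QC thresholds; defaults follow common 60k-panel practice
    (call rates 0.90, MAF 0.05, monomorphic dropped)."""

    min_snp_call_rate: float = 0.90
    min_sample_call_rate: float = 0.90
    min_maf: float = 0.05
    drop_monomorphic: bool = True
    max_mendelian_conflict_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "min_snp_call_rate",
            "min_sample_call_rate",
            "min_maf",
            "max_mendelian_conflict_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QcResult:
    kept: GenotypeMatrix
    removed_snps: pd.DataFrame  # snp_id, reason
    removed_animals: pd.DataFrame  # animal_id, reason
    conflict_pairs: pd.DataFrame  # parent_id, offspring_id, n_conflicts, n_compared


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Second-allele frequency p_j = sum(codes) / (2 * n called) per marker."""
    called = ~np.isnan(gm.calls)
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        j = int(np.argmax(n_called == 0))
        raise ValueError(
            f"marker {gm.markers['snp_id'][j]!r} has no non-missing calls"
        )
    return np.nansum(gm.calls, axis=0) / (2.0 * n_called)


def mendelian_conflicts(gm: GenotypeMatrix, ped: Pedigree) -> pd.DataFrame:
    """Per genotyped parent-offspring pair: opposite-homozygote conflict
    count and number of markers where both members are called."""
    gidx = {a: i for i, a in enumerate(gm.ids)}
    rows = []
    for off, sire, dam in zip(ped.ids, ped.sires, ped.dams):
        if off not in gidx:
            continue
        o = gm.calls[gidx[off]]
        for parent in (sire, dam):
            if parent is None or parent not in gidx:
                continue
            p = gm.calls[gidx[parent]]
            both = ~np.isnan(o) & ~np.isnan(p)
            conflicts = int(
                np.sum(((o == 0) & (p == 2) | (o == 2) & (p == 0)) & both)
            )
            rows.append(
                {
                    "parent_id": parent,
                    "offspring_id": off,
                    "n_conflicts": conflicts,
                    "n_compared": int(both.sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["parent_id", "offspring_id", "n_conflicts", "n_compared"]
    )


def apply_qc(
    gm: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    pedigree: Pedigree | None = None,
) -> QcResult:
    """Apply the five filters in order; every removal records exactly one
    primary reason.  An empty survivor set is a valid outcome, not an error.
    """
    t = thresholds
    removed_snps: list[dict] = []
    removed_animals: list[dict] = []
    current = gm

    # 1. SNP call rate
    called = ~np.isnan(current.calls)
    snp_cr = called.mean(axis=0) if current.n_animals else np.ones(current.n_markers)
    keep = snp_cr >= t.min_snp_call_rate
    for j in np.flatnonzero(~keep):
        removed_snps.append(
            {"snp_id": current.markers["snp_id"][j], "reason": "snp_call_rate"}
        )
    current = current.subset(marker_mask=keep)

    # 2. sample call rate
    called = ~np.isnan(current.calls)
    sample_cr = called.mean(axis=1) if current.n_markers else np.ones(current.n_animals)
    keep_a = sample_cr >= t.min_sample_call_rate
    for i in np.flatnonzero(~keep_a):
        removed_animals.append(
            {"animal_id": current.ids[i], "reason": "sample_call_rate"}
        )
    current = current.subset(
        animals=[a for a, k in zip(current.ids, keep_a) if k]
    )

    # 3. MAF on the survivors
    if current.n_markers and current.n_animals:
        p = allele_frequencies(current)
        maf = np.minimum(p, 1.0 - p)
        keep = maf >= t.min_maf
        # monomorphic markers fail MAF too; reserve them for step 4's reason
        if t.drop_monomorphic:
            keep |= maf == 0.0
        for j in np.flatnonzero(~keep):
            removed_snps.append(
                {"snp_id": current.markers["snp_id"][j], "reason": "maf"}
            )
        current = current.subset(marker_mask=keep)

    # 4. monomorphic
    if t.drop_monomorphic and current.n_markers and current.n_animals:
        p = allele_frequencies(current)
        keep = (p > 0.0) & (p < 1.0)
        for j in np.flatnonzero(~keep):
            removed_snps.append(
                {"snp_id": current.markers["snp_id"][j], "reason": "monomorphic"}
            )
        current = current.subset(marker_mask=keep)

    # 5. Mendelian conflict rate per genotyped parent-offspring pair
    conflicts = pd.DataFrame(
        columns=["parent_id", "offspring_id", "n_conflicts", "n_compared"]
    )
    if pedigree is not None and current.n_markers and current.n_animals:
        conflicts = mendelian_conflicts(current, pedigree)
        if len(conflicts):
            rate = conflicts["n_conflicts"] / conflicts["n_compared"].clip(lower=1)
            bad = conflicts.loc[
                rate > t.max_mendelian_conflict_rate, "offspring_id"
            ].unique()
            for a in bad:
                removed_animals.append(
                    {"animal_id": a, "reason": "mendelian_conflict"}
                )
            if len(bad):
                current = current.subset(
                    animals=[a for a in current.ids if a not in set(bad)]
                )

    return QcResult(
        kept=current,
        removed_snps=pd.DataFrame(removed_snps, columns=["snp_id", "reason"]),
        removed_animals=pd.DataFrame(
            removed_animals, columns=["animal_id", "reason"]
        ),
        conflict_pairs=conflicts,
    )
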