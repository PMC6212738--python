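"""Pedigree and genomic relationship matrices for single-step evaluation.

Builds the numerator relationship matrix A (tabular method with inbreeding),
its inverse by Henderson's rules with Meuwissen-Luo inbreeding coefficients,
the genotyped-subset matrix A22 and its inverse, the (weighted) genomic
relationship matrix G = ZDZ'q, and the combined single-step inverse

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

with the genomic correction added into the genotyped block.

G construction is two-stage: a base scaling by sum_j d_j 2 p_j (1 - p_j)
(so that reweighting D does not drift the overall scale), then a factor q
matching mean(diag G) to mean(diag A22).  An optional blend
G <- (1 - tau) G + tau A22 (default tau = 0.05) guarantees invertibility:
with allele frequencies estimated from the genotyped animals themselves the
centered genotype columns sum to zero, so the unblended G annihilates the
all-ones vector and is exactly singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "CenteredGenotypes",
    "GenomicMatrix",
    "inbreeding",
    "numerator_relationship",
    "a_inverse",
    "subset_a22",
    "center_genotypes",
    "build_g",
    "invert_g",
    "build_h_inverse",
]


@dataclass
class RelationshipMatrix:
    """Symmetric relationship coefficients over an ordered animal list."""

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str  # {"A", "A-inverse", "A22", "A22-inverse", "G", "H-inverse"}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape inconsistent with ids")
        if len(v) and np.abs(v - v.T).max() > 1e-10:
            raise ValueError(f"{self.kind} matrix is not symmetric")
        self.values = v


@dataclass
class CenteredGenotypes:
    """Allele-frequency-centered genotype matrix Z.

    ``z[i, j] = call_ij - 2 p_j`` for observed calls; missing calls are mean
    imputed (centered value 0).  ``p`` is the second-allele frequency of the
    current genotyped population.
    """

    ids: tuple[str, ...]
    z: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.z.shape[0] != len(self.ids):
            raise ValueError("z rows inconsistent with animal ids")
        if self.z.shape[1] != len(self.p):
            raise ValueError("z columns inconsistent with frequency vector")


@dataclass
class GenomicMatrix:
    """Weighted genomic relationship G with its construction constants.

    ``values`` is the blended matrix used in the evaluation; ``unblended``
    is the exact ZDZ'q needed by SNP-effect back-solving; ``scale`` is the
    total scalar q such that ``unblended = scale * Z D Z'``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    unblended: np.ndarray
    scale: float
    tune_factor: float
    blend_tau: float


# ---------------------------------------------------------------------------
# Pedigree matrices
# ---------------------------------------------------------------------------


def _mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance per animal, in units of
    the additive variance: 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_known with one, 1 with none."""
    s, d = ped.parent_indices()
    out = np.empty(ped.n)
    for i in range(ped.n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            out[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            out[i] = 0.75 - 0.25 * F[max(si, di)]
        else:
            out[i] = 1.0
    return out


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo traversal (no dense A)."""
    s, d = ped.parent_indices()
    F = np.zeros(ped.n)
    for i in range(ped.n):
        if s[i] < 0 or d[i] < 0:
            # F_i = 0.5 a(s,d); with a missing parent the kinship term is 0
            continue
        # accumulate a_ii = sum_j L_ij^2 m_j over ancestors j of i
        L = {i: 1.0}
        aii = 0.0
        while L:
            j = max(L)
            lj = L.pop(j)
            sj, dj = s[j], d[j]
            if sj >= 0 and dj >= 0:
                mj = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0 or dj >= 0:
                mj = 0.75 - 0.25 * F[max(sj, dj)]
            else:
                mj = 1.0
            aii += lj * lj * mj
            if sj >= 0:
                L[sj] = L.get(sj, 0.0) + 0.5 * lj
            if dj >= 0:
                L[dj] = L.get(dj, 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F


def numerator_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular (recursive) method with inbreeding."""
    s, d = ped.parent_indices()
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if i:
            row = np.zeros(i)
            if si >= 0:
                row += A[si, :i]
            if di >= 0:
                row += A[di, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(ids=ped.ids, values=A, kind="A")


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """A^-1 by Henderson's rules with Meuwissen-Luo inbreeding; never forms
    the dense A."""
    s, d = ped.parent_indices()
    F = inbreeding(ped)
    m = _mendelian_variances(ped, F)
    n = ped.n
    Ainv = np.zeros((n, n))
    for i in range(n):
        alpha = 1.0 / m[i]
        Ainv[i, i] += alpha
        for p in (s[i], d[i]):
            if p >= 0:
                Ainv[i, p] -= 0.5 * alpha
                Ainv[p, i] -= 0.5 * alpha
                Ainv[p, p] += 0.25 * alpha
        if s[i] >= 0 and d[i] >= 0:
            Ainv[s[i], d[i]] += 0.25 * alpha
            Ainv[d[i], s[i]] += 0.25 * alpha
    return RelationshipMatrix(ids=ped.ids, values=Ainv, kind="A-inverse")


def subset_a22(
    source: Pedigree | RelationshipMatrix, genotyped_ids
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """A22 (pedigree relationships among genotyped animals) and its inverse.

    The inverse is computed from the dense A22 itself -- subsetting A^-1
    would give the wrong matrix.
    """
    A = source if isinstance(source, RelationshipMatrix) else numerator_relationship(source)
    idx = {a: i for i, a in enumerate(A.ids)}
    unknown = [g for g in genotyped_ids if g not in idx]
    if unknown:
        raise KeyError(f"genotyped ids not in pedigree: {unknown[:5]}")
    sel = [idx[g] for g in genotyped_ids]
    a22 = A.values[np.ix_(sel, sel)]
    a22_inv = np.linalg.inv(a22)
    a22_inv = 0.5 * (a22_inv + a22_inv.T)
    gids = tuple(genotyped_ids)
    return (
        RelationshipMatrix(ids=gids, values=a22, kind="A22"),
        RelationshipMatrix(ids=gids, values=a22_inv, kind="A22-inverse"),
    )


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------


def center_genotypes(gm: GenotypeMatrix, p: np.ndarray) -> CenteredGenotypes:
    """Center calls by twice the allele frequency; impute missing at 2p
    (centered value zero)."""
    p = np.asarray(p, dtype=float)
    if len(p) != gm.n_markers:
        raise ValueError(
            f"frequency vector length {len(p)} != {gm.n_markers} markers"
        )
    z = gm.calls - 2.0 * p
    z[np.isnan(gm.calls)] = 0.0
    return CenteredGenotypes(ids=tuple(gm.ids), z=z, p=p)


def build_g(
    z: CenteredGenotypes,
    weights: np.ndarray | None = None,
    a22: RelationshipMatrix | None = None,
    tune: bool = True,
    blend_tau: float = 0.05,
) -> GenomicMatrix:
    """Weighted genomic relationship G = ZDZ'q.

    Base scaling divides ZDZ' by sum_j d_j 2 p_j (1 - p_j); with ``tune`` a
    further factor matches mean(diag G) to mean(diag A22).  ``blend_tau``
    shrinks toward A22 for invertibility; the unblended matrix is retained
    for exact SNP-effect back-solving.
    """
    d = np.ones(z.z.shape[1]) if weights is None else np.asarray(weights, float)
    if d.shape != (z.z.shape[1],):
        raise ValueError("weight vector length inconsistent with markers")
    if (d < 0).any():
        raise ValueError("SNP weights must be non-negative")
    denom = float(np.sum(d * 2.0 * z.p * (1.0 - z.p)))
    if denom <= 0:
        raise ValueError(
            "sum d_j 2 p_j (1-p_j) is zero: all markers monomorphic or zero-weighted"
        )
    G0 = (z.z * d) @ z.z.T / denom
    tune_factor = 1.0
    if tune:
        if a22 is None:
            raise ValueError("diagonal tuning requires A22")
        mg = float(np.mean(np.diag(G0)))
        if mg <= 0:
            raise ValueError("mean diagonal of base G is zero; cannot tune")
        tune_factor = float(np.mean(np.diag(a22.values))) / mg
    G_unblended = tune_factor * G0
    scale = tune_factor / denom
    if blend_tau and a22 is not None:
        if not (0.0 <= blend_tau < 1.0):
            raise ValueError("blend_tau must be in [0, 1)")
        G = (1.0 - blend_tau) * G_unblended + blend_tau * a22.values
    else:
        G = G_unblended
    G = 0.5 * (G + G.T)
    return GenomicMatrix(
        ids=z.ids,
        values=G,
        unblended=0.5 * (G_unblended + G_unblended.T),
        scale=scale,
        tune_factor=tune_factor,
        blend_tau=float(blend_tau) if a22 is not None else 0.0,
    )


def invert_g(g: GenomicMatrix) -> RelationshipMatrix:
    """Inverse of the (blended) G for the single-step system."""
    try:
        gi = np.linalg.inv(g.values)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "G is singular; enable blending (blend_tau > 0) before inversion"
        ) from exc
    # guard against quietly inverting a numerically singular matrix
    if not np.isfinite(gi).all() or np.linalg.norm(g.values @ gi - np.eye(len(gi)), ord="fro") > 1e-6 * len(gi):
        raise np.linalg.LinAlgError(
            "G is numerically singular; enable blending (blend_tau > 0)"
        )
    return RelationshipMatrix(ids=g.ids, values=0.5 * (gi + gi.T), kind="G-inverse")


def build_h_inverse(
    a_inv: RelationshipMatrix,
    a22_inv: RelationshipMatrix,
    g_inv: RelationshipMatrix,
) -> RelationshipMatrix:
    """H^-1 = A^-1 with (G^-1 - A22^-1) added into the genotyped block."""
    if a22_inv.ids != g_inv.ids:
        raise ValueError("A22^-1 and G^-1 id ordering differs")
    idx = {a: i for i, a in enumerate(a_inv.ids)}
    unknown = [g for g in a22_inv.ids if g not in idx]
    if unknown:
        raise KeyError(f"genotyped ids not in pedigree: {unknown[:5]}")
    sel = np.array([idx[g] for g in a22_inv.ids], dtype=int)
    H = a_inv.values.copy()
    if len(sel):
        H[np.ix_(sel, sel)] += g_inv.values - a22_inv.values
    return RelationshipMatrix(ids=a_inv.ids, values=H, kind="H-inverse")
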