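"""Iteratively weighted single-step GWAS: GEBV back-solving, SNP variance
weights and 5-SNP sliding-window percent-of-genetic-variance scoring.

The loop (default two weighting rounds):

1. D = I; build G = ZDZ'q.
2. Solve the single-step mixed model for GEBVs of all animals.
3. Back-solve SNP effects u = q D Z' G^-1 a_g from the genotyped GEBVs.
4. Reweight d_i = u_i^2 2 p_i (1 - p_i).
5. Normalize so tr(D) = m (total variance kept constant).
6. Rebuild G and repeat from 2.

Back-solving always uses the *unblended* G: blending with A22 is a
numerical device for inverting G inside H^-1, not part of the SNP-effect
map.  Because the centered genotype columns sum to zero, the unblended G
annihilates the all-ones vector; GEBVs are therefore mean-centered across
genotyped animals first (breeding values are defined only up to the base)
and the solve is deflated on that null direction, after which
Z u = (a_g - mean a_g) holds to machine precision.

Window scoring: pct(window) = 100 x Var(sum_{j in window} z_j u_j) / sigma_a^2
over genotyped animals, sliding one SNP at a time within each chromosome
(windows never span chromosome boundaries).  The denominator is the REML
total additive variance by default; ``denominator="empirical"`` uses
Var(Z u), which makes an all-marker window score exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, Pedigree
from .mixed_model import ModelSpec, VarianceComponents, build_design, solve_mme
from .qc import allele_frequencies
from .relationship import (
    CenteredGenotypes,
    GenomicMatrix,
    a_inverse,
    build_g,
    build_h_inverse,
    center_genotypes,
    invert_g,
    subset_a22,
)

__all__ = [
    "SnpEffectSet",
    "WindowScan",
    "backsolve_snp_effects",
    "update_weights",
    "run_ssgwas",
    "window_variance",
    "select_regions",
    "region_snp_table",
    "manhattan_table",
]


@dataclass
class SnpEffectSet:
    """Per-marker effects for one trait plus the weight trajectory
    (initial identity weights followed by each reweighting)."""

    trait: str
    u_hat: np.ndarray
    weight_history: list  # length = iterations completed + 1
    iterations: int
    gebv_genotyped: np.ndarray = field(default=None, repr=False)

    @property
    def weights(self) -> np.ndarray:
        return self.weight_history[-1]


@dataclass
class WindowScan:
    """Sliding-window percent of genetic variance per trait.

    ``windows`` columns: trait, chrom, start_index, snp_ids (comma joined),
    start_bp, end_bp, pct_var.  ``sigma_a_total`` records the per-trait
    denominator used.
    """

    windows: pd.DataFrame
    sigma_a_total: dict
    window_size: int
    denominator: str


def backsolve_snp_effects(
    a_g: np.ndarray,
    z: CenteredGenotypes,
    weights: np.ndarray,
    g: GenomicMatrix,
    ridge: float | None = None,
) -> np.ndarray:
    """Convert genotyped-animal GEBVs to SNP effects:
    u = q D Z' [Z D Z' q]^-1 a_g, using the unblended G.

    ``a_g`` is mean-centered first; the singular direction (all-ones, an
    exact null vector of the unblended G) is deflated so the solve is the
    Moore-Penrose action on the centered GEBVs.  ``ridge`` optionally adds
    a small diagonal instead (legacy behaviour for ill-conditioned G).
    """
    a_g = np.asarray(a_g, float)
    n = len(a_g)
    if g.unblended.shape != (n, n):
        raise ValueError("GEBV vector length inconsistent with G")
    a_c = a_g - a_g.mean()
    G = g.unblended
    if ridge is not None:
        M = G + ridge * np.eye(n)
    else:
        # deflate the known null direction; exact on the 1-orthogonal space
        c = float(np.mean(np.diag(G)))
        M = G + c * np.ones((n, n)) / n
    try:
        sol = np.linalg.solve(M, a_c)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "unblended G is singular beyond its centering null space; "
            "blending is incompatible with exact back-solving -- retry with "
            "ridge=1e-8"
        ) from exc
    d = np.asarray(weights, float)
    return g.scale * d * (z.z.T @ sol)


def update_weights(u_hat: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d_i = u_i^2 2 p_i (1 - p_i), normalized so the weights sum to the
    marker count (total variance constant across iterations)."""
    u_hat = np.asarray(u_hat, float)
    p = np.asarray(p, float)
    if u_hat.shape != p.shape:
        raise ValueError("u_hat and p must have the same length")
    raw = u_hat**2 * 2.0 * p * (1.0 - p)
    total = raw.sum()
    if total <= 0:
        raise ValueError("all SNP weights are zero; nothing to reweight")
    # divide before scaling: m/total can overflow when effects are tiny
    return raw / total * len(raw)


@dataclass
class SsgwasResult:
    effects: dict  # trait -> SnpEffectSet
    scan: WindowScan
    z: CenteredGenotypes
    p: np.ndarray


def run_ssgwas(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    traits_table: pd.DataFrame,
    spec: ModelSpec,
    varcomp: VarianceComponents,
    n_iterations: int = 2,
    window_size: int = 5,
    blend_tau: float = 0.05,
    tune: bool = True,
    denominator: str = "reml",
    threshold_pct: float = 1.0,
) -> SsgwasResult:
    """Run the full weighted single-step scan.

    Variance components stay fixed across iterations -- the weights change
    G, not sigma^2.  Each trait carries its own weight trajectory: the
    multi-trait system is re-solved with that trait's weighted G
    (``n_iterations=0`` gives the classical unweighted SNP effects).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    p = allele_frequencies(genotypes)
    z = center_genotypes(genotypes, p)
    ainv = a_inverse(pedigree)
    a22, a22_inv = subset_a22(pedigree, genotypes.ids)
    design = build_design(traits_table, spec, pedigree.ids)
    Y = traits_table[list(spec.traits)]

    effects: dict[str, SnpEffectSet] = {}
    for ti, trait in enumerate(spec.traits):
        d = np.ones(genotypes.n_markers)
        history = [d.copy()]
        u_hat = None
        a_g = None
        passes = max(1, n_iterations)
        for _ in range(passes):
            g = build_g(z, weights=d, a22=a22, tune=tune, blend_tau=blend_tau)
            ginv = invert_g(g)
            hinv = build_h_inverse(ainv, a22_inv, ginv)
            sol = solve_mme(design, hinv, varcomp, Y)
            a_g = sol.gebv(genotypes.ids, trait)
            u_hat = backsolve_snp_effects(a_g, z, d, g)
            if n_iterations > 0:
                d = update_weights(u_hat, p)
                history.append(d.copy())
        effects[trait] = SnpEffectSet(
            trait=trait,
            u_hat=u_hat,
            weight_history=history,
            iterations=n_iterations,
            gebv_genotyped=a_g,
        )

    sigma_a = {
        trait: float(varcomp.sigma_a[i, i]) for i, trait in enumerate(spec.traits)
    }
    scan = window_variance(
        z,
        {t: e.u_hat for t, e in effects.items()},
        sigma_a,
        genotypes.markers,
        window_size=window_size,
        denominator=denominator,
    )
    return SsgwasResult(effects=effects, scan=scan, z=z, p=p)


def window_variance(
    z: CenteredGenotypes,
    u_hat: dict,
    sigma_a: dict,
    markers: pd.DataFrame,
    window_size: int = 5,
    denominator: str = "reml",
) -> WindowScan:
    """Score every sliding window of ``window_size`` consecutive SNPs on a
    chromosome: 100 x Var(window genetic value across animals) / sigma_a^2.

    A chromosome with fewer markers than the window contributes no windows
    (logged in ``windows.attrs['skipped_chromosomes']``).
    """
    if denominator not in ("reml", "empirical"):
        raise ValueError(f"unknown denominator {denominator!r}")
    rows = []
    skipped = []
    denominators = {}
    for trait, u in u_hat.items():
        u = np.asarray(u, float)
        if denominator == "reml":
            denom = float(sigma_a[trait])
        else:
            denom = float(np.var(z.z @ u, ddof=1))
        denominators[trait] = denom
        for chrom, cidx in markers.groupby("chrom", sort=False).indices.items():
            cidx = np.sort(np.asarray(cidx))
            m_c = len(cidx)
            if m_c < window_size:
                skipped.append((trait, chrom, m_c))
                continue
            zc = z.z[:, cidx]
            uc = u[cidx]
            # genetic value per animal for every window, via cumulative sums
            gv = zc * uc
            cums = np.cumsum(gv, axis=1)
            pad = np.zeros((gv.shape[0], 1))
            cums = np.hstack([pad, cums])
            for s in range(m_c - window_size + 1):
                a_i = cums[:, s + window_size] - cums[:, s]
                var = float(np.var(a_i, ddof=1))
                pct = 100.0 * var / denom if denom > 0 else np.nan
                ids = markers["snp_id"].to_numpy()[cidx[s: s + window_size]]
                rows.append(
                    {
                        "trait": trait,
                        "chrom": chrom,
                        "start_index": int(cidx[s]),
                        "snp_ids": ",".join(ids),
                        "start_bp": int(markers["pos"].to_numpy()[cidx[s]]),
                        "end_bp": int(
                            markers["pos"].to_numpy()[cidx[s + window_size - 1]]
                        ),
                        "pct_var": pct,
                    }
                )
    windows = pd.DataFrame(
        rows,
        columns=[
            "trait",
            "chrom",
            "start_index",
            "snp_ids",
            "start_bp",
            "end_bp",
            "pct_var",
        ],
    )
    windows.attrs["skipped_chromosomes"] = skipped
    return WindowScan(
        windows=windows,
        sigma_a_total=denominators,
        window_size=window_size,
        denominator=denominator,
    )


def select_regions(scan: WindowScan, threshold_pct: float = 1.0) -> pd.DataFrame:
    """Windows at or above the threshold, merged per trait into regions
    when they overlap; the reported percent is the best window's.

    Columns: trait, chrom, start_index, end_index (inclusive marker index
    span), start_bp, end_bp, snp_ids, pct_var.
    """
    w = scan.windows
    selected = w[w["pct_var"] >= threshold_pct]
    rows = []
    for (trait, chrom), grp in selected.groupby(["trait", "chrom"], sort=False):
        grp = grp.sort_values("start_index")
        size = scan.window_size
        current = None
        for _, r in grp.iterrows():
            s, e = int(r["start_index"]), int(r["start_index"]) + size - 1
            if current is not None and s <= current["end_index"]:
                current["end_index"] = max(current["end_index"], e)
                current["end_bp"] = max(current["end_bp"], int(r["end_bp"]))
                current["pct_var"] = max(current["pct_var"], float(r["pct_var"]))
                ids = current["snp_ids"].split(",") + r["snp_ids"].split(",")
                current["snp_ids"] = ",".join(dict.fromkeys(ids))
            else:
                if current is not None:
                    rows.append(current)
                current = {
                    "trait": trait,
                    "chrom": chrom,
                    "start_index": s,
                    "end_index": e,
                    "start_bp": int(r["start_bp"]),
                    "end_bp": int(r["end_bp"]),
                    "snp_ids": r["snp_ids"],
                    "pct_var": float(r["pct_var"]),
                }
        if current is not None:
            rows.append(current)
    return pd.DataFrame(
        rows,
        columns=[
            "trait",
            "chrom",
            "start_index",
            "end_index",
            "start_bp",
            "end_bp",
            "snp_ids",
            "pct_var",
        ],
    )


def region_snp_table(regions: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Expand merged regions to one row per member SNP (the shape of the
    candidate-region report): trait, chrom, pos, snp_id, pct_var."""
    pos_by_id = dict(zip(markers["snp_id"], markers["pos"]))
    rows = []
    for _, r in regions.iterrows():
        for sid in r["snp_ids"].split(","):
            rows.append(
                {
                    "trait": r["trait"],
                    "chrom": r["chrom"],
                    "pos": int(pos_by_id[sid]),
                    "snp_id": sid,
                    "pct_var": float(r["pct_var"]),
                }
            )
    return pd.DataFrame(rows, columns=["trait", "chrom", "pos", "snp_id", "pct_var"])


def manhattan_table(scan: WindowScan) -> pd.DataFrame:
    """One row per window midpoint per trait (position vs percent variance),
    ready for any plotting tool."""
    w = scan.windows.copy()
    w["mid_bp"] = ((w["start_bp"] + w["end_bp"]) // 2).astype(int)
    return w[["trait", "chrom", "mid_bp", "pct_var"]]
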