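"""Synthetic sow populations with known ground truth.

Generates discrete-generation pedigrees, gene-dropped SNP-chip genotypes
and correlated multi-trait phenotypes so that every pipeline stage has a
parameter-recovery test bed: the true breeding values, planted QTL effects
and variance components are all returned alongside the data.

What is emulated
----------------
* a recorded population of which only a modest genotyped fraction carries
  chip genotypes (the genotyped subset is filled from the youngest
  generation backwards);
* six correlated reproduction traits whose default additive/residual
  covariances and genetic/phenotypic correlation structure follow
  published estimates for commercial Large White sows (low-to-moderate
  heritabilities, the strong negative LSY-NPD correlation, etc.);
* categorical fixed effects (farm, last parity, last farrow month/year);
* per-marker founder MAF drawn uniformly from a configurable range,
  missing calls at a configurable rate, and a small number of planted QTL.

Determinism: one global seed; each stage draws from its own
``numpy.random.default_rng([seed, stage])`` stream in a fixed order
(0 pedigree, 1 gene drop incl. map and founder MAF, 2 missingness and
genotyped-subset choice, 3 phenotypes, 4 sow records, 5 gene intervals),
so the full (pedigree, genotypes, traits) triple is bit-for-bit
reproducible and the complete gene-dropped matrix can be re-materialized
independently of the observed subset.

Markers recombine along each chromosome with a Poisson crossover process
(Haldane map, default 1 Morgan per chromosome); linkage can be switched
off, making markers independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneIntervalSet, GenotypeMatrix, Pedigree
from .relationship import inbreeding
from .traits import TRAIT_NAMES, SowRecordSet

__all__ = [
    "QTL",
    "TraitModel",
    "SimulationConfig",
    "GroundTruth",
    "default_trait_model",
    "single_trait_model",
    "simulate_pedigree",
    "simulate_genotypes",
    "complete_genotypes",
    "simulate_phenotypes",
    "simulate_sow_records",
    "simulate_gene_annotation",
    "marker_map_and_maf",
    "qtl_with_variance_share",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTL:
    """A planted causal marker: per-trait additive allele-substitution
    effects at an existing marker position."""

    chrom: str
    pos_bp: int
    effects: tuple[float, ...]


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric square root via eigendecomposition; exact for singular
    covariance targets (a zero matrix yields exactly zero draws)."""
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    return v * np.sqrt(np.clip(w, 0.0, None))


def _psd_clip(m: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Nearest PSD matrix by eigenvalue clipping (printed, rounded
    correlation tables are not always exactly PSD)."""
    m = 0.5 * (np.asarray(m, float) + np.asarray(m, float).T)
    w, v = np.linalg.eigh(m)
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


@dataclass(frozen=True)
class TraitModel:
    """Trait count, names, (co)variance targets and fixed-effect layout.

    ``sigma_a`` is the *total* additive covariance target; planted QTL
    variance is carved out of it and the remainder becomes the polygenic
    covariance of the pedigree recursion.
    """

    names: tuple[str, ...]
    sigma_a: np.ndarray
    sigma_e: np.ndarray
    means: np.ndarray
    fixed_factors: dict = field(
        default_factory=lambda: {
            "farm": 6,
            "last_parity": 10,
            "last_farrow_month": 12,
            "last_farrow_year": 4,
        }
    )
    # per-factor effect s.d. as a fraction of the phenotypic s.d. per trait
    fixed_effect_scale: dict = field(
        default_factory=lambda: {
            "farm": 0.25,
            "last_parity": 0.15,
            "last_farrow_month": 0.10,
            "last_farrow_year": 0.10,
        }
    )

    def __post_init__(self) -> None:
        t = len(self.names)
        for name in ("sigma_a", "sigma_e"):
            m = np.asarray(getattr(self, name), float)
            if m.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if np.abs(m - m.T).max() > 1e-8:
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8 * max(1.0, np.abs(m).max()):
                raise ValueError(f"{name} must be positive semi-definite")

    @property
    def n_traits(self) -> int:
        return len(self.names)

    @property
    def sigma_p(self) -> np.ndarray:
        return np.asarray(self.sigma_a) + np.asarray(self.sigma_e)


# Default six-trait regime: additive and residual variances plus genetic /
# phenotypic correlations typical of commercial Large White sow reproduction
# data (heritabilities 0.07-0.25; LSY and NPD almost perfectly negatively
# correlated by construction of the two traits).
_SA2 = np.array([0.30, 0.44, 1.31, 0.01, 2.78, 115.60])
_SE2 = np.array([2.15, 2.55, 15.46, 0.02, 12.09, 343.50])
_RG = np.array(
    [
        [1.00, 0.87, -0.21, 0.25, 0.90, -0.26],
        [0.87, 1.00, -0.15, 0.08, 0.73, -0.08],
        [-0.21, -0.15, 1.00, -0.53, -0.41, 0.53],
        [0.25, 0.08, -0.53, 1.00, 0.65, -0.99],
        [0.90, 0.73, -0.41, 0.65, 1.00, -0.65],
        [-0.26, -0.08, 0.53, -0.99, -0.65, 1.00],
    ]
)
_RP = np.array(
    [
        [1.00, 0.83, 0.02, -0.10, 0.92, 0.08],
        [0.83, 1.00, 0.05, -0.06, 0.77, 0.05],
        [0.02, 0.05, 1.00, -0.38, -0.14, 0.39],
        [-0.10, -0.06, -0.38, 1.00, 0.29, -0.99],
        [0.92, 0.77, -0.14, 0.29, 1.00, -0.31],
        [0.08, 0.05, 0.39, -0.99, -0.31, 1.00],
    ]
)


def default_trait_model() -> TraitModel:
    sa = np.sqrt(_SA2)
    sp = np.sqrt(_SA2 + _SE2)
    sigma_a = _psd_clip(np.outer(sa, sa) * _RG)
    sigma_p = _psd_clip(np.outer(sp, sp) * _RP)
    sigma_e = _psd_clip(sigma_p - sigma_a, floor=1e-6)
    return TraitModel(
        names=TRAIT_NAMES,
        sigma_a=sigma_a,
        sigma_e=sigma_e,
        means=np.array([10.0, 11.0, 6.0, 2.3, 23.0, 60.0]),
    )


def single_trait_model(
    h2: float, sigma_p: float = 1.0, name: str = "T1", mean: float = 0.0
) -> TraitModel:
    """Convenience single-trait model with heritability ``h2``."""
    sa2 = h2 * sigma_p
    return TraitModel(
        names=(name,),
        sigma_a=np.array([[sa2]]),
        sigma_e=np.array([[sigma_p - sa2]]),
        means=np.array([mean]),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_founders: int = 80
    n_generations: int = 3
    offspring_per_mating: int = 2
    # fraction of each generation that is male; commercial herds run few
    # boars against many sows, so values well below 0.5 are realistic
    male_fraction: float = 0.5
    n_chromosomes: int = 5
    markers_per_chromosome: int = 100
    chromosome_length_bp: int = 140_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    genotyped_fraction: float = 0.5
    linkage: bool = True
    morgans_per_chromosome: float = 1.0
    qtls: tuple[QTL, ...] = ()
    traits: TraitModel = field(default_factory=default_trait_model)

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_generations < 1:
            raise ValueError("need at least 1 offspring generation")
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("male_fraction must be in (0, 1)")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("missing_rate", "genotyped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for q in self.qtls:
            if not 1 <= q.pos_bp <= self.chromosome_length_bp:
                raise ValueError(f"QTL position {q.pos_bp} outside chromosome")
            if len(q.effects) != self.traits.n_traits:
                raise ValueError("QTL effect vector length != trait count")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass
class GroundTruth:
    """True breeding values, QTL effects and realized variance components."""

    tbv: pd.DataFrame  # animals x traits
    qtl: pd.DataFrame  # snp_id, chrom, pos, maf, effect per trait
    sigma_poly: np.ndarray
    sigma_qtl: np.ndarray
    realized_sigma_a: np.ndarray
    realized_sigma_e: np.ndarray


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Discrete generations, random mating: every non-founder has one sire
    and one dam from the previous generation; each dam is mated to one
    random sire and produces ``offspring_per_mating`` offspring."""
    rng = np.random.default_rng([config.seed, 0])
    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []

    def assign_sexes(members: list[str]) -> tuple[list[str], list[str]]:
        n_males = max(1, int(round(config.male_fraction * len(members))))
        n_males = min(n_males, len(members) - 1)
        order = rng.permutation(len(members))
        males = [members[i] for i in sorted(order[:n_males])]
        females = [m for m in members if m not in set(males)]
        return males, females

    gen = [f"G0_{k:05d}" for k in range(config.n_founders)]
    ids += gen
    sires += [None] * len(gen)
    dams += [None] * len(gen)
    for g in range(1, config.n_generations + 1):
        males, females = assign_sexes(gen)
        if not males or not females:
            raise ValueError(f"generation {g - 1} lacks animals of one sex")
        nxt: list[str] = []
        k = 0
        for dam in females:
            sire = males[int(rng.integers(len(males)))]
            for _ in range(config.offspring_per_mating):
                child = f"G{g}_{k:05d}"
                k += 1
                nxt.append(child)
                ids.append(child)
                sires.append(sire)
                dams.append(dam)
        gen = nxt
    return Pedigree(ids=tuple(ids), sires=tuple(sires), dams=tuple(dams))


# ---------------------------------------------------------------------------
# Genotypes (gene dropping)
# ---------------------------------------------------------------------------


def _draw_map_and_maf(rng, config: SimulationConfig):
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    mpc = config.markers_per_chromosome
    pos = np.linspace(1, config.chromosome_length_bp, mpc, dtype=np.int64)
    rows = []
    for c in chroms:
        for j in range(mpc):
            rows.append({"snp_id": f"snp_{c}_{j:04d}", "chrom": c, "pos": int(pos[j])})
    markers = pd.DataFrame(rows)
    lo, hi = config.founder_maf_range
    maf = rng.uniform(lo, hi, size=len(markers))
    return markers, maf


def marker_map_and_maf(config: SimulationConfig):
    """The marker map and sampled founder MAF the gene drop will use
    (identical draws, independent of whether genotypes were generated yet)."""
    rng = np.random.default_rng([config.seed, 1])
    return _draw_map_and_maf(rng, config)


def _recomb_probs(config: SimulationConfig) -> np.ndarray:
    """Per-marker probability that the gamete switches source haplotype
    relative to the previous marker; 0.5 at each chromosome start (free
    recombination between chromosomes and a random starting haplotype)."""
    m = config.n_markers
    mpc = config.markers_per_chromosome
    if config.linkage and mpc > 1:
        d = config.morgans_per_chromosome / (mpc - 1)
        r = 0.5 * (1.0 - np.exp(-2.0 * d))  # Haldane
    else:
        r = 0.5
    probs = np.full(m, r)
    probs[::mpc] = 0.5
    return probs


def _gene_drop(ped: Pedigree, config: SimulationConfig):
    """Drop founder haplotypes through the pedigree; returns the marker map,
    founder MAF and the complete (no-missing) allele-count matrix."""
    rng = np.random.default_rng([config.seed, 1])
    markers, maf = _draw_map_and_maf(rng, config)
    m = len(markers)
    n = ped.n
    s, d = ped.parent_indices()
    rprob = _recomb_probs(config)
    hap = np.zeros((n, 2, m), dtype=np.uint8)
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            hap[i] = rng.random((2, m)) < maf
        else:
            for h, parent in enumerate((s[i], d[i])):
                switches = rng.random(m) < rprob
                inh = np.logical_xor.accumulate(switches)
                hap[i, h] = np.where(inh, hap[parent, 1], hap[parent, 0])
    calls = hap.sum(axis=1).astype(float)
    return markers, maf, calls


def complete_genotypes(ped: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """The full gene-dropped matrix for every animal, no missingness."""
    markers, _, calls = _gene_drop(ped, config)
    return GenotypeMatrix(ids=list(ped.ids), markers=markers, calls=calls)


def genotyped_subset_ids(ped: Pedigree, config: SimulationConfig) -> list[str]:
    """Which animals carry chip genotypes: youngest generations first, in
    pedigree order, up to round(fraction * n)."""
    k = int(round(config.genotyped_fraction * ped.n))
    g = ped.generations()
    order = sorted(range(ped.n), key=lambda i: (-g[i], i))
    chosen = sorted(order[:k])
    return [ped.ids[i] for i in chosen]


def simulate_genotypes(ped: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Observed genotype matrix: gene-dropped calls for the genotyped subset
    with missingness applied at ``missing_rate``."""
    markers, _, calls = _gene_drop(ped, config)
    rng = np.random.default_rng([config.seed, 2])
    gids = genotyped_subset_ids(ped, config)
    idx = {a: i for i, a in enumerate(ped.ids)}
    sub = calls[[idx[a] for a in gids], :].copy()
    if config.missing_rate > 0:
        mask = rng.random(sub.shape) < config.missing_rate
        sub[mask] = np.nan
    return GenotypeMatrix(ids=gids, markers=markers, calls=sub)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _qtl_marker_indices(markers: pd.DataFrame, qtls) -> list[int]:
    out = []
    key = {(c, p): j for j, (c, p) in enumerate(zip(markers["chrom"], markers["pos"]))}
    for q in qtls:
        j = key.get((q.chrom, q.pos_bp))
        if j is None:
            raise ValueError(
                f"QTL at {q.chrom}:{q.pos_bp} does not coincide with a marker"
            )
        out.append(j)
    return out


def qtl_with_variance_share(
    config: SimulationConfig,
    chrom: str,
    marker_index_on_chrom: int,
    share: float,
    trait_index: int = 0,
) -> QTL:
    """A QTL at an existing marker whose Hardy-Weinberg variance
    2p(1-p)a^2 equals ``share`` of the target additive variance of one
    trait (p = the founder MAF the gene drop will sample there)."""
    markers, maf = marker_map_and_maf(config)
    on_c = markers.index[markers["chrom"] == str(chrom)]
    j = int(on_c[marker_index_on_chrom])
    p = maf[j]
    sa2 = float(np.asarray(config.traits.sigma_a)[trait_index, trait_index])
    a = np.sqrt(share * sa2 / (2.0 * p * (1.0 - p)))
    effects = [0.0] * config.traits.n_traits
    effects[trait_index] = float(a)
    return QTL(chrom=str(chrom), pos_bp=int(markers["pos"][j]), effects=tuple(effects))


def simulate_phenotypes(
    ped: Pedigree, genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multi-trait phenotypes for every pedigree animal.

    breeding value = QTL allele counts x effects (centered at 2p) plus a
    polygenic deviation realized by the Mendelian-sampling recursion
    (founders ~ N(0, Sigma_poly); non-founders get the parent average plus
    a deviation with variance (0.5 - 0.25(F_s + F_d)) Sigma_poly).
    phenotype = trait mean + fixed-level effects + breeding value +
    residual ~ N(0, Sigma_e).
    """
    tm = config.traits
    t = tm.n_traits
    _qtl_marker_indices(genotypes.markers, config.qtls)  # validate positions
    markers, maf, calls = _gene_drop(ped, config)
    qidx = _qtl_marker_indices(markers, config.qtls)

    # split total additive covariance into QTL part and polygenic remainder
    sigma_qtl = np.zeros((t, t))
    for q, j in zip(config.qtls, qidx):
        a = np.asarray(q.effects, float)
        sigma_qtl += 2.0 * maf[j] * (1.0 - maf[j]) * np.outer(a, a)
    sigma_poly = np.asarray(tm.sigma_a, float) - sigma_qtl
    wmin = np.linalg.eigvalsh(sigma_poly).min()
    if wmin < -1e-6 * max(1.0, np.abs(tm.sigma_a).max()):
        raise ValueError(
            "planted QTL variance exceeds the target additive covariance"
        )
    L_poly = _psd_sqrt(_psd_clip(sigma_poly))
    L_res = _psd_sqrt(np.asarray(tm.sigma_e, float))

    rng = np.random.default_rng([config.seed, 3])
    n = ped.n
    s, d = ped.parent_indices()
    F = inbreeding(ped)

    bv = np.zeros((n, t))
    for i in range(n):
        zdraw = rng.standard_normal(t)
        if s[i] >= 0 and d[i] >= 0:
            mean = 0.5 * (bv[s[i]] + bv[d[i]])
            var_factor = 0.5 - 0.25 * (F[s[i]] + F[d[i]])
        elif s[i] >= 0 or d[i] >= 0:
            mean = 0.5 * bv[max(s[i], d[i])]
            var_factor = 0.75 - 0.25 * F[max(s[i], d[i])]
        else:
            mean = np.zeros(t)
            var_factor = 1.0
        bv[i] = mean + np.sqrt(var_factor) * (L_poly @ zdraw)

    for q, j in zip(config.qtls, qidx):
        a = np.asarray(q.effects, float)
        bv += np.outer(calls[:, j] - 2.0 * maf[j], a)

    # categorical fixed effects
    sp_sd = np.sqrt(np.diag(tm.sigma_p))
    levels: dict[str, np.ndarray] = {}
    fixed_part = np.zeros((n, t))
    for factor, n_levels in tm.fixed_factors.items():
        effects = rng.standard_normal((n_levels, t)) * (
            tm.fixed_effect_scale.get(factor, 0.0) * sp_sd
        )
        assign = rng.integers(n_levels, size=n)
        levels[factor] = assign
        fixed_part += effects[assign]

    resid = rng.standard_normal((n, t)) @ L_res.T
    y = np.asarray(tm.means, float) + fixed_part + bv + resid

    table = pd.DataFrame(y, index=list(ped.ids), columns=list(tm.names))
    for factor, assign in levels.items():
        table[factor] = [f"{factor}_{v + 1}" for v in assign]
    table.index.name = "animal"

    truth = GroundTruth(
        tbv=pd.DataFrame(bv, index=list(ped.ids), columns=list(tm.names)),
        qtl=pd.DataFrame(
            [
                {
                    "snp_id": markers["snp_id"][j],
                    "chrom": q.chrom,
                    "pos": q.pos_bp,
                    "maf": maf[j],
                    **{f"effect_{nm}": e for nm, e in zip(tm.names, q.effects)},
                }
                for q, j in zip(config.qtls, qidx)
            ]
        ),
        sigma_poly=sigma_poly,
        sigma_qtl=sigma_qtl,
        realized_sigma_a=np.atleast_2d(np.cov(bv, rowvar=False)),
        realized_sigma_e=np.atleast_2d(np.cov(resid, rowvar=False)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Sow-record and gene-interval layers
# ---------------------------------------------------------------------------


def simulate_sow_records(ped: Pedigree, config: SimulationConfig) -> SowRecordSet:
    """Litter-level records feeding trait derivation: litters per sow
    truncated-Poisson (>= 1, max 10 parities), gestation ~ 115 d with small
    noise, lactation ~ 24 d, wean-to-conception a few days to weeks with an
    occasional open last litter.  These distributions are generator
    defaults, deliberately not calibrated to any particular herd.
    """
    rng = np.random.default_rng([config.seed, 4])
    rows = []
    herd = {}
    for sow in ped.ids:
        n_litters = int(min(1 + rng.poisson(2.5), 10))
        farm = f"farm_{rng.integers(6) + 1}"
        year = int(2012 + rng.integers(4))
        month = int(rng.integers(12) + 1)
        total = 0.0
        for parity in range(1, n_litters + 1):
            gest = float(np.clip(np.round(115 + rng.normal(0, 1.5)), 108, 125))
            lact = float(np.clip(np.round(rng.normal(24, 3)), 14, 35))
            w2c = float(np.round(4 + rng.exponential(6)))
            open_last = parity == n_litters and rng.random() < 0.3
            born = int(rng.poisson(11))
            weaned = int(min(born, rng.poisson(10)))
            rows.append(
                {
                    "sow": sow,
                    "parity": parity,
                    "pigs_weaned": weaned,
                    "born_alive": born,
                    "w2c_days": np.nan if open_last else w2c,
                    "gestation_days": gest,
                    "lactation_days": lact,
                    "farrow_month": month,
                    "farrow_year": year,
                    "farm": farm,
                }
            )
            total += gest + lact + (0.0 if open_last else w2c)
            month = int(1 + (month + int(gest + lact + w2c) // 30 - 1) % 12)
        herd[sow] = total + float(rng.uniform(20, 60))
    return SowRecordSet(
        litters=pd.DataFrame(rows), herd_days=pd.Series(herd, name="herd_days")
    )


def simulate_gene_annotation(
    config: SimulationConfig, genes_per_chromosome: int = 20
) -> GeneIntervalSet:
    """Synthetic gene intervals covering each chromosome, including one gene
    straddling every planted QTL so annotation always has a true target."""
    rng = np.random.default_rng([config.seed, 5])
    rows = []
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        starts = np.sort(
            rng.integers(1, config.chromosome_length_bp - 200_000, genes_per_chromosome)
        )
        for k, st in enumerate(starts):
            length = int(rng.integers(5_000, 150_000))
            rows.append(
                {
                    "gene": f"GENE{chrom}_{k + 1:03d}",
                    "chrom": chrom,
                    "start": int(st),
                    "end": int(st + length),
                }
            )
    for q in config.qtls:
        rows.append(
            {
                "gene": f"QTLGENE_{q.chrom}_{q.pos_bp}",
                "chrom": str(q.chrom),
                "start": max(1, q.pos_bp - 10_000),
                "end": q.pos_bp + 10_000,
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return GeneIntervalSet(entries=df)
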