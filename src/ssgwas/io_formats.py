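"""Readers and writers for every external representation the pipeline touches.

Three in-memory value types live here because every other module consumes
them: :class:`Pedigree` (topologically ordered animal/sire/dam records),
:class:`GenotypeMatrix` (animals x markers allele counts with a marker map)
and :class:`GeneIntervalSet` (gene symbols with 1-based inclusive intervals).

Coordinate convention: all genomic coordinates are held 1-based inclusive
internally.  BED input (0-based half-open) is converted at the boundary by
incrementing the start; GFF3 is already 1-based inclusive.

Genotype coding convention: calls count copies of the *second* allele of a
locus, where the second allele is the lexicographically larger allele
observed at that locus.  This choice is arbitrary (either orientation gives
the same scan) but it is fixed and recorded so runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = ("0", "", "NA", "na", "nan")

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "GeneIntervalSet",
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_gene_annotation",
    "write_region_table",
    "read_trait_table",
    "write_trait_table",
    "write_window_scan",
]


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pedigree:
    """Ordered pedigree: parents always precede their offspring.

    ``sires[i]``/``dams[i]`` are ``None`` for unknown parents.  Construct via
    :meth:`from_records`, which validates, detects cycles and topologically
    sorts arbitrary input order.
    """

    ids: tuple[str, ...]
    sires: tuple[str | None, ...]
    dams: tuple[str | None, ...]

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, a in enumerate(self.ids):
            if a in seen:
                raise ValueError(f"duplicate animal id {a!r} in pedigree")
            seen[a] = i
        for i, (s, d) in enumerate(zip(self.sires, self.dams)):
            for p in (s, d):
                if p is None:
                    continue
                if p not in seen:
                    raise ValueError(
                        f"parent {p!r} of {self.ids[i]!r} has no pedigree record"
                    )
                if seen[p] >= i:
                    raise ValueError(
                        f"pedigree not topologically ordered: parent {p!r} "
                        f"does not precede offspring {self.ids[i]!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam positions as int arrays, -1 for unknown."""
        idx = self.index()
        s = np.array([idx[p] if p is not None else -1 for p in self.sires])
        d = np.array([idx[p] if p is not None else -1 for p in self.dams])
        return s, d

    def generations(self) -> np.ndarray:
        """Generation number per animal (founders = 0)."""
        s, d = self.parent_indices()
        g = np.zeros(self.n, dtype=int)
        for i in range(self.n):
            gp = [g[p] for p in (s[i], d[i]) if p >= 0]
            g[i] = max(gp) + 1 if gp else 0
        return g

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build from (animal, sire, dam) triples in any order.

        Unknown parents may be given as ``None`` or any of the conventional
        sentinels ("0", empty).  Raises on duplicate ids and cycles (a cycle
        error lists one offending cycle).
        """

        def norm(p):
            if p is None:
                return None
            p = str(p).strip()
            return None if p in UNKNOWN_PARENT else p

        animals = [str(r[0]).strip() for r in records]
        if len(set(animals)) != len(animals):
            dup = next(a for a in animals if animals.count(a) > 1)
            raise ValueError(f"duplicate animal id {dup!r} in pedigree")
        parents = {a: (norm(r[1]), norm(r[2])) for a, r in zip(animals, records)}
        known = set(animals)
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None and p not in known:
                    raise ValueError(
                        f"parent {p!r} of {a!r} has no pedigree record"
                    )

        # Kahn topological sort, stable in input order.
        order: list[str] = []
        placed: set[str] = set()
        pending = list(animals)
        while pending:
            progress = []
            for a in pending:
                s, d = parents[a]
                if all(p is None or p in placed for p in (s, d)):
                    order.append(a)
                    placed.add(a)
                else:
                    progress.append(a)
            if len(progress) == len(pending):
                cycle = _find_cycle(parents, progress)
                raise ValueError(
                    "pedigree contains a cycle: " + " -> ".join(cycle)
                )
            pending = progress
        return cls(
            ids=tuple(order),
            sires=tuple(parents[a][0] for a in order),
            dams=tuple(parents[a][1] for a in order),
        )


def _find_cycle(parents, candidates) -> list[str]:
    """Walk unresolvable parent links from a stuck node until one repeats."""
    stuck = set(candidates)
    node = candidates[0]
    path: list[str] = []
    pos: dict[str, int] = {}
    while node is not None and node not in pos:
        pos[node] = len(path)
        path.append(node)
        node = next(
            (p for p in parents.get(node, (None, None)) if p in stuck), None
        )
    if node is None:  # pragma: no cover - only reachable on malformed input
        return path
    return path[pos[node]:] + [node]


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with header ``animal,sire,dam`` (extra columns
    ignored); unknown parents coded "0" or empty.  Output is topologically
    ordered regardless of file order."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"animal", "sire", "dam"} - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    return Pedigree.from_records(
        list(zip(df["animal"], df["sire"], df["dam"]))
    )


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(
        {
            "animal": ped.ids,
            "sire": [s if s is not None else "0" for s in ped.sires],
            "dam": [d if d is not None else "0" for d in ped.dams],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Animals x markers second-allele counts, NaN for missing calls.

    ``markers`` has columns ``snp_id``, ``chrom``, ``pos`` (1-based bp) and is
    kept sorted by (chrom, pos); ``calls`` columns follow that order.
    """

    ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        required = {"snp_id", "chrom", "pos"}
        if not required <= set(self.markers.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.ids)} animals x {len(self.markers)} markers"
            )
        if (self.markers["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.calls[~ok].flat[0]
            raise ValueError(f"genotype codes must be 0/1/2/missing, got {bad}")
        order = self.markers.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, animals=None, marker_mask=None) -> "GenotypeMatrix":
        ids, calls, markers = self.ids, self.calls, self.markers
        if animals is not None:
            pos = {a: i for i, a in enumerate(ids)}
            unknown = [a for a in animals if a not in pos]
            if unknown:
                raise KeyError(f"animals not in genotype matrix: {unknown[:5]}")
            sel = [pos[a] for a in animals]
            ids = list(animals)
            calls = calls[sel, :]
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask, dtype=bool)
            markers = markers.loc[marker_mask].reset_index(drop=True)
            calls = calls[:, marker_mask]
        return GenotypeMatrix(ids=ids, markers=markers.copy(), calls=calls.copy())


def read_genotypes(path, format: str, map_path=None) -> GenotypeMatrix:
    """Read genotypes from PLINK text PED/MAP (``format="ped-map"``) or a
    0/1/2/NA matrix TSV with a companion map TSV (``format="matrix-tsv"``).

    PED allele pairs are coded as counts of the lexicographically larger
    allele observed at the locus; a locus with more than two alleles raises.
    """
    if format == "ped-map":
        return _read_ped_map(path, map_path)
    if format == "matrix-tsv":
        if map_path is None:
            raise ValueError("matrix-tsv format requires map_path")
        return _read_matrix_tsv(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_map(map_path) -> pd.DataFrame:
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    return pd.DataFrame(
        {"snp_id": mp["snp_id"], "chrom": mp["chrom"], "pos": mp["pos"].astype(int)}
    )


def _read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    if map_path is None:
        map_path = str(ped_path).rsplit(".", 1)[0] + ".map"
    markers = _read_map(map_path)
    m = len(markers)
    ids: list[str] = []
    pairs: list[list[str]] = []
    with open(ped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ValueError(
                    f"PED line for {tok[1] if len(tok) > 1 else '?'} has "
                    f"{len(tok) - 6} allele fields, expected {2 * m}"
                )
            ids.append(tok[1])
            pairs.append(tok[6:])
    calls = np.full((len(ids), m), np.nan)
    for j in range(m):
        a1 = [p[2 * j] for p in pairs]
        a2 = [p[2 * j + 1] for p in pairs]
        alleles = sorted(set(a1) | set(a2) - {"0"})
        alleles = [a for a in alleles if a != "0"]
        if len(alleles) > 2:
            raise ValueError(
                f"locus {markers['snp_id'][j]!r} has >2 alleles: {alleles}"
            )
        counted = alleles[-1] if alleles else None  # lexicographically larger
        for i in range(len(ids)):
            if a1[i] == "0" or a2[i] == "0":
                continue
            calls[i, j] = (a1[i] == counted) + (a2[i] == counted)
    return GenotypeMatrix(ids=ids, markers=markers, calls=calls)


def _read_matrix_tsv(path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    mp = pd.read_csv(path if map_path is None else map_path, sep="\t", dtype={"chrom": str, "snp_id": str})
    required = {"snp_id", "chrom", "pos"}
    if not required <= set(mp.columns):
        raise ValueError(f"genotype map TSV needs columns {sorted(required)}")
    if list(df.columns) != list(mp["snp_id"]):
        if set(df.columns) != set(mp["snp_id"]):
            raise ValueError("map/calls marker sets differ")
        df = df[list(mp["snp_id"])]
    return GenotypeMatrix(
        ids=[str(i) for i in df.index],
        markers=mp[["snp_id", "chrom", "pos"]].astype({"pos": int}),
        calls=df.to_numpy(dtype=float),
    )


def write_genotypes(gm: GenotypeMatrix, path, map_path) -> None:
    """Write the matrix-TSV dialect (calls TSV + map TSV); round-trips via
    :func:`read_genotypes`."""
    out = pd.DataFrame(gm.calls, index=gm.ids, columns=gm.markers["snp_id"])
    # integer-looking codes, NA for missing
    with open(path, "w") as fh:
        fh.write("animal\t" + "\t".join(gm.markers["snp_id"]) + "\n")
        for aid, row in zip(gm.ids, gm.calls):
            cells = ["NA" if math.isnan(v) else str(int(v)) for v in row]
            fh.write(str(aid) + "\t" + "\t".join(cells) + "\n")
    gm.markers.to_csv(map_path, sep="\t", index=False)
    del out


# ---------------------------------------------------------------------------
# Gene annotation intervals
# ---------------------------------------------------------------------------


@dataclass
class GeneIntervalSet:
    """Gene symbols with 1-based inclusive (chrom, start, end) intervals."""

    entries: pd.DataFrame  # columns gene, chrom, start, end

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"gene intervals need columns {sorted(required)}")
        self.entries = self.entries.reset_index(drop=True)
        bad = self.entries["start"] > self.entries["end"]
        if bad.any():
            g = self.entries.loc[bad, "gene"].iloc[0]
            raise ValueError(f"gene {g!r} has start > end after conversion")
        if (self.entries["start"] < 1).any():
            raise ValueError("gene interval starts must be >= 1")


def read_gene_annotation(path, format: str) -> GeneIntervalSet:
    """Read gene intervals from BED (0-based half-open; converted by adding 1
    to starts) or GFF3 (1-based inclusive, via gffutils; ``gene`` features,
    name from Name/gene_name/gene_id/ID attributes)."""
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}
        )
        if df.shape[1] < 4:
            df[3] = [f"feature_{i}" for i in range(len(df))]
        out = pd.DataFrame(
            {
                "gene": df[3].astype(str),
                "chrom": df[0].astype(str),
                "start": df[1].astype(int) + 1,  # 0-based -> 1-based
                "end": df[2].astype(int),
            }
        )
        return GeneIntervalSet(entries=out)
    if format == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        rows = []
        for feat in db.all_features():
            if feat.featuretype != "gene":
                continue
            name = None
            for key in ("Name", "gene_name", "gene_id", "ID"):
                if key in feat.attributes:
                    name = feat.attributes[key][0]
                    break
            rows.append(
                {
                    "gene": name or feat.id,
                    "chrom": str(feat.seqid),
                    "start": int(feat.start),
                    "end": int(feat.end),
                }
            )
        if not rows:
            raise ValueError(f"no gene features found in {path}")
        return GeneIntervalSet(entries=pd.DataFrame(rows))
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

REGION_TABLE_COLUMNS = [
    "trait",
    "chrom",
    "snp_pos",
    "snp_id",
    "gene_location",
    "candidate_gene",
    "pct_var",
]


def write_region_table(regions: pd.DataFrame, path) -> None:
    """Write the seven-column candidate-region TSV (trait, chromosome, SNP
    position, SNP id, gene location, gene, % variance with 2 decimals).

    ``gene_location`` carries "start-end" for within-gene hits and
    "<kb> kb upstream/downstream gene" for flanking hits.
    """
    df = regions.copy() if len(regions) else pd.DataFrame(columns=REGION_TABLE_COLUMNS)
    missing = set(REGION_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    df = df[REGION_TABLE_COLUMNS]
    if len(df):
        df = df.assign(pct_var=[f"{v:.2f}" for v in df["pct_var"]])
    df.to_csv(path, sep="\t", index=False)


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return df


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="animal")


def write_window_scan(scan: pd.DataFrame, path) -> None:
    """Window-scan TSV (chrom, window bp span, snp ids, trait, pct) usable by
    any plotting tool; one row per window per trait."""
    scan.to_csv(path, sep="\t", index=False)
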