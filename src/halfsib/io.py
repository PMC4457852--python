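"""Readers, writers and core containers for half-sib linkage data.

The pipeline works on chip-era tabular data: a phenotype table (animal id,
mean ovulation rate, birth year), a biallelic SNP genotype table with a
marker map, and the derived per-daughter paternal-haplotype tracks.
Genotypes are stored as counts of a per-marker designated reference allele
(0/1/2, -1 for missing); every downstream computation is symmetric to which
allele is designated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

__all__ = [
    "MISSING",
    "SnpMap",
    "PhenotypeRecord",
    "GenotypeTable",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_snp_map",
    "write_snp_map",
    "qc_filter",
]


class SnpMap:
    """Ordered marker map: id, chromosome label, bp position, cM position.

    Markers are sorted by (chromosome, pos_bp); within a chromosome bp
    positions must be strictly increasing and cM positions non-decreasing.
    Chromosome order follows first appearance after a natural sort.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"marker_id", "chrom", "pos_bp", "pos_cM"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"SnpMap missing columns: {sorted(missing_cols)}")
        df = df.copy()
        df["marker_id"] = df["marker_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        df["pos_cM"] = df["pos_cM"].astype(float)
        df = df.sort_values(
            ["chrom", "pos_bp"], key=lambda s: _natural_key(s) if s.name == "chrom" else s
        ).reset_index(drop=True)
        if df["marker_id"].duplicated().any():
            dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos_bp"].to_numpy()) > 0):
                raise ValueError(f"non-increasing bp positions on chromosome {chrom}")
            if not np.all(np.diff(sub["pos_cM"].to_numpy()) >= 0):
                raise ValueError(f"decreasing cM positions on chromosome {chrom}")
        self.df = df
        self._index = pd.Index(df["marker_id"])

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Positional indices (into the global marker order) of one chromosome."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def loc(self, marker_id: str) -> int:
        return int(self._index.get_loc(marker_id))

    def subset(self, indices: np.ndarray) -> "SnpMap":
        return SnpMap(self.df.iloc[indices])

    def __len__(self) -> int:
        return self.n_markers

    def __repr__(self) -> str:
        return f"SnpMap({self.n_markers} markers, {len(self.chromosomes())} chromosomes)"


def _natural_key(s: pd.Series) -> pd.Series:
    def key(v: str):
        return (0, int(v)) if str(v).isdigit() else (1, str(v))

    return s.map(key)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One daughter's mean ovulation rate (corpora lutea per cycle) and cohort year."""

    animal_id: str
    mean_or: float
    birth_year: int

    def __post_init__(self):
        if self.mean_or < 1.0:
            raise ValueError(
                f"{self.animal_id}: mean ovulation rate {self.mean_or} < 1 "
                "(a cycle record requires at least one corpus luteum)"
            )


@dataclass
class GenotypeTable:
    """Individuals x markers biallelic genotype codes.

    ``codes[i, j]`` counts copies of marker j's designated allele in animal i
    (0, 1 or 2), with -1 for a missing call. Rows align with ``animal_ids``;
    columns align with ``snp_map``.
    """

    animal_ids: list[str]
    snp_map: SnpMap
    codes: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.animal_ids), self.snp_map.n_markers):
            raise ValueError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.animal_ids)} animals x {self.snp_map.n_markers} markers"
            )
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype codes outside {{-1,0,1,2}}")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids in genotype table")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def row(self, animal_id: str) -> np.ndarray:
        return self.codes[self.animal_ids.index(animal_id)]

    def call_rate_animals(self) -> np.ndarray:
        return (self.codes >= 0).mean(axis=1)

    def call_rate_markers(self) -> np.ndarray:
        return (self.codes >= 0).mean(axis=0)

    def drop_animals(self, ids: set[str]) -> "GenotypeTable":
        keep = [i for i, a in enumerate(self.animal_ids) if a not in ids]
        return GenotypeTable(
            [self.animal_ids[i] for i in keep], self.snp_map, self.codes[keep]
        )


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path, dialect: str = "auto") -> list[PhenotypeRecord]:
    """Read a phenotype table: animal id, mean ovulation rate, birth year.

    ``dialect`` is one of "auto", "tab", "comma", "whitespace". A header row
    is detected by a non-numeric second field. Duplicate animal ids are an
    error.
    """
    sep = {"auto": None, "tab": "\t", "comma": ",", "whitespace": r"\s+"}.get(dialect)
    if dialect not in ("auto", "tab", "comma", "whitespace"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty phenotype file")
    if sep is None:
        sep = _sniff_sep(lines[0])
    records: list[PhenotypeRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        fields = _split(line, sep)
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
        if lineno == 1 and not _is_number(fields[1]):
            continue  # header
        aid = fields[0]
        try:
            mean_or = float(fields[1])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-numeric ovulation rate {fields[1]!r}"
            ) from None
        try:
            year = int(float(fields[2]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric birth year {fields[2]!r}") from None
        if aid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate animal id {aid!r}")
        seen.add(aid)
        records.append(PhenotypeRecord(aid, mean_or, year))
    return records


def write_phenotypes(records: list[PhenotypeRecord], path) -> None:
    df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "mean_or": [r.mean_or for r in records],
            "birth_year": [r.birth_year for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _sniff_sep(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return r"\s+"


def _split(line: str, sep: str) -> list[str]:
    if sep == r"\s+":
        return line.split()
    return [f.strip() for f in line.split(sep)]


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# marker map


def read_snp_map(path) -> SnpMap:
    """Read a marker map: TSV/CSV with marker_id/chrom/pos_bp[/pos_cM] columns,
    or a PLINK .map file (chrom, id, cM, bp). Missing cM defaults to 1 cM/Mb."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if "marker_id" in cols:
        df.columns = cols
    else:
        # PLINK .map: no header; re-read positionally
        df = pd.read_csv(
            path, sep=None, engine="python", header=None,
            names=["chrom", "marker_id", "pos_cM", "pos_bp"],
        )
    if "pos_cM" not in df.columns and "pos_cm" not in df.columns:
        df["pos_cM"] = df["pos_bp"] / 1e6  # 1 cM/Mb default
    if "pos_cm" in df.columns:
        df = df.rename(columns={"pos_cm": "pos_cM"})
    if (df["pos_cM"] == 0).all():
        df["pos_cM"] = df["pos_bp"] / 1e6
    return SnpMap(df[["marker_id", "chrom", "pos_bp", "pos_cM"]])


def write_snp_map(snp_map: SnpMap, path) -> None:
    snp_map.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, map_path=None) -> tuple[GenotypeTable, SnpMap]:
    """Read genotypes in long, wide, or PLINK PED(+MAP) layout (auto-detected).

    * long: columns animal_id, marker_id[, chrom, pos_bp], code — one call per row
    * wide: first column animal_id, remaining columns named by marker id
    * PED: standard 6 lead columns then two allele columns per marker; codes
      count the second ("B") allele per marker; "0 0" is missing

    Long/wide layouts without positional columns require ``map_path``.
    Unrecognized codes are mapped to missing, with a logged count. The
    detected layout is logged so a mismatch with expectations is visible.
    """
    path = str(path)
    if path.endswith(".ped"):
        if map_path is None:
            raise ValueError("PED input requires a .map file")
        return _read_ped(path, map_path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "marker_id" in cols or ("snp_id" in cols and "animal_id" in cols):
        logger.info("read_genotypes: detected long layout in %s", path)
        return _read_long(df, cols, map_path)
    logger.info("read_genotypes: detected wide layout in %s", path)
    return _read_wide(df, map_path)


def _code_series(raw: pd.Series, where: str) -> np.ndarray:
    codes = pd.to_numeric(raw, errors="coerce")
    bad = codes.isna() | ~codes.isin([0, 1, 2])
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: %d unrecognized genotype codes set to missing", where, n_bad)
    return np.where(bad, -1, codes.fillna(-1)).astype(np.int8)


def _read_long(df: pd.DataFrame, cols: dict, map_path) -> tuple[GenotypeTable, SnpMap]:
    marker_col = cols.get("marker_id", cols.get("snp_id"))
    animal_col = cols["animal_id"]
    code_col = cols.get("code", cols.get("genotype", df.columns[-1]))
    if map_path is not None:
        snp_map = read_snp_map(map_path)
    else:
        if "chrom" not in cols or ("pos_bp" not in cols and "pos" not in cols):
            raise ValueError("long layout without chrom/pos columns requires map_path")
        pos_col = cols.get("pos_bp", cols.get("pos"))
        mdf = df[[marker_col, cols["chrom"], pos_col]].drop_duplicates()
        mdf.columns = ["marker_id", "chrom", "pos_bp"]
        mdf["pos_bp"] = mdf["pos_bp"].astype(np.int64)
        mdf["pos_cM"] = mdf["pos_bp"] / 1e6
        snp_map = SnpMap(mdf)
    unknown = set(df[marker_col]) - set(snp_map.marker_ids)
    if unknown:
        raise ValueError(f"markers absent from map: {sorted(unknown)[:10]}")
    animals = list(dict.fromkeys(df[animal_col]))
    codes = np.full((len(animals), snp_map.n_markers), -1, dtype=np.int8)
    ai = {a: i for i, a in enumerate(animals)}
    mi = {m: j for j, m in enumerate(snp_map.marker_ids)}
    rows = df[animal_col].map(ai).to_numpy()
    colidx = df[marker_col].map(mi).to_numpy()
    codes[rows, colidx] = _code_series(df[code_col], "long genotypes")
    return GenotypeTable(animals, snp_map, codes), snp_map


def _read_wide(df: pd.DataFrame, map_path) -> tuple[GenotypeTable, SnpMap]:
    if map_path is None:
        raise ValueError("wide layout requires map_path")
    snp_map = read_snp_map(map_path)
    animals = df.iloc[:, 0].astype(str).tolist()
    marker_cols = list(df.columns[1:])
    unknown = set(marker_cols) - set(snp_map.marker_ids)
    if unknown:
        raise ValueError(f"markers absent from map: {sorted(unknown)[:10]}")
    codes = np.full((len(animals), snp_map.n_markers), -1, dtype=np.int8)
    mi = {m: j for j, m in enumerate(snp_map.marker_ids)}
    for c in marker_cols:
        codes[:, mi[c]] = _code_series(df[c], f"marker {c}")
    return GenotypeTable(animals, snp_map, codes), snp_map


def _read_ped(ped_path, map_path) -> tuple[GenotypeTable, SnpMap]:
    snp_map = read_snp_map(map_path)
    animals: list[str] = []
    rows: list[np.ndarray] = []
    # per-marker designated allele = the "B" allele: for A/B coding literally B,
    # otherwise the lexicographically larger observed allele
    with open(ped_path) as fh:
        table = [ln.split() for ln in fh if ln.strip()]
    m = snp_map.n_markers
    for fields in table:
        if len(fields) != 6 + 2 * m:
            raise ValueError(
                f"PED line for {fields[1] if len(fields) > 1 else '?'}: expected "
                f"{6 + 2 * m} fields, got {len(fields)}"
            )
    allele_pairs = np.array([f[6:] for f in table], dtype="U8").reshape(len(table), m, 2)
    designated = []
    for j in range(m):
        obs = sorted(a for a in np.unique(allele_pairs[:, j, :]) if a != "0")
        if len(obs) > 2:
            raise ValueError(f"marker {snp_map.marker_ids[j]}: >2 alleles {obs}")
        # count the "B" allele for A/B chip coding, else the larger label
        designated.append("B" if set(obs) <= {"A", "B"} else (max(obs) if obs else "?"))
    for f, pair_row in zip(table, allele_pairs):
        animals.append(f[1])
        code = np.full(m, -1, dtype=np.int8)
        for j in range(m):
            a1, a2 = pair_row[j]
            if a1 == "0" or a2 == "0":
                continue
            code[j] = (a1 == designated[j]) + (a2 == designated[j])
        rows.append(code)
    logger.info("read_genotypes: detected PED layout (%d animals)", len(animals))
    return GenotypeTable(animals, snp_map, np.array(rows)), snp_map


def write_genotypes(gt: GenotypeTable, path) -> None:
    """Write a genotype table in long layout (round-trips with read_genotypes)."""
    n, m = gt.codes.shape
    df = pd.DataFrame(
        {
            "animal_id": np.repeat(gt.animal_ids, m),
            "marker_id": np.tile(gt.snp_map.marker_ids, n),
            "chrom": np.tile(gt.snp_map.df["chrom"].to_numpy(), n),
            "pos_bp": np.tile(gt.snp_map.df["pos_bp"].to_numpy(), n),
            "code": gt.codes.ravel(),
        }
    )
    df = df[df["code"] >= 0]  # missing calls are simply absent rows
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC


def qc_filter(gt: GenotypeTable, min_call_rate: float = 0.95) -> GenotypeTable:
    """Drop animals, then markers, with call rate below ``min_call_rate``.

    The animal-then-marker order is fixed; both passes use the same threshold
    (the chip-QC convention of excluding samples and SNPs below 95% call rate).
    Idempotent. Raises if every animal would be removed.
    """
    if not 0 < min_call_rate <= 1:
        raise ValueError("min_call_rate must be in (0, 1]")
    keep_a = gt.call_rate_animals() >= min_call_rate
    if not keep_a.any():
        raise ValueError("qc_filter would remove all animals")
    n_drop_a = int((~keep_a).sum())
    animals = [a for a, k in zip(gt.animal_ids, keep_a) if k]
    codes = gt.codes[keep_a]
    keep_m = (codes >= 0).mean(axis=0) >= min_call_rate
    n_drop_m = int((~keep_m).sum())
    if n_drop_a or n_drop_m:
        logger.info("qc_filter: removed %d animals, %d markers", n_drop_a, n_drop_m)
    snp_map = gt.snp_map.subset(np.flatnonzero(keep_m))
    return GenotypeTable(animals, snp_map, codes[:, keep_m])
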