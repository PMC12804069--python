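"""Readers and writers for PLINK binary genotypes and the pipeline's tabular formats.

Dosages count copies of the A1 allele (PLINK's counted allele). Missing
genotypes are stored as :data:`MISSING` (-1) in the int8 dosage matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MISSING = np.int8(-1)

_BED_MAGIC = b"\x6c\x1b"
_BED_VARIANT_MAJOR = b"\x01"

# 2-bit PLINK codes -> A1 dosage: 00 -> 2, 01 -> missing, 10 -> 1, 11 -> 0
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, int(MISSING): 0b01}


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK binary files."""


class TableValidationError(ValueError):
    """Raised when a pedigree/phenotype table fails validation."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-dosage matrix with marker map metadata.

    ``dosage[i, j]`` is the A1-allele count of individual ``i`` at marker
    ``j``; -1 marks a missing call.
    """

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    dosage: np.ndarray
    a1: np.ndarray = None
    a2: np.ndarray = None
    sex: np.ndarray = None

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        dos = np.asarray(self.dosage)
        # float dosage arises after mean imputation; integer input stays int8
        self.dosage = dos.astype(np.float64) if dos.dtype.kind == "f" else dos.astype(np.int8)
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if not (len(self.marker_ids) == len(self.chromosome) == len(self.position_bp) == m):
            raise ValueError("marker metadata length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker IDs")
        if self.a1 is None:
            self.a1 = np.full(m, "A", dtype=object)
        if self.a2 is None:
            self.a2 = np.full(m, "B", dtype=object)
        if self.sex is None:
            self.sex = np.full(n, "0", dtype=object)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        """Return a copy restricted to ``marker_ids`` (panel order preserved)."""
        wanted = set(marker_ids)
        missing = wanted - set(self.marker_ids)
        if missing:
            raise KeyError(f"markers not in panel: {sorted(missing)[:5]} ...")
        mask = np.array([mid in wanted for mid in self.marker_ids])
        return GenotypeMatrix(
            individual_ids=self.individual_ids.copy(),
            marker_ids=self.marker_ids[mask],
            chromosome=self.chromosome[mask],
            position_bp=self.position_bp[mask],
            dosage=self.dosage[:, mask].copy(),
            a1=self.a1[mask],
            a2=self.a2[mask],
            sex=self.sex.copy(),
        )

    def subset_individuals(self, individual_ids) -> "GenotypeMatrix":
        idx = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = np.array([idx[i] for i in individual_ids], dtype=int)
        return replace(
            self,
            individual_ids=self.individual_ids[rows],
            dosage=self.dosage[rows, :].copy(),
            sex=self.sex[rows],
        )


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK ``.bed``/``.bim``/``.fam`` triplet (variant-major only)."""
    prefix = Path(prefix)
    bed_path = prefix.parent / (prefix.name + ".bed")
    bim_path = prefix.parent / (prefix.name + ".bim")
    fam_path = prefix.parent / (prefix.name + ".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    if fam["iid"].duplicated().any():
        dups = fam.loc[fam["iid"].duplicated(), "iid"].tolist()
        raise TableValidationError(f"duplicate individual IDs in .fam: {dups}")
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "bp", "a1", "a2"], dtype=str)
    if bim["snp"].duplicated().any():
        dups = bim.loc[bim["snp"].duplicated(), "snp"].tolist()
        raise TableValidationError(f"duplicate marker IDs in .bim: {dups}")

    n = len(fam)
    m = len(bim)
    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:2]!r} (expected 6c 1b)")
    if raw[2:3] == b"\x00":
        raise PlinkFormatError(
            f"{bed_path}: sample-major mode (byte 0x00) is not supported; "
            "re-export in variant-major order")
    if raw[2:3] != _BED_VARIANT_MAJOR:
        raise PlinkFormatError(f"{bed_path}: unknown mode byte {raw[2]:#04x}")
    bytes_per_marker = math.ceil(n / 4)
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: truncated or padded .bed — {len(raw)} bytes at offset 3, "
            f"expected {expected} for {n} individuals x {m} markers")

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    # unpack 2-bit codes, low-order bits first within each byte
    codes = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        codes[:, k::4] = (data >> shift) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()  # individuals x markers

    return GenotypeMatrix(
        individual_ids=fam["iid"].to_numpy(dtype=object),
        marker_ids=bim["snp"].to_numpy(dtype=object),
        chromosome=bim["chrom"].to_numpy(dtype=object),
        position_bp=bim["bp"].astype(np.int64).to_numpy(),
        dosage=dosage,
        a1=bim["a1"].to_numpy(dtype=object),
        a2=bim["a2"].to_numpy(dtype=object),
        sex=fam["sex"].to_numpy(dtype=object),
    )


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write ``g`` as variant-major ``.bed``/``.bim``/``.fam``; round-trips with read_plink."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.dosage.shape

    fam = pd.DataFrame({
        "fid": g.individual_ids, "iid": g.individual_ids,
        "father": "0", "mother": "0", "sex": g.sex, "pheno": "-9",
    })
    fam.to_csv(prefix.parent / (prefix.name + ".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame({
        "chrom": g.chromosome, "snp": g.marker_ids, "cm": 0,
        "bp": g.position_bp, "a1": g.a1, "a2": g.a2,
    })
    bim.to_csv(prefix.parent / (prefix.name + ".bim"), sep="\t", header=False, index=False)

    dosage = g.dosage
    if dosage.dtype.kind == "f":
        if not np.all(np.isin(np.unique(dosage), [-1.0, 0.0, 1.0, 2.0])):
            raise PlinkFormatError(
                "cannot write non-integer (imputed) dosages to .bed")
        dosage = dosage.astype(np.int8)
    code_lut = np.empty(256, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        code_lut[dos & 0xFF] = code
    codes = code_lut[dosage.T.astype(np.int8).view(np.uint8)]  # markers x individuals
    pad = (-n) % 4
    if pad:
        # pad with homozygous A2 (code 11), ignored on read
        codes = np.hstack([codes, np.full((m, pad), 0b11, dtype=np.uint8)])
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.parent / (prefix.name + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_VARIANT_MAJOR)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# pedigree / phenotype tables

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "birth_year"]
PHENOTYPE_COLUMNS = ["id", "trait", "value", "sex", "cg"]

UNKNOWN_PARENT = "0"


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Validate a pedigree table: unique IDs, acyclic, plausible birth years.

    Unknown parents are coded ``"0"``. Returns the table with normalized
    dtypes; raises :class:`TableValidationError` on structural problems.
    """
    missing_cols = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
    if missing_cols:
        raise TableValidationError(f"pedigree missing columns: {missing_cols}")
    ped = ped.copy()
    for c in ("id", "sire", "dam", "sex"):
        ped[c] = ped[c].astype(str)
    ped.loc[ped["sire"].isin(("", "nan", "None", "NA")), "sire"] = UNKNOWN_PARENT
    ped.loc[ped["dam"].isin(("", "nan", "None", "NA")), "dam"] = UNKNOWN_PARENT
    ped["birth_year"] = ped["birth_year"].astype(int)

    dup = ped.loc[ped["id"].duplicated(), "id"].tolist()
    if dup:
        raise TableValidationError(f"duplicate individual IDs in pedigree: {dup}")

    out_of_window = ped.loc[(ped["birth_year"] < 1900) | (ped["birth_year"] > 2100), "id"]
    if len(out_of_window):
        warnings.warn(
            f"{len(out_of_window)} pedigree birth years outside 1900-2100 "
            f"(e.g. {out_of_window.iloc[0]})", stacklevel=2)

    parents = {row.id: (row.sire, row.dam) for row in ped.itertuples()}
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def check(node: str, stack: list[str]) -> None:
        if node == UNKNOWN_PARENT or node not in parents:
            return
        s = state.get(node)
        if s == 2:
            return
        if s == 1:
            cycle = stack[stack.index(node):] + [node]
            raise TableValidationError(
                f"pedigree cycle detected: {' -> '.join(cycle)}")
        state[node] = 1
        stack.append(node)
        for p in parents[node]:
            check(p, stack)
        stack.pop()
        state[node] = 2

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(parents) * 3 + 100))
    try:
        for node in parents:
            check(node, [])
    finally:
        sys.setrecursionlimit(old_limit)
    return ped


def validate_phenotypes(ph: pd.DataFrame, ped: pd.DataFrame | None = None,
                        genotyped_ids=None) -> pd.DataFrame:
    """Validate a phenotype table; optionally cross-reference pedigree/genotypes."""
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in ph.columns]
    if missing_cols:
        raise TableValidationError(f"phenotype table missing columns: {missing_cols}")
    if len(ph) == 0:
        raise TableValidationError("phenotype table has no records")
    ph = ph.copy()
    for c in ("id", "trait", "sex", "cg"):
        ph[c] = ph[c].astype(str)
    ph["value"] = ph["value"].astype(float)
    if not np.isfinite(ph["value"]).all():
        bad = ph.loc[~np.isfinite(ph["value"]), "id"].tolist()
        raise TableValidationError(f"non-finite phenotype values for: {bad}")
    dup = ph.loc[ph.duplicated(["id", "trait"]), ["id", "trait"]]
    if len(dup):
        raise TableValidationError(
            f"multiple records per individual x trait: {dup.to_records(index=False).tolist()}")
    known = set()
    if ped is not None:
        known |= set(ped["id"].astype(str))
    if genotyped_ids is not None:
        known |= set(map(str, genotyped_ids))
    if known:
        orphans = sorted(set(ph["id"]) - known)
        if orphans:
            raise TableValidationError(
                f"phenotyped individuals absent from pedigree and genotypes: {orphans[:5]}")
    return ph


def read_tables(pedigree_path, phenotype_path,
                genotyped_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate pedigree + phenotype CSVs."""
    ped = validate_pedigree(pd.read_csv(pedigree_path, dtype=str))
    ph = validate_phenotypes(pd.read_csv(phenotype_path), ped=ped,
                             genotyped_ids=genotyped_ids)
    missing_dams = set(ph["id"].map(
        dict(zip(ped["id"], ped["dam"]))).dropna()) - set(ped["id"]) - {UNKNOWN_PARENT}
    if missing_dams:
        warnings.warn(
            f"{len(missing_dams)} dams of phenotyped animals absent from pedigree; "
            "their records get no maternal link", stacklevel=2)
    return ped, ph


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "genotypes", "pedigree", "phenotypes", "trait", "scenario", "out",
    "varcomp", "maf_min", "call_rate_min", "hwe_p_min", "top_fraction",
    "ridge", "n_weight_iterations", "n_replicates", "cutoff_year",
    "train_fraction", "seed",
}

_CONFIG_DEFAULTS = {
    "maf_min": 0.05, "call_rate_min": 0.90, "hwe_p_min": 1e-5,
    "top_fraction": 0.10, "ridge": 0.01, "n_weight_iterations": 10,
    "n_replicates": 5, "cutoff_year": 2010, "train_fraction": 2.0 / 3.0,
    "seed": 1,
}


@dataclass
class RunConfig:
    """Validated run configuration (file paths, thresholds, seed)."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - _CONFIG_KEYS
        if unknown:
            raise TableValidationError(
                f"unknown config keys (typo?): {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(self.values)
        self.values = merged
        v = self.values
        for key, lo, hi in (("maf_min", 0, 0.5), ("call_rate_min", 0, 1),
                            ("hwe_p_min", 0, 1), ("top_fraction", 0, 1),
                            ("train_fraction", 0, 1)):
            if not (lo < float(v[key]) <= hi):
                raise TableValidationError(f"config {key}={v[key]} outside ({lo}, {hi}]")
        if float(v["ridge"]) < 0:
            raise TableValidationError("ridge must be >= 0")
        for key in ("n_weight_iterations", "n_replicates", "seed", "cutoff_year"):
            v[key] = int(v[key])

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        if overrides:
            values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(values)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)
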