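"""Genotype data model, file readers/writers, QC statistics and filtering.

Dosage matrices are stored lines x markers as float arrays with ``np.nan``
for missing calls.  Two marker classes are supported:

* ``codominant`` -- biallelic SNP dosages in {0, 1, 2}, counting copies of
  the alternate allele (GBS-style calls).
* ``dominant`` -- presence/absence tags in {0, 1} (rAmpSeq-style markers),
  where 1 means the tag amplified.

All QC statistics are computed over non-missing entries only.  Imputation
may introduce fractional dosages; the value-domain invariant applies to
called (pre-imputation) data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CODOMINANT = "codominant"
DOMINANT = "dominant"

# IUPAC single-letter diplotype codes used in HapMap genotype columns.
_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}
_HAPMAP_MISSING = {"N", "NN", "./.", ".", "--"}


class GenotypeError(ValueError):
    """Raised for malformed genotype input or contract violations."""


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with identifiers and optional map.

    Parameters
    ----------
    line_ids, marker_ids
        Unique identifiers for rows and columns respectively.
    dosages
        Float array, shape ``(n_lines, n_markers)``; ``np.nan`` marks a
        missing call.
    marker_class
        ``"codominant"`` (0/1/2) or ``"dominant"`` (0/1).
    chrom, pos
        Optional per-marker map coordinates (1-based positions, physical
        bp or genetic cM depending on provenance).
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    marker_class: str = CODOMINANT
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-D lines x markers array")
        n, m = self.dosages.shape
        if len(self.line_ids) != n:
            raise GenotypeError(
                f"{len(self.line_ids)} line_ids for {n} dosage rows"
            )
        if len(self.marker_ids) != m:
            raise GenotypeError(
                f"{len(self.marker_ids)} marker_ids for {m} dosage columns"
            )
        if len(set(self.line_ids)) != n:
            raise GenotypeError("line_ids must be unique")
        if len(set(self.marker_ids)) != m:
            raise GenotypeError("marker_ids must be unique")
        if self.marker_class not in (CODOMINANT, DOMINANT):
            raise GenotypeError(f"unknown marker_class {self.marker_class!r}")
        hi = 2.0 if self.marker_class == CODOMINANT else 1.0
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > hi):
            raise GenotypeError(
                f"dosage outside [0, {hi:g}] for {self.marker_class} markers"
            )
        for name in ("chrom", "pos"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != m:
                    raise GenotypeError(f"{name} length {len(arr)} != {m} markers")
                setattr(self, name, arr)

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset markers by integer index, keeping order as given."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            line_ids=self.line_ids,
            marker_ids=self.marker_ids[idx],
            dosages=self.dosages[:, idx],
            marker_class=self.marker_class,
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
        )

    def take_lines(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self, line_ids=self.line_ids[idx], dosages=self.dosages[idx, :]
        )


@dataclass
class MarkerQC:
    """Per-marker QC: minor-allele (or minor-presence-class) frequency and
    missing rate.  ``maf`` is ``np.nan`` for all-missing markers; the
    ``undefined`` mask flags those."""

    marker_ids: np.ndarray
    maf: np.ndarray
    missing_rate: np.ndarray

    @property
    def undefined(self) -> np.ndarray:
        return np.isnan(self.maf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "maf": self.maf,
                "missing_rate": self.missing_rate,
            }
        )


# ---------------------------------------------------------------------------
# QC, filtering, imputation, subsampling
# ---------------------------------------------------------------------------

def compute_qc(geno: GenotypeMatrix) -> MarkerQC:
    """Per-marker minor allele frequency and missing rate.

    Codominant: p = (sum of dosages) / (2 * non-missing count), maf =
    min(p, 1-p).  Dominant: q = presence fraction among non-missing calls,
    maf = min(q, 1-q).  Markers with no non-missing call get maf = nan and
    missing_rate = 1.
    """
    d = geno.dosages
    n_obs = np.sum(~np.isnan(d), axis=0).astype(float)
    missing_rate = 1.0 - n_obs / geno.n_lines
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.nansum(d, axis=0)
        denom = 2.0 * n_obs if geno.marker_class == CODOMINANT else n_obs
        p = np.where(n_obs > 0, total / np.where(denom > 0, denom, 1.0), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return MarkerQC(marker_ids=geno.marker_ids, maf=maf, missing_rate=missing_rate)


def filter_markers(
    geno: GenotypeMatrix,
    qc: MarkerQC | None = None,
    maf_gt: float = 0.05,
    missing_lt: float | None = 0.20,
) -> GenotypeMatrix:
    """Keep markers with maf strictly greater than ``maf_gt`` and (when
    ``missing_lt`` is given) missing rate strictly less than ``missing_lt``.

    Strict inequalities: a marker at exactly the MAF threshold is removed.
    Marker order is preserved.  Markers with undefined maf never survive.
    """
    if not 0.0 <= maf_gt <= 0.5:
        raise GenotypeError(f"maf_gt={maf_gt} outside [0, 0.5]")
    if missing_lt is not None and not 0.0 <= missing_lt <= 1.0:
        raise GenotypeError(f"missing_lt={missing_lt} outside [0, 1]")
    if qc is None:
        qc = compute_qc(geno)
    with np.errstate(invalid="ignore"):
        keep = qc.maf > maf_gt
    keep &= ~np.isnan(qc.maf)
    if missing_lt is not None:
        keep &= qc.missing_rate < missing_lt
    return geno.take_markers(np.flatnonzero(keep))


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing cell by its marker's non-missing mean dosage."""
    d = geno.dosages.copy()
    miss = np.isnan(d)
    if not miss.any():
        return replace(geno, dosages=d)
    n_obs = np.sum(~miss, axis=0)
    if np.any(n_obs == 0):
        bad = geno.marker_ids[n_obs == 0]
        raise GenotypeError(
            f"cannot impute all-missing markers {list(bad[:5])}; filter them first"
        )
    col_mean = np.nansum(d, axis=0) / n_obs
    d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return replace(geno, dosages=d)


def subsample_markers(
    geno: GenotypeMatrix, n_markers: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Uniform random marker subset without replacement, genomic order kept."""
    if n_markers > geno.n_markers:
        raise GenotypeError(
            f"requested {n_markers} markers but only {geno.n_markers} available"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(geno.n_markers, size=n_markers, replace=False))
    return geno.take_markers(idx)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def read_genotypes(path: str | Path, format: str = "hapmap") -> GenotypeMatrix:
    """Read a genotype matrix from HapMap, VCF, or CSV dosage files.

    HapMap: tab-delimited with the 11 standard metadata columns, genotype
    columns holding single-letter IUPAC diplotype codes (heterozygotes map
    to dosage 1, ``N`` to missing).  VCF: GT field only, requires cyvcf2.
    CSV: the dosage dialect written by :func:`write_csv` (lines x markers,
    first column ``line_id``).
    """
    path = Path(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "csv":
        return read_csv(path)
    raise GenotypeError(f"unknown genotype format {format!r}")


def _read_hapmap(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12:
            raise GenotypeError(
                f"{path}: HapMap header has {len(header)} columns; "
                "expected 11 metadata columns plus at least one genotype column"
            )
        line_ids = header[11:]
        marker_ids: list[str] = []
        chroms: list[str] = []
        poss: list[int] = []
        rows: list[np.ndarray] = []
        seen: set[str] = set()
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise GenotypeError(
                    f"{path}:{lineno}: {len(fields)} fields, expected {len(header)}"
                )
            rs, alleles = fields[0], fields[1]
            if rs in seen:
                raise GenotypeError(f"{path}:{lineno}: duplicate marker name {rs!r}")
            seen.add(rs)
            alt = alleles.split("/")[-1] if "/" in alleles else None
            ref = alleles.split("/")[0] if "/" in alleles else None
            row = np.empty(len(line_ids))
            for j, call in enumerate(fields[11:]):
                row[j] = _hapmap_call_to_dosage(call, ref, alt, path, lineno)
            marker_ids.append(rs)
            chroms.append(fields[2])
            poss.append(int(fields[3]) if fields[3].isdigit() else -1)
            rows.append(row)
    if not rows:
        raise GenotypeError(f"{path}: no marker records found")
    return GenotypeMatrix(
        line_ids=np.array(line_ids, dtype=object),
        marker_ids=np.array(marker_ids, dtype=object),
        dosages=np.vstack(rows).T,
        marker_class=CODOMINANT,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
    )


def _hapmap_call_to_dosage(
    call: str, ref: str | None, alt: str | None, path: Path, lineno: int
) -> float:
    call = call.strip()
    if call in _HAPMAP_MISSING:
        return np.nan
    if len(call) == 1:
        if call in _IUPAC_HET:
            return 1.0
        base = call
    elif len(call) == 2:  # two-letter diplotype variant
        if call[0] != call[1]:
            return 1.0
        base = call[0]
    else:
        raise GenotypeError(f"{path}:{lineno}: malformed genotype call {call!r}")
    if ref is not None and base == ref:
        return 0.0
    if alt is not None and base == alt:
        return 2.0
    raise GenotypeError(
        f"{path}:{lineno}: call {call!r} matches neither allele {ref}/{alt}"
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise GenotypeError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    line_ids = np.array(vcf.samples, dtype=object)
    marker_ids, chroms, poss, rows = [], [], [], []
    seen: set[str] = set()
    for var in vcf:
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        if mid in seen:
            raise GenotypeError(f"{path}: duplicate marker name {mid!r}")
        seen.add(mid)
        gts = var.genotype.array()
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        rows.append(alleles.sum(axis=1))
        marker_ids.append(mid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows:
        raise GenotypeError(f"{path}: no variant records found")
    return GenotypeMatrix(
        line_ids=line_ids,
        marker_ids=np.array(marker_ids, dtype=object),
        dosages=np.vstack(rows).T,
        marker_class=CODOMINANT,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
    )


def read_csv(path: str | Path, marker_class: str = CODOMINANT) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise GenotypeError(f"{path}: no marker columns")
    return GenotypeMatrix(
        line_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        dosages=df.to_numpy(dtype=float),
        marker_class=marker_class,
    )


def write_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as lines x markers CSV (index column line_id)."""
    df = pd.DataFrame(geno.dosages, index=geno.line_ids, columns=geno.marker_ids)
    df.index.name = "line_id"
    df.to_csv(path)


def write_hapmap(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write codominant genotypes as HapMap text (alleles fixed to A/C)."""
    if geno.marker_class != CODOMINANT:
        raise GenotypeError("HapMap output requires codominant genotypes")
    code = {0.0: "A", 1.0: "M", 2.0: "C"}
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + [str(s) for s in geno.line_ids]) + "\n")
        for j in range(geno.n_markers):
            chrom = str(geno.chrom[j]) if geno.chrom is not None else "0"
            pos = str(int(geno.pos[j])) if geno.pos is not None else str(j + 1)
            calls = [
                "N" if np.isnan(v) else code[float(v)]
                for v in geno.dosages[:, j]
            ]
            meta = [str(geno.marker_ids[j]), "A/C", chrom, pos, "+"] + ["NA"] * 6
            fh.write("\t".join(meta + calls) + "\n")
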