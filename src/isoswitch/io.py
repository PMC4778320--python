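"""Domain containers and flat-file readers/writers.

The pipeline's central objects are thin wrappers around pandas frames:

* :class:`IsoformCatalog` — isoform -> gene mapping plus transcript lengths.
* :class:`IsoformMatrix` — isoform x sample abundance matrix with an explicit
  scale tag (``raw`` counts, ``uq_normalized``, or ``log2``).
* :class:`SampleAnnotation` — per-sample tissue flag, intrinsic subtype and
  RNA Integrity Number (RIN).

All on-disk formats are plain TSV (plus GTF for annotations and RSEM
``*.isoforms.results`` for quantifications), so every intermediate artifact is
inspectable with standard command-line tools and round-trips exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

SUBTYPES = ("Basal", "Her2", "LumA", "LumB", "NormalLike")
"""Intrinsic (PAM50-style) subtype labels accepted in annotations."""

Scale = Literal["raw", "uq_normalized", "log2"]


class IsoswitchError(ValueError):
    """Raised for invalid inputs anywhere in the pipeline."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class IsoformCatalog:
    """Isoform -> gene mapping with transcript lengths (nucleotides).

    ``frame`` is indexed by isoform_id with columns ``gene_id`` (str) and
    ``length`` (int >= 1).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not {"gene_id", "length"} <= set(f.columns):
            raise IsoswitchError("catalog frame needs gene_id and length columns")
        if f.index.duplicated().any():
            dup = f.index[f.index.duplicated()][0]
            raise IsoswitchError(f"duplicated isoform_id in catalog: {dup!r}")
        if (f["length"] < 1).any():
            bad = f.index[f["length"] < 1][0]
            raise IsoswitchError(f"non-positive length for isoform {bad!r}")
        self.frame = f.astype({"gene_id": str, "length": int})

    @property
    def isoform_ids(self) -> pd.Index:
        return self.frame.index

    def gene_of(self, isoform_id: str) -> str:
        return self.frame.at[isoform_id, "gene_id"]

    def length_of(self, isoform_id: str) -> int:
        return int(self.frame.at[isoform_id, "length"])

    def isoforms_of(self, gene_id: str) -> list[str]:
        return list(self.frame.index[self.frame["gene_id"] == gene_id])

    def genes(self) -> pd.Index:
        return pd.Index(self.frame["gene_id"].unique())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class IsoformMatrix:
    """Isoform x sample abundance matrix with an explicit scale tag."""

    values: pd.DataFrame
    scale: Scale = "raw"
    normalization_target: float | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise IsoswitchError(f"duplicated isoform_id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise IsoswitchError(f"duplicated sample_id: {dup!r}")
        if v.isna().any().any():
            iso = v.index[v.isna().any(axis=1)][0]
            raise IsoswitchError(f"missing value in row {iso!r}; encode absence as 0")
        if self.scale in ("raw", "uq_normalized") and (v.to_numpy() < 0).any():
            r, c = np.argwhere(v.to_numpy() < 0)[0]
            raise IsoswitchError(
                f"negative abundance at isoform {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        self.values = v.astype(float)

    @property
    def isoform_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleAnnotation:
    """Per-sample covariates: tissue (tumor/normal), subtype, RIN score.

    ``frame`` is indexed by sample_id with columns ``tissue``, ``subtype``
    and ``rin``. Subtype ``"NA"`` marks samples without an intrinsic-subtype
    call (typically adjacent-normal tissue); they are excluded from subtype
    contrasts but kept in the switching regressions.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not {"tissue", "subtype", "rin"} <= set(f.columns):
            raise IsoswitchError("annotation needs tissue, subtype, rin columns")
        if f.index.duplicated().any():
            dup = f.index[f.index.duplicated()][0]
            raise IsoswitchError(f"duplicated sample_id: {dup!r}")
        bad_tissue = set(f["tissue"]) - {"tumor", "normal"}
        if bad_tissue:
            raise IsoswitchError(f"unknown tissue value(s): {sorted(bad_tissue)}")
        bad_sub = set(f["subtype"]) - set(SUBTYPES) - {"NA"}
        if bad_sub:
            raise IsoswitchError(f"unknown subtype value(s): {sorted(bad_sub)}")
        rin = f["rin"].astype(float)
        if ((rin < 1) | (rin > 10)).any():
            bad = f.index[(rin < 1) | (rin > 10)][0]
            raise IsoswitchError(f"RIN outside [1,10] for sample {bad!r}")
        f = f.copy()
        f["rin"] = rin
        self.frame = f

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def rin(self) -> pd.Series:
        return self.frame["rin"]

    def tumor_samples(self) -> pd.Index:
        return self.frame.index[self.frame["tissue"] == "tumor"]


@dataclass
class ValidationReport:
    """Result of cross-checking matrix, catalog and annotation consistency."""

    missing_isoforms: list[str] = field(default_factory=list)
    missing_samples: list[str] = field(default_factory=list)
    rin_out_of_range: list[str] = field(default_factory=list)
    extra_catalog_isoforms: list[str] = field(default_factory=list)

    @property
    def blocking(self) -> bool:
        return bool(self.missing_isoforms or self.missing_samples)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

#: RSEM isoforms.results columns that are metadata, not per-sample abundance
_RSEM_META = {
    "transcript_id",
    "gene_id",
    "length",
    "effective_length",
    "TPM",
    "FPKM",
    "IsoPct",
}


def read_isoform_matrix(path: str | Path, format: str = "tsv"):
    """Read an isoform x sample abundance matrix.

    ``format="tsv"``: first column isoform_id, one column per sample, header
    required. Returns an :class:`IsoformMatrix` with ``scale="raw"``.

    ``format="rsem_isoforms"``: an RSEM-style table with ``transcript_id``,
    ``gene_id`` and abundance columns. A lone ``expected_count`` column is a
    single sample named after the file stem; any non-standard extra columns
    are treated as one sample each (merged multi-sample export). Returns
    ``(IsoformMatrix, IsoformCatalog)``; lengths default to 1 when absent.
    """
    path = Path(path)
    if format == "tsv":
        frame = _read_strict_tsv(path)
        frame = frame.set_index(frame.columns[0])
        frame.index.name = "isoform_id"
        try:
            values = frame.astype(float)
        except ValueError as exc:
            raise IsoswitchError(f"non-numeric abundance in {path.name}: {exc}") from exc
        return IsoformMatrix(values=values, scale="raw")
    if format == "rsem_isoforms":
        frame = pd.read_csv(path, sep="\t")
        need = {"transcript_id", "gene_id"}
        if not need <= set(frame.columns):
            raise IsoswitchError(
                f"{path.name}: RSEM isoform results need columns {sorted(need)}"
            )
        sample_cols = [c for c in frame.columns if c not in _RSEM_META and c != "expected_count"]
        frame = frame.set_index("transcript_id")
        frame.index.name = "isoform_id"
        abund = {}
        if "expected_count" in frame.columns:
            abund[path.name.split(".")[0]] = frame["expected_count"].astype(float)
        for c in sample_cols:
            abund[c] = frame[c].astype(float)
        if not abund:
            raise IsoswitchError(f"{path.name}: no abundance column found")
        matrix = IsoformMatrix(values=pd.DataFrame(abund), scale="raw")
        lengths = (
            frame["length"].astype(int)
            if "length" in frame.columns
            else pd.Series(1, index=frame.index)
        )
        catalog = IsoformCatalog(
            frame=pd.DataFrame({"gene_id": frame["gene_id"], "length": lengths})
        )
        return matrix, catalog
    raise IsoswitchError(f"unknown matrix format {format!r}")


def _read_strict_tsv(path: Path) -> pd.DataFrame:
    """Read a TSV rejecting ragged rows (pandas would silently pad/NaN them)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().rstrip("\n").split("\n")
    rows = [ln.split("\t") for ln in lines]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise IsoswitchError(f"{path.name}: ragged row {i + 1} ({len(r)} != {width} fields)")
    return pd.DataFrame(rows[1:], columns=rows[0])


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_catalog(path: str | Path, format: str = "tsv") -> IsoformCatalog:
    """Read an isoform catalog from a TSV or a GTF.

    TSV columns: ``isoform_id``, ``gene_id``, optional ``length`` (defaults
    to 1). GTF: exon features with ``transcript_id``/``gene_id`` attributes;
    a transcript's length is the sum of its exon lengths under 1-based
    inclusive coordinates (end - start + 1). Overlapping exons within one
    transcript and transcripts with no exons are rejected as malformed.
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t")
        if not {"isoform_id", "gene_id"} <= set(frame.columns):
            raise IsoswitchError(f"{path.name}: catalog TSV needs isoform_id, gene_id")
        if "length" not in frame.columns:
            frame["length"] = 1
        _reject_multi_gene(frame["isoform_id"], frame["gene_id"])
        frame = frame.drop_duplicates(subset=["isoform_id", "gene_id"])
        frame = frame.set_index("isoform_id")
        return IsoformCatalog(frame=frame[["gene_id", "length"]])
    if format == "gtf":
        return _read_gtf(path)
    raise IsoswitchError(f"unknown catalog format {format!r}")


def _reject_multi_gene(isoforms: Iterable[str], genes: Iterable[str]) -> None:
    mapping: dict[str, str] = {}
    for iso, gene in zip(isoforms, genes):
        if iso in mapping and mapping[iso] != gene:
            raise IsoswitchError(
                f"isoform {iso!r} mapped to two genes: {mapping[iso]!r}, {gene!r}"
            )
        mapping[iso] = gene


def _read_gtf(path: Path) -> IsoformCatalog:
    exons: dict[str, list[tuple[int, int]]] = {}
    gene_of: dict[str, str] = {}
    seen_transcripts: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise IsoswitchError(f"{path.name}:{lineno}: fewer than 9 GTF fields")
            feature, start, end, attrs = parts[2], int(parts[3]), int(parts[4]), parts[8]
            attr = dict(_GTF_ATTR.findall(attrs))
            tid, gid = attr.get("transcript_id"), attr.get("gene_id")
            if tid is None or gid is None:
                continue
            if tid in gene_of and gene_of[tid] != gid:
                raise IsoswitchError(
                    f"transcript {tid!r} mapped to two genes: {gene_of[tid]!r}, {gid!r}"
                )
            gene_of[tid] = gid
            seen_transcripts.add(tid)
            if feature == "exon":
                exons.setdefault(tid, []).append((start, end))
    records = []
    for tid in sorted(seen_transcripts):
        if tid not in exons:
            raise IsoswitchError(f"transcript {tid!r} has no exon features")
        ivs = sorted(exons[tid])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise IsoswitchError(
                    f"transcript {tid!r} has overlapping exons [{s1},{e1}] and [{s2},{e2}]"
                )
        length = sum(e - s + 1 for s, e in ivs)
        records.append((tid, gene_of[tid], length))
    frame = pd.DataFrame(records, columns=["isoform_id", "gene_id", "length"])
    return IsoformCatalog(frame=frame.set_index("isoform_id"))


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV with columns sample_id, tissue, subtype, rin."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subtype": str})
    need = {"sample_id", "tissue", "subtype", "rin"}
    if not need <= set(frame.columns):
        raise IsoswitchError(f"annotation TSV needs columns {sorted(need)}")
    frame["subtype"] = frame["subtype"].fillna("NA")
    return SampleAnnotation(frame=frame.set_index("sample_id"))


# ---------------------------------------------------------------------------
# writers (exact round-trip: floats serialized with repr precision)
# ---------------------------------------------------------------------------


def write_isoform_matrix(matrix: IsoformMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="isoform_id")


def write_catalog(catalog: IsoformCatalog, path: str | Path) -> None:
    catalog.frame.to_csv(path, sep="\t", index_label="isoform_id")


def write_annotation(annot: SampleAnnotation, path: str | Path) -> None:
    annot.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_inputs(
    matrix: IsoformMatrix, catalog: IsoformCatalog, annot: SampleAnnotation
) -> ValidationReport:
    """Cross-check inputs; blocking iff a matrix isoform lacks a catalog entry
    or a matrix sample lacks annotation. Extra catalog rows are a warning only.
    """
    report = ValidationReport()
    cat_ids = set(catalog.isoform_ids)
    report.missing_isoforms = sorted(set(matrix.isoform_ids) - cat_ids)
    report.missing_samples = sorted(set(matrix.sample_ids) - set(annot.sample_ids))
    report.extra_catalog_isoforms = sorted(cat_ids - set(matrix.isoform_ids))
    rin = annot.frame["rin"]
    report.rin_out_of_range = sorted(annot.frame.index[(rin < 1) | (rin > 10)])
    return report
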