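"""Reading and writing the tables and sequences a culture-enrichment analysis touches.

The central artifact is the OTU count table produced by upstream 16S read
processing (primer trimming, pair merging, 97 %-similarity clustering — all
upstream of this package).  Two on-disk dialects are supported:

* ``tsv_classic`` — the classic QIIME-style tab-separated table, OTUs as rows,
  samples as columns, optional trailing ``taxonomy`` column.
* ``biom_json`` — a minimal dense BIOM-style JSON document (ids plus a dense
  matrix).

In memory the canonical orientation is always samples x OTUs, and counts are
always integers; relative abundances are a computed view, never stored.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """The file does not parse under the named dialect."""


class ValidationError(ValueError):
    """The file parses but violates a content invariant."""


ROLES = frozenset({"culture_independent", "plate_pool", "no_growth_control", "dna_control"})
ATMOSPHERES = frozenset({"anaerobic", "aerobic", "none"})
STORAGE_STATES = frozenset({"fresh", "frozen", "aerobic_exposed"})

# IUPAC nucleotide codes, ambiguity codes included (U accepted and treated as T
# downstream).
IUPAC_RE = re.compile(r"^[ACGTURYSWKMBDHVN]*$")


@dataclass(frozen=True, order=True)
class ConditionSpec:
    """One culture condition: a medium incubated under one atmosphere."""

    medium: str
    atmosphere: str

    def __post_init__(self) -> None:
        if not self.medium:
            raise ValidationError("condition medium must be non-empty")
        if self.atmosphere not in ("anaerobic", "aerobic"):
            raise ValidationError(
                f"condition atmosphere must be anaerobic/aerobic, got {self.atmosphere!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.medium} ({self.atmosphere})"


@dataclass
class SampleMetadata:
    """Role and provenance of one sequenced sample.

    ``culture_independent`` samples are direct fecal sequencing; ``plate_pool``
    samples are pooled colonies from one culture condition; the two control
    roles carry sterilized-sample and naked-DNA plate controls.
    """

    sample_id: str
    role: str
    donor: str
    medium: str = ""
    atmosphere: str = "none"
    storage: str = "fresh"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(f"sample {self.sample_id}: unknown role {self.role!r}")
        if self.atmosphere not in ATMOSPHERES:
            raise ValidationError(
                f"sample {self.sample_id}: unknown atmosphere {self.atmosphere!r}"
            )
        if self.storage not in STORAGE_STATES:
            raise ValidationError(f"sample {self.sample_id}: unknown storage {self.storage!r}")
        if self.role == "culture_independent":
            if self.medium or self.atmosphere != "none":
                raise ValidationError(
                    f"sample {self.sample_id}: culture_independent samples take no "
                    "medium/atmosphere"
                )
        if self.role == "plate_pool":
            if not self.medium:
                raise ValidationError(f"sample {self.sample_id}: plate_pool needs a medium")
            if self.atmosphere not in ("anaerobic", "aerobic"):
                raise ValidationError(
                    f"sample {self.sample_id}: plate_pool atmosphere must be "
                    "anaerobic or aerobic"
                )

    @property
    def condition(self) -> ConditionSpec:
        if self.role != "plate_pool":
            raise ValueError(f"sample {self.sample_id} is not a plate pool")
        return ConditionSpec(self.medium, self.atmosphere)


@dataclass
class AnalysisConfig:
    """Thresholds governing the analysis.

    * ``min_cultured_reads`` — an OTU counts as cultured only when it reaches
      this many reads in at least one plate pool (default 10; below that,
      plate-pool replicates are poorly reproducible).
    * ``abundance_thresholds`` — relative-abundance cutoffs (fractions) at
      which the cultured proportion is reported; defaults 0.01 % and 0.1 %.
    * ``identity_threshold`` — pairwise 16S identity below which an isolate is
      flagged as putatively novel (default 0.97, the OTU-definition cutoff).
    """

    min_cultured_reads: int = 10
    abundance_thresholds: tuple[float, ...] = (0.0001, 0.001)
    identity_threshold: float = 0.97
    rarefaction_depths: tuple[int, ...] = (500, 2000, 10000, 50000)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.abundance_thresholds = tuple(self.abundance_thresholds)
        self.rarefaction_depths = tuple(self.rarefaction_depths)
        if self.min_cultured_reads < 1:
            raise ValidationError("min_cultured_reads must be >= 1")
        for t in self.abundance_thresholds:
            if not 0.0 < t < 1.0:
                raise ValidationError(f"abundance threshold {t} outside (0, 1)")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValidationError("identity_threshold must be in (0, 1]")


class OtuTable:
    """Integer count matrix, samples x OTUs, with optional taxonomy strings.

    Taxonomy values are stored verbatim (semicolon-delimited lineage strings);
    rank parsing happens downstream in the targeted-isolation stage.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        otu_ids: Sequence[str],
        counts: np.ndarray,
        taxonomy: Mapping[str, str] | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.otu_ids = list(otu_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        self.taxonomy = dict(taxonomy) if taxonomy else None
        if self.taxonomy:
            stray = set(self.taxonomy) - set(self.otu_ids)
            if stray:
                raise ValidationError(f"taxonomy keys not in otu_ids: {sorted(stray)[:5]}")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._otu_index = {o: j for j, o in enumerate(self.otu_ids)}

    # ---- basic views -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts; all-zero samples stay all-zero."""
        totals = self.sample_totals().astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe[:, None]

    def counts_for(self, sample_id: str) -> np.ndarray:
        return self.counts[self._sample_index[sample_id]]

    def otu_index(self, otu_id: str) -> int:
        return self._otu_index[otu_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self._sample_index[s] for s in sample_ids]
        return OtuTable(list(sample_ids), self.otu_ids, self.counts[idx], self.taxonomy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def concat(cls, tables: Iterable["OtuTable"]) -> "OtuTable":
        """Stack tables sample-wise; all must share the same OTU axis."""
        tables = list(tables)
        if not tables:
            raise ValueError("no tables to concatenate")
        otu_ids = tables[0].otu_ids
        for t in tables[1:]:
            if t.otu_ids != otu_ids:
                raise ValidationError("cannot concat tables with different OTU ids")
        taxonomy: dict[str, str] = {}
        for t in tables:
            if t.taxonomy:
                taxonomy.update(t.taxonomy)
        sample_ids = [s for t in tables for s in t.sample_ids]
        counts = np.vstack([t.counts for t in tables]) if tables else np.zeros((0, 0))
        return cls(sample_ids, otu_ids, counts, taxonomy or None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and (self.taxonomy or {}) == (other.taxonomy or {})
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


# ---------------------------------------------------------------------------
# OTU table I/O
# ---------------------------------------------------------------------------

_TSV_HEADER = "#OTU ID"


def read_otu_table(path: str | Path, dialect: str = "tsv_classic") -> OtuTable:
    """Read an OTU table; orientation is normalized to samples x OTUs.

    ``tsv_classic`` stores OTUs as rows and samples as columns with an optional
    trailing ``taxonomy`` column; ``biom_json`` is a dense BIOM-style JSON
    document (also OTUs-as-rows on disk).
    """
    path = Path(path)
    if dialect == "tsv_classic":
        return _read_tsv_classic(path)
    if dialect == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv_classic(path: Path) -> OtuTable:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (line 1: missing header)")
    header = lines[0].split("\t")
    if header[0] != _TSV_HEADER:
        raise FormatError(f"{path}: line 1: header must start with {_TSV_HEADER!r}")
    has_tax = bool(header[1:]) and header[-1].lower() == "taxonomy"
    sample_ids = header[1:-1] if has_tax else header[1:]
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    taxonomy: dict[str, str] = {}
    ncol = len(header)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise FormatError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(parts)}"
            )
        otu_id = parts[0]
        vals = parts[1 : 1 + len(sample_ids)]
        row = []
        for sid, v in zip(sample_ids, vals):
            try:
                iv = int(v)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: count for OTU {otu_id!r}, sample "
                    f"{sid!r} is not an integer: {v!r}"
                ) from None
            if iv < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative count for OTU {otu_id!r}, "
                    f"sample {sid!r}: {iv}"
                )
            row.append(iv)
        otu_ids.append(otu_id)
        rows.append(row)
        if has_tax and parts[-1]:
            taxonomy[otu_id] = parts[-1]
    counts = (
        np.array(rows, dtype=np.int64).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int64)
    )
    return OtuTable(sample_ids, otu_ids, counts, taxonomy or None)


def _read_biom_json(path: Path) -> OtuTable:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from None
    for key in ("rows", "columns", "data"):
        if key not in doc:
            raise FormatError(f"{path}: missing BIOM key {key!r}")
    if doc.get("matrix_type", "dense") != "dense":
        raise FormatError(f"{path}: only dense matrix_type is supported")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    data = np.asarray(doc["data"], dtype=float)
    if data.size == 0:
        data = data.reshape(len(otu_ids), len(sample_ids))
    if data.shape != (len(otu_ids), len(sample_ids)):
        raise FormatError(
            f"{path}: data shape {data.shape} does not match "
            f"{len(otu_ids)} rows x {len(sample_ids)} columns"
        )
    if data.size and not np.all(np.equal(np.mod(data, 1), 0)):
        bad = np.argwhere(np.mod(data, 1) != 0)[0]
        raise ValidationError(
            f"{path}: non-integer count at OTU {otu_ids[bad[0]]!r}, "
            f"sample {sample_ids[bad[1]]!r}"
        )
    taxonomy: dict[str, str] = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax is not None:
            taxonomy[r["id"]] = tax if isinstance(tax, str) else ";".join(tax)
    return OtuTable(sample_ids, otu_ids, data.T, taxonomy or None)


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "tsv_classic") -> None:
    """Write a table so that :func:`read_otu_table` reproduces it exactly."""
    path = Path(path)
    if dialect == "tsv_classic":
        has_tax = table.taxonomy is not None
        header = [_TSV_HEADER, *table.sample_ids] + (["taxonomy"] if has_tax else [])
        lines = ["\t".join(header)]
        mat = table.counts.T  # OTUs x samples on disk
        for j, otu_id in enumerate(table.otu_ids):
            row = [otu_id, *(str(v) for v in mat[j])]
            if has_tax:
                row.append(table.taxonomy.get(otu_id, ""))
            lines.append("\t".join(row))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif dialect == "biom_json":
        rows = []
        for otu_id in table.otu_ids:
            meta = None
            if table.taxonomy is not None and otu_id in table.taxonomy:
                meta = {"taxonomy": table.taxonomy[otu_id]}
            rows.append({"id": otu_id, "metadata": meta})
        doc = {
            "id": None,
            "format": "Biological Observation Matrix (dense JSON)",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": [table.n_otus, table.n_samples],
            "rows": rows,
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        path.write_text(json.dumps(doc, sort_keys=True), encoding="utf-8")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sample metadata I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ["sample_id", "role", "donor", "medium", "atmosphere", "storage"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample-metadata TSV (six required columns, enum-checked)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = SampleMetadata(
                sample_id=row.sample_id,
                role=row.role,
                donor=row.donor,
                medium=row.medium,
                atmosphere=row.atmosphere,
                storage=row.storage if row.storage else "fresh",
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        if rec.sample_id in seen:
            raise ValidationError(f"{path}: row {i}: duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)
        records.append(rec)
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "role": r.role,
            "donor": r.donor,
            "medium": r.medium,
            "atmosphere": r.atmosphere,
            "storage": r.storage,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs, file order.

    Sequences must be IUPAC nucleotides (ambiguity codes allowed); duplicate
    ids are rejected.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not IUPAC_RE.match(seq):
            bad = next(ch for ch in seq if not IUPAC_RE.match(ch))
            raise ValidationError(
                f"{path}: record {rec.id!r}: non-IUPAC character {bad!r}"
            )
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
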