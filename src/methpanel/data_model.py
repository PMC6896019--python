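"""Domain types and TSV readers/writers for methylation beta-value data.

The package works on small, targeted CpG panels (the bundled annotation covers
the 22 Illumina HumanMethylation450 probes of the *GSDME* locus on 7p15.3).
All file formats are tab-separated UTF-8 text with an ``NA`` missing-value
token, matching the TCGA Level-3 text convention.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


class Region(str, enum.Enum):
    """Genomic zone of a panel CpG relative to the gene."""

    GENE_BODY = "gene_body"
    PROMOTER = "promoter"
    UPSTREAM = "upstream"


#: Accepted spellings of region labels in annotation files, lower-cased.
_REGION_ALIASES = {
    "gene body": Region.GENE_BODY,
    "gene_body": Region.GENE_BODY,
    "body": Region.GENE_BODY,
    "putative promoter": Region.PROMOTER,
    "promoter": Region.PROMOTER,
    "upstream region": Region.UPSTREAM,
    "upstream": Region.UPSTREAM,
}


class ParseError(ValueError):
    """A delimited-text input could not be interpreted."""


class ValidationError(ValueError):
    """Parsed data violate a type invariant."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """One 450K array probe of the panel.

    ``coordinate`` is the 1-based position on GRCh37/hg19, as annotated by
    Illumina; no liftover is attempted.
    """

    probe_index: int
    illumina_name: str
    chromosome: str
    coordinate: int
    region: Region

    def __post_init__(self) -> None:
        if self.coordinate <= 0:
            raise ValidationError(
                f"probe {self.illumina_name}: coordinate must be positive, "
                f"got {self.coordinate}"
            )


@dataclass(frozen=True)
class CohortRecord:
    """Dataset-level sample counts: solid-tissue normal (NT) vs primary tumor (TP)."""

    dataset_code: str
    n_normal: int
    n_tumor: int

    @property
    def total(self) -> int:
        return self.n_normal + self.n_tumor

    def passes_inclusion(self) -> bool:
        """Cohort-inclusion rule: normal/tumor ratio >= 10% or >= 10 normals."""
        if self.n_tumor == 0:
            return self.n_normal >= 10
        return (self.n_normal / self.n_tumor) >= 0.10 or self.n_normal >= 10


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotations joined to one row of a :class:`BetaMatrix`."""

    sample_id: str
    patient_barcode: str
    tissue: str  # "NT" or "TP"
    tumor_type: str
    stage: int | None = None  # ordinal 1-4 (I-IV)
    age_at_diagnosis: float | None = None
    gender: str | None = None
    ethnicity: str | None = None
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.tissue not in ("NT", "TP"):
            raise ValidationError(
                f"sample {self.sample_id}: tissue must be NT or TP, got {self.tissue!r}"
            )
        if self.stage is not None and self.stage not in (1, 2, 3, 4):
            raise ValidationError(
                f"sample {self.sample_id}: stage must be in 1..4, got {self.stage}"
            )


@dataclass
class BetaMatrix:
    """Samples x probes matrix of beta-values.

    Beta-values are the ratio of methylated probe intensity over total
    intensity and lie in [0, 1]; missing entries are NaN.
    """

    values: pd.DataFrame  # index = sample_ids, columns = probe_ids

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        bad &= ~np.isnan(vals)
        if bad.any():
            cells = [
                f"({idx[i]}, {cols[j]})={vals[i, j]!r}"
                for i, j in zip(*np.nonzero(bad))
            ][:20]
            raise ValidationError(
                "beta-values outside [0, 1] at cells: " + ", ".join(cells)
            )

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.values.columns]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        return BetaMatrix(self.values.loc[:, list(probe_ids)].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_probe_table(path: str | Path) -> list[ProbeAnnotation]:
    """Read a probe annotation TSV into :class:`ProbeAnnotation` records.

    Expected columns: ``probe_index``, ``illumina_name``, ``coordinate``,
    ``region``, ``chromosome``. Region labels are normalized
    ("Putative Promoter" -> promoter, "Upstream Region" -> upstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_index", "illumina_name", "coordinate", "region", "chromosome"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    records: list[ProbeAnnotation] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            coordinate = int(row.coordinate)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path} row {row_no}: malformed coordinate {row.coordinate!r}"
            ) from None
        key = str(row.region).strip().lower()
        if key not in _REGION_ALIASES:
            raise ParseError(
                f"{path} row {row_no}: unknown region label {row.region!r}"
            )
        records.append(
            ProbeAnnotation(
                probe_index=int(row.probe_index),
                illumina_name=str(row.illumina_name),
                chromosome=str(row.chromosome),
                coordinate=coordinate,
                region=_REGION_ALIASES[key],
            )
        )
    if len({r.probe_index for r in records}) != len(records):
        raise ValidationError(f"{path}: duplicate probe_index values")
    return records


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read a cohort-overview TSV; each row's printed total is verified."""
    df = pd.read_csv(path, sep="\t")
    required = {"dataset_code", "n_normal", "n_tumor", "total"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    records: list[CohortRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = CohortRecord(
            dataset_code=str(row.dataset_code),
            n_normal=int(row.n_normal),
            n_tumor=int(row.n_tumor),
        )
        if rec.total != int(row.total):
            raise ValidationError(
                f"{path} row {row_no} ({rec.dataset_code}): "
                f"{rec.n_normal} + {rec.n_tumor} != printed total {row.total}"
            )
        records.append(rec)
    return records


def _meta_from_frame(df: pd.DataFrame) -> list[SampleMeta]:
    def opt(v):
        return None if pd.isna(v) else v

    metas = []
    for row in df.itertuples(index=False):
        stage = opt(getattr(row, "stage", None))
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                patient_barcode=str(row.patient_barcode),
                tissue=str(row.tissue),
                tumor_type=str(row.tumor_type),
                stage=None if stage is None else int(stage),
                age_at_diagnosis=opt(getattr(row, "age_at_diagnosis", None)),
                gender=opt(getattr(row, "gender", None)),
                ethnicity=opt(getattr(row, "ethnicity", None)),
                expression=opt(getattr(row, "expression", None)),
            )
        )
    return metas


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: sample sheet must have a sample_id column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample_id values {dups}")
    return _meta_from_frame(df)


def read_beta_matrix(
    path: str | Path,
    sample_sheet: str | Path,
    orientation: str = "samples_by_probes",
) -> tuple[BetaMatrix, list[SampleMeta]]:
    """Read a beta matrix TSV and join it to its sample sheet.

    ``orientation`` declares the file layout; ``probes_by_samples`` files are
    transposed on load. Samples absent from the sheet are dropped with a
    logged warning count.
    """
    if orientation not in ("samples_by_probes", "probes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    if orientation == "probes_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    metas = read_sample_sheet(sample_sheet)
    by_id = {m.sample_id: m for m in metas}
    keep = [s for s in df.index if s in by_id]
    n_dropped = df.shape[0] - len(keep)
    if n_dropped:
        logger.warning("dropped %d samples without sample-sheet metadata", n_dropped)
    bm = BetaMatrix(df.loc[keep])
    joined = [by_id[s] for s in keep]
    _check_pairing(joined)
    return bm, joined


def _check_pairing(metas: Iterable[SampleMeta]) -> None:
    seen: set[tuple[str, str, str]] = set()
    for m in metas:
        key = (m.patient_barcode, m.tumor_type, m.tissue)
        if key in seen:
            raise ValidationError(
                f"patient {m.patient_barcode} has more than one {m.tissue} "
                f"sample in {m.tumor_type}"
            )
        seen.add(key)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_beta_matrix(bm: BetaMatrix, path: str | Path) -> None:
    bm.values.to_csv(
        path, sep="\t", na_rep=NA_TOKEN, float_format="%.6f", index_label="sample_id"
    )


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "patient_barcode": [m.patient_barcode for m in metas],
            "tissue": [m.tissue for m in metas],
            "tumor_type": [m.tumor_type for m in metas],
            "stage": [m.stage for m in metas],
            "age_at_diagnosis": [m.age_at_diagnosis for m in metas],
            "gender": [m.gender for m in metas],
            "ethnicity": [m.ethnicity for m in metas],
            "expression": [m.expression for m in metas],
        }
    )
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=False, float_format="%.6f")


def write_probe_table(probes: Sequence[ProbeAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "probe_index": [p.probe_index for p in probes],
            "illumina_name": [p.illumina_name for p in probes],
            "coordinate": [p.coordinate for p in probes],
            "region": [p.region.value for p in probes],
            "chromosome": [p.chromosome for p in probes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("methpanel") / "data" / name)


def load_probe_annotation() -> list[ProbeAnnotation]:
    """The bundled 22-probe GSDME 450K annotation, sorted by coordinate."""
    probes = read_probe_table(_data_path("gsdme_450k_probes.tsv"))
    probes.sort(key=lambda p: p.coordinate)
    return probes


def load_cohort_registry() -> list[CohortRecord]:
    """The bundled 14-dataset TCGA cohort overview."""
    return read_cohort_table(_data_path("tcga_cohorts.tsv"))
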