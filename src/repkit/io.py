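"""Readers and writers for clonotype-table dialects and the design file.

Three table dialects are supported and auto-detected from the header:

* MiXCR ``exportClones`` TSV (column matching case-insensitive),
* AIRR Rearrangement TSV (column matching case-sensitive, per the standard),
* the canonical TSV emitted by :func:`write_canonical_table`.

The Experiment Design File is a CSV or TSV with mandatory columns
``sample_id`` and ``file``; every other column is a grouping variable.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    ClonotypeRecord,
    Repertoire,
    ValidationError,
    build_repertoire,
)

log = logging.getLogger("repkit.io")

CANONICAL_COLUMNS = ["sample_id", "count", "freq", "cdr3_nt", "cdr3_aa", "v_gene", "j_gene"]


# ---------------------------------------------------------------------------
# gene-call cleanup


def clean_gene_call(raw: str) -> tuple[str, bool]:
    """Collapse a V/J call to gene level.

    Multi-hit strings are split on comma and the first (best) hit kept;
    allele and score annotations are stripped by deleting from the first
    ``*`` or ``(`` to the end of the token.  Returns the cleaned label and
    whether the call was ambiguous (multiple hits listed).
    """
    raw = str(raw).strip()
    hits = [h for h in raw.split(",") if h.strip()]
    ambiguous = len(hits) > 1
    first = hits[0].strip() if hits else ""
    first = re.split(r"[*(]", first, maxsplit=1)[0].strip()
    return first, ambiguous


# ---------------------------------------------------------------------------
# clonotype table dialects


def _ci_lookup(columns: Sequence[str]) -> dict[str, str]:
    """lowercase name -> actual name (first occurrence wins)."""
    out: dict[str, str] = {}
    for c in columns:
        out.setdefault(c.lower(), c)
    return out


def detect_dialect(path: str | Path) -> str:
    """Return ``mixcr``, ``airr`` or ``canonical`` from header inspection."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    lower = {c.lower() for c in cols}
    if "clonecount" in lower:
        dialect = "mixcr"
    elif {"junction", "v_call"} <= set(cols) and (
        "duplicate_count" in cols or "consensus_count" in cols
    ):
        dialect = "airr"
    elif set(CANONICAL_COLUMNS) <= set(cols):
        dialect = "canonical"
    else:
        raise ValidationError(
            f"{path}: cannot identify clonotype-table dialect from header "
            f"(tried mixcr, airr, canonical); columns: {cols}"
        )
    log.info("%s: detected dialect %s", path, dialect)
    return dialect


def _pick(lookup: dict[str, str], *names: str) -> str | None:
    for n in names:
        if n in lookup:
            return lookup[n]
    return None


def read_mixcr_table(path: str | Path) -> list[ClonotypeRecord]:
    """Parse a MiXCR ``exportClones`` TSV into clonotype records.

    ``bestVHit``/``bestJHit`` are preferred over ``allVHitsWithScore`` /
    ``allJHitsWithScore``; ``nSeqCDR3`` over ``nSeqImputedCDR3``.  Rows with
    unparsable counts are rejected with their row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lookup = _ci_lookup(df.columns)

    col_count = _pick(lookup, "clonecount")
    col_nt = _pick(lookup, "nseqcdr3", "nseqimputedcdr3")
    col_aa = _pick(lookup, "aaseqcdr3", "aaseqimputedcdr3")
    col_v = _pick(lookup, "bestvhit", "allvhitswithscore", "bestvgene")
    col_j = _pick(lookup, "bestjhit", "alljhitswithscore", "bestjgene")
    for col, names in [
        (col_count, "cloneCount"),
        (col_nt, "nSeqCDR3/nSeqImputedCDR3"),
        (col_aa, "aaSeqCDR3"),
        (col_v, "bestVHit/allVHitsWithScore"),
        (col_j, "bestJHit/allJHitsWithScore"),
    ]:
        if col is None:
            raise ValidationError(
                f"{path}: missing mandatory column {names} (dialect: mixcr)"
            )
    if df.empty:
        warnings.warn(f"{path}: header-only file, no clonotypes", stacklevel=2)
        return []

    records: list[ClonotypeRecord] = []
    bad_rows: list[int] = []
    n_ambiguous = 0
    for i in range(len(df)):
        row = df.iloc[i]
        try:
            count = int(round(float(row[col_count])))
        except (TypeError, ValueError):
            bad_rows.append(i + 2)  # 1-based file row, after header
            continue
        v_gene, amb_v = clean_gene_call(row[col_v])
        j_gene, amb_j = clean_gene_call(row[col_j])
        n_ambiguous += int(amb_v) + int(amb_j)
        records.append(
            ClonotypeRecord(
                cdr3_nt=str(row[col_nt]).upper(),
                cdr3_aa=str(row[col_aa]),
                v_gene=v_gene,
                j_gene=j_gene,
                count=count,
            )
        )
    if bad_rows:
        raise ValidationError(
            f"{path}: unparsable cloneCount in rows {bad_rows} (dialect: mixcr)"
        )
    if n_ambiguous:
        log.info("%s: %d ambiguous multi-gene hits, kept first listed", path, n_ambiguous)
    return records


def read_airr_table(path: str | Path) -> list[ClonotypeRecord]:
    """Parse an AIRR Rearrangement TSV into clonotype records.

    Column matching is case-sensitive.  ``duplicate_count`` is the count
    source; ``consensus_count`` is used (and logged) as a fallback.  A
    ``productive`` column, when present, is carried onto the records so the
    functional filter can use the upstream call.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = set(df.columns)
    for required in ("junction", "junction_aa", "v_call", "j_call"):
        if required not in cols:
            raise ValidationError(
                f"{path}: missing mandatory column {required} (dialect: airr)"
            )
    if "duplicate_count" in cols:
        col_count = "duplicate_count"
    elif "consensus_count" in cols:
        col_count = "consensus_count"
        log.info("%s: duplicate_count missing, falling back to consensus_count", path)
    else:
        raise ValidationError(
            f"{path}: missing mandatory column duplicate_count "
            f"(no consensus_count fallback either; dialect: airr)"
        )
    if df.empty:
        warnings.warn(f"{path}: header-only file, no clonotypes", stacklevel=2)
        return []

    has_productive = "productive" in cols
    records: list[ClonotypeRecord] = []
    bad_rows: list[int] = []
    for i in range(len(df)):
        raw_count = df.iloc[i][col_count]
        try:
            count = int(round(float(raw_count)))
        except (TypeError, ValueError):
            bad_rows.append(i + 2)
            continue
        v_gene, _ = clean_gene_call(df.iloc[i]["v_call"])
        j_gene, _ = clean_gene_call(df.iloc[i]["j_call"])
        productive: bool | None = None
        if has_productive:
            val = str(df.iloc[i]["productive"]).strip().upper()
            if val in ("T", "TRUE", "1"):
                productive = True
            elif val in ("F", "FALSE", "0"):
                productive = False
        records.append(
            ClonotypeRecord(
                cdr3_nt=str(df.iloc[i]["junction"]).upper(),
                cdr3_aa=str(df.iloc[i]["junction_aa"]),
                v_gene=v_gene,
                j_gene=j_gene,
                count=count,
                productive=productive,
            )
        )
    if bad_rows:
        raise ValidationError(
            f"{path}: unparsable {col_count} in rows {bad_rows} (dialect: airr)"
        )
    return records


def read_canonical_table(path: str | Path) -> list[ClonotypeRecord]:
    """Read the canonical TSV written by :func:`write_canonical_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing mandatory columns {missing} (dialect: canonical)"
        )
    records = []
    for i in range(len(df)):
        records.append(
            ClonotypeRecord(
                cdr3_nt=df.iloc[i]["cdr3_nt"],
                cdr3_aa=df.iloc[i]["cdr3_aa"],
                v_gene=df.iloc[i]["v_gene"],
                j_gene=df.iloc[i]["j_gene"],
                count=int(df.iloc[i]["count"]),
            )
        )
    return records


def read_clonotype_table(path: str | Path) -> tuple[list[ClonotypeRecord], str]:
    """Auto-detect the dialect and parse; returns (records, dialect)."""
    dialect = detect_dialect(path)
    reader = {
        "mixcr": read_mixcr_table,
        "airr": read_airr_table,
        "canonical": read_canonical_table,
    }[dialect]
    return reader(path), dialect


def load_repertoire(
    path: str | Path, sample_id: str, key_mode: str = "nt+vj"
) -> tuple[Repertoire, str]:
    """Read a clonotype table and aggregate it under ``key_mode``."""
    records, dialect = read_clonotype_table(path)
    return build_repertoire(records, key_mode, sample_id=sample_id), dialect


def write_canonical_table(rep: Repertoire, path: str | Path) -> None:
    """Write the canonical TSV; round-trips losslessly through its reader.

    Frequencies are formatted with 10 significant digits so a re-read
    repertoire's frequencies still sum to 1 within 1e-8.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in rep.records:
            fh.write(
                "\t".join(
                    [
                        rep.sample_id,
                        str(r.count),
                        format(r.freq, ".10g"),
                        r.cdr3_nt,
                        r.cdr3_aa,
                        r.v_gene,
                        r.j_gene,
                    ]
                )
                + "\n"
            )


def write_airr_table(rep: Repertoire, path: str | Path) -> None:
    """Write a minimal AIRR Rearrangement TSV view of a repertoire."""
    path = Path(path)
    cols = ["sequence_id", "junction", "junction_aa", "v_call", "j_call",
            "duplicate_count", "productive"]
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, r in enumerate(rep.records):
            fh.write(
                "\t".join(
                    [
                        f"{rep.sample_id}-{i + 1}",
                        r.cdr3_nt,
                        r.cdr3_aa,
                        r.v_gene,
                        r.j_gene,
                        str(r.count),
                        "T" if r.is_productive else "F",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# experiment design file


@dataclass(slots=True)
class DesignSample:
    sample_id: str
    path: Path
    variables: dict[str, str] = field(default_factory=dict)


@dataclass(slots=True)
class StudyDesign:
    """Sample manifest with arbitrary grouping variables."""

    samples: list[DesignSample]
    variables: list[str]

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __getitem__(self, sample_id: str) -> DesignSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass(slots=True)
class SampleGroup:
    label: str
    members: list[str]


def read_design_file(path: str | Path, check_files: bool = True) -> StudyDesign:
    """Read an Experiment Design File (CSV or TSV, sniffed).

    Mandatory columns: ``sample_id`` and ``file``; all other columns are
    grouping variables.  Relative file paths are resolved against the design
    file's directory.  Duplicate sample ids are an error; missing referenced
    files are reported all at once.
    """
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for required in ("sample_id", "file"):
        if required not in df.columns:
            raise ValidationError(
                f"{path}: design file needs column {required!r}; "
                f"found {list(df.columns)}"
            )
    variables = [c for c in df.columns if c not in ("sample_id", "file")]
    ids = list(df["sample_id"])
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate sample_id values {dupes}")

    samples = []
    for i in range(len(df)):
        p = Path(df.iloc[i]["file"])
        if not p.is_absolute():
            p = path.parent / p
        samples.append(
            DesignSample(
                sample_id=df.iloc[i]["sample_id"],
                path=p,
                variables={v: df.iloc[i][v] for v in variables},
            )
        )
    if check_files:
        missing = [str(s.path) for s in samples if not s.path.exists()]
        if missing:
            raise ValidationError(
                f"{path}: referenced files not found: {missing}"
            )
    return StudyDesign(samples=samples, variables=variables)


def group_samples(design: StudyDesign, variables: Sequence[str]) -> list[SampleGroup]:
    """Group samples by the observed value combinations of ``variables``.

    The group label joins variable values with ``/`` in the requested order;
    groups are emitted in lexicographic label order.  An empty variable list
    yields one group ``all`` containing every sample.
    """
    unknown = [v for v in variables if v not in design.variables]
    if unknown:
        raise ValidationError(
            f"unknown grouping variables {unknown}; declared: {design.variables}"
        )
    if not variables:
        return [SampleGroup(label="all", members=design.sample_ids())]
    groups: dict[str, list[str]] = {}
    for s in design.samples:
        label = "/".join(s.variables[v] for v in variables)
        groups.setdefault(label, []).append(s.sample_id)
    return [SampleGroup(label=k, members=groups[k]) for k in sorted(groups)]
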