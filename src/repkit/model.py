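"""Core repertoire data model.

A clonotype is identified by one of four key modes: the CDR3 nucleotide
sequence (``nt``), the CDR3 amino-acid sequence (``aa``), or either of those
combined with the V and J gene calls (``nt+vj`` / ``aa+vj``).  A
:class:`Repertoire` is a set of clonotype records aggregated under one such
mode, with read counts summed and frequencies normalized to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

KEY_MODES = ("nt", "aa", "nt+vj", "aa+vj")

FREQ_TOL = 1e-9


class RepkitError(Exception):
    """Base class for user-facing errors."""


class ValidationError(RepkitError):
    """Malformed input data."""


class EmptyRepertoireError(RepkitError):
    """An operation received or produced a repertoire with no clonotypes."""


@dataclass(slots=True)
class ClonotypeRecord:
    """One clonotype: CDR3 sequences, gene calls, read count and frequency.

    ``cdr3_aa`` may contain ``*`` (stop) or ``_`` (frameshift) for
    non-productive rearrangements.  ``productive`` carries an upstream
    productivity call when the source dialect provides one; ``None`` means
    "not stated" and productivity is then judged from ``cdr3_aa`` alone.
    ``nt_variants`` counts the distinct nucleotide sequences merged into this
    record (1 unless the repertoire was collapsed to amino-acid level).
    """

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    freq: float = 0.0
    productive: bool | None = None
    nt_variants: int = 1

    def key(self, mode: str) -> tuple[str, ...]:
        if mode == "nt":
            return (self.cdr3_nt,)
        if mode == "aa":
            return (self.cdr3_aa,)
        if mode == "nt+vj":
            return (self.cdr3_nt, self.v_gene, self.j_gene)
        if mode == "aa+vj":
            return (self.cdr3_aa, self.v_gene, self.j_gene)
        raise ValidationError(f"unknown key mode {mode!r}; choose from {KEY_MODES}")

    @property
    def is_productive(self) -> bool:
        if self.productive is False:
            return False
        aa = self.cdr3_aa
        return bool(aa) and "*" not in aa and "_" not in aa


@dataclass(slots=True)
class Repertoire:
    """One sample's clonotypes aggregated under ``key_mode``.

    Records are stored in deterministic order: descending count, then
    lexicographic key.  Invariants: keys unique under ``key_mode``,
    ``total_reads == sum(count)`` and frequencies sum to 1.
    """

    sample_id: str
    records: list[ClonotypeRecord] = field(default_factory=list)
    key_mode: str = "nt+vj"
    total_reads: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_clones(self) -> int:
        return len(self.records)

    def counts(self) -> np.ndarray:
        return np.array([r.count for r in self.records], dtype=np.int64)

    def freqs(self) -> np.ndarray:
        return np.array([r.freq for r in self.records], dtype=float)

    def keys(self) -> list[tuple[str, ...]]:
        return [r.key(self.key_mode) for r in self.records]

    def freq_by_key(self) -> dict[tuple[str, ...], float]:
        return {r.key(self.key_mode): r.freq for r in self.records}

    def rekey(self, key_mode: str) -> "Repertoire":
        """Re-aggregate under a different key mode (no-op if unchanged)."""
        if key_mode == self.key_mode:
            return self
        return build_repertoire(self.records, key_mode, sample_id=self.sample_id)


def _validate_mode(mode: str) -> None:
    if mode not in KEY_MODES:
        raise ValidationError(f"unknown key mode {mode!r}; choose from {KEY_MODES}")


def build_repertoire(
    records: Iterable[ClonotypeRecord],
    key_mode: str = "nt+vj",
    sample_id: str = "sample",
) -> Repertoire:
    """Aggregate raw records into a normalized :class:`Repertoire`.

    Records sharing a key under ``key_mode`` are merged (counts summed,
    ``nt_variants`` recomputed as the number of distinct nucleotide
    sequences).  Frequencies are recomputed as ``count / total_reads``.
    Output order is descending count with lexicographic key tie-break.

    Raises
    ------
    EmptyRepertoireError
        If ``records`` is empty.
    ValidationError
        If any record has a negative count (the offending row is named).
    """
    _validate_mode(key_mode)
    records = list(records)
    if not records:
        raise EmptyRepertoireError(f"sample {sample_id!r}: no clonotype records")
    merged: dict[tuple[str, ...], list[ClonotypeRecord]] = {}
    for i, rec in enumerate(records):
        if rec.count < 0:
            raise ValidationError(
                f"sample {sample_id!r}: negative count {rec.count} in record {i}"
            )
        merged.setdefault(rec.key(key_mode), []).append(rec)

    out: list[ClonotypeRecord] = []
    for group in merged.values():
        total = sum(r.count for r in group)
        rep = max(group, key=lambda r: r.count)  # representative fields
        nt_variants = len({r.cdr3_nt for r in group})
        productive = rep.productive
        out.append(
            replace(
                rep,
                count=total,
                nt_variants=nt_variants,
                productive=productive,
            )
        )
    total_reads = int(sum(r.count for r in out))
    for r in out:
        r.freq = r.count / total_reads if total_reads > 0 else 0.0
    out.sort(key=lambda r: (-r.count, r.key(key_mode)))
    return Repertoire(
        sample_id=sample_id, records=out, key_mode=key_mode, total_reads=total_reads
    )


def collapse_to_aa(rep: Repertoire) -> Repertoire:
    """Merge nucleotide-level clonotypes by amino-acid sequence.

    ``nt``-keyed input becomes ``aa``-keyed; ``nt+vj`` becomes ``aa+vj``.
    Counts are summed and each output record's ``nt_variants`` is the number
    of distinct nucleotide sequences merged into it.  Total reads are
    conserved exactly.  An already aa-keyed repertoire is returned unchanged
    with a warning.
    """
    if rep.key_mode.startswith("aa"):
        warnings.warn(
            f"sample {rep.sample_id!r} is already aa-keyed ({rep.key_mode}); no-op",
            stacklevel=2,
        )
        return rep
    new_mode = "aa" if rep.key_mode == "nt" else "aa+vj"
    return build_repertoire(rep.records, new_mode, sample_id=rep.sample_id)


def filter_functional(rep: Repertoire) -> Repertoire:
    """Drop non-productive clonotypes and renormalize.

    A record is non-productive when its amino-acid CDR3 contains ``*`` or
    ``_`` (or is empty), or when an upstream ``productive`` call is False.
    """
    kept = [r for r in rep.records if r.is_productive]
    if not kept:
        raise EmptyRepertoireError(
            f"sample {rep.sample_id!r}: no productive clonotypes remain"
        )
    return build_repertoire(kept, rep.key_mode, sample_id=rep.sample_id)


def downsample(rep: Repertoire, depth: int, seed: int) -> Repertoire:
    """Rarefy to ``depth`` reads without replacement.

    Draws are multivariate hypergeometric over clone read counts, so a
    draw at ``depth == total_reads`` returns the repertoire unchanged.
    Clones drawn to zero are dropped.  Fully reproducible for a fixed seed.
    """
    if depth <= 0:
        raise ValidationError(f"depth must be positive, got {depth}")
    if depth > rep.total_reads:
        raise ValidationError(
            f"sample {rep.sample_id!r}: cannot downsample to depth {depth} "
            f"> total reads {rep.total_reads}"
        )
    rng = np.random.default_rng(seed)
    counts = rep.counts()
    drawn = rng.multivariate_hypergeometric(counts, depth)
    kept = [
        replace(rec, count=int(c))
        for rec, c in zip(rep.records, drawn)
        if c > 0
    ]
    return build_repertoire(kept, rep.key_mode, sample_id=rep.sample_id)
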