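"""Per-sample descriptive statistics.

V/J segment usage, CDR3 length spectratype (optionally stratified by J
segment), the ranked clonotype frequency distribution, and top clones.
All mass distributions support two weightings: ``read`` (fraction of reads)
and ``clonotype`` (fraction of clones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import ClonotypeRecord, EmptyRepertoireError, Repertoire, ValidationError

WEIGHTINGS = ("read", "clonotype")


def _weights(rep: Repertoire, weighting: str) -> list[float]:
    if weighting == "read":
        return [r.count / rep.total_reads for r in rep.records]
    if weighting == "clonotype":
        n = rep.n_clones
        return [1.0 / n for _ in rep.records]
    raise ValidationError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def _require_nonempty(rep: Repertoire, op: str) -> None:
    if not rep.records or rep.total_reads == 0:
        raise EmptyRepertoireError(f"{op}: repertoire {rep.sample_id!r} is empty")


@dataclass(slots=True)
class UsageProfile:
    """Fraction of the repertoire assigned to each V (or J) segment."""

    segment_class: str  # "V" or "J"
    weighting: str
    weights: dict[str, float]  # ordered: descending fraction, label tie-break

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment": list(self.weights), "fraction": list(self.weights.values())}
        )


def segment_usage(
    rep: Repertoire, segment_class: str = "V", weighting: str = "read"
) -> UsageProfile:
    """Gene-segment usage profile.

    ``read`` weighting sums read counts per segment over total reads;
    ``clonotype`` weighting counts clones per segment over the number of
    clones.  Segments are ordered by descending fraction, label tie-break.
    """
    _require_nonempty(rep, "segment_usage")
    if segment_class not in ("V", "J"):
        raise ValidationError(f"segment_class must be 'V' or 'J', got {segment_class!r}")
    attr = "v_gene" if segment_class == "V" else "j_gene"
    acc: dict[str, float] = {}
    for rec, w in zip(rep.records, _weights(rep, weighting)):
        seg = getattr(rec, attr)
        acc[seg] = acc.get(seg, 0.0) + w
    ordered = dict(sorted(acc.items(), key=lambda kv: (-kv[1], kv[0])))
    return UsageProfile(segment_class=segment_class, weighting=weighting, weights=ordered)


@dataclass(slots=True)
class SpectratypeTable:
    """Repertoire mass per CDR3 length, optionally split by J segment.

    ``rows`` maps length -> fraction when unstratified, and
    (length, j_gene) -> fraction when stratified.  Cells always sum to 1.
    """

    unit: str  # "nt" or "aa"
    weighting: str
    stratified: bool
    rows: dict

    @property
    def peak_length(self) -> int:
        """Argmax length of the marginal distribution (smallest on ties)."""
        marginal = self.marginal()
        best = max(marginal.values())
        return min(l for l, v in marginal.items() if v == best)

    def marginal(self) -> dict[int, float]:
        if not self.stratified:
            return dict(self.rows)
        out: dict[int, float] = {}
        for (length, _j), v in self.rows.items():
            out[length] = out.get(length, 0.0) + v
        return out

    def to_frame(self) -> pd.DataFrame:
        if self.stratified:
            return pd.DataFrame(
                [
                    {"length": l, "j_gene": j, "fraction": v}
                    for (l, j), v in sorted(self.rows.items())
                ]
            )
        return pd.DataFrame(
            [{"length": l, "fraction": v} for l, v in sorted(self.rows.items())]
        )


def spectratype(
    rep: Repertoire,
    unit: str = "nt",
    stratify_by_j: bool = False,
    weighting: str = "read",
) -> SpectratypeTable:
    """CDR3 length distribution in the chosen unit (``nt`` or ``aa``)."""
    _require_nonempty(rep, "spectratype")
    if unit not in ("nt", "aa"):
        raise ValidationError(f"unit must be 'nt' or 'aa', got {unit!r}")
    attr = "cdr3_nt" if unit == "nt" else "cdr3_aa"
    rows: dict = {}
    for rec, w in zip(rep.records, _weights(rep, weighting)):
        length = len(getattr(rec, attr))
        key = (length, rec.j_gene) if stratify_by_j else length
        rows[key] = rows.get(key, 0.0) + w
    return SpectratypeTable(
        unit=unit, weighting=weighting, stratified=stratify_by_j, rows=rows
    )


def clonotype_frequency_distribution(rep: Repertoire) -> pd.DataFrame:
    """Clones ranked by descending frequency with the cumulative sum.

    Columns: ``rank`` (1-based), ``freq``, ``cumulative_freq``.  Row order
    follows the repertoire's deterministic order, which sorts by descending
    count.
    """
    _require_nonempty(rep, "clonotype_frequency_distribution")
    freqs = rep.freqs()
    cumulative = freqs.cumsum()
    return pd.DataFrame(
        {
            "rank": range(1, len(freqs) + 1),
            "freq": freqs,
            "cumulative_freq": cumulative,
        }
    )


def d50(rep: Repertoire) -> int:
    """Minimal number of top clones whose cumulative frequency reaches 0.5."""
    _require_nonempty(rep, "d50")
    total = 0.0
    for i, r in enumerate(rep.records, start=1):
        total += r.freq
        if total >= 0.5:
            return i
    return rep.n_clones


def top_clonotypes(rep: Repertoire, n: int) -> list[ClonotypeRecord]:
    """First ``n`` records in deterministic order (fewer if the repertoire
    is smaller, with a warning)."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if n > rep.n_clones:
        import warnings

        warnings.warn(
            f"requested top {n} of {rep.n_clones} clones; returning all",
            stacklevel=2,
        )
    return rep.records[:n]
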